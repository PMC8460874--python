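"""End-to-end drivers tying the simulator to the two detection arms."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .caller import ContextParams, GeneAnnotation, Vicinity, analyze_vicinities, call_insertions, vicinity_count_table
from .calibration import predicted_genes_for_params
from .classifier import AluKmerIndex, build_index
from .io import fetch_sequence
from .simulate import LocusSet, SimConfig, SimulatedReads, generate_locus_set, simulate_reads


def alu_library(locus_set: LocusSet) -> list[str]:
    """Classifier library: the consensus plus every annotated genomic copy."""
    return [locus_set.consensus] + [
        fetch_sequence(locus_set.genome, a.interval) for a in locus_set.repeats
    ]


@dataclass
class InsertionStudy:
    """A simulated non-reference-insertion experiment, analyzed once."""

    locus_set: LocusSet
    sim: SimulatedReads
    classifier: AluKmerIndex
    vicinities: list[Vicinity]
    annotation: GeneAnnotation
    gold_genes: set[str]

    @property
    def vicinity_counts(self) -> pd.DataFrame:
        return vicinity_count_table(self.vicinities)

    def predicted_genes(self, params: ContextParams = ContextParams()) -> set[str]:
        return predicted_genes_for_params(self.vicinity_counts, params)

    def calls(self, params: ContextParams = ContextParams()):
        return call_insertions(self.vicinities, self.annotation, params, self.locus_set.repeats)


def simulate_insertion_study(
    seed: int = 0,
    n_genes: int = 20,
    n_insertions: int = 5,
    **config_overrides,
) -> InsertionStudy:
    """Generate a locus set with planted non-reference insertions, simulate
    reads, and run the alignment-heavy half of the caller once.

    The gold standard is the set of genes carrying a planted insertion; the
    resulting vicinities can be filtered under any parameter tuple.
    """
    config = SimConfig(
        seed=seed, n_genes=n_genes, n_novel_insertions=n_insertions, **config_overrides
    )
    locus_set = generate_locus_set(config)
    sim = simulate_reads(locus_set)
    classifier = build_index(alu_library(locus_set))
    vicinities, annotation = analyze_vicinities(
        sim.records, locus_set.genome, locus_set.annotation, locus_set.consensus, classifier
    )
    gold = {e.gene_id for e in locus_set.truth if e.kind == "novel_insertion"}
    return InsertionStudy(locus_set, sim, classifier, vicinities, annotation, gold)
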