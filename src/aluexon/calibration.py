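"""Simulation-based calibration of the context-filter parameters.

The protocol: excise expressed Alu elements from a reference genome (shifting
all downstream annotation coordinates by the cumulative deleted length), run
the insertion caller on reads carrying those Alu sequences against the
excised genome, and score predicted genes against the gold set of genes that
harbored an excision.  Metrics: Sn = TP/(TP+FN), Pr = TP/(TP+FP),
F = 2*Sn*Pr/(Sn+Pr) (0 when Sn+Pr = 0) and Acc = (Sn+Pr)/2.  The parameter
grid is searched exhaustively; vicinities are aligned once and re-filtered
per tuple.
"""

from __future__ import annotations

import itertools
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import ContextParams, Vicinity, context_filter
from .io import AluAnnotation, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

# the published calibration grid, with the elided ranges read as uniform steps
DEFAULT_GRID: dict[str, tuple] = {
    "min_signals": (1, 2),
    "min_signalnone": tuple(range(1, 11)),
    "min_s2sn": tuple(round(0.1 * i, 1) for i in range(6)),       # 0 .. 0.5
    "min_s2sru": tuple(round(0.5 * i, 1) for i in range(5)),      # 0 .. 2
    "min_s2ru": (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.5),
}


# ---------------------------------------------------------------------------
# Excision
# ---------------------------------------------------------------------------


@dataclass
class ExcisionPlan:
    """Which Alu elements were excised and how coordinates shift."""

    excised_alus: list[AluAnnotation]
    # chrom -> (sorted original start positions of excisions, cumulative deleted length up to and including each)
    shift_index: dict[str, tuple[list[int], list[int]]]
    gold_genes: set[str]

    def shift(self, chrom: str, pos: int) -> int:
        """Map an original coordinate onto the excised genome."""
        starts, cums = self.shift_index.get(chrom, ([], []))
        i = bisect_right(starts, pos)
        return pos - (cums[i - 1] if i else 0)

    def unshift(self, chrom: str, pos: int) -> int:
        """Inverse map: excised-genome coordinate back to the original."""
        starts, cums = self.shift_index.get(chrom, ([], []))
        # binary-search the original position whose shift equals pos
        orig = pos
        for _ in range(len(starts) + 1):
            new = pos + (cums[bisect_right(starts, orig) - 1] if bisect_right(starts, orig) else 0)
            if new == orig:
                return orig
            orig = new
        return orig


def select_alus_for_excision(
    alus: Sequence[AluAnnotation],
    n_draws: int,
    rng: np.random.Generator,
) -> list[AluAnnotation]:
    """Randomly draw Alu elements with replacement, then deduplicate —
    n_draws draws typically leave somewhat fewer unique elements."""
    if not alus:
        return []
    idx = rng.integers(0, len(alus), size=n_draws)
    seen: dict[int, AluAnnotation] = {}
    for i in idx:
        seen.setdefault(int(i), alus[int(i)])
    return sorted(seen.values(), key=lambda a: (a.interval.chrom, a.interval.start))


def excise_alus(
    genome: Mapping[str, str],
    alus_to_remove: Sequence[AluAnnotation],
    transcripts: Sequence[TranscriptModel],
) -> tuple[dict[str, str], list[TranscriptModel], ExcisionPlan]:
    """Delete Alu spans from the genome and lift the annotation.

    Alu elements overlapping an annotated exon are excluded from excision
    (with a warning): the exonic copy is the caller's business, not the
    simulator's.  Gold genes are those whose span contained an excised Alu.
    """
    exon_by_chrom: dict[str, list[GenomicInterval]] = {}
    for tx in transcripts:
        for ex in tx.exons:
            exon_by_chrom.setdefault(ex.chrom, []).append(ex)
    kept: list[AluAnnotation] = []
    for alu in sorted(alus_to_remove, key=lambda a: (a.interval.chrom, a.interval.start)):
        if any(alu.interval.overlaps(ex) for ex in exon_by_chrom.get(alu.interval.chrom, [])):
            logger.warning("Alu %s overlaps an annotated exon; not excised", alu.interval)
            continue
        if kept and kept[-1].interval.overlaps(alu.interval):
            raise ValueError("excision targets overlap each other")
        kept.append(alu)

    new_genome = {}
    shift_index: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, seq in genome.items():
        spans = [a.interval for a in kept if a.interval.chrom == chrom]
        pieces = []
        cursor = 0
        starts, cums = [], []
        cum = 0
        for iv in spans:
            pieces.append(seq[cursor : iv.start - 1])
            cum += iv.length()
            starts.append(iv.start)
            cums.append(cum)
            cursor = iv.end
        pieces.append(seq[cursor:])
        new_genome[chrom] = "".join(pieces)
        shift_index[chrom] = (starts, cums)

    gold = set()
    for tx in transcripts:
        span = tx.span()
        if any(a.interval.chrom == span.chrom and span.overlaps(a.interval) for a in kept):
            gold.add(tx.gene_id)

    plan = ExcisionPlan(kept, shift_index, gold)
    lifted = [
        TranscriptModel(
            tx.transcript_id,
            tx.gene_id,
            tx.strand,
            [
                GenomicInterval(
                    ex.chrom,
                    plan.shift(ex.chrom, ex.start),
                    plan.shift(ex.chrom, ex.end),
                    ex.strand,
                )
                for ex in tx.exons
            ],
        )
        for tx in transcripts
    ]
    return new_genome, lifted, plan


def lift_alus(alus: Iterable[AluAnnotation], plan: ExcisionPlan) -> list[AluAnnotation]:
    """Shift surviving (non-excised) repeat annotations onto the excised genome."""
    excised = {(a.interval.chrom, a.interval.start, a.interval.end) for a in plan.excised_alus}
    out = []
    for alu in alus:
        iv = alu.interval
        if (iv.chrom, iv.start, iv.end) in excised:
            continue
        out.append(
            AluAnnotation(
                GenomicInterval(iv.chrom, plan.shift(iv.chrom, iv.start), plan.shift(iv.chrom, iv.end), iv.strand),
                alu.subfamily,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class CalibrationPoint:
    params: ContextParams
    tp: int
    fp: int
    gold_size: int
    sn: float = field(init=False)
    pr: float = field(init=False)
    f_value: float = field(init=False)
    acc: float = field(init=False)

    def __post_init__(self) -> None:
        self.sn = self.tp / self.gold_size if self.gold_size else 0.0
        reported = self.tp + self.fp
        self.pr = self.tp / reported if reported else 0.0
        self.f_value = (
            2 * self.sn * self.pr / (self.sn + self.pr) if (self.sn + self.pr) > 0 else 0.0
        )
        self.acc = (self.sn + self.pr) / 2


def evaluate(
    predicted_genes: set[str], gold_genes: set[str], params: ContextParams = ContextParams()
) -> CalibrationPoint:
    """Sn/Pr/F/Acc of a predicted gene set against the gold genes."""
    if not gold_genes:
        raise ValueError("empty gold standard")
    tp = len(predicted_genes & gold_genes)
    fp = len(predicted_genes - gold_genes)
    return CalibrationPoint(params=params, tp=tp, fp=fp, gold_size=len(gold_genes))


def predicted_genes_for_params(
    vicinity_counts: pd.DataFrame, params: ContextParams
) -> set[str]:
    """Genes with at least one vicinity passing the context filter."""
    out = set()
    for row in vicinity_counts.itertuples(index=False):
        if context_filter(row.s, row.sn, row.ru, row.sru, params):
            out.add(row.gene_id)
    return out


def grid_search(
    vicinity_counts: pd.DataFrame,
    gold_genes: set[str],
    grid: Mapping[str, Sequence] = DEFAULT_GRID,
) -> list[CalibrationPoint]:
    """One CalibrationPoint per parameter tuple, ranked by F-value (ties by
    precision, then sensitivity).  The count table is computed once; only the
    filter is re-applied per tuple."""
    names = ("min_signals", "min_signalnone", "min_s2sn", "min_s2sru", "min_s2ru")
    values = [grid[n] for n in names]
    if any(len(v) == 0 for v in values):
        raise ValueError("empty parameter grid")
    points = []
    for combo in itertools.product(*values):
        params = ContextParams(**dict(zip(names, combo)))
        predicted = predicted_genes_for_params(vicinity_counts, params)
        points.append(evaluate(predicted, gold_genes, params))
    points.sort(key=lambda p: (-p.f_value, -p.pr, -p.sn, p.params.as_tuple()))
    return points


def calibration_table(points: Sequence[CalibrationPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "min_signals": [p.params.min_signals for p in points],
            "min_signalnone": [p.params.min_signalnone for p in points],
            "min_s2sn": [p.params.min_s2sn for p in points],
            "min_s2sru": [p.params.min_s2sru for p in points],
            "min_s2ru": [p.params.min_s2ru for p in points],
            "tp": [p.tp for p in points],
            "fp": [p.fp for p in points],
            "sn": [p.sn for p in points],
            "pr": [p.pr for p in points],
            "f_value": [p.f_value for p in points],
            "acc": [p.acc for p in points],
        }
    )
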