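"""Seedable synthetic data: toy genomes with intronic Alu copies, transcripts
with exonized Alu exons, planted non-reference Alu insertions, and paired-end
reads emitted directly as alignment records with per-read truth labels.

The generator plays the role of the mapper: it knows every fragment's true
origin, so it writes the alignment a mapper would produce.  A mate whose
sequence overlaps a planted non-reference insert is emitted unmapped (its
sequence does not exist in the genome); a pre-mRNA mate falling inside an
intronic Alu copy is emitted unmapped and the pair non-concordant, mimicking
a multi-mapping discard — these are the shadow reads.  Everything else maps
with spliced CIGARs.  Mapping noise is modelled only as an optional
probability of mis-set concordance flags.

Defaults describe a small but realistic short-read experiment: 100 bp pairs,
~300 +/- 30 bp fragments, 30x coverage, 0.5% base error, 10% pre-mRNA
fraction, intronic Alu copies at 10% divergence from the consensus (aged,
AluS-like) and planted novel inserts at 2% divergence (young, AluY-like).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import packaged_alu_consensus, reverse_complement
from .io import (
    AluAnnotation,
    GenomicInterval,
    ReadAlignmentRecord,
    TranscriptModel,
    write_fasta,
    write_gtf,
    write_repeats_bed,
    write_sam,
)
from .tissue import TissueCountMatrix

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Knobs of the synthetic study; the seed fully determines the output."""

    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_length: tuple[int, int] = (120, 260)
    intron_length: tuple[int, int] = (800, 1400)
    intergenic_length: tuple[int, int] = (300, 600)
    n_intronic_alus: int = 1
    alu_divergence: float = 0.10
    n_fixed_exonizations: int = 0
    n_novel_insertions: int = 0
    novel_alu_divergence: float = 0.02
    planted_exon_length: tuple[int, int] = (100, 200)
    read_length: int = 100
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    coverage: float = 30.0
    error_rate: float = 0.005
    fraction_premrna: float = 0.1
    guaranteed_signal_pairs: int = 5
    concordance_noise: float = 0.0
    shadow_min_alu_overlap: int = 25  # bases of Alu copy turning a pre-mRNA mate into a multimapper
    alu_intron_offset: int = 120  # Alu copy distance from the intron's 5' end
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        for rate in (self.alu_divergence, self.novel_alu_divergence, self.error_rate,
                     self.fraction_premrna, self.concordance_noise):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate out of [0,1]: {rate}")
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length,
                       self.intergenic_length, self.planted_exon_length):
            if lo < 1 or hi < lo:
                raise ValueError(f"bad range ({lo}, {hi})")
        if self.read_length < 1 or self.coverage < 0:
            raise ValueError("read_length must be positive and coverage non-negative")
        if self.n_fixed_exonizations + self.n_novel_insertions > self.n_genes:
            raise ValueError("more planted events than genes")
        if self.exons_per_gene[0] < 4 and (self.n_fixed_exonizations or self.n_novel_insertions):
            raise ValueError("planted events need genes with at least 4 exons")


@dataclass
class Isoform:
    """A transcript as ordered parts: genomic exons and/or novel inserts."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    parts: list[tuple[str, object]]  # ("genome", GenomicInterval) | ("insert", str)

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        chunks = []
        for kind, payload in self.parts:
            if kind == "genome":
                iv = payload
                chunks.append(genome[iv.chrom][iv.start - 1 : iv.end])
            else:
                chunks.append(payload)
        return "".join(chunks)

    def has_insert(self) -> bool:
        return any(kind == "insert" for kind, _ in self.parts)

    def to_transcript_model(self) -> TranscriptModel:
        if self.has_insert():
            raise ValueError("isoform with a non-reference insert has no genomic model")
        return TranscriptModel(
            self.transcript_id, self.gene_id, self.strand,
            [payload for _, payload in self.parts],
        )


@dataclass
class PlantedEvent:
    kind: str  # "fixed_exon" | "novel_insertion"
    gene_id: str
    exon: GenomicInterval | None  # genomic coordinates for fixed events
    insert_after_exon_index: int
    sequence: str  # exon sequence in genome plus-strand orientation


@dataclass
class LocusSet:
    config: SimConfig
    consensus: str
    genome: dict[str, str]
    annotation: list[TranscriptModel]  # reference isoforms (the annotation-database analog)
    isoforms: dict[str, list[Isoform]]  # gene -> all isoforms incl. planted ones
    repeats: list[AluAnnotation]
    gene_spans: dict[str, GenomicInterval]
    truth: list[PlantedEvent] = field(default_factory=list)

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [e.kind for e in self.truth],
                "gene_id": [e.gene_id for e in self.truth],
                "chrom": [e.exon.chrom if e.exon else "." for e in self.truth],
                "start": [e.exon.start if e.exon else -1 for e in self.truth],
                "end": [e.exon.end if e.exon else -1 for e in self.truth],
                "after_exon": [e.insert_after_exon_index for e in self.truth],
            }
        )

    def assembled_transcripts(self) -> list[TranscriptModel]:
        """Every isoform representable on the genome (the assembler analog)."""
        return [
            iso.to_transcript_model()
            for isos in self.isoforms.values()
            for iso in isos
            if not iso.has_insert()
        ]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


_SUBFAMILIES = ("AluJb", "AluSx", "AluY")


def generate_locus_set(config: SimConfig, consensus: str | None = None) -> LocusSet:
    """Build the toy genome, annotation, repeat track and isoform catalogue.

    Genes are laid head to tail on one chromosome.  Each gene receives
    ``n_intronic_alus`` antisense Alu copies (mutated from the consensus at
    ``alu_divergence``) centered in distinct introns.  The first
    ``n_fixed_exonizations`` genes gain an extra isoform exonizing part of an
    intronic copy; the next ``n_novel_insertions`` genes gain an isoform with
    an Alu-derived exon that is absent from the genome.  Infeasible length
    constraints raise before anything is produced.
    """
    rng = np.random.default_rng(config.seed)
    consensus = (consensus or packaged_alu_consensus()).upper()
    alu_len = len(consensus)
    if config.intron_length[0] < alu_len + 120:
        raise ValueError("introns too short to host an Alu copy with flanking margins")
    if config.planted_exon_length[1] > alu_len:
        raise ValueError("planted exon length exceeds the Alu consensus length")

    chrom = config.chrom
    genome_parts: list[str] = []
    cursor = 1  # next genomic coordinate (1-based)
    annotation: list[TranscriptModel] = []
    isoforms: dict[str, list[Isoform]] = {}
    repeats: list[AluAnnotation] = []
    gene_spans: dict[str, GenomicInterval] = {}
    truth: list[PlantedEvent] = []

    for g in range(config.n_genes):
        gene_id = f"gene{g:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_ex)
        intron_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1, size=n_ex - 1)
        spacer = int(rng.integers(config.intergenic_length[0], config.intergenic_length[1] + 1))
        genome_parts.append(_random_seq(rng, spacer))
        cursor += spacer

        exons: list[GenomicInterval] = []
        intron_ivs: list[GenomicInterval] = []
        for i in range(n_ex):
            ex_len = int(exon_lens[i])
            exons.append(GenomicInterval(chrom, cursor, cursor + ex_len - 1, strand))
            genome_parts.append(_random_seq(rng, ex_len))
            cursor += ex_len
            if i < n_ex - 1:
                in_len = int(intron_lens[i])
                intron_ivs.append(GenomicInterval(chrom, cursor, cursor + in_len - 1))
                genome_parts.append(_random_seq(rng, in_len))
                cursor += in_len

        # plant antisense Alu copies centered in distinct introns
        alu_strand = "-" if strand == "+" else "+"
        gene_alus: list[AluAnnotation] = []
        intron_order = list(rng.permutation(len(intron_ivs)))
        for a in range(min(config.n_intronic_alus, len(intron_ivs))):
            intron = intron_ivs[intron_order[a]]
            # near the intron's 5' end: close enough to the exon for pre-mRNA
            # fragments to anchor, and inside the unspliced shadow window
            offset = min(config.alu_intron_offset, (intron.length() - alu_len) // 2)
            start = intron.start + offset
            alu_iv = GenomicInterval(chrom, start, start + alu_len - 1, alu_strand)
            copy = _mutate(consensus, config.alu_divergence, rng)
            plus_seq = copy if alu_strand == "+" else reverse_complement(copy)
            # splice the copy into the already-emitted genome sequence
            _overwrite(genome_parts, cursor, alu_iv, plus_seq)
            subfamily = _SUBFAMILIES[a % len(_SUBFAMILIES)]
            alu = AluAnnotation(alu_iv, subfamily)
            repeats.append(alu)
            gene_alus.append(alu)

        gene_spans[gene_id] = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
        ref = Isoform(
            f"{gene_id}.ref", gene_id, chrom, strand,
            [("genome", ex) for ex in exons],
        )
        isoforms[gene_id] = [ref]
        annotation.append(ref.to_transcript_model())

        planted_len = int(rng.integers(config.planted_exon_length[0], config.planted_exon_length[1] + 1))
        mid = max(2, min(n_ex - 2, n_ex // 2))  # insert after this many exons
        if g < config.n_fixed_exonizations and gene_alus:
            # exonize a sub-interval of an intronic copy that sits between two exons
            alu = gene_alus[0]
            after = next(
                i for i, intron in enumerate(intron_ivs) if intron.contains(alu.interval)
            )
            ex_start = alu.interval.start + (alu.interval.length() - planted_len) // 2
            alu_exon = GenomicInterval(chrom, ex_start, ex_start + planted_len - 1, strand)
            parts = [("genome", ex) for ex in exons[: after + 1]]
            parts.append(("genome", alu_exon))
            parts += [("genome", ex) for ex in exons[after + 1 :]]
            iso = Isoform(f"{gene_id}.aluexon", gene_id, chrom, strand, parts)
            isoforms[gene_id].append(iso)
            truth.append(PlantedEvent("fixed_exon", gene_id, alu_exon, after,
                                      genome_parts_seq(genome_parts, cursor, alu_exon)))
        elif config.n_fixed_exonizations <= g < config.n_fixed_exonizations + config.n_novel_insertions:
            # a young Alu-derived exon present in the transcript, absent from the genome
            src = _mutate(consensus, config.novel_alu_divergence, rng)
            off = int(rng.integers(0, alu_len - planted_len + 1))
            insert_seq = reverse_complement(src[off : off + planted_len])
            parts = [("genome", ex) for ex in exons[:mid]]
            parts.append(("insert", insert_seq))
            parts += [("genome", ex) for ex in exons[mid:]]
            iso = Isoform(f"{gene_id}.novel", gene_id, chrom, strand, parts)
            isoforms[gene_id].append(iso)
            truth.append(PlantedEvent("novel_insertion", gene_id, None, mid - 1, insert_seq))

    genome = {chrom: "".join(genome_parts)}
    assert len(genome[chrom]) == cursor - 1
    return LocusSet(
        config=config,
        consensus=consensus,
        genome=genome,
        annotation=annotation,
        isoforms=isoforms,
        repeats=repeats,
        gene_spans=gene_spans,
        truth=truth,
    )


def _overwrite(parts: list[str], cursor: int, iv: GenomicInterval, seq: str) -> None:
    """Replace genome bases of ``iv`` inside the emitted parts list."""
    # walk parts from the end to locate the span (it lies in the last intron emitted)
    end = cursor - 1
    for idx in range(len(parts) - 1, -1, -1):
        start = end - len(parts[idx]) + 1
        if start <= iv.start and iv.end <= end:
            local = iv.start - start
            parts[idx] = parts[idx][:local] + seq + parts[idx][local + len(seq) :]
            return
        end = start - 1
    raise AssertionError(f"interval {iv} not contained in any emitted part")


def genome_parts_seq(parts: list[str], cursor: int, iv: GenomicInterval) -> str:
    """Sequence of ``iv`` from the partial genome under construction."""
    joined = "".join(parts)
    assert len(joined) == cursor - 1
    return joined[iv.start - 1 : iv.end]


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _part_layout(iso: Isoform) -> list[tuple[int, int, str, object]]:
    """(tx_start, tx_end_exclusive, kind, payload) per part, transcript coords."""
    layout = []
    off = 0
    for kind, payload in iso.parts:
        ln = payload.length() if kind == "genome" else len(payload)
        layout.append((off, off + ln, kind, payload))
        off += ln
    return layout


def _map_segment(layout, tx_start: int, length: int):
    """Genome blocks covered by a transcript segment, plus inserted-base count."""
    blocks: list[tuple[int, int]] = []  # (genomic start 1-based, length)
    insert_bases = 0
    tx_end = tx_start + length
    for p_start, p_end, kind, payload in layout:
        lo = max(tx_start, p_start)
        hi = min(tx_end, p_end)
        if lo >= hi:
            continue
        if kind == "insert":
            insert_bases += hi - lo
        else:
            blocks.append((payload.start + (lo - p_start), hi - lo))
    return blocks, insert_bases


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> str:
    ops = []
    for i, (start, ln) in enumerate(blocks):
        if i:
            gap = start - (blocks[i - 1][0] + blocks[i - 1][1])
            if gap > 0:
                ops.append(f"{gap}N")
        ops.append(f"{ln}M")
    # merge adjacent M (zero-gap blocks)
    merged: list[str] = []
    for op in ops:
        if merged and op.endswith("M") and merged[-1].endswith("M"):
            merged[-1] = f"{int(merged[-1][:-1]) + int(op[:-1])}M"
        else:
            merged.append(op)
    return "".join(merged)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    return _mutate(seq, rate, rng)


@dataclass
class SimulatedReads:
    records: list[ReadAlignmentRecord]
    truth: pd.DataFrame  # read_id, gene_id, label


def simulate_reads(locus_set: LocusSet, config: SimConfig | None = None,
                   seed_offset: int = 1) -> SimulatedReads:
    """Paired-end fragments from every isoform plus a pre-mRNA share.

    Labels: ``normal`` (both mates mapped), ``signal`` (one mate overlaps a
    planted insert and is emitted unmapped), ``shadow`` (pre-mRNA mate inside
    an intronic Alu copy, emitted unmapped), ``premrna`` (pre-mRNA pair fully
    mappable), ``dropped`` (both mates unmappable).
    """
    config = config or locus_set.config
    rng = np.random.default_rng(config.seed + seed_offset)
    rl = config.read_length
    chrom = config.chrom
    records: list[ReadAlignmentRecord] = []
    truth_rows: list[tuple[str, str, str, int]] = []

    def emit_pair(read_id: str, gene_id: str, iso: Isoform | None, layout, spliced: str,
                  frag_start: int, frag_len: int, premrna_alus: list[GenomicInterval] | None):
        label = "premrna" if premrna_alus is not None else "normal"
        mates = []
        unmapped_insert_bases = 0
        for mate_index in (1, 2):
            if mate_index == 1:
                tx_start, rev = frag_start, False
            else:
                tx_start, rev = frag_start + frag_len - rl, True
            raw = spliced[tx_start : tx_start + rl]
            seq = reverse_complement(raw) if rev else raw
            seq = _apply_errors(seq, config.error_rate, rng)
            blocks, insert_bases = _map_segment(layout, tx_start, rl)
            mapped = insert_bases == 0
            if not mapped:
                unmapped_insert_bases = max(unmapped_insert_bases, insert_bases)
            if mapped and premrna_alus is not None:
                # multi-mapping discard of pre-mRNA reads inside an Alu copy
                read_iv = GenomicInterval(chrom, blocks[0][0], blocks[-1][0] + blocks[-1][1] - 1)
                overlap = max((read_iv.overlap_length(a) for a in premrna_alus), default=0)
                if overlap >= config.shadow_min_alu_overlap:
                    mapped = False
            if mapped:
                iv = GenomicInterval(chrom, blocks[0][0],
                                     blocks[-1][0] + blocks[-1][1] - 1,
                                     "-" if rev else "+")
                mates.append((mate_index, True, iv, _blocks_to_cigar(blocks), seq))
            else:
                mates.append((mate_index, False, None, None, seq))
        n_mapped = sum(1 for m in mates if m[1])
        if n_mapped == 0:
            label = "dropped"
        elif n_mapped == 1:
            label = "shadow" if premrna_alus is not None else "signal"
        concordant = n_mapped == 2
        if config.concordance_noise and rng.random() < config.concordance_noise:
            concordant = not concordant
        for mate_index, mapped, iv, cigar, seq in mates:
            records.append(ReadAlignmentRecord(read_id, mate_index, mapped, iv, cigar, seq, concordant))
        truth_rows.append((read_id, gene_id, label, unmapped_insert_bases))

    def draw_fragment(total_len: int):
        frag = int(np.clip(rng.normal(config.fragment_mean, config.fragment_sd),
                           rl + 10, max(rl + 10, total_len)))
        start = int(rng.integers(0, max(1, total_len - frag + 1)))
        return start, frag

    for gene_id, isos in sorted(locus_set.isoforms.items()):
        span = locus_set.gene_spans[gene_id]
        gene_alus = [a.interval for a in locus_set.repeats if span.overlaps(a.interval)]
        pre_layout = [(0, span.length(), "genome", span)]
        pre_seq = locus_set.genome[chrom][span.start - 1 : span.end]
        for iso in isos:
            layout = _part_layout(iso)
            spliced = iso.spliced_sequence(locus_set.genome)
            total = len(spliced)
            if total < rl + 10:
                continue
            n_frags = int(round(config.coverage * total / (2 * rl)))
            for fi in range(n_frags):
                read_id = f"{iso.transcript_id}:{fi}"
                if iso is isos[0] and rng.random() < config.fraction_premrna:
                    start, frag = draw_fragment(span.length())
                    emit_pair(read_id, gene_id, None, pre_layout, pre_seq, start, frag, gene_alus)
                else:
                    start, frag = draw_fragment(total)
                    emit_pair(read_id, gene_id, iso, layout, spliced, start, frag, None)
            # guaranteed chimeric signal pairs across the insert's 5' junction
            if iso.has_insert():
                ins_start = next(s for s, _e, kind, _p in layout if kind == "insert")
                frag = int(config.fragment_mean)
                for gi in range(config.guaranteed_signal_pairs):
                    alu_part = 55 + (gi * 5) % 21  # 55..75 Alu bases in the chimeric mate
                    tx_end = ins_start + alu_part  # fragment/mate2 end
                    start = tx_end - frag
                    if start < 0:
                        start, frag_i = 0, tx_end
                    else:
                        frag_i = frag
                    emit_pair(f"{iso.transcript_id}:sig{gi}", gene_id, iso, layout,
                              spliced, start, frag_i, None)

    truth = pd.DataFrame(truth_rows, columns=["read_id", "gene_id", "label", "insert_bases"])
    return SimulatedReads(records=records, truth=truth)


# ---------------------------------------------------------------------------
# Cohort helpers
# ---------------------------------------------------------------------------


def per_sample_transcripts(
    locus_set: LocusSet,
    n_samples: int,
    include_prob: float = 1.0,
    seed_offset: int = 2,
) -> dict[str, list[TranscriptModel]]:
    """Per-sample assembled-transcript sets: the reference isoform always,
    each genome-representable alternative isoform with ``include_prob``."""
    rng = np.random.default_rng(locus_set.config.seed + seed_offset)
    out: dict[str, list[TranscriptModel]] = {}
    for s in range(n_samples):
        sample = f"sample{s:02d}"
        txs: list[TranscriptModel] = []
        for gene_id, isos in sorted(locus_set.isoforms.items()):
            for i, iso in enumerate(isos):
                if iso.has_insert():
                    continue
                if i == 0 or rng.random() < include_prob:
                    txs.append(iso.to_transcript_model())
        out[sample] = txs
    return out


def simulate_intron_tissue_matrix(
    n_background: int = 40,
    n_specific: int = 5,
    target_tissue: str = "brain",
    other_tissues: Sequence[str] = ("liver", "heart", "lung"),
    samples_per_tissue: int = 200,
    seed: int = 0,
) -> TissueCountMatrix:
    """An intron x sample count matrix with planted single-tissue introns.

    Background introns are expressed everywhere (Poisson mean 30); planted
    introns are expressed in ~80% of the target tissue's samples and absent
    elsewhere.  Per-tissue sample counts default to a repository-scale 200:
    the absence statistic grows linearly with tissue sample counts (a fully
    absent tissue contributes (0.15 N)^2 / (0.85 N) ~ 0.0265 N), so cohorts
    of only tens of samples per tissue cannot reach p <= 0.001 by design.
    """
    rng = np.random.default_rng(seed)
    tissues = [target_tissue, *other_tissues]
    samples, sample_tissue = [], {}
    for t in tissues:
        for i in range(samples_per_tissue):
            name = f"{t}_{i:02d}"
            samples.append(name)
            sample_tissue[name] = t
    rows, index = [], []
    for i in range(n_background):
        rows.append(rng.poisson(30, size=len(samples)))
        index.append(f"intron_bg{i:03d}")
    for i in range(n_specific):
        counts = np.zeros(len(samples), dtype=int)
        for j, s in enumerate(samples):
            if sample_tissue[s] == target_tissue and rng.random() < 0.8:
                counts[j] = rng.poisson(50) + 10
        rows.append(counts)
        index.append(f"intron_ts{i:03d}")
    counts = pd.DataFrame(np.vstack(rows), index=index, columns=samples)
    return TissueCountMatrix(counts, sample_tissue)


def write_locus_set(locus_set: LocusSet, outdir: str) -> None:
    """FASTA/GTF/BED/TSV snapshot of a generated locus set."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_fasta(locus_set.genome, os.path.join(outdir, "genome.fa"))
    write_gtf(locus_set.annotation, os.path.join(outdir, "annotation.gtf"))
    write_gtf(locus_set.assembled_transcripts(), os.path.join(outdir, "transcripts.gtf"))
    write_repeats_bed(locus_set.repeats, os.path.join(outdir, "repeats.bed"))
    locus_set.truth_table().to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)


def write_reads(sim: SimulatedReads, locus_set: LocusSet, outdir: str) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    references = {chrom: len(seq) for chrom, seq in locus_set.genome.items()}
    write_sam(sim.records, os.path.join(outdir, "reads.sam"), references)
    sim.truth.to_csv(os.path.join(outdir, "read_truth.tsv"), sep="\t", index=False)
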