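"""Non-reference Alu insertion calling from anchored non-concordant pairs.

Pipeline: (1) keep non-concordant pairs with exactly one mapped mate whose
unmapped mate classifies as an Alu read; (2) anchor the mapped mate to
annotated exons; (3) test each Alu mate as *signal* (spliced alignment
against anchor exon + Alu consensus + adjacent exon explains >=80% of the
read at >80% identity with >=10 Alu bases) and as *shadow* (near-exact local
match, >=80% coverage at >=93% identity, to the 500 bp introns flanking the
anchor exon or to the anchor-exon..farthest-neighbor region); (4) cluster
anchors into vicinities, apply the five-condition context filter to the
S/SN/RU/SRU read counts, and infer an insertion interval per signal cluster.

Category partition per mate: S = signal and not shadow; SRU = signal and
shadow; RU = shadow only; none = neither.  SN jointly counts S and none.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .align import ALU_LABEL, AlignmentResult, Scoring, DEFAULT_SCORING, local_align, spliced_align
from .classifier import AluKmerIndex, reverse_complement
from .io import (
    AluAnnotation,
    GenomicInterval,
    ReadAlignmentRecord,
    TranscriptModel,
    fetch_sequence,
)

logger = logging.getLogger(__name__)

SIGNAL_MIN_COVERAGE = 0.80
SIGNAL_MIN_IDENTITY = 0.80  # strict: identity must exceed this
SIGNAL_MIN_ALU_BASES = 10
SHADOW_MIN_COVERAGE = 0.80
SHADOW_MIN_IDENTITY = 0.93  # inclusive
UNSPLICED_WINDOW = 500


@dataclass(frozen=True)
class ContextParams:
    """Cutoffs of the five-condition vicinity filter (calibrated defaults)."""

    min_signals: int = 2
    min_signalnone: int = 5
    min_s2sn: float = 0.0
    min_s2sru: float = 2.0
    min_s2ru: float = 0.5

    def as_tuple(self) -> tuple:
        return (self.min_signals, self.min_signalnone, self.min_s2sn, self.min_s2sru, self.min_s2ru)


def _ratio(num: float, den: float) -> float:
    """s/x ratios with an empty denominator counting as +inf (condition met)."""
    return math.inf if den == 0 else num / den


def context_filter(s: int, sn: int, ru: int, sru: int, params: ContextParams) -> bool:
    """True iff all five conditions hold at the given cutoffs."""
    return (
        s >= params.min_signals
        and sn >= params.min_signalnone
        and _ratio(s, sn) >= params.min_s2sn
        and _ratio(s, sru) >= params.min_s2sru
        and _ratio(s, ru) >= params.min_s2ru
    )


def signal_test(result: AlignmentResult) -> bool:
    """Signal: alignment explains >=80% of the read, identity strictly >80%,
    and covers >=10 Alu bases."""
    return (
        result.query_coverage >= SIGNAL_MIN_COVERAGE
        and result.identity > SIGNAL_MIN_IDENTITY
        and result.alu_bases >= SIGNAL_MIN_ALU_BASES
    )


def _passes_shadow(result: AlignmentResult) -> bool:
    return result.query_coverage >= SHADOW_MIN_COVERAGE and result.identity >= SHADOW_MIN_IDENTITY


def categorize_mate(signal: bool, shadow: bool) -> str:
    """Total category map over the two test outcomes."""
    if signal and not shadow:
        return "S"
    if signal and shadow:
        return "SRU"
    if shadow:
        return "RU"
    return "none"


# ---------------------------------------------------------------------------
# Annotation index
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]  # merged, sorted, non-overlapping

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)


class GeneAnnotation:
    """Per-gene merged exons plus an interval index for anchoring."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        raw: dict[str, list[GenomicInterval]] = {}
        strands: dict[str, str] = {}
        for tx in transcripts:
            raw.setdefault(tx.gene_id, []).extend(tx.exons)
            strands.setdefault(tx.gene_id, tx.strand)
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for gene_id, exons in raw.items():
            merged: list[GenomicInterval] = []
            for ex in sorted(exons, key=lambda e: e.start):
                if merged and ex.start <= merged[-1].end + 1:
                    last = merged[-1]
                    merged[-1] = GenomicInterval(ex.chrom, last.start, max(last.end, ex.end))
                else:
                    merged.append(GenomicInterval(ex.chrom, ex.start, ex.end))
            gm = GeneModel(gene_id, merged[0].chrom, strands[gene_id], merged)
            self.genes[gene_id] = gm
            tree = self._trees.setdefault(gm.chrom, IntervalTree())
            for ex in merged:
                tree.addi(ex.start, ex.end + 1, (gene_id, ex))

    def overlapping_exons(self, iv: GenomicInterval) -> list[tuple[str, GenomicInterval]]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return sorted((hit.data for hit in tree.overlap(iv.start, iv.end + 1)))

    def neighbors(self, gene_id: str, exon: GenomicInterval):
        """(previous exon, next exon) of a merged exon within its gene."""
        exons = self.genes[gene_id].exons
        idx = exons.index(exon)
        prev_ex = exons[idx - 1] if idx > 0 else None
        next_ex = exons[idx + 1] if idx < len(exons) - 1 else None
        return prev_ex, next_ex


# ---------------------------------------------------------------------------
# Candidate collection
# ---------------------------------------------------------------------------


def pair_records(records: Iterable[ReadAlignmentRecord]) -> Iterator[tuple[ReadAlignmentRecord, ReadAlignmentRecord]]:
    by_read: dict[str, dict[int, ReadAlignmentRecord]] = {}
    for rec in records:
        mates = by_read.setdefault(rec.read_id, {})
        mates[rec.mate_index] = rec
        if len(mates) == 2:
            yield mates[1], mates[2]
            del by_read[rec.read_id]


def collect_candidate_pairs(
    records: Iterable[ReadAlignmentRecord],
    classifier: AluKmerIndex,
) -> list[tuple[ReadAlignmentRecord, ReadAlignmentRecord]]:
    """(anchor, float) pairs: non-concordant, exactly one mate mapped, and the
    unmapped mate classified as an Alu read."""
    out = []
    for m1, m2 in pair_records(records):
        if m1.is_concordant_pair or m2.is_concordant_pair:
            continue
        if m1.mapped == m2.mapped:
            continue
        anchor, floater = (m1, m2) if m1.mapped else (m2, m1)
        if not floater.sequence:
            continue
        if classifier.classify_read(floater.sequence):
            out.append((anchor, floater))
    return out


@dataclass
class MateRecord:
    """An anchored candidate pair with its test verdicts."""

    anchor: ReadAlignmentRecord
    mate_sequence: str
    anchor_exon: GenomicInterval
    gene_id: str
    orientation: str  # anchor alignment strand
    multi_exon: bool = False
    signal: bool = False
    shadow: bool = False
    category: str = "none"
    signal_result: AlignmentResult | None = None


def anchor_to_exons(
    pairs: Sequence[tuple[ReadAlignmentRecord, ReadAlignmentRecord]],
    annotation: GeneAnnotation,
) -> list[MateRecord]:
    """Assign anchors to overlapping annotated exons; intronic anchors drop.

    An anchor overlapping several exons joins each group, flagged multi.
    """
    out = []
    for anchor, floater in pairs:
        assert anchor.interval is not None
        hits = annotation.overlapping_exons(anchor.interval)
        for gene_id, exon in hits:
            out.append(
                MateRecord(
                    anchor=anchor,
                    mate_sequence=floater.sequence,
                    anchor_exon=exon,
                    gene_id=gene_id,
                    orientation=anchor.interval.strand,
                    multi_exon=len(hits) > 1,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Signal / shadow evaluation
# ---------------------------------------------------------------------------


def signal_align(
    query: str,
    anchor_exon_seq: str,
    consensus: str,
    prev_exon_seq: str | None,
    next_exon_seq: str | None,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[bool, AlignmentResult]:
    """Spliced alignment against exon / Alu-consensus / adjacent-exon
    concatenations.

    Both read orientations, both consensus orientations and both flank
    concatenations (anchor->Alu->next, prev->Alu->anchor) are tried; a mate
    is a signal when any configuration passes the test.  The reported result
    is the passing configuration of highest score, else the overall best.
    """
    configs = []
    for alu in (consensus, reverse_complement(consensus)):
        configs.append([("exon1", anchor_exon_seq), (ALU_LABEL, alu), ("exon2", next_exon_seq or "")])
        configs.append([("exon1", prev_exon_seq or ""), (ALU_LABEL, alu), ("exon2", anchor_exon_seq)])
    best: AlignmentResult | None = None
    best_pass: AlignmentResult | None = None
    for q in (query, reverse_complement(query)):
        for segments in configs:
            res = spliced_align(q, segments, scoring)
            if best is None or res.score > best.score:
                best = res
            if signal_test(res) and (best_pass is None or res.score > best_pass.score):
                best_pass = res
    assert best is not None
    return best_pass is not None, (best_pass or best)


def shadow_test(
    query: str,
    anchor_exon: GenomicInterval,
    gene: GeneModel,
    annotation: GeneAnnotation,
    genome: Mapping[str, str],
    scoring: Scoring = DEFAULT_SCORING,
) -> bool:
    """Shadow: near-exact local genomic match explaining the read.

    First the *unspliced* test against the 500 bp windows flanking the anchor
    exon on both sides, then the *region* test against the span from the
    anchor exon to the farther of its two neighboring exons.  Windows at a
    contig edge are truncated.  Both read orientations are tried.
    """
    chrom_len = len(genome[anchor_exon.chrom])
    targets: list[str] = []
    left_start = max(1, anchor_exon.start - UNSPLICED_WINDOW)
    if left_start < anchor_exon.start:
        targets.append(
            fetch_sequence(genome, GenomicInterval(anchor_exon.chrom, left_start, anchor_exon.start - 1))
        )
    right_end = min(chrom_len, anchor_exon.end + UNSPLICED_WINDOW)
    if right_end > anchor_exon.end:
        targets.append(
            fetch_sequence(genome, GenomicInterval(anchor_exon.chrom, anchor_exon.end + 1, right_end))
        )
    prev_ex, next_ex = annotation.neighbors(gene.gene_id, anchor_exon)
    far = None
    if prev_ex is not None and next_ex is not None:
        far = prev_ex if (anchor_exon.start - prev_ex.end) >= (next_ex.start - anchor_exon.end) else next_ex
    else:
        far = prev_ex or next_ex
    if far is not None:
        region = GenomicInterval(
            anchor_exon.chrom,
            min(anchor_exon.start, far.start),
            max(anchor_exon.end, far.end),
        )
        targets.append(fetch_sequence(genome, region))
    queries = (query, reverse_complement(query))
    for target in targets:
        if not target:
            continue
        for q in queries:
            if _passes_shadow(local_align(q, target, scoring)):
                return True
    return False


def evaluate_mates(
    mates: Sequence[MateRecord],
    annotation: GeneAnnotation,
    genome: Mapping[str, str],
    consensus: str,
    scoring: Scoring = DEFAULT_SCORING,
) -> None:
    """Run signal and shadow tests in place and assign categories."""
    for m in mates:
        gene = annotation.genes[m.gene_id]
        prev_ex, next_ex = annotation.neighbors(m.gene_id, m.anchor_exon)
        m.signal, m.signal_result = signal_align(
            m.mate_sequence,
            fetch_sequence(genome, m.anchor_exon),
            consensus,
            fetch_sequence(genome, prev_ex) if prev_ex else None,
            fetch_sequence(genome, next_ex) if next_ex else None,
            scoring,
        )
        m.shadow = shadow_test(m.mate_sequence, m.anchor_exon, gene, annotation, genome, scoring)
        m.category = categorize_mate(m.signal, m.shadow)


# ---------------------------------------------------------------------------
# Clustering and vicinities
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    interval: GenomicInterval
    orientation: str
    category: str
    reads: list[MateRecord] = field(default_factory=list)


def _single_linkage(mates: Sequence[MateRecord]) -> list[list[MateRecord]]:
    """Group mates whose anchor intervals chain by >=1 bp overlap."""
    ordered = sorted(mates, key=lambda m: (m.anchor.interval.start, m.anchor.interval.end))
    groups: list[list[MateRecord]] = []
    cur: list[MateRecord] = []
    cur_end = -1
    for m in ordered:
        iv = m.anchor.interval
        if cur and iv.start <= cur_end:
            cur.append(m)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                groups.append(cur)
            cur = [m]
            cur_end = iv.end
    if cur:
        groups.append(cur)
    return groups


def cluster_anchors(mates: Sequence[MateRecord]) -> list[Cluster]:
    """Single-linkage overlap clusters, separate per (orientation, category)."""
    buckets: dict[tuple[str, str], list[MateRecord]] = {}
    for m in mates:
        buckets.setdefault((m.orientation, m.category), []).append(m)
    clusters = []
    for (orientation, category), members in sorted(buckets.items()):
        for group in _single_linkage(members):
            chrom = group[0].anchor.interval.chrom
            clusters.append(
                Cluster(
                    interval=GenomicInterval(
                        chrom,
                        min(m.anchor.interval.start for m in group),
                        max(m.anchor.interval.end for m in group),
                    ),
                    orientation=orientation,
                    category=category,
                    reads=list(group),
                )
            )
    return clusters


@dataclass
class Vicinity:
    """The clustered neighborhood around a putative insertion in one gene."""

    gene_id: str
    span: GenomicInterval
    reads: list[MateRecord]
    clusters: list[Cluster]

    @property
    def s(self) -> int:
        return sum(1 for m in self.reads if m.category == "S")

    @property
    def ru(self) -> int:
        return sum(1 for m in self.reads if m.category == "RU")

    @property
    def sru(self) -> int:
        return sum(1 for m in self.reads if m.category == "SRU")

    @property
    def sn(self) -> int:
        return self.s + sum(1 for m in self.reads if m.category == "none")


def build_vicinities(mates: Sequence[MateRecord]) -> list[Vicinity]:
    """Per gene: single-linkage anchor clusters over all categories; each read
    counts once per gene (multi-exon anchors deduplicated)."""
    by_gene: dict[str, dict[str, MateRecord]] = {}
    for m in mates:
        gene_reads = by_gene.setdefault(m.gene_id, {})
        gene_reads.setdefault(m.anchor.read_id, m)  # dedup per gene
    vicinities = []
    for gene_id, reads in sorted(by_gene.items()):
        for group in _single_linkage(list(reads.values())):
            chrom = group[0].anchor.interval.chrom
            span = GenomicInterval(
                chrom,
                min(m.anchor.interval.start for m in group),
                max(m.anchor.interval.end for m in group),
            )
            vicinities.append(Vicinity(gene_id, span, group, cluster_anchors(group)))
    return vicinities


def infer_insertion_intervals(vicinity: Vicinity, gene_span: GenomicInterval) -> list[GenomicInterval]:
    """One interval per S cluster: from the S cluster to the closest cluster
    in the opposing orientation in its direction of search, else the gene end.
    """
    s_clusters = [c for c in vicinity.clusters if c.category == "S"]
    if not s_clusters:
        raise ValueError("vicinity has no S cluster")
    intervals = []
    for sc in s_clusters:
        if sc.orientation == "+":
            opposing = [
                c for c in vicinity.clusters
                if c.orientation == "-" and c is not sc and c.interval.start > sc.interval.end
            ]
            if opposing:
                nearest = min(opposing, key=lambda c: c.interval.start)
                start, end = sc.interval.end, nearest.interval.start
            else:
                start, end = sc.interval.end, gene_span.end
        else:
            opposing = [
                c for c in vicinity.clusters
                if c.orientation == "+" and c is not sc and c.interval.end < sc.interval.start
            ]
            if opposing:
                nearest = max(opposing, key=lambda c: c.interval.end)
                start, end = nearest.interval.end, sc.interval.start
            else:
                start, end = gene_span.start, sc.interval.start
        start = max(gene_span.start, min(start, gene_span.end))
        end = max(gene_span.start, min(end, gene_span.end))
        if end < start:
            start, end = end, start
        intervals.append(GenomicInterval(gene_span.chrom, start, end))
    return intervals


@dataclass
class InsertionCall:
    gene_id: str
    vicinity: Vicinity
    insertion_interval: GenomicInterval
    s: int
    sn: int
    ru: int
    sru: int
    passed_context_filter: bool = True
    repeat_rich: bool = False


def repeat_coverage_fraction(iv: GenomicInterval, repeats: Sequence[AluAnnotation]) -> float:
    covered = 0
    for rep in repeats:
        covered += iv.overlap_length(rep.interval)
    return min(1.0, covered / iv.length())


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def analyze_vicinities(
    records: Iterable[ReadAlignmentRecord],
    genome: Mapping[str, str],
    annotation: GeneAnnotation | Iterable[TranscriptModel],
    consensus: str,
    classifier: AluKmerIndex,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[list[Vicinity], GeneAnnotation]:
    """Alignment-heavy half of the caller: candidate collection, anchoring,
    signal/shadow tests and vicinity construction (no parameter filtering).

    The resulting vicinities can be re-filtered under many parameter tuples
    without re-alignment, which is what the calibration grid search does.
    """
    if not isinstance(annotation, GeneAnnotation):
        annotation = GeneAnnotation(annotation)
    pairs = collect_candidate_pairs(records, classifier)
    mates = anchor_to_exons(pairs, annotation)
    evaluate_mates(mates, annotation, genome, consensus, scoring)
    return build_vicinities(mates), annotation


def vicinity_count_table(vicinities: Sequence[Vicinity]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": v.gene_id,
            "chrom": v.span.chrom,
            "start": v.span.start,
            "end": v.span.end,
            "s": v.s,
            "sn": v.sn,
            "ru": v.ru,
            "sru": v.sru,
        }
        for v in vicinities
    ]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "s", "sn", "ru", "sru"])


def call_insertions(
    vicinities: Sequence[Vicinity],
    annotation: GeneAnnotation,
    params: ContextParams = ContextParams(),
    repeats: Sequence[AluAnnotation] = (),
    repeat_rich_frac: float = 0.5,
) -> list[InsertionCall]:
    """Apply the context filter and emit one call per S cluster of each
    passing vicinity, with its inferred insertion interval."""
    calls = []
    for v in vicinities:
        if not context_filter(v.s, v.sn, v.ru, v.sru, params):
            continue
        gene_span = annotation.genes[v.gene_id].span()
        for iv in infer_insertion_intervals(v, gene_span):
            calls.append(
                InsertionCall(
                    gene_id=v.gene_id,
                    vicinity=v,
                    insertion_interval=iv,
                    s=v.s,
                    sn=v.sn,
                    ru=v.ru,
                    sru=v.sru,
                    repeat_rich=repeat_coverage_fraction(iv, repeats) > repeat_rich_frac,
                )
            )
    return calls
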