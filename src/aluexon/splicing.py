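"""Cassette (exon-skipping) events, junction read counting, and PSI.

A *simple* skip event requires an inclusion isoform (..., A, E, B, ...) and a
skipping isoform (..., A, B, ...) of the same gene with the flanking exons A
and B coordinate-identical in both; events with any change to a flank are not
simple and are excluded.  Per sample, PSI for an event is

    PSI = (L + R) / (L + R + 2 * S)

where L and R are spliced-read counts of the two inclusion introns and S the
count of the skipping intron; PSI is undefined when L + R + S falls below the
low-read cutoff (default 10 reads).  Events categorize as minor (PSI < 0.35),
equal (0.35 <= PSI < 0.65) or major (PSI >= 0.65); the equal category's lower
bound closes the gap left between the published minor (<0.35) and equal
(>=0.36) boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, median
from typing import Iterable, Mapping, Sequence

from .io import GenomicInterval, ReadAlignmentRecord, TranscriptModel, splice_gaps

DEFAULT_MIN_TOTAL_READS = 10
MINOR_MAX = 0.35
MAJOR_MIN = 0.65

IntronKey = tuple[str, int, int]


def intron_key(iv: GenomicInterval) -> IntronKey:
    return (iv.chrom, iv.start, iv.end)


def count_junction_reads(
    records: Iterable[ReadAlignmentRecord],
    introns: Iterable[GenomicInterval] | None = None,
) -> dict[IntronKey, int]:
    """Spliced-alignment support per intron.

    A spliced read contributes 1 to an intron iff one of its splice gaps
    covers exactly that reference span (exact-boundary matching; near-miss
    junctions are not merged).  With ``introns`` given, counts are restricted
    to those spans; otherwise every observed junction is counted.
    """
    wanted = {intron_key(iv) for iv in introns} if introns is not None else None
    counts: dict[IntronKey, int] = {}
    for rec in records:
        for gap in splice_gaps(rec):
            key = intron_key(gap)
            if wanted is not None and key not in wanted:
                continue
            counts[key] = counts.get(key, 0) + 1
    if wanted is not None:
        for key in wanted:
            counts.setdefault(key, 0)
    return counts


@dataclass
class SkipEvent:
    """One alternative-splicing pattern of a cassette exon.

    iLeft/iRight are the two inclusion introns flanking the skipped exon;
    iSpan is the skipping intron covering both and the exon.
    """

    skipped_exon: GenomicInterval
    iLeft: GenomicInterval
    iRight: GenomicInterval
    iSpan: GenomicInterval
    gene_id: str
    inclusion_transcripts: set[str] = field(default_factory=set)
    skipping_transcripts: set[str] = field(default_factory=set)
    per_sample_counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.iSpan.start == self.iLeft.start and self.iSpan.end == self.iRight.end
        assert self.iLeft.end + 1 == self.skipped_exon.start
        assert self.skipped_exon.end + 1 == self.iRight.start

    def key(self) -> tuple:
        return (intron_key(self.skipped_exon), intron_key(self.iLeft), intron_key(self.iRight))


def detect_exon_skipping(transcripts: Iterable[TranscriptModel]) -> list[SkipEvent]:
    """Enumerate simple cassette events from the isoforms of each gene.

    For every internal exon E of an inclusion isoform with flanks A and B,
    an event is emitted iff some other isoform of the gene splices A directly
    to B with A and B unchanged.  An exon skipped in several flanking-intron
    contexts yields several patterns.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    events: dict[tuple, SkipEvent] = {}
    for gene_id, txs in sorted(by_gene.items()):
        if len(txs) < 2:
            continue
        # junctions (A, B) realized as consecutive exon pairs per isoform
        adjacency: dict[tuple, set[str]] = {}
        for tx in txs:
            for a, b in zip(tx.exons, tx.exons[1:]):
                adjacency.setdefault((intron_key(a), intron_key(b)), set()).add(tx.transcript_id)
        for tx in txs:
            for i in range(1, len(tx.exons) - 1):
                a, e, b = tx.exons[i - 1], tx.exons[i], tx.exons[i + 1]
                skippers = adjacency.get((intron_key(a), intron_key(b)))
                if not skippers:
                    continue
                ev_key = (intron_key(e), intron_key(a), intron_key(b))
                ev = events.get(ev_key)
                if ev is None:
                    ev = SkipEvent(
                        skipped_exon=e,
                        iLeft=GenomicInterval(e.chrom, a.end + 1, e.start - 1),
                        iRight=GenomicInterval(e.chrom, e.end + 1, b.start - 1),
                        iSpan=GenomicInterval(e.chrom, a.end + 1, b.start - 1),
                        gene_id=gene_id,
                    )
                    events[ev_key] = ev
                ev.inclusion_transcripts.add(tx.transcript_id)
                ev.skipping_transcripts |= skippers
    return sorted(events.values(), key=lambda e: (e.skipped_exon.chrom, e.skipped_exon.start))


def attach_junction_counts(
    events: Sequence[SkipEvent],
    per_sample_counts: Mapping[str, Mapping[IntronKey, int]],
) -> None:
    """Fill each event's per-sample (L, R, S) counts from junction tallies."""
    for ev in events:
        for sample, counts in per_sample_counts.items():
            ev.per_sample_counts[sample] = (
                counts.get(intron_key(ev.iLeft), 0),
                counts.get(intron_key(ev.iRight), 0),
                counts.get(intron_key(ev.iSpan), 0),
            )


def compute_psi(
    count_ileft: int,
    count_iright: int,
    count_ispan: int,
    min_total: int = DEFAULT_MIN_TOTAL_READS,
) -> float | None:
    """PSI = (L + R) / (L + R + 2S); None below the low-read cutoff."""
    if min(count_ileft, count_iright, count_ispan) < 0:
        raise ValueError("negative junction count")
    total = count_ileft + count_iright + count_ispan
    if total == 0 or total < min_total:
        return None
    inclusion = count_ileft + count_iright
    return inclusion / (inclusion + 2 * count_ispan)


def categorize_psi(summary_psi: float | None) -> str | None:
    """minor (< 0.35), equal ([0.35, 0.65)) or major (>= 0.65)."""
    if summary_psi is None:
        return None
    if not (0.0 <= summary_psi <= 1.0):
        raise ValueError(f"PSI out of [0,1]: {summary_psi}")
    if summary_psi < MINOR_MAX:
        return "minor"
    if summary_psi >= MAJOR_MIN:
        return "major"
    return "equal"


@dataclass
class PsiRecord:
    event: SkipEvent
    per_sample_psi: dict[str, float | None]
    summary_psi: float | None
    category: str | None


def summarize_psi(
    event: SkipEvent,
    min_total: int = DEFAULT_MIN_TOTAL_READS,
    summary: str = "median",
) -> PsiRecord:
    """Per-sample PSI plus the cohort summary (median by default, mean by flag)."""
    per_sample = {
        s: compute_psi(l, r, sp, min_total) for s, (l, r, sp) in event.per_sample_counts.items()
    }
    defined = [v for v in per_sample.values() if v is not None]
    if defined:
        agg = median(defined) if summary == "median" else mean(defined)
    else:
        agg = None
    return PsiRecord(event, per_sample, agg, categorize_psi(agg))
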