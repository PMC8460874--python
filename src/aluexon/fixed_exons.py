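"""Detection of exonization events at Alu elements present in the reference.

Candidate exons come from per-sample assembled transcript models.  An exon is
called an Alu exon when (i) it is internal to a transcript (has at least one
exon on each side), (ii) the overlapped Alu is antisense to the transcript
strand, and (iii) its length is strictly between the configured bounds
(default 40 < L < 400 bp).  Calls are merged across samples into a locus
table; exons already present in a reference annotation (exact coordinate
match) are flagged known.  Samples without an assembled transcript for an
exon can still be counted as supporting it when both flanking introns have
spliced-read support (the rescue step).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io import AluAnnotation, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 40
DEFAULT_MAX_LEN = 400


@dataclass
class AluExonCall:
    """A candidate exonized Alu exon with its locus and per-sample support."""

    exon: GenomicInterval
    gene_id: str
    alu: AluAnnotation
    frame: int  # exon length mod 3
    samples_with_assembly_support: set[str] = field(default_factory=set)
    samples_with_intron_support: set[str] = field(default_factory=set)
    known: bool = False
    flanking_introns: tuple[GenomicInterval, GenomicInterval] | None = None


def find_alu_overlapping_exons(
    transcripts: Iterable[TranscriptModel],
    alus: Iterable[AluAnnotation],
) -> list[tuple[GenomicInterval, TranscriptModel, AluAnnotation]]:
    """All (exon, transcript, alu) triples with >=1 bp overlap.

    Each triple is reported once per transcript; overlap is computed on
    inclusive coordinates (abutting intervals do not overlap).
    """
    trees: dict[str, IntervalTree] = {}
    for alu in alus:
        iv = alu.interval
        # IntervalTree is half-open; end+1 makes the inclusive end queryable
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, alu)
    out = []
    for tx in transcripts:
        tree = trees.get(tx.chrom)
        if tree is None:
            continue
        for exon in tx.exons:
            for hit in sorted(tree.overlap(exon.start, exon.end + 1)):
                out.append((exon, tx, hit.data))
    return out


def filter_candidates(
    pairs: Sequence[tuple[GenomicInterval, TranscriptModel, AluAnnotation]],
    sample: str = "sample",
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[AluExonCall]:
    """Apply the internal / antisense / length criteria to overlap triples.

    Length bounds are strict (``min_len < L < max_len``).  Candidates on
    unstranded transcripts are dropped and counted in the skip log.
    """
    calls: dict[tuple[str, int, int], AluExonCall] = {}
    n_unstranded = 0
    for exon, tx, alu in pairs:
        if tx.strand not in "+-":
            n_unstranded += 1
            continue
        idx = tx.exons.index(exon)
        if idx == 0 or idx == len(tx.exons) - 1:
            continue  # criterion i: internal only
        if alu.interval.strand not in "+-" or alu.interval.strand == tx.strand:
            continue  # criterion ii: Alu antisense to the gene
        length = exon.length()
        if not (min_len < length < max_len):
            continue  # criterion iii
        key = (exon.chrom, exon.start, exon.end)
        call = calls.get(key)
        if call is None:
            call = AluExonCall(
                exon=exon,
                gene_id=tx.gene_id,
                alu=alu,
                frame=length % 3,
                flanking_introns=(
                    GenomicInterval(exon.chrom, tx.exons[idx - 1].end + 1, exon.start - 1),
                    GenomicInterval(exon.chrom, exon.end + 1, tx.exons[idx + 1].start - 1),
                ),
            )
            calls[key] = call
        call.samples_with_assembly_support.add(sample)
    if n_unstranded:
        logger.info("dropped %d candidates on unstranded transcripts", n_unstranded)
    return list(calls.values())


def detect_sample_calls(
    transcripts: Iterable[TranscriptModel],
    alus: Iterable[AluAnnotation],
    sample: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[AluExonCall]:
    """Convenience: overlap search plus filtering for one sample."""
    pairs = find_alu_overlapping_exons(transcripts, alus)
    return filter_candidates(pairs, sample=sample, min_len=min_len, max_len=max_len)


def merge_across_samples(
    per_sample_calls: Mapping[str, Sequence[AluExonCall]],
    reference_exons: Iterable[GenomicInterval] = (),
) -> list[AluExonCall]:
    """Merge per-sample calls into a comprehensive exon list.

    Calls with identical exon coordinates merge (union of supporting
    samples); distinct exon intervals over the same Alu locus remain distinct
    rows of one locus.  ``known`` is set by exact coordinate identity with a
    reference-annotation exon.
    """
    known_keys = {(e.chrom, e.start, e.end) for e in reference_exons}
    merged: dict[tuple[str, int, int], AluExonCall] = {}
    for sample in sorted(per_sample_calls):
        for call in per_sample_calls[sample]:
            key = (call.exon.chrom, call.exon.start, call.exon.end)
            existing = merged.get(key)
            if existing is None:
                existing = AluExonCall(
                    exon=call.exon,
                    gene_id=call.gene_id,
                    alu=call.alu,
                    frame=call.frame,
                    flanking_introns=call.flanking_introns,
                )
                existing.known = key in known_keys
                merged[key] = existing
            existing.samples_with_assembly_support |= call.samples_with_assembly_support
    return sorted(merged.values(), key=lambda c: (c.exon.chrom, c.exon.start, c.exon.end))


def rescue_by_intron_support(
    call: AluExonCall,
    junction_counts: Mapping[tuple[tuple[str, int, int], str], int],
    samples: Iterable[str],
    min_reads: int = 1,
) -> AluExonCall:
    """Add intron-level support: a sample supports the exon when *both*
    flanking introns have >= min_reads spliced alignments in that sample.

    ``junction_counts`` maps ((chrom, start, end), sample) -> read count.
    Calls without known flanking introns are returned unchanged (flagged in
    the log).
    """
    if call.flanking_introns is None:
        logger.warning("exon %s has no flanking-intron context; rescue skipped", call.exon)
        return call
    left, right = call.flanking_introns
    lkey = (left.chrom, left.start, left.end)
    rkey = (right.chrom, right.start, right.end)
    for sample in samples:
        if (
            junction_counts.get((lkey, sample), 0) >= min_reads
            and junction_counts.get((rkey, sample), 0) >= min_reads
        ):
            call.samples_with_intron_support.add(sample)
    return call


def locus_table(calls: Sequence[AluExonCall], min_samples: int = 2) -> pd.DataFrame:
    """Tabulate merged calls: one row per distinct exon, with its Alu locus.

    ``robust`` marks exons supported (by assembly or intron rescue) in at
    least ``min_samples`` samples.
    """
    rows = []
    for c in calls:
        support = c.samples_with_assembly_support | c.samples_with_intron_support
        rows.append(
            {
                "chrom": c.exon.chrom,
                "start": c.exon.start,
                "end": c.exon.end,
                "length": c.exon.length(),
                "gene_id": c.gene_id,
                "alu_locus": f"{c.alu.interval.chrom}:{c.alu.interval.start}-{c.alu.interval.end}",
                "alu_subfamily": c.alu.subfamily,
                "alu_family": c.alu.family_class,
                "frame": c.frame,
                "known": c.known,
                "n_samples_assembly": len(c.samples_with_assembly_support),
                "n_samples_total": len(support),
                "robust": len(support) >= min_samples,
            }
        )
    return pd.DataFrame(rows)
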