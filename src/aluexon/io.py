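"""Readers/writers for on-disk formats and the shared coordinate convention.

All coordinates inside the package are **1-based inclusive** on both ends,
matching GTF/SAM native coordinates and the convention in which a 142 bp exon
spans positions ``start..start+141``.  BED input (0-based, half-open) is
converted at the boundary, as is pysam's 0-based in-memory representation.
Every other module consumes only the types defined here; no module re-parses
files on its own.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pysam

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on a chromosome, 1-based on both ends."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end < start: {self.end} < {self.start}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def to_bed_fields(self, name: str = ".", score: int = 0) -> str:
        """BED6 line (0-based half-open) for this interval."""
        return (
            f"{self.chrom}\t{self.start - 1}\t{self.end}\t{name}\t{score}\t"
            f"{self.strand if self.strand != '.' else '.'}"
        )

    @classmethod
    def from_bed(cls, chrom: str, start0: int, end0: int, strand: str = ".") -> "GenomicInterval":
        """Build from BED (0-based half-open) coordinates."""
        return cls(chrom, start0 + 1, end0, strand)


def opposite_strand(strand: str) -> str:
    return {"+": "-", "-": "+"}.get(strand, ".")


@dataclass
class TranscriptModel:
    """A transcript as an ordered chain of exons on one chromosome."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.chrom != b.chrom:
                raise ValueError(f"{self.transcript_id}: exons on multiple chromosomes")
            if b.start <= a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons {a} / {b}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, 1-based inclusive."""
        return [
            GenomicInterval(self.chrom, a.end + 1, b.start - 1, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]


ALU_FAMILY_CLASSES = ("AluJ", "AluS", "AluY", "Alu-generic")


def alu_family_class(subfamily: str) -> str:
    """Age class of an Alu subfamily name (AluJb -> AluJ, AluSx1 -> AluS...).

    Names beginning with ``Alu`` but lacking a J/S/Y age letter (e.g. plain
    ``Alu``) fall into the generic bucket.
    """
    for fam in ("AluJ", "AluS", "AluY"):
        if subfamily.startswith(fam):
            return fam
    return "Alu-generic"


@dataclass(frozen=True)
class AluAnnotation:
    interval: GenomicInterval
    subfamily: str

    @property
    def family_class(self) -> str:
        return alu_family_class(self.subfamily)


@dataclass
class ReadAlignmentRecord:
    """One mate of a paired-end read, mapped or not.

    ``interval`` carries the alignment strand (``-`` when the read aligned
    reverse-complemented).  Unmapped mates keep their sequence; their
    ``interval`` and ``cigar`` are ``None``.
    """

    read_id: str
    mate_index: int  # 1 or 2
    mapped: bool
    interval: GenomicInterval | None
    cigar: str | None
    sequence: str
    is_concordant_pair: bool

    @property
    def is_reverse(self) -> bool:
        return self.mapped and self.interval is not None and self.interval.strand == "-"


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str) -> list[TranscriptModel]:
    """Parse exon features of a GTF file into transcript models.

    Coordinates are kept as-is (GTF is natively 1-based inclusive).  Exon
    records without a transcript_id are skipped with a warning; structurally
    malformed lines raise with the offending line number.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tx -> (gene_id, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line ({len(fields)} fields)")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            attributes = _parse_gtf_attributes(attrs)
            tx = attributes.get("transcript_id")
            if not tx:
                logger.warning("%s:%d: exon without transcript_id skipped", path, lineno)
                continue
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand if strand in "+-" else ".")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            exons_by_tx.setdefault(tx, []).append(iv)
            meta.setdefault(tx, (attributes.get("gene_id", tx), iv.strand))
    return [
        TranscriptModel(tx, meta[tx][0], meta[tx][1], exons)
        for tx, exons in exons_by_tx.items()
    ]


def write_gtf(transcripts: Iterable[TranscriptModel], path: str, source: str = "aluexon") -> None:
    with open(path, "w") as fh:
        for tx in sorted(transcripts, key=lambda t: (t.chrom, t.exons[0].start, t.transcript_id)):
            for ex in tx.exons:
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start}\t{ex.end}\t.\t{tx.strand}\t.\t"
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";\n'
                )


# ---------------------------------------------------------------------------
# Repeat annotations
# ---------------------------------------------------------------------------


def read_repeatmasker(path: str, dialect: str = "bed6") -> list[AluAnnotation]:
    """Read a repeat annotation track, retaining Alu records only.

    dialect ``bed6``: 0-based half-open, converted on input.
    dialect ``rm_out``: native RepeatMasker .out (1-based inclusive, 'C' for
    minus strand, three header lines).
    """
    if dialect not in ("bed6", "rm_out"):
        raise ValueError(f"unknown repeat dialect {dialect!r}")
    out: list[AluAnnotation] = []
    with open(path) as fh:
        if dialect == "bed6":
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                chrom, start0, end0, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
                if not name.startswith("Alu"):
                    continue
                out.append(AluAnnotation(GenomicInterval.from_bed(chrom, start0, end0, strand), name))
        else:
            for line in fh:
                f = line.split()
                if len(f) < 11 or not f[0].isdigit():
                    continue  # header / blank lines
                chrom, start, end = f[4], int(f[5]), int(f[6])
                strand = "-" if f[8] == "C" else "+"
                name = f[9]
                if not name.startswith("Alu"):
                    continue
                out.append(AluAnnotation(GenomicInterval(chrom, start, end, strand), name))
    return out


def write_repeats_bed(alus: Iterable[AluAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        for alu in sorted(alus, key=lambda a: (a.interval.chrom, a.interval.start)):
            fh.write(alu.interval.to_bed_fields(name=alu.subfamily) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> dict[str, str]:
    """Plain FASTA reader returning {name: sequence} (uppercased)."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(genome: Mapping[str, str], iv: GenomicInterval) -> str:
    """Sequence of a 1-based inclusive interval from an in-memory genome."""
    seq = genome[iv.chrom][iv.start - 1 : iv.end]
    return seq


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _cigar_reference_length(cigartuples) -> int:
    # ops consuming reference: M(0), D(2), N(3), =(7), X(8)
    return sum(ln for op, ln in cigartuples if op in (0, 2, 3, 7, 8))


def read_sam(path: str) -> Iterator[ReadAlignmentRecord]:
    """Stream alignment records from a SAM file via pysam.

    The concordance flag is the SAM proper-pair bit.  Mapped records whose
    CIGAR-implied query length disagrees with the stored sequence are rejected
    with a warning.  Unmapped mates are yielded with their sequence retained.
    """
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate_index = 1 if rec.is_read1 or not rec.is_paired else 2
            seq = rec.query_sequence or ""
            if not rec.is_unmapped:
                if rec.cigartuples is None:
                    logger.warning("%s: mapped record %s lacks CIGAR; rejected", path, rec.query_name)
                    continue
                qlen = rec.infer_query_length()
                if seq and qlen is not None and qlen != len(seq):
                    logger.warning(
                        "%s: CIGAR/sequence length mismatch for %s; rejected", path, rec.query_name
                    )
                    continue
                iv = GenomicInterval(
                    rec.reference_name,
                    rec.reference_start + 1,
                    rec.reference_start + _cigar_reference_length(rec.cigartuples),
                    "-" if rec.is_reverse else "+",
                )
                yield ReadAlignmentRecord(
                    read_id=rec.query_name,
                    mate_index=mate_index,
                    mapped=True,
                    interval=iv,
                    cigar=rec.cigarstring,
                    sequence=seq,
                    is_concordant_pair=rec.is_proper_pair,
                )
            else:
                yield ReadAlignmentRecord(
                    read_id=rec.query_name,
                    mate_index=mate_index,
                    mapped=False,
                    interval=None,
                    cigar=None,
                    sequence=seq,
                    is_concordant_pair=rec.is_proper_pair,
                )


def write_sam(
    records: Iterable[ReadAlignmentRecord],
    path: str,
    references: Mapping[str, int],
) -> None:
    """Write records as SAM.  ``references`` maps chromosome -> length.

    Unmapped mates of a pair are placed at their mate's position per SAM
    convention when the mate is mapped (tracked within each read_id).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
    }
    records = list(records)
    by_read: dict[str, dict[int, ReadAlignmentRecord]] = {}
    for r in records:
        by_read.setdefault(r.read_id, {})[r.mate_index] = r
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        refs = list(references)
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.is_paired = True
            if r.mate_index == 1:
                a.is_read1 = True
            else:
                a.is_read2 = True
            mate = by_read.get(r.read_id, {}).get(3 - r.mate_index)
            a.is_proper_pair = r.is_concordant_pair
            if r.mapped and r.interval is not None:
                a.reference_id = refs.index(r.interval.chrom)
                a.reference_start = r.interval.start - 1
                a.cigarstring = r.cigar
                a.is_reverse = r.interval.strand == "-"
                a.mapping_quality = 60
            else:
                a.is_unmapped = True
                if mate is not None and mate.mapped and mate.interval is not None:
                    a.reference_id = refs.index(mate.interval.chrom)
                    a.reference_start = mate.interval.start - 1
            if mate is not None:
                if mate.mapped and mate.interval is not None:
                    a.next_reference_id = refs.index(mate.interval.chrom)
                    a.next_reference_start = mate.interval.start - 1
                    a.mate_is_reverse = mate.interval.strand == "-"
                else:
                    a.mate_is_unmapped = True
                    if r.mapped and r.interval is not None:
                        a.next_reference_id = refs.index(r.interval.chrom)
                        a.next_reference_start = r.interval.start - 1
            out.write(a)


# ---------------------------------------------------------------------------
# CIGAR helpers shared by splicing / simulation
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def splice_gaps(record: ReadAlignmentRecord) -> list[GenomicInterval]:
    """Reference spans skipped by N operations (the introns of a spliced read)."""
    if not record.mapped or record.cigar is None or record.interval is None:
        return []
    gaps = []
    pos = record.interval.start
    for n, op in parse_cigar(record.cigar):
        if op == "N":
            gaps.append(GenomicInterval(record.interval.chrom, pos, pos + n - 1))
            pos += n
        elif op in "MD=X":
            pos += n
    return gaps


# convenience re-exports used across the package
__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "AluAnnotation",
    "ReadAlignmentRecord",
    "alu_family_class",
    "opposite_strand",
    "read_gtf",
    "write_gtf",
    "read_repeatmasker",
    "write_repeats_bed",
    "read_fasta",
    "write_fasta",
    "fetch_sequence",
    "read_sam",
    "write_sam",
    "parse_cigar",
    "splice_gaps",
]
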