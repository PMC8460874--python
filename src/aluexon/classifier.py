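"""k-mer classification of reads as Alu-derived.

Replaces a general metagenomic classifier with a purpose-built exact-k-mer
index over an Alu sequence library (consensus plus annotated genomic
instances).  A read is called an Alu read when at least ``min_hit_frac`` of
its k-mers (canonicalized) are present in the library index.  The low default
fraction keeps chimeric exon-Alu mates — which may carry only a few tens of
Alu bases — classifiable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from .io import read_fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def packaged_alu_consensus() -> str:
    """The representative ~300 bp Alu consensus shipped with the package."""
    path = resources.files("aluexon.data") / "alu_consensus.fa"
    with resources.as_file(path) as p:
        return next(iter(read_fasta(str(p)).values()))


@dataclass
class AluKmerIndex:
    """Canonical k-mer set over an Alu sequence library."""

    k: int = 31
    min_hit_frac: float = 0.1
    kmer_set: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 < self.min_hit_frac <= 1):
            raise ValueError("min_hit_frac must be in (0, 1]")

    def add_sequence(self, seq: str) -> None:
        seq = seq.upper()
        for i in range(len(seq) - self.k + 1):
            kmer = seq[i : i + self.k]
            if "N" in kmer:
                continue
            self.kmer_set.add(canonical_kmer(kmer))

    def hit_fraction(self, read: str) -> float:
        read = read.upper()
        n = len(read) - self.k + 1
        if n <= 0:
            return 0.0
        hits = sum(
            1
            for i in range(n)
            if "N" not in read[i : i + self.k]
            and canonical_kmer(read[i : i + self.k]) in self.kmer_set
        )
        return hits / n

    def classify_read(self, read: str) -> bool:
        """True iff the read's canonical-k-mer hit fraction reaches the cutoff."""
        if len(read) < self.k:
            logger.warning("read shorter than k=%d; classified non-Alu", self.k)
            return False
        return self.hit_fraction(read) >= self.min_hit_frac


def build_index(
    alu_sequences: Iterable[str], k: int = 31, min_hit_frac: float = 0.1
) -> AluKmerIndex:
    """Index every canonical k-mer of the given Alu library sequences."""
    index = AluKmerIndex(k=k, min_hit_frac=min_hit_frac)
    n = 0
    for seq in alu_sequences:
        index.add_sequence(seq)
        n += 1
    if n == 0:
        raise ValueError("empty Alu sequence library")
    return index
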