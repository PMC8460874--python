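"""Small de Bruijn assembler for the reads bounding an insertion interval,
and contig prioritization against the gene region.

The assembler walks unambiguous (non-branching) paths of the k-mer graph
(default k = 23), after one round of tip clipping (dead-end branches of at
most 2k bases hanging off a junction).  Bubbles are deliberately not popped:
haplotype differences are supposed to surface as separate contigs.  An
external assembler can be substituted upstream; anything producing sequences
can feed :func:`prioritize_contigs`.

A contig is *prioritized* (a candidate novel insert) when it lacks a
high-quality local alignment to the gene region on either strand, high
quality meaning >=90% identity together with >=80% contig coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import Scoring, DEFAULT_SCORING, local_align
from .classifier import reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_K = 23
HQ_MIN_IDENTITY = 0.90
HQ_MIN_COVERAGE = 0.80


@dataclass
class Contig:
    sequence: str
    supporting_read_ids: set[str] = field(default_factory=set)
    best_identity: float = 0.0
    best_coverage: float = 0.0
    prioritized: bool = False


def _kmer_graph(reads: Mapping[str, str], k: int):
    """Edge multiset (k-mers) and node adjacency of the de Bruijn graph."""
    edges: dict[str, int] = {}
    edge_reads: dict[str, set[str]] = {}
    for rid, seq in reads.items():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            edges[kmer] = edges.get(kmer, 0) + 1
            edge_reads.setdefault(kmer, set()).add(rid)
    out_edges: dict[str, list[str]] = {}
    in_deg: dict[str, int] = {}
    for kmer in edges:
        u, v = kmer[:-1], kmer[1:]
        out_edges.setdefault(u, []).append(v)
        in_deg[v] = in_deg.get(v, 0) + 1
        in_deg.setdefault(u, in_deg.get(u, 0))
        out_edges.setdefault(v, out_edges.get(v, []))
    return edges, edge_reads, out_edges, in_deg


def _walk_contigs(out_edges, in_deg) -> list[list[str]]:
    """Maximal non-branching node paths (contigs as node lists)."""

    def is_junction(node: str) -> bool:
        return not (in_deg.get(node, 0) == 1 and len(out_edges.get(node, [])) == 1)

    paths = []
    visited_edges: set[tuple[str, str]] = set()
    for node in sorted(out_edges):
        if not is_junction(node):
            continue
        for nxt in sorted(out_edges[node]):
            if (node, nxt) in visited_edges:
                continue
            path = [node, nxt]
            visited_edges.add((node, nxt))
            while not is_junction(path[-1]):
                following = out_edges[path[-1]][0]
                visited_edges.add((path[-1], following))
                path.append(following)
            paths.append(path)
    # isolated cycles (every node 1-in-1-out)
    for node in sorted(out_edges):
        for nxt in sorted(out_edges[node]):
            if (node, nxt) in visited_edges:
                continue
            path = [node, nxt]
            visited_edges.add((node, nxt))
            while path[-1] != node:
                following = out_edges[path[-1]][0]
                visited_edges.add((path[-1], following))
                path.append(following)
            paths.append(path)
    return paths


def assemble_reads(reads: Mapping[str, str] | Iterable[str], k: int = DEFAULT_K) -> list[Contig]:
    """Assemble reads into contigs along unambiguous de Bruijn paths.

    ``reads`` maps read id -> sequence (a bare iterable gets synthetic ids).
    Reads shorter than k contribute nothing; an empty graph yields an empty
    contig list with a warning.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if not isinstance(reads, Mapping):
        reads = {f"read{i}": s for i, s in enumerate(reads)}
    edges, edge_reads, out_edges, in_deg = _kmer_graph(reads, k)
    if not edges:
        logger.warning("no read reaches k=%d bases; nothing to assemble", k)
        return []

    # one round of tip clipping: drop dead-end branches <= 2k bases that hang
    # off a junction with an alternative continuation
    paths = _walk_contigs(out_edges, in_deg)
    tips = []
    for path in paths:
        seq_len = len(path[0]) + len(path) - 1
        if seq_len > 2 * k:
            continue
        start, end = path[0], path[-1]
        dead_end = len(out_edges.get(end, [])) == 0 and len(out_edges.get(start, [])) > 1
        dead_start = in_deg.get(start, 0) == 0 and in_deg.get(end, 0) > 1
        if dead_end or dead_start:
            tips.append(path)
    if tips:
        for path in tips:
            for u, v in zip(path, path[1:]):
                out_edges[u].remove(v)
                in_deg[v] -= 1
        paths = _walk_contigs(out_edges, in_deg)

    contigs = []
    for path in paths:
        seq = path[0] + "".join(node[-1] for node in path[1:])
        support: set[str] = set()
        for u, v in zip(path, path[1:]):
            support |= edge_reads.get(u + v[-1], set())
        contigs.append(Contig(sequence=seq, supporting_read_ids=support))
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    return contigs


def prioritize_contigs(
    contigs: Sequence[Contig],
    gene_region_sequence: str,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[Contig]:
    """Align each contig (both strands) to the gene region and flag those
    without a high-quality match (>=90% identity and >=80% contig coverage).

    All contigs are returned with their best identity/coverage populated;
    ``prioritized`` marks the candidates worth curating.
    """
    for contig in contigs:
        best_id, best_cov, hq = 0.0, 0.0, False
        for query in (contig.sequence, reverse_complement(contig.sequence)):
            res = local_align(query, gene_region_sequence, scoring)
            if res.identity >= HQ_MIN_IDENTITY and res.query_coverage >= HQ_MIN_COVERAGE:
                hq = True
            if (res.identity, res.query_coverage) > (best_id, best_cov):
                best_id, best_cov = res.identity, res.query_coverage
        contig.best_identity = best_id
        contig.best_coverage = best_cov
        contig.prioritized = not hq
    return list(contigs)
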