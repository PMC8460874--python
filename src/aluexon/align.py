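"""Local and spliced-local alignment shared by the insertion caller and
contig prioritization.

The core is an affine-gap Smith-Waterman over a *segmented* target: the
target is an ordered list of labelled sequences (e.g. anchor exon, Alu
consensus, adjacent exon) and the alignment may, at zero cost, jump from any
position of one segment to any position of a later segment.  Such a jump
models a splice: the skipped target bases (segment suffix, intervening
segments, segment prefix) are free, exactly as an intron would be.  With a
single segment the algorithm reduces to standard affine-gap local alignment.

Scoring defaults: match +1, mismatch -1, gap open -2 (charged for the first
gap base), gap extend -0.5.  Identity is matches / aligned columns with gap
columns counted; query coverage is the spanned query fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

ALU_LABEL = "Alu"

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4 (never matches)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


DEFAULT_SCORING = Scoring()

_NEG = -1e18


@njit(cache=True)
def _spliced_dp(q, t, segid, n_seg, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.float64)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.float64)
    Hp = np.zeros((n + 1, m + 1), dtype=np.uint8)
    Ep = np.zeros((n + 1, m + 1), dtype=np.uint8)
    Fp = np.zeros((n + 1, m + 1), dtype=np.uint8)
    carry_val = np.full(n + 1, _NEG, dtype=np.float64)
    carry_arg = np.zeros(n + 1, dtype=np.int32)
    carg_snap = np.zeros((n_seg, n + 1), dtype=np.int32)
    segmax = np.full(n + 1, _NEG, dtype=np.float64)
    segarg = np.zeros(n + 1, dtype=np.int32)
    cur_seg = 0
    best = 0.0
    bi = 0
    bj = 0
    for j in range(1, m + 1):
        s = segid[j - 1]
        if s != cur_seg:
            for i in range(n + 1):
                if segmax[i] > carry_val[i]:
                    carry_val[i] = segmax[i]
                    carry_arg[i] = segarg[i]
                segmax[i] = _NEG
            cur_seg = s
            for i in range(n + 1):
                carg_snap[s, i] = carry_arg[i]
        for i in range(1, n + 1):
            e = H[i, j - 1] + gap_open
            ep = 0
            if E[i, j - 1] + gap_ext > e:
                e = E[i, j - 1] + gap_ext
                ep = 1
            E[i, j] = e
            Ep[i, j] = ep
            f = H[i - 1, j] + gap_open
            fp = 0
            if F[i - 1, j] + gap_ext > f:
                f = F[i - 1, j] + gap_ext
                fp = 1
            F[i, j] = f
            Fp[i, j] = fp
            if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                sc = match
            else:
                sc = mismatch
            d = H[i - 1, j - 1]
            dp = 1
            if carry_val[i - 1] > d:
                d = carry_val[i - 1]
                dp = 4
            h = 0.0
            hp = 0
            if d + sc > h:
                h = d + sc
                hp = dp
            if e > h:
                h = e
                hp = 2
            if f > h:
                h = f
                hp = 3
            H[i, j] = h
            Hp[i, j] = hp
            if h > segmax[i]:
                segmax[i] = h
                segarg[i] = j
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, Hp, Ep, Fp, carg_snap


@njit(cache=True)
def _traceback(q, t, segid, n_seg, bi, bj, Hp, Ep, Fp, carg_snap):  # pragma: no cover
    matches = 0
    cols = 0
    seg_qbases = np.zeros(n_seg, dtype=np.int64)
    i = bi
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            hp = Hp[i, j]
            if hp == 0:
                break
            if hp == 1 or hp == 4:
                cols += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    matches += 1
                seg_qbases[segid[j - 1]] += 1
                if hp == 1:
                    i -= 1
                    j -= 1
                else:
                    s = segid[j - 1]
                    jo = carg_snap[s, i - 1]
                    i -= 1
                    j = jo
            elif hp == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            ep = Ep[i, j]
            j -= 1
            state = 0 if ep == 0 else 1
        else:
            cols += 1
            fp = Fp[i, j]
            i -= 1
            state = 0 if fp == 0 else 2
    return matches, cols, seg_qbases, i, j


@dataclass
class AlignmentResult:
    """Summary of the best spliced-local alignment of a query."""

    score: float
    query_length: int
    qstart: int  # 0-based, inclusive
    qend: int  # 0-based, exclusive
    matches: int
    columns: int
    seg_query_bases: dict[str, int] = field(default_factory=dict)

    @property
    def query_coverage(self) -> float:
        """Fraction of the query spanned by the alignment."""
        if self.query_length == 0:
            return 0.0
        return (self.qend - self.qstart) / self.query_length

    @property
    def identity(self) -> float:
        """Matches over aligned columns (gap columns included)."""
        if self.columns == 0:
            return 0.0
        return self.matches / self.columns

    @property
    def alu_bases(self) -> int:
        """Query bases aligned within Alu-labelled target segments."""
        return sum(v for k, v in self.seg_query_bases.items() if k == ALU_LABEL)


def spliced_align(
    query: str,
    target_segments: Sequence[tuple[str, str]],
    scoring: Scoring = DEFAULT_SCORING,
) -> AlignmentResult:
    """Best spliced-local alignment of ``query`` against ordered labelled
    target segments, with free splice-like jumps at segment boundaries.

    ``target_segments`` is a list of ``(label, sequence)``; repeated labels
    accumulate in the per-segment base counts.
    """
    if not query:
        raise ValueError("empty query")
    if not target_segments:
        raise ValueError("no target segments")
    labels = [lab for lab, _ in target_segments]
    q = encode_sequence(query)
    parts = []
    segid_parts = []
    for idx, (_, seq) in enumerate(target_segments):
        parts.append(encode_sequence(seq))
        segid_parts.append(np.full(len(seq), idx, dtype=np.int32))
    t = np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)
    segid = np.concatenate(segid_parts) if segid_parts else np.empty(0, dtype=np.int32)
    if t.shape[0] == 0:
        return AlignmentResult(0.0, len(query), 0, 0, 0, 0, {lab: 0 for lab in labels})
    best, bi, bj, Hp, Ep, Fp, carg = _spliced_dp(
        q, t, segid, len(target_segments),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    if best <= 0.0:
        return AlignmentResult(0.0, len(query), 0, 0, 0, 0, {lab: 0 for lab in labels})
    matches, cols, seg_qbases, qstart, _tstart = _traceback(
        q, t, segid, len(target_segments), bi, bj, Hp, Ep, Fp, carg
    )
    seg_counts: dict[str, int] = {}
    for lab, cnt in zip(labels, seg_qbases):
        seg_counts[lab] = seg_counts.get(lab, 0) + int(cnt)
    return AlignmentResult(
        score=float(best),
        query_length=len(query),
        qstart=int(qstart),
        qend=int(bi),
        matches=int(matches),
        columns=int(cols),
        seg_query_bases=seg_counts,
    )


def local_align(query: str, target: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult:
    """Plain affine-gap local alignment (a single-segment spliced alignment)."""
    return spliced_align(query, [("target", target)], scoring)
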