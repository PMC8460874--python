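"""Independent brute-force oracles used by the test suite.

These are written from first principles, without reusing the package's
implementation code, so that agreement is evidence of correctness.
"""

from __future__ import annotations

NEG = float("-inf")


def spliced_score_oracle(
    query: str,
    segments: list[str],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_ext: float = -0.5,
) -> float:
    """Best local alignment score of query vs the segmented target, where the
    alignment may jump for free from any position of one segment to any
    position of a later segment.  Plain dictionary-of-rows DP, no traceback.
    """
    target = "".join(segments)
    seg_of = []
    for si, seg in enumerate(segments):
        seg_of.extend([si] * len(seg))
    n, m = len(query), len(target)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    # best H over all columns of segments strictly before segment s, per row
    nseg = len(segments)
    best_before = [[NEG] * (nseg + 1) for _ in range(n + 1)]
    best = 0.0
    # prefix maxima over segments, recomputed per row as columns fill in
    seg_row_max = [[NEG] * nseg for _ in range(n + 1)]
    for j in range(1, m + 1):
        s = seg_of[j - 1]
        for i in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_ext)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_ext)
            sub = match if query[i - 1] == target[j - 1] else mismatch
            carry = max((seg_row_max[i - 1][t] for t in range(s)), default=NEG)
            diag = max(H[i - 1][j - 1], carry)
            H[i][j] = max(0.0, diag + sub, E[i][j], F[i][j])
            if H[i][j] > seg_row_max[i][s]:
                seg_row_max[i][s] = H[i][j]
            if H[i][j] > best:
                best = H[i][j]
    return best


def overlap_components_oracle(intervals: list[tuple[int, int]]) -> list[set[int]]:
    """Connected components of the interval-overlap graph via networkx."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(intervals)))
    for a in range(len(intervals)):
        for b in range(a + 1, len(intervals)):
            s1, e1 = intervals[a]
            s2, e2 = intervals[b]
            if s1 <= e2 and s2 <= e1:
                g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g)]


def contig_paths_oracle(reads: list[str], k: int) -> set[str]:
    """Contig sequences as maximal unambiguous walks of the k-mer graph,
    enumerated recursively (no tip trimming)."""
    kmers = set()
    for r in reads:
        for i in range(len(r) - k + 1):
            kmers.add(r[i : i + k])
    succ: dict[str, set[str]] = {}
    pred: dict[str, set[str]] = {}
    nodes = set()
    for km in kmers:
        u, v = km[:-1], km[1:]
        succ.setdefault(u, set()).add(v)
        pred.setdefault(v, set()).add(u)
        nodes.update((u, v))

    def branching(v: str) -> bool:
        return len(succ.get(v, ())) != 1 or len(pred.get(v, ())) != 1

    contigs = set()
    for v in nodes:
        if not branching(v):
            continue
        for w in succ.get(v, ()):  # start a walk along each out-edge
            path = v + w[-1]
            cur = w
            while not branching(cur):
                cur = next(iter(succ[cur]))
                path += cur[-1]
            contigs.add(path)
    if not contigs and nodes:  # pure cycle
        v = min(nodes)
        path = v
        cur = next(iter(succ[v]))
        while cur != v:
            path += cur[-1]
            cur = next(iter(succ[cur]))
        path += cur[-1]
        contigs.add(path)
    return contigs
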