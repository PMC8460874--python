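import numpy as np
import pytest

from aluexon.align import AlignmentResult
from aluexon.caller import (
    Cluster,
    ContextParams,
    MateRecord,
    Vicinity,
    _passes_shadow,
    categorize_mate,
    cluster_anchors,
    context_filter,
    infer_insertion_intervals,
    signal_test,
)
from aluexon.io import GenomicInterval, ReadAlignmentRecord
from oracles import overlap_components_oracle


def result(coverage: float, identity: float, alu_bases: int) -> AlignmentResult:
    """Synthesize an AlignmentResult with the requested derived metrics."""
    qlen = 10000
    qend = int(round(coverage * qlen))
    cols = 10000
    matches = int(round(identity * cols))
    return AlignmentResult(
        score=float(matches),
        query_length=qlen,
        qstart=0,
        qend=qend,
        matches=matches,
        columns=cols,
        seg_query_bases={"Alu": alu_bases},
    )


class TestThresholdBoundaries:
    @pytest.mark.parametrize(
        "coverage,identity,alu_bases,expected",
        [
            (0.80, 0.81, 10, True),   # all three at their passing boundary
            (0.80, 0.80, 50, False),  # identity must strictly exceed 80%
            (0.95, 0.99, 9, False),   # one Alu base short
            (0.79, 0.99, 50, False),  # coverage below 80%
            (1.00, 1.00, 10, True),
        ],
    )
    def test_signal_boundaries(self, coverage, identity, alu_bases, expected):
        assert signal_test(result(coverage, identity, alu_bases)) is expected

    @pytest.mark.parametrize(
        "coverage,identity,expected",
        [
            (0.80, 0.93, True),   # both bounds inclusive
            (0.80, 0.929, False),
            (0.79, 0.99, False),
            (1.00, 1.00, True),
        ],
    )
    def test_shadow_boundaries(self, coverage, identity, expected):
        assert _passes_shadow(result(coverage, identity, 0)) is expected

    def test_thresholds_monotone(self, rng):
        """Improving identity or coverage never flips pass -> fail."""
        for _ in range(50):
            cov, ident = rng.random(), rng.random()
            base_sig = signal_test(result(cov, ident, 20))
            base_sha = _passes_shadow(result(cov, ident, 0))
            better = result(min(1.0, cov + 0.1), min(1.0, ident + 0.1), 20)
            if base_sig:
                assert signal_test(better)
            if base_sha:
                assert _passes_shadow(better)


class TestCategories:
    @pytest.mark.parametrize(
        "signal,shadow,category",
        [(True, False, "S"), (False, True, "RU"), (True, True, "SRU"), (False, False, "none")],
    )
    def test_partition(self, signal, shadow, category):
        assert categorize_mate(signal, shadow) == category

    def test_sn_includes_s_and_none(self):
        reads = [mate(100, 199, "+", cat) for cat in ("S", "S", "none", "RU", "SRU")]
        v = Vicinity("g", GenomicInterval("chr1", 100, 199), reads, [])
        assert (v.s, v.sn, v.ru, v.sru) == (2, 3, 1, 1)
        assert v.s <= v.sn


class TestContextFilter:
    PARAMS = ContextParams(2, 5, 0, 2, 0.5)

    @pytest.mark.parametrize(
        "s,sn,ru,sru,expected",
        [
            # hand-computed against conditions i-v at cutoffs (2, 5, 0, 2, 0.5)
            (2, 5, 0, 0, True),
            (1, 5, 0, 0, False),   # i fails
            (2, 4, 0, 0, False),   # ii fails
            (2, 5, 5, 0, False),   # v: 2/5 = 0.4 < 0.5
            (2, 5, 4, 0, True),    # v: 2/4 = 0.5
            (2, 5, 0, 1, True),    # iv: 2/1 = 2
            (2, 5, 0, 2, False),   # iv: 2/2 = 1 < 2
            (3, 6, 0, 1, True),
            (3, 6, 6, 0, True),    # v: 0.5 exactly
            (3, 6, 7, 0, False),
            (0, 5, 0, 0, False),
            (5, 5, 0, 0, True),
            (5, 10, 10, 2, True),  # 0.5, 2.5 pass
            (5, 10, 11, 2, False),
            (5, 10, 10, 3, False), # iv: 5/3 < 2
            (2, 5, 1, 1, True),    # 2/1=2, 2/1=2
            (2, 5, 2, 1, True),    # 2/2=1 >= 0.5
            (2, 5, 2, 2, False),
            (10, 10, 0, 5, True),  # iv: 2 exactly
            (10, 10, 0, 6, False),
        ],
    )
    def test_hand_computed_table(self, s, sn, ru, sru, expected):
        assert context_filter(s, sn, ru, sru, self.PARAMS) is expected

    def test_zero_denominator_counts_as_satisfied(self):
        assert context_filter(2, 5, 0, 0, ContextParams(2, 5, 0, 100, 100))


def mate(start, end, orientation="+", category="none", read_id=None):
    iv = GenomicInterval("chr1", start, end, orientation)
    anchor = ReadAlignmentRecord(
        read_id or f"r{start}-{end}-{orientation}-{category}", 1, True, iv, f"{end-start+1}M", "A" * (end - start + 1), False
    )
    m = MateRecord(anchor, "ACGT", GenomicInterval("chr1", start, end), "g1", orientation)
    m.category = category
    return m


class TestClustering:
    def test_mutually_overlapping_same_orientation_one_cluster(self):
        ms = [mate(100, 200, "+", "S", f"a{i}") for i in range(3)]
        clusters = cluster_anchors(ms)
        assert len(clusters) == 1 and len(clusters[0].reads) == 3

    def test_opposite_orientations_separate(self):
        clusters = cluster_anchors([mate(100, 200, "+", "S", "a"), mate(150, 250, "-", "S", "b")])
        assert len(clusters) == 2

    def test_categories_separate(self):
        clusters = cluster_anchors([mate(100, 200, "+", "S", "a"), mate(150, 250, "+", "RU", "b")])
        assert {c.category for c in clusters} == {"S", "RU"}

    def test_single_linkage_chain(self):
        # A overlaps B, B overlaps C, A does not overlap C -> one cluster
        ms = [mate(100, 200, "+", "S", "a"), mate(180, 300, "+", "S", "b"), mate(280, 400, "+", "S", "c")]
        clusters = cluster_anchors(ms)
        assert len(clusters) == 1
        assert clusters[0].interval == GenomicInterval("chr1", 100, 400)

    def test_matches_connected_components_oracle(self, rng):
        spans = []
        for _ in range(40):
            s = int(rng.integers(1, 5000))
            spans.append((s, s + int(rng.integers(50, 400))))
        ms = [mate(s, e, "+", "S", f"r{i}") for i, (s, e) in enumerate(spans)]
        clusters = cluster_anchors(ms)
        got = sorted(
            sorted(int(m.anchor.read_id[1:]) for m in c.reads) for c in clusters
        )
        expected = sorted(sorted(c) for c in overlap_components_oracle(spans))
        assert got == expected


class TestInsertionInterval:
    def make_vicinity(self, clusters):
        return Vicinity("g1", GenomicInterval("chr1", 1, 10000), [], clusters)

    def cluster(self, start, end, orientation, category="S"):
        return Cluster(GenomicInterval("chr1", start, end), orientation, category, [])

    def test_interval_to_nearest_opposing_cluster(self):
        v = self.make_vicinity([self.cluster(1000, 1150, "+"), self.cluster(2400, 2500, "-", "RU")])
        gene = GenomicInterval("chr1", 1, 10000)
        assert infer_insertion_intervals(v, gene) == [GenomicInterval("chr1", 1150, 2400)]

    def test_gene_end_fallback(self):
        v = self.make_vicinity([self.cluster(1000, 1150, "+")])
        gene = GenomicInterval("chr1", 1, 9999)
        assert infer_insertion_intervals(v, gene) == [GenomicInterval("chr1", 1150, 9999)]

    def test_two_s_clusters_two_intervals(self):
        v = self.make_vicinity([self.cluster(1000, 1150, "+"), self.cluster(3000, 3100, "+")])
        gene = GenomicInterval("chr1", 1, 9999)
        assert len(infer_insertion_intervals(v, gene)) == 2

    def test_minus_orientation_searches_upstream(self):
        v = self.make_vicinity([self.cluster(5000, 5100, "-"), self.cluster(2000, 2100, "+", "RU")])
        gene = GenomicInterval("chr1", 1, 9999)
        assert infer_insertion_intervals(v, gene) == [GenomicInterval("chr1", 2100, 5000)]

    def test_no_s_cluster_is_an_error(self):
        v = self.make_vicinity([self.cluster(1000, 1150, "+", "RU")])
        with pytest.raises(ValueError):
            infer_insertion_intervals(v, GenomicInterval("chr1", 1, 9999))


class TestEndToEnd:
    def test_planted_insertions_recovered_and_clean_genes_silent(self, insertion_study):
        """Default parameters recover >=90% of planted insertion genes and make
        no call in genes without a planted event."""
        predicted = insertion_study.predicted_genes(ContextParams())
        gold = insertion_study.gold_genes
        assert len(predicted & gold) / len(gold) >= 0.9
        assert predicted - gold == set()

    def test_insertion_intervals_lie_within_their_genes(self, insertion_study):
        for call in insertion_study.calls():
            span = insertion_study.annotation.genes[call.gene_id].span()
            assert span.contains(call.insertion_interval)

    def test_vicinity_counts_consistent(self, insertion_study):
        for v in insertion_study.vicinities:
            assert v.s <= v.sn
            cats = [m.category for m in v.reads]
            assert v.s + v.ru + v.sru + cats.count("none") == len(v.reads)

    def test_shadow_only_vicinities_never_called(self, insertion_study):
        shadow_only = [v for v in insertion_study.vicinities if v.s == 0 and (v.ru or v.sru)]
        assert shadow_only, "simulation should produce shadow-read vicinities"
        assert all(not context_filter(v.s, v.sn, v.ru, v.sru, ContextParams()) for v in shadow_only)
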