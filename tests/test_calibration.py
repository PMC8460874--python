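import itertools

import numpy as np
import pandas as pd
import pytest

from aluexon.caller import ContextParams, context_filter
from aluexon.calibration import (
    DEFAULT_GRID,
    CalibrationPoint,
    evaluate,
    excise_alus,
    grid_search,
    lift_alus,
    predicted_genes_for_params,
    select_alus_for_excision,
)
from aluexon.io import AluAnnotation, GenomicInterval, TranscriptModel, fetch_sequence
from aluexon.simulate import SimConfig, generate_locus_set


class TestExcision:
    def test_single_excision_shift_arithmetic(self):
        genome = {"chr1": "A" * 10000}
        alus = [AluAnnotation(GenomicInterval("chr1", 5000, 5299, "-"), "AluY")]
        tx = TranscriptModel("t", "g", "+", [GenomicInterval("chr1", 6000, 6100, "+")])
        _, lifted, plan = excise_alus(genome, alus, [tx])
        assert lifted[0].exons[0] == GenomicInterval("chr1", 5700, 5800, "+")

    def test_two_excisions_shift_by_sum(self):
        genome = {"chr1": "A" * 20000}
        alus = [
            AluAnnotation(GenomicInterval("chr1", 2000, 2299, "-"), "AluY"),
            AluAnnotation(GenomicInterval("chr1", 5000, 5199, "-"), "AluY"),
        ]
        tx = TranscriptModel("t", "g", "+", [GenomicInterval("chr1", 9000, 9100, "+")])
        new_genome, lifted, plan = excise_alus(genome, alus, [tx])
        assert lifted[0].exons[0].start == 9000 - 300 - 200
        assert len(new_genome["chr1"]) == 20000 - 500

    def test_exon_overlapping_alu_not_excised(self):
        genome = {"chr1": "A" * 10000}
        alus = [AluAnnotation(GenomicInterval("chr1", 5000, 5299, "-"), "AluY")]
        tx = TranscriptModel("t", "g", "+", [GenomicInterval("chr1", 5100, 5200, "+")])
        _, lifted, plan = excise_alus(genome, alus, [tx])
        assert plan.excised_alus == []
        assert lifted[0].exons[0] == tx.exons[0]

    def test_lifted_exon_sequences_identical(self):
        """Excision + lift preserves every exon's base content."""
        ls = generate_locus_set(SimConfig(seed=5, n_genes=8))
        new_genome, lifted, plan = excise_alus(ls.genome, ls.repeats, ls.annotation)
        assert plan.excised_alus  # intronic copies are all excisable
        by_id = {t.transcript_id: t for t in ls.annotation}
        for tx in lifted:
            orig = by_id[tx.transcript_id]
            for ex_new, ex_old in zip(tx.exons, orig.exons):
                assert fetch_sequence(new_genome, ex_new) == fetch_sequence(ls.genome, ex_old)
        assert plan.gold_genes == {t.gene_id for t in ls.annotation}

    def test_shift_then_unshift_is_identity(self):
        ls = generate_locus_set(SimConfig(seed=6, n_genes=5))
        _, _, plan = excise_alus(ls.genome, ls.repeats, ls.annotation)
        rng = np.random.default_rng(0)
        excised_spans = [(a.interval.start, a.interval.end) for a in plan.excised_alus]
        for pos in rng.integers(1, len(ls.genome["chr1"]), size=100):
            pos = int(pos)
            if any(s <= pos <= e for s, e in excised_spans):
                continue  # deleted bases have no image
            assert plan.unshift("chr1", plan.shift("chr1", pos)) == pos

    def test_sampling_with_replacement_deduplicates(self):
        alus = [
            AluAnnotation(GenomicInterval("chr1", 1000 * i + 1, 1000 * i + 300, "-"), "AluY")
            for i in range(50)
        ]
        rng = np.random.default_rng(0)
        chosen = select_alus_for_excision(alus, 100, rng)
        assert len(chosen) < 100
        assert len({(a.interval.start) for a in chosen}) == len(chosen)

    def test_lift_alus_drops_excised(self):
        ls = generate_locus_set(SimConfig(seed=7, n_genes=4))
        _, _, plan = excise_alus(ls.genome, ls.repeats[:2], ls.annotation)
        survivors = lift_alus(ls.repeats, plan)
        assert len(survivors) == len(ls.repeats) - len(plan.excised_alus)


class TestEvaluate:
    def test_published_style_worked_counts(self):
        gold = {f"g{i}" for i in range(954)}
        predicted = {f"g{i}" for i in range(291)} | {f"x{i}" for i in range(231)}
        point = evaluate(predicted, gold)
        assert (point.tp, point.fp) == (291, 231)
        assert round(point.sn, 3) == 0.305
        assert round(point.pr, 3) == 0.557
        assert round(point.f_value, 3) == 0.394
        assert round(point.acc, 3) == 0.431

    def test_perfect_and_disjoint_predictions(self):
        gold = {"a", "b"}
        perfect = evaluate(gold, gold)
        assert (perfect.sn, perfect.pr, perfect.f_value, perfect.acc) == (1, 1, 1, 1)
        disjoint = evaluate({"c"}, gold)
        assert (disjoint.sn, disjoint.pr, disjoint.f_value) == (0, 0, 0)

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            evaluate({"a"}, set())

    def test_metric_bounds(self, rng):
        universe = [f"g{i}" for i in range(30)]
        for _ in range(20):
            gold = set(rng.choice(universe, size=10, replace=False))
            predicted = set(rng.choice(universe, size=int(rng.integers(0, 20)), replace=False))
            p = evaluate(predicted, gold)
            assert 0 <= p.sn <= 1 and 0 <= p.pr <= 1 and 0 <= p.acc <= 1
            assert p.f_value <= min(2 * p.sn, 2 * p.pr) + 1e-12


class TestGridSearch:
    def make_counts(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4"],
                "chrom": ["chr1"] * 4,
                "start": [1, 1, 1, 1],
                "end": [2, 2, 2, 2],
                "s": [5, 2, 0, 1],
                "sn": [6, 5, 4, 9],
                "ru": [0, 3, 5, 0],
                "sru": [1, 0, 2, 4],
            }
        )

    def test_single_tuple_grid(self):
        grid = {k: (v,) for k, v in zip(
            ("min_signals", "min_signalnone", "min_s2sn", "min_s2sru", "min_s2ru"),
            (2, 5, 0, 2, 0.5),
        )}
        points = grid_search(self.make_counts(), {"g1", "g3"}, grid)
        assert len(points) == 1
        assert points[0].params.as_tuple() == (2, 5, 0, 2, 0.5)

    def test_default_grid_size(self):
        sizes = [len(v) for v in DEFAULT_GRID.values()]
        assert np.prod(sizes) == 2 * 10 * 6 * 5 * 7 == 4200

    def test_ranking_matches_exhaustive_rescoring(self):
        counts = self.make_counts()
        gold = {"g1", "g2"}
        grid = {
            "min_signals": (1, 2),
            "min_signalnone": (4, 6),
            "min_s2sn": (0.0,),
            "min_s2sru": (0.0, 2.0),
            "min_s2ru": (0.0, 0.5),
        }
        points = grid_search(counts, gold, grid)
        assert len(points) == 16
        for point in points:
            predicted = {
                row.gene_id
                for row in counts.itertuples()
                if context_filter(row.s, row.sn, row.ru, row.sru, point.params)
            }
            assert point.tp == len(predicted & gold)
            assert point.fp == len(predicted - gold)
        fs = [p.f_value for p in points]
        assert fs == sorted(fs, reverse=True)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(self.make_counts(), {"g1"}, {**DEFAULT_GRID, "min_signals": ()})

    def test_best_tuple_recovers_planted_signal_depth(self, insertion_study):
        """On simulated data with >=5 true signal pairs per insertion, the
        top-F tuple's MIN_SIGNALS stays at or below the planted depth and the
        best F-value is perfect separation."""
        points = grid_search(insertion_study.vicinity_counts, insertion_study.gold_genes)
        best = points[0]
        assert best.f_value == 1.0
        assert best.params.min_signals <= 5
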