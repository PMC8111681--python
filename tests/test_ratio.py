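import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_expr, make_surv
from ratiosurv.containers import ValidationError
from ratiosurv.ratio import (RatioScreen, RatioSpec, ScreenConfig,
                             assemble_pools, auc, cross_platform_validate,
                             enumerate_ratios, horizon_labels, ratio_score)


class TestEnumerate:
    def test_single_gene_pools_full_dedup(self):
        specs = enumerate_ratios(["a"], ["b"], ScreenConfig(sizes=(1,)))
        assert len(specs) == 1

    def test_pools_3_2_with_full(self):
        cfg = ScreenConfig(sizes=(1, 2))
        specs = enumerate_ratios(["a", "b", "c"], ["x", "y"], cfg)
        # 3*2 + 3*1 + distinct full 3:2
        assert len(specs) == 10
        assert specs[-1] == RatioSpec(("a", "b", "c"), ("x", "y"))

    def test_count_formula_random_pools(self, rng):
        for _ in range(20):
            n, d = rng.integers(1, 9), rng.integers(1, 9)
            sizes = tuple(range(1, rng.integers(2, 5)))
            num = [f"n{i}" for i in range(n)]
            den = [f"d{i}" for i in range(d)]
            cfg = ScreenConfig(sizes=sizes, include_full=True)
            specs = enumerate_ratios(num, den, cfg)
            expect = sum(math.comb(n, k) * math.comb(d, k) for k in sizes)
            if not (n == d and n in sizes):
                expect += 1  # distinct full ratio appended
            assert len(specs) == expect
            assert len(set(specs)) == len(specs)

    def test_overlapping_pools_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_ratios(["a", "b"], ["b", "c"])

    def test_deterministic_order(self):
        a = enumerate_ratios(["a", "b"], ["x", "y"], ScreenConfig(sizes=(1, 2)))
        b = enumerate_ratios(["a", "b"], ["x", "y"], ScreenConfig(sizes=(1, 2)))
        assert a == b


class TestRatioScore:
    def test_unscaled_sum(self):
        expr = make_expr([[6.0], [4.0], [2.0], [3.0]])
        spec = RatioSpec(("g0", "g1"), ("g2", "g3"))
        s = ratio_score(expr, spec, scale=False)
        assert s.iloc[0] == pytest.approx(2.0)

    def test_within_sample_scale_invariance(self, rng):
        arr = rng.uniform(1, 10, (6, 5))
        expr = make_expr(arr)
        arr2 = arr.copy()
        arr2[:, 2] *= 7.0
        expr2 = make_expr(arr2)
        spec = RatioSpec(("g0", "g1"), ("g3", "g4"))
        s1 = ratio_score(expr, spec, scale=False)
        s2 = ratio_score(expr2, spec, scale=False)
        np.testing.assert_allclose(s1, s2)

    def test_swap_equivariance(self, rng):
        expr = make_expr(rng.uniform(1, 10, (6, 8)))
        spec = RatioSpec(("g0", "g1"), ("g3", "g4"))
        rev = RatioSpec(("g3", "g4"), ("g0", "g1"))
        np.testing.assert_allclose(ratio_score(expr, spec),
                                   1.0 / ratio_score(expr, rev))

    def test_hand_unit_median_scaling(self):
        # medians: g0 -> 2, g1 -> 4, g2 -> 8
        expr = make_expr([[1.0, 2.0, 4.0],
                          [2.0, 4.0, 8.0],
                          [4.0, 8.0, 16.0]])
        spec = RatioSpec(("g0", "g1"), ("g2",))
        s = ratio_score(expr, spec)
        # scaled columns: g0 [.5,1,2], g1 [.5,1,2], g2 [.5,1,2]
        np.testing.assert_allclose(s, [2.0, 2.0, 2.0])

    def test_missing_gene_rejected(self, rng):
        expr = make_expr(rng.uniform(1, 5, (2, 3)))
        with pytest.raises(ValidationError, match="absent"):
            ratio_score(expr, RatioSpec(("g0",), ("nope",)))


class TestHorizonLabels:
    def test_hand_example(self):
        surv = make_surv([10, 20, 30, 40], [1, 0, 1, 0])
        lab = horizon_labels(surv, 25.0)
        assert lab.tolist() == [1, -1, 0, 0]

    def test_horizon_before_all_times(self):
        surv = make_surv([10, 20], [1, 0])
        lab = horizon_labels(surv, 5.0)
        assert (lab == 0).all()

    def test_all_events_before_horizon(self):
        surv = make_surv([1, 2], [1, 1])
        lab = horizon_labels(surv, 10.0)
        assert (lab == 1).all()

    def test_event_at_horizon_is_positive(self):
        surv = make_surv([25.0], [1])
        assert horizon_labels(surv, 25.0).iloc[0] == 1


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 1, 0, 0], [0, 0, 1, 1]) == 1.0

    def test_all_tied(self):
        assert auc([2, 2, 2, 2], [0, 0, 1, 1]) == 0.5

    def test_brute_force_four_pairs(self):
        # pos scores [1, 3], neg [2, 4]: neg>pos in 3 of 4 pairs
        assert auc([1, 3, 2, 4], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_matches_sklearn_trapezoid(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(50):
            n = rng.integers(6, 40)
            scores = rng.choice(np.linspace(0, 1, 7), n)  # forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            ours = auc(scores, labels)
            ref = roc_auc_score(1 - labels, scores)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([1, 2], [1, 1])


class TestScreen:
    def test_single_combo(self, rng):
        expr = make_expr(rng.uniform(1, 5, (2, 50)))
        surv = make_surv(rng.uniform(1, 100, 50), rng.integers(0, 2, 50))
        cfg = ScreenConfig(sizes=(1,), horizons=(50.0,))
        res = RatioScreen(expr, surv, ["g0"], ["g1"], cfg).fit()
        assert len(res.table) == 1

    def test_null_mean_auc_near_half(self, rng):
        n = 400
        expr = make_expr(2.0 ** rng.normal(5, 1, (8, n)))
        surv = make_surv(np.ceil(rng.exponential(60, n)),
                         rng.integers(0, 2, n))
        cfg = ScreenConfig(sizes=(1, 2), horizons=(40.0,))
        res = RatioScreen(expr, surv, [f"g{i}" for i in range(4)],
                          [f"g{i}" for i in range(4, 8)], cfg).fit()
        assert res.table["mean_auc"].mean() == pytest.approx(0.5, abs=0.02)

    def test_rerun_reproduces_identical_table(self, small_cohort):
        c = small_cohort
        num = list(c.planted.numerator)
        den = list(c.planted.denominator)
        cfg = ScreenConfig(sizes=(1, 2, 3), horizons=(1000.0, 2000.0))
        t1 = RatioScreen(c.expr, c.survival, num, den, cfg).fit().table
        t2 = RatioScreen(c.expr, c.survival, num, den, cfg).fit().table
        assert t1.to_csv() == t2.to_csv()

    def test_vectorized_scores_match_ratio_score(self, small_cohort):
        c = small_cohort
        num = list(c.planted.numerator)
        den = list(c.planted.denominator)
        cfg = ScreenConfig(sizes=(1, 2, 3), horizons=(1000.0,))
        screen = RatioScreen(c.expr, c.survival, num, den, cfg)
        specs = enumerate_ratios(num, den, cfg)
        mat = screen._score_matrix(specs)
        for j in (0, 5, len(specs) - 1):
            direct = ratio_score(c.expr, specs[j]).loc[
                screen.records.sample_ids]
            np.testing.assert_allclose(mat[:, j], direct, rtol=1e-10)


class TestPools:
    def test_dedup_preserves_order(self):
        num, den = assemble_pools(
            {"a": ["x", "y"], "b": ["y", "z"]}, {"c": ["q"]})
        assert num == ["x", "y", "z"] and den == ["q"]

    def test_both_sides_rejected(self):
        with pytest.raises(ValidationError):
            assemble_pools({"a": ["x"]}, {"b": ["x"]})


class TestCrossPlatform:
    def test_identical_cohort_identical_auc(self, small_cohort):
        c = small_cohort
        cfg = ScreenConfig(horizons=(1000.0, 2000.0))
        row1 = cross_platform_validate(c.planted, c.expr, c.survival, cfg)
        row2 = cross_platform_validate(c.planted, c.expr, c.survival, cfg)
        pd.testing.assert_series_equal(row1, row2)

    def test_same_truth_resimulation_close(self):
        from ratiosurv.simulate import SimulationConfig, simulate_cohort
        base = dict(n_genes=60, n_samples=400, module_sizes=(20, 20),
                    gamma=-1.0)
        c1 = simulate_cohort(SimulationConfig(seed=21, **base))
        c2 = simulate_cohort(SimulationConfig(seed=22, **base))
        cfg = ScreenConfig(horizons=(1500.0,))
        a1 = cross_platform_validate(c1.planted, c1.expr, c1.survival, cfg)
        a2 = cross_platform_validate(c2.planted, c2.expr, c2.survival, cfg)
        assert abs(a1["auc@1500"] - a2["auc@1500"]) < 0.05

    def test_shuffled_survival_null(self, rng):
        from ratiosurv.simulate import SimulationConfig, simulate_cohort
        c = simulate_cohort(SimulationConfig(
            n_genes=60, n_samples=2000, module_sizes=(20, 20),
            gamma=-1.0, seed=9))
        perm = rng.permutation(c.survival.sample_ids)
        shuffled = make_surv(c.survival.time.loc[perm].to_numpy(),
                             c.survival.event.loc[perm].to_numpy(),
                             prefix="S")
        shuffled.time.index = c.survival.sample_ids
        shuffled.event.index = c.survival.sample_ids
        cfg = ScreenConfig(horizons=(1500.0,))
        row = cross_platform_validate(c.planted, c.expr, shuffled, cfg)
        assert row["auc@1500"] == pytest.approx(0.5, abs=0.03)

    def test_missing_gene_rejected(self, rng):
        expr = make_expr(rng.uniform(1, 5, (2, 10)))
        surv = make_surv(rng.uniform(1, 50, 10), np.ones(10, dtype=int))
        with pytest.raises(ValidationError, match="missing"):
            cross_platform_validate(RatioSpec(("zz",), ("g0",)), expr, surv)


class TestGeneFrequency:
    def test_counts_genes_among_top_ranked(self, small_cohort):
        c = small_cohort
        num = list(c.planted.numerator)
        den = list(c.planted.denominator)
        cfg = ScreenConfig(sizes=(1, 2, 3), horizons=(1500.0,), top_n=10)
        res = RatioScreen(c.expr, c.survival, num, den, cfg).fit()
        freq = res.gene_frequency()
        assert freq.max() <= 10
        assert set(freq.index) <= set(num + den)
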