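import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_expr
from ratiosurv.containers import ConfigError, TraitTable, ValidationError
from ratiosurv.network import (CoexpressionNetwork, NetworkConfig, adjacency,
                               bicor, bicor_matrix, bicor_pvalue,
                               detect_modules, kme, module_eigengenes,
                               module_relatedness, module_trait_stats,
                               regress_covariates, tom)


def bicor_oracle(x, y):
    """Direct textbook biweight-midcorrelation formula, coded independently."""
    def wvec(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        a = np.where(np.abs(u) < 1, 1.0, 0.0)
        return (v - med) * (1 - u**2) ** 2 * a
    xs, ys = wvec(x), wvec(y)
    return np.sum(xs * ys) / np.sqrt(np.sum(xs**2) * np.sum(ys**2))


class TestBicor:
    def test_self_correlation(self, rng):
        x = rng.normal(0, 1, 30)
        assert bicor(x, x) == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x = rng.normal(0, 1, 30)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            x, y = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
            assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_too_short(self):
        with pytest.raises(ValidationError):
            bicor([1.0, 2.0], [3.0, 4.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            bicor(np.ones(10), np.arange(10.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100),
           seed=st.integers(0, 100))
    def test_positive_affine_invariance(self, scale, shift, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(0, 1, 25), r.normal(0, 1, 25)
        assert bicor(scale * x + shift, y) == pytest.approx(bicor(x, y),
                                                            abs=1e-9)

    def test_matrix_agrees_with_pairwise(self, rng):
        rows = rng.normal(0, 1, (6, 40))
        m = bicor_matrix(rows)
        assert np.allclose(m, m.T)
        for i in range(6):
            for j in range(i + 1, 6):
                assert m[i, j] == pytest.approx(bicor(rows[i], rows[j]),
                                                abs=1e-12)


class TestAdjacencyTom:
    @pytest.mark.parametrize("r,expected", [(1.0, 1.0), (-1.0, 0.0),
                                            (0.0, 0.5**6)])
    def test_signed_powers(self, r, expected):
        corr = np.array([[1.0, r], [r, 1.0]])
        a = adjacency(corr, NetworkConfig(beta=6, signed=True))
        assert a[0, 1] == pytest.approx(expected)

    def test_beta_below_one_rejected(self):
        with pytest.raises(ConfigError):
            NetworkConfig(beta=0.5)

    def test_triangle_closed_form(self):
        # all off-diagonal entries equal: TOM_ij reduces to a
        for a_val in (0.1, 0.4, 0.9):
            adj = np.full((3, 3), a_val)
            np.fill_diagonal(adj, 1.0)
            t = tom(adj)
            assert t[0, 1] == pytest.approx(a_val)

    def test_identity_adjacency(self):
        t = tom(np.eye(5))
        off = t[~np.eye(5, dtype=bool)]
        assert np.all(off == 0)

    def test_matches_naive_loop_oracle(self, rng):
        for _ in range(10):
            n = 6
            a = rng.uniform(0, 1, (n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            t = tom(a)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    num = sum(a[i, u] * a[u, j] for u in range(n)
                              if u not in (i, j)) + a[i, j]
                    ki = sum(a[i, u] for u in range(n) if u != i)
                    kj = sum(a[j, u] for u in range(n) if u != j)
                    expect = num / (min(ki, kj) + 1 - a[i, j])
                    assert t[i, j] == pytest.approx(expect, abs=1e-12)

    def test_asymmetric_rejected(self):
        a = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValidationError):
            tom(a)


class TestDetectModules:
    def _expr_from_blocks(self, rng, n=100, block=50, within=0.9, between=-0.2):
        f = rng.standard_normal(n)
        noise_sd = np.sqrt(1 / within - 1)
        X = np.vstack([f + noise_sd * rng.standard_normal((block, n)),
                       -f + noise_sd * rng.standard_normal((block, n))])
        return make_expr(2.0 ** (X + 6))

    def test_planted_blocks_recovered(self, rng):
        expr = self._expr_from_blocks(rng)
        res = CoexpressionNetwork(expr, NetworkConfig(min_module_size=10)).fit()
        labels = res.modules.labels
        assert set(labels.unique()) == {"M1", "M2"}
        first = labels.iloc[:50]
        second = labels.iloc[50:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_noise_genes_unassigned(self, rng):
        X = rng.standard_normal((150, 80))
        expr = make_expr(2.0 ** (X + 6))
        res = CoexpressionNetwork(expr, NetworkConfig(min_module_size=10)).fit()
        frac = (res.modules.labels == "UNASSIGNED").mean()
        assert frac >= 0.9

    def test_duplicated_rows_single_module(self, rng):
        row = rng.uniform(1, 10, 60)
        expr = make_expr(np.tile(row, (12, 1)))
        diss = 1 - tom(adjacency(bicor_matrix(np.log2(expr.values + 1)),
                                 NetworkConfig(min_module_size=5)))
        assign = detect_modules(diss, expr.gene_ids,
                                NetworkConfig(min_module_size=5))
        assert assign.labels.nunique() == 1
        assert assign.labels.iloc[0] == "M1"

    def test_anticorrelated_pair_merges_in_unsigned_mode(self, rng):
        expr = self._expr_from_blocks(rng)
        res = CoexpressionNetwork(
            expr, NetworkConfig(min_module_size=10, signed=False)).fit()
        # unsigned network cannot separate the anticorrelated blocks
        m1 = res.modules.members("M1")
        assert any(g in m1 for g in expr.gene_ids[:50])
        assert any(g in m1 for g in expr.gene_ids[50:])


class TestEigengenesKme:
    def test_rank_one_module(self, rng):
        from ratiosurv.network import ModuleAssignment
        profile = rng.uniform(1, 10, 30)
        expr = make_expr(np.tile(profile, (5, 1)))
        assign = ModuleAssignment(pd.Series("M1", index=expr.gene_ids))
        me = module_eigengenes(expr, assign)
        assert me.variance_explained["M1"] == pytest.approx(1.0)
        z = np.log2(profile + 1)
        z = (z - z.mean()) / z.std()
        v = me.values["M1"].to_numpy()
        assert abs(np.corrcoef(v, z)[0, 1]) == pytest.approx(1.0)

    def test_sign_orientation(self, small_cohort):
        c = small_cohort
        assign_labels = c.true_modules.copy()
        from ratiosurv.network import ModuleAssignment
        assign = ModuleAssignment(assign_labels.replace(
            {"NOISE": "UNASSIGNED", "TM1": "M1", "TM2": "M2",
             "TM3": "M3", "TM4": "M4"}))
        me = module_eigengenes(c.expr, assign)
        km = kme(c.expr, me, assign)
        for m in me.modules:
            members = assign.members(m)
            assert km.kme.loc[members, m].mean() > 0

    def test_two_gene_module_matches_svd_oracle(self, rng):
        expr = make_expr(rng.uniform(1, 10, (2, 20)))
        from ratiosurv.network import ModuleAssignment
        assign = ModuleAssignment(pd.Series(["M1", "M1"], index=expr.gene_ids))
        me = module_eigengenes(expr, assign)
        z = np.log2(expr.values.to_numpy() + 1)
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        assert abs(np.dot(me.values["M1"], vt[0])) > 1 - 1e-10

    def test_gene_identical_to_eigengene(self, small_cohort, rng):
        c = small_cohort
        from ratiosurv.network import ModuleAssignment
        assign = ModuleAssignment(c.true_modules.replace(
            {"NOISE": "UNASSIGNED", "TM1": "M1", "TM2": "M2",
             "TM3": "M3", "TM4": "M4"}))
        me = module_eigengenes(c.expr, assign)
        km = kme(c.expr, me, assign)
        # duplicated genes in a module: own kME well above hub threshold
        dup_expr = make_expr(np.tile(rng.uniform(1, 5, 40), (6, 1)))
        dup_assign = ModuleAssignment(
            pd.Series("M1", index=dup_expr.gene_ids))
        dme = module_eigengenes(dup_expr, dup_assign)
        dkm = kme(dup_expr, dme, dup_assign)
        assert dkm.hub.all()
        assert np.allclose(dkm.kme["M1"], 1.0)

    def test_random_gene_low_kme(self, rng):
        n = 200
        f = rng.standard_normal(n)
        X = np.vstack([f + 0.3 * rng.standard_normal((10, n)),
                       rng.standard_normal((1, n))])  # last gene independent
        expr = make_expr(2.0 ** (X + 6))
        from ratiosurv.network import ModuleAssignment
        labels = pd.Series(["M1"] * 10 + ["UNASSIGNED"], index=expr.gene_ids)
        assign = ModuleAssignment(labels)
        me = module_eigengenes(expr, assign)
        km = kme(expr, me, assign)
        assert abs(km.kme.loc["g10", "M1"]) < 0.3
        # cross-check against a direct Pearson computation
        logg = np.log2(expr.values.loc["g10"] + 1)
        expect = np.corrcoef(logg, me.values["M1"])[0, 1]
        assert km.kme.loc["g10", "M1"] == pytest.approx(expect, abs=1e-12)


class TestTraitStats:
    def _me_traits(self, rng, n=120):
        from ratiosurv.network import EigengeneMatrix
        vals = rng.standard_normal((n, 2))
        vals /= np.linalg.norm(vals, axis=0)
        samples = [f"s{i}" for i in range(n)]
        me = EigengeneMatrix(pd.DataFrame(vals, index=samples,
                                          columns=["M1", "M2"]),
                             {"M1": 0.5, "M2": 0.5})
        subtype = rng.choice(["LumA", "LumB", "HER2", "TNBC"], n)
        traits = TraitTable(pd.DataFrame({
            "subtype": subtype, "TNBC": (subtype == "TNBC").astype(int),
            "age": rng.uniform(30, 80, n)}, index=samples))
        return me, traits

    def test_trait_equal_to_eigengene(self, rng):
        me, traits = self._me_traits(rng)
        traits.table["echo"] = me.values["M1"]
        res = module_trait_stats(me, traits)
        row = res[(res.module == "M1") & (res.trait == "echo")].iloc[0]
        assert row.bicor == pytest.approx(1.0)
        assert row.p == np.finfo(float).tiny

    def test_student_t_hand_computation(self):
        # n=6 hand data: r known, t = r sqrt(4)/sqrt(1-r^2)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.1, 2.3, 2.8, 4.2, 4.9, 6.4])
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt(4) / np.sqrt(1 - r**2)
        from scipy import stats as ss
        assert bicor_pvalue(r, 6) == pytest.approx(2 * ss.t.sf(abs(t), 4))

    def test_null_kruskal_uniform(self, rng):
        from scipy import stats as ss
        ps = []
        for _ in range(500):
            groups = [rng.standard_normal(12) for _ in range(4)]
            ps.append(ss.kruskal(*groups).pvalue)
        assert ss.kstest(ps, "uniform").pvalue > 0.01


class TestRelatedness:
    def test_identical_eigengenes_merge_at_zero(self, rng):
        from ratiosurv.network import EigengeneMatrix
        v = rng.standard_normal(30)
        me = EigengeneMatrix(pd.DataFrame({"M1": v, "M2": v,
                                           "M3": rng.standard_normal(30)}))
        link, flat = module_relatedness(me)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert flat["M1"] == flat["M2"]

    def test_anticorrelated_pair_distance_two(self, rng):
        from ratiosurv.network import EigengeneMatrix
        v = rng.standard_normal(30)
        me = EigengeneMatrix(pd.DataFrame({"M1": v, "M2": -v}))
        link, _ = module_relatedness(me)
        assert link[-1, 2] == pytest.approx(2.0, abs=1e-12)


class TestRegressCovariates:
    def test_zero_covariates_identity(self, rng):
        expr = make_expr(rng.uniform(1, 10, (5, 20)))
        traits = TraitTable(pd.DataFrame(index=expr.sample_ids))
        out = regress_covariates(expr, traits, [])
        pd.testing.assert_frame_equal(out.values, expr.values)

    def test_residual_orthogonal_to_covariate(self, rng):
        n = 100
        age = rng.uniform(30, 80, n)
        logx = 2.0 * age / 10 + rng.normal(0, 0.5, n)
        expr = make_expr(2.0 ** logx[None, :])
        traits = TraitTable(pd.DataFrame({"age": age},
                                         index=expr.sample_ids))
        out = regress_covariates(expr, traits, ["age"])
        resid = np.log2(out.values.to_numpy()[0] + 1.0)
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-8

    def test_binary_covariate_equalizes_group_means(self, rng):
        n = 60
        grp = rng.integers(0, 2, n).astype(float)
        logx = 3.0 + grp * 2.0 + rng.normal(0, 0.3, n)
        expr = make_expr(2.0 ** logx[None, :])
        traits = TraitTable(pd.DataFrame({"grp": grp}, index=expr.sample_ids))
        out = regress_covariates(expr, traits, ["grp"])
        resid = np.log2(out.values.to_numpy()[0] + 1.0)
        assert resid[grp == 1].mean() == pytest.approx(resid[grp == 0].mean(),
                                                       abs=1e-8)

    def test_collinear_rejected(self, rng):
        n = 30
        a = rng.uniform(0, 1, n)
        expr = make_expr(rng.uniform(1, 5, (3, n)))
        traits = TraitTable(pd.DataFrame({"a": a, "b": 2 * a},
                                         index=expr.sample_ids))
        with pytest.raises(ValidationError, match="collinear"):
            regress_covariates(expr, traits, ["a", "b"])


class TestSoftThreshold:
    def test_block_structure_yields_choice_and_table(self, rng):
        from ratiosurv.network import pick_soft_threshold
        f = rng.standard_normal(80)
        X = np.vstack([f + 0.6 * rng.standard_normal((40, 80)),
                       rng.standard_normal((60, 80))])
        corr = np.corrcoef(X)
        beta, table = pick_soft_threshold(corr, betas=[2, 4, 6, 8, 12])
        assert set(table.columns) == {"beta", "r2", "mean_k"}
        assert len(table) == 5
        # connectivity falls as beta grows
        assert table["mean_k"].is_monotonic_decreasing
        if beta is not None:
            assert table.loc[table.beta == beta, "r2"].iloc[0] >= 0.8
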