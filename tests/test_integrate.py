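import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nlpipe import (
    DataModelError,
    LipidomeMatrix,
    ancom_w,
    clr_transform,
    conditional_attenuation,
    dietary_pca,
    fisher_exact,
    lipidome_profile,
    nested_lrt,
    variance_dissection,
)


class TestClr:
    def test_uniform_composition_maps_to_zero(self):
        np.testing.assert_allclose(clr_transform([1 / 3, 1 / 3, 1 / 3]), 0.0, atol=1e-12)

    def test_reference_values(self):
        out = clr_transform([0.5, 0.25, 0.25])
        gm = (0.5 * 0.25 * 0.25) ** (1 / 3)
        np.testing.assert_allclose(out, np.log(np.array([0.5, 0.25, 0.25]) / gm), atol=1e-12)
        np.testing.assert_allclose(out, [0.462, -0.231, -0.231], atol=5e-4)

    def test_rows_sum_to_zero_and_closure_invariance(self, rng):
        comp = rng.dirichlet(np.ones(6), size=20)
        out = clr_transform(comp)
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(clr_transform(comp * 7.0), out, atol=1e-10)

    def test_all_zero_row_errors(self):
        with pytest.raises(DataModelError):
            clr_transform([0.0, 0.0, 0.0])


class TestDietaryPCA:
    def _comp(self, rng, n=100, k=6):
        return pd.DataFrame(rng.dirichlet(np.ones(k), size=n),
                            columns=[f"g{j}" for j in range(k)])

    def test_scores_centered_and_variance_preserved(self, rng):
        comp = self._comp(rng)
        res = dietary_pca(comp, n_components=6)
        np.testing.assert_allclose(res.scores.mean(), 0.0, atol=1e-10)
        clr = clr_transform(comp)
        total_var = ((clr - clr.mean()) ** 2).to_numpy().sum() / len(comp)
        np.testing.assert_allclose(res.scores.var(ddof=0).sum(), total_var, atol=1e-8)

    def test_dominant_group_loads_pc1(self, rng):
        n = 200
        comp = self._comp(rng, n)
        clr = clr_transform(comp).to_numpy()
        clr[:, 0] += rng.normal(0, 3.0, n)  # blow up one food group's CLR variance
        back = np.exp(clr)
        comp2 = pd.DataFrame(back / back.sum(axis=1, keepdims=True), columns=comp.columns)
        res = dietary_pca(comp2, n_components=2)
        assert np.abs(res.loadings["diet_pc1"]).idxmax() == "g0"

    def test_too_few_samples_errors(self, rng):
        with pytest.raises(DataModelError):
            dietary_pca(self._comp(rng, n=2))


class TestLipidomeProfile:
    def _matrix(self, arr):
        df = pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])],
                          columns=[f"l{j}" for j in range(arr.shape[1])])
        return LipidomeMatrix(df, transform_state="inverse_normal")

    def test_single_hit_equals_standardized_lipid(self, rng):
        arr = rng.normal(3, 2, (50, 3))
        matrix = self._matrix(arr)
        with pytest.warns(UserWarning, match="single hit"):
            prof = lipidome_profile(matrix, ["l1"])
        z = (arr[:, 1] - arr[:, 1].mean()) / arr[:, 1].std()
        np.testing.assert_allclose(prof.scores.to_numpy(), z, atol=1e-10)
        assert prof.variance_explained == 1.0

    def test_one_factor_hits_explain_majority(self, rng):
        n, k = 400, 10
        f = rng.normal(0, 1, n)
        arr = 0.7 * f[:, None] + np.sqrt(1 - 0.49) * rng.normal(0, 1, (n, k))
        prof = lipidome_profile(self._matrix(arr), [f"l{j}" for j in range(k)])
        assert prof.variance_explained >= 0.5
        np.testing.assert_allclose(np.linalg.norm(prof.loadings), 1.0, atol=1e-10)

    def test_sign_alignment_with_effects(self, rng):
        n, k = 200, 4
        f = rng.normal(0, 1, n)
        arr = 0.8 * f[:, None] + 0.4 * rng.normal(0, 1, (n, k))
        hits = [f"l{j}" for j in range(k)]
        effects = pd.Series([-0.8, -1.2, -0.9, -1.1], index=hits)  # negative LWAS effects
        prof = lipidome_profile(self._matrix(arr), hits, effects=effects)
        assert prof.sign_aligned
        # aligned loadings point the same way as the effect directions
        assert (np.sign(prof.loadings.to_numpy()) == -1).all()

    def test_global_sign_flip_flips_scores_only(self, rng):
        arr = rng.normal(0, 1, (100, 5))
        hits = [f"l{j}" for j in range(5)]
        p1 = lipidome_profile(self._matrix(arr), hits)
        p2 = lipidome_profile(self._matrix(arr), hits, global_flip=True)
        np.testing.assert_allclose(p2.scores, -p1.scores, atol=1e-10)
        assert p1.variance_explained == p2.variance_explained


class TestVarianceDissection:
    def test_orthogonal_terms_order_invariant(self, rng):
        n = 300
        x1, x2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # orthogonalize
        y = x1 + 0.5 * x2 + rng.normal(0, 1, n)
        data = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        d12 = variance_dissection("y", [("x1", ["x1"]), ("x2", ["x2"])], data)
        d21 = variance_dissection("y", [("x2", ["x2"]), ("x1", ["x1"])], data)
        assert abs(d12.table.loc["x1", "r2"] - d21.table.loc["x1", "r2"]) < 1e-3
        assert abs(d12.total_r2 - d21.total_r2) < 1e-12

    def test_exact_response_puts_all_variance_first(self, rng):
        n = 50
        x1 = rng.normal(0, 1, n)
        data = pd.DataFrame({"y": x1, "x1": x1, "x2": rng.normal(0, 1, n)})
        d = variance_dissection("y", [("x1", ["x1"]), ("x2", ["x2"])], data)
        assert abs(d.table.loc["x1", "r2"] - 1.0) < 1e-12
        assert d.table.loc["x2", "r2"] < 1e-12

    def test_r2_sums_to_total(self, rng):
        n = 200
        data = pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=["y", "a", "b", "c"])
        data["y"] = data["a"] - data["b"] + rng.normal(0, 1, n)
        terms = [("a", ["a"]), ("b", ["b"]), ("c", ["c"])]
        d = variance_dissection("y", terms, data)
        term_sum = d.table.drop(index="residual")["r2"].sum()
        assert abs(term_sum - d.total_r2) < 1e-10
        assert abs(term_sum + d.table.loc["residual", "r2"] - 1.0) < 1e-10

    def test_known_signal_fraction_recovered(self, rng):
        n = 600
        pgs = rng.normal(0, 1, n)
        y = np.sqrt(0.10) * pgs + np.sqrt(0.90) * rng.normal(0, 1, n)
        data = pd.DataFrame({"y": y, "pgs": pgs, "junk": rng.normal(0, 1, n)})
        d = variance_dissection("y", [("pgs", ["pgs"]), ("junk", ["junk"])], data)
        assert 0.05 <= d.table.loc["pgs", "r2"] <= 0.15


class TestConditionalAttenuation:
    def test_independent_mediator_changes_nothing(self, rng):
        n = 500
        t = rng.normal(0, 1, n)
        data = pd.DataFrame({
            "profile": 0.5 * t + rng.normal(0, 1, n),
            "trait": t, "mediator": rng.normal(0, 1, n),
        })
        out = conditional_attenuation("profile", "trait", "mediator", [], data)
        assert abs(out.attrs["attenuation"]) < 0.02

    def test_full_mediation_removes_trait_term(self, rng):
        n = 800
        t = rng.normal(0, 1, n)
        med = t + 0.3 * rng.normal(0, 1, n)
        data = pd.DataFrame({
            "profile": med + 0.5 * rng.normal(0, 1, n),  # trait acts only through mediator
            "trait": t, "mediator": med,
        })
        out = conditional_attenuation("profile", "trait", "mediator", [], data)
        assert out.loc["with_mediator", "r2"] < 0.01
        assert out.loc["without_mediator", "r2"] > 0.3

    def test_partial_mediation_halves_r2(self, rng):
        n = 3000
        t = rng.normal(0, 1, n)
        med = t + rng.normal(0, 1, n)
        direct, indirect = 0.5, 0.5
        data = pd.DataFrame({
            "profile": direct * t + indirect * med + rng.normal(0, 1, n),
            "trait": t, "mediator": med,
        })
        out = conditional_attenuation("profile", "trait", "mediator", [], data)
        assert out.loc["with_mediator", "r2"] < out.loc["without_mediator", "r2"]
        ratio = out.loc["with_mediator", "r2"] / out.loc["without_mediator", "r2"]
        assert 0.05 < ratio < 0.55


class TestNestedLrt:
    def test_equal_models_give_zero(self, rng):
        data = pd.DataFrame({"y": rng.normal(0, 1, 50), "x": rng.normal(0, 1, 50)})
        lrt, p = nested_lrt(["x"], ["x"], "y", data)
        assert lrt == 0.0 and p == 1.0

    def test_null_added_term_calibrated(self):
        pvals = []
        for i in range(200):
            rng = np.random.default_rng(3000 + i)
            n = 100
            data = pd.DataFrame({"y": rng.normal(0, 1, n), "x": rng.normal(0, 1, n),
                                 "z": rng.normal(0, 1, n)})
            pvals.append(nested_lrt(["x"], ["x", "z"], "y", data)[1])
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.01 <= frac <= 0.10

    def test_logistic_matches_mle_oracle(self, rng):
        import statsmodels.api as sm
        n = 300
        x = rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.4 * x + 0.6 * z)))).astype(float)
        data = pd.DataFrame({"y": y, "x": x, "z": z})
        lrt, p = nested_lrt(["x"], ["x", "z"], "y", data, family="logistic")
        f0 = sm.Logit(y, np.column_stack([np.ones(n), x])).fit(disp=0)
        f1 = sm.Logit(y, np.column_stack([np.ones(n), x, z])).fit(disp=0)
        assert abs(lrt - 2 * (f1.llf - f0.llf)) < 1e-6
        assert abs(p - stats.chi2.sf(2 * (f1.llf - f0.llf), 1)) < 1e-6

    def test_non_nested_rejected(self, rng):
        data = pd.DataFrame({"y": rng.normal(0, 1, 30), "x": rng.normal(0, 1, 30),
                             "z": rng.normal(0, 1, 30)})
        with pytest.raises(DataModelError):
            nested_lrt(["x"], ["z"], "y", data)


class TestAncomW:
    def _counts(self, rng, n=100, m=5):
        rel = rng.dirichlet(np.ones(m) * 2, size=n)
        return pd.DataFrame(
            np.vstack([rng.multinomial(20_000, rel[i]) for i in range(n)]),
            columns=[f"t{j}" for j in range(m)], index=[f"s{i}" for i in range(n)])

    def test_three_features_w_values_quantized(self, rng):
        counts = self._counts(rng, m=3)
        x = pd.Series(rng.normal(0, 1, 100), index=counts.index)
        res = ancom_w(counts, x, min_prevalence=1)
        assert set(np.round(res.table["W"] * 2).astype(int)).issubset({0, 1, 2})

    def test_feature_order_invariance(self, rng):
        counts = self._counts(rng, m=6)
        x = pd.Series(rng.normal(0, 1, 100), index=counts.index)
        r1 = ancom_w(counts, x, min_prevalence=1).table["W"]
        perm = list(counts.columns[::-1])
        r2 = ancom_w(counts[perm], x, min_prevalence=1).table["W"]
        pd.testing.assert_series_equal(r1.sort_index(), r2.sort_index())

    def test_prevalence_filter_and_min_features(self, rng):
        counts = self._counts(rng, m=4)
        counts["t3"] = 0
        counts.loc[counts.index[:5], "t3"] = 1
        x = pd.Series(rng.normal(0, 1, 100), index=counts.index)
        res = ancom_w(counts, x, min_prevalence=10)
        assert "t3" not in res.table.index
        with pytest.raises(DataModelError):
            ancom_w(counts[["t0", "t1"]], x, min_prevalence=1)


class TestFisherExact:
    def test_symmetric_table(self):
        or_, ci, p = fisher_exact([[1, 1], [1, 1]])
        assert abs(or_ - 1.0) < 1e-9 and p == 1.0

    def test_diagonal_table_enumeration(self):
        # Hypergeom(N=4, K=2, n=2): P(X=0) + P(X=2) = 1/6 + 1/6 = 1/3
        _, _, p = fisher_exact([[2, 0], [0, 2]])
        assert abs(p - 1 / 3) < 1e-12

    @pytest.mark.parametrize("table", [
        [[3, 9], [4, 742]],
        [[5, 2], [3, 11]],
        [[1, 7], [6, 2]],
    ])
    def test_p_matches_hypergeometric_brute_force(self, table):
        a, b = table[0]
        c, d = table[1]
        N, K, n = a + b + c + d, a + b, a + c
        pmf = stats.hypergeom(N, K, n)
        p_obs = pmf.pmf(a)
        brute = sum(pmf.pmf(k) for k in range(max(0, n - (N - K)), min(K, n) + 1)
                    if pmf.pmf(k) <= p_obs * (1 + 1e-9))
        _, _, p = fisher_exact(table)
        assert abs(p - brute) < 1e-12

    def test_zero_margin_errors(self):
        with pytest.raises(DataModelError):
            fisher_exact([[0, 0], [1, 2]])
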