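"""Weighted matrix regression, AICc permutation, and model averaging."""

from __future__ import annotations

import math

import numpy as np
import pytest
import statsmodels.api as sm

from popcompare.matrices import PairwiseMatrix
from popcompare.mrmpa import (
    MatrixRegressionProblem,
    aicc,
    model_average,
    pair_weight_matrix,
    permutation_test,
    residual_normality,
    vectorize,
    wls_fit,
)


def square(labels, fn):
    return PairwiseMatrix.from_function(labels, fn)


def toy_problem(k=5, seed=0, slope=2.0, noise=0.0, extra=False):
    """Response linear in a distance-like predictor (+ optional second one)."""
    rng = np.random.default_rng(seed)
    labels = tuple(f"s{i}" for i in range(k))
    xs = {l: rng.random() * 10 for l in labels}
    zs = {l: rng.random() * 5 for l in labels}
    dist = square(labels, lambda a, b: abs(xs[a] - xs[b]))
    clim = square(labels, lambda a, b: abs(zs[a] - zs[b]))
    resp_vals = dist.values * slope + rng.normal(0, noise, (k, k))
    resp_vals = (resp_vals + resp_vals.T) / 2
    np.fill_diagonal(resp_vals, 0)
    resp = PairwiseMatrix(labels, resp_vals)
    w = square(labels, lambda a, b: 1.0 + (xs[a] + xs[b]) / 20)
    preds = {"dist": dist}
    if extra:
        preds["clim"] = clim
    return MatrixRegressionProblem(resp, preds, w)


class TestVectorize:
    def test_pair_count(self):
        prob = toy_problem(k=4)
        y, X, w, dropped = vectorize(prob)
        assert len(y) == 6 and X.shape == (6, 2) and dropped == 0

    def test_pair_weights_sum_sample_sizes(self):
        wm = pair_weight_matrix({"Namakia": 13, "Marambitsy": 21})
        assert wm["Namakia", "Marambitsy"] == 34
        wmin = pair_weight_matrix({"a": 13, "b": 21}, rule="min")
        assert wmin["a", "b"] == 13

    def test_relabelling_leaves_coefficients_unchanged(self):
        prob = toy_problem(k=5, seed=3, noise=0.05)
        y, X, w, _ = vectorize(prob)
        fit = wls_fit(y, X, w)
        order = list(prob.labels)[::-1]
        prob2 = MatrixRegressionProblem(
            prob.response.reorder(order),
            {n: m.reorder(order) for n, m in prob.predictors.items()},
            prob.weights.reorder(order),
        )
        y2, X2, w2, _ = vectorize(prob2)
        fit2 = wls_fit(y2, X2, w2)
        assert np.allclose(fit.params, fit2.params)

    def test_na_pairs_dropped_listwise_until_unidentifiable(self):
        prob = toy_problem(k=3)
        vals = prob.response.values.copy()
        vals[0, 1] = vals[1, 0] = np.nan
        resp = PairwiseMatrix(prob.labels, vals)
        with pytest.raises(ValueError, match="unidentifiable"):
            vectorize(
                MatrixRegressionProblem(resp, prob.predictors, prob.weights)
            )


class TestWls:
    def test_exact_linear_recovery(self):
        prob = toy_problem(k=6, slope=3.5, noise=0.0)
        y, X, w, _ = vectorize(prob)
        fit = wls_fit(y, X, w)
        assert fit.params[1] == pytest.approx(3.5)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_equal_weights_match_ols(self):
        prob = toy_problem(k=6, noise=0.3, seed=5)
        y, X, _, _ = vectorize(prob)
        fit = wls_fit(y, X, np.full(len(y), 7.0))
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.params, ols.params)
        assert np.allclose(fit.bse, ols.bse)

    def test_duplicated_predictor_rank_error(self):
        prob = toy_problem(k=5)
        y, X, w, _ = vectorize(prob)
        X2 = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank deficient"):
            wls_fit(y, X2, w)


class TestAicc:
    def test_parsimony_ordering(self):
        assert aicc(1.0, 10, 2) < aicc(1.0, 10, 3)

    def test_correction_pole(self):
        with pytest.raises(ValueError, match="correction-term pole"):
            aicc(1.0, 4, 3)

    def test_saturated_sentinel(self):
        assert aicc(0.0, 10, 3) == -math.inf

    def test_weight_rescaling_leaves_aicc_differences_unchanged(self):
        prob = toy_problem(k=6, noise=0.2, seed=9, extra=True)
        y, X1, w, _ = vectorize(prob, ["dist"])
        _, X2, _, _ = vectorize(prob, ["dist", "clim"])

        def aicc_pair(wvec):
            out = []
            for X in (X1, X2):
                fit = wls_fit(y, X, wvec)
                out.append(aicc(fit.rss, fit.n, fit.n_params))
            return out

        a = aicc_pair(w)
        b = aicc_pair(w * 2.0)
        assert a[0] - a[1] == pytest.approx(b[0] - b[1], abs=1e-9)
        # mean-1 normalization makes even absolute values invariant
        assert a == pytest.approx(b, abs=1e-9)


class TestPermutation:
    def test_exhaustive_p_on_perfect_fit(self):
        """Response exactly linear in the predictor at k=5: only label
        permutations preserving the fit tie with the observed AICc."""
        prob = toy_problem(k=5, slope=2.0, noise=0.0)
        p = permutation_test(prob, ["dist"], exhaustive=True)
        assert 1 / 120 <= p <= 5 / 120

    def test_monte_carlo_close_to_exhaustive(self):
        # weak signal so the p-value sits well inside (0, 1)
        prob = toy_problem(k=5, slope=0.3, noise=3.0, seed=21)
        p_ex = permutation_test(prob, ["dist"], exhaustive=True)
        assert 0.05 < p_ex < 0.95
        B = 4000
        p_mc = permutation_test(prob, ["dist"], B=B, seed=10)
        se = math.sqrt(p_ex * (1 - p_ex) / B)
        # the exhaustive count includes the identity tie; allow for it
        assert abs(p_mc - p_ex) <= 3 * se + 1 / 120 + 1 / B

    def test_plus_one_correction_flag(self):
        prob = toy_problem(k=5, slope=2.0, noise=0.0)
        p_corr = permutation_test(prob, ["dist"], B=99, seed=0)
        p_raw = permutation_test(prob, ["dist"], B=99, seed=0, plus_one=False)
        assert p_corr == pytest.approx(p_raw + (1 - 100 * p_raw) / 100, abs=1e-12)

    def test_constant_predictor_is_na_with_warning(self):
        resp = toy_problem(k=4).response
        labels = resp.labels
        const = square(labels, lambda a, b: 3.0)
        w = square(labels, lambda a, b: 1.0)
        prob = MatrixRegressionProblem(resp, {"c": const}, w)
        with pytest.warns(UserWarning, match="constant"):
            assert math.isnan(permutation_test(prob, ["c"], B=99))

    def test_multi_predictor_needs_explicit_target(self):
        prob = toy_problem(k=5, extra=True)
        with pytest.raises(ValueError, match="explicit"):
            permutation_test(prob, ["dist", "clim"], B=99)


class TestModelAverage:
    def test_weights_sum_to_one_and_match_definition(self):
        prob = toy_problem(k=6, noise=0.4, seed=2, extra=True)
        res = model_average(prob, B=99, seed=0)
        w = res.models["akaike_weight"].to_numpy()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        delta = res.models["delta"].to_numpy()
        expect = np.exp(-delta / 2) / np.exp(-delta / 2).sum()
        assert np.allclose(w, expect)
        # delta-of-2 pair: weight ratio e^{-1}
        assert math.exp(-1.0) == pytest.approx(0.269 / 0.731, abs=5e-3)

    def test_model_set_is_all_subsets_plus_intercept(self):
        prob = toy_problem(k=6, noise=0.4, extra=True)
        res = model_average(prob, B=99, seed=0)
        assert set(res.models["model"]) == {
            "(intercept)", "dist", "clim", "dist + clim"
        }
        assert set(res.predictors["predictor"]) == {"dist", "clim"}

    def test_total_weight_sums_models_containing_predictor(self):
        prob = toy_problem(k=6, noise=0.4, seed=4, extra=True)
        res = model_average(prob, B=99, seed=0)
        by_model = dict(zip(res.models["model"], res.models["akaike_weight"]))
        tw = dict(zip(res.predictors["predictor"], res.predictors["total_aicc_weight"]))
        assert tw["dist"] == pytest.approx(by_model["dist"] + by_model["dist + clim"])

    def test_strong_signal_detected(self):
        prob = toy_problem(k=7, slope=2.0, noise=0.1, seed=6, extra=True)
        res = model_average(prob, B=499, seed=1)
        row = res.predictors.set_index("predictor").loc["dist"]
        assert row["total_aicc_weight"] > 0.8
        assert row["perm_p_full_model"] < 0.05
        assert row["beta_avg"] == pytest.approx(2.0, rel=0.15)


class TestResidualNormality:
    def test_gaussian_residuals_rarely_rejected(self):
        rng = np.random.default_rng(12)
        ok = sum(
            residual_normality(rng.normal(size=50))[1] > 0.05 for _ in range(100)
        )
        assert ok >= 90

    def test_bimodal_residuals_rejected(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(20):
            r = np.concatenate([rng.normal(-4, 0.3, 25), rng.normal(4, 0.3, 25)])
            hits += residual_normality(r)[1] < 0.05
        assert hits >= 18

    def test_preconditions(self):
        with pytest.raises(ValueError):
            residual_normality(np.array([1.0, 2.0]))
        w, p = residual_normality(np.zeros(10))
        assert math.isnan(w) and math.isnan(p)
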