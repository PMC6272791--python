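import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plsvip import (
    autoscale,
    compute_vip,
    f_statistic,
    fit_from_json,
    fit_pls_nipals,
    fit_to_json,
    loo_q2_per_component,
    predict,
    q_squared,
    r_squared,
    rmse,
    select_n_components,
)
from plsvip.pls import VIP_WEIGHT_MODES

from conftest import make_strong_problem


class TestAutoscale:
    def test_symmetric_column(self):
        Xs, ys, p = autoscale(np.array([[1.0], [2.0], [3.0]]), [1.0, 2.0, 3.0])
        assert np.allclose(Xs.ravel(), [-1, 0, 1])
        assert np.allclose(ys, [-1, 0, 1])

    def test_idempotent_on_scaled(self, rng):
        X = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        Xs, ys, _ = autoscale(X, y)
        Xs2, ys2, _ = autoscale(Xs, ys)
        assert np.allclose(Xs2, Xs, atol=1e-12) and np.allclose(ys2, ys, atol=1e-12)

    def test_round_trip(self, rng):
        X = rng.standard_normal((15, 3)) * 5 + 2
        y = rng.standard_normal(15) * 3 - 1
        Xs, ys, p = autoscale(X, y)
        assert np.allclose(Xs * p.x_sds + p.x_means, X)
        assert np.allclose(p.unscale_y(ys), y)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            autoscale(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]), [1.0, 2.0, 3.0])


class TestNipals:
    def test_exact_linear_one_component(self):
        X, y = make_strong_problem(n=30, m_noise=4, seed=2)
        # y = 2*x0 exactly: with noise descriptors orthogonal-ish, a few
        # components recover it; at A=1 residuals are already tiny because the
        # weight vector concentrates on x0
        fit = fit_pls_nipals(X[["x0"]], y, 1)
        assert np.max(np.abs(predict(fit, X[["x0"]]) - y)) < 1e-8

    @pytest.mark.parametrize("seed,n,m,A", [(0, 20, 5, 3), (1, 25, 8, 4), (2, 30, 6, 2)])
    def test_matches_sklearn_nipals(self, seed, n, m, A):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        fit = fit_pls_nipals(X, y, A)
        ref = sklearn.PLSRegression(n_components=A, scale=True).fit(X, y.reshape(-1, 1))
        assert np.allclose(predict(fit, X), ref.predict(X).ravel(), atol=1e-8)

    def test_ols_limit(self, rng):
        n, m = 15, 4
        X = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        fit = fit_pls_nipals(X, y, m)
        Xi = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
        assert np.allclose(predict(fit, X), Xi @ beta, atol=1e-6)

    def test_invariants(self, rng):
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        fit = fit_pls_nipals(X, y, 4)
        assert np.allclose(np.linalg.norm(fit.W, axis=0), 1.0)
        G = fit.T.T @ fit.T
        assert np.allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)
        via_scores = fit.scaling.unscale_y(fit.T @ fit.q)
        via_coef = predict(fit, X)
        assert np.allclose(via_scores, via_coef, atol=1e-8)

    def test_a_too_large_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError, match="A="):
            fit_pls_nipals(X, rng.standard_normal(5), 5)

    def test_rank_collapse_names_achievable_rank(self, rng):
        z = rng.standard_normal(12)
        X = np.column_stack([z, 2 * z + 1, -z, z * 3])  # rank 1 after centering
        with pytest.raises(ValueError, match="achievable rank is 1"):
            fit_pls_nipals(X, z + rng.standard_normal(12) * 0.1, 3)

    def test_deterministic(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        a = fit_pls_nipals(X, y, 3)
        b = fit_pls_nipals(X, y, 3)
        assert np.array_equal(predict(a, X), predict(b, X))


class TestPredict:
    def test_training_reproduces_fitted(self, rng):
        X = pd.DataFrame(rng.standard_normal((18, 4)), columns=list("abcd"))
        y = rng.standard_normal(18)
        fit = fit_pls_nipals(X, y, 2)
        assert np.allclose(predict(fit, X), fit.fitted_values, atol=1e-10)

    def test_duplicate_compound_gets_same_value(self, rng):
        X = rng.standard_normal((12, 3))
        y = rng.standard_normal(12)
        fit = fit_pls_nipals(X, y, 2)
        assert predict(fit, X[4:5])[0] == pytest.approx(predict(fit, X)[4], abs=1e-12)

    def test_batching_invariance(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        Xn = rng.standard_normal((6, 3))
        fit = fit_pls_nipals(X, y, 2)
        whole = predict(fit, Xn)
        rows = np.array([predict(fit, Xn[i : i + 1])[0] for i in range(6)])
        assert np.allclose(whole, rows, atol=1e-12)

    def test_column_mismatch_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 3)), columns=list("abc"))
        fit = fit_pls_nipals(X, rng.standard_normal(10), 2)
        with pytest.raises(ValueError, match="columns"):
            predict(fit, X.rename(columns={"c": "z"}))


class TestComponentSelection:
    def test_recovers_planted_rank(self):
        rng = np.random.default_rng(9)
        Z = rng.standard_normal((40, 2))
        X = Z @ rng.standard_normal((2, 6))  # exactly rank 2
        y = Z @ np.array([1.0, -0.5])
        assert select_n_components(X, y, A_max=5) == 2

    def test_pure_noise_q2_small(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((30, 8))
            y = rng.standard_normal(30)
            A = select_n_components(X, y, A_max=5)
            q2 = loo_q2_per_component(X, y, 5)[A - 1]
            hits += q2 <= 0.2
            assert 1 <= A <= 5
        assert hits >= 9  # noise never cross-validates well

    def test_a_max_one(self, rng):
        X = rng.standard_normal((15, 4))
        assert select_n_components(X, rng.standard_normal(15), A_max=1) == 1


class TestVIP:
    def test_single_descriptor_is_one(self, rng):
        x = rng.standard_normal(20)
        fit = fit_pls_nipals(x[:, None], 2 * x + rng.standard_normal(20) * 0.1, 1)
        vip = compute_vip(fit)
        assert vip.vip == pytest.approx([1.0])

    def test_duplicated_descriptors_equal_vip(self, rng):
        x = rng.standard_normal(25)
        noise = rng.standard_normal(25)
        X = np.column_stack([x, x, noise])
        fit = fit_pls_nipals(X, 3 * x + 0.05 * rng.standard_normal(25), 2)
        vip = compute_vip(fit)
        assert vip.vip[0] == pytest.approx(vip.vip[1], abs=1e-10)
        assert vip.vip[0] > vip.vip[2]

    def test_formula_oracle(self, rng):
        """Straight-line evaluation of the VIP definition matches the operation."""
        X = rng.standard_normal((18, 5))
        y = rng.standard_normal(18)
        fit = fit_pls_nipals(X, y, 3)
        ys = fit.ys_train
        m, A = 5, 3
        tss = np.sum((ys - ys.mean()) ** 2)
        weights = [max(0.0, 1 - np.sum((ys - fit.T[:, a] * fit.q[a]) ** 2) / tss)
                   for a in range(A)]
        expected = [np.sqrt(m * sum(fit.W[j, a] ** 2 * weights[a] for a in range(A))
                            / sum(weights)) for j in range(m)]
        assert np.allclose(compute_vip(fit).vip, expected, atol=1e-10)

    @pytest.mark.parametrize("mode", ["y_contribution", "component_ssy"])
    def test_sum_of_squares_is_m(self, mode, rng):
        for _ in range(5):
            n, m, A = 20, int(rng.integers(2, 9)), 2
            X = rng.standard_normal((n, m))
            y = rng.standard_normal(n)
            vip = compute_vip(fit_pls_nipals(X, y, A), weight=mode)
            assert np.sum(vip.vip**2) == pytest.approx(m, abs=1e-6)
            assert np.all(np.isfinite(vip.vip)) and np.all(vip.vip >= 0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), m=st.integers(2, 10), A=st.integers(1, 3))
    def test_normalisation_property(self, seed, m, A):
        """Sum of squared VIPs equals the descriptor count on arbitrary fits."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((15, m))
        y = rng.standard_normal(15)
        vip = compute_vip(fit_pls_nipals(X, y, min(A, m)))
        assert np.sum(vip.vip**2) == pytest.approx(m, abs=1e-6)

    def test_literal_score_weighting(self, rng):
        """The raw-score weighting keeps the normalisation where its r²(y,t)
        terms are positive (scores on the response scale)."""
        y = rng.standard_normal(25)
        X = np.column_stack([y + 0.1 * rng.standard_normal(25) for _ in range(3)])
        vip = compute_vip(fit_pls_nipals(X, y, 1), weight="eq2_literal")
        assert np.sum(vip.vip**2) == pytest.approx(3, abs=1e-6)

    def test_literal_weighting_degenerate_error(self):
        """On wide scale-mismatched noise every raw-score r² clamps to zero."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 50))
        y = rng.standard_normal(20)
        with pytest.raises(ValueError, match="degenerate"):
            compute_vip(fit_pls_nipals(X, y, 1), weight="eq2_literal")


class TestMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(y, y) == 1.0
        assert rmse(y, y) == 0.0

    def test_null_model_q2_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 6.0])
        assert q_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0)

    def test_f_statistic_formula(self):
        assert f_statistic(0.9064, 65, 7) == pytest.approx(78.86, abs=0.02)

    def test_q2_not_above_r2_on_training(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            Z = rng.standard_normal((25, 2))
            X = np.column_stack([Z @ rng.standard_normal(2) for _ in range(5)])
            y = Z @ np.array([1.0, 0.5]) + 0.2 * rng.standard_normal(25)
            fit = fit_pls_nipals(X, y, 2)
            r2 = r_squared(y, predict(fit, X))
            q2 = loo_q2_per_component(X, y, 2)[1]
            assert q2 <= r2 + 1e-12  # PRESS >= RSS

    def test_degenerate_obs_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSerialization:
    def test_round_trip_lossless(self, rng):
        X = pd.DataFrame(rng.standard_normal((16, 5)), columns=list("abcde"),
                         index=[f"c{i}" for i in range(16)])
        y = rng.standard_normal(16)
        fit = fit_pls_nipals(X, y, 3)
        doc = fit_to_json(fit)
        clone = fit_from_json(doc)
        assert clone.A == fit.A
        assert clone.descriptor_names == fit.descriptor_names
        assert clone.training_ids == fit.training_ids
        for attr in ("W", "P", "T", "q", "coef"):
            assert np.allclose(getattr(clone, attr), getattr(fit, attr), atol=1e-12)
        Xn = rng.standard_normal((4, 5))
        assert np.allclose(predict(clone, Xn), predict(fit, Xn), atol=1e-12)
        json.loads(doc)  # valid JSON document
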