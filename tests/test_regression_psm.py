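"""OLS, logistic propensity model, matching, ATT and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agestrata.regression_psm import (
    Matches,
    balance_report,
    estimate_att,
    fit_logit,
    fit_ols,
    match_kernel,
    match_nn,
)


def _random_design(seed, n=20, p=2):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    y = rng.normal(size=n)
    return y, X


class TestOLS:
    def test_exact_interpolation(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = 1.5 + 2.0 * X["a"] - 0.5 * X["b"]
        res = fit_ols(y, X)
        np.testing.assert_allclose(res.params, [1.5, 2.0, -0.5], atol=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_intercept_only_is_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        res = fit_ols(y, pd.DataFrame(index=range(4)))
        assert res.params["const"] == pytest.approx(y.mean())

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_normal_equations_oracle(self, seed):
        y, X = _random_design(seed, n=20, p=3)
        res = fit_ols(y, X)
        Xd = np.column_stack([np.ones(20), X.to_numpy()])
        beta_ref = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        np.testing.assert_allclose(res.params.to_numpy(), beta_ref, atol=1e-8)

    def test_matches_statsmodels(self):
        """Independent cross-check of coefficients, SEs and p-values."""
        import statsmodels.api as sm

        y, X = _random_design(4, n=60, p=3)
        res = fit_ols(y, X)
        ref = sm.OLS(y, sm.add_constant(X.to_numpy())).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ref.params, atol=1e-10)
        np.testing.assert_allclose(res.bse.to_numpy(), ref.bse, atol=1e-10)
        np.testing.assert_allclose(res.pvalues.to_numpy(), ref.pvalues, atol=1e-10)
        assert res.r_squared == pytest.approx(ref.rsquared)

    def test_collinear_terms_named(self):
        y, X = _random_design(5, n=20, p=2)
        X["dup"] = X["x0"] * 2.0
        with pytest.raises(ValueError, match="dup|x0"):
            fit_ols(y, X)

    def test_listwise_deletion_reported(self):
        y, X = _random_design(6, n=25, p=2)
        X.loc[0, "x0"] = np.nan
        res = fit_ols(y, X)
        assert res.n_used == 24


class TestLogit:
    def test_intercept_only_gives_treated_fraction(self):
        t = np.array([1, 1, 0, 0, 0, 1])
        ps = fit_logit(t, np.zeros((6, 1)))
        np.testing.assert_allclose(ps, t.mean(), atol=1e-8)

    def test_monotone_in_single_covariate(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(80, 1))
        t = (rng.random(80) < 1 / (1 + np.exp(-1.5 * x[:, 0]))).astype(int)
        ps = fit_logit(t, x)
        order = np.argsort(x[:, 0])
        assert np.all(np.diff(ps[order]) >= -1e-12)

    def test_grid_search_oracle(self):
        """MLE coefficients match an independent dense grid maximizer."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        t = (rng.random(30) < 1 / (1 + np.exp(-(0.4 + 0.8 * x)))).astype(int)

        def ll(b0, b1):
            eta = b0 + b1 * x[None, None, :]
            return (t * eta - np.log1p(np.exp(eta))).sum(axis=-1)

        lo = np.array([-5.0, -5.0])
        hi = np.array([5.0, 5.0])
        for _ in range(4):  # successive grid refinement to ~1e-4
            b0g = np.linspace(lo[0], hi[0], 101)
            b1g = np.linspace(lo[1], hi[1], 101)
            L = ll(b0g[:, None, None], b1g[None, :, None])
            i, j = np.unravel_index(np.argmax(L), L.shape)
            step = (hi - lo) / 100
            center = np.array([b0g[i], b1g[j]])
            lo, hi = center - 2 * step, center + 2 * step
        # package coefficients recovered from the score equations via its scores
        ps = fit_logit(t, x[:, None])
        eta = np.log(ps / (1 - ps))
        b1_hat = np.polyfit(x, eta, 1)[0]
        b0_hat = eta.mean() - b1_hat * x.mean()
        np.testing.assert_allclose([b0_hat, b1_hat], center, atol=1e-4)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logit(np.ones(10), np.zeros((10, 1)))

    def test_separation_detected(self):
        x = np.r_[np.zeros(10), np.ones(10)][:, None]
        t = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(ValueError, match="separation"):
            fit_logit(t, x)


class TestNearestNeighbourMatching:
    def test_nearest_and_tie_rule(self):
        ps = np.array([0.2, 0.8, 0.25])
        t = np.array([0, 0, 1])
        m = match_nn(ps, t)
        assert m.control_idx[0].tolist() == [0]
        # exactly between two controls -> lower index
        ps2 = np.array([0.2, 0.4, 0.3])
        m2 = match_nn(ps2, np.array([0, 0, 1]))
        assert m2.control_idx[0].tolist() == [0]

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle(self, seed):
        """Matches agree with exhaustive nearest search on random configurations."""
        rng = np.random.default_rng(seed)
        n = 30
        ps = rng.random(n)
        t = (rng.random(n) < 0.4).astype(int)
        if t.sum() in (0, n):
            t[0], t[1] = 1, 0
        m = match_nn(ps, t)
        controls = np.flatnonzero(t == 0)
        for i, sel in zip(m.treated_idx, m.control_idx):
            d = np.abs(ps[controls] - ps[i])
            assert sel[0] == controls[np.argmin(d)]

    def test_caliper_drops_off_support(self):
        ps = np.array([0.1, 0.9, 0.12, 0.5])
        t = np.array([0, 0, 1, 1])
        m = match_nn(ps, t, caliper=0.1)
        assert m.n_dropped == 1
        assert m.treated_idx.tolist() == [2]

    def test_no_controls_rejected(self):
        with pytest.raises(ValueError):
            match_nn(np.array([0.5]), np.array([1]))


class TestKernelMatching:
    def test_single_control_gets_full_weight(self):
        ps = np.array([0.50, 0.52])
        m = match_kernel(ps, np.array([0, 1]), bandwidth=0.06)
        assert m.weights[0] == pytest.approx([1.0])

    def test_equidistant_controls_split_weight(self):
        ps = np.array([0.48, 0.52, 0.50])
        m = match_kernel(ps, np.array([0, 0, 1]), bandwidth=0.06)
        np.testing.assert_allclose(m.weights[0], [0.5, 0.5])

    def test_hand_computed_weights(self):
        """Weights equal the Epanechnikov kernel ratios on a 10-unit layout."""
        ps = np.array([0.10, 0.14, 0.18, 0.22, 0.26, 0.40, 0.20, 0.50, 0.60, 0.70])
        t = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1])
        h = 0.1
        m = match_kernel(ps, t, bandwidth=h)
        controls = np.flatnonzero(t == 0)
        for i, sel, w in zip(m.treated_idx, m.control_idx, m.weights):
            u = (ps[i] - ps[controls]) / h
            k = np.where(np.abs(u) < 1, 0.75 * (1 - u**2), 0.0)
            expected = k[np.isin(controls, sel)] / k.sum()
            np.testing.assert_allclose(w, expected, atol=1e-12)

    def test_no_support_treated_dropped(self):
        ps = np.array([0.1, 0.9])
        m = match_kernel(ps, np.array([0, 1]), bandwidth=0.05)
        assert m.n_dropped == 1 and m.treated_idx.size == 0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_weights_nonnegative_and_normalized(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        ps = rng.random(n)
        t = (rng.random(n) < 0.5).astype(int)
        if t.sum() in (0, n):
            t[0], t[1] = 1, 0
        m = match_kernel(ps, t, bandwidth=0.2)
        for w in m.weights:
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestATT:
    def test_identical_outcomes_give_zero(self):
        y = np.array([2.0, 2.0, 2.0, 2.0])
        m = match_nn(np.array([0.4, 0.6, 0.41, 0.59]), np.array([0, 0, 1, 1]))
        att, se, _ = estimate_att(y, m, n_boot=50, seed=0)
        assert att == 0.0

    def test_self_matching_att_exactly_zero(self):
        """Treated units matched to exact copies of themselves."""
        rng = np.random.default_rng(3)
        y_t = rng.normal(size=10)
        y = np.concatenate([y_t, y_t])
        ps = np.concatenate([rng.random(10)] * 2)
        t = np.r_[np.ones(10, int), np.zeros(10, int)]
        m = match_nn(ps, t)
        att, _, _ = estimate_att(y, m, n_boot=50, seed=0)
        assert att == 0.0

    def test_sign_matches_mean_matched_difference(self):
        rng = np.random.default_rng(4)
        n = 60
        ps = rng.random(n)
        t = (rng.random(n) < 0.5).astype(int)
        t[:2] = [1, 0]
        y = rng.normal(size=n) + 0.8 * t
        m = match_nn(ps, t)
        att, _, _ = estimate_att(y, m, n_boot=50, seed=1)
        diffs = [y[i] - w @ y[c] for i, c, w in zip(m.treated_idx, m.control_idx, m.weights)]
        assert np.sign(att) == np.sign(np.mean(diffs))

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError):
            estimate_att(np.zeros(2), Matches(np.array([], dtype=int), [], []))


class TestBalance:
    def test_identical_groups_zero_bias(self):
        X = pd.DataFrame({"a": np.tile([1.0, 2.0, 3.0], 4)})
        t = np.r_[np.ones(6, int), np.zeros(6, int)]
        m = match_nn(np.full(12, 0.5), t)
        rep = balance_report(X, t, m)
        np.testing.assert_allclose(rep.bias_before, 0.0, atol=1e-12)

    def test_plugin_bias_value(self):
        """Means 1.0 vs 0.5 with unit variances -> 50% standardized bias."""
        rng = np.random.default_rng(5)
        a_t = rng.normal(0, 1, 2000)
        a_c = rng.normal(0, 1, 2000)
        a_t = (a_t - a_t.mean()) / a_t.std(ddof=1) + 1.0
        a_c = (a_c - a_c.mean()) / a_c.std(ddof=1) + 0.5
        X = pd.DataFrame({"a": np.r_[a_t, a_c]})
        t = np.r_[np.ones(2000, int), np.zeros(2000, int)]
        m = match_nn(np.full(4000, 0.5), t)
        rep = balance_report(X, t, m)
        assert rep.bias_before[0] == pytest.approx(50.0, abs=1e-6)

    def test_matching_improves_balance_on_confounded_data(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.normal(size=(n, 2))
        t = (rng.random(n) < 1 / (1 + np.exp(-(x[:, 0] + 0.5 * x[:, 1])))).astype(int)
        X = pd.DataFrame(x, columns=["x0", "x1"])
        ps = fit_logit(t, x)
        m = match_nn(ps, t)
        rep = balance_report(X, t, m)
        assert rep.mean_bias_after < rep.mean_bias_before
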