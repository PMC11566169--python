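"""Stratum construction, Gibbs sampler validity, variance decomposition, summaries."""

import numpy as np
import pandas as pd
import pytest

import agestrata as ag
from agestrata.maihda import (
    MCMCSettings,
    N_STRATA,
    build_strata,
    caterpillar_data,
    compute_pcv,
    compute_vpc,
    fit_two_level,
    flag_interactions,
    stratum_design,
    stratum_summaries,
    stratum_table_skeleton,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["gender", "health_class", "ses_class", "fp_category"])


class TestBuildStrata:
    def test_full_factorial_occupies_all_24(self):
        skel = stratum_table_skeleton()
        rec = skel.rename(columns={"health": "health_class", "ses": "ses_class"})
        rec["fp_category"] = rec["fp"].map({"none": 0, "middle": 1, "high": 2})
        ids, strata, n_exc = build_strata(rec)
        assert sorted(ids.tolist()) == list(range(1, 25))
        assert (strata["n"] == 1).all()
        assert n_exc == 0

    def test_reference_cell_is_stratum_one(self):
        ids, _, _ = build_strata(_records([("women", "healthy", "high", 0)]))
        assert ids.tolist() == [1]

    def test_layout_matches_published_ordering(self):
        """Stratum 13 opens the men's block: men/healthy/high-SES/no-FP."""
        ids, strata, _ = build_strata(_records([("men", "healthy", "high", 0)]))
        assert ids.tolist() == [13]
        row = strata.loc[strata.stratum_id == 13].iloc[0]
        assert (row.gender, row.health, row.ses, row.fp) == ("men", "healthy", "high", "none")

    def test_single_record_leaves_23_empty(self):
        ids, strata, _ = build_strata(_records([("men", "unhealthy", "low", 2)]))
        assert (strata["n"] == 0).sum() == 23
        assert strata.loc[strata["n"] == 1, "stratum_id"].iloc[0] == ids[0] == 24

    def test_gender_aliases_accepted(self):
        a, _, _ = build_strata(_records([("female", "healthy", "high", 0)]))
        b, _, _ = build_strata(_records([("women", "healthy", "high", 0)]))
        assert a.tolist() == b.tolist()

    def test_missing_dimension_excluded_and_counted(self):
        rec = _records([("women", "healthy", "high", 0), ("women", None, "high", 1)])
        ids, _, n_exc = build_strata(rec)
        assert n_exc == 1 and ids.tolist() == [1, -1]


class TestVarianceArithmetic:
    def test_vpc_reproduces_published_values(self):
        assert compute_vpc(0.1335, 0.8828) == pytest.approx(13.14, abs=0.01)
        assert compute_vpc(0.0196, 0.8830) == pytest.approx(2.17, abs=0.01)

    def test_vpc_edge_cases(self):
        assert compute_vpc(0.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            compute_vpc(0.0, 0.0)
        with pytest.raises(ValueError):
            compute_vpc(-0.1, 1.0)

    def test_pcv_reproduces_published_value(self):
        pcv = compute_pcv(0.1335, 0.0196)
        assert pcv == pytest.approx(85.33, abs=0.02)
        assert 100.0 - pcv == pytest.approx(14.67, abs=0.02)

    def test_pcv_edge_cases(self):
        assert compute_pcv(0.5, 0.5) == 0.0
        assert compute_pcv(0.7, 0.0) == 100.0
        assert compute_pcv(0.1, 0.2) < 0  # reported as-is
        with pytest.raises(ValueError):
            compute_pcv(0.0, 0.1)

    def test_vpc_posterior_draws_stay_in_range(self):
        rng = np.random.default_rng(0)
        s2u = rng.gamma(2, 0.05, 500)
        s2e = rng.gamma(5, 0.2, 500)
        v = compute_vpc(s2u, s2e)
        assert np.all((v >= 0) & (v <= 100))


class TestSampler:
    def test_matches_independent_reference_on_two_stratum_toy(self):
        """Gibbs posterior means of gamma0 and sigma2_e agree with an
        ensemble sampler run on the analytically u-marginalized posterior."""
        import emcee

        rng = np.random.default_rng(42)
        g1 = rng.normal(0.3, 1.0, 60)
        g2 = rng.normal(-0.2, 1.0, 60)
        y = np.concatenate([g1, g2])
        ids = np.repeat([1, 2], 60)
        stats = [(len(g), g.mean(), ((g - g.mean()) ** 2).sum()) for g in (g1, g2)]

        def logpost(p):
            g0, lsu, lse = p
            s2u, s2e = np.exp(2 * lsu), np.exp(2 * lse)
            ll = 0.0
            for n, ybar, ssw in stats:
                v = s2e + n * s2u
                ll += -0.5 * (n * np.log(2 * np.pi) + (n - 1) * np.log(s2e)
                              + np.log(v) + ssw / s2e + n * (ybar - g0) ** 2 / v)
            prior = (-0.5 * g0 ** 2 / 100
                     - np.log1p(np.exp(2 * lsu)) - np.log1p(np.exp(2 * lse))
                     + lsu + lse)
            return ll + prior

        nw = 32
        p0 = np.column_stack([rng.normal(0, 0.3, nw), rng.normal(-1, 0.3, nw),
                              rng.normal(0, 0.3, nw)])
        sampler = emcee.EnsembleSampler(nw, 3, logpost)
        sampler.run_mcmc(p0, 8000, progress=False)
        ch = sampler.get_chain(discard=2000, flat=True)
        g0_ref = ch[:, 0].mean()
        s2e_ref = np.exp(2 * ch[:, 2]).mean()

        fit = fit_two_level(
            y, ids, settings=MCMCSettings(warmup=2000, total=22000, seed=5),
            diagnostics=False,
        )
        assert fit.sigma2_e.mean() == pytest.approx(s2e_ref, rel=0.02)
        # gamma0's posterior SD is ~1.1 here; compare within Monte-Carlo error
        assert fit.theta[:, :, 0].mean() == pytest.approx(g0_ref, abs=0.15)

    def test_deterministic_given_seed(self):
        y, ids, _ = ag.generate_two_level(30, sigma2_u=0.1, sigma2_e=0.5, seed=0)
        st = MCMCSettings(warmup=50, total=150, seed=3)
        f1 = fit_two_level(y, ids, settings=st, diagnostics=False)
        f2 = fit_two_level(y, ids, settings=st, diagnostics=False)
        np.testing.assert_array_equal(f1.theta, f2.theta)
        np.testing.assert_array_equal(f1.sigma2_u, f2.sigma2_u)

    def test_no_stratum_structure_gives_small_vpc(self):
        y, ids, _ = ag.generate_two_level(200, sigma2_u=0.0, sigma2_e=1.0, seed=1)
        fit = fit_two_level(y, ids, settings=MCMCSettings(warmup=500, total=1500, seed=1),
                            diagnostics=False)
        vpc = compute_vpc(fit.sigma2_u.mean(), fit.sigma2_e.mean())
        assert vpc < 2.0

    def test_partial_pooling_shrinks_toward_zero(self):
        """Posterior-mean stratum effects lie between 0 and the raw
        stratum-mean deviations."""
        y, ids, _ = ag.generate_two_level(100, sigma2_u=0.3, sigma2_e=0.8, seed=2)
        fit = fit_two_level(y, ids, settings=MCMCSettings(warmup=500, total=2500, seed=2),
                            diagnostics=False)
        g0 = fit.theta[:, :, 0].mean()
        u_hat = fit.u.mean(axis=(0, 1))
        for j in range(N_STRATA):
            raw_dev = y[ids == j + 1].mean() - g0
            lo, hi = sorted((0.0, raw_dev))
            assert lo - 0.03 <= u_hat[j] <= hi + 0.03

    def test_rhat_reported_and_converged(self):
        y, ids, _ = ag.generate_two_level(100, sigma2_u=0.15, sigma2_e=0.9, seed=4)
        fit = fit_two_level(y, ids, settings=MCMCSettings(warmup=500, total=1500,
                                                          n_chains=2, seed=4))
        assert fit.rhat and max(fit.rhat.values()) < 1.05
        assert fit.converged

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_two_level(np.ones(10), np.repeat([1, 2], 5))  # constant outcome
        with pytest.raises(ValueError):
            fit_two_level(np.random.default_rng(0).normal(size=5), np.array([1] * 5))
        with pytest.raises(ValueError):
            fit_two_level(np.zeros(3), np.array([0, 1, 2]))  # id out of range


@pytest.fixture(scope="module")
def fits():
    sc = ag.additive_effects_scenario()
    y, ids, _ = ag.generate_two_level(150, **sc, seed=6)
    st = MCMCSettings(warmup=500, total=1500, seed=6)
    D, names = stratum_design()
    null = fit_two_level(y, ids, settings=st, diagnostics=False)
    main = fit_two_level(y, ids, design=D[:, 1:], design_names=names[1:],
                         settings=st, diagnostics=False)
    return null, main


class TestStratumSummaries:
    def test_posterior_mean_identity(self, fits):
        _, main = fits
        tab = stratum_summaries(main)
        np.testing.assert_allclose(
            tab["predicted_mean"] - tab["expected_mean"], tab["random_mean"], atol=1e-8
        )

    def test_null_model_expected_is_intercept(self, fits):
        null, _ = fits
        tab = stratum_summaries(null)
        g0 = null.theta[:, :, 0].mean()
        np.testing.assert_allclose(tab["expected_mean"], g0, atol=1e-10)
        np.testing.assert_allclose(
            tab["predicted_mean"], g0 + null.u.mean(axis=(0, 1)), atol=1e-10
        )

    def test_injected_interaction_dominates_random_effects(self):
        """A +0.3 offset in one stratum, large against the residual stratum
        SD, yields that stratum the largest random-effect posterior mean."""
        sc = ag.additive_effects_scenario()
        delta = np.zeros(N_STRATA)
        delta[8] = 0.3
        y, ids, _ = ag.generate_two_level(
            300, gamma0=sc["gamma0"], beta=sc["beta"],
            sigma2_u=0.001, sigma2_e=sc["sigma2_e"], delta=delta, seed=7)
        D, names = stratum_design()
        main = fit_two_level(y, ids, design=D[:, 1:], design_names=names[1:],
                             settings=MCMCSettings(warmup=500, total=1500, seed=7),
                             diagnostics=False)
        tab = stratum_summaries(main)
        assert tab["random_mean"].idxmax() == 8

    def test_empty_strata_flagged_as_prior_dominated(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=200)
        ids = np.repeat([1, 24], 100)
        fit = fit_two_level(y, ids, settings=MCMCSettings(warmup=200, total=600, seed=8),
                            diagnostics=False)
        tab = stratum_summaries(fit)
        assert tab["empty"].sum() == 22
        assert not tab.loc[tab.stratum_id.isin([1, 24]), "empty"].any()


class TestFlaggingAndPlots:
    def _summaries(self):
        return pd.DataFrame(
            {
                "stratum_id": [1, 2, 3],
                "n": [10, 20, 30],
                "random_mean": [0.277, 0.02, -0.40],
                "random_lo": [0.124, -0.10, -0.60],
                "random_hi": [0.441, 0.15, -0.20],
                "flag": [True, False, True],
            }
        )

    def test_interval_excluding_zero_is_flagged(self):
        flagged = flag_interactions(self._summaries())
        assert flagged["stratum_id"].tolist() == [3, 1]  # |effect| descending

    def test_interval_containing_zero_not_flagged(self):
        flagged = flag_interactions(self._summaries())
        assert 2 not in flagged["stratum_id"].tolist()

    def test_caterpillar_rank_ordering(self):
        tab = self._summaries()
        cat = caterpillar_data(tab, "random")
        assert cat["rank"].tolist() == [1, 2, 3]
        assert cat["random_mean"].is_monotonic_increasing
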