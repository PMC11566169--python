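"""Intersectional MAIHDA: strata, Bayesian two-level models, variance decomposition.

MAIHDA (multilevel analysis of individual heterogeneity and discriminatory
accuracy) nests individuals (level 1) within intersectional strata
(level 2) — here the 24 = 2 x 2 x 2 x 3 cells of gender x health status x
socioeconomic status x family participation. Two random-intercept models
are fitted by a blocked Gibbs sampler:

    null:  y_ij = gamma0 + u_j + e_ij
    main:  y_ij = gamma0 + x_j' beta + u_j + e_ij

with u_j ~ N(0, sigma2_u), e_ij ~ N(0, sigma2_e), weakly informative
priors (Normal(0, 10^2) on the fixed effects; half-Cauchy(0, 1) on both
SDs, implemented through the inverse-gamma parameter expansion of Huang &
Wand so every conditional stays conjugate).

General intersectionality is summarized by the variance partition
coefficient VPC = sigma2_u / (sigma2_u + sigma2_e) of each model and by
the proportional change in variance PCV = (sigma2_u,null -
sigma2_u,main) / sigma2_u,null; 100 - PCV is the share of between-stratum
variation attributed to interactions. Specific intersectionality is read
off per-stratum expected (fixed-effects-only) and predicted (fixed +
random) outcomes and the stratum random effects, whose 95% credible
intervals flag strata with interaction residuals distinguishable from 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GENDER_LEVELS",
    "HEALTH_LEVELS",
    "SES_LEVELS",
    "FP_LEVELS",
    "N_STRATA",
    "MCMCSettings",
    "MAIHDAFit",
    "VarianceDecomposition",
    "build_strata",
    "stratum_design",
    "fit_two_level",
    "compute_vpc",
    "compute_pcv",
    "variance_decomposition",
    "stratum_summaries",
    "flag_interactions",
    "caterpillar_data",
]

logger = logging.getLogger(__name__)

# Dimension orderings fix the stratum ids: women/healthy/high-SES/no-FP
# is stratum 1; men/unhealthy/low-SES/high-FP is stratum 24.
GENDER_LEVELS = ("women", "men")
HEALTH_LEVELS = ("healthy", "unhealthy")
SES_LEVELS = ("high", "low")
FP_LEVELS = ("none", "middle", "high")
N_STRATA = 2 * 2 * 2 * 3

_GENDER_ALIASES = {"women": 0, "female": 0, "men": 1, "male": 1}


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings. Defaults follow the published run: 5,000 warm-up
    iterations out of 10,000 total (per chain)."""

    warmup: int = 5000
    total: int = 10000
    n_chains: int = 2
    seed: int = 0
    beta_prior_sd: float = 10.0
    sd_prior_scale: float = 1.0  # half-Cauchy scale for both SDs
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if not 0 <= self.warmup < self.total:
            raise ValueError("need 0 <= warmup < total")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class MAIHDAFit:
    """Posterior draws and diagnostics for one two-level model.

    Draw arrays have shape (n_chains, n_kept, ...): ``theta`` holds the
    intercept followed by any fixed-effect coefficients (column order in
    ``param_names``); ``u`` the 24 stratum effects; ``sigma2_u`` /
    ``sigma2_e`` the variance components.
    """

    model: str
    param_names: list[str]
    theta: np.ndarray
    u: np.ndarray
    sigma2_u: np.ndarray
    sigma2_e: np.ndarray
    design: np.ndarray  # (N_STRATA, p) incl. intercept column
    stratum_n: np.ndarray
    settings: MCMCSettings
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    converged: bool = True

    def posterior_mean(self, name: str) -> np.ndarray | float:
        arr = getattr(self, name)
        return arr.mean(axis=(0, 1))

    def summary(self) -> pd.DataFrame:
        """Fixed effects and variance components: mean and 95% CrI."""
        rows = []
        for i, nm in enumerate(self.param_names):
            d = self.theta[:, :, i].ravel()
            rows.append((nm, d.mean(), *np.percentile(d, [2.5, 97.5])))
        for nm, d in (("sigma2_u", self.sigma2_u), ("sigma2_e", self.sigma2_e)):
            d = d.ravel()
            rows.append((nm, d.mean(), *np.percentile(d, [2.5, 97.5])))
        return pd.DataFrame(rows, columns=["parameter", "mean", "ci_lo", "ci_hi"])


@dataclass
class VarianceDecomposition:
    """Posterior-mean variance shares, in percent."""

    vpc_null: float
    vpc_adjusted: float
    pcv: float
    interaction_share: float


# ---------------------------------------------------------------------------
# Stratum construction
# ---------------------------------------------------------------------------

def _stratum_index(g: int, h: int, s: int, f: int) -> int:
    return g * 12 + h * 6 + s * 3 + f + 1


def stratum_table_skeleton() -> pd.DataFrame:
    rows = []
    for g, gender in enumerate(GENDER_LEVELS):
        for h, health in enumerate(HEALTH_LEVELS):
            for s, ses in enumerate(SES_LEVELS):
                for f, fp in enumerate(FP_LEVELS):
                    rows.append(
                        (_stratum_index(g, h, s, f), gender, health, ses, fp)
                    )
    return pd.DataFrame(rows, columns=["stratum_id", "gender", "health", "ses", "fp"])


def build_strata(records: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame, int]:
    """Assign each record to one of the 24 intersectional strata.

    `records` needs columns ``gender`` (women/female or men/male),
    ``health_class`` (healthy/unhealthy), ``ses_class`` (high/low) and
    ``fp_category`` (0/1/2). Returns ``(ids, strata, n_excluded)`` where
    ``ids`` holds 1-24 per record (-1 for records with a missing
    dimension, which are excluded and counted) and ``strata`` is the full
    24-row table with member counts, empty strata retained with n = 0.
    """
    n = len(records)
    ids = np.full(n, -1, dtype=int)
    g = records["gender"].map(_GENDER_ALIASES)
    h = records["health_class"].map({"healthy": 0, "unhealthy": 1})
    s = records["ses_class"].map({"high": 0, "low": 1})
    f = pd.to_numeric(records["fp_category"], errors="coerce")
    ok = g.notna() & h.notna() & s.notna() & f.isin([0, 1, 2])
    ids[ok.to_numpy()] = (
        g[ok].astype(int) * 12 + h[ok].astype(int) * 6 + s[ok].astype(int) * 3
        + f[ok].astype(int) + 1
    ).to_numpy()
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("build_strata excluded %d records with missing dimensions", n_excluded)
    strata = stratum_table_skeleton()
    counts = np.bincount(ids[ids > 0], minlength=N_STRATA + 1)[1:]
    strata["n"] = counts
    return ids, strata, n_excluded


def stratum_design(fp_coding: str = "binary") -> tuple[np.ndarray, list[str]]:
    """Stratum-level fixed-effect design (24 x p), intercept included.

    ``fp_coding="binary"`` contrasts any family participation against
    none (one column); ``"three_level"`` uses separate middle/high
    dummies. Remaining contrasts: male vs women, unhealthy vs healthy,
    low vs high SES (reference levels match the published table).
    """
    tab = stratum_table_skeleton()
    cols = [np.ones(N_STRATA)]
    names = ["intercept"]
    cols.append((tab["gender"] == "men").to_numpy(float))
    names.append("male")
    cols.append((tab["health"] == "unhealthy").to_numpy(float))
    names.append("unhealthy")
    cols.append((tab["ses"] == "low").to_numpy(float))
    names.append("low_ses")
    if fp_coding == "binary":
        cols.append((tab["fp"] != "none").to_numpy(float))
        names.append("fp_any")
    elif fp_coding == "three_level":
        cols.append((tab["fp"] == "middle").to_numpy(float))
        names.append("fp_middle")
        cols.append((tab["fp"] == "high").to_numpy(float))
        names.append("fp_high")
    else:
        raise ValueError("fp_coding must be 'binary' or 'three_level'")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def _run_chain(
    y: np.ndarray,
    gid: np.ndarray,  # 0-based stratum index per record
    design: np.ndarray,  # (N_STRATA, p) stratum-level design incl. intercept
    settings: MCMCSettings,
    seed_key: tuple[int, int],
) -> dict[str, np.ndarray]:
    """One chain of the collapsed blocked Gibbs sampler.

    Fixed effects are drawn from their conditional with the stratum
    effects integrated out (GLS against the compound-symmetric marginal
    covariance), which mixes well even when few strata identify the
    intercept; u, then the two variances (with their parameter-expansion
    auxiliaries), follow conjugately. Because covariates are constant
    within stratum, each iteration runs on per-stratum sufficient
    statistics — O(24), independent of n.
    """
    rng = np.random.default_rng(seed_key)
    n = y.size
    J, p = design.shape
    tau2 = settings.beta_prior_sd ** 2
    A2 = settings.sd_prior_scale ** 2

    n_j = np.bincount(gid, minlength=J).astype(float)
    sum_y = np.bincount(gid, weights=y, minlength=J)
    occ = n_j > 0
    ybar = np.zeros(J)
    ybar[occ] = sum_y[occ] / n_j[occ]
    ss_within = float(((y - ybar[gid]) ** 2).sum())
    ss_j = np.bincount(gid, weights=(y - ybar[gid]) ** 2, minlength=J)

    # moment-based initialization
    s2u = max(ybar[occ].var(), 1e-3)
    s2e = max(ss_within / max(n - occ.sum(), 1), 1e-3)
    a_u = a_e = 1.0
    u = np.zeros(J)
    eye = np.eye(p)

    n_keep = settings.total - settings.warmup
    out = {
        "theta": np.empty((n_keep, p)),
        "u": np.empty((n_keep, J)),
        "sigma2_u": np.empty(n_keep),
        "sigma2_e": np.empty(n_keep),
    }
    for it in range(settings.total):
        # fixed effects | variances, u marginalized out:
        # y_j ~ N(n_j x_j' theta, s2e I + s2u 11') per stratum
        v_j = s2e + n_j * s2u  # marginal variance of a stratum sum direction
        w = np.where(occ, n_j / v_j, 0.0)
        prec = (design.T * w) @ design + eye / tau2
        rhs = design.T @ np.where(occ, sum_y / v_j, 0.0)
        L = np.linalg.cholesky(prec)
        m = np.linalg.solve(prec, rhs)
        theta = m + np.linalg.solve(L.T, rng.standard_normal(p))

        # stratum effects | theta, variances (empty strata draw from prior)
        fixed = design @ theta
        prec_u = n_j / s2e + 1.0 / s2u
        mean_u = (sum_y - n_j * fixed) / s2e / prec_u
        u = mean_u + rng.standard_normal(J) / np.sqrt(prec_u)

        # variances (half-Cauchy via inverse-gamma parameter expansion)
        s2u = _inv_gamma(rng, (J + 1) / 2.0, 1.0 / a_u + 0.5 * (u @ u))
        a_u = _inv_gamma(rng, 1.0, 1.0 / A2 + 1.0 / s2u)
        # residual SS from stratum stats:
        # sum_j [ SS_j + n_j (ybar_j - fixed_j - u_j)^2 ]
        dev = ybar - fixed - u
        sse = float((ss_j + n_j * dev ** 2)[occ].sum())
        s2e = _inv_gamma(rng, (n + 1) / 2.0, 1.0 / a_e + 0.5 * sse)
        a_e = _inv_gamma(rng, 1.0, 1.0 / A2 + 1.0 / s2e)

        k = it - settings.warmup
        if k >= 0:
            out["theta"][k] = theta
            out["u"][k] = u
            out["sigma2_u"][k] = s2u
            out["sigma2_e"][k] = s2e
    return out


def _diagnostics(fit: MAIHDAFit) -> None:
    """Split R-hat and bulk ESS (arviz) for the scalar parameters."""
    import arviz as az

    data = {
        "sigma2_u": fit.sigma2_u,
        "sigma2_e": fit.sigma2_e,
    }
    for i, nm in enumerate(fit.param_names):
        data[nm] = fit.theta[:, :, i]
    idata = az.from_dict(posterior=data)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    fit.rhat = {k: float(rhat[k].values) for k in data}
    fit.ess = {k: float(ess[k].values) for k in data}
    if fit.settings.n_chains >= 2:
        worst = max(fit.rhat.values())
        fit.converged = bool(worst < fit.settings.rhat_threshold)
        if not fit.converged:
            logger.warning("chains not converged: max split R-hat %.3f", worst)


def fit_two_level(
    y,
    stratum_ids,
    design: np.ndarray | None = None,
    design_names: list[str] | None = None,
    settings: MCMCSettings = MCMCSettings(),
    diagnostics: bool = True,
) -> MAIHDAFit:
    """Sample the posterior of a two-level random-intercept model by Gibbs.

    Parameters
    ----------
    y : outcome per record (the standardized participation score).
    stratum_ids : 1-based stratum id per record (1-24; records with other
        ids are rejected).
    design : optional (24, p-1) stratum-level covariate matrix *without*
        the intercept (use :func:`stratum_design` and drop its first
        column, or pass the full matrix from ``stratum_design`` via
        ``design=D[:, 1:], design_names=names[1:]``). ``None`` fits the
        null (intercept-only) model.
    settings : MCMC settings; draws are reproducible given the seed.

    Empty strata stay in the model; their effects are drawn from the
    prior conditional and shrink accordingly.
    """
    y = np.asarray(y, dtype=float)
    ids = np.asarray(stratum_ids, dtype=int)
    if y.shape != ids.shape:
        raise ValueError("y and stratum_ids must align")
    if np.any(~np.isfinite(y)):
        raise ValueError("y must be finite")
    if np.any((ids < 1) | (ids > N_STRATA)):
        raise ValueError("stratum ids must lie in 1..24")
    if np.unique(ids).size < 2:
        raise ValueError("need at least two occupied strata")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; variance model is degenerate")
    gid = ids - 1

    if design is None:
        full = np.ones((N_STRATA, 1))
        names = ["intercept"]
        model = "null"
    else:
        design = np.asarray(design, dtype=float)
        if design.shape[0] != N_STRATA:
            raise ValueError(f"design must have {N_STRATA} rows")
        full = np.column_stack([np.ones(N_STRATA), design])
        names = ["intercept"] + (
            design_names
            if design_names is not None
            else [f"x{i}" for i in range(design.shape[1])]
        )
        model = "main"
    chains = [
        _run_chain(y, gid, full, settings, (settings.seed, c))
        for c in range(settings.n_chains)
    ]
    fit = MAIHDAFit(
        model=model,
        param_names=names,
        theta=np.stack([c["theta"] for c in chains]),
        u=np.stack([c["u"] for c in chains]),
        sigma2_u=np.stack([c["sigma2_u"] for c in chains]),
        sigma2_e=np.stack([c["sigma2_e"] for c in chains]),
        design=full,
        stratum_n=np.bincount(gid, minlength=N_STRATA).astype(int),
        settings=settings,
    )
    if diagnostics:
        _diagnostics(fit)
    return fit


# ---------------------------------------------------------------------------
# Variance decomposition
# ---------------------------------------------------------------------------

def compute_vpc(sigma2_u, sigma2_e):
    """Variance partition coefficient, percent: 100 * s2u / (s2u + s2e).

    Accepts scalars or aligned draw arrays (giving the VPC posterior).
    """
    s2u = np.asarray(sigma2_u, dtype=float)
    s2e = np.asarray(sigma2_e, dtype=float)
    if np.any(s2u < 0) or np.any(s2e < 0):
        raise ValueError("variance components must be nonnegative")
    tot = s2u + s2e
    if np.any(tot == 0):
        raise ValueError("VPC undefined when both variances are zero")
    out = 100.0 * s2u / tot
    return float(out) if out.ndim == 0 else out


def compute_pcv(sigma2_u_null, sigma2_u_main):
    """Proportional change in between-stratum variance, percent.

    100 * (s2u_null - s2u_main) / s2u_null; negative values (variance
    increasing under main effects) are reported as-is.
    """
    s2n = np.asarray(sigma2_u_null, dtype=float)
    s2m = np.asarray(sigma2_u_main, dtype=float)
    if np.any(s2n <= 0):
        raise ValueError("null-model between-stratum variance must be positive")
    out = 100.0 * (s2n - s2m) / s2n
    return float(out) if out.ndim == 0 else out


def variance_decomposition(fit_null: MAIHDAFit, fit_main: MAIHDAFit) -> VarianceDecomposition:
    """VPC/PCV at posterior means of the variance components."""
    s2u_n = float(fit_null.sigma2_u.mean())
    s2e_n = float(fit_null.sigma2_e.mean())
    s2u_m = float(fit_main.sigma2_u.mean())
    s2e_m = float(fit_main.sigma2_e.mean())
    pcv = compute_pcv(s2u_n, s2u_m)
    return VarianceDecomposition(
        vpc_null=compute_vpc(s2u_n, s2e_n),
        vpc_adjusted=compute_vpc(s2u_m, s2e_m),
        pcv=pcv,
        interaction_share=100.0 - pcv,
    )


# ---------------------------------------------------------------------------
# Stratum-level summaries
# ---------------------------------------------------------------------------

def stratum_summaries(fit: MAIHDAFit) -> pd.DataFrame:
    """Per-stratum expected, predicted and random-effect summaries.

    Per draw and stratum j: expected_j = x_j' theta (fixed effects only,
    the stratum's own covariate pattern; just gamma0 for the null model),
    predicted_j = expected_j + u_j, random effect = u_j. Summaries are
    posterior means with equal-tailed 95% credible intervals; ``flag``
    marks strata whose random-effect interval excludes 0. Strata with
    n = 0 are prior-dominated and marked ``empty``.
    """
    theta = fit.theta.reshape(-1, fit.theta.shape[-1])  # (draws, p)
    u = fit.u.reshape(-1, N_STRATA)
    expected = theta @ fit.design.T  # (draws, 24)
    predicted = expected + u

    def _summ(a):
        return a.mean(axis=0), np.percentile(a, 2.5, axis=0), np.percentile(a, 97.5, axis=0)

    e_m, e_lo, e_hi = _summ(expected)
    p_m, p_lo, p_hi = _summ(predicted)
    r_m, r_lo, r_hi = _summ(u)

    tab = stratum_table_skeleton()
    tab["n"] = fit.stratum_n
    tab["expected_mean"], tab["expected_lo"], tab["expected_hi"] = e_m, e_lo, e_hi
    tab["predicted_mean"], tab["predicted_lo"], tab["predicted_hi"] = p_m, p_lo, p_hi
    tab["random_mean"], tab["random_lo"], tab["random_hi"] = r_m, r_lo, r_hi
    tab["flag"] = (r_lo > 0) | (r_hi < 0)
    tab["empty"] = fit.stratum_n == 0
    if tab["empty"].any():
        logger.warning(
            "%d empty strata: their summaries are prior-dominated",
            int(tab["empty"].sum()),
        )
    return tab


def flag_interactions(summaries: pd.DataFrame) -> pd.DataFrame:
    """Strata whose random-effect 95% CrI excludes 0, by |effect| descending."""
    flagged = summaries[summaries["flag"]].copy()
    return flagged.reindex(
        flagged["random_mean"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)


def caterpillar_data(summaries: pd.DataFrame, value: str = "random") -> pd.DataFrame:
    """Rank-ordered stratum effects with credible intervals (plot data)."""
    cols = [f"{value}_mean", f"{value}_lo", f"{value}_hi"]
    out = summaries[["stratum_id", "n"] + cols].copy()
    out = out.sort_values(f"{value}_mean", ignore_index=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
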