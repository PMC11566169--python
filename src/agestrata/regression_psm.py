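"""Association analysis: OLS regression and propensity-score matching.

The primary association model regresses the social-participation score on
family participation and controls by ordinary least squares with classical
standard errors. Robustness is assessed by propensity-score matching:
a logistic propensity model (treatment = any family participation),
1-nearest-neighbour matching with replacement and Epanechnikov kernel
matching, the average treatment effect on the treated (ATT) with a seeded
bootstrap SE, and covariate balance diagnostics (standardized bias,
pseudo-R^2 and LR chi^2 of the re-fitted propensity model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OLSResult",
    "PSMResult",
    "BalanceReport",
    "Matches",
    "fit_ols",
    "fit_logit",
    "match_nn",
    "match_kernel",
    "estimate_att",
    "balance_report",
]

logger = logging.getLogger(__name__)


@dataclass
class OLSResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    n_used: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


@dataclass
class Matches:
    """Matched sets: for each on-support treated record index, the matched
    control indices and their (normalized) weights."""

    treated_idx: np.ndarray
    control_idx: list[np.ndarray]
    weights: list[np.ndarray]
    n_dropped: int = 0


@dataclass
class PSMResult:
    method: str
    propensity: np.ndarray
    matches: Matches
    att: float
    se: float
    t_value: float
    n_treated_on_support: int
    mean_unmatched_treated: float = np.nan
    mean_unmatched_control: float = np.nan
    mean_matched_treated: float = np.nan
    mean_matched_control: float = np.nan


@dataclass
class BalanceReport:
    covariates: list[str]
    bias_before: np.ndarray
    bias_after: np.ndarray
    mean_bias_before: float
    mean_bias_after: float
    med_bias_before: float
    med_bias_after: float
    pseudo_r2_before: float
    pseudo_r2_after: float
    lr_chi2_before: float
    lr_chi2_after: float
    p_value_before: float
    p_value_after: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "bias_before_pct": self.bias_before,
                "bias_after_pct": self.bias_after,
            }
        )


def fit_ols(y, X: pd.DataFrame, add_intercept: bool = True) -> OLSResult:
    """OLS with classical (homoskedastic) standard errors.

    Rows with any missing value in y or X are dropped listwise;
    ``n_used`` reports the analyzed sample. Rank deficiency raises with
    the offending columns named.
    """
    X = pd.DataFrame(X).copy()
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    if add_intercept:
        X.insert(0, "const", 1.0)
    keep = y.notna() & X.notna().all(axis=1)
    Xm = X.loc[keep].to_numpy(dtype=float)
    ym = y.loc[keep].to_numpy(dtype=float)
    n, p = Xm.shape
    if n <= p:
        raise ValueError(f"need n > p; got n={n}, p={p}")
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        # name columns involved in the dependency via QR pivoting
        _, R, piv = _qr_pivot(Xm)
        bad = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    beta, _, _, _ = np.linalg.lstsq(Xm, ym, rcond=None)
    resid = ym - Xm @ beta
    dof = n - p
    sigma2 = resid @ resid / dof
    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    ss_tot = np.sum((ym - ym.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    cols = list(X.columns)
    return OLSResult(
        params=pd.Series(beta, index=cols),
        bse=pd.Series(se, index=cols),
        tvalues=pd.Series(tvals, index=cols),
        pvalues=pd.Series(pvals, index=cols),
        r_squared=float(r2),
        n_used=int(n),
    )


def _qr_pivot(A: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(A, pivoting=True)
    return Q, R, piv


def _logit_irls(
    t: np.ndarray, X: np.ndarray, weights: np.ndarray | None = None,
    max_iter: int = 100, tol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """Weighted logistic MLE by iteratively reweighted least squares.

    Returns (coefficients, log-likelihood). Converges on the score norm.
    """
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (w * (t - mu))
        if np.linalg.norm(score) < 1e-8:
            break
        W = w * mu * (1.0 - mu)
        H = X.T @ (W[:, None] * X)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "propensity model failed (singular Hessian); "
                "likely perfect separation — reduce covariates"
            ) from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 40:
            raise ValueError(
                "propensity coefficients diverged; perfect separation "
                "suspected — reduce covariates"
            )
    eta = X @ beta
    ll = float(np.sum(w * (t * eta - np.log1p(np.exp(eta)))))
    return beta, ll


def fit_logit(treatment, X) -> np.ndarray:
    """Logistic propensity scores P(treated | x), intercept added internally."""
    t = np.asarray(treatment, dtype=float)
    if not (np.any(t == 1) and np.any(t == 0)):
        raise ValueError("both treatment classes must be present")
    Xd = np.column_stack([np.ones(len(t)), np.asarray(X, dtype=float)])
    beta, _ = _logit_irls(t, Xd)
    return 1.0 / (1.0 + np.exp(-(Xd @ beta)))


def match_nn(
    propensity,
    treatment,
    k: int = 1,
    with_replacement: bool = True,
    caliper: float | None = None,
) -> Matches:
    """k-nearest-neighbour matching on the propensity score.

    Each treated unit is matched to its k closest controls by absolute
    propensity difference; equidistant controls resolve to the lower
    record index. With a caliper, treated units whose nearest control is
    farther than the caliper are dropped from support (counted).
    """
    ps = np.asarray(propensity, dtype=float)
    t = np.asarray(treatment, dtype=int)
    treated = np.flatnonzero(t == 1)
    controls = np.flatnonzero(t == 0)
    if controls.size == 0:
        raise ValueError("no control units to match against")
    if not with_replacement:
        raise NotImplementedError("only matching with replacement is supported")
    if k == 1 and caliper is None:
        # vectorized fast path; argmin's first-hit rule = lowest-index tie-break
        sel = controls[np.abs(ps[treated][:, None] - ps[controls][None, :]).argmin(axis=1)]
        return Matches(
            treated, [np.array([c]) for c in sel],
            [np.ones(1)] * treated.size, n_dropped=0,
        )
    kept_t, m_idx, m_w = [], [], []
    dropped = 0
    for i in treated:
        d = np.abs(ps[controls] - ps[i])
        # stable sort on (distance, index): controls is index-sorted already
        order = np.argsort(d, kind="stable")[:k]
        if caliper is not None and d[order[0]] > caliper:
            dropped += 1
            continue
        sel = controls[order]
        kept_t.append(i)
        m_idx.append(sel)
        m_w.append(np.full(sel.size, 1.0 / sel.size))
    if dropped:
        logger.info("nearest-neighbour matching dropped %d off-support treated", dropped)
    return Matches(np.asarray(kept_t, dtype=int), m_idx, m_w, n_dropped=dropped)


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    out = 0.75 * (1.0 - u ** 2)
    out[np.abs(u) >= 1.0] = 0.0
    return out


def match_kernel(propensity, treatment, bandwidth: float = 0.06) -> Matches:
    """Epanechnikov kernel matching: every control inside the bandwidth
    contributes with weight proportional to the kernel of the propensity
    distance; weights are normalized per treated unit. Treated units with
    no control within the bandwidth are dropped from support."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    ps = np.asarray(propensity, dtype=float)
    t = np.asarray(treatment, dtype=int)
    treated = np.flatnonzero(t == 1)
    controls = np.flatnonzero(t == 0)
    if controls.size == 0:
        raise ValueError("no control units to match against")
    kept_t, m_idx, m_w = [], [], []
    dropped = 0
    kmat = _epanechnikov((ps[treated][:, None] - ps[controls][None, :]) / bandwidth)
    for row, i in enumerate(treated):
        kw = kmat[row]
        tot = kw.sum()
        if tot <= 0:
            dropped += 1
            continue
        nz = np.flatnonzero(kw > 0)
        kept_t.append(i)
        m_idx.append(controls[nz])
        m_w.append(kw[nz] / tot)
    if dropped:
        logger.info("kernel matching dropped %d off-support treated", dropped)
    return Matches(np.asarray(kept_t, dtype=int), m_idx, m_w, n_dropped=dropped)


def _treated_differences(y: np.ndarray, matches: Matches) -> np.ndarray:
    return np.array(
        [
            y[i] - float(w @ y[c])
            for i, c, w in zip(matches.treated_idx, matches.control_idx, matches.weights)
        ]
    )


def estimate_att(
    y,
    matches: Matches,
    n_boot: int = 200,
    seed: int = 0,
    propensity=None,
    treatment=None,
    matcher=None,
) -> tuple[float, float, float]:
    """ATT with a seeded bootstrap standard error.

    ATT is the mean over on-support treated units of (own outcome minus
    the weighted mean outcome of matched controls). When ``propensity``,
    ``treatment`` and a ``matcher`` callable (``matcher(ps, t) ->
    Matches``) are supplied, the SE comes from a record-level bootstrap:
    records are resampled with replacement and re-matched each draw,
    which captures control reuse and matching variability. Without that
    context the SE falls back to resampling the per-treated matched
    differences (which understates design variability). t = ATT / SE.
    """
    y = np.asarray(y, dtype=float)
    if matches.treated_idx.size == 0:
        raise ValueError("no treated units on support")
    diffs = _treated_differences(y, matches)
    att = float(diffs.mean())
    rng = np.random.default_rng(seed)
    if matcher is not None and propensity is not None and treatment is not None:
        ps = np.asarray(propensity, dtype=float)
        t_arr = np.asarray(treatment, dtype=int)
        n = y.size
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            tb = t_arr[idx]
            if tb.sum() in (0, n):
                continue
            mb = matcher(ps[idx], tb)
            if mb.treated_idx.size == 0:
                continue
            boots.append(_treated_differences(y[idx], mb).mean())
        se = float(np.std(boots, ddof=1))
    else:
        m = diffs.size
        boot_means = diffs[rng.integers(0, m, size=(n_boot, m))].mean(axis=1)
        se = float(boot_means.std(ddof=1))
    t = att / se if se > 0 else (0.0 if att == 0 else np.inf * np.sign(att))
    return att, se, float(t)


def att_analysis(
    y, propensity, treatment, matches: Matches, method: str,
    n_boot: int = 200, seed: int = 0, matcher=None,
) -> PSMResult:
    """Full ATT summary mirroring a matched/unmatched comparison table."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(treatment, dtype=int)
    att, se, tval = estimate_att(
        y, matches, n_boot=n_boot, seed=seed,
        propensity=propensity, treatment=treatment, matcher=matcher,
    )
    matched_controls = (
        float(
            np.mean(
                [w @ y[c] for c, w in zip(matches.control_idx, matches.weights)]
            )
        )
        if matches.treated_idx.size
        else np.nan
    )
    return PSMResult(
        method=method,
        propensity=np.asarray(propensity, dtype=float),
        matches=matches,
        att=att,
        se=se,
        t_value=tval,
        n_treated_on_support=int(matches.treated_idx.size),
        mean_unmatched_treated=float(y[t == 1].mean()),
        mean_unmatched_control=float(y[t == 0].mean()),
        mean_matched_treated=float(y[matches.treated_idx].mean()),
        mean_matched_control=matched_controls,
    )


def _standardized_bias(
    xt_mean, xc_mean, st2, sc2
) -> float:
    denom = np.sqrt((st2 + sc2) / 2.0)
    if denom == 0:
        logger.warning("zero pooled variance; standardized bias reported as 0")
        return 0.0
    return 100.0 * (xt_mean - xc_mean) / denom


def balance_report(
    X: pd.DataFrame, treatment, matches: Matches
) -> BalanceReport:
    """Covariate balance before vs after matching.

    Standardized bias is 100 * (mean_T - mean_C) / sqrt((s2_T + s2_C)/2)
    with *pre-matching* group variances in the denominator throughout, so
    before/after biases share a scale. Post-matching control means weight
    controls by their total match weight. Pseudo-R^2 (McFadden) and the
    LR chi^2 come from re-fitting the propensity model on the matched
    sample (treated on support + weighted controls).
    """
    X = pd.DataFrame(X)
    t = np.asarray(treatment, dtype=int)
    Xv = X.to_numpy(dtype=float)
    tr, co = t == 1, t == 0

    st2 = Xv[tr].var(ddof=1, axis=0)
    sc2 = Xv[co].var(ddof=1, axis=0)

    # aggregate control match weights over all treated units
    cw = np.zeros(len(t))
    for c, w in zip(matches.control_idx, matches.weights):
        cw[c] += w
    on_support = matches.treated_idx

    before, after = [], []
    for j in range(Xv.shape[1]):
        before.append(
            _standardized_bias(Xv[tr, j].mean(), Xv[co, j].mean(), st2[j], sc2[j])
        )
        xt_post = Xv[on_support, j].mean()
        xc_post = float(cw @ Xv[:, j] / cw.sum())
        after.append(_standardized_bias(xt_post, xc_post, st2[j], sc2[j]))
    before = np.asarray(before)
    after = np.asarray(after)

    def _fit_stats(tt, XX, ww=None):
        Xd = np.column_stack([np.ones(len(tt)), XX])
        w = np.ones(len(tt)) if ww is None else ww
        try:
            _, ll = _logit_irls(tt, Xd, weights=w)
            p_bar = float(np.average(tt, weights=w))
            n_eff = w.sum()
            ll0 = n_eff * (p_bar * np.log(p_bar) + (1 - p_bar) * np.log(1 - p_bar))
            lr = 2.0 * (ll - ll0)
            pr2 = 1.0 - ll / ll0
            pval = float(stats.chi2.sf(max(lr, 0.0), XX.shape[1]))
            return pr2, lr, pval
        except ValueError:
            return np.nan, np.nan, np.nan

    pr2_b, lr_b, p_b = _fit_stats(t.astype(float), Xv)
    # matched sample: on-support treated (weight 1) + all controls with
    # their aggregated match weights
    ctrl_nz = np.flatnonzero(cw > 0)
    idx = np.concatenate([on_support, ctrl_nz])
    tw = np.concatenate([np.ones(on_support.size), cw[ctrl_nz]])
    pr2_a, lr_a, p_a = _fit_stats(t[idx].astype(float), Xv[idx], tw)

    return BalanceReport(
        covariates=list(X.columns),
        bias_before=before,
        bias_after=after,
        mean_bias_before=float(np.mean(np.abs(before))),
        mean_bias_after=float(np.mean(np.abs(after))),
        med_bias_before=float(np.median(np.abs(before))),
        med_bias_after=float(np.median(np.abs(after))),
        pseudo_r2_before=pr2_b,
        pseudo_r2_after=pr2_a,
        lr_chi2_before=lr_b,
        lr_chi2_after=lr_a,
        p_value_before=p_b,
        p_value_after=p_a,
    )
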