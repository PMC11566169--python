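"""Latent class analysis of categorical indicators by expectation-maximization.

The composite health index (self-rated health, CES-D band, IADL band) and
the composite socioeconomic index (hukou, education, income bracket) are
each built from a finite mixture of independent categorical indicators:

    P(x_i) = sum_k pi_k * prod_j rho_{k, j, x_ij}

with class weights pi on the K-simplex and item-response probabilities
rho_{k,j,.} on the L_j-simplex for each indicator j. Parameters are
estimated by EM with seeded random restarts, candidate class counts are
compared by AIC/BIC, and respondents receive their modal posterior class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "LCASpec",
    "LCAFit",
    "em_fit",
    "information_criteria",
    "select_k",
    "modal_assignment",
]

logger = logging.getLogger(__name__)

# Item-response probabilities are kept off the simplex boundary so the
# log-likelihood stays finite on sparse cells.
_RHO_FLOOR = 1e-6


@dataclass(frozen=True)
class LCASpec:
    """Settings for one EM fit: class count, convergence rule, restarts."""

    n_classes: int
    max_iter: int = 1000
    tol: float = 1e-6
    n_starts: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")


@dataclass
class LCAFit:
    """A fitted K-class model.

    ``item_response[j]`` is the (K, L_j) matrix of level probabilities for
    indicator j; ``posterior`` the (n, K) class-membership probabilities.
    ``n_params = (K - 1) + K * sum_j (L_j - 1)``.
    """

    n_classes: int
    class_weights: np.ndarray
    item_response: list[np.ndarray]
    loglik: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
    posterior: np.ndarray
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(default=None, repr=False)


def _validate_data(data: np.ndarray) -> tuple[np.ndarray, list[int]]:
    x = np.asarray(data)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("indicator table must be a nonempty 2-D array")
    if np.any(~np.isfinite(np.asarray(x, dtype=float))):
        raise ValueError("indicator table contains missing values")
    x = x.astype(np.int64)
    if x.min() < 0:
        raise ValueError("indicator levels must be nonnegative integer codes")
    levels = [int(x[:, j].max()) + 1 for j in range(x.shape[1])]
    return x, levels


def _log_component_densities(
    x: np.ndarray, log_rho: list[np.ndarray]
) -> np.ndarray:
    """(n, K) matrix of log P(x_i | class k)."""
    n, J = x.shape
    K = log_rho[0].shape[0]
    out = np.zeros((n, K))
    for j in range(J):
        out += log_rho[j][:, x[:, j]].T  # (n, K)
    return out


def _m_step(
    x: np.ndarray, resp: np.ndarray, levels: list[int]
) -> tuple[np.ndarray, list[np.ndarray]]:
    n, J = x.shape
    K = resp.shape[1]
    nk = resp.sum(axis=0)
    pi = nk / n
    rho: list[np.ndarray] = []
    for j in range(J):
        L = levels[j]
        counts = np.zeros((K, L))
        for c in range(L):
            counts[:, c] = resp[x[:, j] == c].sum(axis=0)
        r = counts / np.maximum(nk[:, None], 1e-300)
        r = np.clip(r, _RHO_FLOOR, 1.0 - _RHO_FLOOR)
        r /= r.sum(axis=1, keepdims=True)
        rho.append(r)
    pi = np.clip(pi, 1e-12, 1.0)
    pi /= pi.sum()
    return pi, rho


def _run_em(
    x: np.ndarray,
    levels: list[int],
    resp0: np.ndarray,
    spec: LCASpec,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray, float, bool, int, np.ndarray]:
    pi, rho = _m_step(x, resp0, levels)
    prev = -np.inf
    trace = []
    converged = False
    for it in range(1, spec.max_iter + 1):
        log_comp = _log_component_densities(x, [np.log(r) for r in rho])
        log_joint = log_comp + np.log(pi)[None, :]
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_joint - log_norm[:, None])
        if abs(ll - prev) < spec.tol:
            converged = True
            break
        prev = ll
        pi, rho = _m_step(x, resp, levels)
    return pi, rho, resp, ll, converged, it, np.asarray(trace)


def em_fit(data, spec: LCASpec) -> LCAFit:
    """Fit a K-class latent class model by EM with random restarts.

    Accepts an integer-coded (n, J) array or DataFrame (levels 0..L_j-1,
    no missing values). The best of ``spec.n_starts`` Dirichlet-random
    responsibility initializations is returned; the observed-data
    log-likelihood is non-decreasing across iterations within each start.
    Deterministic given ``spec.seed``.
    """
    x, levels = _validate_data(np.asarray(data))
    n, J = x.shape
    K = spec.n_classes
    if n < K:
        raise ValueError(f"need at least K={K} records, got {n}")

    rng = np.random.default_rng(spec.seed)
    best = None
    n_starts = 1 if K == 1 else spec.n_starts
    for _ in range(n_starts):
        resp0 = rng.dirichlet(np.ones(K), size=n) if K > 1 else np.ones((n, 1))
        result = _run_em(x, levels, resp0, spec)
        if best is None or result[3] > best[3]:
            best = result
    pi, rho, resp, ll, converged, n_iter, trace = best
    if not converged:
        logger.warning(
            "LCA (K=%d) did not converge in %d iterations (|dll| tol %.1e)",
            K, spec.max_iter, spec.tol,
        )
    p = (K - 1) + K * sum(L - 1 for L in levels)
    aic, bic = information_criteria_values(ll, p, n)
    return LCAFit(
        n_classes=K,
        class_weights=pi,
        item_response=rho,
        loglik=ll,
        n_params=p,
        n_obs=n,
        aic=aic,
        bic=bic,
        posterior=resp,
        converged=converged,
        n_iter=n_iter,
        loglik_trace=trace,
    )


def information_criteria_values(loglik: float, n_params: int, n: int) -> tuple[float, float]:
    if n <= 0:
        raise ValueError("n must be positive")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * np.log(n)
    return aic, bic


def information_criteria(fit: LCAFit, n: int | None = None) -> tuple[float, float]:
    """AIC and BIC of a fit: -2l + 2p and -2l + p ln n."""
    return information_criteria_values(fit.loglik, fit.n_params, n or fit.n_obs)


def select_k(fits: list[LCAFit]) -> int:
    """Choose the class count minimizing BIC; ties break toward fewer classes."""
    if not fits:
        raise ValueError("no candidate fits")
    ordered = sorted(fits, key=lambda f: (f.bic, f.n_classes))
    return ordered[0].n_classes


def comparison_table(fits: list[LCAFit]):
    """Model-comparison rows (K, loglik, n_params, AIC, BIC) for reporting."""
    import pandas as pd

    return pd.DataFrame(
        {
            "n_classes": [f.n_classes for f in fits],
            "loglik": [f.loglik for f in fits],
            "n_params": [f.n_params for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
            "converged": [f.converged for f in fits],
        }
    ).sort_values("n_classes", ignore_index=True)


def class_profile_means(fit: LCAFit, level_scores: list[np.ndarray] | None = None) -> np.ndarray:
    """Per-class mean indicator level, averaged over indicators.

    ``level_scores[j]`` optionally rescores indicator j's levels (used to
    neutralize a catch-all "missing" level); defaults to the level index.
    """
    K = fit.n_classes
    means = np.zeros(K)
    for j, rho in enumerate(fit.item_response):
        scores = (
            np.arange(rho.shape[1], dtype=float)
            if level_scores is None
            else np.asarray(level_scores[j], dtype=float)
        )
        means += rho @ scores
    return means / len(fit.item_response)


def modal_assignment(
    fit: LCAFit,
    labels: tuple[str, str],
    better: str = "lower",
    level_scores: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Assign each record its modal posterior class, with substantive labels.

    For a 2-class fit, the class whose mean indicator profile is
    ``better`` ("lower", e.g. lower ordinal health codes = healthy, or
    "higher", e.g. more education/income = high SES) receives
    ``labels[0]``. The mapping is invariant to permuting class indices.
    Posterior ties resolve toward the lower class index with a warning.
    """
    if fit.n_classes != 2:
        raise ValueError("modal assignment with labeling requires K = 2")
    if better not in ("lower", "higher"):
        raise ValueError("better must be 'lower' or 'higher'")
    profiles = class_profile_means(fit, level_scores)
    first = int(np.argmin(profiles)) if better == "lower" else int(np.argmax(profiles))
    class_labels = np.empty(2, dtype=object)
    class_labels[first] = labels[0]
    class_labels[1 - first] = labels[1]

    post = fit.posterior
    if np.any(np.isclose(post[:, 0], post[:, 1])):
        logger.warning("posterior ties in modal assignment; resolved to class 0")
    modal = np.argmax(post, axis=1)
    return class_labels[modal]
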