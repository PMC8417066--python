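"""Internal-consistency coefficients for ordinal sum scores.

The central coefficient is categorical omega: the reliability of the
*observed* ordinal sum score implied by a one-factor model with thresholds.
Writing X_i = 1 + sum_c 1{Z_i > tau_ic} for the observed item and Z the
latent standard-normal response, the covariance of two items under latent
correlation rho is

    Cov(X_i, X_j) = sum_{c,d} [ Phi2(tau_ic, tau_jd; rho)
                                - Phi(tau_ic) Phi(tau_jd) ],

so both the true-score variance of the sum (latent correlations
lambda_i lambda_j) and its total variance (full implied polychoric matrix,
including any freed error correlation) can be evaluated exactly from the
fitted loadings and thresholds.  A freed error covariance contributes to
the total but not to the true score — it is treated as correlated error.

Cronbach's alpha on the integer codes and item-rest correlations are
provided for comparability, and bias-corrected accelerated (BCa) bootstrap
intervals for any statistic of the response matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr
from scipy.stats import bootstrap as _scipy_bootstrap

from ._bvn import bvn_cdf
from .types import ResponseMatrix


def _pair_cov(ti: np.ndarray, tj: np.ndarray, rho: float) -> float:
    """Cov(X_i, X_j) for thresholded standard normals with correlation rho."""
    if len(ti) == 0 or len(tj) == 0:
        return 0.0
    rho = float(np.clip(rho, -1.0, 1.0))
    if rho == 1.0 and np.array_equal(ti, tj):
        grid = ndtr(np.minimum(ti[:, None], tj[None, :]))
    else:
        grid = bvn_cdf(ti[:, None], tj[None, :], rho)
    return float((grid - ndtr(ti)[:, None] * ndtr(tj)[None, :]).sum())


def categorical_omega(
    loadings,
    thresholds,
    theta_pair: tuple[int, int] | None = None,
    theta: float = 0.0,
) -> float:
    """Green-Yang style reliability of the ordinal sum score.

    ``loadings`` are standardized one-factor loadings; ``thresholds`` is a
    sequence of ordered cut-point arrays, one per item; ``theta`` is an
    optional freed error covariance (latent-correlation metric) between
    ``theta_pair`` that counts toward total, not true-score, variance.
    """
    lam = np.asarray(loadings, dtype=float)
    taus = [np.asarray(t, dtype=float) for t in thresholds]
    if len(taus) != len(lam):
        raise ValueError("need one threshold vector per item")
    for t in taus:
        if len(t) > 1 and (np.diff(t) <= 0).any():
            raise ValueError("thresholds must be strictly increasing per item")
    # a negative loading marks a mirror-coded item: score it in the trait
    # direction (flip the loading, mirror the thresholds) so the sum score
    # is always the properly keyed one
    taus = [(-t[::-1] if l < 0 else t) for l, t in zip(lam, taus)]
    lam = np.abs(lam)
    p = len(lam)
    true_sum = 0.0
    total_sum = 0.0
    for i in range(p):
        for j in range(p):
            rho_true = lam[i] * lam[j] if i != j else lam[i] ** 2
            rho_total = 1.0 if i == j else lam[i] * lam[j]
            if theta_pair is not None and i != j and set((i, j)) == set(theta_pair):
                rho_total += theta
            true_sum += _pair_cov(taus[i], taus[j], rho_true)
            total_sum += _pair_cov(taus[i], taus[j], rho_total)
    if total_sum <= 0:
        raise ValueError("degenerate total variance")
    return true_sum / total_sum


def cronbach_alpha(data: ResponseMatrix):
    """Alpha on integer-coded items, plus item-rest correlations."""
    X = data.to_numpy()
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least two items")
    item_vars = X.var(axis=0, ddof=1)
    zero = np.nonzero(item_vars == 0)[0]
    if len(zero):
        raise ValueError(f"zero-variance item: {data.items[zero[0]]}")
    total_var = X.sum(axis=1).var(ddof=1)
    alpha = (p / (p - 1)) * (1.0 - item_vars.sum() / total_var)
    total = X.sum(axis=1)
    item_rest = np.array([
        np.corrcoef(X[:, i], total - X[:, i])[0, 1] for i in range(p)
    ])
    return float(alpha), item_rest


def bootstrap_ci(
    data,
    statistic,
    n_boot: int = 1000,
    method: str = "bca",
    seed: int | None = None,
    confidence_level: float = 0.95,
) -> tuple[float, float]:
    """BCa bootstrap interval for ``statistic(rows)`` over respondent resamples.

    ``data`` is a 2-D array or ResponseMatrix resampled by rows; a
    degenerate bootstrap distribution falls back to the percentile method
    with a warning.
    """
    X = data.to_numpy() if isinstance(data, ResponseMatrix) else np.asarray(data)
    rng = np.random.default_rng(seed)
    idx = np.arange(len(X))

    def stat(indices):
        return statistic(X[np.asarray(indices, dtype=int)])

    scipy_method = {"bca": "BCa", "percentile": "percentile"}[method.lower()]
    try:
        res = _scipy_bootstrap(
            (idx,), stat, n_resamples=n_boot, method=scipy_method,
            confidence_level=confidence_level, vectorized=False, rng=rng,
        )
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
        if np.isnan(lo) or np.isnan(hi):
            raise ValueError("degenerate bootstrap distribution")
        return lo, hi
    except ValueError:
        if scipy_method == "percentile":
            raise
        warnings.warn("degenerate bootstrap distribution; percentile fallback")
        reps = np.array([
            stat(rng.integers(0, len(X), len(X))) for _ in range(n_boot)
        ])
        q = (1.0 - confidence_level) / 2.0
        return float(np.quantile(reps, q)), float(np.quantile(reps, 1.0 - q))


@dataclass
class ReliabilityResult:
    omega_categorical: float
    omega_categorical_theta: float | None
    alpha: float
    item_rest: np.ndarray
    omega_ci: tuple[float, float] | None
    alpha_ci: tuple[float, float] | None
    n_bootstrap: int
    seed: int | None


def reliability_report(
    data: ResponseMatrix,
    theta_pair: tuple[str, str] | None = ("p4", "p5"),
    n_bootstrap: int = 1000,
    seed: int | None = None,
    estimator: str = "uls",
) -> ReliabilityResult:
    """One-stop reliability analysis: fit a one-factor model on the
    polychoric matrix, then compute categorical omega (with and without the
    freed error covariance), alpha, item-rest correlations, and BCa CIs.
    """
    import pandas as pd

    items = data.items
    pair_idx = None
    if theta_pair is not None and all(i in items for i in theta_pair):
        pair_idx = (items.index(theta_pair[0]), items.index(theta_pair[1]))

    def boot_rm(Xb):
        return ResponseMatrix(pd.DataFrame(Xb, columns=items),
                              data.polarity, data.n_categories)

    omega_plain = _omega_from_matrix(data, None, estimator)
    omega_theta = _omega_from_matrix(data, pair_idx, estimator) if pair_idx else None
    alpha, item_rest = cronbach_alpha(data)

    omega_ci = alpha_ci = None
    if n_bootstrap:
        X = data.to_numpy().astype(int)
        omega_ci = bootstrap_ci(
            X, lambda Xb: _omega_from_matrix(boot_rm(Xb), pair_idx, estimator),
            n_boot=n_bootstrap, seed=seed,
        )
        alpha_ci = bootstrap_ci(
            X, lambda Xb: cronbach_alpha(boot_rm(Xb))[0],
            n_boot=n_bootstrap, seed=seed,
        )
    return ReliabilityResult(
        omega_categorical=omega_plain,
        omega_categorical_theta=omega_theta,
        alpha=alpha,
        item_rest=item_rest,
        omega_ci=omega_ci,
        alpha_ci=alpha_ci,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def _omega_from_matrix(data: ResponseMatrix, pair_idx, estimator) -> float:
    from .cfa import build_cfa_spec, fit_cfa
    from .polychoric import polychoric_matrix

    poly = polychoric_matrix(data)
    spec = build_cfa_spec("one_factor", data.polarity,
                          theta=pair_idx, item_names=data.items)
    fit = fit_cfa(poly, data.n, spec, estimator=estimator)
    taus = [poly.thresholds[c] for c in data.items]
    return categorical_omega(
        fit.standardized_loadings, taus,
        theta_pair=pair_idx, theta=_theta_cov(fit),
    )


def _theta_cov(fit) -> float:
    """Recover the raw (covariance-metric) theta from a fitted model."""
    if fit.spec.theta_pair is None:
        return 0.0
    i, j = fit.spec.theta_pair
    return float(fit.implied[i, j] - fit.standardized_loadings[i]
                 * fit.standardized_loadings[j])
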