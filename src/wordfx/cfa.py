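"""Confirmatory factor models on polychoric correlation matrices.

Three structures for a balanced mixed-worded scale, each optionally adding
a single free error covariance (theta) between one item pair:

``one_factor``   all items on one standardized factor.
``two_factor``   positives on factor 1, recoded negatives on factor 2,
                 factors standardized and freely correlated.
``riifa``        one substantive factor with free loadings plus an
                 orthogonal method factor whose unstandardized loadings are
                 fixed to +1 (positives) and -1 (recoded negatives); only
                 the method-factor variance is free, so the standardized
                 method loadings share a single magnitude.

Point estimation minimizes a least-squares discrepancy between the sample
correlation matrix and the model-implied correlation matrix (fitting the
correlation structure, so the implied diagonal is exactly 1), either
unweighted or diagonally weighted by the large-sample correlation-variance
proxy.
Chi-square statistics for fit indices are computed from the normal-theory
ML discrepancy evaluated at the least-squares solution — an approximation
to mean-and-variance-adjusted categorical estimators, adequate for point
estimates but not for reproducing scaled test statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.stats import ncx2

from .polychoric import PolychoricResult
from .types import NEGATIVE, POSITIVE

KINDS = ("one_factor", "two_factor", "riifa")


@dataclass
class CFAModelSpec:
    kind: str
    item_polarity: list[str]
    theta_pair: tuple[int, int] | None = None   # item indices
    item_names: list[str] | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown model kind: {self.kind}")
        if self.kind == "riifa" and NEGATIVE not in self.item_polarity:
            raise ValueError("riifa requires negatively worded items")
        if self.kind == "two_factor" and (
            POSITIVE not in self.item_polarity or NEGATIVE not in self.item_polarity
        ):
            raise ValueError("two_factor requires both polarities")

    @property
    def p(self) -> int:
        return len(self.item_polarity)

    @property
    def method_signs(self) -> np.ndarray:
        return np.array([1.0 if s == POSITIVE else -1.0 for s in self.item_polarity])

    @property
    def n_free_structural(self) -> int:
        n = self.p                       # loadings
        if self.kind in ("two_factor", "riifa"):
            n += 1                       # factor correlation / method variance
        if self.theta_pair is not None:
            n += 1
        return n

    @property
    def df(self) -> int:
        return self.p * (self.p - 1) // 2 - self.n_free_structural


def build_cfa_spec(kind, item_polarity, theta=None, item_names=None) -> CFAModelSpec:
    """Assemble a model spec; ``theta`` is an item-name pair, index pair,
    True (items "p4"/"p5", the study's flagged pair) or None."""
    pair = None
    if theta is True:
        if item_names is None or "p4" not in item_names or "p5" not in item_names:
            raise ValueError("theta=True needs item names including p4 and p5")
        pair = (item_names.index("p4"), item_names.index("p5"))
    elif theta not in (None, False):
        a, b = theta
        if isinstance(a, str):
            if item_names is None:
                raise ValueError("item-name theta pair needs item_names")
            pair = (item_names.index(a), item_names.index(b))
        else:
            pair = (int(a), int(b))
    return CFAModelSpec(kind=kind, item_polarity=list(item_polarity),
                        theta_pair=pair, item_names=item_names)


# --------------------------------------------------------------------------
# implied structure
# --------------------------------------------------------------------------

def _blocks(spec: CFAModelSpec) -> np.ndarray:
    return np.array([0 if s == POSITIVE else 1 for s in spec.item_polarity])


def implied_correlation(spec: CFAModelSpec, lam, extra, theta) -> np.ndarray:
    """Model-implied correlation matrix (unit diagonal by construction)."""
    lam = np.asarray(lam, dtype=float)
    p = spec.p
    if spec.kind == "one_factor":
        S = np.outer(lam, lam)
    elif spec.kind == "two_factor":
        phi = extra
        b = _blocks(spec)
        fac = np.where(b[:, None] == b[None, :], 1.0, phi)
        S = np.outer(lam, lam) * fac
    else:  # riifa
        s = extra
        c = spec.method_signs
        S = np.outer(lam, lam) + (s**2) * np.outer(c, c)
    if spec.theta_pair is not None:
        i, j = spec.theta_pair
        S[i, j] += theta
        S[j, i] += theta
    np.fill_diagonal(S, 1.0)
    return S


def _split_params(x, spec: CFAModelSpec):
    p = spec.p
    lam = x[:p]
    i = p
    extra = None
    if spec.kind in ("two_factor", "riifa"):
        extra = x[i]
        i += 1
    theta = x[i] if spec.theta_pair is not None else 0.0
    return lam, extra, theta


@dataclass
class CFAFit:
    spec: CFAModelSpec
    standardized_loadings: np.ndarray
    communalities: np.ndarray
    factor_correlation: float | None
    method_loading: float | None          # common standardized magnitude
    theta_standardized: float | None
    discrepancy_value: float              # ULS: sum of squared off-diag residuals
    chi_square: float
    df: int
    sample_size: int
    R: np.ndarray = field(repr=False, default=None)
    implied: np.ndarray = field(repr=False, default=None)
    params: np.ndarray = field(repr=False, default=None)
    heywood: bool = False

    @property
    def residuals(self) -> np.ndarray:
        return self.R - self.implied


def _ml_discrepancy(R: np.ndarray, S: np.ndarray) -> float:
    p = len(R)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        return np.inf
    _, logdet_R = np.linalg.slogdet(R)
    return float(logdet_S - logdet_R + np.trace(np.linalg.solve(S, R)) - p)


def _as_matrix(R) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(R, PolychoricResult):
        return R.to_numpy(), R.items
    if isinstance(R, pd.DataFrame):
        return R.to_numpy(dtype=float), list(R.columns)
    return np.asarray(R, dtype=float), None


def fit_cfa(R, n: int, spec: CFAModelSpec, estimator: str = "uls") -> CFAFit:
    """Least-squares fit of the correlation structure.

    ``R`` may be a PolychoricResult, DataFrame or plain array; ``n`` is the
    sample size behind it (used only for chi-square-based statistics).

    ``estimator="uls"`` minimizes unweighted squared residuals;
    ``"dwls"`` weights each residual by the reciprocal of the large-sample
    correlation variance proxy (1 - r^2)^2, mirroring the diagonally
    weighted estimators used for categorical data.
    """
    Rm, _ = _as_matrix(R)
    p = spec.p
    if Rm.shape != (p, p):
        raise ValueError("matrix does not match the item polarity map")
    if n <= p:
        raise ValueError("sample size must exceed the item count")
    iu = np.triu_indices(p, k=1)
    if estimator == "uls":
        w = np.ones(len(iu[0]))
    elif estimator == "dwls":
        w = 1.0 / (1.0 - Rm[iu] ** 2)
    else:
        raise ValueError(f"unknown estimator: {estimator}")

    def resid(x):
        lam, extra, theta = _split_params(x, spec)
        return (Rm - implied_correlation(spec, lam, extra, theta))[iu] * w

    # start from the leading eigenvector's loading pattern
    vals, vecs = np.linalg.eigh(Rm)
    lam0 = np.abs(vecs[:, -1]) * np.sqrt(vals[-1])
    x0 = list(np.clip(lam0, 0.1, 0.95))
    lower = [-2.0] * p
    upper = [2.0] * p
    if spec.kind == "two_factor":
        x0 += [0.5]; lower += [-0.999]; upper += [0.999]
    elif spec.kind == "riifa":
        x0 += [0.2]; lower += [0.0]; upper += [2.0]
    if spec.theta_pair is not None:
        x0 += [0.0]; lower += [-1.0]; upper += [1.0]

    sol = least_squares(resid, x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise RuntimeError(
            f"CFA did not converge; gradient norm {np.linalg.norm(sol.grad):.3g}"
        )
    lam, extra, theta = _split_params(sol.x, spec)
    implied = implied_correlation(spec, lam, extra, theta)

    if spec.kind == "riifa":
        h2 = lam**2 + extra**2
        method_loading = float(extra)
        factor_corr = None
    else:
        h2 = lam**2
        method_loading = None
        factor_corr = float(extra) if spec.kind == "two_factor" else None
    heywood = bool((h2 > 1.0 + 1e-10).any())
    if heywood:
        warnings.warn("Heywood case: communality above 1; estimate reported as is")

    # theta reported as a residual correlation (covariance over residual SDs)
    theta_std = None
    if spec.theta_pair is not None:
        i, j = spec.theta_pair
        psi_i, psi_j = 1.0 - h2[i], 1.0 - h2[j]
        denom = np.sqrt(max(psi_i * psi_j, 1e-12))
        theta_std = float(theta / denom)

    chi_square = (n - 1) * _ml_discrepancy(Rm, implied)
    return CFAFit(
        spec=spec,
        standardized_loadings=lam,
        communalities=h2,
        factor_correlation=factor_corr,
        method_loading=method_loading,
        theta_standardized=theta_std,
        discrepancy_value=float(np.sum((Rm - implied)[iu] ** 2)),
        chi_square=float(chi_square),
        df=spec.df,
        sample_size=n,
        R=Rm,
        implied=implied,
        params=sol.x,
        heywood=heywood,
    )


def independence_baseline(R, n: int) -> tuple[float, int]:
    """Chi-square and df of the zero-correlation baseline model."""
    Rm, _ = _as_matrix(R)
    p = len(Rm)
    chi = (n - 1) * _ml_discrepancy(Rm, np.eye(p))
    return float(chi), p * (p - 1) // 2


def _rmsea_ci(chi, df, n, level=0.90):
    lo_p = (1.0 - level) / 2.0
    hi_p = 1.0 - lo_p

    def ncp_for(prob):
        # lambda such that P(X2_{df, lambda} <= chi) = prob
        f = lambda lam: ncx2.cdf(chi, df, lam) - prob
        if f(0.0) < 0:
            return 0.0
        hi = max(chi * 2, 10.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e8:
                return np.nan
        return brentq(f, 0.0, hi)

    lam_lo = ncp_for(hi_p)
    lam_hi = ncp_for(lo_p)
    denom = df * (n - 1)
    return (float(np.sqrt(max(lam_lo, 0.0) / denom)),
            float(np.sqrt(max(lam_hi, 0.0) / denom)))


def fit_indices(fit: CFAFit, baseline: tuple[float, int] | None = None) -> dict:
    """CFI / TLI / RMSEA (90% CI) / SRMR with conventional qualitative bands."""
    if baseline is None:
        baseline = independence_baseline(fit.R, fit.sample_size)
    chi_b, df_b = baseline
    chi, df, n = fit.chi_square, fit.df, fit.sample_size
    if df == 0:
        cfi, tli, rmsea, ci = 1.0, 1.0, 0.0, (0.0, 0.0)
    else:
        d_m = max(chi - df, 0.0)
        d_b = max(chi_b - df_b, d_m, 0.0)
        cfi = 1.0 - (d_m / d_b if d_b > 0 else 0.0)
        tli = ((chi_b / df_b) - (chi / df)) / ((chi_b / df_b) - 1.0)
        rmsea = float(np.sqrt(d_m / (df * (n - 1))))
        ci = _rmsea_ci(chi, df, n)
    iu = np.triu_indices(len(fit.R), k=1)
    srmr = float(np.sqrt(np.mean(fit.residuals[iu] ** 2)))
    return {
        "chi_square": chi,
        "df": df,
        "CFI": float(cfi),
        "TLI": float(tli),
        "RMSEA": rmsea,
        "RMSEA_90ci": ci,
        "SRMR": srmr,
        "CFI_band": "excellent" if cfi >= 0.95 else
                    "acceptable" if cfi >= 0.90 else "poor",
        "RMSEA_band": "close" if rmsea < 0.05 else
                      "reasonable" if rmsea < 0.08 else "poor",
        "SRMR_band": "good" if srmr <= 0.05 else
                     "acceptable" if srmr <= 0.08 else "poor",
    }


# --------------------------------------------------------------------------
# modification indices (score statistics on the ML discrepancy)
# --------------------------------------------------------------------------

def _extended_implied(spec, x, cand, a):
    lam, extra, theta = _split_params(x, spec)
    S = implied_correlation(spec, lam, extra, theta)
    kind, i, j = cand
    if kind == "error_cov":
        S = S.copy()
        S[i, j] += a
        S[j, i] += a
    else:  # cross_loading: item i on factor j of the two-factor model
        lam2 = lam.copy()
        b = _blocks(spec)
        phi = extra
        S = S.copy()
        for k in range(spec.p):
            if k == i:
                continue
            # added loading a of item i on factor j changes row/col i
            same = 1.0 if b[k] == j else phi
            S[i, k] += a * lam2[k] * same
            S[k, i] = S[i, k]
    np.fill_diagonal(S, 1.0)
    return S


def modification_indices(fit: CFAFit) -> pd.DataFrame:
    """MI (expected chi-square drop) and SEPC for each fixed parameter.

    Candidates are the fixed error covariances and, for the two-factor
    model, the fixed zero cross-loadings.  Each MI is the expected drop in
    the normal-theory chi-square when the candidate is freed, obtained by
    locally re-optimizing the ML discrepancy over the free parameters plus
    the candidate, warm-started at the fitted solution (an iterated
    score/Lagrange-multiplier statistic: the one-step quadratic
    approximation is carried to convergence, which keeps MIs accurate even
    for grossly misfitting fixed parameters).  The SEPC is the value the
    candidate takes in that re-optimization, expressed in the standardized
    metric (residual correlations for error covariances).
    """
    from scipy.optimize import minimize as _minimize

    spec, Rm, x = fit.spec, fit.R, fit.params
    n, p = fit.sample_size, fit.spec.p

    def fg(z, cand=None):
        """ML discrepancy and analytic gradient over (x, [a])."""
        if cand is None:
            xv, a = z, 0.0
        else:
            xv, a = z[:-1], z[-1]
        lam, extra, theta = _split_params(xv, spec)
        S = implied_correlation(spec, lam, extra, theta)
        if cand is not None:
            S = _extended_implied(spec, xv, cand, a)
        eigs = np.linalg.eigvalsh(S)
        if eigs.min() <= 1e-10:
            # large finite barrier keeps the line search functional
            return 1e6 * (1.0 - eigs.min()), np.zeros_like(z)
        Sinv = np.linalg.inv(S)
        _, logdet_S = np.linalg.slogdet(S)
        _, logdet_R = np.linalg.slogdet(Rm)
        f = logdet_S - logdet_R + np.trace(Sinv @ Rm) - p
        A = Sinv - Sinv @ Rm @ Sinv        # dF/dS
        b = _blocks(spec)
        phi = extra if spec.kind == "two_factor" else None
        fac = (np.where(b[:, None] == b[None, :], 1.0, phi)
               if spec.kind == "two_factor" else np.ones((p, p)))

        grad = np.zeros(len(xv))
        # loadings (implied diagonal fixed at 1 contributes nothing)
        AL = (A * fac) @ lam
        grad[:p] = 2.0 * (AL - np.diag(A) * lam)
        i = p
        if spec.kind == "two_factor":
            cross = b[:, None] != b[None, :]
            grad[i] = float((A * cross * np.outer(lam, lam)).sum())
            i += 1
        elif spec.kind == "riifa":
            s = extra
            c = spec.method_signs
            grad[i] = 2.0 * s * float(c @ A @ c - np.trace(A))
            i += 1
        if spec.theta_pair is not None:
            ti, tj = spec.theta_pair
            grad[i] = 2.0 * A[ti, tj]
        if cand is None:
            return f, grad
        kind, ci, cj = cand
        if kind == "error_cov":
            g_a = 2.0 * A[ci, cj]
        else:  # cross_loading of item ci on factor cj
            w = np.where(b == cj, 1.0, phi)
            w[ci] = 0.0
            g_a = 2.0 * float((A[ci] * lam * w).sum())
            # the added term a*lam_k*w_k in row ci also moves with lam and phi
            mask = np.ones(p, dtype=bool)
            mask[ci] = False
            grad[:p][mask] += 2.0 * a * (A[ci] * w)[mask]
            wphi = (b != cj) & mask
            grad[p] += 2.0 * a * float((A[ci] * lam)[wphi].sum())
        return f, np.concatenate([grad, [g_a]])

    # re-optimize the restricted model under ML so every drop is against
    # the same fitting function
    base = _minimize(fg, x, jac=True, method="L-BFGS-B")
    x_ml, f0 = base.x, base.fun

    candidates = []
    freed = set()
    if spec.theta_pair is not None:
        freed.add(tuple(sorted(spec.theta_pair)))
    for i in range(p):
        for j in range(i + 1, p):
            if (i, j) not in freed:
                candidates.append(("error_cov", i, j))
    if spec.kind == "two_factor":
        b = _blocks(spec)
        for i in range(p):
            candidates.append(("cross_loading", i, 1 - b[i]))

    rows = []
    names = spec.item_names or [f"x{i + 1}" for i in range(p)]
    for cand in candidates:
        sol = _minimize(fg, np.concatenate([x_ml, [0.0]]), args=(cand,),
                        jac=True, method="L-BFGS-B")
        mi = (n - 1) * max(f0 - sol.fun, 0.0)
        sepc = float(sol.x[-1])
        kind, i, j = cand
        if kind == "error_cov":
            # express as residual correlation, like the fitted theta
            lam, _, _ = _split_params(sol.x[:-1], spec)
            h2 = lam**2 if spec.kind != "riifa" else lam**2 + sol.x[p] ** 2
            psi = 1.0 - h2
            sepc /= np.sqrt(max(psi[i] * psi[j], 1e-12))
            label = f"{names[i]}~~{names[j]}"
        else:
            label = f"{names[i]}=~F{j + 1}"
        rows.append({"parameter": label, "kind": kind, "MI": float(mi),
                     "SEPC": float(sepc)})
    return (pd.DataFrame(rows)
            .sort_values("MI", ascending=False)
            .reset_index(drop=True))
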