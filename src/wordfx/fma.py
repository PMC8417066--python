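"""Constrained two-class factor mixture models for wording-effect screening.

Both models posit two latent classes over a one-factor structure for a
mixed-worded scale: class 1 collects *inconsistent* respondents, whose
recoded negatively worded items load with flipped sign, and class 2 the
*consistent* majority.  The sign structure identifies the labels — no
label switching is possible.

``steinmann``
    Positive items: loadings/intercepts shared across classes, loadings
    positive.  Negative items: consistent-class loadings positive and free,
    inconsistent-class loadings equal in magnitude with opposite sign;
    intercepts free per class.  Consistent-class factor standardized
    (mean 0, variance 1); inconsistent-class mean/variance free.
    Uniquenesses shared.  38 free parameters for a 5+5 scale.

``arias``
    All loadings fixed: +1 for positives in both classes, -1/+1 for
    negatives in the inconsistent/consistent class.  Intercepts shared,
    factor means fixed at 0, class factor variances free, uniquenesses
    shared.  23 free parameters for a 5+5 scale.

Items are treated as continuous Gaussian within class; estimation is
maximum likelihood by a generalized EM algorithm (the constrained M-step
is solved numerically, which preserves the EM monotonicity guarantee),
with random multistart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from scipy.special import logsumexp

from .synth import CONSISTENT, INCONSISTENT
from .types import NEGATIVE, POSITIVE, ResponseMatrix

_LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# model specifications
# --------------------------------------------------------------------------

@dataclass
class FMASpec:
    """Constraint template for one of the two published screening models."""

    model_name: str                       # "steinmann" | "arias"
    item_polarity: list[str]
    loading_constraints: dict = field(default_factory=dict)
    intercept_constraints: dict = field(default_factory=dict)
    factor_mean_constraints: tuple = ("free", "fixed(0)")
    factor_variance_constraints: tuple = ("free", "fixed(1)")
    residual_constraints: str = "shared_across_classes"
    n_classes: int = 2

    @property
    def p(self) -> int:
        return len(self.item_polarity)

    @property
    def pos_idx(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.item_polarity) if s == POSITIVE])

    @property
    def neg_idx(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.item_polarity) if s == NEGATIVE])

    @property
    def n_free_parameters(self) -> int:
        npos, nneg, p = len(self.pos_idx), len(self.neg_idx), self.p
        if self.model_name == "steinmann":
            # loadings (npos shared + nneg magnitudes), intercepts
            # (npos shared + 2*nneg), psi, alpha1, phi1, mixing weight
            return (npos + nneg) + (npos + 2 * nneg) + p + 3
        # arias: intercepts, psi, phi1, phi2, mixing weight
        return p + p + 3


def _check_polarity(item_polarity: list[str]) -> None:
    if POSITIVE not in item_polarity or NEGATIVE not in item_polarity:
        raise ValueError(
            "classes not identifiable without both positively and negatively "
            "worded items"
        )


def steinmann_spec(item_polarity: list[str]) -> FMASpec:
    """Sign-flip-linked model with free inconsistent-class factor moments."""
    _check_polarity(item_polarity)
    loading = {
        POSITIVE: "free_shared_across_classes (positivity_bound)",
        NEGATIVE: "free_with_sign_flip_link (class 1 = -class 2)",
    }
    intercept = {POSITIVE: "shared", NEGATIVE: "class_specific"}
    return FMASpec(
        model_name="steinmann",
        item_polarity=list(item_polarity),
        loading_constraints=loading,
        intercept_constraints=intercept,
        factor_mean_constraints=("free", "fixed(0)"),
        factor_variance_constraints=("free", "fixed(1)"),
    )


def arias_spec(item_polarity: list[str]) -> FMASpec:
    """Unit-loading model with class-specific factor variances."""
    _check_polarity(item_polarity)
    loading = {
        POSITIVE: "fixed(+1) both classes",
        NEGATIVE: "fixed(-1) class 1, fixed(+1) class 2",
    }
    intercept = {POSITIVE: "shared", NEGATIVE: "shared"}
    return FMASpec(
        model_name="arias",
        item_polarity=list(item_polarity),
        loading_constraints=loading,
        intercept_constraints=intercept,
        factor_mean_constraints=("fixed(0)", "fixed(0)"),
        factor_variance_constraints=("free", "free"),
    )


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class FMAParameters:
    """Structured parameter set; class index 0 = inconsistent, 1 = consistent."""

    loadings: np.ndarray          # (2, p)
    intercepts: np.ndarray        # (2, p)
    uniquenesses: np.ndarray      # (p,) shared across classes
    factor_means: np.ndarray      # (2,)
    factor_variances: np.ndarray  # (2,)
    mixing_weight: float          # P(class 1 = inconsistent)

    def class_moments(self):
        mu = self.intercepts + self.factor_means[:, None] * self.loadings
        sigma = [
            self.factor_variances[k] * np.outer(self.loadings[k], self.loadings[k])
            + np.diag(self.uniquenesses)
            for k in range(2)
        ]
        return mu, np.array(sigma)


def _theta_size(spec: FMASpec) -> int:
    npos, nneg, p = len(spec.pos_idx), len(spec.neg_idx), spec.p
    if spec.model_name == "steinmann":
        return (npos + nneg) + (npos + 2 * nneg) + p + 2  # + pi handled separately
    return p + p + 2


def _unpack(theta: np.ndarray, spec: FMASpec) -> FMAParameters:
    pos, neg, p = spec.pos_idx, spec.neg_idx, spec.p
    npos, nneg = len(pos), len(neg)
    if spec.model_name == "steinmann":
        i = 0
        mag = np.empty(p)
        mag[pos] = np.exp(theta[i:i + npos]); i += npos
        mag[neg] = np.exp(theta[i:i + nneg]); i += nneg
        nu = np.zeros((2, p))
        nu[:, pos] = theta[i:i + npos]; i += npos
        nu[0, neg] = theta[i:i + nneg]; i += nneg
        nu[1, neg] = theta[i:i + nneg]; i += nneg
        psi = np.exp(theta[i:i + p]); i += p
        alpha1 = theta[i]; i += 1
        phi1 = np.exp(theta[i]); i += 1
        lam = np.vstack([mag, mag])
        lam[0, neg] *= -1.0
        return FMAParameters(lam, nu, psi, np.array([alpha1, 0.0]),
                             np.array([phi1, 1.0]), np.nan)
    # arias
    i = 0
    nu1 = theta[i:i + p]; i += p
    psi = np.exp(theta[i:i + p]); i += p
    phi1 = np.exp(theta[i]); i += 1
    phi2 = np.exp(theta[i]); i += 1
    lam = np.ones((2, p))
    lam[0, neg] *= -1.0
    return FMAParameters(lam, np.vstack([nu1, nu1]), psi, np.zeros(2),
                         np.array([phi1, phi2]), np.nan)


def _pack(params: FMAParameters, spec: FMASpec) -> np.ndarray:
    pos, neg = spec.pos_idx, spec.neg_idx
    if spec.model_name == "steinmann":
        return np.concatenate([
            np.log(np.abs(params.loadings[1, pos])),
            np.log(np.abs(params.loadings[1, neg])),
            params.intercepts[1, pos],
            params.intercepts[0, neg],
            params.intercepts[1, neg],
            np.log(params.uniquenesses),
            [params.factor_means[0]],
            [np.log(params.factor_variances[0])],
        ])
    return np.concatenate([
        params.intercepts[0],
        np.log(params.uniquenesses),
        [np.log(params.factor_variances[0])],
        [np.log(params.factor_variances[1])],
    ])


# --------------------------------------------------------------------------
# likelihood machinery
# --------------------------------------------------------------------------

def _class_logdens(Y: np.ndarray, params: FMAParameters) -> np.ndarray:
    """(n, 2) per-class Gaussian log densities."""
    mu, sigmas = params.class_moments()
    n, p = Y.shape
    out = np.empty((n, 2))
    for k in range(2):
        L = np.linalg.cholesky(sigmas[k])
        dev = Y - mu[k]
        sol = solve_triangular(L, dev.T, lower=True)
        out[:, k] = -0.5 * (p * _LOG2PI + (sol**2).sum(axis=0)) \
            - np.log(np.diag(L)).sum()
    return out


def _observed_loglik(Y, params: FMAParameters, pi: float) -> float:
    ld = _class_logdens(Y, params)
    return float(logsumexp(ld + np.log([pi, 1.0 - pi]), axis=1).sum())


def _neg_q_and_grad(theta, spec, Nk, mk, Sk):
    """Expected complete-data -loglik (structural part) and its gradient."""
    params = _unpack(theta, spec)
    mu, sigmas = params.class_moments()
    pos, neg, p = spec.pos_idx, spec.neg_idx, spec.p
    q = 0.0
    g_mu = np.zeros((2, p))
    G = np.zeros((2, p, p))
    for k in range(2):
        Sinv = np.linalg.inv(sigmas[k])
        d = mk[k] - mu[k]
        C = Sk[k] + np.outer(d, d)
        sign, logdet = np.linalg.slogdet(sigmas[k])
        q += -0.5 * Nk[k] * (logdet + np.trace(Sinv @ C))
        g_mu[k] = Nk[k] * (Sinv @ d)
        G[k] = 0.5 * Nk[k] * (Sinv @ C @ Sinv - Sinv)

    lam, psi, phi = params.loadings, params.uniquenesses, params.factor_variances
    d_psi = G[0].diagonal() + G[1].diagonal()          # dQ/dpsi
    d_phi = np.array([lam[k] @ G[k] @ lam[k] for k in range(2)])

    if spec.model_name == "steinmann":
        alpha1 = params.factor_means[0]
        # magnitude gradient: lam[1] = +mag, lam[0] = sign-flipped mag
        sign0 = np.ones(p); sign0[neg] = -1.0
        d_mag = (2 * phi[1] * (G[1] @ lam[1])
                 + 2 * phi[0] * (G[0] @ lam[0]) * sign0
                 + alpha1 * g_mu[0] * sign0)
        mag = np.abs(lam[1])
        grad = np.concatenate([
            (d_mag * mag)[pos],
            (d_mag * mag)[neg],
            (g_mu[0] + g_mu[1])[pos],
            g_mu[0][neg],
            g_mu[1][neg],
            d_psi * psi,
            [lam[0] @ g_mu[0]],                        # alpha1
            [d_phi[0] * phi[0]],                       # log phi1
        ])
    else:
        grad = np.concatenate([
            g_mu[0] + g_mu[1],
            d_psi * psi,
            [d_phi[0] * phi[0]],
            [d_phi[1] * phi[1]],
        ])
    return -q, -grad


# --------------------------------------------------------------------------
# fitted result
# --------------------------------------------------------------------------

@dataclass
class FMAFit:
    spec: FMASpec
    parameters: FMAParameters
    loglikelihood: float
    n_free_parameters: int
    posteriors: np.ndarray
    entropy: float
    n_starts_run: int
    best_loglik_replications: int
    converged: bool
    loglik_history: np.ndarray = field(repr=False, default=None)

    def standardized_loadings(self) -> np.ndarray:
        """Within-class completely standardized loadings, (2, p)."""
        lam, phi, psi = (self.parameters.loadings,
                         self.parameters.factor_variances,
                         self.parameters.uniquenesses)
        sd = np.sqrt(lam**2 * phi[:, None] + psi[None, :])
        return lam * np.sqrt(phi)[:, None] / sd


@dataclass
class ClassAssignment:
    labels: np.ndarray        # strings
    max_posterior: np.ndarray

    @property
    def n_inconsistent(self) -> int:
        return int((self.labels == INCONSISTENT).sum())


# --------------------------------------------------------------------------
# EM driver
# --------------------------------------------------------------------------

def _em(Y, spec, theta0, pi0, max_iter, tol, floor):
    theta, pi = theta0.copy(), float(pi0)
    history = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        params = _unpack(theta, spec)
        ld = _class_logdens(Y, params) + np.log([pi, 1.0 - pi])
        ll = float(logsumexp(ld, axis=1).sum())
        history.append(ll)
        if ll + 1e-6 < prev:
            raise RuntimeError(f"EM loglikelihood decreased: {prev} -> {ll}")
        if abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
        w = np.exp(ld - logsumexp(ld, axis=1, keepdims=True))
        Nk = w.sum(axis=0)
        pi = float(np.clip(Nk[0] / len(Y), floor, 1.0 - floor))
        mk = (w.T @ Y) / Nk[:, None]
        Sk = np.empty((2, Y.shape[1], Y.shape[1]))
        for k in range(2):
            dev = Y - mk[k]
            Sk[k] = (dev * w[:, [k]]).T @ dev / Nk[k]
        res = minimize(_neg_q_and_grad, theta, args=(spec, Nk, mk, Sk),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": 60, "ftol": 1e-12, "gtol": 1e-9})
        if -res.fun > -_neg_q_and_grad(theta, spec, Nk, mk, Sk)[0]:
            theta = res.x
        # else keep theta: generalized EM step made no improvement
    return theta, pi, history, converged


def _base_init(Y, spec, rng):
    p = Y.shape[1]
    means = Y.mean(axis=0)
    var = Y.var(axis=0)
    pos, neg = spec.pos_idx, spec.neg_idx
    pi = rng.uniform(0.03, 0.35)
    if spec.model_name == "steinmann":
        mag = np.sqrt(np.clip(var * 0.5, 1e-3, None)) * rng.uniform(0.6, 1.4, p)
        nu = np.zeros((2, p))
        nu[:, :] = means + rng.normal(0, 0.2, p)
        nu[0, neg] += rng.normal(-0.5, 0.5, len(neg))
        lam = np.vstack([mag, mag]); lam[0, neg] *= -1
        params = FMAParameters(lam, nu, np.clip(var * 0.5, 1e-3, None)
                               * rng.uniform(0.5, 1.5, p),
                               np.array([rng.normal(0, 0.5), 0.0]),
                               np.array([np.exp(rng.normal(0, 0.5)), 1.0]), pi)
    else:
        lam = np.ones((2, p)); lam[0, neg] *= -1
        phi2 = max(float(np.var(Y.mean(axis=1))), 1e-2) * rng.uniform(0.5, 2.0)
        params = FMAParameters(
            lam, np.vstack([means, means]) + rng.normal(0, 0.1, p),
            np.clip(var * 0.5, 1e-3, None) * rng.uniform(0.5, 1.5, p),
            np.zeros(2),
            np.array([phi2 * rng.uniform(0.2, 1.0), phi2]), pi)
    return _pack(params, spec), pi


def fit_fma(
    data,
    spec: FMASpec,
    n_starts: int = 200,
    seed: int | None = None,
    n_final: int | None = None,
    init_iters: int = 15,
    max_iter: int = 5000,
    tol: float = 1e-7,
) -> FMAFit:
    """Fit a constrained two-class factor mixture by multistart generalized EM.

    ``data`` is a ResponseMatrix (integer codes consumed as continuous, as
    in the source methodology) or a plain (n, p) float array.
    """
    Y = data.to_numpy() if isinstance(data, ResponseMatrix) else np.asarray(data, float)
    n = len(Y)
    if n <= spec.n_free_parameters:
        raise ValueError("sample size must exceed the free-parameter count")
    rng = np.random.default_rng(seed)
    floor = 1.0 / (2.0 * n)
    if n_final is None:
        n_final = max(1, n_starts // 10)

    stage1 = []
    for _ in range(n_starts):
        theta0, pi0 = _base_init(Y, spec, rng)
        try:
            theta, pi, hist, _ = _em(Y, spec, theta0, pi0, init_iters, tol, floor)
            stage1.append((hist[-1], theta, pi))
        except (np.linalg.LinAlgError, FloatingPointError):
            continue
    if not stage1:
        raise RuntimeError("no multistart replication converged; diagnostics: "
                           f"{n_starts} starts all failed in the initial stage")
    stage1.sort(key=lambda t: -t[0])

    finals = []
    for ll0, theta, pi in stage1[:n_final]:
        try:
            theta_f, pi_f, hist, conv = _em(Y, spec, theta, pi, max_iter, tol, floor)
            finals.append((hist[-1], theta_f, pi_f, hist, conv))
        except (np.linalg.LinAlgError, FloatingPointError):
            continue
    if not finals:
        raise RuntimeError("all final-stage optimizations failed")
    finals.sort(key=lambda t: -t[0])
    best_ll, theta, pi, hist, conv = finals[0]
    replications = sum(1 for f in finals if abs(f[0] - best_ll) < 1e-2)

    params = _unpack(theta, spec)
    params.mixing_weight = pi
    if pi < 1.0 / n:
        warnings.warn("class may be empty: mixing weight below 1/N")
    ld = _class_logdens(Y, params) + np.log([pi, 1.0 - pi])
    post = np.exp(ld - logsumexp(ld, axis=1, keepdims=True))
    return FMAFit(
        spec=spec,
        parameters=params,
        loglikelihood=best_ll,
        n_free_parameters=spec.n_free_parameters,
        posteriors=post,
        entropy=entropy_index(post),
        n_starts_run=n_starts,
        best_loglik_replications=replications,
        converged=conv,
        loglik_history=np.array(hist),
    )


# --------------------------------------------------------------------------
# classification utilities
# --------------------------------------------------------------------------

def entropy_index(posteriors: np.ndarray) -> float:
    """Relative entropy E = 1 - sum(-p log p) / (N log K); 1 = perfect."""
    P = np.asarray(posteriors, dtype=float)
    if P.ndim != 2:
        raise ValueError("posteriors must be an N x K matrix")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    n, k = P.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(k)))


def classify(fit: FMAFit) -> ClassAssignment:
    """Modal class assignment; posterior ties go to the consistent class."""
    if not fit.converged:
        raise ValueError("cannot classify from a non-converged fit")
    p_inc = fit.posteriors[:, 0]
    labels = np.where(p_inc > 0.5, INCONSISTENT, CONSISTENT)
    return ClassAssignment(labels=labels,
                           max_posterior=np.maximum(p_inc, 1.0 - p_inc))


_KAPPA_BANDS = [
    (0.0, "none"),
    (0.20, "none-to-slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost-perfect"),
]


def kappa_band(kappa: float) -> str:
    if kappa <= 0:
        return "none"
    for upper, band in _KAPPA_BANDS[1:]:
        if kappa <= upper + 1e-12:
            return band
    return "almost-perfect"


def cohen_kappa(a: ClassAssignment, b: ClassAssignment):
    """Chance-corrected agreement between two screens, with qualitative band."""
    la, lb = np.asarray(a.labels), np.asarray(b.labels)
    if la.shape != lb.shape:
        raise ValueError("assignments must cover the same respondents")
    n = len(la)
    cats = [INCONSISTENT, CONSISTENT]
    table = np.array([[np.sum((la == r) & (lb == c)) for c in cats] for r in cats],
                     dtype=float)
    po = np.trace(table) / n
    pe = (table.sum(axis=1) * table.sum(axis=0)).sum() / n**2
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return kappa, kappa_band(kappa)


def screen_sample(data: ResponseMatrix, assignment: ClassAssignment) -> ResponseMatrix:
    """Drop rows labeled inconsistent; original row identifiers are kept."""
    if len(assignment.labels) != data.n:
        raise ValueError("assignment must cover all rows")
    keep = assignment.labels == CONSISTENT
    return ResponseMatrix(data.data.loc[keep], data.polarity, data.n_categories)
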