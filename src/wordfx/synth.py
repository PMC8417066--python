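"""Synthetic mixed-worded Likert data with a planted inconsistent class.

Emulates the structure of the motivating self-esteem study: a balanced
10-item scale (5 positively worded items, 5 recoded negatively worded
items) answered on a 4-point Likert scale by ~632 respondents, of whom a
small minority (~8%) respond inconsistently — their recoded negative items
load with flipped sign on the common factor.  Two planting mechanisms are
provided, mirroring the two constrained factor-mixture screening models:

``steinmann``
    Consistent-class loadings shared with the inconsistent class up to the
    sign flip on negative items; negative-item intercepts are class
    specific (default: shifted down one item SD in the inconsistent class,
    reproducing the lower observed negative-item means of flagged
    respondents); inconsistent-class factor mean/variance free.

``arias``
    Unit loadings (+1 positives, -1 negatives in the inconsistent class),
    shared intercepts, zero factor means, class-specific factor variances.

Continuous latent responses are y = nu + lambda_k f + eps with
f ~ N(alpha_k, Phi_k) and eps ~ N(0, diag(psi)), then discretized by
per-item thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .types import (
    NEGATIVE,
    POSITIVE,
    ResponseMatrix,
    default_item_names,
    default_polarity,
)

INCONSISTENT = "inconsistent"
CONSISTENT = "consistent"

# Default consistent-class standardized loadings, in the 0.45-0.78 band
# typical of well-behaved self-esteem items (positives then negatives).
_DEFAULT_STD_LOADINGS = np.array(
    [0.74, 0.78, 0.67, 0.65, 0.56, 0.49, 0.60, 0.45, 0.59, 0.50]
)
# Item intercepts on the 1..4 response metric (skewed toward agreement,
# as observed for self-esteem scales).
_DEFAULT_INTERCEPTS = np.array(
    [3.74, 3.66, 3.49, 3.42, 3.26, 3.21, 3.52, 2.89, 3.40, 3.29]
)
# Cumulative marginal proportions used to place default cut points.
_DEFAULT_CUM_PROPS = np.array([0.05, 0.15, 0.45])


def _default_spec_arrays(n_pos: int, n_neg: int):
    p = n_pos + n_neg
    if p == 10:
        std = _DEFAULT_STD_LOADINGS.copy()
        nu = _DEFAULT_INTERCEPTS.copy()
    else:
        std = np.linspace(0.45, 0.78, p)
        nu = np.full(p, 3.3)
    # unit unstandardized loadings; uniquenesses back out the standardized ones
    lam = np.ones(p)
    psi = (1.0 - std**2) / std**2
    sd = np.sqrt(lam**2 + psi)
    thresholds = nu[:, None] + sd[:, None] * ndtri(_DEFAULT_CUM_PROPS)[None, :]
    return lam, nu, psi, thresholds


@dataclass
class GeneratorSpec:
    """Population parameters for the two-class generating model.

    Class 1 is the inconsistent class (negative-item loadings flipped),
    class 2 the consistent reference class.
    """

    n_pos: int = 5
    n_neg: int = 5
    n_categories: int = 4
    mixing_weight: float = 0.08
    loadings: np.ndarray | None = None        # consistent-class, all > 0
    intercepts: np.ndarray | None = None
    uniquenesses: np.ndarray | None = None
    class_factor_means: tuple[float, float] = (0.0, 0.0)
    class_factor_variances: tuple[float, float] = (0.5, 1.0)
    thresholds: np.ndarray | None = None      # (p, n_categories - 1)
    seed: int = 0
    neg_intercept_shift: float = -1.0         # steinmann class-1 shift, in item SDs

    def __post_init__(self):
        lam, nu, psi, tau = _default_spec_arrays(self.n_pos, self.n_neg)
        if self.loadings is None:
            self.loadings = lam
        if self.intercepts is None:
            self.intercepts = nu
        if self.uniquenesses is None:
            self.uniquenesses = psi
        if self.thresholds is None:
            self.thresholds = tau
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.uniquenesses = np.asarray(self.uniquenesses, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.validate()

    @property
    def p(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def polarity(self) -> list[str]:
        return default_polarity(self.n_pos, self.n_neg)

    def validate(self) -> None:
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError("mixing_weight must lie in [0, 1]")
        if self.n_categories < 2:
            raise ValueError("need at least two response categories")
        for name, arr in [
            ("loadings", self.loadings),
            ("intercepts", self.intercepts),
            ("uniquenesses", self.uniquenesses),
        ]:
            if arr.shape != (self.p,):
                raise ValueError(f"{name} must have length {self.p}")
        if (self.uniquenesses <= 0).any():
            raise ValueError("uniquenesses must be positive")
        if any(v <= 0 for v in self.class_factor_variances):
            raise ValueError("class factor variances must be positive")
        if self.thresholds.shape[0] != self.p:
            raise ValueError("thresholds must have one row per item")
        if self.thresholds.shape[1] and (np.diff(self.thresholds, axis=1) <= 0).any():
            raise ValueError("thresholds must be strictly increasing per item")


@dataclass
class LabeledResponses:
    """Generated responses with ground-truth class labels and factor scores."""

    responses: ResponseMatrix
    true_class: np.ndarray           # strings in {inconsistent, consistent}
    latent_scores: np.ndarray
    continuous: np.ndarray = field(repr=False, default=None)

    def write(self, csv_path: str | Path, sidecar_path: str | Path, spec: GeneratorSpec) -> None:
        self.responses.write_csv(csv_path)
        payload = {
            "true_class": self.true_class.tolist(),
            "latent_scores": self.latent_scores.tolist(),
            "spec": {
                "n_pos": spec.n_pos,
                "n_neg": spec.n_neg,
                "n_categories": spec.n_categories,
                "mixing_weight": spec.mixing_weight,
                "loadings": spec.loadings.tolist(),
                "intercepts": spec.intercepts.tolist(),
                "uniquenesses": spec.uniquenesses.tolist(),
                "class_factor_means": list(spec.class_factor_means),
                "class_factor_variances": list(spec.class_factor_variances),
                "thresholds": spec.thresholds.tolist(),
                "seed": spec.seed,
            },
        }
        Path(sidecar_path).write_text(json.dumps(payload, indent=1))


def discretize(continuous_matrix: np.ndarray, thresholds) -> np.ndarray:
    """Map continuous values to categories: c iff value in (tau_{c-1}, tau_c].

    ``thresholds`` is per-item (rows) or a single shared vector.  An empty
    threshold list yields a single category everywhere.
    """
    X = np.atleast_2d(np.asarray(continuous_matrix, dtype=float))
    tau = np.asarray(thresholds, dtype=float)
    if tau.ndim == 1:
        tau = np.tile(tau, (X.shape[1], 1))
    if tau.shape[1] and (np.diff(tau, axis=1) <= 0).any():
        raise ValueError("thresholds must be strictly increasing per item")
    out = np.empty(X.shape, dtype=int)
    for j in range(X.shape[1]):
        # category = 1 + number of thresholds strictly below the value
        out[:, j] = 1 + np.searchsorted(tau[j], X[:, j], side="left")
    return out


def class_loadings(spec: GeneratorSpec, mechanism: str) -> np.ndarray:
    """(2, p) loading matrix: row 0 inconsistent, row 1 consistent."""
    neg = np.array([s == NEGATIVE for s in spec.polarity])
    if mechanism == "arias":
        lam2 = np.ones(spec.p)
    elif mechanism == "steinmann":
        lam2 = spec.loadings.copy()
    else:
        raise ValueError(f"unknown mechanism: {mechanism}")
    lam1 = lam2.copy()
    lam1[neg] *= -1.0
    return np.vstack([lam1, lam2])


def generate_responses(
    spec: GeneratorSpec,
    n: int,
    mechanism: str = "arias",
    continuous: bool = False,
) -> LabeledResponses:
    """Draw ``n`` respondents from the two-class model.

    With ``continuous=True`` the discretization step is skipped and the raw
    Gaussian responses are wrapped in the (integer-free) output, which
    makes exact parameter-recovery checks possible for the mixture fitters.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if spec.n_neg == 0:
        raise ValueError("classes not identifiable without negatively worded items")
    rng = np.random.default_rng(spec.seed)
    lam = class_loadings(spec, mechanism)
    nu = np.vstack([spec.intercepts, spec.intercepts])
    if mechanism == "steinmann":
        neg = np.array([s == NEGATIVE for s in spec.polarity])
        sd = np.sqrt(spec.loadings**2 * spec.class_factor_variances[0] + spec.uniquenesses)
        nu[0, neg] = nu[0, neg] + spec.neg_intercept_shift * sd[neg]
    alpha = np.asarray(spec.class_factor_means, dtype=float)
    phi = np.asarray(spec.class_factor_variances, dtype=float)

    k = (rng.random(n) >= spec.mixing_weight).astype(int)  # 0 = inconsistent
    f = alpha[k] + np.sqrt(phi[k]) * rng.standard_normal(n)
    eps = rng.standard_normal((n, spec.p)) * np.sqrt(spec.uniquenesses)
    Y = nu[k] + f[:, None] * lam[k] + eps

    labels = np.where(k == 0, INCONSISTENT, CONSISTENT)
    items = default_item_names(spec.n_pos, spec.n_neg)
    if continuous:
        df = pd.DataFrame(Y, columns=items)
        responses = ResponseMatrix.__new__(ResponseMatrix)
        responses.data = df
        responses.polarity = spec.polarity
        responses.n_categories = spec.n_categories
    else:
        codes = discretize(Y, spec.thresholds)
        responses = ResponseMatrix(
            pd.DataFrame(codes, columns=items), spec.polarity, spec.n_categories
        )
    return LabeledResponses(responses=responses, true_class=labels,
                            latent_scores=f, continuous=Y)
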