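"""Two-step polychoric correlation estimation for ordinal items.

The polychoric correlation treats each ordinal item as a discretized
standard-normal latent response: item ``X`` takes category ``c`` when the
latent variable falls in ``(tau_{c-1}, tau_c]``.  Thresholds are estimated
from the marginal category proportions; the correlation of each latent pair
is then estimated by maximizing the bivariate-normal contingency-table
likelihood with the thresholds held fixed (the classic two-step estimator,
which agrees with joint ML to ~1e-3 in practice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtri

from ._bvn import bvn_cdf
from .types import ResponseMatrix

RHO_BOUND = 0.999
#: returned magnitude for perfectly associated tables
PERFECT_EPS = 1e-3


class DegenerateItemError(ValueError):
    """Raised when an item shows fewer than two observed categories."""


@dataclass
class PolychoricResult:
    """Symmetric PSD polychoric correlation matrix plus per-item thresholds."""

    matrix: pd.DataFrame
    thresholds: dict[str, np.ndarray]
    smoothed: bool = False

    @property
    def items(self) -> list[str]:
        return list(self.matrix.columns)

    def to_numpy(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def write_csv(self, path) -> None:
        self.matrix.to_csv(path)

    @classmethod
    def read_matrix_csv(cls, path) -> pd.DataFrame:
        return pd.read_csv(path, index_col=0)


def estimate_thresholds(
    column: np.ndarray,
    n_categories: int | None = None,
    empty_policy: str = "merge",
) -> np.ndarray:
    """Thresholds tau_c = Phi^-1(cumulative proportion through category c).

    ``empty_policy`` governs categories with zero observed frequency:
    ``"merge"`` collapses them into their neighbour (only thresholds between
    observed categories are returned); ``"error"`` raises.  A column with a
    single observed category is degenerate and always raises.
    """
    column = np.asarray(column)
    if column.size == 0:
        raise ValueError("empty column")
    if n_categories is None:
        n_categories = int(column.max())
    counts = np.bincount(column.astype(int), minlength=n_categories + 1)[1:]
    if (counts == 0).any():
        if empty_policy == "error":
            empty = np.nonzero(counts == 0)[0] + 1
            raise ValueError(f"categories with zero frequency: {list(empty)}")
        counts = counts[counts > 0]
    if len(counts) < 2:
        raise DegenerateItemError("item has a single observed category")
    cum = np.cumsum(counts[:-1]) / counts.sum()
    return ndtri(cum)


def _cell_probs(rho: float, tx: np.ndarray, ty: np.ndarray) -> np.ndarray:
    """Bivariate-normal rectangle probabilities over the threshold grid."""
    ax = np.concatenate(([-np.inf], tx, [np.inf]))
    ay = np.concatenate(([-np.inf], ty, [np.inf]))
    grid = bvn_cdf(ax[:, None], ay[None, :], rho)
    probs = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return np.clip(probs, 1e-300, None)


def _pair_from_table(table: np.ndarray, tx: np.ndarray, ty: np.ndarray):
    def nll(rho):
        return -(table * np.log(_cell_probs(rho, tx, ty))).sum()

    res = minimize_scalar(nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": 1e-5})
    rho = float(res.x)
    converged = bool(res.success)
    if abs(rho) >= RHO_BOUND - 1e-4:
        # perfect association: likelihood increases toward the boundary
        rho = np.sign(rho) * (1.0 - PERFECT_EPS)
        warnings.warn("polychoric correlation at boundary; returning +-(1-eps)")
        converged = False
    return rho, converged


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xu, xi = np.unique(x, return_inverse=True)
    yu, yi = np.unique(y, return_inverse=True)
    table = np.zeros((len(xu), len(yu)))
    np.add.at(table, (xi, yi), 1.0)
    return table


def polychoric_pair(x, y, return_info: bool = False):
    """Two-step polychoric correlation of two ordinal vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    tx = estimate_thresholds(x)
    ty = estimate_thresholds(y)
    table = _contingency(x, y)
    rho, converged = _pair_from_table(table, tx, ty)
    if return_info:
        return rho, converged
    return rho


def nearest_psd_correlation(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues and rescale back to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, floor, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def polychoric_matrix(
    data: ResponseMatrix,
    empty_policy: str = "merge",
    thresholds: dict[str, np.ndarray] | None = None,
) -> PolychoricResult:
    """Pairwise polychoric correlation matrix with PSD repair.

    ``thresholds`` may be supplied to skip marginal re-estimation (useful in
    permutation loops, where column margins are unchanged by construction).
    """
    if data.p < 2:
        raise ValueError("need at least two items")
    X = data.data.to_numpy().astype(int)
    items = data.items
    if thresholds is None:
        thresholds = {
            c: estimate_thresholds(X[:, i], data.n_categories, empty_policy)
            for i, c in enumerate(items)
        }
    p = data.p
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            table = _contingency(X[:, i], X[:, j])
            rho, _ = _pair_from_table(table, thresholds[items[i]], thresholds[items[j]])
            R[i, j] = R[j, i] = rho
    smoothed = False
    min_eig = np.linalg.eigvalsh(R).min()
    if min_eig < -1e-8:
        R = nearest_psd_correlation(R)
        smoothed = True
    return PolychoricResult(
        matrix=pd.DataFrame(R, index=items, columns=items),
        thresholds=thresholds,
        smoothed=smoothed,
    )
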