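"""Eigenvalues and permutation-based parallel analysis on polychoric matrices.

Parallel analysis retains factors whose empirical eigenvalues exceed those
of comparison data with the same margins but no inter-item structure.  The
comparison sets are built by independently permuting each item's column of
the observed data (so the marginal category distributions are preserved
exactly), computing the polychoric correlation matrix of each permuted set,
and averaging eigenvalues across sets rank by rank (the mean criterion).
Retention follows the sequential rule: stop at the first rank where the
empirical eigenvalue no longer exceeds its random counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .polychoric import polychoric_matrix
from .types import ResponseMatrix


def correlation_eigenvalues(matrix) -> np.ndarray:
    """Descending eigenvalues of a full correlation matrix."""
    R = np.asarray(matrix, dtype=float) if not isinstance(matrix, pd.DataFrame) \
        else matrix.to_numpy(dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("matrix must have a unit diagonal")
    return np.sort(np.linalg.eigvalsh(R))[::-1]


@dataclass
class ParallelAnalysisResult:
    empirical_eigenvalues: np.ndarray
    mean_random_eigenvalues: np.ndarray
    n_retained: int
    n_random_sets: int
    seed: int | None

    def scree_frame(self) -> pd.DataFrame:
        """Both eigenvalue series, ready for scree plotting/export."""
        ranks = np.arange(1, len(self.empirical_eigenvalues) + 1)
        return pd.DataFrame({
            "rank": ranks,
            "empirical": self.empirical_eigenvalues,
            "mean_random": self.mean_random_eigenvalues,
        })


def _retained(empirical: np.ndarray, random_mean: np.ndarray) -> int:
    m = 0
    for e, r in zip(empirical, random_mean):
        if e > r:
            m += 1
        else:
            break
    return m


def parallel_analysis(
    data: ResponseMatrix,
    n_sets: int = 1000,
    seed: int | None = None,
    fast_pearson: bool = False,
) -> ParallelAnalysisResult:
    """Permutation parallel analysis with the mean criterion.

    ``fast_pearson=True`` swaps the polychoric matrices inside the
    permutation loop for Pearson correlations on the integer codes (a test
    convenience; the default matches the reference ordinal methodology).
    """
    X = data.data.to_numpy().astype(int)
    n, p = X.shape
    rng = np.random.default_rng(seed)

    if fast_pearson:
        empirical = correlation_eigenvalues(np.corrcoef(X, rowvar=False))
    else:
        emp_res = polychoric_matrix(data)
        empirical = correlation_eigenvalues(emp_res.to_numpy())
        # permutations preserve margins, so thresholds can be reused
        thresholds = emp_res.thresholds

    rand = np.empty((n_sets, p))
    for s in range(n_sets):
        perm = np.column_stack([X[rng.permutation(n), j] for j in range(p)])
        if fast_pearson:
            R = np.corrcoef(perm, rowvar=False)
        else:
            perm_rm = ResponseMatrix(
                pd.DataFrame(perm, columns=data.items),
                data.polarity, data.n_categories,
            )
            R = polychoric_matrix(perm_rm, thresholds=thresholds).to_numpy()
        rand[s] = correlation_eigenvalues(R)
    mean_random = rand.mean(axis=0)

    return ParallelAnalysisResult(
        empirical_eigenvalues=empirical,
        mean_random_eigenvalues=mean_random,
        n_retained=_retained(empirical, mean_random),
        n_random_sets=n_sets,
        seed=seed,
    )


def permutation_preserves_margins(original: np.ndarray, permuted: np.ndarray) -> bool:
    """Check that each column's category counts are unchanged."""
    for j in range(original.shape[1]):
        if not np.array_equal(np.bincount(original[:, j]), np.bincount(permuted[:, j])):
            return False
    return True
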