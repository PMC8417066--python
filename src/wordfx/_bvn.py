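"""Fast vectorized standard bivariate normal CDF.

Uses the single-integral (trigonometric) form

    Phi2(h, k, rho) = Phi(h) Phi(k)
        + (1 / 2 pi) * Int_0^{asin(rho)} exp(-(h^2 + k^2 - 2 h k sin t)
                                             / (2 cos^2 t)) dt,

evaluated with fixed Gauss-Legendre nodes.  The substitution r = sin(t)
removes the endpoint singularity at |rho| = 1, so a modest node count is
accurate over the whole admissible range.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

_N_NODES = 48
_GL_X, _GL_W = np.polynomial.legendre.leggauss(_N_NODES)

# Arguments beyond +-_CLAMP are numerically +-inf for a standard normal.
_CLAMP = 8.5


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    ``h`` and ``k`` broadcast against each other; ``rho`` is scalar.
    Infinite limits are allowed.
    """
    h = np.clip(np.asarray(h, dtype=float), -_CLAMP, _CLAMP)
    k = np.clip(np.asarray(k, dtype=float), -_CLAMP, _CLAMP)
    rho = float(rho)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation out of range: {rho}")

    base = ndtr(h) * ndtr(k)
    if rho == 0.0:
        return base

    alpha = np.arcsin(rho)
    # map Gauss-Legendre nodes from [-1, 1] to [0, alpha]
    t = 0.5 * alpha * (_GL_X + 1.0)
    w = 0.5 * abs(alpha) * _GL_W * np.sign(alpha)

    hh = h[..., None]
    kk = k[..., None]
    cos2 = np.cos(t) ** 2
    integrand = np.exp(-(hh**2 + kk**2 - 2.0 * hh * kk * np.sin(t)) / (2.0 * cos2))
    return base + (integrand * w).sum(axis=-1) / (2.0 * np.pi)
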