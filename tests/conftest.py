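import numpy as np
import pandas as pd
import pytest

from wordfx import GeneratorSpec, ResponseMatrix, generate_responses
from wordfx.types import default_polarity


@pytest.fixture(scope="session")
def polarity55():
    return default_polarity(5, 5)


@pytest.fixture(scope="session")
def clean_one_factor():
    """Uncontaminated strong one-factor ordinal data (lambda=0.8, n=1000)."""
    rng = np.random.default_rng(20240915)
    n, p, lam = 1000, 10, 0.8
    f = rng.standard_normal(n)
    z = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, p))
    cuts = np.array([-0.6745, 0.0, 0.6745])
    codes = 1 + np.searchsorted(cuts, z.reshape(-1)).reshape(n, p)
    cols = [f"p{i+1}" for i in range(5)] + [f"n{i+1}" for i in range(5)]
    return ResponseMatrix(pd.DataFrame(codes, columns=cols),
                          default_polarity(5, 5), 4)


@pytest.fixture(scope="session")
def contaminated_continuous():
    """Planted 10% inconsistent class, continuous responses (Arias pattern)."""
    spec = GeneratorSpec(mixing_weight=0.10, seed=31,
                         class_factor_variances=(0.5, 1.0))
    return generate_responses(spec, 2000, mechanism="arias", continuous=True)
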