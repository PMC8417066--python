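import numpy as np
from scipy.special import ndtri

from wordfx import GeneratorSpec


def symmetric_spec(**kwargs):
    """Generator spec with equal loadings/intercepts across blocks, so the
    positive and negative item blocks are exchangeable."""
    sd = np.sqrt(2.0)
    tau = 3.0 + sd * ndtri([0.25, 0.5, 0.75])
    return GeneratorSpec(
        loadings=np.ones(10),
        intercepts=np.full(10, 3.0),
        uniquenesses=np.ones(10),
        thresholds=np.tile(tau, (10, 1)),
        **kwargs,
    )
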