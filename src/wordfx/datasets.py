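"""Packaged polychoric correlation matrices from the motivating study.

Three 10x10 polychoric matrices for the Rosenberg Self-Esteem Scale
(items p1-p5 positively worded, n1-n5 recoded negatively worded):

``total``      the full sample (N = 632);
``steinmann``  after removing respondents flagged by the sign-flip-linked
               mixture screen (N = 588);
``arias``      after removing respondents flagged by the unit-loading
               mixture screen (N = 582).

One printed cell of the total-sample matrix (p3-p4) appears as ".052" in
the source table, an evident typo for 0.52; the fixture encodes 0.52.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .types import default_polarity

SAMPLE_SIZES = {"total": 632, "steinmann": 588, "arias": 582}

RSES_POLARITY = default_polarity(5, 5)


def table1_matrix(sample: str) -> pd.DataFrame:
    """Load one of the packaged 10x10 polychoric matrices."""
    if sample not in SAMPLE_SIZES:
        raise KeyError(f"sample must be one of {sorted(SAMPLE_SIZES)}")
    ref = resources.files("wordfx.data") / f"table1_{sample}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, index_col=0)


def table1_sample_size(sample: str) -> int:
    return SAMPLE_SIZES[sample]
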