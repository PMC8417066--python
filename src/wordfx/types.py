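"""Shared containers: ordinal response matrices with item polarity."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class ResponseMatrix:
    """N x p matrix of integer Likert codes plus item polarity labels.

    ``data`` holds one column per item (codes in ``1..n_categories``);
    ``polarity`` marks each item as positively worded or as a recoded
    negatively worded item.  Row index identifies respondents and is
    preserved by screening operations.
    """

    data: pd.DataFrame
    polarity: list[str]
    n_categories: int

    def __post_init__(self):
        if len(self.polarity) != self.data.shape[1]:
            raise ValueError("polarity must label every item")
        bad = set(self.polarity) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"unknown polarity labels: {sorted(bad)}")
        values = self.data.to_numpy()
        if values.size and (values.min() < 1 or values.max() > self.n_categories):
            raise ValueError("category codes outside [1, n_categories]")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]

    @property
    def items(self) -> list[str]:
        return list(self.data.columns)

    @property
    def positive_items(self) -> list[str]:
        return [c for c, s in zip(self.data.columns, self.polarity) if s == POSITIVE]

    @property
    def negative_items(self) -> list[str]:
        return [c for c, s in zip(self.data.columns, self.polarity) if s == NEGATIVE]

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def polarity_map(self) -> dict[str, str]:
        return dict(zip(self.data.columns, self.polarity))

    # ---- I/O ---------------------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        polarity: list[str] | dict[str, str],
        n_categories: int | None = None,
    ) -> "ResponseMatrix":
        df = pd.read_csv(path)
        if isinstance(polarity, dict):
            polarity = [polarity[c] for c in df.columns]
        if n_categories is None:
            n_categories = int(df.to_numpy().max())
        return cls(df, list(polarity), n_categories)


def read_polarity_yaml(path: str | Path) -> dict[str, str]:
    """Read an item -> polarity mapping from YAML ({item: positive|negative})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {str(k): str(v) for k, v in raw.items()}


def default_item_names(n_pos: int, n_neg: int) -> list[str]:
    return [f"p{i + 1}" for i in range(n_pos)] + [f"n{i + 1}" for i in range(n_neg)]


def default_polarity(n_pos: int, n_neg: int) -> list[str]:
    return [POSITIVE] * n_pos + [NEGATIVE] * n_neg
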