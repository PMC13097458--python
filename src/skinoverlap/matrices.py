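"""Square overlap matrices shared by the individual- and gamut-level methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OverlapMatrix"]


@dataclass
class OverlapMatrix:
    """Percentages of overlap between ordered group pairs.

    Rows are reference groups, columns comparison groups; ``values[i, j]``
    is the percentage of group i's samples (or gamut cubes) that overlap
    group j.  The diagonal is 100 by convention — a group trivially
    overlaps itself — and is excluded from medians and correlations
    downstream.
    """

    method: str
    groups: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.groups)
        if self.values.shape != (k, k):
            raise ValueError(f"values must be {k}×{k}, got {self.values.shape}")
        if np.any(self.values < -1e-9) or np.any(self.values > 100 + 1e-9):
            raise ValueError("overlap percentages must lie in [0, 100]")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def cell(self, reference: str, comparison: str) -> float:
        i = self.groups.index(reference)
        j = self.groups.index(comparison)
        return float(self.values[i, j])

    def off_diagonal(self) -> np.ndarray:
        """Off-diagonal cells in row-major order (56 cells for 8 groups)."""
        mask = ~np.eye(self.n_groups, dtype=bool)
        return self.values[mask]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.groups), columns=list(self.groups))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="reference", float_format="%.6g")

    @classmethod
    def from_csv(cls, path, method: str) -> "OverlapMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("matrix CSV must have identical row and column group order")
        return cls(method=method, groups=tuple(df.index), values=df.to_numpy(dtype=float))
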