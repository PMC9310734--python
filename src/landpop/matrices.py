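"""Labelled symmetric distance matrices with zero diagonal.

The kind tag records what the matrix measures: geographic (IBD), terrain
resistance (IBR_Terrain), habitat resistance (IBR_Habitat), historical
instability (IBI), environmental (IBE), FST, or individual genetic distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

KINDS = ("IBD", "IBR_Terrain", "IBR_Habitat", "IBI", "IBE", "FST", "genetic", "")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        finite = np.isfinite(self.values)
        sym_ok = np.allclose(
            self.values[finite & finite.T & np.ones_like(finite)],
            self.values.T[finite & finite.T & np.ones_like(finite)],
            atol=1e-12, rtol=0,
        )
        if not sym_ok or not np.array_equal(np.isinf(self.values), np.isinf(self.values.T)):
            raise ValueError("distance matrix must be symmetric to 1e-12")
        if not np.allclose(np.diag(self.values), 0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def transform(self, fn, kind: str | None = None) -> "DistanceMatrix":
        out = fn(self.values.copy())
        np.fill_diagonal(out, 0.0)
        return DistanceMatrix(list(self.labels), out, self.kind if kind is None else kind)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        # align columns to row order by label, not by position
        df = df.loc[:, list(df.index)]
        return cls(list(df.index), df.to_numpy(), kind)
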