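"""Labelled symmetric pairwise matrices (F_ST, distances, dissimilarities, weights)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["PairwiseMatrix"]


@dataclass(frozen=True)
class PairwiseMatrix:
    """A symmetric matrix over labelled populations with zero diagonal.

    ``NaN`` marks an explicitly unavailable pair (e.g. no shared typed locus,
    no finite-cost path); consumers drop such pairs listwise and log the count.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if v.shape != (k, k):
            raise ValueError(f"matrix shape {v.shape} does not match {k} labels")
        if len(set(self.labels)) != k:
            raise ValueError("duplicate labels")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(v - v.T), initial=0.0)
        if asym > 1e-9:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:g})")
        nan_mismatch = np.isnan(v) != np.isnan(v.T)
        if nan_mismatch.any():
            raise ValueError("asymmetric NA pattern")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_function(
        cls, labels: Sequence[str], fn: Callable[[str, str], float]
    ) -> "PairwiseMatrix":
        k = len(labels)
        v = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                v[i, j] = v[j, i] = fn(labels[i], labels[j])
        return cls(tuple(labels), v)

    # -- access -----------------------------------------------------------

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    @property
    def n(self) -> int:
        return len(self.labels)

    def pairs(self) -> list[tuple[str, str]]:
        """Unordered pairs in the canonical lower-triangle unrolling order:
        ``(0,1), (0,2), ..., (1,2), ...`` by label order."""
        return [
            (self.labels[i], self.labels[j])
            for i in range(self.n)
            for j in range(i + 1, self.n)
        ]

    def condensed(self) -> np.ndarray:
        """Off-diagonal values in :meth:`pairs` order."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def permute(self, perm: Sequence[int]) -> np.ndarray:
        """Values with rows and columns permuted by the same index vector."""
        perm = np.asarray(perm)
        return self.values[np.ix_(perm, perm)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    # -- I/O ----------------------------------------------------------------

    def write(self, path: str | Path, sep: str = "\t") -> None:
        """Write as a labelled square delimited table."""
        self.to_dataframe().to_csv(path, sep=sep, index_label="")

    def write_lower_triangle(self, path: str | Path, sep: str = "\t") -> None:
        """Write as a labelled lower-triangle table (first row is the header)."""
        lines = [sep.join([""] + list(self.labels[:-1]))]
        for i, lab in enumerate(self.labels):
            cells = [f"{self.values[i, j]:.6g}" for j in range(i)]
            lines.append(sep.join([lab] + cells))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "PairwiseMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        labels = tuple(str(x) for x in df.index)
        if tuple(str(x) for x in df.columns) != labels:
            raise ValueError(f"{path}: row and column labels differ")
        return cls(labels, df.to_numpy(dtype=float))
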