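"""Labeled symmetric distance matrices.

``DistanceMatrix`` is the lingua franca between the morphometric, genetic
and tree-space stages: a square, symmetric, nonnegative matrix with a zero
diagonal and unique string labels.  I/O covers labeled CSV and square
PHYLIP, the two plain-text formats used throughout the package.
"""

from __future__ import annotations

import io
from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix", "FeatureMatrix"]

_SYM_TOL = 1e-12


class DistanceMatrix:
    """Symmetric nonnegative matrix over uniquely labeled objects.

    Parameters
    ----------
    labels
        Unique object labels, one per row/column.
    values
        Square array of pairwise distances.  Must be symmetric to 1e-12;
        the diagonal is forced to zero.
    """

    def __init__(self, labels: Sequence[str], values: np.ndarray) -> None:
        labels = [str(l) for l in labels]
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError(f"values shape {values.shape} does not match {n} labels")
        if len(set(labels)) != n:
            raise ValueError("duplicate labels in DistanceMatrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite entries in DistanceMatrix")
        if np.any(values < -_SYM_TOL):
            raise ValueError("negative entries in DistanceMatrix")
        if np.max(np.abs(values - values.T), initial=0.0) > max(_SYM_TOL, 1e-9 * np.max(np.abs(values), initial=0.0)):
            raise ValueError("matrix is not symmetric")
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        np.clip(values, 0.0, None, out=values)
        self.labels: list[str] = labels
        self.values: np.ndarray = values

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"DistanceMatrix(n={self.n}, labels={self.labels[:4]}...)"

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns in the given label order."""
        if set(labels) != set(self.labels):
            raise ValueError("label sets differ")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Row-major upper-triangle (i<j) vector of length n(n-1)/2."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    # ------------------------------- I/O ------------------------------
    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError("CSV row and column labels differ")
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    def to_phylip(self, path) -> None:
        """Write square (lower+upper) PHYLIP distance format."""
        lines = [f"{self.n}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "  " + "  ".join(f"{v:.10g}" for v in row))
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w") as fh:
                fh.write(text)

    @classmethod
    def from_phylip(cls, path) -> "DistanceMatrix":
        if hasattr(path, "read"):
            text = path.read()
        else:
            with open(path) as fh:
                text = fh.read()
        lines = [l for l in text.splitlines() if l.strip()]
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for line in lines[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels, np.array(rows))


def check_aligned(*matrices: DistanceMatrix) -> None:
    """Raise unless all matrices share identical labels in identical order."""
    ref = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != ref:
            raise ValueError(
                "distance matrices are not label-aligned; reorder() them first "
                f"({ref[:3]}... vs {m.labels[:3]}...)"
            )


class FeatureMatrix:
    """Colonies x traits value table (optionally standardized per trait)."""

    def __init__(self, colony_ids: Sequence[str], trait_names: Sequence[str], values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(colony_ids), len(trait_names)):
            raise ValueError("values shape does not match ids/traits")
        if len(set(colony_ids)) != len(list(colony_ids)):
            raise ValueError("duplicate colony ids")
        self.colony_ids = [str(c) for c in colony_ids]
        self.trait_names = [str(t) for t in trait_names]
        self.values = values

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.colony_ids, columns=self.trait_names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float))
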