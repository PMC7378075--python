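"""Core data containers for the clustering pipeline.

The pipeline operates on a genes × cells expression matrix, a cells × cells
Euclidean distance matrix, and a cells × l embedded coordinate matrix
(l = 2 by default). Containers validate their invariants at construction so
that downstream stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "DistanceMatrix",
    "Embedding",
    "Clustering",
]

_SYM_TOL = 1e-9


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes × cells matrix of non-negative expression values.

    Rows are genes, columns are cells. Values must be finite and >= 0.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", _check_unique(self.gene_ids, "gene"))
        object.__setattr__(self, "cell_ids", _check_unique(self.cell_ids, "cell"))
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if np.any(values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric cell × cell dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_ids", _check_unique(self.cell_ids, "cell"))
        n = len(self.cell_ids)
        if values.shape != (n, n):
            raise ValueError(f"distance matrix shape {values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(values)):
            raise ValueError("distances must be finite")
        if np.any(values < 0):
            raise ValueError("distances must be non-negative")
        if np.any(np.abs(np.diagonal(values)) > _SYM_TOL):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(np.abs(values - values.T) > _SYM_TOL):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass(frozen=True)
class Embedding:
    """Cells × l reduced coordinates produced by t-SNE, with its seed."""

    coords: np.ndarray
    seed: int
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2:
            raise ValueError("embedding coordinates must be 2-D")
        n, l = coords.shape
        if not 2 <= l <= n:
            raise ValueError(f"embedding dimension l={l} must satisfy 2 <= l <= {n}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("embedding coordinates must be finite")
        if self.cell_ids:
            ids = _check_unique(self.cell_ids, "cell")
            if len(ids) != n:
                raise ValueError("cell_ids length does not match coordinates")
            object.__setattr__(self, "cell_ids", ids)

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def l(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class Clustering:
    """An assignment of each cell to one of k clusters.

    Labels are integers in [0, k) and every cluster index occurs at least
    once.
    """

    labels: np.ndarray
    k: int
    centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        present = np.unique(labels)
        if present.min(initial=0) < 0 or present.max(initial=0) >= self.k:
            raise ValueError(f"labels must lie in [0, {self.k})")
        if len(present) != self.k:
            raise ValueError("every cluster index in [0, k) must be non-empty")
        if self.centroids is not None:
            centroids = np.asarray(self.centroids, dtype=float)
            if centroids.shape[0] != self.k:
                raise ValueError("centroids must have k rows")
            object.__setattr__(self, "centroids", centroids)

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    def members(self, c: int) -> frozenset[int]:
        """Indices of the cells assigned to cluster ``c``."""
        return frozenset(np.flatnonzero(self.labels == c).tolist())
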