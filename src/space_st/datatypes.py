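"""Core in-memory containers for spot-level spatial transcriptomics.

The conventions are fixed package-wide: expression matrices are genes x spots
(genes are rows), coordinates are spots x d with d = 2 by default, and spot
identifiers align the two axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_ids(ids: list[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class RawCounts:
    """Raw (or otherwise nonnegative) expression values, genes x spots."""

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("empty expression matrix")
        self.gene_ids = _check_ids(list(self.gene_ids), "gene")
        self.spot_ids = _check_ids(list(self.spot_ids), "spot")
        if len(self.gene_ids) != m or len(self.spot_ids) != n:
            raise ValueError("identifier lists do not match matrix dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if np.any(self.values < 0):
            raise ValueError("negative expression values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpressionMatrix:
    """Expression values on the analysis scale (possibly normalized)."""

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.gene_ids = _check_ids(list(self.gene_ids), "gene")
        self.spot_ids = _check_ids(list(self.spot_ids), "spot")
        m, n = self.values.shape
        if len(self.gene_ids) != m or len(self.spot_ids) != n:
            raise ValueError("identifier lists do not match matrix dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[rows], list(gene_ids), list(self.spot_ids), self.normalized
        )


@dataclass
class SpatialCoords:
    """Spot coordinates, spots x d (d = 2 for standard spot arrays)."""

    coords: np.ndarray
    spot_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coordinates must be a 2-D array (spots x d)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not self.spot_ids:
            self.spot_ids = [f"spot_{i}" for i in range(self.coords.shape[0])]
        self.spot_ids = _check_ids(list(self.spot_ids), "spot")
        if len(self.spot_ids) != self.coords.shape[0]:
            raise ValueError("spot identifiers do not match coordinate rows")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]
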