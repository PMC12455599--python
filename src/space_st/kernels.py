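"""Spatial kernel bank: Gaussian and Cosine spot-similarity matrices.

Ten kernels by default — five Gaussian ``exp(-d^2 / 2l^2)`` and five Cosine
``cos(2 pi d / phi)`` — with the scale parameters ``l`` and ``phi`` set to
quantiles of the nonzero pairwise-distance distribution so the bank spans
short- to long-range spatial structure. Cosine kernels may be indefinite;
the score-test null distribution handles mixed-sign eigenvalue weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import SpatialCoords

DEFAULT_QUANTILES = (0.1, 0.25, 0.5, 0.75, 0.9)


@dataclass(frozen=True)
class KernelSpec:
    family: str  # "gaussian" or "cosine"
    scale: float  # lengthscale l (gaussian) or period phi (cosine)

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "cosine"):
            raise ValueError(f"unknown kernel family: {self.family!r}")
        if not self.scale > 0:
            raise ValueError("kernel scale must be positive")


@dataclass
class KernelMatrix:
    K: np.ndarray
    spec: KernelSpec


def pairwise_distances(coords: SpatialCoords | np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between all spot pairs."""
    xy = coords.coords if isinstance(coords, SpatialCoords) else np.asarray(coords, float)
    if xy.shape[0] < 2:
        raise ValueError("need at least two spots")
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinates")
    return squareform(pdist(xy))


def gaussian_kernel(D: np.ndarray, l: float) -> KernelMatrix:
    if not l > 0:
        raise ValueError("gaussian lengthscale must be positive")
    return KernelMatrix(np.exp(-(D**2) / (2.0 * l * l)), KernelSpec("gaussian", float(l)))


def cosine_kernel(D: np.ndarray, phi: float) -> KernelMatrix:
    if not phi > 0:
        raise ValueError("cosine period must be positive")
    return KernelMatrix(np.cos(2.0 * np.pi * D / phi), KernelSpec("cosine", float(phi)))


def distance_scales(
    coords: SpatialCoords,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
    max_spots: int = 5000,
    seed: int = 0,
) -> np.ndarray:
    """Quantiles of the nonzero pairwise-distance distribution.

    For more than ``max_spots`` spots the quantiles are estimated from a
    fixed-seed subsample (memory guard).
    """
    xy = coords.coords
    if xy.shape[0] > max_spots:
        rng = np.random.default_rng(seed)
        xy = xy[rng.choice(xy.shape[0], max_spots, replace=False)]
    d = pdist(xy)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("all coordinates identical: zero distance range")
    return np.quantile(d, quantiles)


def make_kernel_bank(
    coords: SpatialCoords,
    n_each: int = 5,
    quantiles: tuple[float, ...] | None = None,
    families: tuple[str, ...] = ("gaussian", "cosine"),
) -> list[KernelMatrix]:
    """Build the kernel bank (default 5 Gaussian + 5 Cosine = 10 kernels)."""
    if coords.n_spots < 3:
        raise ValueError("need at least three spots for a kernel bank")
    if quantiles is None:
        quantiles = DEFAULT_QUANTILES if n_each == 5 else tuple(np.linspace(0.1, 0.9, n_each))
    if len(quantiles) != n_each:
        raise ValueError("number of quantiles must equal n_each")
    scales = distance_scales(coords, tuple(quantiles))
    D = pairwise_distances(coords)
    bank: list[KernelMatrix] = []
    for family in families:
        for s in scales:
            if family == "gaussian":
                bank.append(gaussian_kernel(D, s))
            else:
                bank.append(cosine_kernel(D, s))
    return bank
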