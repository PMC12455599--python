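"""Clustering evaluation: adjusted Rand index and percentage of abnormal spots.

PAS is the fraction of spots whose domain label differs from at least
``disagree_min`` of their ``n_neighbors`` nearest spots (defaults 6 of 10);
low PAS means spatially coherent domains.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .datatypes import SpatialCoords


def ari(a, b) -> float:
    """Adjusted Rand index between two labelings (permutation-model
    chance correction on the contingency table)."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


def pas(
    labels,
    coords: SpatialCoords | np.ndarray,
    n_neighbors: int = 10,
    disagree_min: int = 6,
) -> float:
    """Percentage of abnormal spots.

    Neighbors are the ``n_neighbors`` nearest spots by Euclidean distance,
    excluding the spot itself; distance ties at the neighborhood boundary are
    broken deterministically by ascending spot index.
    """
    labels = np.asarray(labels).ravel()
    xy = coords.coords if isinstance(coords, SpatialCoords) else np.asarray(coords, float)
    n = xy.shape[0]
    if labels.size != n:
        raise ValueError("labels do not match the number of spots")
    if n <= n_neighbors:
        raise ValueError("need more spots than neighbors")
    abnormal = 0
    idx = np.arange(n)
    # full distance matrix in chunks; lexsort gives the deterministic
    # (distance, index) tie-break
    chunk = max(1, int(2e7) // n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = np.sqrt(((xy[start:stop, None, :] - xy[None, :, :]) ** 2).sum(-1))
        scale = max(d.max(), 1e-300)
        for i in range(start, stop):
            # quantize so that exact-tie neighbor sets survive rigid motions
            # of the coordinates (floating-point jitter), then break ties by
            # ascending spot index
            row = np.round(d[i - start] / scale, 9)
            row[i] = np.inf  # exclude self
            order = np.lexsort((idx, row))[:n_neighbors]
            if (labels[order] != labels[i]).sum() >= disagree_min:
                abnormal += 1
    return abnormal / n
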