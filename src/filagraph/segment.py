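"""Foreground estimation: split the likelihood image into filament and
non-filament pixels by two-class 1-D clustering.

Clustering scalar values into two classes reduces to a threshold: centroids
are initialised at the minimum and maximum value and iterated to convergence
(each value assigned to the nearer centroid, centroids recomputed), after
which the decision boundary is the midpoint of the converged centroids.  The
resulting mask is cleaned by removing small connected components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import remove_small_objects

__all__ = ["BinaryMask", "cluster_threshold", "estimate_foreground"]

DEFAULT_MIN_OBJECT_PX = 20


@dataclass
class BinaryMask:
    """Binary foreground mask plus the threshold that produced it."""

    values: np.ndarray  # bool
    min_object_px: int
    threshold: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def cluster_threshold(values: np.ndarray, max_iter: int = 500) -> float:
    """Two-class 1-D clustering threshold (midpoint of converged centroids).

    Returns NaN for degenerate input where all values are equal.
    """
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return float("nan")
    c0, c1 = lo, hi
    for _ in range(max_iter):
        t = 0.5 * (c0 + c1)
        low = v < t
        # Both clusters are nonempty while c0 < t < c1 and min/max straddle t.
        n0 = float(c0) if not low.any() else float(v[low].mean())
        n1 = float(c1) if low.all() else float(v[~low].mean())
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    return 0.5 * (c0 + c1)


def estimate_foreground(
    lik_values: np.ndarray, min_object_px: int = DEFAULT_MIN_OBJECT_PX
) -> BinaryMask:
    """Binary foreground mask from a likelihood map.

    Foreground is the cluster with the larger centroid, i.e. exactly the set
    ``{pixels >= t*}`` for the converged threshold ``t*``.  8-connected
    components smaller than ``min_object_px`` are removed.  A constant input
    yields an all-background mask (with a warning), not an error.
    """
    values = getattr(lik_values, "values", lik_values)
    values = np.asarray(values, dtype=float)
    if min_object_px < 1:
        raise ValueError("min_object_px must be >= 1")
    t = cluster_threshold(values)
    if np.isnan(t):
        warnings.warn(
            "degenerate likelihood image (all values equal): all-background mask",
            stacklevel=2,
        )
        return BinaryMask(
            values=np.zeros(values.shape, dtype=bool),
            min_object_px=min_object_px,
            threshold=float("nan"),
        )
    mask = values >= t
    if min_object_px > 1:
        # remove components strictly smaller than min_object_px
        mask = remove_small_objects(mask, max_size=min_object_px - 1, connectivity=2)
    return BinaryMask(values=mask, min_object_px=min_object_px, threshold=t)
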