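"""Constant-curvature arc geometry shared by the simulator and template bank.

Filaments are modelled as circular arcs: the simplest one-parameter family of
curved centerlines, matched by the curvature axis of the template bank.
Coordinates are (row, col) with row increasing downwards; an orientation of
``theta`` radians points along ``(sin(theta), cos(theta))``, i.e. it is the
angle of the tangent measured from the +col axis.
"""

from __future__ import annotations

import numpy as np

__all__ = ["arc_points", "polyline_length", "min_dist_to_polyline"]


def arc_points(
    length_px: float,
    curvature_per_px: float = 0.0,
    orientation_rad: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
    step_px: float = 0.5,
) -> np.ndarray:
    """Sample a constant-curvature arc of total arc length ``length_px``.

    The arc is centred (by arc length) on ``center``; ``orientation_rad`` is
    the tangent direction at the arc midpoint and ``curvature_per_px`` the
    signed curvature (1/radius).  Returns an ``(N, 2)`` float array of
    (row, col) points spaced ``step_px`` apart in arc length, endpoints
    included.
    """
    if length_px <= 0:
        raise ValueError(f"length_px must be positive, got {length_px}")
    if step_px <= 0:
        raise ValueError(f"step_px must be positive, got {step_px}")
    n = max(int(np.ceil(length_px / step_px)), 1)
    s = np.linspace(-0.5 * length_px, 0.5 * length_px, n + 1)
    if abs(curvature_per_px) < 1e-12:
        u = s
        v = np.zeros_like(s)
    else:
        r = 1.0 / curvature_per_px
        phi = s * curvature_per_px
        u = r * np.sin(phi)
        v = r * (1.0 - np.cos(phi))
    ct, st = np.cos(orientation_rad), np.sin(orientation_rad)
    rows = center[0] + u * st + v * ct
    cols = center[1] + u * ct - v * st
    return np.column_stack([rows, cols])


def polyline_length(points: np.ndarray, closed: bool = False) -> float:
    """Arc length of a polyline given as an (N, 2) array of points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    if len(pts) < 2:
        return 0.0
    total = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    if closed:
        total += float(np.linalg.norm(pts[-1] - pts[0]))
    return total


def min_dist_to_polyline(
    query: np.ndarray, poly: np.ndarray, chunk: int = 4096
) -> np.ndarray:
    """Exact minimum distance from each query point to a polyline.

    ``query`` is (K, 2), ``poly`` is (M, 2) with M >= 1.  Distances are to the
    segments of the polyline (projection onto each segment, clipped to its
    endpoints), so the result does not depend on the sampling step of the
    polyline beyond its chord error.
    """
    q = np.asarray(query, dtype=float)
    p = np.asarray(poly, dtype=float)
    if len(p) == 1:
        return np.linalg.norm(q - p[0], axis=1)
    a = p[:-1]
    ab = p[1:] - a
    denom = np.maximum((ab**2).sum(axis=1), 1e-300)
    out = np.empty(len(q), dtype=float)
    for lo in range(0, len(q), chunk):
        block = q[lo : lo + chunk]
        ap = block[:, None, :] - a[None, :, :]
        t = np.clip((ap * ab).sum(axis=-1) / denom, 0.0, 1.0)
        proj = a + t[..., None] * ab
        d = np.linalg.norm(block[:, None, :] - proj, axis=-1)
        out[lo : lo + chunk] = d.min(axis=1)
    return out
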