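"""Synthetic filament-network images with known ground truth.

The generator emulates maximum-projected fluorescence micrographs of labelled
filament networks: each filament is a constant-curvature arc with a Gaussian
cross-section, lengths are Gaussian with a truncation floor, and the image is
corrupted by additive Gaussian noise over a uniform background.  Every image
carries a full ground-truth record (centerlines and lengths) so that tracing
accuracy can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .geometry import arc_points, polyline_length
from .image import IntensityImage

__all__ = [
    "SyntheticNetworkSpec",
    "GroundTruthFilament",
    "GroundTruthNetwork",
    "sample_filament",
    "render_network",
    "generate_validation_bank",
]

#: Margin (px) kept between a centerline and the frame when placing filaments.
_PLACEMENT_MARGIN_PX = 3.0
#: Placement attempts before falling back to border clipping.
_MAX_PLACEMENT_TRIES = 200
#: Resampling attempts for the truncated length distribution.
_MAX_LENGTH_TRIES = 1000
#: Identifiability constraint of the validation protocol: two centerlines
#: closer than this are optically merged at the default ridge width ...
_MERGE_DIST_PX = 3.0
#: ... which is acceptable only where they cross at a resolvable angle.
#: Contacts below this local tangent angle (tangential overlaps, smooth
#: tip-to-tip continuations) render as one unbroken ridge whose ground-truth
#: identity no pixel pattern can express; such placements are resampled.
_MIN_CROSSING_ANGLE_DEG = 20.0
#: Whole-network resampling attempts for the identifiability constraint.
_MAX_OVERLAP_TRIES = 100


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Parameters of one synthetic network image.

    Defaults follow the validation conditions used throughout the package:
    128x128 px frames, Gaussian lengths with mean 50 px and SD 20 px
    truncated at 10 px, a 1.5 px Gaussian ridge cross-section, curvature up
    to 0.02/px, and additive Gaussian noise with SD equal to 10% of the
    foreground peak.
    """

    image_height_px: int = 128
    image_width_px: int = 128
    n_filaments: int = 10
    length_mean_px: float = 50.0
    length_sd_px: float = 20.0
    min_length_px: float = 10.0
    width_sigma_px: float = 1.5
    curvature_max_per_px: float = 0.02
    foreground_peak: float = 200.0
    background_level: float = 20.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px < 1 or self.image_width_px < 1:
            raise ValueError("zero-area image")
        if self.n_filaments < 0:
            raise ValueError("n_filaments must be >= 0")
        if self.length_mean_px <= 0:
            raise ValueError("length_mean_px must be positive")
        if self.length_sd_px < 0:
            raise ValueError("length_sd_px must be nonnegative")
        if self.min_length_px <= 0:
            raise ValueError("min_length_px must be positive")
        if self.min_length_px > self.length_mean_px + 4.0 * self.length_sd_px:
            raise ValueError(
                "min_length_px lies above the plausible range of the length "
                "distribution (mean + 4 SD); truncated resampling would not "
                "terminate"
            )
        if self.width_sigma_px <= 0:
            raise ValueError("width_sigma_px must be positive")
        if self.curvature_max_per_px < 0:
            raise ValueError("curvature_max_per_px must be nonnegative")
        if self.foreground_peak <= 0:
            raise ValueError("foreground_peak must be positive")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background_level and noise_sd must be >= 0")


@dataclass
class GroundTruthFilament:
    """One true filament: its centerline polyline and derived geometry."""

    centerline: np.ndarray  # (N, 2) float (row, col)
    length_px: float
    curvature_per_px: float
    orientation_rad: float


@dataclass
class GroundTruthNetwork:
    """Ground truth for one rendered image."""

    filaments: list[GroundTruthFilament]
    spec: SyntheticNetworkSpec = field(repr=False)

    def __len__(self) -> int:
        return len(self.filaments)

    @property
    def lengths_px(self) -> np.ndarray:
        return np.asarray([f.length_px for f in self.filaments], dtype=float)


def _draw_length(spec: SyntheticNetworkSpec, rng: np.random.Generator) -> float:
    """Gaussian length with truncated resampling below ``min_length_px``."""
    for _ in range(_MAX_LENGTH_TRIES):
        length = float(rng.normal(spec.length_mean_px, spec.length_sd_px))
        if length >= spec.min_length_px:
            return length
    raise RuntimeError("length resampling did not terminate")  # pragma: no cover


def _in_frame(points: np.ndarray, spec: SyntheticNetworkSpec, margin: float) -> np.ndarray:
    h, w = spec.image_height_px, spec.image_width_px
    return (
        (points[:, 0] >= margin)
        & (points[:, 0] <= h - 1 - margin)
        & (points[:, 1] >= margin)
        & (points[:, 1] <= w - 1 - margin)
    )


def sample_filament(
    spec: SyntheticNetworkSpec, rng: np.random.Generator
) -> GroundTruthFilament:
    """Draw one filament from the network distribution.

    Length ~ Normal(mean, sd) resampled until above the floor; orientation
    uniform on [0, pi); signed curvature uniform on
    [-curvature_max, +curvature_max]; midpoint uniform over the frame.
    Placement is resampled (keeping the drawn length) until the whole
    centerline lies inside the frame with a small margin, so every true
    filament is fully visible and its recorded length equals the drawn
    length.  If no in-frame placement is found — possible only for lengths
    close to the frame diagonal — the arc is clipped at the border and the
    clipped portion removed from the recorded length.
    """
    length = _draw_length(spec, rng)
    curvature = (
        float(rng.uniform(-spec.curvature_max_per_px, spec.curvature_max_per_px))
        if spec.curvature_max_per_px > 0
        else 0.0
    )
    h, w = spec.image_height_px, spec.image_width_px
    margin = min(_PLACEMENT_MARGIN_PX, 0.45 * min(h - 1, w - 1))

    pts = None
    orientation = 0.0
    for _ in range(_MAX_PLACEMENT_TRIES):
        orientation = float(rng.uniform(0.0, np.pi))
        center = (float(rng.uniform(0, h - 1)), float(rng.uniform(0, w - 1)))
        cand = arc_points(length, curvature, orientation, center, step_px=0.5)
        if bool(np.all(_in_frame(cand, spec, margin))):
            pts = cand
            break
    if pts is None:
        # Fall back to border clipping: keep the longest contiguous in-frame run.
        orientation = float(rng.uniform(0.0, np.pi))
        center = (float(rng.uniform(0, h - 1)), float(rng.uniform(0, w - 1)))
        cand = arc_points(length, curvature, orientation, center, step_px=0.5)
        inside = _in_frame(cand, spec, 0.0)
        if not inside.any():
            # Degenerate frame; pin the midpoint to the frame centre instead.
            center = ((h - 1) / 2.0, (w - 1) / 2.0)
            cand = arc_points(length, curvature, orientation, center, step_px=0.5)
            inside = _in_frame(cand, spec, 0.0)
        runs = np.split(np.flatnonzero(inside), np.flatnonzero(np.diff(np.flatnonzero(inside)) > 1) + 1)
        best = max(runs, key=len)
        pts = cand[best]
        if len(pts) < 2:
            pts = cand[best[0] : best[0] + 1]

    return GroundTruthFilament(
        centerline=pts,
        length_px=polyline_length(pts),
        curvature_per_px=curvature,
        orientation_rad=orientation,
    )


def _local_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangent at every sample point of a polyline (central difference)."""
    t = np.gradient(np.asarray(points, dtype=float), axis=0)
    norm = np.linalg.norm(t, axis=1, keepdims=True)
    return t / np.maximum(norm, 1e-12)


def _tangentially_overlaps(
    fil: GroundTruthFilament, placed: list[GroundTruthFilament]
) -> bool:
    """Identifiability check used when composing a network.

    Filaments may cross freely, but wherever two centerlines come closer
    than the optical merging distance their local tangents must differ by a
    resolvable angle.  A tangential overlap or a smooth tip-to-tip
    continuation renders as one unbroken ridge — the image cannot express
    that it is two filaments, so no tracer (and no human) could recover the
    true count.  Such placements are resampled.
    """
    pts = fil.centerline
    tans = _local_tangents(pts)
    cos_min = np.cos(np.radians(_MIN_CROSSING_ANGLE_DEG))
    for other in placed:
        diff = pts[:, None, :] - other.centerline[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        nearest = d.argmin(axis=1)
        close = d[np.arange(len(pts)), nearest] < _MERGE_DIST_PX
        if not close.any():
            continue
        other_tans = _local_tangents(other.centerline)
        dots = np.abs(
            (tans[close] * other_tans[nearest[close]]).sum(axis=1)
        )
        if (dots > cos_min).any():
            return True
    return False


def _render_filament(
    canvas: np.ndarray, fil: GroundTruthFilament, spec: SyntheticNetworkSpec
) -> None:
    """Stamp one Gaussian-cross-section ridge onto ``canvas`` (max composite)."""
    from .geometry import min_dist_to_polyline

    pts = fil.centerline
    pad = 3.0 * spec.width_sigma_px + 1.0
    r0 = max(int(np.floor(pts[:, 0].min() - pad)), 0)
    r1 = min(int(np.ceil(pts[:, 0].max() + pad)), canvas.shape[0] - 1)
    c0 = max(int(np.floor(pts[:, 1].min() - pad)), 0)
    c1 = min(int(np.ceil(pts[:, 1].max() + pad)), canvas.shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d = min_dist_to_polyline(grid, pts).reshape(rr.shape)
    ridge = spec.foreground_peak * np.exp(-0.5 * (d / spec.width_sigma_px) ** 2)
    region = canvas[r0 : r1 + 1, c0 : c1 + 1]
    np.maximum(region, ridge, out=region)


def render_network(
    spec: SyntheticNetworkSpec,
) -> tuple[IntensityImage, GroundTruthNetwork]:
    """Render one synthetic network image and its ground truth.

    Ridges are composited by pixelwise maximum (emulating fluorophore
    saturation at crossings), the background level is added, then zero-mean
    Gaussian noise, and the result is clipped at zero.  Identical specs
    (including the seed) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    filaments: list[GroundTruthFilament] = []
    for _ in range(spec.n_filaments):
        fil = sample_filament(spec, rng)
        for _ in range(_MAX_OVERLAP_TRIES):
            if not _tangentially_overlaps(fil, filaments):
                break
            fil = sample_filament(spec, rng)
        filaments.append(fil)
    canvas = np.zeros((spec.image_height_px, spec.image_width_px), dtype=float)
    for fil in filaments:
        _render_filament(canvas, fil, spec)
    canvas += spec.background_level
    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    np.clip(canvas, 0.0, None, out=canvas)
    image = IntensityImage(canvas, meta={"synthetic": True, "seed": spec.seed})
    return image, GroundTruthNetwork(filaments=filaments, spec=spec)


def derive_image_seed(master_seed: int, level_index: int, image_index: int) -> int:
    """Deterministic per-image seed from (master seed, level, image)."""
    ss = np.random.SeedSequence((int(master_seed), int(level_index), int(image_index)))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_validation_bank(
    base_spec: SyntheticNetworkSpec,
    density_levels: list[int],
    images_per_level: int,
    seed: int,
) -> list[tuple[IntensityImage, GroundTruthNetwork]]:
    """Generate the validation image bank: one image set per density level.

    Each returned pair uses ``base_spec`` with ``n_filaments`` replaced by the
    density level and a per-image seed derived deterministically from the
    master seed, so the whole bank is reproducible from ``(base_spec, seed)``.
    """
    if not density_levels:
        raise ValueError("density_levels must be nonempty")
    if images_per_level < 1:
        raise ValueError("images_per_level must be >= 1")
    bank = []
    for li, level in enumerate(density_levels):
        for ii in range(images_per_level):
            img_spec = dataclasses.replace(
                base_spec,
                n_filaments=int(level),
                seed=derive_image_seed(seed, li, ii),
            )
            bank.append(render_network(img_spec))
    return bank
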