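"""Bank of artificial curvilinear filament templates.

Each template is a constant-curvature ridge with a Gaussian cross-section,
rendered on a small odd-sized square grid, then mean-subtracted and
L2-normalised.  Zero mean makes correlation responses invariant to additive
intensity offsets; unit norm makes responses comparable across templates of
different size.  The bank enumerates all requested combinations of length
(scale), width, rotation and signed curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import arc_points, min_dist_to_polyline

__all__ = ["TemplateSpec", "FilamentTemplateBank", "build_bank"]

#: Default bank parameters (free parameters of the method; two scales, two
#: widths, 12 rotations and five signed curvatures give 240 templates).
DEFAULT_LENGTHS_PX = (15.0, 25.0)
DEFAULT_WIDTH_SIGMAS_PX = (1.5, 2.5)
DEFAULT_N_ROTATIONS = 12
DEFAULT_CURVATURES_PER_PX = (0.0, 0.01, -0.01, 0.02, -0.02)


@dataclass(frozen=True)
class TemplateSpec:
    length_px: float
    width_sigma_px: float
    curvature_per_px: float
    rotation_rad: float

    def __post_init__(self) -> None:
        if self.length_px <= 0:
            raise ValueError("length_px must be positive")
        if self.width_sigma_px <= 0:
            raise ValueError("width_sigma_px must be positive")
        if not (0.0 <= self.rotation_rad < np.pi):
            raise ValueError("rotation_rad must lie in [0, pi)")
        if abs(self.curvature_per_px) * self.length_px >= np.pi:
            raise ValueError(
                "template arc must subtend less than a half circle "
                f"(|curvature| * length = {abs(self.curvature_per_px) * self.length_px:.3f} >= pi)"
            )


@dataclass
class FilamentTemplateBank:
    """An ordered list of (TemplateSpec, kernel) pairs.

    Kernels are zero-mean, unit-norm 2-D float arrays on odd-sized square
    grids.  ``_fft_cache`` holds per-correlation-shape kernel FFTs so a bank
    can be reused across many same-shaped images cheaply.
    """

    templates: list[tuple[TemplateSpec, np.ndarray]]
    _fft_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.templates)

    @property
    def specs(self) -> list[TemplateSpec]:
        return [s for s, _ in self.templates]

    @property
    def kernels(self) -> list[np.ndarray]:
        return [k for _, k in self.templates]

    @property
    def max_kernel_shape(self) -> tuple[int, int]:
        hs = max(k.shape[0] for k in self.kernels)
        ws = max(k.shape[1] for k in self.kernels)
        return hs, ws

    @property
    def rotations_rad(self) -> np.ndarray:
        return np.unique([s.rotation_rad for s in self.specs])


def render_template(spec: TemplateSpec) -> np.ndarray:
    """Render one template kernel: ridge on the smallest odd square grid
    containing the arc plus 3 sigma of padding, mean-subtracted, unit-norm."""
    pts = arc_points(
        spec.length_px, spec.curvature_per_px, spec.rotation_rad, (0.0, 0.0), 0.25
    )
    extent = float(np.abs(pts).max()) + 3.0 * spec.width_sigma_px
    half = int(np.ceil(extent))
    size = 2 * half + 1
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d = min_dist_to_polyline(grid, pts).reshape(size, size)
    kernel = np.exp(-0.5 * (d / spec.width_sigma_px) ** 2)
    kernel -= kernel.mean()
    norm = np.linalg.norm(kernel)
    if norm == 0:  # pragma: no cover - cannot happen for finite sigma
        raise ValueError("degenerate template kernel")
    return kernel / norm


def build_bank(
    lengths_px=DEFAULT_LENGTHS_PX,
    width_sigmas_px=DEFAULT_WIDTH_SIGMAS_PX,
    n_rotations: int = DEFAULT_N_ROTATIONS,
    curvatures_per_px=DEFAULT_CURVATURES_PER_PX,
) -> FilamentTemplateBank:
    """Build the template bank over the requested parameter grid.

    Rotations are equally spaced over [0, pi) — ridge templates are symmetric
    under direction reversal, so the upper half-circle is redundant; signed
    curvatures cover both bending directions instead.
    """
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    if not lengths_px or not width_sigmas_px or not len(list(curvatures_per_px)):
        raise ValueError("lengths, widths and curvatures must be nonempty")
    rotations = np.arange(n_rotations) * (np.pi / n_rotations)
    templates: list[tuple[TemplateSpec, np.ndarray]] = []
    for length in lengths_px:
        for sigma in width_sigmas_px:
            for curv in curvatures_per_px:
                for rot in rotations:
                    spec = TemplateSpec(
                        length_px=float(length),
                        width_sigma_px=float(sigma),
                        curvature_per_px=float(curv),
                        rotation_rad=float(rot),
                    )
                    templates.append((spec, render_template(spec)))
    return FilamentTemplateBank(templates=templates)
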