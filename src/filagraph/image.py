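"""The in-memory grayscale image container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IntensityImage"]


@dataclass
class IntensityImage:
    """A 2-D nonnegative grayscale image.

    Parameters
    ----------
    pixels
        2-D float array of nonnegative intensities.  Values are kept on the
        scale of the source file (no rescaling on load).
    pixel_size_um
        Physical edge length of one pixel in micrometres, if known.  When
        set, filament lengths are additionally reported in micrometres.
    meta
        Free-form metadata (source path, bit depth, ...).
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"pixels must be 2-D, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise ValueError("zero-area image")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be nonnegative")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
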