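"""Filament-likelihood (enhanced) image construction.

The original image is correlated with every template in the bank; the best
(maximum) response at each pixel scores how ridge-like its neighbourhood is,
and the winning template's rotation gives a rough local orientation.  The
likelihood image is the pixelwise product of the min-max-normalised best
response and the min-max-normalised original intensity: both cues must be
high, which suppresses diffuse background fluorescence (high intensity, no
ridge structure) as well as isolated noise spikes (ridge-like response at low
intensity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .image import IntensityImage
from .templates import FilamentTemplateBank

__all__ = ["LikelihoodImage", "best_response", "likelihood_image", "enhance"]


@dataclass
class LikelihoodImage:
    """Per-pixel filament likelihood in [0, 1] plus best-template metadata."""

    values: np.ndarray
    best_rotation_rad: np.ndarray
    best_template_index: np.ndarray
    response: np.ndarray = field(repr=False, default=None)
    #: True where the full correlation footprint fits inside the frame; a
    #: border band of half the largest kernel is flagged False.
    valid: np.ndarray = field(repr=False, default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _minmax(a: np.ndarray) -> np.ndarray:
    """Min-max normalise to [0, 1]; a zero-range input maps to all zeros."""
    a = np.asarray(a, dtype=float)
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def best_response(
    image: IntensityImage, bank: FilamentTemplateBank
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximum zero-padded correlation response over the template bank.

    Kernels are zero-mean, so correlating them is identical to correlating
    against locally mean-subtracted image patches (the mean term cancels);
    responses are therefore invariant to additive intensity offsets.
    Negative responses are clamped to zero.  Returns ``(response,
    best_rotation_rad, best_template_index)``; argmax ties keep the lowest
    template index.
    """
    if len(bank) == 0:
        raise ValueError("template bank is empty")
    img = np.asarray(image.pixels, dtype=float)
    h, w = img.shape
    kh, kw = bank.max_kernel_shape
    if not any(k.shape[0] <= h and k.shape[1] <= w for k in bank.kernels):
        raise ValueError(
            f"image {img.shape} is smaller than every kernel in the bank"
        )
    fh = scipy.fft.next_fast_len(h + kh - 1)
    fw = scipy.fft.next_fast_len(w + kw - 1)
    shape = (fh, fw)

    cache_key = (shape, kh, kw)
    if cache_key not in bank._fft_cache:
        ffts = []
        for _, kernel in bank.templates:
            # Embed each kernel centred in the common (kh, kw) frame; the
            # zero padding leaves mean, norm and correlation unchanged.
            padded = np.zeros((kh, kw))
            oh = (kh - kernel.shape[0]) // 2
            ow = (kw - kernel.shape[1]) // 2
            padded[oh : oh + kernel.shape[0], ow : ow + kernel.shape[1]] = kernel
            # Correlation = convolution with the flipped kernel.
            ffts.append(scipy.fft.rfft2(padded[::-1, ::-1], shape))
        bank._fft_cache[cache_key] = ffts
    kernel_ffts = bank._fft_cache[cache_key]

    # Correlate the mean-subtracted image: with zero-mean kernels this leaves
    # interior responses unchanged while making the zero padding equivalent
    # to constant-extension, so a constant image scores exactly zero
    # everywhere (borders included) and adding an offset never changes the
    # response.
    img_fft = scipy.fft.rfft2(img - img.mean(), shape)
    r0, c0 = (kh - 1) // 2, (kw - 1) // 2
    response = np.full((h, w), -np.inf)
    best_idx = np.zeros((h, w), dtype=np.int32)
    for idx, kfft in enumerate(kernel_ffts):
        full = scipy.fft.irfft2(img_fft * kfft, shape)
        same = full[r0 : r0 + h, c0 : c0 + w]
        better = same > response
        response[better] = same[better]
        best_idx[better] = idx
    np.clip(response, 0.0, None, out=response)

    rotations = np.asarray([s.rotation_rad for s in bank.specs])
    best_rot = rotations[best_idx]
    return response, best_rot, best_idx


def likelihood_image(
    response: np.ndarray, image: IntensityImage
) -> np.ndarray:
    """Combine best template response with the original intensity.

    Both maps are min-max normalised to [0, 1] (globally) and multiplied
    pixelwise; a zero-range input normalises to all zeros.
    """
    response = np.asarray(response, dtype=float)
    if response.shape != image.pixels.shape:
        raise ValueError(
            f"shape mismatch: response {response.shape} vs image {image.pixels.shape}"
        )
    return _minmax(response) * _minmax(image.pixels)


def enhance(image: IntensityImage, bank: FilamentTemplateBank) -> LikelihoodImage:
    """Full enhancement step: best response, then the combined likelihood."""
    response, best_rot, best_idx = best_response(image, bank)
    values = likelihood_image(response, image)
    kh, kw = bank.max_kernel_shape
    valid = np.zeros(values.shape, dtype=bool)
    mr, mc = kh // 2, kw // 2
    if values.shape[0] > 2 * mr and values.shape[1] > 2 * mc:
        valid[mr : values.shape[0] - mr, mc : values.shape[1] - mc] = True
    return LikelihoodImage(
        values=values,
        best_rotation_rad=best_rot,
        best_template_index=best_idx,
        response=response,
        valid=valid,
    )
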