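import numpy as np
import pytest
from scipy.ndimage import rotate as nd_rotate

from filagraph.geometry import arc_points, min_dist_to_polyline
from filagraph.templates import TemplateSpec, build_bank, render_template


def test_kernels_zero_mean_unit_norm(small_bank):
    for spec, kernel in small_bank.templates:
        assert abs(kernel.mean()) < 1e-9
        assert abs(np.linalg.norm(kernel) - 1.0) < 1e-9
        assert kernel.shape[0] % 2 == 1 and kernel.shape[1] % 2 == 1


def test_bank_covers_parameter_grid_once():
    bank = build_bank([15.0, 25.0], [1.5], 6, [0.0, 0.01, -0.01])
    assert len(bank) == 2 * 1 * 6 * 3
    combos = {
        (s.length_px, s.width_sigma_px, s.curvature_per_px, s.rotation_rad)
        for s in bank.specs
    }
    assert len(combos) == len(bank)
    rotations = bank.rotations_rad
    assert np.allclose(np.diff(rotations), np.pi / 6)
    assert rotations[0] == 0.0 and rotations[-1] < np.pi


def test_straight_horizontal_kernel_mirror_symmetric():
    kernel = render_template(TemplateSpec(15.0, 1.5, 0.0, 0.0))
    assert np.allclose(kernel, kernel[::-1, :], atol=1e-12)


def test_quarter_turn_kernel_equals_rot90():
    k0 = render_template(TemplateSpec(15.0, 1.5, 0.0, 0.0))
    k90 = render_template(TemplateSpec(15.0, 1.5, 0.0, np.pi / 2))
    assert k0.shape == k90.shape
    assert np.allclose(np.rot90(k0), k90, atol=1e-9)


def test_rotated_kernel_matches_image_rotation_oracle():
    # independent oracle: render the unrotated raw ridge on a common grid,
    # resample it with a spline image rotation, then normalise both
    theta = np.pi / 6
    half, sigma, length = 14, 1.5, 15.0

    def raw(angle):
        pts = arc_points(length, 0.0, angle, (0.0, 0.0), 0.25)
        rr, cc = np.mgrid[-half : half + 1, -half : half + 1]
        grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        d = min_dist_to_polyline(grid, pts).reshape(rr.shape)
        return np.exp(-0.5 * (d / sigma) ** 2)

    def normed(k):
        k = k - k.mean()
        return k / np.linalg.norm(k)

    direct = normed(raw(theta))
    resampled = normed(nd_rotate(raw(0.0), -np.degrees(theta), reshape=False, order=3))
    assert np.linalg.norm(direct - resampled) < 0.05


def test_half_circle_invariant_rejected():
    with pytest.raises(ValueError):
        TemplateSpec(length_px=200.0, width_sigma_px=1.5, curvature_per_px=0.02, rotation_rad=0.0)
    with pytest.raises(ValueError):
        build_bank([200.0], [1.5], 4, [0.02])


def test_self_match_recovers_orientation(small_bank):
    # correlating a rendered straight ridge against the bank, the winning
    # template's rotation lands within one angular bin of the truth
    rng = np.random.default_rng(0)
    n_rot = 8
    bin_width = np.pi / n_rot
    for theta in rng.uniform(0, np.pi, size=10):
        pts = arc_points(21.0, 0.0, theta, (24.0, 24.0), 0.25)
        rr, cc = np.mgrid[0:49, 0:49]
        grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        d = min_dist_to_polyline(grid, pts).reshape(49, 49)
        image = np.exp(-0.5 * (d / 1.5) ** 2)
        scores = []
        for spec, kernel in small_bank.templates:
            kh, kw = kernel.shape
            patch = image[
                24 - kh // 2 : 24 + kh // 2 + 1, 24 - kw // 2 : 24 + kw // 2 + 1
            ]
            scores.append(((patch - patch.mean()) * kernel).sum())
        best = small_bank.specs[int(np.argmax(scores))].rotation_rad
        delta = abs(best - theta) % np.pi
        assert min(delta, np.pi - delta) <= bin_width + 1e-9
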