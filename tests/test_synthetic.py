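import dataclasses

import numpy as np
import pytest

from filagraph import (
    SyntheticNetworkSpec,
    generate_validation_bank,
    render_network,
    sample_filament,
)
from filagraph.geometry import polyline_length


def test_degenerate_length_distribution_gives_constant_lengths():
    spec = SyntheticNetworkSpec(
        length_sd_px=0.0, length_mean_px=50.0, curvature_max_per_px=0.0, seed=1
    )
    rng = np.random.default_rng(spec.seed)
    for _ in range(5):
        fil = sample_filament(spec, rng)
        assert fil.length_px == pytest.approx(50.0, abs=0.05)
        assert fil.curvature_per_px == 0.0


def test_sampled_length_distribution_matches_spec():
    # mean 50 px, SD 20 px, truncated at 10 px: the sample mean of many draws
    # sits close to the configured mean (truncation adds a small upward bias,
    # well below the 2 px check here)
    spec = SyntheticNetworkSpec(seed=3)
    rng = np.random.default_rng(spec.seed)
    lengths = [sample_filament(spec, rng).length_px for _ in range(1000)]
    assert np.mean(lengths) == pytest.approx(50.0, abs=2.0)
    assert min(lengths) >= spec.min_length_px - 0.05


def test_truncated_gaussian_moments_within_3_se():
    spec = SyntheticNetworkSpec(seed=11)
    rng = np.random.default_rng(spec.seed)
    n = 10_000
    lengths = np.array([sample_filament(spec, rng).length_px for _ in range(n)])
    # analytic truncated-normal moments for (mu=50, sd=20, lower=10)
    from scipy.stats import truncnorm

    a = (spec.min_length_px - spec.length_mean_px) / spec.length_sd_px
    dist = truncnorm(a, np.inf, loc=spec.length_mean_px, scale=spec.length_sd_px)
    assert abs(lengths.mean() - dist.mean()) < 3 * dist.std() / np.sqrt(n)
    assert abs(lengths.std() - dist.std()) < 3 * dist.std() / np.sqrt(n)


def test_ground_truth_length_equals_centerline_arc_length():
    spec = SyntheticNetworkSpec(seed=5)
    rng = np.random.default_rng(spec.seed)
    for _ in range(10):
        fil = sample_filament(spec, rng)
        assert fil.length_px == pytest.approx(
            polyline_length(fil.centerline), abs=0.5
        )


def test_same_seed_same_network():
    spec = SyntheticNetworkSpec(n_filaments=6, seed=42)
    img1, truth1 = render_network(spec)
    img2, truth2 = render_network(spec)
    assert np.array_equal(img1.pixels, img2.pixels)
    for f1, f2 in zip(truth1.filaments, truth2.filaments):
        assert np.array_equal(f1.centerline, f2.centerline)


def test_empty_network_is_background_plus_noise():
    spec = SyntheticNetworkSpec(
        n_filaments=0, background_level=20.0, noise_sd=5.0, seed=0
    )
    img, truth = render_network(spec)
    assert len(truth) == 0
    assert img.pixels.mean() == pytest.approx(20.0, abs=0.5)


def test_noise_free_filament_peak_on_centerline():
    spec = SyntheticNetworkSpec(
        n_filaments=1,
        noise_sd=0.0,
        background_level=20.0,
        curvature_max_per_px=0.0,
        seed=2,
    )
    img, truth = render_network(spec)
    mid = truth.filaments[0].centerline[len(truth.filaments[0].centerline) // 2]
    r, c = int(round(mid[0])), int(round(mid[1]))
    patch = img.pixels[r - 1 : r + 2, c - 1 : c + 2]
    # centerline pixel within half a pixel of the true curve: at most
    # peak*exp(-0.5*(0.5/1.5)^2) below the full peak
    assert patch.max() >= 20.0 + 200.0 * np.exp(-0.5 * (0.5 / 1.5) ** 2)
    assert img.pixels.max() <= 20.0 + 200.0 + 1e-6


def test_rendered_intensity_grows_with_density():
    totals = []
    for n in [1, 3, 6]:
        spec = SyntheticNetworkSpec(
            n_filaments=n, noise_sd=0.0, background_level=0.0, seed=9
        )
        img, _ = render_network(spec)
        totals.append(img.pixels.sum())
    assert totals[0] < totals[1] < totals[2]


def test_validation_bank_shape_and_determinism():
    base = SyntheticNetworkSpec(image_height_px=48, image_width_px=48, seed=0)
    bank1 = generate_validation_bank(base, [1, 2], 3, seed=123)
    bank2 = generate_validation_bank(base, [1, 2], 3, seed=123)
    assert len(bank1) == 6
    assert [len(t) for _, t in bank1] == [1, 1, 1, 2, 2, 2]
    for (i1, t1), (i2, t2) in zip(bank1, bank2):
        assert np.array_equal(i1.pixels, i2.pixels)

    single = generate_validation_bank(base, [1], 1, seed=5)
    assert len(single) == 1 and len(single[0][1]) == 1


def test_spec_validation_errors():
    with pytest.raises(ValueError):
        SyntheticNetworkSpec(length_mean_px=-1.0)
    with pytest.raises(ValueError):
        SyntheticNetworkSpec(length_mean_px=20.0, length_sd_px=1.0, min_length_px=90.0)
    with pytest.raises(ValueError):
        SyntheticNetworkSpec(image_height_px=0)
    with pytest.raises(ValueError):
        generate_validation_bank(SyntheticNetworkSpec(), [], 1, 0)
    with pytest.raises(ValueError):
        generate_validation_bank(SyntheticNetworkSpec(), [1], 0, 0)


def test_network_count_matches_spec():
    spec = SyntheticNetworkSpec(n_filaments=7, seed=13)
    _, truth = render_network(spec)
    assert len(truth.filaments) == 7
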