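import numpy as np
import pytest

from filagraph import (
    PipelineConfig,
    SyntheticNetworkSpec,
    build_bank,
    render_network,
)


@pytest.fixture(scope="session")
def default_bank():
    """Full default template bank, shared across the session (FFTs cached)."""
    return PipelineConfig().build_template_bank()


@pytest.fixture(scope="session")
def small_bank():
    """A cheap bank for tests that only need a working bank."""
    return build_bank(
        lengths_px=[15.0],
        width_sigmas_px=[1.5],
        n_rotations=8,
        curvatures_per_px=[0.0],
    )


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture()
def single_filament():
    """A clean, noise-free image containing one straight filament."""
    spec = SyntheticNetworkSpec(
        n_filaments=1,
        length_sd_px=0.0,
        curvature_max_per_px=0.0,
        noise_sd=0.0,
        background_level=0.0,
        seed=7,
    )
    return render_network(spec)


def render_clean_separated(n_filaments, seed, min_dist_px=8.0, straight=False):
    """Noise-free network whose filaments keep a clearance from each other.

    Deterministically scans seeds until a network with pairwise centerline
    distance above ``min_dist_px`` comes up; used where ground truth must be
    trivially recoverable (no crossings at all).
    """
    from scipy.spatial.distance import cdist

    kwargs = dict(
        noise_sd=0.0,
        background_level=0.0,
        n_filaments=n_filaments,
    )
    if straight:
        kwargs["curvature_max_per_px"] = 0.0
    for s in range(seed, seed + 400):
        image, truth = render_network(SyntheticNetworkSpec(seed=s, **kwargs))
        ok = True
        for i in range(n_filaments):
            for j in range(i + 1, n_filaments):
                d = cdist(
                    truth.filaments[i].centerline, truth.filaments[j].centerline
                ).min()
                if d < min_dist_px:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return image, truth
    raise RuntimeError("no separated network found")  # pragma: no cover
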