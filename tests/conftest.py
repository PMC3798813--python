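"""Shared fixtures: small simulated scenes reused across test modules."""

import numpy as np
import pytest

from echotrace.synthetic_data import (
    MWaveGridParams,
    SpringSceneParams,
    TwitchSceneParams,
    simulate_mwave_grid,
    simulate_spring_sequence,
    simulate_twitch_sequence,
)


@pytest.fixture(scope="session")
def spring_short():
    """2 s oscillating-spring clip (1.0 mm pk-pk, 2 Hz) with ground truth."""
    params = SpringSceneParams(
        duration_s=2.0, peak_to_peak_mm=1.0, frequency_hz=2.0, seed=11
    )
    seq, gt = simulate_spring_sequence(params)
    return params, seq, gt


@pytest.fixture(scope="session")
def twitch_short():
    """2.5 s twitch clip (1.0 mm shortening, 0.5 mm thickening)."""
    params = TwitchSceneParams(duration_s=2.5, seed=7)
    seq, gt, seg = simulate_twitch_sequence(params)
    return params, seq, gt, seg


@pytest.fixture(scope="session")
def mwave_rec():
    """Default 20 s, 32-channel M-wave grid recording."""
    return simulate_mwave_grid(MWaveGridParams(seed=5))


@pytest.fixture()
def speckle_frame():
    """A reproducible smoothed-speckle frame for tracking tests."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(123)
    img = gaussian_filter(rng.random((120, 160)), 2.0)
    img = (img - img.min()) / (img.max() - img.min())
    return (200 * img).astype(np.uint8)
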