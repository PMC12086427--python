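import numpy as np
import pytest

from neurostates import StateSegmentation
from neurostates.simulate import draw_boundaries, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_recording():
    """Moderate-SNR 100-s recording (5.12 Hz, 32 channels, 18 states)."""
    gen = np.random.default_rng(7)
    bounds = draw_boundaries(gen, 512, 18)
    rec, _ = simulate_recording(
        512, 32, bounds, pattern_scale=1.0, noise_sd=0.5, seed=77
    )
    return rec, bounds


def make_segmentation(boundaries, T, fs=5.12, subject_id="s", curve=None):
    boundaries = np.asarray(boundaries, dtype=int)
    return StateSegmentation(
        boundaries=boundaries,
        selected_k=boundaries.size + 1,
        tdistance_curve=curve or {},
        T=T,
        sampling_rate_hz=fs,
        subject_id=subject_id,
    )
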