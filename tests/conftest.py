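"""Shared fixtures.

Expensive randomised studies are session-scoped so that module-level
property tests and the acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrkymo.phantom import PhantomConfig, generate_phantom_series
from mrkymo.series import Plane


@pytest.fixture(scope="session")
def noiseless_coronal():
    """Small noiseless coronal phantom (3 cycles, 31 frames) with truth."""
    config = PhantomConfig(duration_s=18.0, noise_sigma=0.0, seed=11)
    series, truth = generate_phantom_series(config)
    return config, series, truth


@pytest.fixture(scope="session")
def noisy_coronal():
    """Default-noise coronal phantom used by integration tests."""
    config = PhantomConfig(duration_s=18.0, seed=7)
    series, truth = generate_phantom_series(config)
    return config, series, truth


@pytest.fixture(scope="session")
def static_phantom():
    """Phantom with all amplitudes zero and no noise."""
    config = PhantomConfig(
        duration_s=18.0,
        noise_sigma=0.0,
        amplitude_hf_right_mm=0.0,
        amplitude_hf_left_mm=0.0,
        amplitude_rl_mm=0.0,
        amplitude_ap_right_mm=0.0,
        amplitude_ap_left_mm=0.0,
        seed=3,
    )
    series, truth = generate_phantom_series(config)
    return config, series, truth


@pytest.fixture(scope="session")
def recovery_study_result():
    from mrkymo.validation import expansion_recovery_study

    return expansion_recovery_study(n_sessions=50, seed=101)


@pytest.fixture(scope="session")
def phase_study_result():
    from mrkymo.validation import phase_recovery_study

    return phase_recovery_study(n_runs=100, seed=202)


@pytest.fixture(scope="session")
def cycle_flag_result():
    from mrkymo.validation import cycle_flag_study

    return cycle_flag_study(n_runs=100, seed=303)


@pytest.fixture(scope="session")
def coverage_fraction():
    from mrkymo.validation import icc_ci_coverage_study

    return icc_ci_coverage_study(n_sim=1000, seed=404)


@pytest.fixture(scope="session")
def binarized_phantom_frames():
    """100 binarised gradient frames from randomised noisy phantoms."""
    from mrkymo.preprocess import binarize, median_denoise, sobel_magnitude, upsample

    rng = np.random.default_rng(55)
    frames = []
    while len(frames) < 100:
        config = PhantomConfig(
            plane=list(Plane)[int(rng.integers(0, 3))],
            matrix_size=96,
            duration_s=13.0,
            breathing_period_s=6.0,
            noise_sigma=float(rng.uniform(0, 10)),
            seed=int(rng.integers(0, 2**20)),
        )
        series, _ = generate_phantom_series(config)
        den = median_denoise(upsample(series, 256))
        for k in range(0, den.n_frames, 5):
            mask, _ = binarize(sobel_magnitude(den.frames[k]))
            frames.append(mask)
    return frames[:100]
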