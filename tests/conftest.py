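"""Shared fixtures: synthetic slow-wave trains and offline phase oracle."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sps

from somnostim.core import Recording

FS = 250.0


def slow_wave_train(duration: float, seed: int, f_lo: float = 0.6,
                    f_hi: float = 1.0, amp: float = 75.0,
                    noise: float = 5.0, fs: float = FS) -> np.ndarray:
    """Continuous train of asymmetric slow-oscillation cycles.

    Each cycle draws its own frequency from [f_lo, f_hi]: a raised-cosine
    down half-wave of depth ``amp`` followed by an up half-wave of 0.6 amp,
    plus white measurement noise.
    """
    rng = np.random.default_rng(seed)
    x = np.zeros(int(duration * fs))
    t = 0.0
    while True:
        f = rng.uniform(f_lo, f_hi)
        n = int(round(fs / f))
        i0 = int(t * fs)
        if i0 + n >= x.size:
            break
        tt = np.arange(n) / n
        down = -amp * np.sin(np.pi * np.minimum(tt * 2, 1)) ** 2 * (tt < 0.5)
        up = 0.6 * amp * np.sin(np.pi * np.maximum(tt * 2 - 1, 0)) ** 2 * (tt >= 0.5)
        x[i0:i0 + n] += down + up
        t += n / fs
    return x + rng.normal(0, noise, x.size)


def oracle_phase_deg(x: np.ndarray, fs: float = FS,
                     band: tuple = (0.5, 1.5)) -> np.ndarray:
    """Offline slow-oscillation phase: acausal band-pass + analytic signal.

    0 deg at the positive-going zero crossing (sine convention), matching
    the stimulation engine's phase definition.
    """
    sos = sps.butter(2, list(band), btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return (np.degrees(np.angle(sps.hilbert(y))) + 90.0) % 360.0


@pytest.fixture(scope="session")
def permissive_nrem_thresholds():
    """Thresholds that disable NREM gating, for engine tests on bare trains."""
    return {"low_delta": 1e-9, "high_delta": 1e-9, "high_beta": 1e9}


@pytest.fixture()
def train_recording():
    return Recording(slow_wave_train(600.0, seed=0), FS)
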