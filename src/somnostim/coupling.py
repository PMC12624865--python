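"""Slow-oscillation-phase to fast-sigma-amplitude coupling (zMI).

Coupling between the ~1 Hz slow-oscillation phase and the 13-16 Hz
fast-spindle amplitude is quantified with the entropy-based modulation
index: the mean sigma amplitude per 20 deg phase bin forms a distribution
whose Kullback-Leibler divergence from uniform, normalised by log N,
gives MI in [0, 1]. The empirical MI is z-scored against a surrogate null
built by cutting each amplitude epoch at a random sample and swapping the
two parts, which preserves the amplitude distribution while destroying
the phase alignment.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import EpochSet

__all__ = [
    "PACConfig", "extract_phase", "extract_amplitude", "modulation_index",
    "cut_and_reverse", "zscore_mi", "stimulus_pac",
]


@dataclass
class PACConfig:
    phase_band: tuple = (0.5, 1.5)     # Hz, slow-oscillation range around 1 Hz
    amp_band: tuple = (13.0, 16.0)     # Hz, fast sigma
    n_phase_bins: int = 18             # 20 deg each
    window_post_stim: float = 2.0      # s analysed after each stimulus
    n_surrogates: int = 200
    seed: int | None = None
    eps: float = 1e-12                 # additive smoothing for empty bins

    def __post_init__(self) -> None:
        if self.n_phase_bins <= 0 or 360 % self.n_phase_bins:
            raise ValueError("n_phase_bins must divide 360")
        if self.phase_band[1] > self.amp_band[0]:
            raise ValueError("phase and amplitude bands must not overlap")
        if self.n_surrogates < 1:
            raise ValueError("need at least one surrogate")


def _bandpass(x: np.ndarray, fs: float, band: tuple) -> np.ndarray:
    sos = sps.butter(3, list(band), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def extract_phase(epoch: np.ndarray, fs: float, phase_band: tuple = (0.5, 1.5),
                  min_amplitude: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase (radians, (-pi, pi]) of the band-passed epoch.

    Convention: phase 0 at the band-passed signal's peaks (cosine phase).
    Returns (phase, reliable) where ``reliable`` is False when the
    analytic amplitude is below ``min_amplitude`` (degenerate phase).
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.size < 2 * fs / phase_band[0]:
        raise ValueError("epoch shorter than two cycles of the band's low edge")
    analytic = sps.hilbert(_bandpass(epoch, fs, phase_band))
    return np.angle(analytic), np.abs(analytic) >= min_amplitude


def extract_amplitude(epoch: np.ndarray, fs: float,
                      amp_band: tuple = (13.0, 16.0)) -> np.ndarray:
    """Analytic-signal amplitude envelope of the band-passed epoch."""
    epoch = np.asarray(epoch, dtype=float)
    return np.abs(sps.hilbert(_bandpass(epoch, fs, amp_band)))


def modulation_index(phase: np.ndarray, amplitude: np.ndarray,
                     n_bins: int = 18, eps: float = 1e-12) -> float:
    """Entropy-based modulation index in [0, 1].

    Mean amplitude per phase bin, normalised to a distribution P;
    MI = (log N - H(P)) / log N. Empty bins receive ``eps`` mass.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    bins = ((phase + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    mean_amp = np.full(n_bins, eps)
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            mean_amp[b] = max(amplitude[sel].mean(), eps)
    p = mean_amp / mean_amp.sum()
    h = -np.sum(p * np.log(p))
    return float((np.log(n_bins) - h) / np.log(n_bins))


def cut_and_reverse(amplitude: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Cut at a random interior sample and swap the order of the parts.

    Preserves the amplitude multiset exactly while shifting the
    phase-amplitude alignment by a random lag.
    """
    n = amplitude.size
    cut = int(rng.integers(1, n))
    return np.concatenate([amplitude[cut:], amplitude[:cut]])


def zscore_mi(phase: np.ndarray, amplitude: np.ndarray,
              config: PACConfig | None = None,
              epoch_bounds: list[tuple[int, int]] | None = None) -> dict:
    """z-scored modulation index against the cut-and-reverse null.

    When ``epoch_bounds`` is given (concatenated epochs), each surrogate
    applies an independent cut within every epoch segment before
    recomputing MI; otherwise the whole series is cut once.
    """
    config = config or PACConfig()
    rng = np.random.default_rng(config.seed)
    mi_emp = modulation_index(phase, amplitude, config.n_phase_bins, config.eps)
    bounds = epoch_bounds or [(0, len(amplitude))]
    null = np.empty(config.n_surrogates)
    for s in range(config.n_surrogates):
        surr = np.concatenate([cut_and_reverse(amplitude[a:b], rng)
                               for a, b in bounds])
        null[s] = modulation_index(phase, surr, config.n_phase_bins, config.eps)
    sd = null.std(ddof=1)
    if sd == 0:
        warnings.warn("degenerate surrogate distribution (sd = 0)", stacklevel=2)
        return {"mi": mi_emp, "zmi": np.nan, "null_mean": float(null.mean()),
                "null_sd": 0.0}
    return {"mi": mi_emp, "zmi": float((mi_emp - null.mean()) / sd),
            "null_mean": float(null.mean()), "null_sd": float(sd)}


def stimulus_pac(epoch_sets: dict, fs: float,
                 config: PACConfig | None = None) -> pd.DataFrame:
    """Per night x stimulus-category zMI table.

    ``epoch_sets`` maps (night, category) to an :class:`EpochSet` aligned
    at stimulus onset with at least ``window_post_stim`` seconds after it.
    Phase and sigma amplitude are restricted to (0, 2] s post-stimulus and
    concatenated across epochs within each night x category before MI.
    Categories without epochs yield NaN entries.
    """
    config = config or PACConfig()
    rows = []
    for (night, category), es in epoch_sets.items():
        if not isinstance(es, EpochSet) or len(es) == 0:
            rows.append({"night": night, "category": category, "n_epochs": 0,
                         "mi": np.nan, "zmi": np.nan})
            continue
        pre = es.window[0]
        i0 = int(round(pre * fs))
        i1 = i0 + int(round(config.window_post_stim * fs))
        phases, amps, bounds, pos = [], [], [], 0
        for ep in es.epochs:
            ph, _ = extract_phase(ep, fs, config.phase_band)
            am = extract_amplitude(ep, fs, config.amp_band)
            seg_ph, seg_am = ph[i0:i1], am[i0:i1]
            phases.append(seg_ph)
            amps.append(seg_am)
            bounds.append((pos, pos + seg_am.size))
            pos += seg_am.size
        res = zscore_mi(np.concatenate(phases), np.concatenate(amps),
                        config, epoch_bounds=bounds)
        rows.append({"night": night, "category": category, "n_epochs": len(es),
                     "mi": res["mi"], "zmi": res["zmi"]})
    return pd.DataFrame(rows)
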