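"""Deterministic filtering, epoching, artifact masking and sleep architecture.

The analysis filter chain reproduces a zero-phase Kaiser-window FIR cascade
(low-pass with half-amplitude point at 39.86 Hz, order 46; high-pass with
half-amplitude point at 0.37 Hz, order 2988, both specified at 250 Hz;
orders are rescaled proportionally at other rates). The scoring chain is a
forward-backward third-order Butterworth band-pass 0.5-35 Hz followed by
polyphase resampling to 128 Hz.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import EpochSet, Hypnogram, NREM_STAGES, Recording, SLEEP_STAGES, STAGES

__all__ = [
    "FilterSpec", "filter_for_analysis", "filter_for_scoring",
    "detect_artifacts", "extract_epochs", "sleep_architecture",
]

#: Reference design rate and filter orders of the analysis chain.
_DESIGN_FS = 250.0
_LP_ORDER, _LP_CUT = 46, 39.86     # half-amplitude (-6 dB) point, Hz
_HP_ORDER, _HP_CUT = 2988, 0.37
_KAISER_BETA = 5.0


@dataclass
class FilterSpec:
    """Descriptive record of a filtering step applied to a recording."""

    family: str          # "FIR-Kaiser" | "IIR-Butterworth"
    kind: str            # lowpass | highpass | bandpass | notch
    edges: tuple
    order: int
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order <= 0:
            raise ValueError("filter order must be positive")


def _kaiser_fir(order: int, cutoff: float, fs: float, pass_zero: bool) -> np.ndarray:
    numtaps = order + 1
    if numtaps % 2 == 0:       # type I (odd length) keeps exact linear phase
        numtaps += 1
    return sps.firwin(numtaps, cutoff, window=("kaiser", _KAISER_BETA),
                      pass_zero=pass_zero, fs=fs)


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # symmetric odd-length kernel + centred convolution = exact zero phase
    return sps.fftconvolve(x, taps, mode="same")


def filter_for_analysis(recording: Recording) -> Recording:
    """Zero-phase Kaiser FIR cascade: 30 Hz low-pass then 0.5 Hz high-pass."""
    fs = recording.fs
    if _LP_CUT >= fs / 2:
        raise ValueError("low-pass cutoff at or above Nyquist")
    scale = fs / _DESIGN_FS
    lp = _kaiser_fir(int(round(_LP_ORDER * scale)), _LP_CUT, fs, pass_zero=True)
    hp = _kaiser_fir(int(round(_HP_ORDER * scale)), _HP_CUT, fs, pass_zero=False)
    out = _zero_phase_fir(_zero_phase_fir(recording.data, lp), hp)
    return Recording(out, fs, recording.start_time, recording.channel)


def filter_for_scoring(recording: Recording, target_fs: float = 128.0) -> Recording:
    """Forward-backward Butterworth band-pass 0.5-35 Hz, resampled to 128 Hz."""
    fs = recording.fs
    if fs <= 70.0:
        raise ValueError("sampling rate must exceed twice the 35 Hz band edge")
    sos = sps.butter(3, [0.5, 35.0], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, recording.data)
    from fractions import Fraction
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    y = sps.resample_poly(y, frac.numerator, frac.denominator)
    return Recording(y, target_fs, recording.start_time, recording.channel)


def _epoch_band_power(data: np.ndarray, fs: float, epoch_len: float,
                      band: tuple, n_epochs: int) -> np.ndarray:
    sos = sps.butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, data) ** 2
    spe = int(round(epoch_len * fs))
    power = np.full(n_epochs, np.nan)
    for i in range(n_epochs):
        seg = y[i * spe:(i + 1) * spe]
        if seg.size:
            power[i] = seg.mean()
    return power


def detect_artifacts(recording: Recording, hypnogram: Hypnogram,
                     params: dict | None = None) -> np.ndarray:
    """Automatic two-band moving-threshold artifact mask over NREM epochs.

    An NREM epoch is flagged when its 0.75-4.5 Hz or 20-30 Hz power exceeds
    a multiple of the moving median over neighbouring NREM epochs.
    Non-NREM epochs are never flagged. Returns one boolean per hypnogram
    epoch (True = artifactual).
    """
    p = {"delta_band": (0.75, 4.5), "beta_band": (20.0, 30.0),
         "delta_mult": 4.0, "beta_mult": 4.0, "window_epochs": 15}
    p.update(params or {})
    n_epochs = len(hypnogram)
    stages = hypnogram.as_array()
    nrem = np.isin(stages, NREM_STAGES)
    mask = np.zeros(n_epochs, dtype=bool)
    if not nrem.any():
        return mask
    for band, mult in ((p["delta_band"], p["delta_mult"]),
                       (p["beta_band"], p["beta_mult"])):
        power = _epoch_band_power(recording.data, recording.fs,
                                  hypnogram.epoch_len, band, n_epochs)
        nrem_idx = np.flatnonzero(nrem & np.isfinite(power))
        if nrem_idx.size == 0:
            continue
        series = pd.Series(power[nrem_idx])
        ref = series.rolling(p["window_epochs"], center=True, min_periods=3).median()
        ref = ref.fillna(series.median()).to_numpy()
        mask[nrem_idx] |= power[nrem_idx] > mult * ref
    if nrem.any() and mask[nrem].all():
        warnings.warn("every NREM epoch flagged artifactual", stacklevel=2)
    return mask


def extract_epochs(recording: Recording, times, window: tuple[float, float],
                   labels: pd.DataFrame | None = None) -> EpochSet:
    """Sample-accurate epochs of ``(pre, post)`` seconds around event times.

    Events whose window does not fit inside the recording are dropped and
    counted in ``n_dropped``.
    """
    pre, post = window
    times = np.asarray(times, dtype=float)
    fs = recording.fs
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    n_len = n_pre + n_post
    centers = np.round((times - recording.start_time) * fs).astype(int)
    keep = (centers - n_pre >= 0) & (centers + n_post <= recording.n_samples)
    n_dropped = int((~keep).sum())
    kept = np.flatnonzero(keep)
    epochs = np.empty((kept.size, n_len))
    for j, i in enumerate(kept):
        epochs[j] = recording.data[centers[i] - n_pre:centers[i] + n_post]
    if labels is not None:
        labels = labels.iloc[kept].reset_index(drop=True)
    else:
        labels = pd.DataFrame(index=range(kept.size))
    return EpochSet(epochs if kept.size else np.empty((0, n_len)),
                    (pre, post), times[keep], fs, labels, n_dropped)


def sleep_architecture(hypnogram: Hypnogram, lights_off: float,
                       lights_on: float) -> pd.Series:
    """Sleep-architecture metrics from a hypnogram (minutes, percentages).

    TTB = lights interval; TST = minutes asleep; SL = latency from lights
    off to the first sleep epoch; WASO = wake after sleep onset and before
    the final awakening; REML = sleep onset to first REM epoch;
    SEF = 100 * TST / TTB. Stage percentages are relative to TTB.
    """
    el = hypnogram.epoch_len
    i0 = int(round(lights_off / el))
    i1 = int(round(lights_on / el))
    if i0 < 0 or i1 > len(hypnogram) or i1 <= i0:
        raise ValueError("hypnogram does not cover the lights interval")
    stages = hypnogram.as_array()[i0:i1]
    minutes_per_epoch = el / 60.0
    ttb = (i1 - i0) * minutes_per_epoch

    sleep = np.isin(stages, SLEEP_STAGES)
    out = {"TTB_min": ttb}
    if not sleep.any():
        out.update({"TST_min": 0.0, "SL_min": np.nan, "WASO_min": np.nan,
                    "REML_min": np.nan, "SEF_pct": 0.0})
    else:
        onset = int(np.argmax(sleep))
        last = len(sleep) - 1 - int(np.argmax(sleep[::-1]))
        tst = float(sleep.sum()) * minutes_per_epoch
        waso = float((~sleep[onset:last + 1]).sum()) * minutes_per_epoch
        rem = np.flatnonzero(stages == "REM")
        reml = (rem[0] - onset) * minutes_per_epoch if rem.size else np.nan
        out.update({"TST_min": tst, "SL_min": onset * minutes_per_epoch,
                    "WASO_min": waso, "REML_min": reml,
                    "SEF_pct": 100.0 * tst / ttb})
    for s in STAGES:
        out[f"{s}_pct"] = 100.0 * float((stages == s).sum()) / (i1 - i0)
    return pd.Series(out)
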