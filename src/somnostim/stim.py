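"""Offline emulator of the closed-loop stimulation device.

Reproduces the device's behaviour on a recorded (or synthetic) night:
causal NREM detection from trailing 80 s band powers, slow-wave phase
tracking with a second-order phase-locked loop (PLL), stimulus triggering
at the 45 deg target phase inside free-running 6 s ON / 6 s OFF windows
under an inter-stimulus-interval (ISI) constraint and an arousal veto,
and offline reconstruction of sham flags in OFF windows.

The emulator is behavioural: the device's exact loop equations and
classifier thresholds are not public, so loop constants and power
thresholds are configuration with defaults calibrated on the bundled
synthetic generator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sps

from .core import Hypnogram, NREM_STAGES, Recording, StimulusLog

__all__ = [
    "StimEngineConfig", "detect_nrem_online", "pll_phase", "run_stimulation",
    "reconstruct_sham_flags", "engine_state", "calibrate_nrem_thresholds",
]


@dataclass
class StimEngineConfig:
    target_phase: float = 45.0          # deg, on the down-to-up transition
    min_isi: float = 0.5                # s (0.5 short-ISI, 1.0 long-ISI protocol)
    window_on: float = 6.0
    window_off: float = 6.0
    stable_nrem_start: float = 600.0    # s of continuous NREM before stimulation
    stable_nrem_tolerance: float = 0.0  # s, flag dropouts shorter than this ignored
    stim_stop_after_first: float = 9000.0   # s (2.5 h)
    nrem_bands: dict = field(default_factory=lambda: {
        "low_delta": (2.0, 4.0), "high_delta": (3.0, 5.0), "high_beta": (20.0, 30.0)})
    nrem_history: float = 80.0          # s trailing power window
    #: µV² thresholds on trailing-80 s band power; calibrated on the
    #: synthetic generator's default nights (see calibrate_nrem_thresholds).
    nrem_power_thresholds: dict = field(default_factory=lambda: {
        "low_delta": 78.0, "high_delta": 56.0, "high_beta": 32.0})
    arousal_beta_window: float = 1.0    # s
    arousal_beta_ratio_threshold: float = 3.0   # trailing-1 s vs trailing-80 s beta
    stim_duration: float = 0.05         # s, 50 ms pink-noise burst (metadata)
    volume_db: float = 55.0             # dB SPL, metadata only (study range 46-64)
    # PLL constants
    pll_band: tuple = (0.5, 1.5)        # Hz causal band-pass ahead of the loop
    pll_center_freq: float = 1.0        # Hz free-running centre frequency
    pll_natural_freq: float = 0.5       # Hz loop natural frequency
    pll_damping: float = 1.0
    pll_freq_limits: tuple = (0.3, 2.0)  # Hz NCO clamp
    pll_err_tau: float = 0.14           # s one-pole smoothing of the phase error
    pll_amp_floor: float = 0.05         # quadrature-amplitude floor (unit-RMS input)
    min_wave_amplitude: float = 20.0    # µV envelope a wave needs to be triggerable

    def __post_init__(self) -> None:
        if not 0 <= self.target_phase < 360:
            raise ValueError("target_phase must be in [0, 360)")
        if self.min_isi <= 0 or self.window_on <= 0 or self.window_off <= 0:
            raise ValueError("min_isi and window durations must be positive")
        if self.stable_nrem_start <= 0:
            raise ValueError("stable_nrem_start must be positive")


def _trailing_mean(x: np.ndarray, n: int) -> np.ndarray:
    """Causal mean over the previous ``n`` samples (shorter at the start)."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty(x.size)
    idx = np.arange(1, x.size + 1)
    lo = np.maximum(idx - n, 0)
    out = (c[idx] - c[lo]) / (idx - lo)
    return out


def _band_power_series(data: np.ndarray, fs: float, band: tuple,
                       window_s: float) -> np.ndarray:
    sos = sps.butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    y = sps.sosfilt(sos, data) ** 2
    return _trailing_mean(y, int(round(window_s * fs)))


def detect_nrem_online(recording: Recording, config: StimEngineConfig | None = None
                       ) -> np.ndarray:
    """Causal per-sample NREM flag from trailing 80 s band powers.

    flag = low-delta power > threshold AND high-delta power > threshold AND
    high-beta power < threshold; the first 80 s are always False.
    """
    config = config or StimEngineConfig()
    fs = recording.fs
    if recording.duration < config.nrem_history:
        raise ValueError("recording shorter than the NREM history window")
    th = config.nrem_power_thresholds
    ld = _band_power_series(recording.data, fs, config.nrem_bands["low_delta"],
                            config.nrem_history)
    hd = _band_power_series(recording.data, fs, config.nrem_bands["high_delta"],
                            config.nrem_history)
    hb = _band_power_series(recording.data, fs, config.nrem_bands["high_beta"],
                            config.nrem_history)
    flags = (ld > th["low_delta"]) & (hd > th["high_delta"]) & (hb < th["high_beta"])
    flags[:int(round(config.nrem_history * fs))] = False
    return flags


def calibrate_nrem_thresholds(recording: Recording, hypnogram: Hypnogram,
                              config: StimEngineConfig | None = None) -> dict:
    """Fit band-power thresholds from a stage-labelled night.

    Each threshold is the geometric mean of the median trailing-window
    power inside NREM (N2/N3) and outside it.
    """
    config = config or StimEngineConfig()
    fs = recording.fs
    stage = hypnogram.sample_stages(recording.n_samples, fs)
    nrem = np.isin(stage, NREM_STAGES)
    warm = np.arange(recording.n_samples) >= int(config.nrem_history * fs)
    out = {}
    for name, band in config.nrem_bands.items():
        p = _band_power_series(recording.data, fs, band, config.nrem_history)
        out[name] = float(np.sqrt(np.median(p[nrem & warm]) *
                                  np.median(p[~nrem & warm])))
    return out


@njit(cache=True)
def _pll_loop(y: np.ndarray, dy: np.ndarray, dt: float, wc: float, kp: float,
              ki: float, wlo: float, whi: float, err_alpha: float,
              amp_floor: float):
    """Second-order PLL with a derivative-quadrature phase detector.

    For a band-limited input A sin(theta), the pair (w_hat * y, dy/dt)
    approximates A*w*(sin(theta), cos(theta)), so atan2 gives the
    instantaneous phase without the double-frequency product of a mixing
    detector; the loop then tracks the wrapped phase error through a PI
    filter. When the quadrature amplitude falls below ``amp_floor`` the
    loop free-runs (error forced to zero).
    """
    n = y.size
    phi = np.empty(n)
    freq = np.empty(n)
    locked = np.zeros(n, dtype=np.bool_)
    ph = 0.0
    v = 0.0
    ef = 0.0
    two_pi = 2.0 * np.pi
    for k in range(n):
        w_est = wc + v
        si = w_est * y[k]
        co = dy[k]
        if np.hypot(si, co) > amp_floor * w_est:
            locked[k] = True
            inst = np.arctan2(si, co)
            err = inst - (ph % two_pi)
            # wrap to (-pi, pi]
            while err > np.pi:
                err -= two_pi
            while err <= -np.pi:
                err += two_pi
        else:
            err = 0.0
        ef += err_alpha * (err - ef)
        v += ki * ef * dt
        w = wc + kp * ef + v
        if w < wlo:
            w = wlo
            v = wlo - wc - kp * ef
        elif w > whi:
            w = whi
            v = whi - wc - kp * ef
        phi[k] = ph
        freq[k] = w
        ph += w * dt
    return phi, freq, locked


def pll_phase(recording: Recording, config: StimEngineConfig | None = None,
              return_freq: bool = False, return_lock: bool = False):
    """Causal slow-wave phase estimate in degrees (continuous, unwrapped).

    0 deg is the positive-going zero crossing of the tracked component, so
    the 45 deg target lies on the down-to-up transition. The signal is
    band-passed causally ahead of the loop and amplitude-normalised by a
    trailing RMS; the reported phase is corrected for the causal filter's
    phase response at the loop's instantaneous frequency.
    """
    config = config or StimEngineConfig()
    fs = recording.fs
    dt = 1.0 / fs
    sos = sps.butter(2, list(config.pll_band), btype="bandpass", fs=fs, output="sos")
    y = sps.sosfilt(sos, recording.data)
    rms = np.sqrt(np.maximum(_trailing_mean(y ** 2, int(5 * fs)), 1.0))  # 1 µV floor
    y_norm = y / rms

    dy = np.gradient(y_norm) * fs
    wn = 2 * np.pi * config.pll_natural_freq
    kp = 2 * config.pll_damping * wn
    ki = wn ** 2
    wlo, whi = (2 * np.pi * f for f in config.pll_freq_limits)
    err_alpha = dt / (dt + config.pll_err_tau)
    phi, freq, locked = _pll_loop(y_norm, dy, dt,
                                  2 * np.pi * config.pll_center_freq,
                                  kp, ki, wlo, whi, err_alpha,
                                  config.pll_amp_floor)

    # compensate the causal band-pass filter's phase at the tracked frequency
    fgrid = np.linspace(config.pll_freq_limits[0], config.pll_freq_limits[1], 200)
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * fgrid / fs)
    filt_phase = np.unwrap(np.angle(h))
    corr = np.interp(freq / (2 * np.pi), fgrid, filt_phase)
    phase_deg = np.degrees(phi - corr)
    if return_lock:
        # slow-wave envelope in µV from the (unnormalised) quadrature pair
        env = np.hypot(freq * 2 * np.pi * y, np.gradient(y) * fs) / (freq * 2 * np.pi)
        return phase_deg, freq / (2 * np.pi), locked, env
    return (phase_deg, freq / (2 * np.pi)) if return_freq else phase_deg


def _phase_crossings(phase_deg: np.ndarray, target: float, fs: float,
                     refractory: float = 0.25) -> np.ndarray:
    """Sample indices where the unwrapped phase crosses target + k*360."""
    k = np.floor((phase_deg - target) / 360.0)
    idx = np.flatnonzero(np.diff(k) >= 1) + 1
    if idx.size == 0:
        return idx
    keep = [idx[0]]
    min_gap = refractory * fs
    for i in idx[1:]:
        if i - keep[-1] >= min_gap:
            keep.append(i)
    return np.asarray(keep)


def _stable_nrem_onset(flags: np.ndarray, fs: float, need_s: float,
                       tol_s: float) -> int | None:
    """First sample index after ``need_s`` of uninterrupted True flags.

    Flag dropouts shorter than ``tol_s`` do not reset the counter.
    """
    need = int(round(need_s * fs))
    tol = int(round(tol_s * fs))
    run = 0
    gap = 0
    for i, f in enumerate(flags):
        if f:
            run += gap + 1 if gap and gap <= tol else 1
            gap = 0
        else:
            gap += 1
            if gap > tol:
                run = 0
                gap = 0
        if run >= need:
            return i
    return None


def engine_state(recording: Recording, config: StimEngineConfig) -> dict:
    """Shared intermediates of the trigger logic (flags, veto, phase)."""
    fs = recording.fs
    flags = detect_nrem_online(recording, config)
    beta = sps.sosfilt(sps.butter(4, list(config.nrem_bands["high_beta"]),
                                  btype="bandpass", fs=fs, output="sos"),
                       recording.data) ** 2
    short = _trailing_mean(beta, int(round(config.arousal_beta_window * fs)))
    long = _trailing_mean(beta, int(round(config.nrem_history * fs)))
    veto = short > config.arousal_beta_ratio_threshold * np.maximum(long, 1e-12)
    phase, _, locked, env = pll_phase(recording, config, return_lock=True)
    crossings = _phase_crossings(phase, config.target_phase, fs)
    # only crossings where the loop is locked onto a wave of triggerable
    # amplitude may emit a stimulus (real or sham)
    ok = locked & (env >= config.min_wave_amplitude)
    crossings = crossings[ok[crossings]]
    onset = _stable_nrem_onset(flags, fs, config.stable_nrem_start,
                               config.stable_nrem_tolerance)
    return {"flags": flags, "veto": veto, "phase": phase, "locked": locked,
            "crossings": crossings, "stable_onset": onset}


def run_stimulation(recording: Recording, config: StimEngineConfig | None = None,
                    state: dict | None = None) -> StimulusLog:
    """Emulate a full stimulation night; returns the real-stimulus log.

    The free-running ON/OFF window clock starts at the first eligible
    trigger; real stimuli are emitted at target-phase crossings inside ON
    windows when the NREM flag holds, no arousal veto is active, the time
    since the previous real stimulus is >= min_isi, and less than 2.5 h
    have passed since the first stimulus.
    """
    config = config or StimEngineConfig()
    st = state or engine_state(recording, config)
    fs = recording.fs
    entries = []
    t0 = None           # window clock start
    first_stim = None
    last_real = None
    period = config.window_on + config.window_off
    if st["stable_onset"] is not None:
        onset_t = st["stable_onset"] / fs
        for i in st["crossings"]:
            t = i / fs
            if t < onset_t or not st["flags"][i] or st["veto"][i]:
                continue
            if first_stim is not None and t - first_stim >= config.stim_stop_after_first:
                break
            if t0 is None:
                t0 = t
            in_on = ((t - t0) % period) < config.window_on
            if not in_on:
                continue
            if last_real is not None and t - last_real < config.min_isi:
                continue
            isi = np.nan if last_real is None else t - last_real
            entries.append((t, "real", "on", isi,
                            float(st["phase"][i] % 360.0)))
            if first_stim is None:
                first_stim = t
            last_real = t
    df = pd.DataFrame(entries, columns=StimulusLog.COLUMNS)
    return StimulusLog(df, window_clock_start=t0,
                       window_on=config.window_on, window_off=config.window_off)


def reconstruct_sham_flags(recording: Recording, stim_log: StimulusLog,
                           config: StimEngineConfig | None = None,
                           state: dict | None = None) -> StimulusLog:
    """Apply the trigger criteria inside OFF windows; merge sham entries.

    The ISI constraint for shams is counted from the last sham within the
    same OFF window; real entries pass through unchanged.
    """
    config = config or StimEngineConfig()
    if stim_log.window_clock_start is None or len(stim_log) == 0:
        return stim_log
    st = state or engine_state(recording, config)
    fs = recording.fs
    t0 = stim_log.window_clock_start
    period = config.window_on + config.window_off
    first_stim = stim_log.real["time_s"].iloc[0]
    end_t = first_stim + config.stim_stop_after_first
    entries = []
    last_sham_window = None
    last_sham = None
    for i in st["crossings"]:
        t = i / fs
        if t < t0 or t >= end_t:
            continue
        off_pos = (t - t0) % period
        if off_pos < config.window_on:
            continue
        if not st["flags"][i] or st["veto"][i]:
            continue
        window_idx = int((t - t0) // period)
        if window_idx == last_sham_window and t - last_sham < config.min_isi:
            continue
        isi = np.nan if window_idx != last_sham_window else t - last_sham
        entries.append((t, "sham", "off", isi, float(st["phase"][i] % 360.0)))
        last_sham_window, last_sham = window_idx, t
    sham_df = pd.DataFrame(entries, columns=StimulusLog.COLUMNS)
    parts = [df for df in (stim_log.entries, sham_df) if not df.empty]
    merged = (pd.concat(parts).sort_values("time_s").reset_index(drop=True)
              if parts else stim_log.entries)
    return StimulusLog(merged, window_clock_start=t0,
                       window_on=config.window_on, window_off=config.window_off)
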