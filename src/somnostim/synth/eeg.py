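"""Synthetic sleep-EEG generator.

Builds ground-truthed single-channel nights with the statistical structure
the analysis pipeline assumes: a 1/f^alpha background scaled per sleep
stage, raised-cosine slow oscillations and sigma-band spindle bursts in
NREM, stereotyped K-complexes (P200/N550/P900 morphology), and an
ISI-dependent evoked K-complex probability that saturates at a plateau for
long inter-stimulus intervals.

All amplitudes are µV, all times seconds. Every generator draws from a
single ``numpy.random.Generator`` seeded per call, so fixed seeds give
bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import Hypnogram, NREM_STAGES, Recording, STAGES, StimulusLog

__all__ = [
    "EEGGenConfig", "KCTemplate", "EvokedModel", "GroundTruth",
    "DEFAULT_TRANSITIONS", "stationary_distribution", "generate_hypnogram",
    "generate_eeg", "insert_kcomplex", "simulate_evoked_responses",
    "evoked_probability",
]


@dataclass
class KCTemplate:
    """Stereotyped K-complex waveform: P200 / N550 / P900 components.

    The waveform is a sum of Gaussian bumps at the three component
    latencies; the N550 bump is corrected so that the waveform value at the
    N550 latency equals ``n550_amplitude`` exactly, making the sampled
    extremum land within one sample of ``n550_latency``.
    """

    p200_latency: float = 0.2
    n550_latency: float = 0.55
    p900_latency: float = 0.9
    n550_amplitude: float = -120.0   # µV, the negative extremum
    p200_amplitude: float = 25.0
    p900_amplitude: float = 45.0
    total_duration: float = 1.5      # s, within [0.5, 2]

    def __post_init__(self) -> None:
        if not (self.p200_latency < self.n550_latency < self.p900_latency
                <= self.total_duration):
            raise ValueError("component latencies must be ordered and fit the duration")
        if not 0.5 <= self.total_duration <= 2.0:
            raise ValueError("total_duration must lie in [0.5, 2] s")
        if self.n550_amplitude >= 0:
            raise ValueError("n550_amplitude is a negative peak")

    def sample(self, fs: float) -> np.ndarray:
        """Waveform sampled at ``fs``; starts and ends near zero."""
        n = int(round(self.total_duration * fs)) + 1
        t = np.arange(n) / fs
        widths = (0.06, 0.12, 0.15)
        lats = (self.p200_latency, self.n550_latency, self.p900_latency)
        amps = (self.p200_amplitude, self.n550_amplitude, self.p900_amplitude)
        w = np.zeros(n)
        for a, mu, s in zip(amps, lats, widths):
            w += a * np.exp(-0.5 * ((t - mu) / s) ** 2)
        # correct the N550 bump so the waveform hits the nominal extremum
        resid = self.n550_amplitude - float(np.interp(self.n550_latency, t, w))
        w += resid * np.exp(-0.5 * ((t - self.n550_latency) / widths[1]) ** 2)
        return w


@dataclass
class EvokedModel:
    """ISI-dependent evoked K-complex probability.

    p(ISI) = floor_p + (p_max - floor_p) * (1 - exp(-(ISI - isi_onset)+ / tau)),
    a saturating curve with plateau ``p_max`` (default 0.35, reached for
    ISIs beyond ~1.25 s with the default time constant).
    """

    p_max: float = 0.35
    isi_onset: float = 0.5
    tau: float = 0.25
    floor_p: float = 0.05
    spindle_coupling_prob: float = 0.5
    spindle_lag: float = 0.55       # s after K-complex onset (up-phase)
    spindle_freq: float = 14.5      # Hz, fast-sigma burst carried by the K-complex
    spindle_amplitude: float = 20.0
    spindle_duration: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.floor_p <= self.p_max <= 1:
            raise ValueError("need 0 <= floor_p <= p_max <= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def evoked_probability(model: EvokedModel, isi: float | np.ndarray) -> np.ndarray:
    """p(ISI) of the saturating evoked-response model (vectorised)."""
    isi = np.asarray(isi, dtype=float)
    x = np.maximum(isi - model.isi_onset, 0.0)
    x = np.where(np.isinf(isi), np.inf, x)
    return model.floor_p + (model.p_max - model.floor_p) * (1.0 - np.exp(-x / model.tau))


@dataclass
class EEGGenConfig:
    sampling_rate: float = 250.0
    night_duration: float = 8 * 3600.0
    spectral_slope: float = 1.0           # PSD ~ 1/f^alpha (fallback slope)
    #: Per-stage background RMS (µV). Wake carries ocular/muscle broadband
    #: activity, deep NREM the largest slow activity.
    stage_amplitude_map: dict = field(default_factory=lambda: {
        "Wake": 30.0, "N1": 20.0, "N2": 35.0, "N3": 45.0, "REM": 22.0})
    #: Per-stage spectral exponent: wake EEG is spectrally flat (relatively
    #: beta-rich), deep NREM steep (delta-dominated). None -> spectral_slope
    #: for every stage.
    stage_slope_map: dict | None = field(default_factory=lambda: {
        "Wake": 0.5, "N1": 0.9, "N2": 1.4, "N3": 1.6, "REM": 0.9})
    so_rate: float = 6.0                  # slow oscillations / min in N2+N3
    so_freq_range: tuple = (0.5, 1.25)    # Hz
    so_amplitude: float = 60.0            # µV trough depth
    spindle_rate: float = 2.0             # / min in N2+N3
    spindle_freq_range: tuple = (11.0, 16.0)
    spindle_amplitude: float = 20.0
    spindle_duration: float = 0.8
    kc_template: KCTemplate = field(default_factory=KCTemplate)
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.night_duration <= 0:
            raise ValueError("sampling_rate and night_duration must be positive")
        if self.so_rate < 0 or self.spindle_rate < 0:
            raise ValueError("event rates must be non-negative")
        lo, hi = self.so_freq_range
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValueError("so_freq_range must lie inside (0, Nyquist)")


@dataclass
class GroundTruth:
    """Inserted-event bookkeeping for a synthetic night."""

    so_times: list = field(default_factory=list)         # SO start times, s
    spindle_times: list = field(default_factory=list)    # spindle start times, s
    kc_events: list = field(default_factory=list)        # (start_s, evoked, stim_idx|None)

    def sorted(self) -> "GroundTruth":
        return GroundTruth(sorted(self.so_times), sorted(self.spindle_times),
                           sorted(self.kc_events, key=lambda e: e[0]))


# Default 30 s epoch-to-epoch stage transition probabilities
# (rows/cols ordered Wake, N1, N2, N3, REM).
DEFAULT_TRANSITIONS = np.array([
    [0.85, 0.12, 0.02, 0.00, 0.01],
    [0.08, 0.70, 0.20, 0.00, 0.02],
    [0.02, 0.04, 0.85, 0.06, 0.03],
    [0.01, 0.00, 0.07, 0.90, 0.02],
    [0.03, 0.04, 0.05, 0.00, 0.88],
])


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic transition matrix."""
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    return pi / pi.sum()


def generate_hypnogram(night_duration: float,
                       stage_transition_params: dict | None = None,
                       seed: int | None = None) -> Hypnogram:
    """First-order Markov hypnogram of 30 s epochs.

    ``stage_transition_params`` may contain ``transitions`` (5x5
    row-stochastic matrix in Wake/N1/N2/N3/REM order) and ``initial``
    (stage label, default "Wake").
    """
    if night_duration < 30:
        raise ValueError("night_duration must be at least one 30 s epoch")
    params = stage_transition_params or {}
    P = np.asarray(params.get("transitions", DEFAULT_TRANSITIONS), dtype=float)
    if P.shape != (5, 5) or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("transitions must be a 5x5 row-stochastic matrix")
    rng = np.random.default_rng(seed)
    n_epochs = int(night_duration // 30)
    state = STAGES.index(params.get("initial", "Wake"))
    stages = []
    for _ in range(n_epochs):
        stages.append(STAGES[state])
        state = rng.choice(5, p=P[state])
    return Hypnogram(stages)


def _pink_background(n: int, fs: float, alpha: float, rng: np.random.Generator,
                     f_corner: float = 0.4) -> np.ndarray:
    """Unit-RMS noise with PSD ~ 1/f^alpha above ``f_corner``, flat below.

    The corner keeps the realisation's variance finite and physiological
    (real scalp EEG carries no unbounded infra-slow drift) so that the
    per-stage RMS scaling translates into the intended band powers.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.maximum(f, f_corner) ** (-alpha / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / np.std(x)


def _so_waveform(freq: float, fs: float, amplitude: float) -> np.ndarray:
    """One slow-oscillation cycle: raised-cosine down half-wave then up half-wave."""
    half = int(round(fs / (2 * freq)))
    t1 = np.arange(half) / half
    down = -amplitude * np.sin(np.pi * t1) ** 2
    up = 0.6 * amplitude * np.sin(np.pi * t1) ** 2
    return np.concatenate([down, up])


def _spindle_waveform(freq: float, fs: float, amplitude: float, duration: float) -> np.ndarray:
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    env = np.exp(-0.5 * ((t - duration / 2) / (duration / 6)) ** 2)
    return amplitude * env * np.sin(2 * np.pi * freq * t)


def _poisson_event_times(rng: np.random.Generator, duration: float,
                         rate_per_min: float, refractory: float) -> np.ndarray:
    """Poisson event starts with a hard refractory gap between consecutive events."""
    if rate_per_min <= 0:
        return np.array([])
    mean_gap = 60.0 / rate_per_min
    times, t = [], 0.0
    while True:
        t += max(rng.exponential(mean_gap), refractory)
        if t >= duration:
            break
        times.append(t)
    return np.asarray(times)


def generate_eeg(hypnogram: Hypnogram, config: EEGGenConfig,
                 seed: int | None = None) -> tuple[Recording, GroundTruth]:
    """Synthesize a night of single-channel EEG matching a hypnogram.

    The signal is a per-stage-scaled 1/f^alpha background plus slow
    oscillations and spindle bursts inserted in N2/N3 epochs; every inserted
    event time is returned in the :class:`GroundTruth`.
    """
    if len(hypnogram) == 0:
        raise ValueError("hypnogram must contain at least one epoch")
    fs = config.sampling_rate
    duration = hypnogram.duration
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed if seed is not None else config.noise_seed)

    stage_per_sample = hypnogram.sample_stages(n, fs)
    slope_map = config.stage_slope_map or {}
    slopes = sorted({slope_map.get(s, config.spectral_slope) for s in STAGES})
    # one shaped-noise realisation per distinct slope, blended per sample
    per_slope = {a: _pink_background(n, fs, a, rng) for a in slopes}
    sample_slope = np.array([slope_map.get(s, config.spectral_slope)
                             for s in stage_per_sample])
    background = np.empty(n)
    for a, x in per_slope.items():
        sel = sample_slope == a
        background[sel] = x[sel]
    amp = np.array([config.stage_amplitude_map[s] for s in stage_per_sample])
    # ~1 s ramp between stages to avoid step discontinuities
    from scipy.ndimage import uniform_filter1d
    amp = uniform_filter1d(amp, max(int(fs), 1))
    signal = background * amp

    gt = GroundTruth()
    nrem = np.isin(stage_per_sample, NREM_STAGES)

    for t0 in _poisson_event_times(rng, duration, config.so_rate,
                                   refractory=1.0 + 1.0 / config.so_freq_range[0]):
        i0 = int(round(t0 * fs))
        f = rng.uniform(*config.so_freq_range)
        wf = _so_waveform(f, fs, config.so_amplitude)
        if i0 + wf.size <= n and nrem[i0]:
            signal[i0:i0 + wf.size] += wf
            gt.so_times.append(t0)

    for t0 in _poisson_event_times(rng, duration, config.spindle_rate,
                                   refractory=config.spindle_duration):
        i0 = int(round(t0 * fs))
        f = rng.uniform(*config.spindle_freq_range)
        wf = _spindle_waveform(f, fs, config.spindle_amplitude, config.spindle_duration)
        if i0 + wf.size <= n and nrem[i0]:
            signal[i0:i0 + wf.size] += wf
            gt.spindle_times.append(t0)

    return Recording(signal, fs), gt.sorted()


def insert_kcomplex(signal: np.ndarray, t: float, template: KCTemplate,
                    amplitude_scale: float = 1.0, fs: float = 250.0) -> np.ndarray:
    """Additively superpose a scaled K-complex template at time ``t``.

    Returns a new array; ``signal' - signal`` is exactly the scaled template
    and zero elsewhere.
    """
    wf = template.sample(fs) * amplitude_scale
    i0 = int(round(t * fs))
    if t < 0 or i0 + wf.size > signal.size:
        raise ValueError("K-complex does not fit inside the recording")
    out = np.array(signal, dtype=float, copy=True)
    out[i0:i0 + wf.size] += wf
    return out


def simulate_evoked_responses(recording: Recording, stim_log: StimulusLog,
                              model: EvokedModel, template: KCTemplate,
                              seed: int | None = None,
                              ) -> tuple[Recording, GroundTruth]:
    """Insert stimulus-evoked K-complexes (and nested spindles) into a night.

    For every real stimulus an evoked K-complex is drawn with probability
    p(ISI) from the saturating model; evoked events start uniformly within
    [0.2, 1.0] s after the stimulus, always inside the 1.5 s association
    window. Sham stimuli never evoke insertions. The first stimulus of a
    night (undefined preceding ISI) is treated as infinitely rested.
    """
    rng = np.random.default_rng(seed)
    out = recording.copy()
    gt = GroundTruth()
    real = stim_log.real
    isis = real["preceding_isi_s"].to_numpy(dtype=float)
    if real["time_s"].size and np.isnan(isis[1:]).any():
        raise ValueError("preceding ISI missing for a non-first stimulus")
    times = real["time_s"].to_numpy(dtype=float)
    if times.size and (times.min() < 0 or times.max() > recording.duration):
        raise ValueError("stimulus times outside the recording")
    fs = recording.fs
    for idx, (t_stim, isi) in enumerate(zip(times, isis)):
        p = float(evoked_probability(model, np.inf if np.isnan(isi) else isi))
        if rng.random() >= p:
            continue
        kc_start = t_stim + rng.uniform(0.2, 1.0)
        if kc_start + template.total_duration > recording.duration:
            continue
        wf = template.sample(fs)          # in-place add on the working copy
        i0 = int(round(kc_start * fs))
        out.data[i0:i0 + wf.size] += wf
        gt.kc_events.append((kc_start, True, idx))
        if rng.random() < model.spindle_coupling_prob:
            sp_start = kc_start + model.spindle_lag
            wf = _spindle_waveform(model.spindle_freq, fs, model.spindle_amplitude,
                                   model.spindle_duration)
            i0 = int(round(sp_start * fs))
            if i0 + wf.size <= out.data.size:
                out.data[i0:i0 + wf.size] += wf
                gt.spindle_times.append(sp_start)
    return out, gt.sorted()
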