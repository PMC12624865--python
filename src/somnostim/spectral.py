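"""Stimulus-locked spectral analysis and cluster-permutation statistics.

Time-frequency maps use complex Morlet wavelets on a linear 1-30 Hz grid
(1 Hz steps) with cycle counts increasing linearly from 3 at 1 Hz to 17.5
at 30 Hz, log-normalised by a whole-epoch per-frequency baseline pooled
over ON and OFF epochs. Paired ON-OFF (or category) contrasts are tested
with a nonparametric cluster-based permutation test: supra-threshold
cells of the paired t map are grouped by contiguity, scored by cluster
mass (sum of t), and compared against the permutation null distribution
of the maximal cluster mass.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sps, stats

from .core import EpochSet, Recording, StimulusLog

__all__ = [
    "TFMap", "ClusterResult", "morlet_tf", "baseline_normalize",
    "match_epoch_counts", "compute_aep", "cluster_permutation_test",
    "find_clusters", "delta_low_swa", "epochs_to_night_maps",
]

DEFAULT_FREQS = np.arange(1.0, 31.0)


def default_cycles(freqs: np.ndarray) -> np.ndarray:
    """Cycle counts linear in frequency: 3 at 1 Hz to 17.5 at 30 Hz."""
    return 3.0 + (freqs - 1.0) * (17.5 - 3.0) / 29.0


@dataclass
class TFMap:
    """Time-frequency power map (n_freqs x n_times)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    normalization: str = "none"          # "none" | "log-baseline"
    valid: np.ndarray | None = None      # False within one wavelet half-support of an edge

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if not np.isfinite(self.power).all():
            raise ValueError("power must be finite")


@dataclass
class ClusterResult:
    clusters: list                 # dicts: cells, mass, sign, significant
    threshold_mass: float          # 95th percentile of the permutation null
    n_permutations: int
    t_map: np.ndarray
    null_max_mass: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c["significant"]]


def morlet_tf(epoch_set: EpochSet, freqs: np.ndarray | None = None,
              n_cycles: np.ndarray | None = None) -> list[TFMap]:
    """Per-epoch Morlet wavelet power maps.

    Cells within one wavelet half-support of an epoch edge are flagged
    invalid (``valid`` mask) and should be excluded from statistics;
    epochs shorter than the longest wavelet are zero-padded by the
    convolution and fully edge-flagged at the affected frequencies.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    n_cycles = default_cycles(freqs) if n_cycles is None else np.asarray(n_cycles)
    if len(epoch_set) == 0:
        return []
    data = epoch_set.epochs[:, None, :]          # (n_epochs, 1 ch, n_times)
    # wavelets span ~10 sigma_t; zero-pad short epochs so the convolution is
    # defined, then crop back (padded cells fall inside the invalid edge mask)
    max_len = int(np.ceil(10 * np.max(n_cycles / freqs / (2 * np.pi)) * epoch_set.fs)) + 2
    pad = max(0, (max_len - data.shape[-1] + 1) // 2 + 1)
    if pad:
        data = np.pad(data, ((0, 0), (0, 0), (pad, pad)))
    power = tfr_array_morlet(data, epoch_set.fs, freqs, n_cycles=n_cycles,
                             output="power", zero_mean=True)
    if pad:
        power = power[..., pad:pad + epoch_set.epochs.shape[1]]
    times = epoch_set.times
    n_t = times.size
    half_support = n_cycles / freqs / 2.0        # s
    valid = np.ones((freqs.size, n_t), dtype=bool)
    for i, hs in enumerate(half_support):
        k = int(np.ceil(hs * epoch_set.fs))
        if k > 0:
            valid[i, :min(k, n_t)] = False
            valid[i, max(n_t - k, 0):] = False
    return [TFMap(power[e, 0], freqs, times, "none", valid.copy())
            for e in range(len(epoch_set))]


def baseline_normalize(maps: list[TFMap], mode: str = "whole-epoch-log") -> list[TFMap]:
    """dB-scale each map against the pooled whole-epoch baseline.

    Per frequency, the baseline is the mean power over all times and all
    supplied maps (ON and OFF pooled); output is 10*log10(power/baseline),
    invariant to global scaling of the inputs.
    """
    if mode != "whole-epoch-log":
        raise ValueError(f"unknown normalisation mode {mode!r}")
    if not maps:
        raise ValueError("need at least one map")
    baseline = np.mean([m.power for m in maps], axis=(0, 2))  # per frequency
    if np.any(baseline <= 0):
        raise ValueError("non-positive baseline power")
    return [TFMap(10.0 * np.log10(m.power / baseline[:, None]), m.freqs,
                  m.times, "log-baseline", m.valid) for m in maps]


def match_epoch_counts(set_a: EpochSet, set_b: EpochSet,
                       seed: int | None = None) -> tuple[EpochSet, EpochSet]:
    """Random subsample of the majority class to the minority count."""
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both epoch sets must be non-empty")
    rng = np.random.default_rng(seed)
    n = min(len(set_a), len(set_b))

    def cut(s: EpochSet) -> EpochSet:
        if len(s) == n:
            return s
        idx = np.sort(rng.choice(len(s), size=n, replace=False))
        return s.subset(idx)

    return cut(set_a), cut(set_b)


def compute_aep(on_epochs: EpochSet, off_epochs: EpochSet) -> dict:
    """Time-domain means per condition and the ON-OFF difference wave."""
    if len(on_epochs) != len(off_epochs):
        warnings.warn("unmatched epoch counts; consider match_epoch_counts",
                      stacklevel=2)
    mean_on = on_epochs.epochs.mean(axis=0)
    mean_off = off_epochs.epochs.mean(axis=0)
    return {"on": mean_on, "off": mean_off, "difference": mean_on - mean_off,
            "times": on_epochs.times}


def find_clusters(mask: np.ndarray, t_map: np.ndarray) -> list[dict]:
    """Contiguous clusters of True cells scored by mass = sum of t.

    2-D masks use 4-neighbourhood contiguity, 1-D masks plain adjacency.
    Positive and negative t cells never join the same cluster.
    """
    clusters = []
    for sign in (1, -1):
        m = mask & (np.sign(t_map) == sign)
        if m.ndim == 1:
            structure = np.ones(3, dtype=bool)
        else:
            structure = ndimage.generate_binary_structure(m.ndim, 1)
        labels, n = ndimage.label(m, structure=structure)
        for lab in range(1, n + 1):
            cells = np.flatnonzero(labels.ravel() == lab)
            mass = float(t_map.ravel()[cells].sum())
            clusters.append({"cells": np.array(np.unravel_index(cells, t_map.shape)).T,
                             "mass": mass, "sign": sign})
    return clusters


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Paired t over axis 0; zero-variance cells get t = 0."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def cluster_permutation_test(data_a: np.ndarray, data_b: np.ndarray,
                             n_perm: int = 2000, alpha: float = 0.05,
                             seed: int | None = None,
                             statistic: str = "mass") -> ClusterResult:
    """Paired cluster-based permutation test on maps or waveforms.

    ``data_a``/``data_b`` are (n_units, ...) paired per unit (night). The
    observed paired t map is thresholded two-tailed at ``alpha``; clusters
    of contiguous supra-threshold cells are scored by mass (sum of t) or
    extent (cell count). The null distribution is the maximal cluster
    statistic under per-unit condition-label swaps (sign flips of the
    paired differences); clusters exceeding its 95th percentile are
    significant (family-wise control).
    """
    a = np.asarray(data_a, dtype=float)
    b = np.asarray(data_b, dtype=float)
    if a.shape != b.shape or a.shape[0] < 2:
        raise ValueError("need >= 2 paired units of equal shape")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations is unreliable", stacklevel=2)
    rng = np.random.default_rng(seed)
    diff = a - b
    n = diff.shape[0]
    shape = diff.shape[1:]
    flat = diff.reshape(n, -1)
    t_crit = stats.t.ppf(1 - alpha / 2, n - 1)

    t_obs = _paired_t(diff)
    clusters = find_clusters(np.abs(t_obs) > t_crit, t_obs)

    def score(c):
        return abs(c["mass"]) if statistic == "mass" else len(c["cells"])

    sumsq = (flat ** 2).sum(axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = np.empty(n_perm)
    sqrt_n = np.sqrt(n)
    for p in range(n_perm):
        m = signs[p] @ flat / n
        var = (sumsq - n * m ** 2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / (np.sqrt(var) / sqrt_n)
        t[~np.isfinite(t)] = 0.0
        t = t.reshape(shape)
        cl = find_clusters(np.abs(t) > t_crit, t)
        null[p] = max((score(c) for c in cl), default=0.0)

    thresh = float(np.quantile(null, 0.95))
    for c in clusters:
        c["significant"] = score(c) > thresh
    return ClusterResult(clusters, thresh, n_perm, t_obs, null)


def epochs_to_night_maps(maps: list[TFMap], nights: np.ndarray) -> np.ndarray:
    """Average per-epoch maps within night, giving (n_nights, n_f, n_t)."""
    nights = np.asarray(nights)
    uniq = np.unique(nights)
    return np.stack([np.mean([m.power for m, g in zip(maps, nights) if g == u], axis=0)
                     for u in uniq])


def delta_low_swa(recording: Recording, stim_log: StimulusLog,
                  band: tuple = (0.5, 1.0)) -> float:
    """ON-minus-OFF low slow-wave-activity (0.5-1 Hz power) for one night.

    Welch power in ``band`` is estimated per 6 s window and averaged
    separately over ON and OFF windows of the stimulation period.
    """
    if stim_log.window_clock_start is None or len(stim_log) == 0:
        raise ValueError("stimulus log carries no window clock")
    fs = recording.fs
    t_end = stim_log.entries["time_s"].max() + stim_log.window_on + stim_log.window_off
    windows = stim_log.windows(min(t_end, recording.duration))
    powers = {"on": [], "off": []}
    for _, w in windows.iterrows():
        i0, i1 = int(w.start_s * fs), int(w.end_s * fs)
        seg = recording.data[i0:i1]
        if seg.size < fs:      # need >= 1 s for the lowest band edge
            continue
        f, pxx = sps.welch(seg, fs=fs, nperseg=min(seg.size, int(4 * fs)))
        sel = (f >= band[0]) & (f <= band[1])
        powers[w.window].append(np.trapezoid(pxx[sel], f[sel]))
    if not powers["on"] or not powers["off"]:
        raise ValueError("need at least one ON and one OFF window")
    return float(np.mean(powers["on"]) - np.mean(powers["off"]))
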