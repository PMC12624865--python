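"""Core containers shared across the pipeline.

All signal amplitudes are in microvolts (µV) and all times in seconds
relative to recording start unless stated otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical sleep-stage labels for 30 s epochs.
STAGES = ("Wake", "N1", "N2", "N3", "REM")
NREM_STAGES = ("N2", "N3")
SLEEP_STAGES = ("N1", "N2", "N3", "REM")

EPOCH_LEN = 30.0  # s, scoring epoch length


@dataclass
class Recording:
    """Single-channel EEG time series.

    Parameters
    ----------
    data : 1-D float array, µV
    fs : sampling rate, Hz
    start_time : offset of the first sample, s (almost always 0)
    channel : label of the electrode site
    """

    data: np.ndarray
    fs: float
    start_time: float = 0.0
    channel: str = "Fpz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("Recording.data must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, self.start_time, self.channel)


@dataclass
class Hypnogram:
    """Sequence of 30 s sleep-stage labels aligned to a recording."""

    stages: list[str]
    epoch_len: float = EPOCH_LEN

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return len(self.stages) * self.epoch_len

    def as_array(self) -> np.ndarray:
        return np.asarray(self.stages, dtype=object)

    def stage_of_time(self, t: float | np.ndarray) -> np.ndarray:
        """Stage label(s) at time(s) ``t`` (seconds)."""
        idx = np.clip((np.asarray(t) / self.epoch_len).astype(int), 0, len(self.stages) - 1)
        return self.as_array()[idx]

    def sample_stages(self, n_samples: int, fs: float) -> np.ndarray:
        """Per-sample stage labels for a recording of ``n_samples`` at ``fs``."""
        t = np.arange(n_samples) / fs
        return self.stage_of_time(t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch_index": np.arange(len(self.stages)), "stage": self.stages})


@dataclass
class StimulusLog:
    """Trigger log of a stimulation night.

    ``entries`` columns: ``time_s``, ``kind`` (``real``/``sham``), ``window``
    (``on``/``off``), ``preceding_isi_s`` (NaN for the first stimulus of its
    stream), ``phase_deg`` (loop phase estimate at trigger).
    ``window_clock_start`` and the window durations allow the ON/OFF window
    boundaries to be reconstructed exactly.
    """

    entries: pd.DataFrame
    window_clock_start: float | None = None
    window_on: float = 6.0
    window_off: float = 6.0

    COLUMNS = ["time_s", "kind", "window", "preceding_isi_s", "phase_deg"]

    def __post_init__(self) -> None:
        for c in self.COLUMNS:
            if c not in self.entries.columns:
                raise ValueError(f"StimulusLog entries missing column {c!r}")
        t = self.entries["time_s"].to_numpy()
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("StimulusLog times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def real(self) -> pd.DataFrame:
        return self.entries[self.entries["kind"] == "real"]

    @property
    def sham(self) -> pd.DataFrame:
        return self.entries[self.entries["kind"] == "sham"]

    def windows(self, until: float) -> pd.DataFrame:
        """ON/OFF window intervals from the free-running window clock."""
        if self.window_clock_start is None:
            raise ValueError("no window clock recorded in this log")
        period = self.window_on + self.window_off
        starts = np.arange(self.window_clock_start, until, period)
        rows = []
        for s in starts:
            rows.append((s, min(s + self.window_on, until), "on"))
            if s + self.window_on < until:
                rows.append((s + self.window_on, min(s + period, until), "off"))
        return pd.DataFrame(rows, columns=["start_s", "end_s", "window"])


@dataclass
class EpochSet:
    """Equal-length signal epochs around alignment times.

    ``epochs`` is (n_epochs, n_samples); ``window`` is (pre, post) seconds
    around each alignment time; ``labels`` carries per-epoch metadata.
    """

    epochs: np.ndarray
    window: tuple[float, float]
    alignment_times: np.ndarray
    fs: float
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        self.alignment_times = np.asarray(self.alignment_times, dtype=float)
        if self.epochs.shape[0] != self.alignment_times.size and self.epochs.size:
            raise ValueError("epochs/alignment_times length mismatch")

    def __len__(self) -> int:
        return 0 if self.epochs.size == 0 else self.epochs.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Epoch-relative sample times (s), 0 at the alignment sample."""
        pre, post = self.window
        n = self.epochs.shape[1] if self.epochs.size else int(round((pre + post) * self.fs))
        return -pre + np.arange(n) / self.fs

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        labels = self.labels.iloc[idx].reset_index(drop=True) if len(self.labels) else self.labels
        return EpochSet(self.epochs[idx], self.window, self.alignment_times[idx],
                        self.fs, labels, self.n_dropped)
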