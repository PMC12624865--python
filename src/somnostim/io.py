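"""Reading and writing of recordings, hypnograms and event logs.

Recordings are stored as raw little-endian float32 samples (µV) with a JSON
sidecar describing sampling rate and channel; EDF files are read through MNE.
Hypnograms are 2-column CSV (epoch_index, stage); stimulus logs are CSV with
documented field names.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Hypnogram, Recording, StimulusLog


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``<path>.dat`` (float32 raw samples) + ``<path>.json`` sidecar."""
    path = Path(path)
    dat = path.with_suffix(".dat")
    rec.data.astype("<f4").tofile(dat)
    meta = {
        "format": "raw-float32-le",
        "unit": "uV",
        "sampling_rate_hz": rec.fs,
        "start_time_s": rec.start_time,
        "channel": rec.channel,
        "n_samples": int(rec.n_samples),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return dat


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`, or an EDF file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".dat"), dtype="<f4").astype(float)
    if data.size != meta["n_samples"]:
        raise ValueError("sample count does not match sidecar metadata")
    return Recording(data, meta["sampling_rate_hz"], meta["start_time_s"], meta["channel"])


def read_edf(path: str | Path, channel: str | None = None) -> Recording:
    """Read one channel of an EDF file as a :class:`Recording` (µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [channel] if channel is not None else [raw.ch_names[0]]
    data = raw.get_data(picks=picks)[0] * 1e6  # MNE returns volts
    return Recording(data, raw.info["sfreq"], 0.0, picks[0])


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    hyp.to_frame().to_csv(path, index=False)
    return path


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    df = df.sort_values("epoch_index")
    return Hypnogram(list(df["stage"]))


def write_stimulus_log(log: StimulusLog, path: str | Path) -> Path:
    path = Path(path)
    log.entries.to_csv(path, index=False)
    meta = {
        "window_clock_start_s": log.window_clock_start,
        "window_on_s": log.window_on,
        "window_off_s": log.window_off,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_stimulus_log(path: str | Path) -> StimulusLog:
    path = Path(path)
    entries = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    kw = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        kw = dict(window_clock_start=meta["window_clock_start_s"],
                  window_on=meta["window_on_s"], window_off=meta["window_off_s"])
    return StimulusLog(entries, **kw)
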