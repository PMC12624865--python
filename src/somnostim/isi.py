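"""ISI binning and K-complex response-probability analysis.

Stimuli are binned by the inter-stimulus interval (ISI) preceding them;
per participant and bin, the proportion of stimuli followed by a
K-complex (starting within 1.5 s) estimates the evoked-response
probability, which saturates for long ISIs. Stimuli are also categorised
around the 1.25 s threshold (above: ISI > 1.25 s; below: ISI <= 1.25 s).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StimulusLog

__all__ = [
    "ISIBinScheme", "STUDY_BINS", "compute_isis", "derive_bins",
    "kc_probability_by_bin", "categorize_stimuli", "stimulus_response_summary",
    "plot_probability_curve",
]


@dataclass
class ISIBinScheme:
    """Ordered ISI bin boundaries (seconds); the last bin is open-ended."""

    edges: tuple
    labels: tuple | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 values")
        if self.labels is None:
            labels = [f"{a:g}-{b:g}s" for a, b in zip(e[:-1], e[1:])]
            labels.append(f">{e[-1]:g}s")
            self.labels = tuple(labels)
        elif len(self.labels) != e.size:
            raise ValueError("need one label per bin (incl. the open-ended last)")

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    def assign(self, isis) -> np.ndarray:
        """Bin index per ISI; -1 for undefined (NaN) or below the first edge.

        Bins are left-open, right-closed (a, b], matching the categorisation
        rule that puts an ISI exactly at a boundary into the lower bin.
        """
        isis = np.asarray(isis, dtype=float)
        idx = np.searchsorted(self.edges, isis, side="left") - 1
        with np.errstate(invalid="ignore"):
            at_first_edge = np.isclose(isis, self.edges[0])
            idx[at_first_edge] = 0
            idx[~np.isfinite(isis) | ((isis < self.edges[0]) & ~at_first_edge)] = -1
        return idx


#: The ten printed study bins: 0.5-0.75, 0.75-1, 1-1.25, 1.25-1.5, 1.5-2,
#: 2-2.5, 2.5-6.5, 6.5-8, 8-10.5 and >10.5 s.
STUDY_BINS = ISIBinScheme((0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 2.5, 6.5, 8.0, 10.5))


def compute_isis(stim_log: StimulusLog | np.ndarray) -> np.ndarray:
    """Preceding ISI per real stimulus; the first of the night is NaN."""
    if isinstance(stim_log, StimulusLog):
        times = stim_log.real["time_s"].to_numpy(dtype=float)
    else:
        times = np.asarray(stim_log, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("stimulus times must be strictly increasing")
    isis = np.full(times.size, np.nan)
    if times.size > 1:
        isis[1:] = np.diff(times)
    return isis


def derive_bins(isis, n_bins: int = 10, grid: float = 0.25) -> ISIBinScheme:
    """Data-driven bins: empirical quantiles snapped to a 0.25 s grid.

    Edges are the 0, 1/n, ..., (n-1)/n quantiles rounded to the grid and
    de-duplicated, giving roughly uniformly populated bins with readable
    boundaries; the last bin is open-ended.
    """
    isis = np.asarray(isis, dtype=float)
    isis = isis[np.isfinite(isis)]
    if np.unique(isis).size < n_bins:
        raise ValueError("too few distinct ISI values for the requested bins")
    q = np.quantile(isis, np.arange(n_bins) / n_bins)
    edges = np.unique(np.round(q / grid) * grid)
    if edges.size < 2:
        raise ValueError("degenerate ISI distribution")
    return ISIBinScheme(tuple(edges))


def kc_probability_by_bin(outcomes: pd.DataFrame,
                          scheme: ISIBinScheme = STUDY_BINS,
                          min_reportable: int = 10) -> pd.DataFrame:
    """Per-participant, per-bin K-complex proportions.

    ``outcomes`` needs columns ``isi``, ``outcome`` (0/1) and optionally
    ``participant`` (single pooled participant assumed otherwise); nights
    per participant are collapsed before binning. Bins with fewer stimuli
    than ``min_reportable`` are flagged ``low_n``.
    """
    if outcomes.empty:
        return pd.DataFrame(columns=["participant", "bin", "bin_label",
                                     "n_stimuli", "n_with_kc", "proportion", "low_n"])
    df = outcomes.copy()
    if "participant" not in df:
        df["participant"] = "pooled"
    df["bin"] = scheme.assign(df["isi"].to_numpy())
    df = df[df["bin"] >= 0]
    rows = []
    for (part, b), grp in df.groupby(["participant", "bin"]):
        n = len(grp)
        k = int(grp["outcome"].sum())
        rows.append({"participant": part, "bin": int(b),
                     "bin_label": scheme.labels[int(b)], "n_stimuli": n,
                     "n_with_kc": k, "proportion": k / n,
                     "low_n": n < min_reportable})
    return pd.DataFrame(rows).sort_values(["participant", "bin"]).reset_index(drop=True)


def group_mean_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Across-participant mean proportion per bin."""
    return (table.groupby(["bin", "bin_label"], sort=True)["proportion"]
            .agg(["mean", "count"]).reset_index())


def categorize_stimuli(isis, threshold: float = 1.25) -> np.ndarray:
    """Label stimuli "above" (ISI > threshold), "below" (<=), "excluded" (NaN)."""
    isis = np.asarray(isis, dtype=float)
    out = np.where(np.isnan(isis), "excluded",
                   np.where(isis > threshold, "above", "below"))
    return out.astype(object)


def stimulus_response_summary(outcomes: pd.DataFrame) -> dict:
    """Per-night response proportion over ON-window real stimuli.

    ``outcomes`` is the association table restricted to one night; only
    rows with kind == "real" (if present) enter the normalisation.
    """
    df = outcomes
    if "kind" in df:
        df = df[df["kind"] == "real"]
    n = len(df)
    n_with = int(df["outcome"].sum()) if n else 0
    return {"n_stimuli": n, "n_with_kc": n_with, "n_without_kc": n - n_with,
            "proportion": n_with / n if n else np.nan}


def plot_probability_curve(table: pd.DataFrame, ax=None):
    """Group-mean K-complex probability versus ISI bin (study-figure style)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for part, grp in table.groupby("participant"):
        ax.plot(grp["bin"], grp["proportion"], color="0.8", lw=0.8, zorder=1)
    mean = group_mean_curve(table)
    ax.plot(mean["bin"], mean["mean"], "o-", color="C0", zorder=2)
    ax.set_xticks(mean["bin"])
    ax.set_xticklabels(mean["bin_label"], rotation=45, ha="right")
    ax.set_xlabel("preceding ISI bin")
    ax.set_ylabel("P(K-complex | stimulus)")
    return ax
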