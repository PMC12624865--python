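"""Finger-tapping and vigilance scoring plus the study's statistical helpers.

The finger-tapping task (FTT) repeats a six-digit sequence on keys 1–4 in
30 s trial blocks. Performance per trial is the percentage of correct
sequences divided by the mean intertap interval (units %/s); tapping
variability is the mean within-attempt standard deviation of intertap
intervals over completed sequences. Session-level consolidation metrics
compare the learning plateau (trials 10–12) with next-morning retrieval.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TapTrial", "TapLog", "TrialScore", "SessionSummary",
    "segment_sequences", "score_trial", "session_summary", "pvt_speed",
    "paired_compare", "percentage_bend_correlation", "outlier_mask",
    "export_model_table",
]


@dataclass
class TapTrial:
    """One 30 s tapping block: tap times (s) and key identities (1–4)."""

    kind: str                     # "L1".."L12" learning, "R1".."R3" retrieval
    times: np.ndarray
    keys: np.ndarray
    target: tuple = (2, 4, 1, 3, 1, 2)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.keys = np.asarray(self.keys, dtype=int)
        order = np.argsort(self.times, kind="stable")
        self.times, self.keys = self.times[order], self.keys[order]
        if self.keys.size and not np.isin(self.keys, [1, 2, 3, 4]).all():
            raise ValueError("tap keys must be in {1,2,3,4}")


@dataclass
class TapLog:
    trials: list = field(default_factory=list)

    def learning(self) -> list:
        return [t for t in self.trials if t.kind.startswith("L")]

    def retrieval(self) -> list:
        return [t for t in self.trials if t.kind.startswith("R")]


@dataclass
class TrialScore:
    pct_correct_sequences: float
    mean_intertap_interval: float   # s
    performance_score: float        # %/s
    tapping_variability: float      # s
    n_completed: int
    n_correct: int


@dataclass
class SessionSummary:
    """Per-metric learning/consolidation summary of one FTT session pair."""

    baseline: dict
    plateau: dict
    learning_rate: dict
    retrieval: dict
    overnight_change: dict


def segment_sequences(taps: TapTrial, target: tuple | None = None) -> list[dict]:
    """Greedy fixed-window segmentation of a tap stream into 6-tap attempts.

    Taps are partitioned into consecutive 6-tap attempts; a trailing partial
    attempt is neither completed nor correct. No realignment happens after
    an error (deterministic position-marker behaviour).
    """
    target = tuple(target if target is not None else taps.target)
    L = len(target)
    attempts = []
    for i in range(0, taps.keys.size, L):
        keys = taps.keys[i:i + L]
        times = taps.times[i:i + L]
        completed = keys.size == L
        attempts.append({
            "completed": completed,
            "correct": completed and tuple(keys) == target,
            "intervals": np.diff(times) if completed else np.array([]),
        })
    return attempts


def score_trial(taps: TapTrial, target: tuple | None = None) -> TrialScore:
    """Score one 30 s tapping trial.

    performance = 100 * n_correct / n_completed / mean-ITI (%/s);
    variability = mean over completed attempts of the SD of their 5
    intervals. With zero completed attempts all metrics are NaN.
    """
    attempts = segment_sequences(taps, target)
    completed = [a for a in attempts if a["completed"]]
    n_completed = len(completed)
    n_correct = sum(a["correct"] for a in completed)
    if n_completed == 0:
        return TrialScore(math.nan, math.nan, math.nan, math.nan, 0, 0)
    all_iti = np.concatenate([a["intervals"] for a in completed])
    mean_iti = float(np.mean(all_iti))
    pct = 100.0 * n_correct / n_completed
    variability = float(np.mean([np.std(a["intervals"], ddof=1) for a in completed]))
    return TrialScore(pct, mean_iti, pct / mean_iti, variability, n_completed, n_correct)


def _metric_dict(score: TrialScore) -> dict:
    return {"performance": score.performance_score,
            "variability": score.tapping_variability}


def session_summary(trial_scores: dict[str, TrialScore]) -> SessionSummary:
    """Learning/consolidation summary from per-trial scores.

    Keys of ``trial_scores`` are trial kinds ("L1".."L12", "R1".."R3").
    Baseline = trial L1; plateau = mean of the last three learning trials;
    learning rate = plateau - baseline; retrieval = mean of R1–R3;
    overnight change = retrieval - plateau, per metric.
    """
    learning = sorted((k for k in trial_scores if k.startswith("L")),
                      key=lambda k: int(k[1:]))
    retrieval = sorted((k for k in trial_scores if k.startswith("R")),
                       key=lambda k: int(k[1:]))
    if len(learning) < 12 or len(retrieval) < 3:
        warnings.warn("fewer than 12 learning or 3 retrieval trials", stacklevel=2)
    if not learning:
        raise ValueError("no learning trials")
    base = _metric_dict(trial_scores[learning[0]])
    metrics = list(base)

    def mean_over(kinds):
        return {m: float(np.mean([_metric_dict(trial_scores[k])[m] for k in kinds]))
                for m in metrics}

    plateau = mean_over(learning[-3:])
    retr = mean_over(retrieval) if retrieval else {m: math.nan for m in metrics}
    rate = {m: plateau[m] - base[m] for m in metrics}
    overnight = {m: retr[m] - plateau[m] for m in metrics}
    return SessionSummary(base, plateau, rate, retr, overnight)


def pvt_speed(rts_ms: np.ndarray) -> tuple[float, int]:
    """Mean response speed 1/RT (s^-1) over nonlapse trials (RT < 500 ms).

    Returns (speed, lapse_count); speed is NaN when every trial is a lapse.
    """
    rts_ms = np.asarray(rts_ms, dtype=float)
    nonlapse = rts_ms[rts_ms < 500.0]
    n_lapse = int(rts_ms.size - nonlapse.size)
    if nonlapse.size == 0:
        return math.nan, n_lapse
    return float(np.mean(1.0 / (nonlapse / 1000.0))), n_lapse


def hedges_g_paired(x: np.ndarray, y: np.ndarray) -> float:
    """Hedges g on paired differences with small-sample correction
    J = 1 - 3/(4*df - 1), df = n - 1."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    sd = np.std(d, ddof=1)
    if sd == 0:
        return 0.0 if np.mean(d) == 0 else math.nan
    j = 1.0 - 3.0 / (4.0 * (d.size - 1) - 1.0)
    return float(np.mean(d) / sd * j)


def paired_compare(x, y, alpha: float = 0.05) -> dict:
    """Paired two-sided comparison with data-driven test selection.

    The differences are screened with Shapiro–Wilk at ``alpha``; a Student
    paired t-test is used when normality is not rejected, otherwise a
    Wilcoxon signed-rank test. Effect size is paired Hedges g.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length paired samples with n >= 3")
    d = x - y
    if np.std(d, ddof=1) == 0:
        return {"test": "undefined", "statistic": math.nan, "p": math.nan,
                "hedges_g": 0.0 if np.mean(d) == 0 else math.nan}
    sw_p = stats.shapiro(d).pvalue
    if sw_p >= alpha:
        res = stats.ttest_rel(x, y)
        test = "t"
    else:
        res = stats.wilcoxon(x, y)
        test = "wilcoxon"
    return {"test": test, "statistic": float(res.statistic),
            "p": float(res.pvalue), "hedges_g": hedges_g_paired(x, y),
            "shapiro_p": float(sw_p)}


def _pbend_transform(v: np.ndarray, beta: float) -> np.ndarray:
    """Wilcox percentage-bend psi scores for one margin.

    The bend scale omega is the (1-beta) order statistic of absolute
    deviations from the median; observations beyond +-omega are flagged,
    the margin is re-centred by the percentage-bend measure of location,
    and the standardised scores are winsorised at +-1.
    """
    n = v.size
    med = np.median(v)
    w = np.sort(np.abs(v - med))
    m = int(np.floor((1.0 - beta) * n))
    omega = w[m - 1]
    if omega <= 0:
        raise ValueError("degenerate margin: bend scale is zero")
    psi = (v - med) / omega
    i1 = int(np.count_nonzero(psi < -1))
    i2 = int(np.count_nonzero(psi > 1))
    s = np.where(np.abs(psi) > 1, 0.0, v)
    pbos = (s.sum() + omega * (i2 - i1)) / (n - i1 - i2)
    return np.clip((v - pbos) / omega, -1.0, 1.0)


def percentage_bend_correlation(x, y, beta: float = 0.2) -> tuple[float, float]:
    """Robust percentage-bend correlation (Wilcox 1994).

    Each margin is standardised by its bend scale around the
    percentage-bend location and winsorised at ±1 (down-weighting the
    flagged 20% of marginal observations); Pearson correlation of the
    transformed scores follows, with p from the t approximation on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    a = _pbend_transform(x, beta)
    b = _pbend_transform(y, beta)
    r = float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))
    n = x.size
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt((n - 2) / (1 - r_clip ** 2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return r, p


def outlier_mask(values) -> np.ndarray:
    """Boolean mask of entries with |z| > 3 (population SD over the sample).

    All-equal input (zero SD) flags nothing.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or not np.isfinite(v).all():
        raise ValueError("need >= 2 finite values")
    sd = np.std(v, ddof=1)
    if sd == 0:
        return np.zeros(v.size, dtype=bool)
    return np.abs((v - np.mean(v)) / sd) > 3.0


def export_model_table(sessions: pd.DataFrame, stim_summaries: pd.DataFrame,
                       kc_summaries: pd.DataFrame) -> pd.DataFrame:
    """Tidy participant x night table ready for external mixed-model fitting.

    Inputs are joined on (participant, night); rows missing any component
    are dropped with a warning. Expected columns: sessions carries
    overnight_change_performance / overnight_change_variability; stim
    summaries median_isi / n_stim; kc summaries prop_kc / n_kc / n_no_kc.
    """
    keys = ["participant", "night"]
    table = sessions.merge(stim_summaries, on=keys).merge(kc_summaries, on=keys)
    n_lost = max(len(sessions), len(stim_summaries), len(kc_summaries)) - len(table)
    if n_lost > 0:
        warnings.warn(f"{n_lost} participant-nights dropped from model table",
                      stacklevel=2)
    return table.sort_values(keys).reset_index(drop=True)
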