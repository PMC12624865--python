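"""Synthetic finger-tapping and vigilance sessions.

Tapping sessions follow a logarithmic (exponential-approach) learning
curve in the mean intertap interval with i.i.d. per-tap errors; retrieval
trials apply a configurable overnight gain to the asymptotic speed and
error rate, emulating sleep-dependent consolidation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..behavior import TapLog, TapTrial

__all__ = ["TapGenConfig", "generate_tapping_session", "generate_pvt_session"]


@dataclass
class TapGenConfig:
    sequence: tuple = (2, 4, 1, 3, 1, 2)
    n_learning_trials: int = 12
    n_retrieval_trials: int = 3
    block_active: float = 30.0        # s of tapping per trial
    iti_floor: float = 0.22           # s, asymptotic intertap interval
    iti_start: float = 0.50           # s, trial-1 intertap interval
    learning_constant: float = 3.0    # trials (e-folding of the approach)
    error_prob: float = 0.08          # per-tap wrong-key probability
    iti_sd: float = 0.05              # s, motor noise
    overnight_gain: float = 0.05      # fractional improvement at retrieval
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != 6 or not set(self.sequence) <= {1, 2, 3, 4}:
            raise ValueError("sequence must be 6 digits from {1,2,3,4}")
        if self.iti_floor > self.iti_start:
            raise ValueError("iti_floor must not exceed iti_start")
        if not 0 <= self.error_prob < 1:
            raise ValueError("error_prob must be in [0, 1)")


def _trial_iti(cfg: TapGenConfig, trial_index: int, floor: float) -> float:
    """Mean intertap interval for 1-based learning trial ``trial_index``."""
    return floor + (cfg.iti_start - floor) * np.exp(-(trial_index - 1) / cfg.learning_constant)


def _emit_trial(cfg: TapGenConfig, kind: str, iti_mean: float, error_prob: float,
                rng: np.random.Generator) -> TapTrial:
    times, keys = [0.0], []
    seq_pos = 0
    while times[-1] <= cfg.block_active:
        key = cfg.sequence[seq_pos % 6]
        if error_prob > 0 and rng.random() < error_prob:
            key = int(rng.choice([k for k in (1, 2, 3, 4) if k != key]))
        keys.append(key)
        seq_pos += 1
        gap = iti_mean if cfg.iti_sd == 0 else rng.normal(iti_mean, cfg.iti_sd)
        while gap <= 0:
            gap = rng.normal(iti_mean, cfg.iti_sd)
        times.append(times[-1] + gap)
    return TapTrial(kind, np.array(times[:-1]), np.array(keys), tuple(cfg.sequence))


def generate_tapping_session(config: TapGenConfig,
                             seed: int | None = None) -> TapLog:
    """Learning trials plus overnight-gain-adjusted retrieval trials.

    With ``error_prob = 0`` and ``iti_sd = 0`` the tap stream is exactly
    periodic: taps at 0, iti, 2*iti, ... while <= 30 s, i.e.
    floor(30/iti) + 1 taps.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    log = TapLog()
    for i in range(1, config.n_learning_trials + 1):
        iti = _trial_iti(config, i, config.iti_floor)
        log.trials.append(_emit_trial(config, f"L{i}", iti, config.error_prob, rng))
    floor_r = config.iti_floor * (1.0 - config.overnight_gain)
    err_r = config.error_prob * (1.0 - config.overnight_gain)
    iti_r = _trial_iti(config, config.n_learning_trials, floor_r)
    for j in range(1, config.n_retrieval_trials + 1):
        log.trials.append(_emit_trial(config, f"R{j}", iti_r, err_r, rng))
    return log


def generate_pvt_session(n_trials: int, rt_params: dict | None = None,
                         lapse_prob: float = 0.02,
                         seed: int | None = None) -> np.ndarray:
    """Psychomotor-vigilance reaction times in ms.

    Nonlapse RTs are a shifted lognormal (``shift_ms`` + LogNormal(mu,
    sigma)); with probability ``lapse_prob`` the RT is drawn from a slow
    tail at >= 500 ms.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0 <= lapse_prob <= 1:
        raise ValueError("lapse_prob must be in [0, 1]")
    p = {"shift_ms": 150.0, "mu": np.log(120.0), "sigma": 0.25, "lapse_scale_ms": 150.0}
    p.update(rt_params or {})
    if p["shift_ms"] < 0 or p["sigma"] < 0 or p["lapse_scale_ms"] < 0:
        raise ValueError("RT parameters must be non-negative")
    rng = np.random.default_rng(seed)
    rts = p["shift_ms"] + rng.lognormal(p["mu"], p["sigma"], n_trials)
    lapse = rng.random(n_trials) < lapse_prob
    rts[lapse] = 500.0 + rng.exponential(p["lapse_scale_ms"], int(lapse.sum()))
    return rts
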