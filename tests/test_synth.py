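"""Synthetic-data generator: hypnograms, EEG, evoked responses, behaviour."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from somnostim.core import Hypnogram, Recording, StimulusLog
from somnostim.synth import (
    DEFAULT_TRANSITIONS, EEGGenConfig, EvokedModel, KCTemplate, TapGenConfig,
    evoked_probability, generate_eeg, generate_hypnogram, generate_pvt_session,
    generate_tapping_session, insert_kcomplex, simulate_evoked_responses,
    stationary_distribution,
)
from somnostim.behavior import score_trial

FS = 250.0


class TestHypnogram:
    def test_forced_n3_transitions_yield_all_n3(self):
        P = np.zeros((5, 5))
        P[:, 3] = 1.0
        h = generate_hypnogram(300, {"transitions": P, "initial": "N3"}, seed=0)
        assert h.stages == ["N3"] * 10

    def test_deterministic_under_fixed_seed(self):
        a = generate_hypnogram(8 * 3600, seed=1)
        b = generate_hypnogram(8 * 3600, seed=1)
        assert a.stages == b.stages

    def test_stage_fractions_match_stationary_distribution(self):
        """Monte-Carlo mean N3 fraction vs the chain's stationary value."""
        pi = stationary_distribution(DEFAULT_TRANSITIONS)
        fracs = [np.mean(np.asarray(generate_hypnogram(8 * 3600, seed=s).stages) == "N3")
                 for s in range(200)]
        assert abs(np.mean(fracs) - pi[3]) < 0.05

    def test_rejects_sub_epoch_duration(self):
        with pytest.raises(ValueError):
            generate_hypnogram(10)


class TestGenerateEEG:
    def test_no_slow_oscillations_outside_nrem(self):
        h = Hypnogram(["Wake"] * 20)
        cfg = EEGGenConfig(night_duration=h.duration, so_rate=10)
        _, gt = generate_eeg(h, cfg, seed=0)
        assert gt.so_times == []

    def test_slow_oscillation_count_matches_thinned_poisson(self):
        """Count vs the refractory-thinned Poisson oracle.

        With exponential gaps of mean theta floored at refractory r, the
        expected gap is r + theta*exp(-r/theta); counts over many seeds
        should match duration / that expectation.
        """
        h = Hypnogram(["N3"] * 10)  # 5 min
        cfg = EEGGenConfig(night_duration=300, so_rate=10)
        theta = 60 / cfg.so_rate
        r = 1.0 + 1.0 / cfg.so_freq_range[0]
        expected = 300 / (r + theta * np.exp(-r / theta))
        counts = [len(generate_eeg(h, cfg, seed=s)[1].so_times) for s in range(20)]
        assert abs(np.mean(counts) - expected) < 4 * np.sqrt(expected / 20)
        assert all(abs(c - expected) < 4 * np.sqrt(expected) for c in counts)

    def test_background_spectral_slope(self):
        """Log-log Welch slope of background-only signal recovers -alpha."""
        h = Hypnogram(["N3"] * 20)
        for alpha in (0.8, 1.5):
            cfg = EEGGenConfig(night_duration=h.duration, so_rate=0,
                               spindle_rate=0, stage_slope_map=None,
                               spectral_slope=alpha)
            rec, _ = generate_eeg(h, cfg, seed=2)
            f, p = sps.welch(rec.data, FS, nperseg=4096)
            sel = (f >= 1) & (f <= 30)
            slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
            assert abs(slope + alpha) < 0.3

    def test_stage_rms_matches_amplitude_map(self):
        h = Hypnogram(["Wake"] * 10 + ["N3"] * 10 + ["N2"] * 10)
        cfg = EEGGenConfig(night_duration=h.duration, so_rate=0, spindle_rate=0)
        rec, _ = generate_eeg(h, cfg, seed=0)
        stage = h.sample_stages(rec.n_samples, FS)
        for s in ("Wake", "N2", "N3"):
            rms = rec.data[stage == s].std()
            assert abs(rms / cfg.stage_amplitude_map[s] - 1) < 0.10

    def test_deterministic_and_ground_truth_sorted(self):
        h = Hypnogram(["N2"] * 10)
        cfg = EEGGenConfig(night_duration=h.duration)
        r1, g1 = generate_eeg(h, cfg, seed=5)
        r2, g2 = generate_eeg(h, cfg, seed=5)
        assert np.array_equal(r1.data, r2.data)
        assert g1.so_times == sorted(g1.so_times)
        assert all(0 <= t <= h.duration for t in g1.so_times + g1.spindle_times)

    def test_rejects_empty_hypnogram(self):
        with pytest.raises(ValueError):
            generate_eeg(Hypnogram([]), EEGGenConfig(night_duration=30), seed=0)


class TestKCTemplate:
    def test_zero_scale_is_identity(self):
        sig = np.random.default_rng(0).standard_normal(2500)
        out = insert_kcomplex(sig, 2.0, KCTemplate(), amplitude_scale=0.0, fs=FS)
        assert np.array_equal(out, sig)

    def test_extremum_at_n550(self):
        tmpl = KCTemplate()
        sig = np.zeros(2500)
        out = insert_kcomplex(sig, 2.0, tmpl, 1.0, fs=FS)
        i = int(np.argmin(out))
        assert abs(i / FS - (2.0 + tmpl.n550_latency)) <= 1.5 / FS
        assert abs(out[i] - tmpl.n550_amplitude) < 0.01 * abs(tmpl.n550_amplitude)

    def test_additivity_of_disjoint_insertions(self):
        sig = np.zeros(5000)
        a = insert_kcomplex(sig, 2.0, KCTemplate(), 1.0, fs=FS)
        b = insert_kcomplex(sig, 10.0, KCTemplate(), 1.0, fs=FS)
        both = insert_kcomplex(a, 10.0, KCTemplate(), 1.0, fs=FS)
        assert np.allclose(both, a + b)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            insert_kcomplex(np.zeros(100), 2.0, KCTemplate(), 1.0, fs=FS)

    def test_latency_ordering_enforced(self):
        with pytest.raises(ValueError):
            KCTemplate(p200_latency=0.6, n550_latency=0.55)


def _stim_log(times: np.ndarray) -> StimulusLog:
    return StimulusLog(pd.DataFrame({
        "time_s": times, "kind": "real", "window": "on",
        "preceding_isi_s": np.concatenate([[np.nan], np.diff(times)]),
        "phase_deg": 45.0}))


class TestEvokedResponses:
    def test_zero_probability_inserts_nothing(self):
        rec = Recording(np.zeros(int(100 * FS)), FS)
        log = _stim_log(np.arange(5.0, 90.0, 3.0))
        model = EvokedModel(p_max=0.0, floor_p=0.0)
        out, gt = simulate_evoked_responses(rec, log, model, KCTemplate(), seed=0)
        assert gt.kc_events == [] and np.array_equal(out.data, rec.data)

    def test_probability_monotone_in_isi(self):
        model = EvokedModel()
        isis = np.linspace(0.0, 15.0, 200)
        p = evoked_probability(model, isis)
        assert np.all(np.diff(p) >= -1e-12)
        assert p.min() >= model.floor_p - 1e-12 and p.max() <= model.p_max + 1e-12

    def test_plateau_fraction_binomial(self):
        """At ISIs deep into saturation the evoked fraction converges to p_max."""
        n = 10_000
        isi = 5.0  # >> isi_onset + 5 tau
        times = 5.0 + isi * np.arange(n)
        rec = Recording(np.zeros(int(times[-1] * FS + 1000)), FS)
        model = EvokedModel(p_max=0.35, floor_p=0.05)
        _, gt = simulate_evoked_responses(rec, _stim_log(times), model,
                                          KCTemplate(), seed=3)
        frac = len(gt.kc_events) / n
        assert abs(frac - 0.35) < 0.01

    def test_evoked_events_inside_association_window(self):
        times = np.arange(5.0, 200.0, 2.0)
        rec = Recording(np.zeros(int(220 * FS)), FS)
        _, gt = simulate_evoked_responses(rec, _stim_log(times), EvokedModel(),
                                          KCTemplate(), seed=4)
        for start, evoked, idx in gt.kc_events:
            assert evoked and 0.2 <= start - times[idx] <= 1.0 < 1.5

    def test_sham_stimuli_never_evoke(self):
        times = np.arange(5.0, 100.0, 2.0)
        df = _stim_log(times).entries
        df["kind"] = "sham"
        df["window"] = "off"
        rec = Recording(np.zeros(int(120 * FS)), FS)
        _, gt = simulate_evoked_responses(rec, StimulusLog(df),
                                          EvokedModel(p_max=1, floor_p=1),
                                          KCTemplate(), seed=0)
        assert gt.kc_events == []


class TestTappingGenerator:
    def test_deterministic_limit_counts_and_accuracy(self):
        cfg = TapGenConfig(error_prob=0.0, iti_sd=0.0)
        log = generate_tapping_session(cfg, seed=0)
        for i, trial in enumerate(log.learning(), start=1):
            iti = cfg.iti_floor + (cfg.iti_start - cfg.iti_floor) * np.exp(
                -(i - 1) / cfg.learning_constant)
            assert trial.keys.size == int(np.floor(30 / iti)) + 1
            score = score_trial(trial)
            assert score.pct_correct_sequences == 100.0

    def test_mean_iti_decreases_over_learning(self):
        """Expected intertap interval strictly decreases over early trials."""
        means = np.zeros(5)
        for seed in range(100):
            log = generate_tapping_session(TapGenConfig(), seed=seed)
            for i, tr in enumerate(log.learning()[:5]):
                means[i] += np.mean(np.diff(tr.times))
        assert np.all(np.diff(means) < 0)

    def test_overnight_gain_speeds_retrieval(self):
        diffs = []
        for seed in range(100):
            log = generate_tapping_session(TapGenConfig(overnight_gain=0.08), seed=seed)
            plateau = np.mean([np.mean(np.diff(t.times)) for t in log.learning()[-3:]])
            retr = np.mean([np.mean(np.diff(t.times)) for t in log.retrieval()])
            diffs.append(retr - plateau)
        assert np.mean(diffs) < 0

    def test_invalid_sequence_rejected(self):
        with pytest.raises(ValueError):
            TapGenConfig(sequence=(2, 4, 1, 3, 1, 5))


class TestPVTGenerator:
    def test_forced_lapses(self):
        rts = generate_pvt_session(50, lapse_prob=1.0, seed=0)
        assert np.all(rts >= 500.0)

    def test_tight_params_no_lapses(self):
        rts = generate_pvt_session(50, {"mu": np.log(100.0), "sigma": 0.1},
                                   lapse_prob=0.0, seed=0)
        assert np.all(rts < 500.0)

    def test_lapse_fraction_binomial(self):
        rts = generate_pvt_session(10_000, lapse_prob=0.1, seed=1)
        assert abs(np.mean(rts >= 500.0) - 0.1) < 0.02

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_pvt_session(0)
        with pytest.raises(ValueError):
            generate_pvt_session(10, {"sigma": -1.0})
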