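"""Morlet maps, baseline normalisation, AEP and cluster-permutation test."""
from __future__ import annotations

import numpy as np
import pytest

from conftest import FS
from somnostim.core import EpochSet, Recording, StimulusLog
from somnostim.spectral import (
    baseline_normalize, cluster_permutation_test, compute_aep, delta_low_swa,
    find_clusters, match_epoch_counts, morlet_tf,
)
import pandas as pd


def _epochs(signals, window=(1.0, 3.0)):
    signals = np.atleast_2d(signals)
    return EpochSet(signals, window, 10.0 + 20 * np.arange(signals.shape[0]), FS)


class TestMorlet:
    def test_tone_peaks_at_its_frequency(self):
        t = np.arange(int(4 * FS)) / FS
        maps = morlet_tf(_epochs(np.sin(2 * np.pi * 10 * t)))
        m = maps[0]
        center = m.power[:, m.power.shape[1] // 2]
        assert abs(m.freqs[np.argmax(center)] - 10.0) <= 1.0

    def test_zero_epoch_zero_power(self):
        maps = morlet_tf(_epochs(np.zeros(int(4 * FS))))
        assert np.allclose(maps[0].power, 0.0)

    def test_amplitude_doubling_quadruples_power(self):
        t = np.arange(int(4 * FS)) / FS
        sig = np.sin(2 * np.pi * 8 * t)
        p1 = morlet_tf(_epochs(sig))[0].power
        p2 = morlet_tf(_epochs(2 * sig))[0].power
        assert np.allclose(p2, 4 * p1, rtol=1e-6)

    def test_separated_tones_additive_power(self):
        """Power of a two-tone sum matches the per-tone powers at their cells."""
        t = np.arange(int(4 * FS)) / FS
        a, b = np.sin(2 * np.pi * 6 * t), 0.7 * np.sin(2 * np.pi * 20 * t)
        pa = morlet_tf(_epochs(a))[0]
        pb = morlet_tf(_epochs(b))[0]
        pab = morlet_tf(_epochs(a + b))[0]
        mid = pa.power.shape[1] // 2
        for m_ref, f in ((pa, 6), (pb, 20)):
            i = int(f - 1)
            assert abs(pab.power[i, mid] - (pa.power[i, mid] + pb.power[i, mid])) \
                <= 0.05 * m_ref.power[i, mid]

    def test_edge_validity_mask(self):
        maps = morlet_tf(_epochs(np.random.default_rng(0).standard_normal(int(4 * FS))))
        v = maps[0].valid
        assert not v[0, 0] and not v[0, -1]          # 1 Hz edges invalid
        assert v[:, v.shape[1] // 2].all()           # centre valid everywhere


class TestBaseline:
    def test_constant_maps_zero_db(self):
        maps = morlet_tf(_epochs(np.random.default_rng(1).standard_normal(int(4 * FS))))
        same = baseline_normalize([maps[0]] * 4)
        # identical maps: each map IS the baseline -> 0 dB at every cell
        pooled = np.mean([m.power for m in same], axis=0)
        assert np.allclose(pooled, same[0].power)
        base = np.mean(maps[0].power, axis=1)
        expect = 10 * np.log10(maps[0].power / base[:, None])
        assert np.allclose(same[0].power, expect)

    def test_global_scaling_invariance(self):
        t = np.arange(int(4 * FS)) / FS
        maps = morlet_tf(_epochs(np.sin(2 * np.pi * 9 * t) + 0.1))
        a = baseline_normalize(maps)[0].power
        scaled = [type(m)(m.power * 7.3, m.freqs, m.times, m.normalization, m.valid)
                  for m in maps]
        b = baseline_normalize(scaled)[0].power
        assert np.allclose(a, b, atol=1e-9)

    def test_ten_times_baseline_is_ten_db(self):
        m = morlet_tf(_epochs(np.random.default_rng(2).standard_normal(int(4 * FS))))[0]
        p = np.ones_like(m.power)
        p[5, 100] = 10.0
        n_cells = p[5].size
        m.power = p
        out = baseline_normalize([m])[0].power
        base = (n_cells - 1 + 10.0) / n_cells
        assert out[5, 100] == pytest.approx(10 * np.log10(10.0 / base))


class TestMatchAndAEP:
    def test_majority_subsampled(self):
        a = _epochs(np.random.default_rng(0).standard_normal((10, 100)), (0.2, 0.2))
        b = _epochs(np.random.default_rng(1).standard_normal((4, 100)), (0.2, 0.2))
        a2, b2 = match_epoch_counts(a, b, seed=0)
        assert len(a2) == len(b2) == 4

    def test_equal_sizes_identity_and_determinism(self):
        a = _epochs(np.random.default_rng(0).standard_normal((6, 100)), (0.2, 0.2))
        b = _epochs(np.random.default_rng(1).standard_normal((3, 100)), (0.2, 0.2))
        a1, _ = match_epoch_counts(a, b, seed=7)
        a2, _ = match_epoch_counts(a, b, seed=7)
        assert np.array_equal(a1.epochs, a2.epochs)
        c, d = match_epoch_counts(b, b, seed=0)
        assert np.array_equal(c.epochs, b.epochs)

    def test_identical_sets_zero_difference(self):
        a = _epochs(np.random.default_rng(0).standard_normal((5, 200)), (0.4, 0.4))
        res = compute_aep(a, a)
        assert np.allclose(res["difference"], 0.0)

    def test_injected_template_recovered(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((40, 300))
        tmpl = np.exp(-0.5 * ((np.arange(300) - 150) / 20.0) ** 2) * 5
        on = _epochs(base + tmpl, (0.6, 0.6))
        off = _epochs(rng.standard_normal((40, 300)), (0.6, 0.6))
        res = compute_aep(on, off)
        err = np.abs(res["difference"] - tmpl).max()
        assert err < 1.5  # noise-limited recovery of the injected shape


def _brute_force_clusters(mask, t_map):
    """Breadth-first connected components (4-neighbourhood), per sign."""
    mask = np.atleast_2d(mask)
    t2 = np.atleast_2d(t_map)
    seen = np.zeros_like(mask, dtype=bool)
    out = []
    H, W = mask.shape
    for i in range(H):
        for j in range(W):
            if not mask[i, j] or seen[i, j]:
                continue
            sign = np.sign(t2[i, j])
            stack, cells = [(i, j)], []
            seen[i, j] = True
            while stack:
                a, b = stack.pop()
                cells.append((a, b))
                for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    x, y = a + da, b + db
                    if (0 <= x < H and 0 <= y < W and mask[x, y]
                            and not seen[x, y] and np.sign(t2[x, y]) == sign):
                        seen[x, y] = True
                        stack.append((x, y))
            out.append((frozenset(cells), sum(t2[c] for c in cells)))
    return out


class TestClusterPermutation:
    def test_identical_data_no_significant_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((6, 10, 12))
        res = cluster_permutation_test(a, a.copy(), n_perm=200, seed=1)
        assert res.significant == []

    def test_injected_block_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((8, 20, 40))
        b = a + rng.standard_normal((8, 20, 40)) * 0.5
        b[:, 5:9, 10:20] += 2.0
        res = cluster_permutation_test(b, a, n_perm=500, seed=2)
        assert len(res.significant) >= 1
        cells = {tuple(c) for cl in res.significant for c in cl["cells"]}
        block = {(i, j) for i in range(5, 9) for j in range(10, 20)}
        assert len(cells & block) / len(block) > 0.5

    def test_one_dimensional_waveforms(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((8, 100))
        b = a + 0.3 * rng.standard_normal((8, 100))
        b[:, 40:55] += 2.0
        res = cluster_permutation_test(b, a, n_perm=500, seed=3)
        sig_cells = {int(c[0]) for cl in res.significant for c in cl["cells"]}
        assert sig_cells & set(range(40, 55))

    def test_cluster_finding_matches_brute_force(self):
        """find_clusters equals a BFS oracle on enumerated binary maps."""
        rng = np.random.default_rng(4)
        # all 512 3x3 maps, plus random 5x5 maps with signed t values
        cases = []
        for code in range(512):
            mask = np.array([(code >> k) & 1 for k in range(9)],
                            dtype=bool).reshape(3, 3)
            cases.append(mask)
        for _ in range(2000):
            cases.append(rng.random((5, 5)) < 0.45)
        for mask in cases:
            t_map = np.where(mask, rng.choice([-1.0, 1.0], mask.shape) *
                             (1 + rng.random(mask.shape)), 0.05)
            mine = {(frozenset(map(tuple, c["cells"])), round(c["mass"], 9))
                    for c in find_clusters(mask, t_map)}
            brute = {(cells, round(mass, 9))
                     for cells, mass in _brute_force_clusters(mask, t_map)}
            assert mine == brute

    def test_zero_variance_cells_are_ignored(self):
        a = np.ones((5, 4, 4))
        b = np.ones((5, 4, 4))
        res = cluster_permutation_test(a, b, n_perm=150, seed=0)
        assert np.allclose(res.t_map, 0.0) and res.clusters == []

    def test_permutation_count_and_exchangeability(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((8, 6, 6))
        b = rng.standard_normal((8, 6, 6))
        r1 = cluster_permutation_test(a, b, n_perm=300, seed=9)
        perm = rng.permutation(8)
        r2 = cluster_permutation_test(a[perm], b[perm], n_perm=300, seed=9)
        assert r1.n_permutations == 300
        assert abs(r1.threshold_mass - r2.threshold_mass) < 0.35 * max(r1.threshold_mass, 1)


class TestDeltaLowSWA:
    def _log_with_windows(self, t0=100.0, span=280.0):
        times = np.arange(t0 + 1.0, t0 + span, 12.0)
        entries = pd.DataFrame({
            "time_s": times, "kind": "real", "window": "on",
            "preceding_isi_s": np.concatenate([[np.nan], np.diff(times)]),
            "phase_deg": 45.0})
        return StimulusLog(entries, window_clock_start=t0)

    def test_identical_statistics_near_zero(self):
        rng = np.random.default_rng(0)
        rec = Recording(rng.standard_normal(int(400 * FS)) * 20, FS)
        log = self._log_with_windows()
        d = delta_low_swa(rec, log)
        f_all = np.abs(d)
        base = delta_low_swa(rec, log, band=(0.5, 1.0))
        assert f_all < 40  # small relative to any injected contrast below

    def test_on_window_injection_positive_and_antisymmetric(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(400 * FS)) * 10
        t = np.arange(x.size) / FS
        t0 = 100.0
        on = ((t - t0) % 12 < 6) & (t >= t0)
        x[on] += 40 * np.sin(2 * np.pi * 0.8 * t[on])
        rec = Recording(x, FS)
        d_on = delta_low_swa(rec, self._log_with_windows())
        assert d_on > 0
        # swapping ON/OFF labels flips the sign: shift the clock by one window
        times = np.arange(t0 + 7.0, t0 + 280.0, 12.0)
        entries = pd.DataFrame({
            "time_s": times, "kind": "real", "window": "on",
            "preceding_isi_s": np.concatenate([[np.nan], np.diff(times)]),
            "phase_deg": 45.0})
        swapped = StimulusLog(entries, window_clock_start=t0 + 6.0)
        d_off = delta_low_swa(rec, swapped)
        assert d_off < 0
        assert abs(d_on + d_off) < 0.35 * abs(d_on)
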