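# somnostim

Analysis pipeline for **phase-targeted auditory stimulation (PTAS)**
sleep-EEG experiments: closed-loop stimulation emulation, K-complex
detection, inter-stimulus-interval (ISI) response curves, stimulus-locked
time-frequency statistics, slow-oscillation–spindle coupling, and
finger-tapping consolidation scoring — all exercisable on a bundled,
ground-truthed synthetic-data generator.

## The problem

During deep sleep, brief noise bursts delivered on the depolarising
up-phase of cortical slow oscillations (up-PTAS) can enhance slow-wave
activity and overnight memory consolidation. A mobile closed-loop device
tracks the frontal EEG in real time, detects NREM sleep, locks onto the
slow-oscillation phase and plays 50 ms pink-noise bursts at the 45°
target phase in alternating 6 s ON/OFF windows, with a protocol-defined
minimum ISI (≥0.5 s vs ≥1 s). The scientific questions downstream —
*which ISIs evoke K-complexes most reliably? do longer ISIs favour
spindle responses and better overnight finger-tapping consolidation?* —
require a reproducible offline chain from raw single-channel EEG to
statistics. `somnostim` provides that chain as a tested Python library.

Core quantitative machinery:

- **Closed-loop emulator** (`somnostim.stim`): causal NREM detection from
  trailing 80 s band powers (2–4, 3–5, 20–30 Hz), a second-order PLL with
  a derivative-quadrature phase detector for slow-wave phase, ISI- and
  arousal-gated triggering at the 45° phase, offline sham reconstruction
  in OFF windows.
- **K-complex detector** (`somnostim.kcomplex`): total-variation
  transient removal, 4 Hz decomposition, Teager–Kaiser energy
  Ψ[x](n) = x(n)² − x(n−1)x(n+1), duration-filtered events, 1.5 s
  stimulus association.
- **ISI analysis** (`somnostim.isi`): per-bin response probability over
  the ten study bins (0.5–0.75 … >10.5 s), saturating near 35% beyond
  1.25 s on the bundled generative model.
- **Spectral statistics** (`somnostim.spectral`): Morlet maps (1–30 Hz,
  3→17.5 cycles), whole-epoch log baseline, AEPs, nonparametric
  cluster-mass permutation tests with family-wise control.
- **Coupling** (`somnostim.coupling`): entropy-based modulation index
  MI = (log N − H(P))/log N over 18 phase bins, z-scored against
  cut-and-reverse surrogates (zMI).
- **Behaviour** (`somnostim.behavior`): finger-tapping performance
  (%correct / mean intertap interval), tapping variability, overnight
  change, PVT response speed, paired test selection with Hedges g,
  percentage-bend correlation, |z|>3 outlier rule.

See `docs/methods.md` for models, assumptions, parameter defaults and
limitations.

## Worked example

Simulate a night, run the closed-loop emulator, detect K-complexes and
estimate the ISI response curve:

```python
import numpy as np, pandas as pd
from somnostim.core import StimulusLog, Hypnogram
from somnostim.synth import (EEGGenConfig, EvokedModel, KCTemplate,
                             generate_eeg, simulate_evoked_responses)
from somnostim.kcomplex import decompose, detect_kcomplexes, associate_stimuli
from somnostim.isi import kc_probability_by_bin

rng = np.random.default_rng(0)
times = 5 + np.cumsum(rng.uniform(0.5, 4.0, 1000))      # stimulus times, s
hyp = Hypnogram(["N3"] * int(np.ceil((times[-1] + 10) / 30)))
cfg = EEGGenConfig(night_duration=hyp.duration)
cfg.stage_amplitude_map["N3"] = 20.0                     # low-noise validation night
rec, _ = generate_eeg(hyp, cfg, seed=1)
log = StimulusLog(pd.DataFrame({
    "time_s": times, "kind": "real", "window": "on",
    "preceding_isi_s": np.concatenate([[np.nan], np.diff(times)]),
    "phase_deg": 45.0}))
rec, truth = simulate_evoked_responses(rec, log, EvokedModel(p_max=0.35),
                                       KCTemplate(), seed=2)
_, low, _ = decompose(rec.data, rec.fs)
events = detect_kcomplexes(low, rec.fs)
out = associate_stimuli(events, log)
out["isi"] = out["preceding_isi_s"]
tab = kc_probability_by_bin(out.dropna(subset=["isi"]))
print(tab[["bin_label", "n_stimuli", "proportion"]].to_string(index=False))
```

Output:

```
bin_label  n_stimuli  proportion
0.5-0.75s         56    0.267857
  0.75-1s         68    0.235294
  1-1.25s         74    0.310811
1.25-1.5s         60    0.300000
   1.5-2s        146    0.321918
   2-2.5s        141    0.333333
 2.5-6.5s        454    0.365639
```

The proportion of stimuli followed by a detected K-complex rises across
the short-ISI bins (where the configured evoked probability is lowest)
and settles near the configured plateau of 0.35 beyond ~1.25 s — the
saturating dose-response relationship the ISI analysis is built to
expose. Counts per bin are modest here, so the short-ISI estimates carry
binomial noise of a few points; the acceptance script runs the same
recovery at larger n.

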