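# Methods

`somnostim` re-implements, as a tested library, the computational chain of
a home-based phase-targeted auditory stimulation (PTAS) sleep experiment:
a closed-loop device that tracks sleep slow oscillations in a frontal EEG
channel and plays 50 ms pink-noise bursts at the 45° phase (the
down-to-up transition), alternating 6 s ON and 6 s OFF windows, under a
minimum inter-stimulus interval (ISI) of ≥0.5 s (short-ISI protocol) or
≥1 s (long-ISI protocol); and an offline analysis chain that detects
evoked K-complexes, relates their probability to the preceding ISI,
contrasts stimulus-locked spectral responses, quantifies
slow-oscillation–spindle coupling, and scores overnight consolidation of
a finger-tapping sequence. Raw recordings from such studies are not
generally redistributable, so every stage is validated against a bundled
synthetic-data generator with known ground truth.

## Synthetic data generator

**Hypnogram.** A first-order Markov chain over 30 s epochs
(Wake/N1/N2/N3/REM) with a default transition matrix whose stationary
distribution (~16% Wake, 13% N1, 35% N2, 21% N3, 16% REM) is in the range
of healthy adult nights. The stationary distribution of the configured
matrix is the oracle for the generator's Monte-Carlo test.

**EEG background.** Spectrally shaped Gaussian noise with PSD ∝ 1/f^α
above a 0.4 Hz corner (flat below it; scalp EEG carries no unbounded
infra-slow drift, and without the corner a steep exponent would put
nearly all variance below 0.5 Hz and invert the band-power ordering
between stages). The exponent is per-stage (Wake 0.5 … N3 1.6, config
`stage_slope_map`) because NREM discrimination by delta/beta band powers —
which the stimulation device's online classifier relies on — presupposes
a stage-dependent spectral shape; a single-exponent mode
(`stage_slope_map=None`) remains available for spectral-slope tests.
Per-stage RMS amplitudes (µV): Wake 30, N1 20, N2 35, N3 45, REM 22.

**Events.** Slow oscillations are single full cycles (raised-cosine down
half-wave of 60 µV, up half-wave at 0.6× that) with per-event frequency
drawn from 0.5–1.25 Hz, Poisson timing at 6/min in N2/N3 and a hard
refractory gap; spindles are Gaussian-enveloped 11–16 Hz bursts (20 µV,
0.8 s, 2/min). K-complexes are a stereotyped P200 (+25 µV) / N550
(−120 µV) / P900 (+45 µV) waveform of 1.5 s built from Gaussian bumps,
with the N550 extremum pinned exactly. These amplitudes are free
parameters chosen as typical frontal values, not estimates of any
particular dataset.

**Evoked responses.** Each real stimulus evokes a K-complex with
probability p(ISI) = floor + (p_max − floor)(1 − e^−(ISI−0.5)/τ), with
p_max = 0.35, floor = 0.05, τ = 0.25 s, so the curve rises across the
0.5–1.25 s bins and plateaus near 0.35 beyond 1.25 s. Evoked onsets fall
uniformly in [0.2, 1.0] s post-stimulus — strictly inside the 1.5 s
association window, so detector recall and association logic remain
separable. With probability 0.5 a fast-sigma burst (14.5 Hz) is nested at
K-complex onset + 0.55 s (the up-phase), which is what the coupling
analysis is expected to pick up. Sham stimuli never evoke insertions.

**Behaviour.** Tapping sessions repeat a 6-digit sequence (keys 1–4) in
30 s blocks; the mean intertap interval follows an exponential approach
from 0.50 s to 0.22 s with trial constant 3, motor noise SD 0.05 s and
i.i.d. 8% wrong-key taps; retrieval trials shrink the asymptote and error
rate by the configured overnight gain (default 5%). Vigilance (PVT)
reaction times are a shifted lognormal with an exponential lapse tail
≥500 ms.

What the generator does **not** emulate: EOG/EMG channels, arousal or
artifact morphology beyond amplitude bursts, REM microstructure,
sequence-position-dependent tapping errors, and any refractory
interaction between consecutive evoked K-complexes beyond linear
superposition. Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration under these idealised statistics, not
performance on real recordings.

## Stimulation engine

The engine is a behavioural emulator (the device's exact loop equations
and thresholds are proprietary/unpublished); all constants are config.

**Online NREM flag** = trailing-80 s band power in 2–4 Hz above
threshold AND 3–5 Hz above threshold AND 20–30 Hz below threshold,
causal, first 80 s false. Thresholds (78 / 56 / 32 µV²) were calibrated
once on three default generator nights as the geometric mean of the
NREM and non-NREM median powers (`calibrate_nrem_thresholds` re-derives
them for any labelled night); on held-out synthetic nights the flag
reaches ≥0.95 sensitivity and ~1.0 specificity outside 90 s
stage-transition margins. Stimulation begins after 600 s of uninterrupted
flags (a tolerance for brief dropouts is configurable, default strict).

**Phase tracking** is a second-order PLL driven by a causal Butterworth
band-pass. The phase detector is a derivative quadrature: for a
band-limited input A·sin θ, atan2(ŵ·y, dy/dt) returns the instantaneous
phase without the double-frequency ripple of a mixing detector, letting
the loop run at a 0.5 Hz natural frequency (damping 1.0, error smoothing
0.14 s) and re-lock within a few seconds after a frequency step. The
loop's prefilter is the slow-oscillation band 0.5–1.5 Hz rather than the
full 0.5–4 Hz delta band: on realistic asymmetric slow-wave cycles the
wide band's instantaneous phase is harmonic-rich and disagrees by tens of
degrees with the fundamental phase that the 45° target refers to; the
narrow band makes the tracked component the fundamental itself. The
reported phase is corrected for the causal prefilter's phase response at
the loop's instantaneous frequency (0° = positive-going zero crossing, so
45° sits on the down-to-up transition). Crossings only trigger when the
quadrature amplitude shows a real wave (lock flag) of at least 20 µV
envelope — emulating the device's slow-wave detection — and when the
trailing-1 s beta power does not exceed 3× the trailing-80 s beta power
(arousal veto; the study describes the signal, not the statistic).

**Windows and ISI.** The free-running 6 s ON/6 s OFF clock starts at the
first eligible trigger and is not reset by arousals. Real stimuli obey
min_isi against the previous real stimulus, including across OFF windows
(the study's ISI bins extend past the 6 s window, implying cross-window
ISIs); sham flags are reconstructed offline by the identical criteria
inside OFF windows, with the ISI constraint counted from the last sham in
the same OFF window. Stimulation stops 2.5 h after the first stimulus.

## Preprocessing

The analysis filter chain reproduces the published design: zero-phase
Kaiser-window FIR low-pass (order 46 at 250 Hz, half-amplitude −6 dB at
39.86 Hz) then high-pass (order 2988, −6 dB at 0.37 Hz); both are odd-
length type-I kernels applied by centred convolution, so the group delay
is exactly zero and the −6 dB points land within 0.001 Hz of the design
values. Orders scale proportionally at other sampling rates. The scoring
chain is a forward-backward 3rd-order Butterworth band-pass 0.5–35 Hz
followed by polyphase resampling to 128 Hz (64/125, anti-aliased).

The artifact mask is a fully automatic stand-in for interactive
semi-automatic routines: an NREM epoch is flagged when its 0.75–4.5 Hz or
20–30 Hz power exceeds 4× the moving median (15-epoch window) of
neighbouring NREM epochs. Sleep-architecture metrics (TTB, TST, SL,
WASO, REML, SEF) follow the standard definitions; stage percentages are
reported relative to time in bed (TTB), the only base on which
Wake% + stage% sums to 100 — noted here because some labs use TST.

## K-complex detection

A three-stage decomposition-plus-energy detector. (1) Transient removal:
total-variation denoising (Chambolle, weight 8 µV) isolates jump-like
content; components of the TV estimate above 4 Hz and 25 µV form the
sparse transient, which is subtracted. (2) The transient-free signal is
split at 4 Hz by a zero-phase Butterworth low-pass into low-frequency and
oscillatory parts; the three components sum to the input exactly.
(3) The Teager-Kaiser energy Ψ[x](n) = x(n)² − x(n−1)x(n+1) of the
low-frequency part is smoothed (0.3 s moving average) and thresholded at
6 µV² — calibrated with `calibrate_tkeo_threshold` against labelled
synthetic nights to separate K-complexes (smoothed peak ≈ 10–12 µV²) from
spontaneous slow oscillations (≈ 3–5 µV²). Supra-threshold runs closer
than 0.1 s merge; run edges extend outward to 5% of the run peak (floored
at 0.5 µV², walking at most 0.3 s) and the reported start subtracts a
0.1 s onset lead, compensating the energy-free lead-in of the waveform;
runs longer than 2 s (overlapping events) are split at their deepest
interior energy minimum; surviving runs of 0.5–2 s become events, with
the N550 at the run's signal minimum.

Stimulus association follows the start-within-1.5 s rule: a stimulus
scores 1 when at least one detected event starts in (t, t+1.5]; each
event counts for at most one stimulus — its nearest preceding one.
Detector quality is assessed only against synthetic ground truth. Two
documented failure modes: at the generator's default N3 background
(45 µV RMS) sensitivity drops to ~0.85, and a spontaneous slow
oscillation starting within ~0.5 s of a K-complex can merge with it and
shift the detected onset; validation fixtures therefore use a 20 µV
("low-noise") N3 background, and the detector-recovery fixture inserts
templates into a background without spontaneous slow oscillations so that
template recovery is not confounded by event collisions.

## ISI analysis

Preceding ISIs are differences of consecutive real-stimulus times; the
night's first stimulus has no ISI and is excluded (no sentinel value).
The ten study bins (0.5–0.75 … >10.5 s) are a packaged constant; a
data-driven alternative snaps empirical quantiles to a 0.25 s grid. Bins
are left-open/right-closed, so an ISI of exactly 1.25 s falls in the
1–1.25 s bin, consistent with the above-threshold rule "ISI > 1.25 s".
Proportions are per participant with nights collapsed; bins under 10
stimuli are flagged low-n.

In the end-to-end recovery test the per-bin reference is the mean of
p(ISI) over the actually drawn ISIs in the bin (p is concave, so the
value at the bin midpoint overstates the expectation — Jensen), and the
binomial 95% bands are Bonferroni-adjusted across the ten bins, since
requiring ten simultaneous unadjusted 95% intervals would reject an
unbiased pipeline about 40% of the time. Two small negative biases are
expected and accepted inside the bands: the at-most-one-stimulus
assignment rule loses a response when its onset falls after the next
stimulus, and overlapping evoked responses at short ISIs can merge into
one detection.

## Spectral analysis

Morlet maps on 1–30 Hz (1 Hz steps) with cycle counts linear from 3 to
17.5, computed with MNE's wavelet convolution; epochs shorter than the
1 Hz wavelet are zero-padded and cells within half a wavelet's nominal
duration (n_cycles/2f) of an epoch edge carry an invalid flag.
Normalisation is 10·log10 of power over the per-frequency whole-epoch
baseline pooled over ON and OFF epochs (scale-invariant by construction).
Epoch counts are matched by seeded subsampling of the majority class.

The cluster-permutation test thresholds the paired t map two-tailed at
α = 0.05, groups supra-threshold cells by 4-neighbour contiguity
(adjacency in 1-D) within sign, and scores clusters by mass (Σt; extent
is available, the choice is configurable because the underlying
literature is ambiguous). The null is the distribution of the maximal
cluster statistic over per-night condition-label swaps — sign flips of
the paired difference maps, which is exactly what swapping all of a
night's matched ON/OFF epochs wholesale induces; clusters above the null's
95th percentile are significant, giving family-wise control (confirmed
at 0.05 ± 0.02 over 500 null simulations). Zero-variance cells get t = 0.

ΔlowSWA is the mean Welch 0.5–1 Hz power over ON windows minus OFF
windows, per 6 s window, using the window clock stored in the stimulus
log.

## Phase-amplitude coupling

Phase: zero-phase band-pass 0.5–1.5 Hz + analytic-signal angle (cosine
convention, 0 at peaks; samples with analytic amplitude below a floor are
flagged unreliable). Amplitude: 13–16 Hz envelope. The modulation index
is the entropy-based statistic on 18 phase bins of 20°,
MI = (log N − H(P))/log N ∈ [0, 1], with 1e−12 additive smoothing for
empty bins. The surrogate null cuts each amplitude epoch at a uniformly
random interior sample and swaps the two parts (preserving the amplitude
multiset exactly), recomputes MI 200 times, and z-scores the empirical
MI. Surrogates are cut per epoch before concatenation: on a strictly
periodic single series a circular shift leaves coupling intact (MI is
rotation-invariant), so the null's power comes from mixing independent
offsets across epochs. Stimulus-locked coupling restricts phase and
amplitude to (0, 2] s post-stimulus and concatenates across epochs within
night × stimulus-category before MI. On null (uncoupled) epochs the zMI
distribution is calibrated (mean ≈ 0, SD ≈ 1).

## Behaviour scoring and statistics

Tap streams are segmented greedily into consecutive 6-tap attempts with
no realignment after errors (deterministic position-marker behaviour).
Per trial: % correct sequences, mean intertap interval over completed
attempts, performance = %correct / mean-ITI (%/s), variability = mean of
within-attempt interval SDs (seconds internally; ms is only a display
convention). Session summary: baseline = trial 1, plateau = mean of the
last three learning trials, learning rate = plateau − baseline,
retrieval = mean of R1–R3, overnight change = retrieval − plateau. The
performance denominator averages over all completed (not only correct)
attempts, mirroring the variability definition; this is configurable via
the segmentation output. PVT speed = mean 1/RT over nonlapse (<500 ms)
trials.

Paired comparisons screen the differences with Shapiro–Wilk at 0.05 and
choose Student's paired t or Wilcoxon signed-rank accordingly; effect
size is Hedges g on difference scores with J = 1 − 3/(4·df − 1). The
percentage-bend correlation implements Wilcox's formula (bend constant
β = 0.2): per margin, the bend scale ω is the ⌊(1−β)n⌋-th order statistic
of |x − median|, observations beyond ±ω are flagged, the margin is
re-centred by the percentage-bend location and standardised scores are
winsorised at ±1 before Pearson correlation; p uses the t approximation
with n−2 df. Outliers use |z| > 3 with the sample SD (no flags when the
SD is zero). `export_model_table` assembles the tidy participant × night
table for external robust mixed-effects fitting, which is out of scope.

## Problem sizes and numerical choices

Validation runs use: 600 s slow-wave trains (3 seeds) for phase accuracy;
400 s nights × 20 seeds for the protocol contrast; 200 inserted templates
for detector recovery; 5000 stimuli (500 per bin, in trains of 25) for
the ISI-curve recovery; 500 two-second epochs for zMI calibration; 500
null datasets of 8 nights × 20×40 cells at 500 permutations for the
cluster test's family-wise error; 100 seeds for tapping-gain sign
recovery. The cluster-finding oracle enumerates all 512 3×3 binary maps
exhaustively plus 8000 random 5×5 maps (the full 2^25 enumeration of 5×5
maps is not computationally meaningful as a test). All randomness flows
through one seeded `numpy.random.Generator` per call; fixed seeds give
bit-identical outputs.

## Known limitations

- The engine is a behavioural emulator, not a firmware clone; absolute
  stimulus counts depend on its configured thresholds.
- Detector sensitivity degrades with background delta amplitude and with
  event collisions (see above); real-data use requires re-calibration of
  the TKEO threshold, as in the original detector family.
- EDF export is not provided (recordings are written as raw float32 +
  JSON sidecar; EDF reading is supported through MNE).
- No spindle detection is exposed; spindles enter only through the
  sigma-band envelope of the coupling analysis.
- Robust linear mixed-effects estimation is deliberately out of scope;
  the package only builds the model-input table.
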