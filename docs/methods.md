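# Methods

This note documents the models, conventions and numerical choices behind
`chemoreflex`, and what the synthetic-data tests do and do not establish
about real recordings.

## ΔF/F₀ baseline model (imaging)

The baseline F₀(t) is the **forward** mean of the w frames t … t+w−1
(default w = 100 frames; 10 s at the 10 frames/s acquisition the defaults
assume).  The last w frames therefore have no complete baseline window and
are dropped: a T-frame movie yields exactly T − w output frames.  Division
uses the same F₀(t), so ΔF/F₀ is invariant under global rescaling of F.
Pixels whose baseline is ≤ 0 (possible after background subtraction) are
masked NaN by default (`nonpositive="mask"`); a hard-error policy is
available.  Because the baseline is a *running* mean, slow multiplicative
drift (bleaching) is absorbed, but the same mechanism attenuates measured
transient amplitudes by roughly the mean activity level within the window —
about 10 % for a cell bursting at 0.2 Hz with amplitude 0.5 and 1 s decay.
This is a property of the estimator, not an implementation artifact, and
tests that check amplitude recovery use sparse bursts where the attenuation
is small.

## Cycle-triggered average and SD image

The CTA aligns movie segments on population-rhythm events and averages them,
attenuating non-rhythm-locked variance by ≈ 1/√N.  Cycle events are local
maxima of the whole-field ΔF/F₀ trace after a 0.5 s moving-mean smoothing,
with minimum separation 1/band_high (2.5 s for the 0.1–0.4 Hz band) and
prominence ≥ 3 noise SDs.  The noise scale is the first-difference MAD
estimator σ = 1.4826·MAD(Δx)/√2: unlike the MAD of the trace itself, it is
insensitive to the slow oscillation, so a clean rhythm of any amplitude
passes while a flat trace yields no events.  CTA mode additionally requires
the population trace to pass the in-band PSD gate; otherwise the caller is
directed to `full_series` mode, where the SD image of the whole ΔF/F₀ series
replaces the SD of the CTA (the appropriate fallback when no coherent
population rhythm exists, e.g. mutant preparations).  The CTA window
(default ±25 frames, ±2.5 s) and the alignment point (trace maxima) are
configuration choices.

The SD image is the per-pixel temporal standard deviation, population
convention (ddof = 0, matching common Z-projection behavior; configurable),
NaN-aware.

## Iterative-threshold ROI discovery

Starting at the 99.5th-percentile intensity, connected components
(8-connectivity) with area in [5, 200] px are accepted and zeroed out; the
threshold is multiplied by 0.95 per iteration until it reaches
median + 2·MAD of the original image.  Two tie-break rules make the search
deterministic and well-behaved: earlier (higher-threshold) acceptances win,
and a component that touches an already-accepted ROI within its
8-neighbourhood is suppressed — after a cell's bright core is zeroed, lower
thresholds re-find the same cell's dimmer skirt as a spurious "new"
component, and the adjacency rule removes exactly those.  The area gate is
calibrated to 4×4-binned pixels where a neuron subtends roughly 5–200 px.
On an exactly flat (or noise-free zero-background) image the stop rule
degenerates; real SD images always carry a noise floor, and the test
fixtures include one.

## Spectral rhythmicity gate

PSD by mean-removed Welch periodogram: Hann window, 50 % overlap, segment
length ≥ 4 slow cycles (40 s at band_low = 0.1 Hz, giving 0.025 Hz bins for
180 s records).  The DC bin is excluded from the peak search (an optional
`min_frequency` floor can exclude more); equal-power peaks resolve to the
lowest frequency.  A trace is accepted iff its peak frequency lies in the
closed band [0.1, 0.4] Hz.  Tones within half a bin of a band edge can
resolve to the neighbouring bin; the acceptance verdict is only guaranteed
for frequencies at least one bin away from the edges.

## Nerve-trace analysis

**Integration.**  Raw signals are full-wave rectified and passed through a
single-pole leaky integrator (discrete exponential smoothing with
α = dt/τ, τ = 50 ms default), emulating an analog RC integrator; a unit step
reaches 1 − 1/e of its asymptote after one time constant.  Raw input should
be sampled at ≥ 1 kHz for the default τ.

**Burst detection.**  Baseline is a rolling median over 10 s (computed on a
≤ 2000-point decimated copy and interpolated back); threshold is baseline +
3 robust SDs (1.4826·MAD of the baseline-subtracted trace).  Supra-threshold
runs shorter than `min_duration_ms` (50 ms default) are dropped *before*
merging, then runs separated by less than the refractory period (300 ms
default) are merged.  Closely spaced bursts whose envelopes do not return
below threshold merge into one detection — a rule consequence, so recovery
tests plant bursts separated by many decay constants.

**Kinetics.**  Amplitude = peak − baseline; time-to-peak uses an onset
refined by back-extrapolating the rising edge (the 20 % and 50 % crossings
projected linearly to baseline), which removes the late bias of a plain
threshold crossing; half-width is the width at 50 % amplitude with
sub-sample interpolation; decay time is peak → 1/e of amplitude (the
convention consistent with exponential-like decays; peak → 50 % available
via `decay_criterion="half"`).  Bursts whose crossings run off the trace are
flagged censored.

**Evoked classification.**  A stimulation is evoked iff the first burst
onset after stimulus onset falls within the response window (default 2 s —
well above the ~0.6–0.7 s latencies the protocol produces, while the fixed
4 s post-burst trigger delay keeps the triggering burst out of the window).
Overlapping stimulation windows are a protocol violation and raise.
Entrainment requires ≥ 5 periodic stimuli; a cycle is "followed" when
exactly one burst falls in the window, and phases are summarized by the
circular mean and resultant length.

## Plethysmography

**Calibration.**  Injections of known volume (2.5–5 μl) produce pressure
lobes; scale = volume / lobe area, integrated over 0.5 s above the local
pre-injection baseline, averaged over injections.  Scales disagreeing by
more than 20 % flag an inconsistent calibration.

**Breath segmentation.**  The trace is smoothed (50 ms moving mean);
baseline is a rolling lower quartile over 2 s — unlike a rolling median it
stays in the expiratory flat even when inspiration fills half the cycle —
and amplitude is the rolling peak-to-peak over 5 s.  Inspiratory onsets are
upward crossings of baseline + 10 % of amplitude.  T_TOT is the inter-onset
interval; V_T is the scale times the baseline-subtracted signal area over
the breath (with the single-lobe waveform model this equals the inspiratory
lobe area; the alternative peak-deflection convention is not used).

**Apneas.**  An apnea is an inter-onset gap exceeding 2 × the rolling-median
T_TOT (11-breath window); the gap breath and its neighbours are excluded
from all summaries.  The threshold is configurable since no community
standard exists.

**Protocols.**  Neonatal: 200 s air, 200 s 8 % CO₂, 400 s air (800 s).
Adult: 100 s air recording, 3 min gas equilibration, 100 s hypercapnic
recording.  Timecourses are binned at 20 s.

**Ratio statistic.**  Per animal and parameter, ratio = mean over the last
100 s of the hypercapnic epoch / mean over the last 100 s of the preceding
normocapnic epoch, using apnea-free breaths only; animals with fewer than 5
such breaths in either window are excluded with a logged reason.  The group
value is the mean over animals of 100·(ratio − 1), with SEM and a paired
t-test on the per-animal window means.  The order of operations matters —
per-animal ratios first, then the group mean — and the alternative (ratio of
group means) is deliberately not the default because the two differ under
between-animal heterogeneity.  Baseline ventilation is reported per gram
(V_E/mass, μl/s/g), normalized at the animal level.

## Statistics

Means ± SEM (sample SD/√n; undefined for n = 1).  Unpaired comparisons use
the pooled-variance Student's t-test (Welch via flag); paired comparisons a
one-sample t on differences.  Degenerate conventions: identical constant
samples → t = 0, p = 1; constant nonzero paired differences → t = ±∞,
p = 0.  No multiple-testing correction is applied.  Stereological counts:
bilateral counts in a 1:4 section series × 4; dorsal fraction =
100·dorsal/(dorsal+ventral).

## Synthetic-data generator

The generator produces the statistical structure the analyses assume, with
complete ground truth and bit-identical output for equal spec + seed.

* **Movies** — cells are 2-D Gaussian footprints (ground-truth masks at the
  2σ contour, support truncated at 4σ); each burst is an instantaneous rise
  followed by exponential decay; burst times are periodic with Gaussian
  cycle-to-cycle jitter; bleaching is monoexponential and multiplicative on
  the whole frame; noise is additive Gaussian.  Defaults follow the
  acquisition regime the analysis assumes: 10 frames/s, 180 s, 128×128 after
  4×4 binning.
* **Nerve traces** — bursts rise linearly over `time_to_peak` and decay
  exponentially with τ = `decay_time`.  This shape has three degrees of
  freedom, so the `half_width` field of the four-number burst-shape tuple is
  retained for interface parity but the realized half-width is
  ttp/2 + τ·ln 2 (≈ 467 ms for the default 228/510 ms), reported in
  `realized_kinetics` and used as ground truth by recovery tests.
  Spontaneous bursts are Poisson; evoked bursts follow each stimulus with a
  Bernoulli success and Gaussian latency.  Additive noise is low-pass
  filtered with the 50 ms integrator pole (an integrated envelope cannot
  carry white noise), then the trace is clipped at zero.
* **Breath traces** — one positive half-sine inspiratory lobe per breath
  (duration 0.4·T_TOT), rendered as per-sample bin averages so lobe area
  encodes volume exactly at any sample rate.  Per-breath T_TOT and V_T are
  Gaussian with specified CVs; hypercapnic epochs scale both by
  multiplicative factors; apnea windows suppress breaths; a calibration lobe
  of known volume is embedded with ±1 s of breaths blanked around it so it
  stays identifiable.  An optional additive-noise level (default 0) is a
  realism knob beyond the core model.

What the generator does **not** model: optics/PSF and motion artifacts,
spike-to-calcium biophysics, photon (shot) noise, airway mechanics and
barometric thermodynamics, behavioral states.  Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
statistical model, not robustness to these real-data effects.

## Problem sizes and defaults in the test battery

The recovery suites use 180 s movies with 20 planted cells at 0.15–0.35 Hz
(≥ 12 px center separation, ΔF/F amplitude 0.4, noise SD 1 on a baseline of
100), 100-seed nerve batches with bursts planted 6 s apart (isolation ≫
decay constant), 100-seed breath batches at CV 0.1 with the Table-style
factor pair (0.805, 1.275), and 10 000-replicate null batteries for the
t-tests.  These sizes give standard errors small enough that a 5 % kinetic
bias or a one-bin spectral error would be detected, while the whole battery
runs in minutes on one CPU.

## Known limitations

* The running-baseline attenuation of transient amplitudes (above) biases
  absolute ΔF/F amplitudes for densely bursting cells; frequency and
  classification results are unaffected.
* The breath detector assumes a dominantly positive inspiratory deflection;
  recordings with strong biphasic lobes would need the onset threshold and
  baseline quantile revisited.
* Burst detection near the trace edges yields censored kinetics rather than
  extrapolated values.
* `iterative_threshold_rois` assumes cells are bright, compact and mutually
  non-adjacent at the binned scale; touching cells merge into one ROI or
  suppress each other via the adjacency rule.
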