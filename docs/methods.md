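# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `driftspec`, and what the synthetic-data tests do and do
not establish about real recordings.

## Signal model

A single-eye gaze recording is modeled, in degrees of visual angle, as

    g(t) = target(t) + drift(t) + saccades(t) + pupil(t) + ε(t),

optionally passed through a causal low-pass filter, with reported timestamps
perturbed by Gaussian jitter.

* **Measurement noise** ε is i.i.d. Gaussian per channel, SD
  `noise_sd_deg`. Default 0.03° for a human eye on a low-noise research
  tracker; artificial-eye recordings default to one third of that (0.01°),
  matching the observation that human data are roughly three times noisier
  than artificial-eye data on the same device. A white noise model is the
  appropriate null: each video frame is processed independently, so
  unfiltered tracker noise carries no temporal correlation.
* **Ocular drift** is a random walk: the cumulative sum of i.i.d. Gaussian
  increments with per-sample SD `drift_step_sd_deg` (default 0.008°, i.e.
  ~0.11° of excursion within a 200-ms window at 1000 Hz — a conventional
  drift magnitude). The walk restarts at each target jump; a random walk has
  power spectrum ∝ 1/f², the α = 2 signature the analysis looks for.
* **Microsaccades** are Poisson-timed (default 1.5 s⁻¹) instantaneous step
  displacements of fixed amplitude (default 0.3°) in a uniformly random
  direction, persistent until the next target. A one-sample step is
  deliberate: the window-selection stage exists to exclude saccades, so their
  intra-saccadic kinematics are irrelevant to the spectra of selected
  windows, and a step is the hardest case for the dispersion screen.
* **Pupil artifact** (optional) adds a slow sinusoid (default 0.1°, 0.2 Hz)
  to both channels, emulating the apparent gaze shift that pupil-size change
  induces in video-based trackers.
* **Recording filter.** Vendor smoothing filters are unpublished, so the
  generator provides two generic causal unit-DC-gain smoothers — a
  moving average of `order` taps (startup handled by holding the first
  sample) and a first-order exponential recursion. Any unit-DC-gain low-pass
  reproduces the qualitative coloring of interest; parameters live in the
  config, not in code.
* **Timestamp jitter.** Reported timestamps are the nominal comb plus
  Gaussian noise, re-sorted; sample *values* stay on the nominal comb,
  mimicking software-timestamp noise rather than true irregular sampling.
  `isi_jitter_pct` parameterizes the observable statistic — SD of the
  inter-sample interval as % of nominal — so per-timestamp noise is drawn at
  pct/√2 (differencing independent noise doubles its variance).

Randomness: one root seed; every stochastic component (noise, drift,
saccades, jitter, pupil) draws from an independent stream spawned from it.
Identical (config, seed) ⇒ bit-identical recordings.

### Stimulus protocol

53 fixation targets: a 4×8 grid spanning 45.5 × 26.8 cm centered on the
screen, plus a 3×7 grid at the outer grid's cell centers. Conversion to
degrees uses deg = atan(cm/65 cm)·180/π. A session is an initial central
fixation followed by a seeded random permutation containing each target four
times — 213 presentations of 1500 ms. The initial central fixation is counted
as a presentation (the 213 total only balances that way); the
`include_initial_center` flag exposes the alternative.

## Window selection

Human data: per presentation, 200-ms candidate windows slide at one-sample
steps (the finest granularity consistent with "each possible window
position"; the original step size is not documented) over
[onset + 200 ms, offset). Window length in samples is round(0.2·fs) — 12
samples at 60 Hz. Candidates containing any invalid sample are disqualified
(the dispersion measure is undefined on gaps). The ceil(N/2) candidates with
smallest dispersion survive (ties at the cut keep the earlier start), and the
survivor whose mean position is nearest the target is selected, earlier start
winning ties. Selection runs per eye; eyes are never averaged.

Artificial-eye data: 200-ms windows at 50-ms steps over the whole recording;
fractional-sample steps round *up*, so a window never starts before its time
slot and a 249-ms recording holds exactly one window.

The implementation is vectorized (stride-tricks sliding windows); the test
suite checks exact agreement with a naive loop-based re-implementation across
60–1000 Hz, and that an injected step displacement ≥5× the quiet dispersion
never lands inside a selected window.

## Spectral estimation

All estimators return one-sided power density (deg²/Hz) with a common
normalization contract: Σ(power over non-DC bins)·Δf equals the variance of
the window (checked to 1e-9). No detrending or mean removal is applied before
the periodogram — the default behavior of standard periodogram routines — so
the window mean sits in the DC bin, which every fit excludes.

* **Periodogram**: rectangular window (boxcar), `scipy.signal.periodogram`.
* **Multitaper** (display only): mean of k eigenspectra with DPSS tapers,
  defaults nw = 4, k = 7 (k ≤ 2nw − 1 enforced).
* **Lomb–Scargle**: `scipy.signal.lombscargle` on mean-centred values at the
  reported timestamps, rescaled by 2/fs, which makes it equal the
  periodogram density bin-for-bin on evenly sampled input (verified to
  1e-6). Its default grid is the even-sampling Fourier grid without DC and
  Nyquist: DC carries no least-squares power and the Nyquist bin is
  degenerate in the Lomb–Scargle normal equations.

**Slope fits.** α = −slope of OLS on (log₁₀ f, log₁₀ S) over (0, f_hi],
f_hi defaulting to Nyquist; a 100-Hz-band fit is produced only when Nyquist
> 100 Hz (below 200 Hz sampling the full-band fit already covers the
fixational range, and reports flag the reuse). α is always fit to *power*
spectra; amplitude spectra (√power) are for display. Per eye, power spectra
are averaged across all selected windows and fit once per channel, then the
horizontal and vertical exponents are averaged. Averaging spectra before
fitting (rather than averaging per-window fits) has lower estimator variance;
the per-window alternative is available via `per_window_alpha=True`.

### Numerical notes

* A *discretely sampled* random walk's expected periodogram is
  σ²/(fs·4 sin²(πf/fs)), which tracks 1/f² at low frequency but flattens
  near Nyquist; a full-band fit therefore recovers α ≈ 1.78–1.80 rather than
  exactly 2 at 1000 Hz with 200-sample windows. This is a property of the
  estimator applied to Brownian motion, shared by any implementation using
  full-band periodogram fits.
* The one-sided periodogram's Nyquist bin has half the interior density by
  convention (it is not doubled). With 100 fit bins this is negligible; with
  the 6–12 bins of 60–120 Hz windows it inflates α by ~+0.1–0.2. The
  estimator cross-check therefore fits both estimators on the common grid
  excluding DC and Nyquist, isolating the sampling-irregularity question the
  check is about; the headline pipeline keeps the conventional full grid.
* Dispersion, selection and tie-breaks use exact float comparisons;
  determinism is guaranteed by fixed iteration order, not by tolerance
  fudging.

## Estimator cross-check

Timestamp jitter is a device property, so the cross-check samples the five
(sampling rate, ISI-jitter) profiles of representative trackers — (1000 Hz,
0%), (250, 0.74), (120, 9.98), (300, 1.15), (60, 1.89) — crossed with three
signal kinds (white, moving-average-filtered white, random walk), 60 eyes of
10 s each. α is estimated per eye with the standard periodogram on the
nominal grid and with Lomb–Scargle on the reported timestamps; the squared
Pearson correlation between the two sets is ≈ 0.9985. Pairing high jitter
with high sampling rates — combinations no real tracker exhibited — would
genuinely degrade the Lomb–Scargle estimate for steep spectra, because the
sample values remain on the nominal comb while the claimed times move; the
cross-check is a statement about realistic devices, not about arbitrary
jitter.

## Hypothesis classification

With whiteness threshold α < 0.5 (unfiltered conditions in practice cluster
well below 0.5, filtered colored conditions well above; the threshold is a
config parameter):

* **oculomotor-consistent** — human-filtered colored while artificial data
  stay white under identical filtering;
* **filter-consistent** — human- and artificial-filtered both colored and
  similar (|Δα| < threshold), artificial-unfiltered white (when present),
  and human-unfiltered either white or substantially whiter than
  human-filtered (α_hu < α_hf − threshold). The asymmetric human condition
  is deliberate: a tracker whose noise floor is low enough to resolve real
  drift legitimately retains color in unfiltered human data;
* **indeterminate** — anything else, including an all-white grid (noise
  floor dominates everything).

The verdict is a deterministic function of the α values and the threshold.

## The 2×2 experiment

`run_condition_grid` simulates human (full 213-presentation protocol) and
artificial (19-s) recordings at 1000 Hz, filtered (moving average, 8 taps)
and unfiltered, with human noise 0.03° over 0.008°-step drift — the low-noise
regime — plus an optional high-noise human variant (0.2°). Typical full-band
exponents: filtered ≈ 1.9 (human) / 1.7 (artificial); unfiltered artificial
≈ 0.0; unfiltered human ≈ 0.7 at low noise and ≈ 0.15 at high noise, and the
classifier returns filter-consistent. The band pattern also reproduces the
low-noise-tracker signature: the filtered human exponent over the first
100 Hz (≈ 2.0) far exceeds the filtered artificial one (≈ 0.8), because
below 100 Hz the human signal contains real drift while the artificial
signal's color comes only from the filter's high-frequency rolloff.

## Problem sizes

Benchmark studies use 19-s artificial recordings at 300 Hz (377 windows),
60-s random-walk traces at 1000 Hz (1197 windows), 60 cross-check eyes of
10 s, and 200 oracle-equivalence trials across five sampling rates — sizes
at which the stochastic quantities are stable to well within their stated
tolerances while the full suite runs in about a minute.

## What the synthetic tests do not show

The generator emulates the statistical structure the analysis assumes —
white sensor noise, random-walk drift, step microsaccades, linear
time-invariant smoothing, timestamp noise on a fixed comb. Real recordings
add nonstationarities the model omits: blinks and data loss beyond a validity
flag, saccade kinematics and post-saccadic oscillations, head-movement
compensation errors, nonlinear or adaptive ("heuristic") vendor filters, and
pupil artifacts richer than a sinusoid. Passing tests establish that the
pipeline measures spectral color correctly on signals of known color, and
that the 2×2 logic discriminates the hypotheses under those conditions — not
that any particular commercial tracker is filtered or unfiltered. Known
limitations: no blink/eyelid model, no vergence or binocular model, no
torsion (a gaze direction determines only two Fick angles), no vendor SDK
ingestion, and no calibration-based pupil-artifact correction.
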