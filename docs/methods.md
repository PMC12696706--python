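# Methods

This note documents the models, conventions and design choices behind
`docbci`: what the synthetic-EEG generator emulates, how each analysis
stage is defined, which knobs matter, and what the passing test suite
does and does not establish about real clinical data.

## Synthetic cohorts

A virtual subject is a `SubjectProfile`: group label (UWS-like or
MCS-like), CRS-R total (drawn uniformly from 4–9 for UWS-like and 10–20
for MCS-like subjects), age, sex and disease duration drawn to match the
published demographic summaries of the two groups, a resting band-power
composition per cortical region, a set of task-modulation factors, and
an attention gain in [0, 1].

**Resting composition.** Group templates are the published resting
medians of the two groups (frontal MCS ≈ 0.35/0.28/0.22/0.10/0.01
across delta/theta/alpha/beta/gamma after normalization; UWS more
delta-dominant; temporal and occipital reuse the parietal template,
which the contrast battery never tests). Per-subject weights are
Dirichlet draws around the template (concentration 30, giving roughly
the published interquartile spread).

**Task modulation.** During imagery cue windows the band weights are
multiplied by group-specific factors and renormalized: the MCS-like
pattern raises delta/theta and suppresses alpha/beta/gamma over frontal
and parietal cortex; the UWS-like pattern only raises parietal gamma
(factor 4, chosen so the session-level median change matches the
published +0.02 after dilution by the cue duty cycle of 5 s in every
12 s trial). Factors receive mild per-subject log-scale jitter
(relative SD 0.15 of the log-factor), so null factors stay exactly 1.

**Signal synthesis.** Each channel is a sum of five band-limited noise
processes: white noise filtered with the same 6th-order Butterworth
bandpass design the analysis chain uses, so generator and analyzer agree
on band edges. Band noise is synthesized with a margin of three periods
of the lower band edge on each side and cropped to the interior, because
reflect-padding a white sequence inflates edge variance for narrow
low-frequency bands.

Because the analysis estimates spectra with short (500 ms) Hamming
windows, the estimator smears narrow bands: a pure 1–4 Hz process loses
roughly a fifth of its measured power into theta and into the sub-1 Hz
region. The generator therefore
*calibrates* its band variances: the expected Welch response of each
unit-variance band process is computed exactly (window/detrend kernel
against the process autocovariance), and the five band variances are
solved by non-negative least squares so that the *measured* relative
powers equal the requested weights. For interior weight vectors (all
the defaults) the solve is exact; corner cases (for example a literal
delta-only profile) are limited by the estimator's reachable set — a
delta-only process can reach at most ≈ 0.81 measured delta fraction
through 500 ms windows, although ≥ 95% of its power lies in 1–4 Hz when
measured with 4-s windows.

Channel RMS is 12 µV. Within the 10–30 µV range typical of scalp EEG,
the low end keeps spontaneous Gaussian excursions of clean data safely
below the ±75 µV artifact screen, so every rejected epoch is
attributable to an injected artifact.

**Artifacts.** Two streams, each a Poisson process with a configurable
events-per-minute rate, both thinned (factor 0.3) inside cue windows
where an engaged subject blinks and moves less:

* *Ocular*: a ~0.5 s gamma-shaped blink, 90–140 µV at Fp1/Fp2 with a
  frontally decaying topography, mirrored (×1.8) on a synthetic EOG
  channel that also carries 5 µV sensor noise.
* *Movement*: a 40 ms transient of 90–150 µV on one random channel plus
  a spatially widespread 0.5 s burst of 8–30 Hz muscle noise
  (15–40 µV RMS per channel) — the component that makes baseline
  windows noisy in the SNR sense.

Ground truth (event samples, the pure artifact signal, the latent
attention trace) is attached to each synthetic recording in
`EEGRecording.truth` for testing.

**Attention linkage.** The latent per-trial attention trace is zero
before the cue and rises to a Gaussian bump peaking `latency_s` (default
4 s) after cue onset with width 1.5 s; the peak is the subject's
attention gain times log-normal trial noise (SD 0.9), clipped to 1. The
gain is an affine map of CRS-R,
`gain = 0.095 + 0.011·CRS-R + N(0, 0.04)` clipped to [0, 1]; the
configured design target for the induced rank correlation between
CRS-R and the measured session attention index is 0.43, and the map's
constants were calibrated by simulation, at design time, to land there.

At Fp1 the attention trace drives the closed loop: beta power is
multiplied by `1 + 3.5·a(t)` and alpha power divided by it, on top of a
tonic alpha-idling factor of 6 active throughout the task recording.
The idling term is what makes the fixed threshold of 50 informative —
without it the normalized index hovers at its calibration median (≈ 50)
and every subject saturates near ceiling; with it the baseline index
sits low and only attention-driven ratio shifts cross the threshold.
The instantaneous Fp1 variance is renormalized so these factors shift
the spectral *composition*, not the channel's total power (otherwise the
bad-channel screen would flag Fp1). These engine constants were fixed
once so that simulated group accuracies and the attention/CRS-R
correlation land in the published regime (≈ 55% vs ≈ 38%, rho ≈ 0.43),
and not revisited.

## Preprocessing

Fixed stage order: broadband filter → band decomposition (on demand) →
bad-channel interpolation → ICA artifact attenuation → common average
reference → 5 s epoching with the amplitude screen.

* **Filtering.** 1–45 Hz 6th-order Butterworth bandpass plus a 50 Hz
  notch (Q = 30), both applied forward–backward (zero phase) so event
  latencies survive for the closed-loop analysis. Pad length is three
  periods of the lowest edge; scipy's default would leave large startup
  transients.
* **Bad channels.** Automated surrogate for visual inspection: a channel
  is flagged when its MAD-based robust amplitude deviates more than 4
  robust SDs *and* more than 30% from the montage median. The
  MAD-based scale is deliberately insensitive to brief transients —
  blink-laden frontal channels must reach the ICA stage, not be
  interpolated away; dead or runaway channels still stand out. Flagged
  channels are replaced by inverse-squared-distance averages of their 4
  nearest good neighbors in 10-10 montage geometry; more than 30% bad
  channels raises a subject-level processing error.
* **ICA.** FastICA (scikit-learn), 30 components, seeded. Components
  whose absolute Pearson correlation with the EOG channel exceeds 0.7
  are zeroed before back-projection. FastICA's convergence criterion is
  structurally unattainable on near-Gaussian backgrounds (only the
  artifact sources are identifiably non-Gaussian), while the blink
  component itself separates robustly (|r| ≈ 0.9); a convergence
  warning therefore does not discard the decomposition. Only a hard
  fit failure triggers the fallback, regression of the EOG signal out
  of every channel, recorded in the QC report.
* **Reference.** Common average over the 30 scalp channels only. The
  synthetic data are generated in average-reference space; the online
  CPz reference of the recording hardware is not simulated.
* **Epoching.** Non-overlapping 5 s windows; an epoch is rejected iff
  any scalp sample strictly exceeds ±75 µV. Rest (500 Hz) and task
  (250 Hz) are processed at native rates; only unitless relative power
  is compared across conditions.
* **SNR.** `10·log10` of mean 8–30 Hz Welch power in cue windows over
  pre-stimulus baselines, averaged over scalp channels. The
  post-cleaning convention also applies the ±75 µV screen to the
  windows themselves (the published pipeline counts bad-epoch rejection
  as part of cleaning).

## Spectra

Welch PSDs use 500 ms Hamming windows with 250 ms overlap, density
scaling, computed per kept 5 s epoch and averaged with equal epoch
weights. Two numerical choices depart from common defaults, both
because a 500 ms window is short relative to the delta band:

* *No per-window detrending.* Mean removal inside a 500 ms window has a
  DC kernel about 2 Hz wide and would remove ~15% of the 1–4 Hz band,
  biasing delta fractions well beyond the 0.01 the band identities
  should hold to. The chain's 1 Hz broadband high-pass already removes
  drift, so detrending is redundant here.
* *4× zero-padding* (0.5 Hz grid): the native 2 Hz grid of a 500 ms
  window cannot place the 1/4/8/15/30/45 Hz band edges accurately
  (flat-spectrum band fractions would be off by more than 0.01 from the
  analytic 3/44 … 15/44).

Relative power assigns bins half-open (`f1 ≤ f < f2`, the top band
closed at 45 Hz), normalizes by the total over [1, 45], and aggregates
regions as unweighted means of per-channel fractions — so the five band
values sum to 1 per channel and per region. The channel-level table
with 10-10 coordinates can be exported for topographic plotting; no
rendering is done here.

## The closed-loop engine

The attention index is reconstructed offline with the same Welch
machinery: per 1 s sliding window (0.5 s hop) at Fp1, `E_beta` and
`E_alpha` are the band sums, `R = E_beta/E_alpha`. The 0–100 scale is
a robust min–max of `log R` fitted on the subject's own resting
calibration segment (2.5th–97.5th percentiles), clipped; subject-
specific scaling is the only way a fixed threshold of 50 is meaningful
across subjects. Windows with zero alpha energy are marked invalid and
excluded. The trial rule: the trailing moving average (3 windows ≈ 2 s)
must exceed 50 at any time inside the imagery window; the first
crossing is the trigger latency, re-crossings are ignored (one glove
actuation per trial). Five practice trials are simulated but excluded
from scoring. Amplitude scaling cancels in R, so the index is
scale-invariant.

## Statistics

Between-group: Wilcoxon rank-sum with midranks; exact enumeration of
all C(n+m, n) rank splits when both groups have ≤ 10 observations,
otherwise a tie-corrected normal approximation with continuity
correction. Within-group (task vs rest): Wilcoxon signed-rank, zero
differences dropped, exact over all 2^n sign patterns for n ≤ 15. The
reported statistic is the sum of negative ranks (0 at the floor when
every difference is positive) with W+ and a descriptive Z alongside,
since the publication's statistic-reporting convention is ambiguous.
Exact p-values are defined symmetrically (`P(|W+−W−| ≥ observed)`),
which coincides with the classical doubled one-tail on these nulls.
Welch's unequal-variance t (pooled available behind a flag) accepts raw
samples or (mean, SD, n) summaries; Pearson's chi-square for 2×2 tables
is uncorrected, with the Fisher exact p attached. Spearman's rho uses
midranks, exact permutation p for n ≤ 9, the t approximation otherwise,
and a seeded 2000-resample percentile bootstrap CI. Quartiles use
linear (type-7) interpolation everywhere. No multiple-testing
correction is applied across the 10 region×band blocks, matching the
raw-p reporting convention; the count of contrasts is emitted so a
reader can apply one.

## Reproducibility and problem sizes

A run is fully described by a `RunConfig` (YAML-serializable); the
master seed derives per-(subject, stage) child seeds via a CRC mix, so a
subject's data do not depend on cohort order. Outputs are plain CSVs
with the config hash in a comment line; identical configs give
byte-identical files. `validate_run` re-checks the invariant suite
(band sums, accuracy bounds, p ranges, row counts) over a completed
run's outputs.

The replication studies use reduced problem sizes, chosen once as a
compromise between estimator noise and simulation cost and kept fixed:

* *Type-I calibration*: 200 null cohorts (no injected effects, groups
  share one template, the Fp1 closed-loop modulation disabled), n=12/19,
  rest 10 s and two short trials per subject, an 8-channel
  frontal+parietal montage (excluding Fp1, which carries closed-loop
  modulation and is not a neutral probe of frontal rhythm).
* *Effect-direction recovery*: 50 cohorts at n=12/19, rest 40 s, four
  standard trials, the same 8-channel montage.
* *Correlation recovery*: 100 cohorts, full 15-trial sessions with 60 s
  resting calibration, Fp1-only synthesis (the engine reads only Fp1).

## What the synthetic benchmark does and does not show

The generator reproduces the *structure* of the published data — group
spectral composition, cue-locked modulation directions and printed
magnitudes, artifact phenomenology, a CRS-R-linked responsiveness
gradient — under stationary Gaussian band-noise assumptions. It does
not model volume conduction or realistic source mixing (artifact
topographies are fixed spatial patterns), non-stationarity beyond the
cue envelope, oscillatory phase structure, electrode drift, or the
device's proprietary online index. Passing tests therefore establish
that the analysis chain is correct and well-calibrated on data with
known ground truth of this structure — not that the clinical effect
sizes themselves are reproduced from real recordings, which are not
publicly available. Published patient-level medians are used only as
generator templates, never as test targets.

## Known limitations

* The contiguous 6th-order Butterworth sub-band tiling loses energy at
  shared edges (band copies overlap at half power), ≈ 9% of broadband
  energy for EEG-weighted spectra; the relative-power path does not use
  the time-domain band copies and is unaffected.
* Exact tests have discrete p floors (e.g. 2/2^7 at n = 7 pairs); the
  battery reports them as computed.
* The EDF+ format is supported for reading user data only; synthetic
  recordings are persisted as NPZ archives.
* FastICA determinism holds for a fixed seed and data; across BLAS
  builds small numeric differences can change which iteration the
  algorithm stops at.
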