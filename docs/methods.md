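# Methods

This note documents the signal model, the analysis procedure, the parameter
defaults and the reasoning behind the open design choices. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Analysis procedure

The pipeline implements the classical spectral workload analysis for
wearable multichannel EEG, in a fixed stage order:

**Screening.** Participants with a pre-task Stanford Sleepiness Scale score
greater than 3 are excluded (a score of exactly 3 is included); they
contribute neither EEG nor behavioral rows to the statistics.

**Filtering.** A Butterworth band-pass with −3 dB points at 0.5 and 32 Hz
is applied to all channels identically, EOG included. The order (default 4)
and phase handling are not dictated by the analysis definition, so both are
explicit parameters. The default is zero-phase forward–backward filtering;
since two passes square the magnitude response, the design cutoffs are
pre-warped (analytic first guess `f·(√2−1)^(∓1/2n)`, then root-finding on
the realized digital response) so the *net* response is −3 dB at the stated
edges. A single-pass variant uses conventional cutoffs. Edge effects are
handled by reflection padding. Filtering all channels with one filter
preserves the linear EEG↔EOG mixing that the next stage assumes; whether
EOG channels should be filtered before regression is genuinely open, and
identical filtering is our documented choice.

**EOG regression.** Each scalp channel is regressed on
`[EOG_H, EOG_V, 1]` by ordinary least squares over the whole recording
(configurable span) and the fitted ocular contribution is subtracted; the
corrected channel keeps its own mean. Channel-wise joint regression with an
intercept is the simplest model consistent with subtracting both EOG
signals from each electrode; blink-epoch-only fitting variants exist but
are off by default. OLS orthogonality guarantees zero post-correction
EEG–EOG covariance on the fit span, and residualizing twice is a no-op —
both are asserted in tests.

**Epoching and rejection.** Each annotated condition interval
(half-open `[start, stop)`, seconds from recording start) is tiled with
non-overlapping 2-s epochs; a trailing partial epoch is dropped. An epoch
is rejected when *any* sample on *any* scalp EEG channel leaves the closed
[−100, +100] µV interval — rejection is recording-wide per epoch because
discard accounting is reported as a single figure per condition. Valid plus
discarded seconds always equal the epochable seconds (conservation is a
tested invariant).

**Spectral estimation.** Power spectra are averaged modified periodograms:
per valid epoch and channel, mean removal, Hamming taper, one-sided
periodogram in density scaling `P(f) = |X(f)|²/(fs·Σw²)` with interior bins
doubled, averaged across epochs. Non-overlapping segment averaging is the
Bartlett-style limit of Welch's method; the Hamming taper follows the
stated estimator. Equivalence with an explicit-loop direct-DFT reference
(≤1e−10 relative) and with `scipy.signal.welch` at zero overlap are both
tested, as is windowed Parseval consistency within 2%. Epoch mean removal
prevents DC leakage into the lowest bins and is flagged as an assumption.
At 256 Hz with 2-s epochs the grid step is 0.5 Hz.

**Theta band power** is the arithmetic mean of the PSD over bins with
4 ≤ f ≤ 8 Hz, both endpoints inclusive (nine bins); inclusivity is a
documented convention. Units are µV²/Hz, absolute (no per-subject baseline
normalization — the magnitudes of channel-level summaries in this
literature are consistent with absolute density units).

**Statistics.** One-way and fully-crossed two-way repeated-measures ANOVAs
are computed from explicit sum-of-squares decompositions; each effect is
tested against its own subject-by-effect interaction error term.
Greenhouse–Geisser ε comes from the double-centered covariance
`ε = (tr S̃)²/((k−1)·ΣS̃²)` (marginal means for main effects,
Kronecker–Helmert contrasts for the interaction), bounded in
[1/(k−1), 1]. Sphericity is diagnosed with Mauchly's test on the
orthonormal-contrast covariance, with the standard small-sample factor and
the two-term asymptotic expansion of the null distribution (the
ezANOVA/SPSS convention). Because reports in this literature mix corrected
and uncorrected degrees of freedom, both are always computed; the
"reported" line uses GG when Mauchly's p ≤ 0.05. Mauchly is an editorial
choice — the correction rule could equally be "always GG", and that mode is
what the code advises when the contrast covariance is singular. Pairwise
contrasts are paired t-tests with Bonferroni correction
(`p·k(k−1)/2`, capped at 1), computed on factor-level marginal means for
two-way designs. Partial η² uses the identity
`F·df1/(F·df1+df2) = SS_eff/(SS_eff+SS_err)`, asserted to float tolerance.
Subjects missing any cell are listwise dropped and counted. p-values come
from scipy's F/t/χ² survival functions; everything else is computed here,
with pingouin used in the tests only as an independent cross-check.
Degenerate inputs: zero error SS reports F as an infinite limit with p at
its exact bound and a flag; zero-variance pairwise differences give p = 1
for a zero mean difference and are flagged otherwise.

## Synthetic cohort model

The generator emulates the study conditions the pipeline is designed for: a
35-subject cohort, three ~5-minute driving scenarios of graded terrain
complexity, and 3-minute eyes-open resting baselines before and after.

Per condition interval and channel, the signal is a sum of

- **1/f^α background** (α = 1), Gaussian noise shaped in the frequency
  domain (no filter transient), spectrum flattened below 0.5 Hz, scaled to
  an RMS of 6.8 µV. This scale puts the background theta floor near
  1.25 µV²/Hz after band-pass filtering, the level needed for baseline
  channel means around 1.85 µV²/Hz;
- a **theta oscillation**: fixed-frequency 6 Hz sinusoid (optional
  frequency jitter) at the condition's injected amplitude. A sinusoid keeps
  Parseval-style checks closed-form: an amplitude A spreads A²/2 of power
  over the nine theta bins, adding A²/9 µV²/Hz to the band mean. Default
  amplitudes (2.32, 3.34, 3.66, 3.77, 2.35 µV for pre-baseline,
  low/medium/high complexity, post-baseline) were derived from that
  closed form to land the cohort channel means at magnitudes typical of
  this literature (≈1.9 at rest, ≈2.4–2.8 under load);
- **ocular artifacts**: positive raised-cosine blinks (~400 ms, 150 µV,
  15/min) on the vertical EOG, step-like saccade deflections (±50 µV,
  8/min) on the horizontal EOG — standard morphologies — each channel plus
  its own 1/f background. Scalp channels receive the *measured* EOG signals
  scaled by per-subject propagation coefficients (frontal > temporal >
  occipital defaults, additive jitter SD 0.02), exactly the linear mixing
  model the regression corrector assumes, so injected coefficients are the
  estimand of the recovery tests;
- **artifact bursts**: 0.5-s Hanning-windowed 10 Hz tone pips at 300 µV on
  one random scalp channel, Poisson at 4.7/min, each confined to a single
  2-s epoch. The rate reproduces discard totals around 45–50 s per 5-min
  scenario; confinement makes the discard accounting exactly recoverable,
  since background+artifact excursions never otherwise cross ±100 µV at the
  default scales.

Between-subject structure: a multiplicative subject amplitude factor
(SD 0.17, matching between-subject SDs around a third of the mean) and
relative subject-by-condition jitter (SD 0.04) on the theta amplitudes.
When the configured scenario amplitudes are strictly ordered, each
subject's jittered scenario amplitudes are re-ordered to match — the
repeated-measures structure of a graded-workload manipulation without rank
inversions; baseline amplitudes keep their natural jitter so that task-free
contrasts (pre vs post) remain unbiased. Channel gains (fixed topographic
profile, F4/O1/O2 high, T4 low) multiply each channel's whole signal and
produce the channel main effect.

Behavioral tables draw task-load scores (clipped to [0, 100]) and engine
stops (rounded, non-negative) from per-condition normal distributions whose
default means/SDs are those of a 39-driver cohort under the same
three-scenario design (13.31 ± 13.10 / 46.05 ± 19.26 / 35.62 ± 14.73 for
task load; 0.03 ± 0.16 / 0.41 ± 0.64 / 0.15 ± 0.37 for stops). Sleepiness
scores default to the 1–3 (alert) range so the screening stage passes
everyone unless configured otherwise.

All randomness flows from one master seed through per-subject
`SeedSequence`-derived streams; outputs are bit-identical across runs.

### What the generator does not emulate

No volume conduction or biophysical head model (channels are independent up
to the shared EOG projection and gain profile); no non-stationarity within
a condition; no realistic inter-channel correlation of background EEG; the
theta "oscillation" is a stationary sinusoid, not burst-like oscillatory
activity. The subject-by-condition amplitude jitter (4%) is deliberately
small so amplitude orderings are stable; real cohorts of this size show
substantially larger condition-level variability, so F statistics on
synthetic cohorts run higher than a comparable field study would produce.
Passing recovery and calibration tests therefore demonstrates correctness
of the estimators and bookkeeping, not expected effect sizes on real data.

## Validation strategy and problem sizes

- Spectral and ANOVA engines are checked against independent oracles
  (explicit-loop DFT and sum-of-squares references, scipy.welch, pingouin).
- Ground-truth recovery runs a full-scale cohort (35 subjects, three 5-min
  scenarios): EOG propagation recovered within ±0.05, burst discard seconds
  recovered exactly, cohort-mean theta strictly ordered with injected
  amplitude per channel. Per-subject strict ordering is asserted only on
  noise-free output: at realistic SNR the medium-to-high band-power gap
  (~0.1 µV²/Hz) is comparable to single-subject estimation noise, so a
  per-subject assertion would not be statistically meaningful.
- Calibration: under spherical no-effect noise (n=35, k=3, 2000
  replicates) the GG-corrected test rejects at ≈5%; power against the
  default graded-workload effect is estimated on replicate cohorts with
  40-s scenarios (40 replicates) — shortened records raise estimation noise
  slightly but leave the subject-level effect untouched, which keeps the
  simulation inside a practical runtime at the package's chosen problem
  sizes.
- EDF round-trips are verified against an independent reader (mne); the
  writer uses 16-bit EDF with a ±500 µV default physical range (headroom
  over the ±100 µV rejection threshold), counts clipped samples, and never
  clips silently.

## Known limitations

- EDF support is deliberately minimal: integer sampling rates, one data
  record per second, sidecar CSV annotations rather than EDF+ annotation
  channels (a documented dialect choice; how scenario boundaries are marked
  in a recording is acquisition-specific).
- No Huynh–Feldt correction, mixed-effects models, between-subjects
  factors, ICA-based artifact removal, or time–frequency analysis.
- ANOVA on engine-stop counts follows the field's practice of treating
  counts as continuous; a count model would be more principled but is out
  of scope.
- Scenario presentation order is recorded by the generator but order
  effects are not modeled in the statistics.
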