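# Methods

`tempocontext` analyzes how the temporal context of serially presented
visual stimuli — at the scale of the previous event (micro), the last five
events (meso), and the session-long event statistics (macro) — shapes
behavioral and neural responses. Every analysis stage is paired with a
synthetic-data generator that plants known effects, so the package is
validated end-to-end by parameter recovery rather than against any
external dataset. This note documents the models, the defaults and their
rationale, the numerical choices, and the limits of what the synthetic
validation shows.

## Conventions

Angles are degrees in [0, 360), counterclockwise from the rightward
horizontal, fixation at the origin. Signed angular differences (Δ
location) live in (−180, 180]; the 180° boundary maps to +180. Times are
seconds relative to stimulus onset. All randomness flows through explicit
`numpy.random.Generator` objects or integer seeds; identical seeds give
bit-identical outputs.

## Context labeling

Each trial is coded repeat (R) or alternate (A) on three reference planes:
task-related (the judged meridian), task-unrelated (orthogonal), and
stimulus-related (a trial is a repeat when |Δ| < 90°). Measure-zero ties
need conventions: |Δ| = 90° codes as alternate, and an angle exactly on a
task plane yields side 0 and invalidates the trial on that plane.

Meso context classifies the four transitions ending at the current trial
(a five-event window, hence 16 patterns). Patterns are merged with their
R↔A complements into eight classes, so repeat/alternate identity is
balanced within each class, and ranked 1 (final event most expected:
RRRR/AAAA) to 8 (maximal final violation: RRRA/AAAR). The intermediate
ordering is generated by a recency-weighted consistency score: evidence
for a repeat is the weighted sum of the preceding transitions (weights
1..3, most recent heaviest), signed by the final transition, with a
half-point tiebreak for agreement with the immediately preceding
transition. The resulting table (RRRR=1, RAAA=2, RARR=3, RRAA=4, RRAR=5,
RARA=6, RAAR=7, RRRA=8, complements implied) ships as an explicit,
overridable constant; any rank table over the eight canonical patterns
can be supplied where a different expectancy convention is preferred.

Sequence validity: a meso window is dropped when it crosses a block
boundary or contains a reproduction trial among its five events; the
micro transition out of a reproduction trial is likewise invalid by
default (`repro_rule="window_plus_next"`), since the reproduction task
interrupts the stream after the response. `repro_rule="none"` keeps
post-reproduction micro transitions.

Macro labels mark a trial expected when its micro code matches the
majority transition type under the session's repeat probability; an
unbiased session (p = 0.5) defines no macro labels.

## Synthetic-data generator

The generator's defaults encode the study designs the analyses assume:

* **Locations.** Blocks of 100 trials (15–20 blocks in a full session;
  tests use fewer). Trial 1 of each block is uniform; later trials pick a
  side on each meridian by that plane's repeat probability relative to the
  previous trial (0.5/0.5 in the unbiased design; 0.75/0.25 in the biased
  designs, counterbalanced 2 × 2 × 2 over task plane and the two biases),
  then draw the angle uniformly within the selected quadrant. The bias
  therefore shapes transition statistics, not marginal position.
* **Reproductions.** 10% of trials, flagged independently. The reported
  angle errs by a von Mises–uniform mixture (defaults κ = 8, g = 0.1)
  whose mean follows a derivative-of-Gaussian serial-bias curve
  μ(Δ) = a·(Δ/w)·exp((1 − (Δ/w)²)/2), peaking at ±a exactly at Δ = ±w
  (defaults a = 2°, w = 45°; positive a = repulsion).
* **Speeded responses.** RT = t₀ + lognormal (t₀ = 0.25 s, log-mean −1.1,
  log-sd 0.35 → median ≈ 0.58 s) plus an additive +0.03 s on unexpected
  trials; choice accuracy 0.97/0.93 for expected/unexpected. These effect
  sizes are not estimates of any dataset; they are plausible magnitudes
  chosen once so that recovery tests have signal.
* **Pupil.** 1 kHz trace = slow drift (smoothed noise, ~5 s correlation
  length, generated at 2 Hz and interpolated) + per-event gamma-shaped
  dilation peaking 1 s post-event, amplitude 1 + 0.5·surprise (surprise:
  macro unexpected = 1; meso (rank−1)/7) + white noise, with Poisson
  blink episodes zeroed to a sentinel (0) and listed explicitly.
* **Sensor epochs.** −0.125..0.5 s at 512 Hz (tests downscale the rate;
  the drift mechanism is rate-invariant). Per trial:
  `amplitude · gain(context) · W·c(θ)` times a gamma-shaped evoked kernel
  rising after 0.05 s and peaking at 0.12 s, with expected stimuli delayed
  by a configurable 0.02 s; plus spatially correlated Gaussian noise and
  an AR(1) across-trial drift (coefficient 0.99, stationary sd
  `drift_sd`) projected on a fixed random sensor pattern, constant within
  an epoch. The drift is the simplest process that reproduces the
  low-frequency repeat-classification bias the shuffle correction targets.

What the generator does **not** emulate: head-geometry sensor covariance,
eye-position artifacts, non-stationary noise, reproduction motor noise,
or behavioral learning curves. Passing recovery tests therefore shows the
*analyses* are correct and well-calibrated under their stated assumptions,
not that real recordings satisfy those assumptions.

## Behavioral analyses

Condition summaries use median RT and mean accuracy after removing trials
with RT > 2 s. Group-level estimates pass once through a 1.5 × IQR fence.
Recall errors are fit by maximum likelihood to
p(e) = (1−g)·f_vM(e; μ, κ) + g/360, with κ ∈ [10⁻³, 200] (bounded in log
space), g ∈ [0, 1], μ ∈ [−180, 180]; L-BFGS-B from one moment-based start
plus nine seeded random restarts; at least 30 responses per fit. κ is
reported as log₁₀κ. The serial-dependence curve bins errors by Δ into 12
equal bins over (−180, 180] (the bin count matches the Δ-binned decoding
analyses; it is configurable because the behavioral bin count is a free
choice) and fits the mixture per bin. Effect sizes are the matched-pairs
rank-biserial correlation (zero differences dropped, ties mid-ranked) and
tie-corrected Kendall's W; the standard tests themselves (Wilcoxon,
Friedman, Levene) are delegated to scipy.

## Pupil preprocessing

Chain, in order: blink masking (sentinel samples or episode list, 0.1 s
buffer), MAD outlier masking (>2.5 unscaled MADs; a zero MAD masks
nothing and warns), linear interpolation (edge gaps take the nearest
value), zero-phase first-order Butterworth filtering, z-scoring,
epoching to −0.5..1.5 s, baselining to the 0.5 s pre-event mean, and
downsampling 1000 → 125 Hz by decimation (the post-decimation baseline
mean is re-subtracted, so retained epochs are exactly zero-mean over the
baseline window). Epochs with more than 50% masked samples are rejected.

Two documented deviations from a literal reading of the printed recipe:

1. **Filter band.** A 15.6 Hz high-pass would eliminate the ~1 s
   dilations the analyses measure, so 15.6 Hz is interpreted as the
   low-pass (smoothing) edge by default; any band, including the literal
   one, is available via `low_cut`/`high_cut`. A 500 Hz edge at a 1 kHz
   rate sits on Nyquist and is clipped just below, with a warning.
2. **Z-score scope.** Per-session z-scoring (standardize the whole
   filtered recording, then epoch) is the default: per-epoch z-scoring
   normalizes each epoch by its own dilation-dominated variance and
   demonstrably erases planted between-condition amplitude ratios — the
   recovery test fails under it. Per-epoch scoring remains available
   (`zscore_scope="epoch"`).

Condition analyses: Spearman correlation between pupil value and an
ordinal sequence rank at each time point, and expected-minus-unexpected
difference waveforms, both per participant, feeding the 1D cluster test.

## LDA decoding and shuffle correction

Side-of-plane labels are decoded per time point by a Gaussian linear
discriminant with pooled *diagonal* covariance and equal priors
("diaglinear" semantics; the paradigm presents both sides equiprobably),
ten-fold stratified cross-validation, fold assignment fixed across time
points, variances floored at 1e−12. The per-time-point fit is vectorized
over the time axis.

Slow across-trial drift makes temporally proximal trials look alike, so a
classifier leaks the predecessor's label and repeat trials score above
chance without any stimulus information. The correction subtracts a
shuffle baseline: the identical cross-validation repeated with labels
permuted (default 100 times, seeded). Crucially, condition splits that
are *functions of the label sequence* (repeat/alternate, the eight
sequence classes) are recomputed from each shuffled sequence — with
fixed splits the baseline would stay flat at chance and miss exactly the
bias being corrected. Fixed, label-independent splits (e.g. macro
expectedness by session bias) stay fixed across shuffles. Corrected =
raw − baseline, chance-centered at 0, and corrected + baseline = raw
holds exactly.

The alternative drift control high-passes the across-trial signal at
0.7 Hz per (sensor, time point), treating the trial index as a time axis
at the presentation rate (default 1/0.3 s); its temporal smearing across
neighboring trials is a documented caveat.

## Inverted encoding model

Forward model: B = WC + E with five channels peaking every 72°, each a
half-wave rectified sinusoid raised to the fifth power (the printed
profile). Per-channel least squares on demeaned data gives
wᵢ = B cᵢᵀ (cᵢ cᵢᵀ)⁻¹ (a joint multivariate solve is available; the two
differ when channel responses correlate, which the overlapping basis
induces). The per-channel training residuals define
Σ̂ᵢ = εᵢεᵢᵀ/(n−1), shrunk toward the scaled identity with the analytic
Ledoit–Wolf intensity λ ∈ [0, 1] (computed in-package so the estimator
matches the (n−1) covariance convention; sklearn's estimator is the test
oracle). Spatial filters vᵢ = Σ̃ᵢ⁻¹wᵢ/(wᵢᵀΣ̃ᵢ⁻¹wᵢ) satisfy vᵢᵀwᵢ = 1
exactly. Decoding converts channel estimates to an angle by the phasor
sum z = Σ cₖ e^{ipφₖ}, θ̂ = arg(z)/p.

Design choices and caveats:

* **Periodicity.** The printed equations double the angle (p = 2), the
  convention for 180°-periodic orientation; spatial location is
  360°-periodic, so p = 1 is the default and p = 2 remains available.
* **Aliasing of the printed basis.** The rectified fifth-power profile
  has Fourier energy at harmonics n ≡ 1 (mod 5), so with five channels
  the phasor decoder carries a deterministic, angle-dependent bias of up
  to ~13.8° even on noiseless data (a unit test freezes this curve
  against a brute-force oracle). It averages out over uniform angles and
  does not affect condition contrasts, but it caps pointwise accuracy. A
  harmonically band-limited raised-cosine alternative
  (`half_angle=True, exponent=6`, harmonics 0..3 only) decodes exactly;
  the end-to-end algebra-identity test uses it — together with
  orthonormal encoder weights and rotation-symmetric folds, so that the
  inversion chain is the only possible error source — and recovers
  presented angles to <1e−6°.
* **Circular summaries.** Accuracy r̂ = Re[R̄], precision from the angular
  deviation σ̂ = √(2(1−|R̄|)), and bias arg(R̄), each per Δ bin (12 bins,
  equal-weight pooling over non-empty bins; presentation-weighted pooling
  is a config option). The printed precision normalization
  p̂ = 1 − 2σ̂/√2 maps a uniform decode distribution to −1 rather than the
  stated floor of 0; both the printed (default) and a rescaled variant
  p̂ = 1 − σ̂/√2 (uniform → 0) are provided.

## Cluster-based permutation inference

Pointwise statistic across participants (default: one-sample matched
rank-biserial; mean and t available), thresholded two-sidedly at α = 0.05
against the same sign-flip permutation ensemble (n = 5000 by default;
paired designs reduce to sign flips of condition differences). Cluster
mass is the summed statistic over contiguous supra-threshold runs. The
null is the distribution of the *maximum* summed cluster value per
permutation, taken across both polarities; its 95th percentile is the
single cluster threshold, which keeps the two-sided family-wise error at
α (separate per-polarity 95% thresholds would double it — the FWER
simulation in the acceptance suite verifies the implemented choice). The
2D variant first smooths along the circular feature axis (uniform kernel,
size 4, wraparound), then clusters with 4-connectivity, wrapping along
features only; smoothing commutes with participant-level sign flips, so
it is applied once to the inputs.

## Problem sizes used in the validation suite

The test and acceptance runs downscale freely where the quantity under
test is scale-invariant: sensor epochs at 32–64 Hz with 8–12 sensors,
sessions of 240–1920 trials, 25–100 label shuffles, 200 replicates at
1000 permutations for the FWER checks, and 20-seed recovery runs for the
mixture model (n = 2000) and drift correction. These sizes were chosen so
each check has the statistical power its tolerance requires.

## Known limitations

* The meso expectancy ordering between the anchor classes is a
  convention; analyses that depend on the intermediate ranks should
  treat the table as a configurable assumption.
* The IEM's printed basis/decoder combination carries the aliasing bias
  described above; absolute per-angle decoding claims should use the
  band-limited basis or more channels.
* `highpass_epochs` assumes evenly spaced presentations when treating the
  trial axis as time.
* The cluster procedure's pointwise cluster-forming rule (two-sided, same
  permutation ensemble) is one defensible choice among several; it is
  configurable and its operating characteristics are verified only for
  the defaults.
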