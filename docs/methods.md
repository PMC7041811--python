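# Methods

This note documents the models, conventions and numerical choices behind
`equispine`, what the synthetic generators do and do not emulate, and the
limitations a user should keep in mind.

## Coordinate conventions and the horse frame

All marker positions live in a right-handed world frame with the vertical
axis +z, in millimetres.  Every angle is computed in a *horse frame* built
per frame from the data themselves: x̂ is the unit horizontal direction of
travel — the smoothed velocity of the tuber sacrale marker — ẑ is vertical,
and ŷ = ẑ × x̂ points to the horse's left.  Heading smoothing is a 0.5 s
moving-regression slope (Savitzky–Golay, polynomial order 1, first
derivative): long enough to suppress the within-stride oscillation, short
enough to track the turning heading on a ~10 m lunge circle.  Because the
frame is heading-based, all reported angles are invariant to translating
the scene and to rotating it about the vertical axis, and straight lines
and circles are processed identically; this invariance is asserted in the
test suite at 1e-6 degrees.

Sign conventions follow the right-hand rule about the frame axes: pelvic
roll positive = right side down (rotation about x̂), pelvic yaw positive =
nose-left (about ẑ), pelvic pitch = sagittal inclination of the tuber
sacrale → inter-coxae midpoint, positive upward.  Back angles are the
signed deviation from collinearity of the two projected spine segments
(positive = apex below the chord sagittally / left of it dorsally, with the
cranial marker leading).  Body tracking is positive when the forehand
tracks right of the direction of travel; head swivel is positive for
cervical bending to the right.  Range of motion is sign-independent, so
these choices affect plots and signed means only.

## Filtering

A zero-phase (forward–backward) 4th-order low-pass Butterworth at 30 Hz is
applied to every marker coordinate before any geometry.  Zero-phase
filtering is chosen because a causal filter's group delay would shift
stride timing; the price is that the effective magnitude response is the
squared Butterworth magnitude.  The filter is digital (bilinear transform),
so its exact gain at frequency f is `1 / (1 + (tan(πf/fs)/tan(πfc/fs))^(2n))`
per pass — the tests use this closed form, not the analog `(f/fc)` one,
which is badly wrong near Nyquist.  Stride-band content (≤ 5 Hz) passes
with gain ≥ 0.99.

Marker gaps are never interpolated into results.  For filtering only, gaps
are bridged linearly so the IIR filter does not ring; every frame inside a
gap stays flagged invalid, and any stride containing an invalid frame of a
needed marker is dropped for the parameters that need it.

## Stride segmentation

At trot the trunk bounces twice per stride, so the vertical sacrum
trajectory has two minima per stride, while pelvic roll completes exactly
one cycle.  Boundaries are placed at the minima of the 10 Hz-filtered
sacrum height (minimum spacing 0.6 of the dominant oscillation period,
found by FFT) at which pelvic roll is increasing — a deterministic rule
that uses only markers this pipeline records.  If roll carries no phase
information (a rigid-pose trial), every second minimum is used instead;
the phase is then arbitrary but consistent.  Trials shorter than 2 s, or
with less than 5 mm of sacrum oscillation half-range, yield an empty
segmentation rather than an error.

A measurement is kept only if it has **more than five complete strides**
(complete = no parameter lost to gaps); the threshold is configurable
(`min_strides`, default 6).  Measurement means weight strides equally.
Stride frequency is the mean of per-stride reciprocal durations.

## Lean correction

On the circle the horse leans into the turn, which would corrupt projection
angles computed in gravity-aligned planes.  The body lean angle is
estimated per stride as the stride-mean (uncorrected) pelvic roll, and the
frame's transverse axes are rotated about x̂ by that angle (piecewise
constant per stride).  By construction the corrected pelvic roll has zero
stride mean; on simulated lunge trials with a constant 10° lean the
residual stride-mean roll is below 0.1° (machine precision in practice).

## Variability model

The between-measurement variability analysis asks: how much does a repeated
trot-up of the same horse under the same condition vary?

1. *Offset adjustment*: within each horse × path × surface cell, the mean
   over that horse's available measurements (M1–M12) is subtracted,
   centring each cell at zero.  This removes the (large) between-horse
   differences and any constant condition effect.
2. *Transform*: the outcome is y = √|d|.  Absolute deviations are strongly
   right-skewed; the square root makes the mixed-model residuals
   acceptably symmetric.
3. *Model*: y ~ day (3-level factor, reference day one) + within-day
   repetition index (numeric 1–5; days one/two have five repetitions, the
   recheck two) + path (reference straight) + surface (reference soft),
   random intercept per horse, REML.  Interactions are not estimable by
   design — circles are never measured on the hard surface — and models
   are not reduced.  Coding day as a factor plus a *numeric* within-day
   repetition index keeps both effects estimable (a full measurement-number
   factor would be aliased with day) and lets a monotone
   variation-vs-repetition trend appear as a single slope.  Speed can be
   added as a linear covariate; when it is, per-condition predictions are
   evaluated at the condition's own mean speed, since circles are ridden
   slower than straights and a common overall mean would leak the speed
   term into the condition contrasts.
4. *Prediction limits*: on the sqrt scale,
   `limit_y = x'β̂ + z₀.₉₇₅ · √(σ̂²_horse + σ̂²_resid)`, with x encoding each
   condition at reference day one and the mean repetition index, squared
   back to original units.  Deviations are zero-centred, so the interval is
   symmetric and only the upper limit is reported, plus the arithmetic mean
   over the four conditions.  This marginal construction (fixed-effects
   mean, total variance, normal quantile; a t quantile is available via
   `use_t`) back-transforms with no bias correction; analytically it sits
   ~1.3 % above the true 97.5th percentile of |d| for half-normal
   deviations, which the Monte-Carlo acceptance test confirms.

Wald t-tests for the fixed effects use a between-within (containment)
denominator df, `n_obs − n_horses − (rank − 1)` — every covariate here
varies within horse.  This is a deliberate approximation standing in for a
Satterthwaite computation (the fitting backend does not expose the REML
information needed); the `df_method` column flags it, and a 1000-simulation
null study in the acceptance suite shows the resulting type-I error is
within the binomial 95 % band around 0.05 for this design size.

Numerical care: REML fits frequently sit at the zero-variance boundary
(offset adjustment removes most horse-level signal).  The default L-BFGS
optimizer can fail or silently return a spurious boundary solution there,
so two optimizers are run and the higher restricted likelihood wins, with
derivative-free fallbacks; an all-constant outcome short-circuits to exact
least squares with both variances zero.  Rank-deficient designs raise an
error naming the aliased columns rather than fitting silently.

## Repeatability (ICC)

Per parameter and condition, measurement means (non offset-adjusted) are
modelled as value ~ 1 + (1 | horse) by REML and
ICC(1) = σ²_horse/(σ²_horse + σ²_resid).  On balanced data this equals the
classical one-way ANOVA estimator (MSB − MSW)/(MSB + (k−1)MSW); the tests
assert agreement to 3 decimals.  Estimates at the boundary are reported as
0 with a `truncated` flag.  Cells without at least two horses with two
repetitions are marked unavailable.  Note the estimator's first-order
small-sample bias, ≈ −2(1−ρ)(1+(k−1)ρ)/(k(H−1)); at H = 12 horses, k = 12
repetitions and ρ = 0.9 this is −0.017, visible in recovery simulations.

## Synthetic generators: what they emulate, and what not

**Marker simulator** (`simulate_trot_markers`).  Kinematic, not dynamic:
angle waveforms are *prescribed* and marker positions constructed so that
the pipeline's own definitions recover them exactly — back-bending via a
chord-perpendicular apex displacement h = c·tan(θ/2) with T15 midway along
the withers–sacrum chord, the pelvic triad built directly from the roll /
pitch / yaw waveforms.  The trot's phase structure is respected (vertical
displacement, back flexion-extension and pelvic pitch at twice stride
frequency; lateral bending, pelvic roll and yaw at stride frequency), the
body is advected along a straight line or circle with the physical bank
angle atan(v²/gr) by default on the lunge, and Gaussian marker noise
(default 3.2 mm, the magnitude of a typical optical-capture calibration
residual) plus optional constant marker-placement offsets can be added.
Default magnitudes are medians typical of over-ground trot (0.75 s stride,
3.79 m/s soft straight, pelvic roll ROM 9.66°, whole-back flexion-extension
ROM 4.98°, 14 strides per straight trot-up).

Not emulated: soft-tissue artefact (noise is white, real skin displacement
is stride-coherent), within-stride speed fluctuation, spinal curvature
matching the circle, asymmetric/lame gait patterns, and inter-marker
correlation of noise.  Consequently a green recovery test establishes that
the *pipeline* is correct, not that real-data accuracy equals the
noise-free tolerances; with the default 3.2 mm noise the small angular ROMs
are biased upward (noise range adds to signal range), exactly as marker
noise does in real recordings.

**Study simulator** (`simulate_measurement_dataset`).  Measurement means
for 12 horses (configurable), 5+5+2 measurements over three days, four
conditions, three horses missing the recheck by default.  Values are
condition mean + horse effect N(0, σ²_horse) + residual whose SD is scaled
by a day factor (default ×1.5 at the recheck) and a within-day repetition
slope (default −0.05 per repetition).  Day and repetition act on the
*residual scale*, not as mean shifts: the variability model measures
dispersion, and only dispersion effects produce the recoverable signatures
(more variation at the recheck, less with repetition) that motivate them.
Default variance components give ICC 0.8 and prediction limits near 1°
(0.4 m/s for speed), and between-horse spread exceeds within-horse spread,
so study-level outputs are magnitude-realistic.  Horse effects are drawn
independently per parameter; real parameters are correlated within horse.

## Data formats

Trajectories: C3D (optional `ezc3d` extra) or a self-describing TSV dialect
(first line `# sampling_rate_hz <rate>`, then one `<label>_X/_Y/_Z` column
triple per marker; gaps = empty fields).  TSV write→read round-trips
bit-exactly.  Measurement tables: CSV or XLSX, one row per horse × day ×
measurement × path × surface, one column per parameter, with a column-name
mapping hook; hard-surface lunge rows are rejected (the protocol has none).
Marker-role → label maps are YAML.

## Known limitations

* Stride segmentation assumes a clear double-bounce trot pattern; walk or
  canter trials will segment wrongly rather than fail loudly.
* The prediction-limit construction is one defensible reading of
  "intervals on the transformed scale"; computing limits on the original
  scale, or at covariate values other than (day one, mean repetition),
  shifts results by a few percent.
* The between-within df approximation is slightly liberal for effects with
  little within-horse replication; for this design simulation shows
  nominal behaviour, but other designs should re-check.
* ICC confidence intervals, two-way ICC forms, interaction terms and any
  lameness-specific modelling are out of scope.
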