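# Methods

This note documents the models, estimators, numerical conventions, and
design choices behind `pointkin`, and what the synthetic-data generator
does and does not emulate.

## Data model and coordinate frame

A trial is a uniformly sampled (default 400 Hz) multi-marker record:
fingertip (LED1), button channel (LED2, on while the answer button is
held), and both shoulders (LED3/LED4), plus metadata (participant,
condition ∈ {left-addressee CP, right-addressee CP, NCP}, target, block,
raw reaction time). All positions are millimetres in a body-centred frame:
origin at the fingertip's button-press position, x right→left along the
shoulder line (its horizontal trace is the reference for all axial
angles), y front→back, z bottom→up. Times are seconds internally;
milliseconds appear only in reported quantities.

Invariants enforced at ingestion: strictly increasing timestamps uniform to
1 ns of the nominal period, finite coordinates, and exactly one true→false
transition of the button channel (the release). The on-disk dialect is
plain CSV (one file per trial plus a manifest); floats are written in
shortest round-tripping form and read with correctly rounded parsing, so
write∘read is the identity.

## Kinematics

**Filtering.** The position filter is the single-coefficient exponential
smoother `xx_i = xx_{i-1} + (x_i − xx_{i-1})·c` with `c = 0.1`, applied per
axis and initialised at the first sample. A literal two-tap variant
(`xx_i = x_{i-1} + (x_i − x_{i-1})·c`, a one-sample blend with essentially
no smoothing) is available behind `recursive=False`; the recursive form is
the default because a 2-tap blend provides no meaningful noise rejection at
400 Hz. Note a consequence documented by the test suite: the recursive
smoother at `c = 0.1` (time constant ≈ 22.5 ms) widens measured movement
durations by roughly 10 ms through second-order phase distortion at the
threshold crossings (≈ 2τ²·v″/|v′|). This bias is a property of the filter
chain, not of the segmentation rule, and cancels out of between-condition
comparisons.

**Velocity.** Tangential speed is the norm of the per-axis central
difference (one-sided at the boundaries) scaled by the sampling rate. The
output has the same length as the input.

**Segmentation.** Onset = first sample with speed ≥ 5 % of the trial's
peak, searched from the series start; offset = first sample after the
global peak below 5 %, or the final sample with a logged warning if speed
never falls back. Thresholds are relative, so segmentation is invariant to
uniform velocity rescaling. A trial is invalid when more than one distinct
peak exceeds half the global maximum; *distinct* requires a prominence of
at least the 5 %-of-peak threshold (`scipy.signal.find_peaks`), because a
strictly-local-maximum count splits the flat top of a bell profile into
several "peaks" under quantisation-level noise. Both fractions live in
`RunConfig` and are reported with results.

**Temporal parameters.** `cRT = RT_raw + (t_onset − t_release)`;
`dur = t_offset − t_onset`; `ttp = t_peak − t_onset`; `maxvel` the peak
tangential speed; `distance` the straight-line norm between the segmented
endpoints; `meanvel = distance/dur`. A detected onset preceding the button
release flags the trial invalid (logged with provenance).

**Time-normalised trajectories.** Twenty points at
`t_onset + k·dur/20, k = 1…20`, positions linearly interpolated between
raw samples (at 400 Hz the interpolation error is far below the 0.1 mm
spatial resolution). The final point coincides with the offset sample.

**ANOVA.** Condition effects (on temporal parameters, and per trajectory
point and axis) use a one-way repeated-measures ANOVA on per-participant
condition means: the condition mean square is tested against the
participant-by-condition interaction. The sums of squares are computed in
closed form (vectorised across the 20 points); when the condition sum of
squares vanishes the convention F = 0, p = 1 applies (a generic fitter
returns 0/0 there). The implementation is cross-checked against
`statsmodels` `AnovaRM` in the test suite. A within-item analysis is the
same computation with item replacing participant.

## Endpoint ellipses

Endpoints are the filtered fingertip positions at movement offset,
projected to the horizontal x–y plane; the analysis uses the central,
rotationally symmetric target so that neither target shape nor array axis
biases the scatter.

**Outlier rule.** Per participant and condition, Cook's distance from an
intercept-only fit of each coordinate: leverage `h = 1/n`,
`D_i = (e_i²/s²)·h/(1−h)²` with `s²` the unbiased residual variance; a
point is excluded when either coordinate exceeds 0.25, in a single pass.
The cutoff interacts with n: at the default 20 endpoints per cell it
excludes points beyond ≈ 2.1 SD (≈ 4 % of a Gaussian cloud — the default
synthetic experiment excludes 4.0 %); below ~10 points it becomes
aggressive, so ellipse cells should contain at least that many trials. A
joint Mahalanobis rule was considered and rejected: the intercept-only
form is the simplest model consistent with measuring each endpoint's
influence on the overall distribution, and it treats the axes
symmetrically.

**Ellipse.** Unbiased sample covariance, eigen-decomposed; λ₁ ≥ λ₂ ≥ 0,
orientation = axial angle of the λ₁ eigenvector in [0°, 180°). "First
eigenvalue" normalisation divides Σ by λ₁ (size is dominated by the major
axis), leaving orientation unchanged with λ₁ = 1. Per-condition averages
are element-wise means of the normalized matrices, re-decomposed.
Near-isotropic ellipses (λ₂/λ₁ > 0.999) carry a `degenerate` flag; their
orientation is meaningless and they are dropped from averages with a
logged warning. For plotting, semi-axes are `sqrt(λ·χ²₂(0.95))`; no
statistic depends on that scaling.

**Axial arithmetic.** Orientations are lines, not vectors: differences are
`min(|a−b|, 180−|a−b|) ∈ [0°, 90°]`. Trunk orientation is the axial angle
of the horizontal projection of the shoulder-to-shoulder vector at
movement onset.

## Monte-Carlo orientation test

The observed statistic mirrors the estimation chain exactly: per-subject
normalized covariances → across-subject average per condition → axial
difference of the two average-ellipse orientations. Under the null
hypothesis that a subject's two condition samples come from one
population, each simulation redraws, per subject and with replacement, n
and m points from that subject's pooled union (n, m = the subject's
original per-condition counts, which may differ after outlier exclusion),
rebuilds both averages, and records the simulated difference;
`p = N/n_sims` with ties at floating-point resolution counted as
exceedances (no +1 correction, so `p·n_sims` is integer). Subject-level
draws come from independently spawned generator streams, so results do not
depend on subject iteration order and a fixed seed reproduces the
exceedance count bit for bit. Simulated iterations with a degenerate
average ellipse are redrawn (up to 100 rounds, counted and logged);
per-subject singular draws (all resampled points identical) are likewise
redrawn.

Properties established by simulation in the test suite: type-I error
3.8 % at nominal 5 % over 500 null datasets (10 subjects × 20 points,
1,000 resamples — the union bootstrap is mildly conservative), and power
increasing with true separation at fixed n. One caveat: under a *large*
true separation the pooled union itself becomes nearly isotropic, which
widens the simulated null and makes power plateau rather than p → 0; even
orthogonal configurations yield p ≈ 0.03 at study scale rather than
arbitrarily small values. This is intrinsic to union resampling (as
opposed to label permutation) and should be kept in mind when reading
small observed p-values. The trunk-angle variant applies the same
resampling scheme with axial circular means (computed on the doubled-angle
circle) as the per-condition summary.

## Synthetic experiments

The generator emulates the study design, not the biomechanics: 10
participants × 300 trials in 30 blocks (10 per condition, each of the 5
cross-arranged targets twice per block, order randomised per block;
condition cycle rotated across participants for counterbalancing).

Per trial the fingertip travels from the button position to the sampled
endpoint along a circular arc (default 15 mm vertical lift) traversed at
minimum-jerk speed *along arc length* — the parametrisation matters: it
guarantees the tangential-speed profile is exactly the single-peaked
minimum-jerk bell regardless of path curvature (a naive additive vertical
lift modulates tangential speed and splits the flat peak). `duration_ms`
(default 600 ± 50 ms) denotes the span between the 5 %-of-peak speed
crossings — the quantity the segmentation measures — so the underlying
movement lasts `duration/√(1−√0.05)` and ground truth is directly
comparable to the pipeline output. Endpoints add a per-condition 2-D
Gaussian deviation given by orientation (defaults 72.8°/112.7°/100.4° for
left-CP/right-CP/NCP), eigenvalue ratio (0.25), and major-axis SD (10 mm);
marker noise is isotropic with SD 0.03 mm (the quantisation noise of a
0.1 mm-resolution tracker, 0.1/√12); the button releases a uniformly
sampled 10–40 ms before movement start; shoulders sit at a fixed trunk
pose with ~1° angular jitter, identical across conditions. An optional
per-condition bias ramp (x shift at movement end, z bump at movement
start, off by default) provides a positive control for the pointwise
trajectory ANOVA.

Not simulated: addressee behaviour, audio instructions, naming responses,
biomechanical arm dynamics, corrective submovements, or any mechanism that
produces real outliers — so passing recovery tests demonstrates estimator
correctness under the assumed generative model, not robustness to real
motor behaviour.

## Problem sizes and tolerances

Orientation recovery uses 10,000 endpoints per condition (±1°; the
asymptotic orientation SE at axis ratio 0.25 is ≈ 0.4°). Calibration uses
500 independent datasets of 10 subjects × 20 points with 1,000 resamples
each; power ordering uses 40 replicates at study scale with 2,000
resamples per pairwise test. Segmentation accuracy is assessed on 1,000
noise-free randomised trials against generator ground truth at a
2-sample (5 ms) tolerance for duration and time-to-peak; with noise, the
time-to-peak estimator degrades first because the bell is flat at its
peak (argmax jitter grows as the square root of noise over curvature),
which is why `ttp` tolerances under noise are quoted as medians, not
maxima. Brute-force oracles (explicit covariance sums, 2×2 closed-form
eigenstructure, hand-evaluated Cook's distances) agree with the
implementation to 1e-12 on small inputs.

## Known limitations

- The filter-induced duration widening (~4 samples at defaults) means
  absolute temporal parameters are systematically long; comparisons across
  conditions are unaffected.
- The union-resampling null is conservative and its power saturates at
  large true separations (see above).
- Cook's cutoff 0.25 is only sensible for cells of roughly 15+ endpoints.
- Degenerate (near-isotropic) endpoint clouds cannot contribute an
  orientation; the pipeline drops them from averages rather than guessing.
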