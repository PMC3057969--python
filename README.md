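# pointkin

Kinematics and endpoint-variability analysis of repeated 3D pointing
gestures, for motor-control and social-cognition experiments that compare
*communicative* pointing (directing an addressee's attention to an object)
with *non-communicative* pointing (reaching toward an object with nobody to
address).

When a person points repeatedly at the same target, the final fingertip
positions scatter into an anisotropic 2-D cloud. The shape and, above all,
the **orientation** of that cloud is informative: the major axis of the
endpoint "tolerance ellipse" reflects the reference frame used to plan the
movement, and it rotates when the pointing gesture acquires a communicative
role. `pointkin` implements the full analysis chain from raw 400 Hz marker
trajectories to a Monte-Carlo test of ellipse-orientation differences
between conditions, plus a synthetic-experiment generator with known ground
truth.

## The analysis

For each trial (fingertip marker sampled at 400 Hz, 0.1 mm resolution):

1. **Filter** each coordinate with the exponential smoother
   `xx_i = xx_{i-1} + (x_i − xx_{i-1})·c`, `c = 0.1`.
2. **Segment** the movement by the relative velocity threshold: onset at the
   first sample where tangential speed reaches 5 % of the trial's peak,
   offset at the first sample after the peak below 5 %. Trials with several
   prominent velocity peaks are invalid (target-selection errors).
3. **Temporal parameters**: corrected reaction time `cRT` (button-release →
   detected-onset gap added to the recorded RT), duration `dur`, time to
   peak velocity `ttp`, peak speed `maxvel`, straight-line `distance`, and
   `meanvel = distance/dur`; each compared across conditions with a one-way
   within-subject ANOVA.
4. **Trajectories**: 20 points per movement at equal time fractions,
   compared pointwise across conditions (per-axis repeated-measures ANOVA).
5. **Endpoint ellipses** (central target): after excluding outliers with
   Cook's distance > 0.25 (intercept-only model per coordinate), the 2×2
   covariance Σ of the (x, y) endpoints is computed per participant and
   condition; each Σ is normalized by its largest eigenvalue λ₁, the
   normalized matrices are averaged across participants, and the
   average-ellipse orientation θ ∈ [0°, 180°) is the axial angle of the
   dominant eigenvector against the frontal-plane axis.
6. **Monte-Carlo orientation test**: for conditions *a*, *b* the statistic
   is the axial difference Δθ = min(|θₐ−θ_b|, 180−|θₐ−θ_b|). Under H₀ each
   subject's two samples (n and m endpoints) are redrawn with replacement
   from their pooled union; both average ellipses are rebuilt per
   simulation, and `p = N / n_sims` where `N` counts simulations with a
   difference at least as large as observed (10,000 simulations by
   default). The same scheme tests trunk-orientation angles from the
   shoulder markers.

## Worked example

```python
import pointkin as pk

config = pk.GeneratorConfig(seed=1)          # 10 participants x 300 trials
trials = [trial for trial, _ in pk.generate_trials(config)]

run = pk.RunConfig(n_permutations=10_000, rng_seed=1)
tables, report = pk.analyze_trials(trials, run)

print(f"{report.n_ingested} trials, {report.n_valid} valid, "
      f"{report.n_outliers_excluded} endpoint outliers excluded "
      f"({100*report.n_outliers_excluded/report.n_central_endpoints:.1f}%)")
print(tables["condition_ellipses"][["condition", "orientation_deg"]]
      .round(1).to_string(index=False))
print(tables["permutation"].query("kind == 'endpoint'")
      [["pair", "observed_diff_deg", "p_value"]].round(3).to_string(index=False))
```

Output:

```
3000 trials, 3000 valid, 24 endpoint outliers excluded (4.0%)
condition  orientation_deg
  left_cp             72.9
 right_cp            124.2
      ncp            105.1
               pair  observed_diff_deg  p_value
left_cp vs right_cp             51.339    0.000
     left_cp vs ncp             32.192    0.000
    right_cp vs ncp             19.147    0.001
```

The generator's default endpoint models place the three conditions'
ellipse axes at 72.8° (left-addressee pointing), 112.7° (right-addressee),
and 100.4° (non-communicative); the pipeline recovers each per-condition
orientation from the simulated endpoints (sampling noise at 20 endpoints
per participant accounts for the deviations above), and the pairwise
Monte-Carlo tests flag the orientation differences. `p_value` is the
fraction of 10,000 union-resampled datasets whose average-ellipse
difference reached the observed one.

The same pipeline is available from the shell:

```bash
pointkin generate --out data/ --seed 1
pointkin analyze --data data/ --out results/ --seed 1
pointkin report --run results/
```

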