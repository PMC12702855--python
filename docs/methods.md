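# Methods

This note documents the models, parameters and numerical conventions behind
`strokekin`, and what the synthetic study conditions do and do not establish
about real recordings.

## Task model and synthetic cohort

One hand-to-mouth (HTM) trial is modelled as four straight-line minimum-jerk
sub-movements of the wrist (start → marker → mouth → marker → start), each a
quintic `x(τ) = x0 + Δ(10τ³ − 15τ⁴ + 6τ⁵)` that starts and ends at rest,
separated by dwell pauses. Defaults: 100 Hz sampling (desk-scale speed;
configurable), 1.2 s per sub-movement, 0.3 s dwells, 0.5 s lead-in/tail.
Joint angles follow per-sub-movement minimum-jerk transitions between
waypoints; the elbow is an affine function of shoulder elevation plus
band-limited (1–4 Hz) coordination noise. Joint torques and muscle forces
are smooth sin²-windowed bursts over the sub-movements they serve, plus a
distinct tonic baseline per muscle and a small nonspecific
postural-stabilization component in every sub-movement (no muscle is silent
during movement). Muscle fiber velocities are proportional to the conjugate
joint's angular velocity with anatomically signed gains (shortening
positive: elbow flexors shorten in phase 2, lengthen in phase 3).

A scalar impairment `s ∈ [0, 1]` (patients: Beta(2,2); controls: 0) drives
five effects, with slopes exposed in `GeneratorConfig.impairment_effects`:

| effect | default at s=1 | consequence |
|---|---|---|
| `work` | −70% effort amplitude | smaller \|W\| |
| `smoothness` | 18% RMS signal-dependent 4–10 Hz motor noise | lower SPARC |
| `cocontraction` | +1.5 N common antagonist baseline | higher CCI |
| `coordination` | 8° elbow-angle noise SD | lower IC |
| `trunk` | ×1 of the per-phase extra lean (up to +10 cm·eq) | higher TD |

The 4–10 Hz noise band sits above voluntary-movement bandwidth and below
the SPARC cutoff, so it degrades smoothness without shifting movement
durations. Muscle-force noise is multiplicative (motor noise grows with
activation), which keeps forces positive by construction and leaves
co-contraction overlap driven by the baseline effect rather than by noise.
Per-subject log-normal multipliers (SD 0.2) on trunk amplitude and
coordination-noise level, drawn independently per phase, provide the
between-subject, between-phase variability without which phase-level
features of one family would be collinear across subjects and sparse-truth
recovery untestable. `noise_scale=0` disables all within-trial stochastic
components.

FMA-UL labels are `round(clip(26 + Σ w_f z_f + ε, 0, 66))` with
cohort-standardized features, default sparse weights
`{TD_2: −3.5, IC_elb_elv_3: +2.5, TD_3: −2.0}` and `ε ~ N(0, 1.5)`. The
defaults place the patient median at ≈26 points; the published cohort's IQR
(2.5) is far narrower than these weights produce (≈9), but a near-constant
label would make an R² near 0.9 uninformative, so the spread is left to the
weight magnitudes and is fully configurable.

**What passing tests do not show about real data.** The generator's
deficits are monotone by construction, its channels carry no sensor
artefacts, soft-tissue motion, EMG crosstalk or model-calibration error,
and its label map is exactly linear-in-features. Results here validate the
*pipeline* (segmentation accuracy, metric correctness, leakage-freeness,
recovery of a known sparse truth) — not the clinical effect sizes, which
require real cohorts.

## Segmentation

Wrist speed is the norm of the central-difference derivative of position.
Onset/offset are the first/last crossings of 10% of peak speed (the
conventional reaching-kinematics threshold; configurable). Within
[onset, offset] the four largest peaks separated by ≥0.3 s are retained;
each interior boundary is the deepest speed minimum between consecutive
peaks, the earliest sample on ties — dwell samples have exactly zero speed
in the noise-free case, so this convention assigns a dwell's start to the
following boundary. Diagnostics (peak prominences, valley depths) replace
the human visual-verification step with an auditable record, and trials
with fewer than four qualifying peaks raise an error carrying the count.
Each generated trial stores its analytically known events (closed-form
threshold crossing of the quintic speed profile; first all-dwell sample for
valleys), so recovery is scored against truth computed independently of the
discrete pipeline.

## Biomarkers

- **Work**: trapezoidal `∫ effort·rate dt` over the phase window; windows
  share their boundary sample, making work exactly additive over adjacent
  phases. Angles are stored in degrees and converted to rad/s only inside
  the work computation. Body-mass normalization is available as a flag and
  off by default (raw joules).
- **SPARC**: zero-pad to the next power of two × 2⁴, normalize the
  magnitude spectrum by its zero-frequency value, set the cutoff `f_c` to
  the largest frequency ≤ 10 Hz where the normalized magnitude still
  reaches 0.05, and return the negated discrete arc length over [0, f_c]
  with the frequency axis scaled by 1/f_c. Parameters are the method's
  canonical defaults. The zero-frequency normalization is part of the
  definition implemented here; for windows whose mean is near zero it
  inflates the metric, so the generator keeps a nonzero DC level in every
  channel. A constant-spectrum degenerate case (only DC above threshold)
  returns 0, the smoothest possible value.
- **CCI** `= 2∫min/∫sum` of the two force series — bounded [0,1],
  symmetric, invariant to joint rescaling. The underlying studies cite an
  overlap integral without printing it; this form is adopted as the
  bounded, unit-free realization consistent with reported value ranges.
- **IC**: sample Pearson correlation of elbow and shoulder-elevation angles
  over the phase; constant windows raise an error rather than return NaN.
- **TD**: `100 · max_t ‖sternum(t) − sternum(t₀)‖` cm, reference at trial
  start; the peak (not mean) excursion matches the forward-lean
  compensation reading of trunk involvement.

Per-trial vectors hold exactly 112 named features in a fixed family-major
order; the subject-level vector is the mean of trials 2–4 of 5
(chronological middle three).

## Group statistics

Shapiro–Wilk at α = 0.05 per group gates each feature into the pooled
(Student) t-test — the pooled form reproduces the published demographic age
p-value (0.513 vs 0.512) better than Welch (0.502) — or the Mann–Whitney U
test with tie-corrected normal-approximation p and no continuity
correction; with all observations tied the variance vanishes and p = 1. An
exact-U option exists for small samples. BH-FDR is applied across all 112
features as one family. Cohen's d uses the (n−1)-weighted pooled SD with
the healthy group first; published d values cannot be reproduced exactly
from rounded summaries under any single pooling convention, so only a
±0.15 band is asserted (the published table even prints different d for
two rows with identical summaries). Recomputation is closest when the
patient group is all 65 subjects, which is what the comparison defaults to.

## Prediction protocol

Standardization lives inside the pipeline, so scaler parameters (and any
RFE selection, off by default) are fit on training partitions only. Nested
CV: 5 outer folds for internal metrics, an inner 5-fold grid search on R²
inside each outer training partition for tuning (fold counts shrink
automatically for desk-sized cohorts). The hyperparameters of the final
refit come from a grid search over the whole development cohort — the
deterministic reading of "fix the optimal values identified during
cross-validation". Lasso α grid: 30 points log-spaced 10⁻³…10¹ on
standardized features; tree-ensemble grids are deliberately small (they are
baselines, not the core). Ties on mean R² resolve toward the sparser model
class (lasso > elastic net > ridge > linear > trees), mirroring the
accuracy-with-interpretability selection rule. Zero-variance training
features get unit scale with a warning instead of an error. Test evaluation
verifies subject-id disjointness and computes R² about the test-set mean.
Only linear pipelines are persisted (plain-JSON scaler + coefficients);
the comparison's winner is always linear in practice.

**Recovered support.** A lasso refit on integer-valued labels always
carries a few coefficients of ≲0.1 points/SD that absorb the ±0.5
quantization residue (they persist, smaller, even for unrounded labels).
The package therefore reads "selected features" at a floor of 0.25 FMA
points per standardized unit — an order of magnitude below the smallest
ground-truth weight and at the quantization scale; any floor between ~0.15
and ~1.5 yields the same set on the default conditions.

## Explanation

For the linear pipeline the interventional Shapley value has the closed
form `φ_ij = β_j (x̃_ij − mean_background(x̃_j))` with the background fixed
to the development cohort; the base value is the mean background
prediction, and additivity (`base + Σφ = f(x)`) holds to machine precision
— asserted, along with agreement with an exhaustive 2^p-coalition
enumeration on small problems. Global importance is mean |φ|; per-subject
force breakdowns list the top-k signed contributions plus an exact
remainder. SHAP for the tree baselines is out of scope: only the
representative (winning, linear) model is explained.

## Determinism and problem sizes

All randomness flows from one root seed through named substreams (profiles,
per-subject heterogeneity, per-trial noise, label noise, CV folds), so two
runs with the same configuration and seed produce byte-identical artifacts
(floats are written with 17 significant digits, which round-trips IEEE
doubles exactly). The shipped study conditions — 85 subjects × 5 trials at
100 Hz, 112 features, 10 protocol replicates in the audit suite — keep a
full test run and the acceptance script in the minutes range on one core;
every size is configurable upward.

## Known limitations

- The generator emits torque/force channels directly with the statistical
  structure the biomarkers need; it performs no musculoskeletal simulation,
  so absolute magnitudes (e.g. triceps work in joules) are plausible rather
  than anatomically derived.
- Segmentation uses the speed profile only; position gating to the
  marker/mouth geometry is deliberately not used, since real deployments
  may not know it.
- Phase-4 inter-joint coordination in the generator is strongly positive,
  unlike the near-zero published healthy value — the affine elbow–shoulder
  coupling is a simplification; no test asserts phase-4 IC levels.
- The Mann–Whitney p matches one specific convention (asymptotic, tie
  corrected, no continuity correction); statistical packages differ at the
  third decimal for small n.
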