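# Methods

`glyvar` implements a complete post-hoc-trial-style analysis of visit-to-visit
HbA1c variability and glycemic-control targets, exercised end-to-end on a
synthetic cohort with known generative truth. This note records the models,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic validation does and does not establish about real data.

## Variability metrics

For a patient with HbA1c measurements `v_1..v_n` ordered by visit time:

* **HVS** (HbA1c variability score) = `100 * #{i : |v_{i+1} - v_i| > 0.5} / (n-1)`.
  The comparison is strict (a change of exactly 0.5 percentage points does not
  count). The customary verbal definition of the score is ambiguous about the denominator
  ("among all measurements" suggests `n`, "changes" suggests `n-1`); we default
  to the number of successive intervals `n-1` — a change requires a pair — and
  expose `hvs_denominator={intervals,measures}`. Duplicate visit timestamps are
  an error, not silently averaged.
* **SD** = ordinary sample standard deviation (`n-1` denominator; a
  `ddof` switch is provided).
* **Mean HbA1c** = arithmetic mean of all visit values, baseline included.
* **VIM** (variation independent of the mean)
  `VIM_i = popmean^x * SD_i / mean_i^x`, with `x` the OLS slope of `log SD`
  on `log mean` across patients and `popmean` the mean of patient means.
  Patients with `SD = 0` are excluded from the exponent fit (log undefined)
  and counted. By construction VIM is approximately uncorrelated with the
  patient mean — its defining property, asserted in the tests.

Patients with fewer than two measurements have no computable HVS/SD and are
excluded up front with a per-patient logged reason; the sensitivity mode
additionally drops follow-up shorter than `min_followup_years`.

## Variability grouping

Patients are partitioned in `(HVS, SD)` space — `(HVS, VIM)` in the
sensitivity variant — by K-means, K-medians, and rank tertiles. Features are
z-scored first (`scale: zscore`, switchable): HVS spans 0–100 while SD spans
roughly 0–2, so unscaled Euclidean clustering would be HVS-only.

K-means is Lloyd's algorithm with k-means++ seeding, 20 restarts, exact
assignment-fixpoint convergence (max 300 iterations), ties in nearest-centroid
assignment broken toward the lowest label, and empty clusters repaired by
re-seeding at the point farthest from its assigned centroid. K-medians uses L1
assignment and coordinate-wise median updates with the same scaffolding. Both
objectives are non-increasing per iteration (asserted on the stored trace).

Quantile (tertile) grouping assigns by rank with stable tie handling: a block
of tied values is never split across a boundary; if ties collapse a group a
warning is emitted.

Internal validation indices — Silhouette (singletons scored 0),
Davies-Bouldin, Calinski-Harabasz — are implemented from their definitions and
cross-checked against naive O(n²) oracles to 1e-8 in the tests. `select_k`
scores k = 2..9 and picks the k maximizing the combined rank of Silhouette
(higher better) and Davies-Bouldin (lower better); Calinski-Harabasz is
reported but not used in the combination; the exact combination rule is a
declared convention of this package. For large cohorts the
pipeline evaluates the Silhouette on a deterministic subsample (default
2,000 points); the other two indices are always exact.

Whatever k wins the table, the analysis grouping uses k = 3 ordered by
within-cluster mean HVS into low/medium/high — three groups are the
scientific object here, and the selection table is reported alongside.

## Survival modeling

All effect estimates come from right-censored Weibull accelerated failure
time models, `log T = Xβ + σW` with `W` standard minimum-Gumbel, fit by
damped-Newton maximization of the exact log-likelihood with analytic gradient
and Hessian (quasi-Newton fallback, then re-polished; gradient at the optimum
below 1e-6 on the internally standardized scale). Continuous covariates are
standardized internally and mapped back, making fits invariant to affine
rescaling. The covariance is the inverse observed information on
`(β, log σ)`.

Because the Weibull family is simultaneously proportional-hazards, effects
are reported as hazard ratios via `HR = exp(-β/σ)` with delta-method 95%
intervals and Wald p-values. AIC/BIC use the exact identities
`2p - 2ll` and `p log n - 2ll` (the log-likelihood includes the `-Σ d log t`
Jacobian so it is the density of `T`, matching standard survival software).

**Stratified treatment effects**: one adjusted fit per variability group
gives the per-group treatment HR; the interaction p-value is a 2-df
likelihood-ratio test of pooled models with/without treatment-by-group
terms; the trend p is a Wald test on a treatment-by-ordinal-group (0/1/2)
coefficient. Adjustment covariates default to age, sex, BMI, systolic blood
pressure, eGFR, and smoking — synthetic analogues of the usual
cardiovascular adjustment set.

## Threshold (two-piecewise) analysis

The exposure (per-patient mean HbA1c) enters either linearly or as hinge
terms `min(x, K)` and `max(x - K, 0)`, continuous at `K` by construction.
`K` is estimated by profile likelihood over a fixed grid (step 0.01
percentage points) spanning the 5th–95th exposure percentiles, snapped to an
absolute lattice so that shifting all exposures by a lattice multiple shifts
`K̂` identically; ties resolve to the smallest K. The two slopes are reported
as per-1% hazard ratios, and curvature is tested by a 1-df LRT of the hinge
model against the single line. The 1-df convention ignores the data-driven
selection of `K̂` and is mildly anti-conservative; the type-I simulation in
the test suite bounds the realized rate accordingly.

The 95% CI for `K` is a patient-level percentile bootstrap (default 500
resamples; 200 minimum). Each replicate repeats the profile search with
staged grids (step 0.2, then 0.05 within ±0.2 of the coarse argmax; the
replicate values feed only percentile quantiles, so 0.05 resolution is
ample against CI widths of ~0.3), warm-started from the full-data solutions;
replicate fits stop when the predicted Newton gain falls below 0.3
log-likelihood units, leaving the returned profile value second-order
accurate (~0.01), far below the between-K differences that decide an argmax.
Segments with fewer than 30 events are flagged as sparse rather than
suppressed. More than 20% failed replicate searches is an error.

## Smooth dose-response curves

A natural cubic spline of the exposure (df = 4; boundary knots at the
observed range, interior knots at quantiles; unpenalized) sits in the AFT
linear predictor next to the covariates. The curve is reported as
`HR(x) = exp(-(s(x) - s(x_ref))/σ)` with pointwise delta-method bands;
the reference is the exposure median, where the HR is exactly 1 — this
normalization also resolves the spline's intercept identifiability. With
df = 1 the curve collapses exactly to the one-piece log-linear model
(asserted). Among the many ways to define a "GAM-style" smooth here, an
unpenalized modest-df spline inside the same AFT likelihood keeps one
estimation machinery for every analysis.

## Synthetic cohort generator

The generator emulates a two-arm glycemic-control trial in high-risk type 2
diabetes at realistic trial scale and produces every downstream input with
recoverable planted truth.

* **Scale and arms**: 10,000 patients, half randomized to intensive
  control. Baseline HbA1c ~ N(8.3, 1.0)%.
* **Trajectories**: exponential approach from baseline toward arm-specific
  long-run targets (6.4% intensive, 7.5% standard — typical achieved
  levels under the two strategies), half-life 4 months, plus stationary AR(1) visit shocks
  (ρ = 0.3). Visits at months 0, 2, 4, 6, 8, 10, 12 then every 4 months to
  60, guaranteeing at least four first-year measurements; the later
  calendar is an assumption. Values clipped to the plausible open interval
  (3, 20)%.
* **Variability strata**: a hidden three-component mixture of shock SDs
  (0.15, 0.45, 0.90)% with weights (0.447, 0.390, 0.163), sized like the
  variability groups such trials report. The stratum drives both the visit-to-visit
  volatility *and* the treatment effect on outcomes, encoding
  treatment-effect modification by variability as generative truth.
* **Outcomes**: Weibull proportional hazards (shape 1.2), time in years.
  The log hazard adds (i) a piecewise-linear effect of the patient's
  full-schedule mean HbA1c with stratum-specific breakpoints and slopes,
  (ii) a stratum-specific treatment log-HR, (iii) small covariate effects.
  Default effect settings encode the reference study conditions as
  generative truth: MACE treatment HRs (0.78, 1.3, 2.0) across strata; mortality hinge
  (0.49 below / 1.57 above) at 7.44% in the medium stratum and
  (0.63 / 1.01) at 7.86% in the high stratum; linear effects elsewhere.
  Baseline rates are calibrated to trial-realistic crude incidences
  (≈ 10% MACE, ≈ 7% death over ~5 years).
* **Censoring and follow-up**: administrative at 5 years; a 15% dropout
  fraction is censored Uniform(3, 5) years, giving a median follow-up
  near 4.8 years. All-cause death ends follow-up and censors MACE.
* **Visit truncation** is off by default: visits are emitted over the full
  schedule regardless of outcome timing, so the measured mean HbA1c equals
  the generative exposure. With truncation on (`truncate_visits_at_followup`),
  early deaths' observed means are dominated by the elevated early-decay
  visits, inducing a strong spurious mean-mortality association (an
  immortal-time artifact worth studying, but fatal to recovery checks) —
  this is also a caveat for follow-up means computed on real data.
* **Reproducibility**: all randomness flows from one master seed through
  named per-variable substreams with fixed draw counts per patient, so the
  cohort is byte-stable under serialization and enlarging `n_patients`
  leaves existing patients unchanged.

Known departures from real data, hence limits of what green tests show:
covariates are drawn independently of the variability stratum (no baseline
confounding — in real cohorts the high-variability patients smoke more,
weigh more, etc.), there is no per-visit hypoglycemia stream, no competing-risk coupling
beyond death-censors-MACE, and HbA1c noise is Gaussian AR(1) rather than
assay/biology-driven. Passing recovery tests demonstrates the estimators are
correct under a correctly specified data model; estimates from any
particular real trial depend on restricted-access data and are not
reproduced here.

## Problem sizes used in validation

Simulation studies in the test suite use the sizes that make their targets
estimable at desk scale: single fits at n = 10,000; interaction-detection
replicates at n = 12,000 (25 replicates, with a 200-replicate null
calibration at n = 900); breakpoint recovery at n = 6,000 (25 replicates,
plus 50 bootstrap-coverage replicates at 200 resamples each); smooth-curve
checks at n = 8,000; byte-reproducibility of the pipeline demonstrated at
n = 1,200 alongside a full-scale default run. The full default pipeline run
(n = 10,000, 8 threshold cells with 200 bootstrap resamples each) takes a
few minutes on one core.

## Degenerate inputs and edge behavior

Zero-spread feature columns, coincident Davies-Bouldin centroids, duplicate
points under Calinski-Harabasz, rank-deficient designs (collinear columns are
named), empty arm-by-group cells, breakpoints outside the observed exposure
range, and all-equal quantile values are errors or warnings with explicit
messages rather than silent results. Non-converged AFT fits are flagged and
refused by downstream conversions.
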