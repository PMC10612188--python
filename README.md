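# glyvar

Visit-to-visit HbA1c variability analysis for glycemic-control cohorts:
variability metrics, machine-learning variability grouping, and
survival-model answers to the question *"what glucose-lowering target is
safest for which patients?"*

Large trials of intensive glucose lowering in type 2 diabetes produced
conflicting answers, and visit-to-visit HbA1c variability is a prime
suspect for the heterogeneity: patients whose HbA1c is low *and stable* do
well under intensive control, while patients with volatile HbA1c may be
harmed by it. `glyvar` packages the full analysis pipeline for studying
this question, exercised end-to-end on a synthetic trial-scale cohort with
known generative truth so that every estimator is validated by recovery.

## What it computes

* **Variability metrics** per patient: the HbA1c variability score
  (HVS — the percentage of successive changes > 0.5 percentage points),
  the SD of all measurements, the mean HbA1c over follow-up, and VIM
  (variation independent of the mean, `popmean^x · SD / mean^x` with `x`
  fitted so VIM is uncorrelated with the mean).
* **Variability groups**: K-means and K-medians in standardized (HVS, SD)
  space plus rank tertiles; Calinski-Harabasz, Davies-Bouldin, and
  Silhouette indices implemented from first principles; k selected over
  2–9 by combined Davies-Bouldin + Silhouette rank; the 3-cluster solution
  ordered into low/medium/high variability by mean HVS.
* **Survival models**: right-censored Weibull accelerated failure time
  regression by exact maximum likelihood (analytic gradient and Hessian).
  Because the Weibull AFT is also proportional-hazards, effects are
  reported as hazard ratios, `HR = exp(-β/σ)`, with delta-method CIs.
  Treatment effects are estimated per variability group with a 2-df
  likelihood-ratio interaction test and an ordinal trend test.
* **Threshold effects**: two-piecewise (hinge) models of mean HbA1c with a
  profile-likelihood inflection point `K`, a patient-level percentile
  bootstrap CI for `K`, per-1% hazard ratios below/above `K`, and a 1-df
  curvature LRT.
* **Smooth dose-response curves**: natural-cubic-spline (df = 4) hazard
  ratio curves normalized to HR = 1 at the median exposure.
* **Synthetic cohort generator**: arm-dependent HbA1c trajectories with a
  hidden low/medium/high volatility mixture, Weibull survival outcomes
  whose treatment effect depends on the hidden stratum and whose log
  hazard is piecewise-linear in mean HbA1c, plus administrative censoring
  and dropout — all byte-reproducible from one seed.

## Worked example

```python
import glyvar as gv
from glyvar.pipeline import RunConfig, run_full_analysis

cfg = RunConfig(simulate=gv.CohortParams(seed=7), seed=7)
bundle = run_full_analysis(cfg, out_dir="results/run7")

print(bundle.treatment_effects.query("method == 'kmeans' and outcome == 'mace'")
      [["group", "hr", "ci_low", "ci_high", "interaction_p"]])
```

On the default 10,000-patient synthetic cohort this prints

```
  group      hr  ci_low  ci_high  interaction_p
    low  0.6712  0.5434   0.8556          0.000
 medium  1.0413  0.8562   1.2491          0.000
   high  1.5193  1.1958   1.9302          0.000
```

— the planted pattern: intensive treatment is protective for MACE in the
low-variability group, useless in the medium group, and harmful in the
high group, with a decisive treatment-by-variability interaction. The
threshold report for all-cause mortality in the medium group shows the
planted U-shape: a hinge at `K ≈ 6.9` with per-1% hazard ratios ≈ 0.19
below and ≈ 1.07 above the inflection and curvature p ≈ 0.003, i.e. below
the inflection a *higher* mean HbA1c predicts *lower* mortality. The
group summary mirrors the construction: mean HVS ≈ 3.5 / 30.3 / 60.2 and
mean SD ≈ 0.34 / 0.65 / 1.00 across the low/medium/high groups, with the
high-variability group the smallest (~22%).

The same stages are scriptable from the shell:

```bash
glyvar simulate --n 10000 --seed 7 --out data/
glyvar metrics --visits data/visits.csv --out metrics.csv
glyvar cluster --metrics metrics.csv --method kmeans --k-range 2:9 --seed 7 --out cl/
glyvar fit --patients data/patients.csv --assignments cl/assignments.csv --outcome mace --out fx/
glyvar run-all --seed 7 --out results/
```

## Layout

| module | contents |
| --- | --- |
| `glyvar.metrics` | HVS, SD, mean HbA1c, VIM and the cohort-level VIM exponent fit |
| `glyvar.cluster` | K-means, K-medians, quantile tertiles, validation indices, k selection |
| `glyvar.aft` | Weibull AFT MLE, hazard-ratio conversion, LRT, stratified effects |
| `glyvar.threshold` | hinge models, inflection search, bootstrap CI, curvature test |
| `glyvar.smooth` | spline dose-response hazard-ratio curves |
| `glyvar.cohort` | synthetic trial generator with planted ground truth |
| `glyvar.pipeline` | config-driven orchestration, eligibility, report bundle, manifest |

See `docs/methods.md` for model details, defaults, numerical choices, and
the limits of what the synthetic validation shows.
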