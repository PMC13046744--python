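# rhythmage

Rest-activity rhythms from wrist accelerometry as digital biomarkers of
biological aging: feature extraction, a Gompertz-based biological-age score,
interpretable classification of accelerated aging, association of rhythm
features with systemic inflammation, and counterfactual mediation of
mortality risk through inflammation.

The package is organised as an analysis project: every computation lives in
the library under `src/rhythmage/`, and the numbered scripts under
`analysis/` drive the pipeline stage by stage on a synthetic cohort whose
ground truth is fully known, so each estimator can be validated by parameter
recovery.

## Who this is for

Biostatisticians and digital-health researchers who work with minute-level
actigraphy (ENMO in milli-g) and want a tested, reproducible implementation
of the full chain from raw epoch data to survival-mediation estimates —
without access to restricted cohort data.

## The models

**Cosinor rhythm model.** Minute-level activity is modelled as
`Y(t) = M + A·cos(2πt/τ + φ) + e(t)`: MESOR `M` (rhythm-adjusted mean,
mg), amplitude `A` (half the peak-to-trough extent), acrophase (clock time
of the fitted maximum) and period `τ` (24 h, optionally searched over
[23, 25] h). The nonlinear fit is linearised on `{1, cos ωt, sin ωt}` and
solved by ordinary least squares. Day-level refits give coefficients of
variation; nonparametric metrics (interdaily stability IS, intradaily
variability IV, relative amplitude (M10−L5)/(M10+L5)), intensity features
(MVPA > 100 mg, sedentary < 40 mg, intensity gradient), DFA scaling
exponents, functional PCA scores of the average 24-h profile and a
simplified sleep detector complete the feature vector.

**Biological age.** Two Gompertz proportional-hazards models
`h(t|x) = b·exp(a·t)·exp(x'β)` are fitted per sex: one on (MESOR,
amplitude, acrophase, chronological age), one on age alone. Biological age
BA solves the 5-year cumulative-hazard equality
`H_full(t*; subject) = H_age-only(t*; BA)` in closed form; age acceleration
AA = BA − CA, with AA > 0 labelled accelerated.

**Downstream analyses.** Accelerated vs decelerated aging is classified
with MRMR-selected features and explained with in-house Shapley
attributions (exact enumeration or permutation sampling); z-scored SII
(platelets × neutrophils / lymphocytes) is regressed on feature quartiles
with Benjamini-Hochberg control; and the mortality effect of binary rhythm
exposures is decomposed into natural direct and indirect effects through
SII with a weighting-based natural-effects Cox model,
`proportion mediated = ln(NIE HR)/ln(TE HR)`, and percentile-bootstrap CIs.

## Worked example

```python
import numpy as np
from rhythmage.features import fit_cosinor, nonparametric_metrics
from rhythmage.synth import SubjectParams, simulate_activity_series

params = SubjectParams("demo", mesor=50, amplitude=20, acrophase_h=14.0,
                       noise_sd=10.0)
series = simulate_activity_series(params, days=7, seed=1)
fit = fit_cosinor(series)
npm = nonparametric_metrics(series)
print(f"MESOR {fit.mesor:.1f} mg, amplitude {fit.amplitude:.1f} mg, "
      f"acrophase {fit.acrophase:.2f} h, IS {npm.is_:.2f}")
```

prints

```
MESOR 49.9 mg, amplitude 19.8 mg, acrophase 14.04 h, IS 0.99
```

— the generator's ground truth (M = 50, A = 20, peak at 14:00) is recovered
despite 10 mg epoch noise, and the interdaily stability near 1 reflects a
perfectly day-to-day-stable rhythm (no day-level variability was simulated).

To run the full analysis on the default n = 2000 synthetic cohort:

```bash
python analysis/01_simulate.py --seed 0
python analysis/02_extract_features.py --seed 0
python analysis/03_cosinor_age.py --seed 0
python analysis/04_classify_aging.py --seed 0
python analysis/05_inflammation.py --seed 0
python analysis/06_mediation.py --seed 0
python analysis/07_report.py --seed 0
```

Artifacts (CSV/JSON plus a hash manifest) land in `results/pipeline/`. On
this cohort the gradient-boosted classifier reaches a test AUC of about
0.90, and cosinor amplitude tops the mean-|Shapley| ranking — lower
amplitude pushing predictions toward accelerated aging — consistent with
amplitude being the strongest rhythm input of the generative hazard.

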