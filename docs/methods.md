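# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Cosinor analysis

The single-component cosinor `Y(t) = M + A·cos(2π(t − t_peak)/τ) + e(t)` is
fitted by ordinary least squares on the linearised basis
`{1, cos ωt, sin ωt}` with `ω = 2π/τ`; amplitude and acrophase follow from
the two harmonic coefficients (`A = √(βc² + βs²)`,
`t_peak = atan2(βs, βc)·τ/2π`). The reported acrophase is the clock time of
the fitted maximum in [0, 24); up-mesor, the upward MESOR crossing, is
`acrophase − τ/4 (mod 24)`. The goodness-of-fit pseudo-F is
`(model SS/2)/(residual SS/(n − 3))`. An all-constant series returns
amplitude 0 with the acrophase flagged undefined. Optional period search
minimises the RSS on a 0.05-h grid over [23, 25] h with bounded refinement.
Timestamps are timezone-naive local time; days are midnight-to-midnight
except sleep, which uses noon-to-noon windows.

Day-level coefficients of variation refit each day (≥ 20 h wear) at a fixed
24-h period; CV = population SD / mean, in percent. Circular quantities
(acrophase, up-mesor) use the SD of unwrapped hours over the mean clock
value; a circular-SD alternative would differ only when day-to-day phase
jitter exceeds several hours.

## Nonparametric metrics, intensity, DFA, fPCA, sleep

IS and IV use the standard hourly-binned forms with p = 24 hour-of-day
bins; M10/L5 are the extrema of rolling 10-h/5-h circular means of the
average 24-h profile, and RA = (M10 − L5)/(M10 + L5). MVPA is mean daily
hours above 100 mg, sedentary time below 40 mg during wear; "insufficient
MVPA" means under 150 min/week (150 exactly is sufficient). The intensity
gradient is the OLS slope of ln(minutes) on ln(bin midpoint) over 25-mg
bins spanning 0–4000 mg with empty bins dropped. DFA integrates the
mean-centred minute series and regresses log fluctuation on log window size
over 4 min–2 h (α1) and 2 h–27 h (α2), first-order detrending, ~10
log-spaced sizes per range. fPCA is the SVD of column-centred average 24-h
profiles; each component's largest-|loading| entry is made positive for
sign reproducibility, and fPC1 is excluded from the downstream feature
vector because it tracks overall amplitude. The sleep detector takes, per
noon-to-noon window, the longest run of epochs whose 5-min rolling ENMO is
below 10 mg, bridging interruptions of ≤ 20 min; onset is reported in hours
since the previous midnight (post-midnight onsets exceed 24), efficiency is
the below-threshold fraction of the window, and sleep is flagged irregular
when the SD of nightly duration exceeds 90 min. All thresholds are keyword
arguments.

Wear QC fails a recording with under 72 h of wear or any hour-of-day bin
with no wear at all; the regularity screen drops subjects below the 5th
percentile of IS or above the 95th percentile of IV (linear-interpolation
percentiles), skipped with a warning below n = 20.

## Gompertz proportional hazards and biological age

The hazard is `h(t|x) = b·e^{at}·e^{x'β}` with censored log-likelihood
`ℓ = Σ δᵢ(ln b + a·tᵢ + ηᵢ) − Σ (b/a)(e^{a·tᵢ} − 1)e^{ηᵢ}`. The fit is
parameterised as (ln b, a, β), warm-started by BFGS and polished by Newton
steps with the analytic Hessian to a gradient ∞-norm below 1e−8. |a| <
1e−8 switches to the exponential-limit series to avoid cancellation; `a`
can be pinned (shared-shape or exponential fits). Biological age solves
`H_full(t*) = H_only(BA)` in closed form,
`BA = [ln b_f + ln((e^{a_f t*}−1)/a_f) + η_full − ln b_o −
ln((e^{a_o t*}−1)/a_o)]/γ_age`, with horizon t* = 5 years (configurable)
and an error if the age-only model's age coefficient is not positive.
Models are fitted per sex; both free-shape (default) and shared-shape modes
exist. The module ships estimation machinery only — externally published
coefficient sets can be supplied as `GompertzPH` objects.

## Classification and attribution

Features are standardised, then pruned greedily: while any pair exceeds
|Spearman ρ| = 0.7, the highest-ρ pair loses its lower-relevance member
(relevance = mutual information with the label; name order breaks ties).
The alternative reading of the correlation rule (keep only high-ρ features)
is available via the threshold semantics of `spearman_prune` but the
cluster-collapsing form is the default. MRMR ranks by the
mutual-information-difference criterion with plug-in MI on 8 equal-frequency
bins. The split is stratified 65/15/20; hyperparameters are chosen on the
validation split and the final model retrains on the combined 80%. MCC is
computed from confusion counts at a 0.5 threshold. Measured MESOR is
excluded from the classifier's feature vector: it belongs to the
biological-age model, not the rhythm-feature set, and in synthetic data it
is nearly collinear with amplitude (Spearman ρ ≈ 0.97).

Shapley values use the value function v(S) = E_background f(x_S, B_~S).
Exact mode enumerates all 2^p coalitions (p ≤ 12) and satisfies efficiency
to machine precision; sampling mode is the seeded permutation estimator and
reports per-cell Monte-Carlo standard errors.

## Inflammation GLMs

SII = platelets × neutrophils / lymphocytes; the outcome is z-scored
(sample SD), so coefficients are in SD units. Quartiles use
linear-interpolation percentile cuts with ties assigned downward; Q4 (the
favourable extreme) is the reference and the trend code runs 0 (Q4) to 3
(Q1), so positive trend coefficients mean "worse rhythm, higher
inflammation". Models are Gaussian identity-link OLS fits with Wald 95%
CIs, complete cases only; constant adjustment columns (e.g. a comorbidity
absent from a sex stratum) are dropped. Interaction models use a 4-level
joint factor with the doubly-favourable cell as reference and the reduced
covariate set. BH-FDR is applied within the main-effects family.

## Natural-effects mediation

The estimator is the weighting form of natural-effects modelling: a
Gaussian linear model for the mediator given exposure and covariates
supplies density-ratio weights `f(M|x*, C)/f(M|X, C)` on a dataset expanded
with both hypothetical exposure levels x*; a weighted Cox fit on (x, x*,
C) gives NDE = exp(coef x) and NIE = exp(coef x*), so log TE = log NDE +
log NIE holds by construction. An imputation-based variant was not
implemented; with a survival outcome the weighting form is the tractable
choice, and its validity here is established by simulation (null- and
full-mediation generators) rather than by matching any published table.
Weights can be truncated at the 1st/99th percentiles (off by default; the
estimator warns when max/min exceeds 1e3, and the full-mediation validation
uses truncation in response to that warning). Bootstrap CIs are percentile
intervals over seeded subject resamples; failed replicates are dropped and
more than 10% failures is an error. Exposure dichotomisations: low
amplitude and rhythm irregularity are bottom-quartile indicators, MVPA
insufficiency is the 150 min/week rule. Inside the bootstrap the weighted
Cox fit uses an in-house Newton solver with Breslow ties (a lifelines
backend is available and the two agree to ~1e−5 in tests); the 5+
covariate set (age, TDI, BMI class, employment, shift work) follows the
mediation adjustment set of the analysis design.

## The synthetic cohort generator

The generator is the package's study population; its defaults were fixed
once to emulate the structure of a mid-life wearable cohort and are not
per-test dials.

Per subject: MESOR ~ N(22, 10) mg floored at 5; amplitude ~ Lognormal(4.15,
0.37) mg; acrophase ~ N(13.9, 1.1) h; a fragmented-rhythm phenotype with
probability 0.10 (amplitude shrunk 70%, 30% of hourly blocks shuffled
within each day); bout propensity ~ N(0.5, 0.9) truncated at 0 bouts/day.
Within a day the mean profile is the cosine with an 8-h window opposite the
acrophase suppressed by 80% (night rest); MVPA bouts add ~200 mg for 20
min near the acrophase. Day-to-day variability has three parts: a lognormal
amplitude multiplier with CV 0.65, whole-day "rest days" (probability 0.2,
profile × 0.25), and Gaussian acrophase jitter with SD 1.3 h. Epoch noise
is mean-preserving lognormal (σ = 0.32) with AR(1) persistence (ρ = 0.6)
plus 4 mg additive noise, truncated at zero. A pure amplitude multiplier
could not produce realistic day-level amplitude CVs (zero-clipping
compresses them), and a whole-profile multiplier produced implausible
multi-hour MVPA days; the adopted mixture reproduces day-level amplitude
CVs near 60%, DFA1 near 1.0, fitted amplitude medians in the mid-30s to
-40s mg and afternoon acrophases, at the cost of an MVPA median (~1.3
h/day) above what population cohorts report.

SII is a linear function of true amplitude, fragmentation, male-specific
MVPA and age plus N(0, 150) noise, floored at 10; platelet, neutrophil and
lymphocyte counts are emitted so the SII identity holds exactly. Survival
is drawn by inverse-CDF from the Gompertz PH model (a = 0.09/y, b =
2.2e−3/y) with log-hazard contributions from age, sex, continuous
amplitude, fragmentation, MVPA insufficiency and a male-specific SII path,
censored administratively at 8 years; the defaults yield ~3.5–4.5% deaths.
`null_mediation_config` (exposure → hazard only) and
`full_mediation_config` (exposure → mediator → hazard only) define the
mediation validation conditions. Subject-level draws come from streams
keyed by (seed, subject index), so the first k subjects are identical for
any cohort size; the SII-noise and survival draws use cohort-level streams.

What the generator does **not** emulate: device noise spectra or
calibration error, non-wear patterns beyond simple gaps, weekday/weekend
structure, seasonal effects, or non-sinusoidal rhythm shapes beyond the
night-rest window and bouts. Passing tests therefore demonstrate estimator
correctness under a cosinor-structured world, not robustness to every
real-data pathology.

## Problem sizes and numerical choices

The default demo cohort is n = 2000 subjects × 7 days of minute epochs,
with 200 bootstrap replicates for mediation CIs; recovery checks use n =
5000 with 20 replicates (Gompertz) and 50–150 replicates elsewhere, sizes
chosen so each estimator's sampling error is small relative to its
tolerance. CSV artifacts are written with 10-significant-digit floats and
hashed into a manifest for reproducibility checks. Ties in quartile cuts go
to the lower group; MI bins are equal-frequency with duplicate edges
collapsed; the Cox solver subtracts the max linear predictor before
exponentiation.

## Known limitations

- The sleep detector is a threshold heuristic, not a validated algorithm;
  its outputs are internally consistent but not comparable to
  polysomnography-calibrated pipelines.
- The natural-effects estimator assumes a correctly specified Gaussian
  mediator model and no exposure-mediator interaction; extreme density
  ratios inflate variance and, untruncated, can bias the direct effect at
  moderate n.
- Hazard-ratio non-collapsibility makes the marginal natural-effect Cox
  model an approximation when the mediator effect is strong and events are
  not rare.
- Biological-age estimates inherit the sampling noise of the per-sex
  Gompertz fits; at a few dozen events per sex the rhythm coefficients are
  imprecise, which blurs the accelerated/decelerated label near AA = 0.
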