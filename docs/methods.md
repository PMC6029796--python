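# Methods

## Study design being emulated

The analysis evaluates an ED-nurse-led outreach program for residential
aged care facility (RACF) residents using a two-hospital (intervention /
control), two-period (pre / post) controlled design. The intervention
effect is identified as the hospital-by-period interaction: with two
hospitals and two periods, a separate "intervention" regressor is
numerically identical to that interaction, and the interaction encoding is
the only estimable one, so the design indicator `x3 = x1·x2` is used
throughout (generator and estimators agree on this convention).

## Synthetic data generator

The generator emulates the hospital information-system extracts the
original analysis drew on. Its defaults *are* the study conditions:

* **Design**: 3-month pre and post windows, one catchment of RACF beds per
  hospital (default 1,000 beds, i.e., counts equal rates).
* **Counts**: monthly ED presentations per cell are Poisson with mean
  `rate × beds/1000`; admissions are a per-episode Bernoulli thinning with
  cell probability `admission_rate / presentation_rate`, so monthly
  admissions are Poisson too and never exceed presentations. Within-cell
  overdispersion is not modelled: the analysis models are Poisson, so the
  generator realizes exactly the structure those models assume.
* **Rates and LOS means**: reference-cell values are the published
  adjusted means of the control hospital pre period (ED rate 74.92,
  admission rate 34.38 per 1,000 beds/month; ED LOS 4.19 h, inpatient LOS
  86.24 h), and the multiplicative hospital/period/intervention ratios are
  the published exponentiated coefficients (rates 0.94/0.90/0.83 for
  presentations, 1.17/1.24/0.53 for admissions; LOS 1.37/2.28/0.53 for ED,
  1.10/0.85/0.81 for inpatient). The realized intervention-cell means then
  reproduce the published with-intervention adjusted means (52.72, 26.29,
  6.95 h, 64.95 h).
* **LOS noise**: gamma with fixed shape (scale = mean/shape). The default
  shape of 1 gives a coefficient of variation of 1 — LOS data are strictly
  positive and highly right-skewed, and the source analysis reports no
  dispersion estimate, so CV ≈ 1 was chosen once as a realistic default.
* **Covariates**: age group, gender, triage, diagnosis group, day and time
  are sampled independently from marginal mixes; the defaults are the
  pre-period ED-cohort frequencies (n = 449) of the original study,
  entered as exact count fractions so each mix sums to one. Only marginals
  were published, so no dependence between covariates is modelled;
  `covariate_effects` optionally multiplies LOS means per level (off by
  default) to make covariate adjustment non-trivial in tests.
* **Coherence**: the monthly table is an aggregation of the episode table
  from a single draw, and a fixed seed yields byte-identical CSV extracts.

What the generator does **not** emulate: RACF-level clustering, seasonal
and day-of-week rate structure, covariate–covariate dependence,
covariate-specific admission propensities, and overdispersed counts.
Passing recovery tests therefore demonstrate internal consistency of
estimator and generator under the stated model, not robustness of the
original study's estimates to violations of it.

## Effect models

Implemented as scikit-learn-style estimators over statsmodels GLMs.

* Rate models: Poisson log link, offset `log(beds/1000)`, no patient-level
  confounders — those are undefined at month level, and the published
  confounder adjustment is attached to the LOS models only. Plain
  maximum-likelihood (Wald) intervals; robust errors are not used because
  the source analysis does not report using them.
* LOS models: gamma GLM with log link, confounders entered as categorical
  terms; dispersion estimated by the Pearson method. A constant outcome
  (zero dispersion) falls back to unit scale, which leaves the
  coefficients at their degenerate MLE.
* **Adjusted means**: marginal standardization — every observed covariate
  row is carried to the target design cell and predictions are averaged on
  the response scale. Because the model is log-linear, the covariate
  factor separates from the cell factor; this is exploited for speed. The
  published account says only "adjusted for all other variables";
  standardization over the pooled covariate distribution is the
  reproducible choice, and it is invariant to recoding of category
  reference levels.
* **Intervals for means and differences**: parametric simulation — draw
  coefficient vectors from N(β̂, Cov(β̂)) (default 10,000 draws), transform,
  take 2.5/97.5 percentiles. The delta method was rejected because the
  published difference intervals are visibly asymmetric. The p-value
  attached to the with/without difference is the Wald p-value of the
  intervention coefficient, matching the published tables.
* **Diagnostics**: standardized deviance residuals against fitted values,
  30-bin histogram, normal quantile pairs with rank-averaged ties, and the
  deviance/df and Pearson χ²/df ratios.

## Cost model

All currency is held in IEEE doubles — exact for whole-dollar inputs at
this magnitude — and rounded to whole AU$ (half away from zero, plain
leading minus) only at rendering. Subtotals are summed in ledger order so
the identities A = A1+A2, B1 = B1a+B1b, B2 = B2a+B2b, B = B1+B2+B3,
C = A+B hold exactly in floating point.

Equipment is annuitized with the factor `AF(L, r) = (1 − (1+r)^−L)/r`
(`AF = L` at `r = 0`), written as `−expm1(−L·log1p(r))/r` to remain
accurate as `r → 0⁺`. Lives below one year are clamped to one year: the
deterministic base case treats the equipment as discarded after a year
(the worst-cost assumption), and the sensitivity range for the life starts
at zero, where a straight division would be undefined. Whether the source
analysis annuitized or divided price by life is not stated; the annuity
form with the cited discount-rate range is implemented.

The baseline parameter configuration reproduces the published ledger to
within 0.5% on the utilisation side (the published table used unrounded
regression outputs while the parameter table prints rounded values; the
program-cost side and the ambulance component are exact).

## Probabilistic sensitivity analysis

* 10,000 trials by default; all varied parameters sampled **mutually
  independently** in a fixed order from a single seeded generator, so runs
  are exactly reproducible. Independence is a documented limitation: the
  rate changes `e`, `f` are statistically coupled with the baselines `a`,
  `b` in reality.
* Distribution conventions: Poisson for the monthly rates `a`, `b` with
  mean = baseline (a Poisson has no free variance; the tabulated standard
  errors describe the regression estimates — an alternative normal sampler
  is available via `count_sampler="normal"`); method-of-moments gamma for
  `c`, `d`; normal for the differences `e`–`h` with no truncation (draws
  may flip sign, which is what allows occasional positive net costs);
  ±25% uniform for the ambulance fraction and triangular for unit costs;
  equipment life Uniform(0, 10) clamped to ≥1 before annuitization;
  discount rate Uniform(0, 0.05).
* The whole ledger is evaluated vectorised over trials (parameter fields
  hold arrays), so a 10,000-trial PSA runs in well under a second.
* Summaries: mean, median, sd (n−1), min, max, percentiles by linear
  interpolation between order statistics (NumPy default).
* **Variance contributions**: signed squared Spearman rank correlation
  shares, `sign(ρᵢ)·ρᵢ²/Σρⱼ²·100`; constant inputs contribute 0. This is
  the convention of spreadsheet-simulation sensitivity charts; the exact
  algorithm of the proprietary add-in used originally is unpublished, so
  only the qualitative ranking and signs are comparable.

Under these conventions the simulated net-cost sd is ~8–9% below the
published value and the simulated mean sits near the deterministic total
rather than the (more negative) published PSA mean; both are consistent
with the documented independent-sampling and distribution-assignment
choices, which the published description does not fully pin down.

## Problem sizes and numerical choices

* Parameter-recovery checks use ~5,000 episodes per replicate
  (catchments of 6,300 beds over 3-month windows) and 200 replicates —
  large enough for near-nominal Wald coverage, small enough to run
  comfortably on a laptop.
* Simulation intervals default to 10,000 coefficient draws, computed in
  chunks of 500 to bound memory.
* GLM fits cap IRLS at 200 iterations and raise with the deviance trace
  on non-convergence.
* Extract CSVs are UTF-8 with header; floats round-trip exactly through
  pandas' shortest-repr formatting.

## Known limitations

* No causal claims beyond the difference-in-differences contrast; no
  mixed effects or RACF-level clustering.
* No correlation structure in the PSA; no value-of-information analysis.
* RACF bed costs are deliberately excluded from the ledger (they continue
  regardless of the patient's location), as in the source analysis.
* Inflation indexation is out of scope: all prices are treated as already
  expressed in analysis-year dollars.
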