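# Methods

This note documents the statistical models, algorithmic choices, and
numerical conventions used by the `endotypes` package, together with the
scope of the synthetic cohort generator and known limitations.

## Problem setting

Intensive-care cohorts with traumatic brain injury (TBI) are clinically
heterogeneous. One axis of heterogeneity is chronic comorbidity burden:
patients arrive with pre-existing conditions (heart failure, renal
failure, alcohol abuse, hypertension, ...) that shape survival,
neurosurgical decision-making, and length of stay independent of the
acute injury. The package implements a discovery pipeline that

1. converts ICD-9-CM diagnosis codes into binary Elixhauser comorbidity
   flags,
2. characterizes pairwise comorbidity co-occurrence as a relative-risk
   network,
3. fits binary latent class models to the flag matrix to find
   comorbidity *endotypes* (data-driven patient subgroups),
4. selects the number of classes by an AIC elbow and certifies the
   solution's run-to-run stability by meta-clustering replicate fits, and
5. compares survival, intervention and length-of-stay outcomes across
   endotypes with covariate adjustment and multiplicity control.

## Elixhauser flag construction

ICD-9-CM codes are mapped to the 31 Elixhauser categories of the
enhanced ICD-9 coding table of Quan et al. (2005), embedded as prefix
lists. Matching is dot-free prefix matching: code `4280` matches prefix
`428`. A code may map to multiple categories; unmapped codes are
collected and reported, never silently dropped. The
`combine_hypertension` option merges uncomplicated and complicated
hypertension into a single flag, giving the 30-category representation
used by the latent class model.

Cohort filtering keeps patients with at least one TBI-range diagnosis
(ICD-9 800-801, 803-804, 850-854, 950.1-950.3, 959.01) and retains only
each patient's first admission (date ties break to the smallest
admission identifier). GCS is banded as mild 14-15, moderate 9-13,
severe 3-8; age as young 16-39, middle 40-69, old 70+.

## Co-occurrence network

For categories *i*, *j* with prevalences `P_i`, `P_j`, joint count
`C_ij` and cohort size `N`, the relative risk of co-occurrence is

    RR_ij = C_ij * N / (P_i * P_j),

the observed joint count over the count expected under independence.
The RR confidence interval is the Katz log-normal approximation
`exp(log RR +- 1.96 / sqrt(C_ij))`; it is undefined (NaN) when
`C_ij = 0`. Edge significance uses the two-sided Fisher exact test on
the 2x2 table `[[C_ij, P_i - C_ij], [P_j - C_ij, N - P_i - P_j + C_ij]]`.
The displayed network keeps edges with `p < 0.05` and `RR > 1.5`
(strict), and caps the *display* RR at 5.0 while preserving the true
value in the edge data.

## Binary latent class model

The flag matrix is modeled as a K-component Bernoulli mixture:

    f(x_i) = sum_k pi_k * prod_j rho_kj^x_ij (1 - rho_kj)^(1 - x_ij)

fitted by expectation-maximization on the observed-data log-likelihood.
Numerical conventions:

- responsibilities are computed in log space with log-sum-exp;
- item probabilities are clamped to `[1e-6, 1 - 1e-6]` (EPS), which
  bounds the degenerate-optimum log-likelihood error at roughly
  `n_cells * 1e-6`;
- convergence is declared at relative log-likelihood change `1e-8`,
  capped at 5000 iterations;
- restarts draw initial responsibilities from a flat Dirichlet; the
  best final log-likelihood wins; empty-class draws are redrawn.

An optional burn-in scheme (`burn_iter`) runs every restart for a fixed
number of iterations and lets only the best continue to convergence
(the emEM strategy). It is used for k-range scans (`burn_iter=40`) and
large recovery fits (`burn_iter=50`), where full multistart would
dominate runtime; the plain best-of-restarts scheme remains the
default.

Model size is `m = (K - 1) + K * J` free parameters and
`AIC = -2 log L + 2m`.

## Class-count selection

`fit_k_range` fits a contiguous K range and records AIC per K.
`detect_elbow` min-max normalizes both axes (making the choice
invariant to affine rescaling of AIC), computes each point's
perpendicular distance to the chord joining the first and last curve
points, and selects the distance-maximizing K. Two guards make the rule
well-behaved off the happy path:

- candidate K values are restricted to the decreasing segment of the
  curve (up to the global AIC minimum); the rising overfit tail cannot
  contain an elbow;
- a curve whose minimum is at the first point never improves on the
  smallest K: the smallest K is returned with a `no_elbow` warning flag.

On structureless data (independent flags) the AIC minimum typically
sits at or adjacent to K=1 and the guard collapses the selection
accordingly.

## Stability meta-clustering

The stability check refits the model R=30 times with
distinct seeds (each replicate itself a best-of-3-restart fit, so
replicate variation is not single-start EM noise), pools the R*K
item-probability profiles, and clusters them with a diagonal-covariance
Gaussian mixture (`reg_covar=1e-6`), choosing the number of
meta-clusters G by BIC over 1..G_max (capped at the number of distinct
rounded profiles). The stability score is the fraction of replicates
that contribute *exactly one* profile to each of the top-K
meta-clusters; a fully stable solution has K recurring profiles and
score 1.0. The representative model is the lowest-AIC replicate, and
labels across fits are aligned by optimal assignment (Hungarian
algorithm on squared row distances).

## Outcome comparison

- Rates are percentages rounded half-up to one decimal (`Decimal`
  arithmetic, matching printed-table conventions).
- Pairwise survival/intervention comparisons: Yates-corrected
  chi-squared, falling back to Fisher exact when any expected cell is
  below 1; Holm step-down adjustment within each comparison family.
- Length-of-stay pairs: Welch t tests, Holm-adjusted.
- Adjusted models: logistic regression of outcome on endotype indicator
  variables (chosen reference dropped) plus age, GCS, male sex. On
  separation failures the fit falls back to an L2-penalized likelihood
  (`alpha=1e-4`) and is flagged.
- ANCOVA: sequential (type I) F table for
  `LOS ~ endotype + age + GCS + male` with endotype first; post-hoc
  comparisons are Tukey-Kramer contrasts on the fitted coefficients
  using the studentized-range distribution (statsmodels' Tukey HSD
  works on raw group values, not covariate-adjusted means).
- Model comparison: linear probability models per predictor-set
  specification, nested pairs compared by F test; discrimination
  summarized by AUC.

## Synthetic cohort generator

`generate_cohort` samples class labels from the mixing weights, flags
from the class-conditional Bernoulli profiles, age from truncated
normals on [16, 100], GCS hierarchically (band, then uniform integer
within band), survival and intervention from logistic models with
class-specific intercepts and shared age/GCS/sex coefficients, and LOS
from moment-matched log-normals rounded to 0.1 day. Intercepts are
derived analytically so each class hits its target marginal rate at the
class covariate means. `emit_icd9_codes` writes ICD-9 codes that
round-trip exactly through the mapper (each category emitted via a code
exclusive to it).

The default scenario fixes five classes over the 30 combined
Elixhauser flags — heart failure/arrhythmia (HFA), healthy (HE), renal
failure with hypertension (RFH), alcohol abuse (AA), hypertension (HTN)
— with a 187/1254/136/177/875 split, baseline flag probability 0.03 and
class signatures in 0.50-0.95. The seed drives sampling only; the
scenario structure is fixed.

Calibration notes (documented because they are deliberate):

- small-class signatures use probabilities 0.90-0.95 only, since an
  item probability near 0.5 in a ~260-patient class cannot be estimated
  to +-0.05 (binomial SE);
- the HTN class carries five signature items strong enough that the
  K=4 to K=5 AIC gain clears the chord-distance threshold; weaker
  signatures cause the elbow to merge HTN into the healthy class at
  K=4. As a side effect the HTN mean flag count (~3.5) is higher than a
  real hypertension-dominated subgroup would show (~2.5).

Generator scope: the generator targets the *structure* needed to
exercise the pipeline (latent classes, separable profiles,
class-dependent outcomes), not epidemiological realism. Flags are
conditionally independent given class; real comorbidities correlate
within class. Admission dynamics, repeat admissions, coding noise and
missing data are out of scope.

## Limitations

- The elbow rule is a geometric convention; other knee detectors can
  pick different K on shallow curves. The no-elbow guard makes the null
  behavior explicit rather than principled.
- The stability score is a package definition (the source analysis
  reports no numeric stability metric).
- Bernoulli-mixture recovery tolerances are sample-size bound: at
  n = 2629 the smallest classes cannot support +-0.05 elementwise
  estimation; recovery claims are made at n = 5000.
- The L2 fallback for separated logistic fits shrinks odds ratios
  toward 1; affected fits are flagged rather than silently reported.
- Tukey-Kramer contrasts assume homoscedastic residuals from the
  ANCOVA model; heavy-tailed LOS can distort post-hoc p-values.
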