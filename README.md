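# endotypes

Comorbidity endotype discovery for ICU cohorts: Elixhauser flag
construction from ICD-9 codes, comorbidity co-occurrence networks,
binary latent class analysis with AIC-elbow model selection, replicate
stability meta-clustering, and covariate-adjusted outcome comparison.

## The scientific problem

Patients entering intensive care with traumatic brain injury (TBI)
differ widely in outcome even at similar injury severity. Part of that
variation comes from chronic comorbidity: pre-existing heart failure,
renal disease, substance abuse or hypertension change both baseline
physiology and treatment decisions. Rather than adjusting for
comorbidities one at a time, an *endotype* analysis asks whether
patients fall into a small number of recurring comorbidity patterns,
and whether those patterns stratify survival, neurosurgical
intervention and length of stay (LOS).

The pipeline implemented here:

1. **Flag construction** — map ICD-9-CM diagnosis codes to the
   Elixhauser comorbidity categories (Quan 2005 enhanced table, 31
   categories, optionally merging the two hypertension flags to give
   30), restrict to first TBI admissions, and band age and GCS.
2. **Co-occurrence network** — for every flag pair, the relative risk
   of co-occurrence `RR = C_ij N / (P_i P_j)` with Katz confidence
   intervals and Fisher exact p-values; the reported network keeps
   edges with `p < 0.05` and `RR > 1.5`.
3. **Latent class analysis** — fit K-class Bernoulli mixtures by EM
   with restarts; choose K by the AIC elbow (maximum distance to the
   first-last chord on the normalized curve).
4. **Stability** — refit 30 times, pool the item-probability profiles,
   meta-cluster them with a Gaussian mixture, and score whether each
   replicate contributes exactly one profile to each recurring
   endotype.
5. **Outcomes** — per-endotype survival/intervention/LOS tables,
   pairwise chi-squared and Welch tests with Holm adjustment, adjusted
   logistic models, ANCOVA with Tukey-Kramer post-hoc contrasts,
   age x severity stratified rates, and predictor-set model comparison
   by F test and AUC.

Because the cohort that motivated this design requires credentialed
access, the package ships a synthetic cohort generator with known
ground truth (five endotypes over 30 flags, class-dependent covariates
and outcomes) so every stage is testable end to end. See
`docs/methods.md` for models, numerical conventions and limitations.

## Worked example

```python
import numpy as np
from endotypes import (default_endotype_scenario, generate_cohort,
                       all_pairs, build_network, fit_k_range,
                       replicate_fits, meta_cluster, assign_classes,
                       outcome_table, pairwise_chisq, ancova_los)

# 1. a cohort with known latent structure (or load your own patient
#    table and run build_comorbidity_matrix over its ICD-9 codes)
scenario = default_endotype_scenario(seed=7, n_patients=2629)
patients, matrix, truth = generate_cohort(scenario)

# 2. comorbidity co-occurrence network
pairs = all_pairs(matrix)
net = build_network(pairs, matrix, p_max=0.05, rr_min=1.5, rr_cap=5.0)
print(net.number_of_edges(), "significant co-occurrence edges")

# 3. how many endotypes? AIC elbow over K = 1..8
curve = fit_k_range(matrix, 1, 8, n_restarts=10, seed=0)
print("selected K =", curve.selected_k)          # -> 5

# 4. is the solution stable across refits?
fits = replicate_fits(matrix, curve.selected_k, r=30, base_seed=0)
report = meta_cluster(fits, seed=0)
print(report.n_meta_clusters, "recurring profiles,",
      "stability", report.stability_score)        # -> 5, 1.0

# 5. outcomes across endotypes
best = fits[report.representative_index]
groups = assign_classes(best)
table = outcome_table(groups, patients)
print(table.table[["n", "survival_rate", "intervention_rate"]])
print(pairwise_chisq(table, "survival").results)
print(ancova_los(patients, groups).tukey)
```

The same flow is available from the shell:

```bash
endotypes simulate --n-patients 2629 --seed 7 --out run/
endotypes select --matrix run/comorbidity_matrix.csv --out run/aic.json
endotypes stability --matrix run/comorbidity_matrix.csv --k 5 \
    --out run/stability.json
endotypes report --out run/full   # full pipeline + manifest.json
```

## Reproduction

All quantitative claims are covered by the test suite; stochastic
checks use fixed seeds and spec-level tolerances (e.g. parameter
recovery within 0.05 elementwise in at least 19 of 20 seeds).

```bash
python -m pytest -q tests/                 # full suite
python -m pytest -q tests/test_acceptance.py   # the 7 acceptance criteria
```

The acceptance script recomputes the headline quantities from scratch —
published-table rate reproduction, likelihood-oracle agreement,
parameter recovery error, elbow selections on structured and
structureless data, stability summary, and null-calibration rejection
rates — and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Known published-table inconsistency: one survival cell prints 40.4% for
51/126, which rounds to 40.5 at one decimal; tests assert the
recomputed value and the script reports the discrepancy.

## Layout

- `src/endotypes/elixhauser.py` — ICD-9 mapping, cohort filtering, bins
- `src/endotypes/cooccurrence.py` — RR statistics and network
- `src/endotypes/lca.py` — Bernoulli-mixture EM, information criteria
- `src/endotypes/selection.py` — AIC curve, elbow, replicate stability
- `src/endotypes/outcomes.py` — tables, tests, adjusted models
- `src/endotypes/synthetic.py` — ground-truth cohort generator
- `src/endotypes/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, parameters, numerical choices, limitations
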