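"""Outcome comparison across comorbidity endotypes.

Covers the full outcome surface: per-endotype contingency tables with
printed-style rates, Holm-adjusted pairwise chi-squared and Welch t
tests, covariate-adjusted logistic regression (odds ratios against a
reference endotype), ANCOVA on length of stay with Tukey post-hoc
contrasts, survival rates stratified by age band and injury severity,
nested-model comparison (linear-probability F tests plus AUC and
pseudo-R^2), and the comorbidity-burden regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .elixhauser import bin_age, bin_gcs

logger = logging.getLogger(__name__)

__all__ = ["OutcomeTable", "PairwiseTestSet", "AdjustedModelResult",
           "AncovaResult", "rate_percent", "outcome_table", "pairwise_chisq",
           "pairwise_los_tests", "adjusted_binary_model", "ancova_los",
           "stratified_rates", "model_comparison",
           "comorbidity_burden_model", "auc_score", "holm_adjust"]


def rate_percent(numerator: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (printed-table style)."""
    if total == 0:
        return float("nan")
    pct = Decimal(100 * numerator) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    return multipletests(np.asarray(p_values, float), method="holm")[1]


def auc_score(y_true, scores) -> float:
    """ROC AUC (rank-based, ties count 1/2)."""
    return float(roc_auc_score(np.asarray(y_true), np.asarray(scores)))


@dataclass
class OutcomeTable:
    """Per-endotype outcome counts, rates and LOS summaries."""

    table: pd.DataFrame  # index: endotype; count/rate/LOS columns
    los_values: dict = field(repr=False, default_factory=dict)

    def counts(self, group, outcome: str) -> tuple[int, int]:
        """(events, non-events) for `outcome` in `group`."""
        row = self.table.loc[group]
        if outcome == "survival":
            return int(row["alive"]), int(row["expired"])
        if outcome == "intervention":
            return int(row["intervention"]), int(row["no_intervention"])
        raise KeyError(outcome)


@dataclass
class PairwiseTestSet:
    """All-pairs test results with Holm-adjusted p-values."""

    outcome: str
    results: pd.DataFrame  # group_a, group_b, statistic, p_raw, p_adj, significant
    alpha: float


@dataclass
class AdjustedModelResult:
    """A covariate-adjusted binary-outcome regression."""

    formula: str
    reference: str | None
    terms: pd.DataFrame  # estimate, odds_ratio, ci_low, ci_high, p_value
    n_obs: int
    n_dropped: int
    deviance: float
    pseudo_r2: float
    auc: float
    linear_r2: float
    penalized: bool = False
    extra: dict = field(default_factory=dict)


@dataclass
class AncovaResult:
    """Sequential ANCOVA F table plus Tukey post-hoc contrasts."""

    anova_table: pd.DataFrame
    tukey: pd.DataFrame  # group_a, group_b, difference, se, t, p_adj
    dropped_terms: list[str]
    model: object = field(repr=False, default=None)


def _group_labels(assignments, class_names=None) -> np.ndarray:
    a = np.asarray(assignments)
    if class_names is not None:
        return np.asarray([class_names[i] for i in a])
    return a.astype(str)


def outcome_table(assignments, patients: pd.DataFrame,
                  class_names=None) -> OutcomeTable:
    """Counts and printed-style rates of survival, intervention and LOS
    by endotype. Zero-member endotypes get NaN rates (flagged)."""
    labels = _group_labels(assignments, class_names)
    rows, los = {}, {}
    groups = (list(class_names) if class_names is not None
              else sorted(set(labels)))
    for g in groups:
        sel = patients.loc[labels == g]
        alive = int(sel["survived"].sum())
        expired = int(len(sel) - alive)
        intv = int(sel["intervention"].sum())
        rows[g] = {
            "n": len(sel), "alive": alive, "expired": expired,
            "survival_rate": rate_percent(alive, len(sel)),
            "intervention": intv, "no_intervention": len(sel) - intv,
            "intervention_rate": rate_percent(intv, len(sel)),
            "los_mean": float(sel["los_days"].mean()) if len(sel) else np.nan,
            "los_sd": float(sel["los_days"].std()) if len(sel) > 1 else np.nan,
        }
        los[g] = sel["los_days"].to_numpy()
        if len(sel) == 0:
            logger.warning("endotype %s has no members; rates undefined", g)
    return OutcomeTable(table=pd.DataFrame(rows).T, los_values=los)


def chisq_2x2(a_events: int, a_nonevents: int,
              b_events: int, b_nonevents: int) -> tuple[float, float, str]:
    """Yates-corrected chi-squared on a 2x2 table, falling back to Fisher
    exact when any expected count is below 1. Returns (stat, p, method)."""
    table = np.array([[a_events, a_nonevents], [b_events, b_nonevents]])
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() \
            or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0, "degenerate"
    expected = stats.contingency.expected_freq(table)
    if expected.min() < 1:
        stat, p = stats.fisher_exact(table)
        return float(stat), float(p), "fisher"
    stat, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(stat), float(p), "chi2-yates"


def pairwise_chisq(table: OutcomeTable, outcome: str,
                   alpha: float = 0.05) -> PairwiseTestSet:
    """All-pairs 2x2 tests on a binary outcome, Holm-adjusted."""
    groups = [g for g in table.table.index if table.table.loc[g, "n"] > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty endotypes")
    recs = []
    for a, b in combinations(groups, 2):
        ea, na = table.counts(a, outcome)
        eb, nb = table.counts(b, outcome)
        stat, p, method = chisq_2x2(ea, na, eb, nb)
        if method == "fisher":
            logger.info("pairwise_chisq %s vs %s: expected cell < 1, "
                        "Fisher fallback", a, b)
        recs.append({"group_a": a, "group_b": b, "statistic": stat,
                     "p_raw": p, "method": method})
    df = pd.DataFrame(recs)
    df["p_adj"] = holm_adjust(df["p_raw"])
    df["significant"] = df["p_adj"] < alpha
    return PairwiseTestSet(outcome=outcome, results=df, alpha=alpha)


def pairwise_los_tests(los_by_group: dict, alpha: float = 0.05
                       ) -> PairwiseTestSet:
    """All-pairs Welch two-sample t tests on LOS, Holm-adjusted."""
    groups = [g for g, v in los_by_group.items() if len(v) >= 2]
    recs = []
    for a, b in combinations(groups, 2):
        xa, xb = np.asarray(los_by_group[a]), np.asarray(los_by_group[b])
        if xa.std() == 0 and xb.std() == 0 and xa.mean() == xb.mean():
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        recs.append({"group_a": a, "group_b": b, "statistic": float(stat),
                     "p_raw": float(p)})
    df = pd.DataFrame(recs)
    df["p_adj"] = holm_adjust(df["p_raw"])
    df["significant"] = df["p_adj"] < alpha
    return PairwiseTestSet(outcome="los", results=df, alpha=alpha)


def _design(patients: pd.DataFrame, labels: np.ndarray,
            reference: str) -> tuple[pd.DataFrame, list[str], int]:
    df = pd.DataFrame({
        "age": patients["age"].to_numpy(dtype=float),
        "gcs": patients["gcs"].to_numpy(dtype=float),
        "male": patients["sex_male"].to_numpy(dtype=float),
        "_group": labels,
    })
    n0 = len(df)
    df = df.dropna()
    groups = [g for g in pd.unique(labels) if g != reference]
    for g in sorted(map(str, groups)):
        df[f"endo_{g}"] = (df["_group"] == g).astype(float)
    cols = [f"endo_{g}" for g in sorted(map(str, groups))] + \
        ["age", "gcs", "male"]
    x = sm.add_constant(df[cols])
    return x, cols, n0 - len(df)


def _fit_logit(y, x):
    """ML logit; on separation/non-convergence refit with a small L2
    ridge (alpha=1e-4) and flag the result."""
    import warnings as _w
    model = sm.Logit(y, x)
    try:
        with _w.catch_warnings():
            _w.simplefilter("error", category=RuntimeWarning)
            res = model.fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) \
                or not np.isfinite(res.bse).all():
            raise RuntimeError("logit did not converge")
        return res, False
    except Exception:
        res = model.fit_regularized(alpha=1e-4, L1_wt=0.0, disp=0,
                                    maxiter=500)
        return res, True


def adjusted_binary_model(patients: pd.DataFrame, assignments,
                          outcome: str = "survived",
                          reference: str = "HE",
                          class_names=None) -> AdjustedModelResult:
    """Logistic regression of a binary outcome on endotype indicators
    plus age, GCS and male sex; Wald 95% CIs and odds ratios.

    The reference endotype's indicator is omitted; refitting with a
    different reference changes only the endotype contrasts, never the
    covariate estimates.
    """
    labels = _group_labels(assignments, class_names)
    if reference not in set(labels):
        raise ValueError(f"reference {reference!r} not among endotypes")
    x, cols, dropped = _design(patients, labels, reference)
    y = patients[outcome].to_numpy(dtype=float)[x.index]
    res, penalized = _fit_logit(y, x)
    params = res.params
    try:
        ci = res.conf_int()
        bse = res.bse
        pvals = res.pvalues
    except Exception:  # regularized fit without covariance
        ci = pd.DataFrame(np.nan, index=params.index, columns=[0, 1])
        bse = pd.Series(np.nan, index=params.index)
        pvals = pd.Series(np.nan, index=params.index)
    terms = pd.DataFrame({
        "estimate": params, "se": bse,
        "odds_ratio": np.exp(params),
        "ci_low": np.exp(ci[0]), "ci_high": np.exp(ci[1]),
        "p_value": pvals,
    }).drop(index="const")

    phat = np.asarray(res.predict(x))
    auc = auc_score(y, phat) if len(np.unique(y)) == 2 else float("nan")
    ll = float(np.sum(y * np.log(phat) + (1 - y) * np.log1p(-phat)))
    p0 = y.mean()
    ll0 = float(len(y) * (p0 * np.log(p0) + (1 - p0) * np.log1p(-p0))) \
        if 0 < p0 < 1 else 0.0
    pseudo_r2 = 1 - ll / ll0 if ll0 != 0 else float("nan")
    lin = sm.OLS(y, x).fit()
    return AdjustedModelResult(
        formula=f"{outcome} ~ endotype + age + gcs + male (ref={reference})",
        reference=reference, terms=terms, n_obs=len(y), n_dropped=dropped,
        deviance=-2 * ll, pseudo_r2=pseudo_r2, auc=auc,
        linear_r2=float(lin.rsquared), penalized=penalized)


def ancova_los(patients: pd.DataFrame, assignments,
               class_names=None) -> AncovaResult:
    """ANCOVA of LOS on endotype adjusting for age, GCS and sex, with
    Tukey post-hoc contrasts on the adjusted group means.

    The F table is sequential (type I) with endotype entered first.
    Post-hoc p-values use the studentized-range distribution on pairwise
    endotype contrasts of the fitted linear model (Tukey-Kramer).
    Constant covariates are dropped with a warning.
    """
    labels = _group_labels(assignments, class_names)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least two endotypes")
    df = pd.DataFrame({
        "los": patients["los_days"].to_numpy(dtype=float),
        "age": patients["age"].to_numpy(dtype=float),
        "gcs": patients["gcs"].to_numpy(dtype=float),
        "male": patients["sex_male"].to_numpy(dtype=float),
        "endotype": pd.Categorical(labels, categories=groups),
    }).dropna()

    covars, dropped_terms = [], []
    for c in ("age", "gcs", "male"):
        if df[c].nunique() < 2:
            dropped_terms.append(c)
            logger.warning("ancova_los: covariate %s is constant; dropped", c)
        else:
            covars.append(c)
    formula = "los ~ C(endotype)" + "".join(f" + {c}" for c in covars)
    fit = sm.OLS.from_formula(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("singular design; check endotype/covariate coding")
    anova = anova_lm(fit, typ=1)

    # Tukey-Kramer contrasts on adjusted means via endotype coefficients
    k = len(groups)
    dof = fit.df_resid
    names = list(fit.params.index)
    coef_index = {}
    for g in groups:
        term = f"C(endotype)[T.{g}]"
        coef_index[g] = names.index(term) if term in names else None
    cov = fit.cov_params().to_numpy()
    params = fit.params.to_numpy()
    recs = []
    for a, b in combinations(groups, 2):
        vec = np.zeros(len(params))
        if coef_index[b] is not None:
            vec[coef_index[b]] += 1
        if coef_index[a] is not None:
            vec[coef_index[a]] -= 1
        diff = float(vec @ params)
        se = float(np.sqrt(vec @ cov @ vec))
        t = diff / se if se > 0 else 0.0
        p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, dof))
        recs.append({"group_a": a, "group_b": b, "difference": diff,
                     "se": se, "t": t, "p_adj": min(p, 1.0)})
    return AncovaResult(anova_table=anova, tukey=pd.DataFrame(recs),
                        dropped_terms=dropped_terms, model=fit)


def stratified_rates(patients: pd.DataFrame, assignments,
                     class_names=None, compare=None,
                     alpha: float = 0.05
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survival rates by endotype x age band x GCS severity, plus
    Holm-adjusted two-proportion comparisons between chosen endotypes
    within each stratum.

    Returns (rate table, pairwise test table). Empty strata are excluded
    from testing.
    """
    labels = _group_labels(assignments, class_names)
    df = patients.copy()
    df["_group"] = labels
    df["age_band"] = df["age"].map(bin_age)
    df["severity"] = df["gcs"].map(bin_gcs)
    rows = []
    for (g, ab, sev), sub in df.groupby(["_group", "age_band", "severity"],
                                        observed=True):
        alive = int(sub["survived"].sum())
        rows.append({"endotype": g, "age_band": ab, "severity": sev,
                     "alive": alive, "expired": len(sub) - alive,
                     "survival_rate": rate_percent(alive, len(sub))})
    rates = pd.DataFrame(rows)

    groups = compare if compare is not None else sorted(set(labels))
    recs = []
    for ab in ("young", "middle_aged", "old"):
        for sev in ("mild", "moderate", "severe"):
            cell = rates[(rates.age_band == ab) & (rates.severity == sev)]
            present = cell.set_index("endotype")
            for a, b in combinations(groups, 2):
                if a not in present.index or b not in present.index:
                    continue
                ra, rb = present.loc[a], present.loc[b]
                na, nb = ra.alive + ra.expired, rb.alive + rb.expired
                if na == 0 or nb == 0:
                    continue
                stat, p, _ = chisq_2x2(int(ra.alive), int(ra.expired),
                                       int(rb.alive), int(rb.expired))
                recs.append({"age_band": ab, "severity": sev, "group_a": a,
                             "group_b": b, "statistic": stat, "p_raw": p})
    tests = pd.DataFrame(recs)
    if len(tests):
        tests["p_adj"] = holm_adjust(tests["p_raw"])
        tests["significant"] = tests["p_adj"] < alpha
    return rates, tests


def _model_matrix(patients, assignments, matrix, spec: str,
                  class_names=None) -> pd.DataFrame:
    """Predictor block for a model-comparison specification.

    `spec` is a '+'-joined list from {comorbidities, endotypes,
    covariates, age, gcs, male}. 'covariates' expands to age+gcs+male.
    """
    labels = _group_labels(assignments, class_names)
    parts = []
    tokens = []
    for tok in spec.split("+"):
        tok = tok.strip()
        tokens.extend(["age", "gcs", "male"] if tok == "covariates"
                      else [tok])
    for tok in tokens:
        if tok == "comorbidities":
            parts.append(pd.DataFrame(
                np.asarray(matrix, dtype=float),
                columns=[f"cm_{c}" for c in range(np.asarray(matrix).shape[1])]))
        elif tok == "endotypes":
            groups = sorted(set(map(str, labels)))[1:]  # drop first as ref
            parts.append(pd.DataFrame(
                {f"endo_{g}": (labels == g).astype(float) for g in groups}))
        elif tok in ("age", "gcs"):
            parts.append(pd.DataFrame({tok: patients[tok].to_numpy(float)}))
        elif tok == "male":
            parts.append(pd.DataFrame(
                {"male": patients["sex_male"].to_numpy(float)}))
        elif tok == "none":
            pass
        else:
            raise ValueError(f"unknown model term {tok!r}")
    if not parts:
        return pd.DataFrame(index=range(len(patients)))
    out = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)
    return out


def model_comparison(patients: pd.DataFrame, assignments, matrix,
                     outcome: str = "survived",
                     model_specs=None, nested_pairs=None,
                     class_names=None) -> dict:
    """Fit a family of survival-prediction models and compare them.

    Every model reports rank-based AUC (from the logistic fit), the
    linear-probability R^2 and F-versus-intercept, and McFadden pseudo
    R^2. Nested pairs are compared by F test on the linear-probability
    fits. Requesting a non-nested pair raises.
    """
    if model_specs is None:
        model_specs = ["comorbidities", "endotypes",
                       "comorbidities+endotypes", "covariates",
                       "comorbidities+covariates", "endotypes+covariates",
                       "comorbidities+endotypes+covariates",
                       "age", "gcs", "male"]
    if nested_pairs is None:
        nested_pairs = [("comorbidities", "comorbidities+endotypes"),
                        ("endotypes", "comorbidities+endotypes")]

    y = patients[outcome].to_numpy(dtype=float)
    fits = {}
    report = {"models": {}, "comparisons": []}
    for spec in model_specs:
        xm = _model_matrix(patients, assignments, matrix, spec, class_names)
        x = sm.add_constant(xm, has_constant="add")
        ols = sm.OLS(y, x).fit()
        logit_res, penalized = _fit_logit(y, x)
        phat = np.asarray(logit_res.predict(x))
        phat = np.clip(phat, 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(phat) + (1 - y) * np.log1p(-phat)))
        p0 = y.mean()
        ll0 = float(len(y) * (p0 * np.log(p0) + (1 - p0) * np.log1p(-p0)))
        fits[spec] = (ols, xm.shape[1])
        report["models"][spec] = {
            "n_predictors": int(xm.shape[1]),
            "auc": auc_score(y, phat) if xm.shape[1] else 0.5,
            "linear_r2": float(ols.rsquared),
            "linear_f": float(ols.fvalue) if xm.shape[1] else float("nan"),
            "linear_f_p": float(ols.f_pvalue) if xm.shape[1] else float("nan"),
            "mcfadden_r2": 1 - ll / ll0 if ll0 != 0 else float("nan"),
            "penalized_logit": penalized,
        }
    for small, big in nested_pairs:
        ols_s, ps = fits[small]
        ols_b, pb = fits[big]
        small_cols = set(ols_s.model.exog_names)
        if not small_cols.issubset(set(ols_b.model.exog_names)):
            raise ValueError(f"models {small!r} and {big!r} are not nested")
        f_table = anova_lm(ols_s, ols_b)
        report["comparisons"].append({
            "restricted": small, "full": big,
            "f": float(f_table["F"].iloc[1]),
            "p": float(f_table["Pr(>F)"].iloc[1]),
            "df_diff": float(f_table["df_diff"].iloc[1]),
        })
    return report


def comorbidity_burden_model(patients: pd.DataFrame, matrix,
                             outcome: str = "survived"
                             ) -> AdjustedModelResult:
    """Logistic regression of survival on the comorbidity count plus age,
    sex and GCS; also reports the Pearson correlation between age and
    comorbidity count (collinearity screen)."""
    count = np.asarray(matrix).sum(axis=1).astype(float)
    df = pd.DataFrame({
        "count": count,
        "age": patients["age"].to_numpy(float),
        "gcs": patients["gcs"].to_numpy(float),
        "male": patients["sex_male"].to_numpy(float),
    })
    n0 = len(df)
    keep = df.dropna().index
    x = sm.add_constant(df.loc[keep])
    y = patients[outcome].to_numpy(float)[keep]
    res, penalized = _fit_logit(y, x)
    params = res.params
    try:
        ci = res.conf_int()
        pvals = res.pvalues
    except Exception:
        ci = pd.DataFrame(np.nan, index=params.index, columns=[0, 1])
        pvals = pd.Series(np.nan, index=params.index)
    terms = pd.DataFrame({
        "estimate": params, "odds_ratio": np.exp(params),
        "ci_low": np.exp(ci[0]), "ci_high": np.exp(ci[1]),
        "p_value": pvals,
    }).drop(index="const")
    if np.std(count) == 0 or np.std(df["age"]) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(df["age"], df["count"])[0])
    phat = np.asarray(res.predict(x))
    return AdjustedModelResult(
        formula=f"{outcome} ~ comorbidity_count + age + gcs + male",
        reference=None, terms=terms, n_obs=len(y), n_dropped=n0 - len(keep),
        deviance=float("nan"), pseudo_r2=float("nan"),
        auc=auc_score(y, phat) if len(np.unique(y)) == 2 else float("nan"),
        linear_r2=float("nan"), penalized=penalized,
        extra={"pearson_r_age_count": r})
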