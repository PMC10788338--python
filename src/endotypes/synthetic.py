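"""Synthetic ICU cohorts with known latent comorbidity structure.

Generates patient tables whose binary comorbidity indicators follow a
K-class latent class model with class-dependent covariates (age, sex,
GCS severity) and outcomes (survival, neurosurgical intervention, length
of stay), so every downstream stage — mapping, network, LCA, selection,
stability, outcome comparison — can be tested against known truth.

The default scenario emulates a TBI-like critical-care cohort of 2,629
patients with five endotypes over 30 comorbidity flags: a large healthy
class, a hypertension class, and smaller heart-failure/arrhythmia,
renal-failure-with-hypertension and alcohol-abuse classes. Class sizes,
age and injury-severity distributions and outcome levels are package
conventions chosen to look like a real TBI cohort; they are fixed
defaults, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .elixhauser import ElixhauserMap, load_mapping, map_codes

__all__ = ["GeneratorConfig", "SyntheticTruth", "ConfigurationError",
           "generate_cohort", "default_endotype_scenario", "emit_icd9_codes"]

_GCS_RANGES = {"mild": (14, 15), "moderate": (9, 13), "severe": (3, 8)}


class ConfigurationError(ValueError):
    """A generator configuration field is invalid."""


@dataclass
class ClassCovariates:
    """Per-class covariate distributions."""

    age_mean: float
    age_sd: float
    p_male: float
    gcs_band_probs: tuple[float, float, float]  # mild, moderate, severe


@dataclass
class LogisticOutcome:
    """Per-class intercepts + shared covariate log-odds coefficients."""

    intercepts: tuple[float, ...]  # one per class
    beta_age: float
    beta_gcs: float
    beta_male: float


@dataclass
class GeneratorConfig:
    n_patients: int
    n_classes: int
    mixing_weights: np.ndarray                 # (K,)
    item_probs: np.ndarray                     # (K, J)
    covariates: list[ClassCovariates]
    survival: LogisticOutcome
    intervention: LogisticOutcome
    los_log_mean: tuple[float, ...]            # per class, log-days
    los_log_sd: tuple[float, ...]
    seed: int = 0
    n_items: int = 30
    emit_icd9: bool = False
    class_names: tuple[str, ...] | None = None
    item_names: tuple[str, ...] | None = None

    def validate(self) -> None:
        pi = np.asarray(self.mixing_weights, dtype=float)
        rho = np.asarray(self.item_probs, dtype=float)
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if pi.shape != (self.n_classes,):
            raise ConfigurationError("mixing_weights length must equal n_classes")
        if abs(pi.sum() - 1.0) > 1e-12 or (pi < 0).any():
            raise ConfigurationError("mixing_weights must be a probability "
                                     "vector summing to 1 (within 1e-12)")
        if rho.shape != (self.n_classes, self.n_items):
            raise ConfigurationError("item_probs must be K x J")
        if ((rho < 0) | (rho > 1)).any():
            raise ConfigurationError("item_probs entries must lie in [0, 1]")
        for c, cov in enumerate(self.covariates):
            p = np.asarray(cov.gcs_band_probs, dtype=float)
            if abs(p.sum() - 1.0) > 1e-12 or (p < 0).any():
                raise ConfigurationError(
                    f"gcs_band_probs for class {c} must sum to 1")
            if not 0 <= cov.p_male <= 1:
                raise ConfigurationError(f"p_male for class {c} not in [0,1]")
        for out in (self.survival, self.intervention):
            if len(out.intercepts) != self.n_classes:
                raise ConfigurationError(
                    "outcome intercepts must have one entry per class")
        if (len(self.los_log_mean) != self.n_classes
                or len(self.los_log_sd) != self.n_classes):
            raise ConfigurationError("los parameters must have one entry "
                                     "per class")

    def to_dict(self) -> dict:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return _plain(asdict(self))


@dataclass
class SyntheticTruth:
    """Generating parameters plus realized latent labels and data."""

    config: GeneratorConfig
    labels: np.ndarray = field(repr=False)     # (N,), 0-based class labels
    matrix: pd.DataFrame = field(repr=False)
    patients: pd.DataFrame = field(repr=False)


def _truncated_normal_ages(rng, mean, sd, size) -> np.ndarray:
    a, b = (16 - mean) / sd, (100 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=rng)


def generate_cohort(config: GeneratorConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw a full synthetic cohort from a generator configuration.

    Sampling model: latent class z_i ~ Categorical(pi); comorbidity flags
    x_ij ~ Bernoulli(rho[z_i, j]); age ~ Normal(mu_z, sd_z) truncated to
    [16, 100]; GCS drawn by severity band then uniform integer within the
    band; survival and intervention ~ Bernoulli(inverse-logit of a linear
    predictor in class intercept, age, GCS, sex); LOS lognormal per class
    rounded to 0.1 day. Deterministic for a fixed config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k, j = config.n_patients, config.n_classes, config.n_items

    z = rng.choice(k, size=n, p=np.asarray(config.mixing_weights, float))
    rho = np.asarray(config.item_probs, dtype=float)
    x = (rng.random((n, j)) < rho[z]).astype(np.int8)

    age = np.empty(n)
    male = np.empty(n, dtype=np.int8)
    gcs = np.empty(n, dtype=np.int64)
    for c in range(k):
        idx = np.flatnonzero(z == c)
        if idx.size == 0:
            continue
        cov = config.covariates[c]
        age[idx] = _truncated_normal_ages(rng, cov.age_mean, cov.age_sd,
                                          idx.size)
        male[idx] = rng.random(idx.size) < cov.p_male
        bands = rng.choice(3, size=idx.size,
                           p=np.asarray(cov.gcs_band_probs, float))
        for b, band in enumerate(("mild", "moderate", "severe")):
            lo, hi = _GCS_RANGES[band]
            sel = idx[bands == b]
            gcs[sel] = rng.integers(lo, hi + 1, size=sel.size)

    def _binary_outcome(model: LogisticOutcome) -> np.ndarray:
        eta = (np.asarray(model.intercepts, float)[z]
               + model.beta_age * age + model.beta_gcs * gcs
               + model.beta_male * male)
        return (rng.random(n) < expit(eta)).astype(np.int8)

    survived = _binary_outcome(config.survival)
    intervention = _binary_outcome(config.intervention)

    los = np.round(np.exp(rng.normal(np.asarray(config.los_log_mean)[z],
                                     np.asarray(config.los_log_sd)[z])), 1)

    ids = np.array([f"P{i:05d}" for i in range(n)])
    patients = pd.DataFrame({
        "patient_id": ids,
        "admission_id": [f"A{i:05d}" for i in range(n)],
        "admission_date": "2001-01-01",
        "age": np.round(age, 1),
        "sex_male": male,
        "gcs": gcs,
        "survived": survived,
        "intervention": intervention,
        "los_days": los,
    })

    item_names = (list(config.item_names) if config.item_names is not None
                  else [f"item_{t:02d}" for t in range(j)])
    matrix = pd.DataFrame(x, columns=item_names, index=ids)
    matrix.index.name = "patient_id"

    truth = SyntheticTruth(config=config, labels=z, matrix=matrix,
                           patients=patients)
    return patients, matrix, truth


# --- default five-endotype scenario -----------------------------------

#: endotype order: heart failure/arrhythmia, healthy, renal failure with
#: hypertension, alcohol abuse, hypertension
_SCENARIO_CLASSES = ("HFA", "HE", "RFH", "AA", "HTN")
_SCENARIO_SIZES = np.array([187, 1254, 136, 177, 875], dtype=float)

#: high-probability comorbidity items per endotype (category -> prob)
_SCENARIO_SIGNATURE = {
    "HFA": {"congestive_heart_failure": 0.95, "cardiac_arrhythmias": 0.95,
            "valvular_disease": 0.90, "pulmonary_circulation": 0.90},
    "HE": {},
    "RFH": {"renal_failure": 0.95, "hypertension": 0.95,
            "diabetes_complicated": 0.95, "fluid_electrolyte": 0.90,
            "deficiency_anemia": 0.90},
    "AA": {"alcohol_abuse": 0.95, "liver_disease": 0.90,
           "drug_abuse": 0.90, "depression": 0.90},
    "HTN": {"hypertension": 0.95, "diabetes_uncomplicated": 0.70,
            "hypothyroidism": 0.60, "obesity": 0.55,
            "peripheral_vascular": 0.50},
}

_SCENARIO_BASELINE = 0.03

_SCENARIO_COVARIATES = {
    "HFA": ClassCovariates(80.0, 10.0, 0.55, (0.50, 0.20, 0.30)),
    "HE": ClassCovariates(44.0, 20.0, 0.65, (0.37, 0.16, 0.47)),
    "RFH": ClassCovariates(79.0, 11.0, 0.55, (0.54, 0.17, 0.29)),
    "AA": ClassCovariates(55.0, 15.0, 0.70, (0.41, 0.20, 0.39)),
    "HTN": ClassCovariates(74.0, 15.0, 0.58, (0.52, 0.17, 0.31)),
}

#: target marginal outcome rates per endotype (survival, intervention)
_SCENARIO_RATES = {
    "HFA": (0.278, 0.273), "HE": (0.785, 0.215), "RFH": (0.404, 0.132),
    "AA": (0.701, 0.232), "HTN": (0.514, 0.257),
}

#: target LOS mean and SD in days per endotype
_SCENARIO_LOS = {
    "HFA": (10.2, 7.2), "HE": (7.3, 6.9), "RFH": (8.7, 6.0),
    "AA": (10.6, 7.5), "HTN": (7.7, 6.4),
}

_BETA_SURV = (-0.02, 0.08, 0.0)       # age, GCS, male log-odds slopes
_BETA_INTV = (-0.002, -0.02, 0.06)


def _scenario_intercepts(betas, rate_key) -> tuple[float, ...]:
    """Intercepts placing each class's rate at its target when covariates
    sit at their class means (mean GCS from band midpoints)."""
    b_age, b_gcs, b_male = betas
    out = []
    for name in _SCENARIO_CLASSES:
        cov = _SCENARIO_COVARIATES[name]
        p_mild, p_mod, p_sev = cov.gcs_band_probs
        mean_gcs = 14.5 * p_mild + 11.0 * p_mod + 5.5 * p_sev
        target = _SCENARIO_RATES[name][rate_key]
        out.append(logit(target) - b_age * cov.age_mean
                   - b_gcs * mean_gcs - b_male * cov.p_male)
    return tuple(out)


def default_endotype_scenario(seed: int = 0,
                              n_patients: int = 2629) -> GeneratorConfig:
    """Five well-separated endotypes over the 30 combined-hypertension
    Elixhauser categories.

    The scenario itself is fixed: `seed` only drives sampling, never the
    class structure. Class proportions follow the 187/1254/136/177/875
    split scaled to `n_patients`.
    """
    mapping = load_mapping(combine_hypertension=True)
    items = list(mapping.categories)
    k = len(_SCENARIO_CLASSES)
    rho = np.full((k, len(items)), _SCENARIO_BASELINE)
    for c, name in enumerate(_SCENARIO_CLASSES):
        for cat, p in _SCENARIO_SIGNATURE[name].items():
            rho[c, items.index(cat)] = p
    pi = _SCENARIO_SIZES / _SCENARIO_SIZES.sum()

    def _lognormal_params(mean, sd):
        sigma2 = np.log1p((sd / mean) ** 2)
        return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)

    los_mu, los_sd = zip(*(_lognormal_params(*_SCENARIO_LOS[nm])
                           for nm in _SCENARIO_CLASSES))

    return GeneratorConfig(
        n_patients=n_patients,
        n_classes=k,
        mixing_weights=pi,
        item_probs=rho,
        covariates=[_SCENARIO_COVARIATES[nm] for nm in _SCENARIO_CLASSES],
        survival=LogisticOutcome(_scenario_intercepts(_BETA_SURV, 0),
                                 *_BETA_SURV),
        intervention=LogisticOutcome(_scenario_intercepts(_BETA_INTV, 1),
                                     *_BETA_INTV),
        los_log_mean=tuple(los_mu),
        los_log_sd=tuple(los_sd),
        seed=seed,
        n_items=len(items),
        class_names=_SCENARIO_CLASSES,
        item_names=tuple(items),
    )


def emit_icd9_codes(truth: SyntheticTruth,
                    mapping: ElixhauserMap | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Attach ICD-9 code lists realizing each patient's comorbidity flags.

    For every active category at least one code belonging to (and only
    to) that category is sampled, so mapping the emitted codes back
    reproduces the comorbidity matrix exactly; inactive categories never
    contribute codes.
    """
    if mapping is None:
        mapping = load_mapping(combine_hypertension=True)
    if list(truth.matrix.columns) != list(mapping.categories):
        raise ConfigurationError("matrix columns do not match the mapping's "
                                 "categories")
    # codes that flag exactly one category under this mapping
    exclusive: dict[str, list[str]] = {}
    for cat in mapping.categories:
        excl = [p for p in sorted(mapping.prefixes[cat])
                if map_codes([p], mapping).sum() == 1]
        if not excl:
            raise ConfigurationError(
                f"category {cat!r} has no single-category code to emit")
        exclusive[cat] = excl

    rng = np.random.default_rng(seed)
    cats = list(mapping.categories)
    code_lists = []
    for row in truth.matrix.to_numpy():
        codes = [str(rng.choice(exclusive[cats[j]]))
                 for j in np.flatnonzero(row)]
        code_lists.append(";".join(codes))
    out = truth.patients.copy()
    out["icd9_codes"] = code_lists
    return out
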