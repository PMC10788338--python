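"""Elixhauser comorbidity flags from ICD-9-CM diagnosis codes.

Maps administrative diagnosis codes to the Elixhauser chronic-condition
categories by dot-free prefix matching, applies cohort selection rules
(diagnosis-based inclusion filter, first qualifying admission per patient),
and bins Glasgow Coma Scale and age into the standard clinical categories.

The embedded mapping is the Quan et al. (2005) enhanced ICD-9-CM Elixhauser
table with hypertension kept as separate uncomplicated/complicated flags
(31 categories); ``combine_hypertension=True`` merges them into a single
flag (30 categories).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ElixhauserMap",
    "load_mapping",
    "normalize_code",
    "map_codes",
    "build_comorbidity_matrix",
    "filter_cohort",
    "bin_gcs",
    "bin_age",
    "GCS_BANDS",
    "AGE_BANDS",
    "DEFAULT_TBI_PREFIXES",
]

# Quan et al. 2005 enhanced ICD-9-CM Elixhauser definition, as dot-free
# code prefixes. A prefix matches any normalized code that starts with it.
_QUAN_ICD9: dict[str, tuple[str, ...]] = {
    "congestive_heart_failure": (
        "39891", "40201", "40211", "40291", "40401", "40403", "40411",
        "40413", "40491", "40493", "4254", "4255", "4256", "4257", "4258",
        "4259", "428",
    ),
    "cardiac_arrhythmias": (
        "4260", "42613", "4267", "4269", "42610", "42612", "4270", "4271",
        "4272", "4273", "4274", "4276", "4277", "4278", "4279", "7850",
        "99601", "99604", "V450", "V533",
    ),
    "valvular_disease": (
        "0932", "394", "395", "396", "397", "424", "7463", "7464", "7465",
        "7466", "V422", "V433",
    ),
    "pulmonary_circulation": (
        "4150", "4151", "416", "4170", "4178", "4179",
    ),
    "peripheral_vascular": (
        "0930", "4373", "440", "441", "4431", "4432", "4433", "4434",
        "4435", "4436", "4437", "4438", "4439", "4471", "5571", "5579",
        "V434",
    ),
    "hypertension_uncomplicated": ("401",),
    "hypertension_complicated": ("402", "403", "404", "405"),
    "paralysis": (
        "3341", "342", "343", "3440", "3441", "3442", "3443", "3444",
        "3445", "3446", "3449",
    ),
    "other_neurological": (
        "3319", "3320", "3321", "3334", "3335", "33392", "334", "335",
        "3362", "340", "341", "345", "3481", "3483", "7803", "7843",
    ),
    "chronic_pulmonary": (
        "4168", "4169", "490", "491", "492", "493", "494", "495", "496",
        "500", "501", "502", "503", "504", "505", "5064", "5081", "5088",
    ),
    "diabetes_uncomplicated": ("2500", "2501", "2502", "2503"),
    "diabetes_complicated": ("2504", "2505", "2506", "2507", "2508", "2509"),
    "hypothyroidism": ("2409", "243", "244", "2461", "2468"),
    "renal_failure": (
        "40301", "40311", "40391", "40402", "40403", "40412", "40413",
        "40492", "40493", "585", "586", "5880", "V420", "V451", "V56",
    ),
    "liver_disease": (
        "07022", "07023", "07032", "07033", "07044", "07054", "0706",
        "0709", "4560", "4561", "4562", "570", "571", "5722", "5723",
        "5724", "5728", "5733", "5734", "5738", "5739", "V427",
    ),
    "peptic_ulcer": (
        "5317", "5319", "5327", "5329", "5337", "5339", "5347", "5349",
    ),
    "aids_hiv": ("042", "043", "044"),
    "lymphoma": ("200", "201", "202", "2030", "2386"),
    "metastatic_cancer": ("196", "197", "198", "199"),
    "solid_tumor": tuple(
        str(c) for c in list(range(140, 173)) + list(range(174, 196))
    ),
    "rheumatoid_arthritis": (
        "446", "7010", "7100", "7101", "7102", "7103", "7104", "7108",
        "7109", "7112", "714", "7193", "720", "725", "7285", "72889",
        "72930",
    ),
    "coagulopathy": ("286", "2871", "2873", "2874", "2875"),
    "obesity": ("2780",),
    "weight_loss": ("260", "261", "262", "263", "7832", "7994"),
    "fluid_electrolyte": ("2536", "276"),
    "blood_loss_anemia": ("2800",),
    "deficiency_anemia": (
        "2801", "2802", "2803", "2804", "2805", "2806", "2807", "2808",
        "2809", "281",
    ),
    "alcohol_abuse": (
        "2652", "2911", "2912", "2913", "2915", "2916", "2917", "2918",
        "2919", "3030", "3039", "3050", "3575", "4255", "5353", "5710",
        "5711", "5712", "5713", "980", "V113",
    ),
    "drug_abuse": (
        "292", "304", "3052", "3053", "3054", "3055", "3056", "3057",
        "3058", "3059", "V6542",
    ),
    "psychoses": (
        "2938", "295", "29604", "29614", "29644", "29654", "297", "298",
    ),
    "depression": ("2962", "2963", "2965", "3004", "309", "311"),
}

# CDC-style TBI surveillance case definition, as dot-free ICD-9 prefixes:
# skull fracture (800-801, 803-804), intracranial injury (850-854),
# injury to optic nerve/pathways subset (9501-9503), head injury
# unspecified (95901).
DEFAULT_TBI_PREFIXES: frozenset[str] = frozenset(
    {"800", "801", "803", "804", "850", "851", "852", "853", "854",
     "9501", "9502", "9503", "95901"}
)

GCS_BANDS = ("mild", "moderate", "severe")
AGE_BANDS = ("young", "middle_aged", "old")

_PREFIX_RE = re.compile(r"^[VE]?\d+$")


@dataclass(frozen=True)
class ElixhauserMap:
    """Ordered comorbidity categories and their ICD-9 code prefixes.

    Attributes
    ----------
    dialect : str
        Name of the embedded definition this map came from.
    categories : tuple of str
        Category names in stable order; length 30 or 31 depending on
        hypertension handling.
    prefixes : dict
        Category name -> frozenset of dot-free code prefixes.
    """

    dialect: str
    categories: tuple[str, ...]
    prefixes: dict[str, frozenset[str]] = field(repr=False)

    def __post_init__(self) -> None:
        for cat in self.categories:
            for p in self.prefixes[cat]:
                if not p or not _PREFIX_RE.match(p):
                    raise ValueError(f"malformed prefix {p!r} in {cat}")

    @property
    def n_categories(self) -> int:
        return len(self.categories)


_DIALECTS = {"quan2005"}


def load_mapping(dialect: str = "quan2005",
                 combine_hypertension: bool = False) -> ElixhauserMap:
    """Load an embedded Elixhauser code table.

    Parameters
    ----------
    dialect : str
        Name of the embedded definition; currently ``"quan2005"``.
    combine_hypertension : bool
        Merge the uncomplicated/complicated hypertension flags into a
        single ``hypertension`` category (30 categories instead of 31).
    """
    if dialect not in _DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; available: {sorted(_DIALECTS)}"
        )
    prefixes = {k: frozenset(v) for k, v in _QUAN_ICD9.items()}
    categories = list(_QUAN_ICD9)
    if combine_hypertension:
        merged = prefixes.pop("hypertension_uncomplicated") | prefixes.pop(
            "hypertension_complicated")
        idx = categories.index("hypertension_uncomplicated")
        categories.remove("hypertension_uncomplicated")
        categories.remove("hypertension_complicated")
        categories.insert(idx, "hypertension")
        prefixes["hypertension"] = merged
    return ElixhauserMap(dialect=dialect, categories=tuple(categories),
                         prefixes=prefixes)


def normalize_code(code: str) -> str:
    """Strip dots and whitespace, uppercase. ``'403.91' -> '40391'``."""
    return code.strip().replace(".", "").upper()


def map_codes(codes, mapping: ElixhauserMap,
              unmatched: list | None = None) -> np.ndarray:
    """Map a patient's diagnosis codes to a binary comorbidity vector.

    Flag j is 1 iff any code starts with a prefix listed under category j;
    one code may set several categories (e.g. ``40391`` sets both
    complicated hypertension and renal failure). Codes matching no
    category are ignored (appended to `unmatched` if given).
    """
    flags = np.zeros(mapping.n_categories, dtype=np.int8)
    for raw in codes:
        code = normalize_code(str(raw))
        hit = False
        for j, cat in enumerate(mapping.categories):
            for p in mapping.prefixes[cat]:
                if code.startswith(p):
                    flags[j] = 1
                    hit = True
                    break
        if not hit and unmatched is not None:
            unmatched.append(code)
    return flags


def build_comorbidity_matrix(patients: pd.DataFrame,
                             mapping: ElixhauserMap,
                             codes_column: str = "icd9_codes") -> pd.DataFrame:
    """Binary patients x categories matrix from a per-patient code column.

    The code column may hold lists of codes or semicolon-joined strings.
    Rows align 1:1 with `patients`; the index is the patient id column.
    """
    unmatched: list[str] = []
    rows = []
    for codes in patients[codes_column]:
        if isinstance(codes, str):
            codes = [c for c in codes.split(";") if c]
        elif codes is None or (isinstance(codes, float) and np.isnan(codes)):
            codes = []
        rows.append(map_codes(codes, mapping, unmatched))
    if unmatched:
        logger.info("map_codes: %d diagnosis codes matched no category "
                    "(%d distinct)", len(unmatched), len(set(unmatched)))
    mat = pd.DataFrame(np.vstack(rows), columns=list(mapping.categories),
                       index=patients["patient_id"].to_numpy())
    mat.index.name = "patient_id"
    return mat


def filter_cohort(admissions: pd.DataFrame,
                  tbi_prefixes=DEFAULT_TBI_PREFIXES,
                  codes_column: str = "icd9_codes") -> pd.DataFrame:
    """Keep TBI-coded admissions, then each patient's earliest one.

    An admission qualifies if at least one of its diagnosis codes starts
    with a prefix in `tbi_prefixes`. Among a patient's qualifying
    admissions the earliest ``admission_date`` is kept; date ties break to
    the lexicographically smallest ``admission_id``. The result has one
    row per patient.
    """
    if not tbi_prefixes:
        raise ValueError("tbi_prefixes must be nonempty")
    prefixes = tuple(sorted(tbi_prefixes))

    def _has_tbi(codes) -> bool:
        if isinstance(codes, str):
            codes = [c for c in codes.split(";") if c]
        return any(normalize_code(str(c)).startswith(prefixes)
                   for c in (codes or []))

    keep = admissions[codes_column].map(_has_tbi)
    out = admissions.loc[keep].copy()
    out["_date"] = pd.to_datetime(out["admission_date"])
    sort_cols = ["patient_id", "_date"]
    if "admission_id" in out.columns:
        sort_cols.append("admission_id")
    out = (out.sort_values(sort_cols, kind="mergesort")
              .drop_duplicates("patient_id", keep="first")
              .drop(columns="_date")
              .reset_index(drop=True))
    if out.empty:
        warnings.warn("filter_cohort: no admissions matched the TBI filter")
    return out


def bin_gcs(gcs) -> str:
    """Band a total GCS score: 14-15 mild, 9-13 moderate, 3-8 severe.

    Missing values (None/NaN) map to ``"missing"``.
    """
    if gcs is None or (isinstance(gcs, float) and np.isnan(gcs)):
        return "missing"
    g = int(gcs)
    if not 3 <= g <= 15:
        raise ValueError(f"GCS must be in 3..15, got {gcs}")
    if g >= 14:
        return "mild"
    if g >= 9:
        return "moderate"
    return "severe"


def bin_age(age) -> str:
    """Band age in years: 16-39 young, 40-69 middle_aged, 70+ old."""
    if age < 16:
        raise ValueError(f"age must be >= 16, got {age}")
    if age < 40:
        return "young"
    if age < 70:
        return "middle_aged"
    return "old"
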