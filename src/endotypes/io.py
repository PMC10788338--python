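"""Delimited-text readers and writers for cohort artifacts.

Patient tables and comorbidity matrices travel as comma-separated text
with a header row and the patient id in the first column; diagnosis
codes are a semicolon-joined field. Fits and reports serialize to JSON,
configurations to YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml


def write_patient_table(patients: pd.DataFrame, path) -> None:
    patients.to_csv(path, index=False)


def read_patient_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "icd9_codes" in df.columns:
        df["icd9_codes"] = df["icd9_codes"].fillna("")
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=True)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
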