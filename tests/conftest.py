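import numpy as np
import pandas as pd
import pytest

from endotypes import synthetic
from endotypes.elixhauser import load_mapping


@pytest.fixture(scope="session")
def quan_map():
    return load_mapping()


@pytest.fixture(scope="session")
def quan_map_30():
    return load_mapping(combine_hypertension=True)


@pytest.fixture(scope="session")
def small_cohort():
    """Default scenario at n=600: patients, matrix, truth."""
    cfg = synthetic.default_endotype_scenario(seed=11, n_patients=600)
    return synthetic.generate_cohort(cfg)


@pytest.fixture()
def multi_admission_table():
    """Handcrafted 10-admission / 6-patient table; 4 patients carry a TBI
    code on at least one admission."""
    rows = [
        # patient, admission, date, codes
        ("p1", "a1", "2001-01-01", "85221;4019"),
        ("p1", "a2", "2003-05-05", "85000"),
        ("p2", "b1", "2002-02-02", "4280"),          # never TBI-coded
        ("p2", "b2", "2002-03-03", "4019"),
        ("p3", "c2", "2000-06-06", "80125"),
        ("p3", "c1", "2000-06-06", "9501"),           # same-day tie
        ("p4", "d1", "1999-12-31", "95901;5849"),
        ("p5", "e1", "2001-07-07", "3051"),           # never TBI-coded
        ("p6", "f1", "2004-04-04", "85400"),
        ("p6", "f2", "2004-01-01", "4019"),           # earlier but not TBI
    ]
    return pd.DataFrame(
        [{"patient_id": p, "admission_id": a, "admission_date": d,
          "age": 50, "sex_male": 1, "gcs": 12, "survived": 1,
          "intervention": 0, "los_days": 3.0, "icd9_codes": c}
         for p, a, d, c in rows])
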