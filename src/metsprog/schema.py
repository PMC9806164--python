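"""Cohort table schema and record-level domain types.

A cohort is a pandas DataFrame with one row per subject per pubertal stage
(``pre``: prepubertal, ``pub``: pubertal).  Units are fixed and never
auto-converted: kg, cm, mm (skinfolds), mmHg, mg/dL and µU/mL for insulin.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd

SEXES = ("girl", "boy")
STAGES = ("pre", "pub")
BMI_CATEGORIES = ("NW", "OW", "OB")

SKINFOLD_COLUMNS = ["sf_bicipital", "sf_tricipital", "sf_subscapular", "sf_suprailiac"]

#: raw measurements, one column each, strictly positive when present
MEASUREMENT_COLUMNS = [
    "weight", "height", "waist", "hip",
    *SKINFOLD_COLUMNS,
    "sbp", "dbp", "total_chol", "ldl", "hdl", "tag", "glucose", "insulin",
]

ID_COLUMNS = ["subject_id", "sex", "stage", "age", "tanner"]
REQUIRED_COLUMNS = ID_COLUMNS + MEASUREMENT_COLUMNS
DERIVED_COLUMNS = ["bmi", "bmi_z", "whr", "sum_sf", "homa_ir"]

#: the analyzed phenotypes (summary-table numeric set minus age and Tanner);
#: these drive the outlier and missing-data exclusion filters
ANALYSIS_VARIABLES = [
    "bmi", "bmi_z", "waist", "whr", "sum_sf",
    "sbp", "dbp", "total_chol", "ldl", "hdl", "tag",
    "glucose", "insulin", "homa_ir",
]


@dataclass
class SubjectRecord:
    """One child at one stage. Thin scalar view over a cohort row."""

    subject_id: str
    sex: str
    stage: str
    age: float
    tanner: int
    weight: float
    height: float
    waist: float
    hip: float
    sf_bicipital: float
    sf_tricipital: float
    sf_subscapular: float
    sf_suprailiac: float
    sbp: float
    dbp: float
    total_chol: float
    ldl: float
    hdl: float
    tag: float
    glucose: float
    insulin: float
    bmi: Optional[float] = None
    bmi_z: Optional[float] = None
    whr: Optional[float] = None
    sum_sf: Optional[float] = None
    homa_ir: Optional[float] = None

    @classmethod
    def from_row(cls, row: pd.Series) -> "SubjectRecord":
        names = {f.name for f in fields(cls)}
        return cls(**{k: row[k] for k in row.index if k in names})

    def to_row(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None:
                out[f.name] = v
        return out


def empty_cohort() -> pd.DataFrame:
    return pd.DataFrame(columns=REQUIRED_COLUMNS)


def is_paired(cohort: pd.DataFrame) -> bool:
    """True when every subject_id has exactly one pre and one pub row."""
    counts = cohort.pivot_table(index="subject_id", columns="stage",
                                values="age", aggfunc="count")
    if not {"pre", "pub"}.issubset(counts.columns):
        return False
    return bool((counts.reindex(columns=["pre", "pub"]).fillna(0) == 1).all().all())


def split_stages(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (pre, pub) frames indexed by subject_id, aligned on subjects."""
    pre = cohort[cohort["stage"] == "pre"].set_index("subject_id").sort_index()
    pub = cohort[cohort["stage"] == "pub"].set_index("subject_id").sort_index()
    if not pre.index.equals(pub.index):
        from .errors import IntegrityError
        raise IntegrityError("cohort is not paired: pre and pub subject sets differ")
    return pre, pub
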