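"""Derived anthropometric/metabolic indices and the MetS component rule.

The syndrome definition used throughout the package: a child is classified as
having metabolic syndrome (MetS) when obese (BMI above the obesity cutoff for
sex and age) AND at least two of the four components are altered:

* hypertension           — SBP or DBP above the sex/age/height 95th percentile
* hyperglycemia          — fasting glucose strictly above 100 mg/dL
* hypertriglyceridemia   — TAG above the sex/age 95th percentile
* low HDL cholesterol    — HDL below the sex/age 5th percentile

Insulin resistance (HOMA-IR above a stage- and sex-specific cutoff) is flagged
as an auxiliary marker; it does not enter the MetS rule. All percentile
comparisons are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .charts import ReferenceChartSet
from .errors import DomainError, ValidationError
from .schema import SKINFOLD_COLUMNS, SubjectRecord

#: HOMA-IR insulin-resistance cutoffs (95th percentile of a Spanish pediatric
#: reference sample): one prepubertal value, pubertal values split by sex
HOMA_IR_CUTOFF_PRE = 2.5
HOMA_IR_CUTOFF_PUB_BOY = 3.38
HOMA_IR_CUTOFF_PUB_GIRL = 3.905

GLUCOSE_CUTOFF = 100.0  # mg/dL, strict ">"

MATTHEWS_DENOMINATOR = 405.0  # HOMA-IR constant for glucose in mg/dL

COMPONENT_FLAGS = ["hypertension", "hyperglycemia", "hypertriglyceridemia", "low_hdl"]


@dataclass
class DerivedMeasures:
    bmi: float
    whr: float
    sum_sf: float
    homa_ir: float
    bmi_z: float | None = None


@dataclass
class ComponentFlags:
    obesity: bool
    hypertension: bool
    hyperglycemia: bool
    hypertriglyceridemia: bool
    low_hdl: bool
    insulin_resistance: bool
    n_altered: int
    mets: bool


def homa_ir(glucose, insulin):
    """HOMA-IR = glucose (mg/dL) x insulin (µU/mL) / 405 (Matthews formula)."""
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if np.any(glucose[~np.isnan(glucose)] <= 0):
        raise DomainError("glucose must be strictly positive")
    if np.any(insulin[~np.isnan(insulin)] < 0):
        raise DomainError("insulin must be non-negative")
    out = glucose * insulin / MATTHEWS_DENOMINATOR
    return float(out) if out.ndim == 0 else out


def bmi(weight, height):
    """BMI = weight (kg) / height (m)^2; height given in cm."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(height[~np.isnan(height)] <= 0):
        raise DomainError("height must be strictly positive")
    out = weight / (height / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def classify_bmi_category(bmi_value, sex, age, charts: ReferenceChartSet):
    """NW / OW / OB by sex- and age-specific cutoffs.

    OB requires BMI strictly above the obesity cutoff; OW is
    ``ow_cutoff < bmi <= ob_cutoff``; a BMI exactly at the obesity cutoff is OW.
    """
    ow, ob = charts.bmi_cutoffs(sex, age)
    b = np.asarray(bmi_value, dtype=float)
    scalar = b.ndim == 0
    b = np.atleast_1d(b)
    cat = np.where(b > np.atleast_1d(ob), "OB",
                   np.where(b > np.atleast_1d(ow), "OW", "NW"))
    return str(cat[0]) if scalar else cat


def bmi_z_from_lms(bmi_value, sex, age, lms_chart: pd.DataFrame):
    """BMI z-score from an LMS table (columns sex, age, L, M, S).

    z = ((bmi/M)^L - 1) / (L*S) for L != 0, else ln(bmi/M)/S; L, M, S are
    linearly interpolated in age within sex.
    """
    b = np.atleast_1d(np.asarray(bmi_value, dtype=float))
    sex = np.broadcast_to(np.atleast_1d(np.asarray(sex, dtype=object)), b.shape)
    age = np.broadcast_to(np.atleast_1d(np.asarray(age, dtype=float)), b.shape)
    out = np.full(b.shape, np.nan)
    for s in np.unique(sex):
        sub = lms_chart[lms_chart["sex"] == s].sort_values("age")
        if sub.empty:
            raise ValidationError(f"LMS chart has no rows for sex {s!r}")
        m = sex == s
        L = np.interp(age[m], sub["age"], sub["L"])
        M = np.interp(age[m], sub["age"], sub["M"])
        S = np.interp(age[m], sub["age"], sub["S"])
        z = np.where(np.abs(L) > 1e-12,
                     ((b[m] / M) ** L - 1.0) / (L * S),
                     np.log(b[m] / M) / S)
        out[m] = z
    return float(out[0]) if np.asarray(bmi_value).ndim == 0 else out


def flag_insulin_resistance(homa, stage, sex):
    """Stage- and sex-specific HOMA-IR flag (strict inequality)."""
    homa = np.asarray(homa, dtype=float)
    stage = np.asarray(stage, dtype=object)
    sex = np.asarray(sex, dtype=object)
    if np.any(homa[~np.isnan(homa)] < 0):
        raise DomainError("HOMA-IR must be non-negative")
    cutoff = np.where(stage == "pre", HOMA_IR_CUTOFF_PRE,
                      np.where(sex == "boy", HOMA_IR_CUTOFF_PUB_BOY,
                               HOMA_IR_CUTOFF_PUB_GIRL))
    out = homa > cutoff
    return bool(out) if out.ndim == 0 else out


def add_derived_measures(cohort: pd.DataFrame, lms_chart: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Return a copy with bmi, whr, sum_sf, homa_ir (and bmi_z when derivable).

    A bmi_z column already present (e.g. emitted by the synthetic generator)
    is kept; otherwise it is computed from ``lms_chart`` when one is supplied.
    """
    df = cohort.copy()
    if (df["hip"].fillna(1) <= 0).any():
        raise DomainError("hip circumference must be strictly positive")
    df["bmi"] = bmi(df["weight"], df["height"])
    df["whr"] = df["waist"] / df["hip"]
    df["sum_sf"] = df[SKINFOLD_COLUMNS].sum(axis=1, skipna=False)
    df["homa_ir"] = homa_ir(df["glucose"], df["insulin"])
    if "bmi_z" not in df.columns and lms_chart is not None:
        df["bmi_z"] = bmi_z_from_lms(df["bmi"], df["sex"], df["age"], lms_chart)
    return df


def compute_derived_measures(record: SubjectRecord, charts: ReferenceChartSet | None = None,
                             lms_chart: pd.DataFrame | None = None) -> DerivedMeasures:
    """Scalar convenience wrapper around :func:`add_derived_measures`."""
    if record.hip is None or record.hip <= 0:
        raise DomainError("hip circumference must be strictly positive")
    b = bmi(record.weight, record.height)
    z = record.bmi_z
    if z is None and lms_chart is not None:
        z = bmi_z_from_lms(b, record.sex, record.age, lms_chart)
    return DerivedMeasures(
        bmi=b,
        whr=record.waist / record.hip,
        sum_sf=sum(getattr(record, c) for c in SKINFOLD_COLUMNS),
        homa_ir=homa_ir(record.glucose, record.insulin),
        bmi_z=z,
    )


def flag_cohort(cohort: pd.DataFrame, charts: ReferenceChartSet,
                bp_rule: str = "either") -> pd.DataFrame:
    """Component alteration flags and the MetS verdict, one row per input row.

    ``bp_rule`` is ``"either"`` (SBP or DBP above p95, the default) or
    ``"sbp"`` (systolic only). Returns a DataFrame with subject_id, stage,
    per-component booleans (plus separate high_sbp/high_dbp), n_altered and
    mets.
    """
    if bp_rule not in ("either", "sbp"):
        raise ValidationError(f"unknown bp_rule {bp_rule!r}")
    df = cohort if "bmi" in cohort.columns else add_derived_measures(cohort)
    sex, age = df["sex"], df["age"]
    cat = classify_bmi_category(df["bmi"].to_numpy(float), sex, age, charts)
    obesity = np.asarray(cat) == "OB"
    high_sbp = df["sbp"].to_numpy(float) > charts.percentile(
        "sbp", "p95", sex, age, df["height"])
    high_dbp = df["dbp"].to_numpy(float) > charts.percentile(
        "dbp", "p95", sex, age, df["height"])
    hypertension = (high_sbp | high_dbp) if bp_rule == "either" else high_sbp
    hyperglycemia = df["glucose"].to_numpy(float) > GLUCOSE_CUTOFF
    hypertg = df["tag"].to_numpy(float) > charts.percentile("tag", "p95", sex, age)
    low_hdl = df["hdl"].to_numpy(float) < charts.percentile("hdl", "p05", sex, age)
    ir = flag_insulin_resistance(df["homa_ir"], df["stage"], sex)
    n_altered = (hypertension.astype(int) + hyperglycemia.astype(int)
                 + hypertg.astype(int) + low_hdl.astype(int))
    out = pd.DataFrame({
        "subject_id": df["subject_id"].to_numpy(),
        "stage": df["stage"].to_numpy(),
        "bmi_category": cat,
        "obesity": obesity,
        "high_sbp": high_sbp,
        "high_dbp": high_dbp,
        "hypertension": hypertension,
        "hyperglycemia": hyperglycemia,
        "hypertriglyceridemia": hypertg,
        "low_hdl": low_hdl,
        "insulin_resistance": np.asarray(ir, dtype=bool),
        "n_altered": n_altered,
    }, index=df.index)
    out["mets"] = out["obesity"] & (out["n_altered"] >= 2)
    return out


def flag_components(record: SubjectRecord, derived: DerivedMeasures,
                    charts: ReferenceChartSet, bp_rule: str = "either"
                    ) -> ComponentFlags:
    """Scalar component flags for one subject at one stage."""
    row = record.to_row()
    row.update({"bmi": derived.bmi, "whr": derived.whr, "sum_sf": derived.sum_sf,
                "homa_ir": derived.homa_ir})
    df = pd.DataFrame([row])
    f = flag_cohort(df, charts, bp_rule=bp_rule).iloc[0]
    return ComponentFlags(
        obesity=bool(f["obesity"]),
        hypertension=bool(f["hypertension"]),
        hyperglycemia=bool(f["hyperglycemia"]),
        hypertriglyceridemia=bool(f["hypertriglyceridemia"]),
        low_hdl=bool(f["low_hdl"]),
        insulin_resistance=bool(f["insulin_resistance"]),
        n_altered=int(f["n_altered"]),
        mets=bool(f["mets"]),
    )
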