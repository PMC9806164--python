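"""Cohort table I/O, validation and the record-exclusion filters.

Exclusion policy (applied per paired subject, in this order):

1. *Outliers*: subjects in the prepubertal normal-weight group with any
   analysis variable strictly above the cohort's empirical 99th percentile
   (linear-interpolation quantile, computed per variable within each stage on
   the full pre-exclusion cohort).  The rule is scoped to the normal-weight
   group only; overweight/obese subjects are never removed by it.
2. *Missingness*: subjects with any missing analysis variable at either stage.

Both filters use the analyzed-phenotype set (:data:`~metsprog.schema.ANALYSIS_VARIABLES`).
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .charts import ReferenceChartSet
from .errors import (IntegrityError, NoAnalyzableSubjectsError, SchemaError,
                     ValidationError)
from .schema import (ANALYSIS_VARIABLES, ID_COLUMNS, MEASUREMENT_COLUMNS,
                     REQUIRED_COLUMNS, SEXES, STAGES)


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_cohort(path, validate: bool = True, require_paired: bool = True
                ) -> pd.DataFrame:
    """Read a cohort table (CSV/TSV, one row per subject-stage)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing mandatory columns: {missing}")
    if validate:
        validate_cohort(df, require_paired=require_paired)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep=_sep_for(path), index=False)


def validate_cohort(cohort: pd.DataFrame, require_paired: bool = True) -> None:
    """Raise on schema, integrity or row-level value violations."""
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort missing mandatory columns: {missing}")
    dup = cohort.duplicated(subset=["subject_id", "stage"])
    if dup.any():
        ids = cohort.loc[dup, "subject_id"].unique()[:5]
        raise IntegrityError(f"duplicate (subject_id, stage) rows, e.g. {list(ids)}")

    problems = []
    bad_sex = ~cohort["sex"].isin(SEXES)
    if bad_sex.any():
        problems.append(f"rows {list(cohort.index[bad_sex][:5])}: sex not in {SEXES}")
    bad_stage = ~cohort["stage"].isin(STAGES)
    if bad_stage.any():
        problems.append(f"rows {list(cohort.index[bad_stage][:5])}: stage not in {STAGES}")
    for col in MEASUREMENT_COLUMNS + ["age"]:
        vals = pd.to_numeric(cohort[col], errors="coerce")
        unparseable = cohort[col].notna() & vals.isna()
        if unparseable.any():
            problems.append(f"column {col}: unparseable values in rows "
                            f"{list(cohort.index[unparseable][:5])}")
        neg = vals <= 0
        if neg.any():
            problems.append(f"column {col}: non-positive values in rows "
                            f"{list(cohort.index[neg][:5])}")
    if not bad_stage.any():
        tanner = pd.to_numeric(cohort["tanner"], errors="coerce")
        pre = cohort["stage"] == "pre"
        bad_t = (pre & (tanner != 0)) | (~pre & ~tanner.isin([1, 2, 3, 4, 5]))
        if bad_t.any():
            problems.append("tanner must be 0 at stage=pre and 1-5 at stage=pub; "
                            f"violated in rows {list(cohort.index[bad_t][:5])}")
    if problems:
        raise ValidationError("; ".join(problems))

    if require_paired:
        counts = cohort.groupby(["subject_id", "stage"]).size().unstack(fill_value=0)
        for stage in STAGES:
            if stage not in counts.columns:
                counts[stage] = 0
        bad = counts[(counts["pre"] != 1) | (counts["pub"] != 1)]
        if len(bad):
            raise IntegrityError(
                f"cohort not paired; offending subjects: {list(bad.index[:5])}")


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

@dataclass
class ExclusionResult:
    retained: pd.DataFrame
    excluded: pd.DataFrame
    log: pd.DataFrame                       # subject_id, stage, variable, reason
    thresholds: pd.DataFrame                # stage, variable, p99


def compute_outlier_thresholds(cohort_with_derived: pd.DataFrame) -> pd.DataFrame:
    """Empirical per-stage, per-variable 99th percentiles (linear interpolation)."""
    rows = []
    for stage in STAGES:
        sub = cohort_with_derived[cohort_with_derived["stage"] == stage]
        for var in ANALYSIS_VARIABLES:
            if var not in sub.columns:
                continue
            vals = sub[var].to_numpy(float)
            if np.isnan(vals).all():
                continue
            rows.append({"stage": stage, "variable": var,
                         "p99": float(np.nanquantile(vals, 0.99))})
    return pd.DataFrame(rows)


def apply_exclusions(cohort: pd.DataFrame, charts: ReferenceChartSet,
                     thresholds: pd.DataFrame | None = None) -> ExclusionResult:
    """Apply the outlier filter, then the missing-data filter.

    ``thresholds`` freezes the >p99 outlier cutoffs (e.g. the ones returned by
    a previous call); by default they are recomputed from the input cohort.
    """
    from .criteria import add_derived_measures, classify_bmi_category

    der = add_derived_measures(cohort)
    if thresholds is None:
        thresholds = compute_outlier_thresholds(der)

    pre = der[der["stage"] == "pre"]
    # the outlier rule is scoped to the normal-weight group; a subject whose
    # BMI is missing has no valid category and is left to the missing filter
    valid = pre["bmi"].notna()
    cat = np.asarray(classify_bmi_category(
        pre.loc[valid, "bmi"].to_numpy(float), pre.loc[valid, "sex"],
        pre.loc[valid, "age"], charts))
    nw_ids = set(pre.loc[valid, "subject_id"][cat == "NW"])

    log_rows = []
    outlier_ids: set = set()
    for _, t in thresholds.iterrows():
        sub = der[der["stage"] == t["stage"]]
        over = sub[t["variable"]].to_numpy(float) > t["p99"]
        for sid in sub.loc[over, "subject_id"]:
            if sid in nw_ids:
                outlier_ids.add(sid)
                log_rows.append({"subject_id": sid, "stage": t["stage"],
                                 "variable": t["variable"], "reason": "outlier"})

    missing_ids: set = set()
    remaining = der[~der["subject_id"].isin(outlier_ids)]
    present = [v for v in ANALYSIS_VARIABLES if v in remaining.columns]
    na = remaining[present].isna()
    for (idx, row) in remaining.loc[na.any(axis=1)].iterrows():
        sid = row["subject_id"]
        missing_ids.add(sid)
        for var in na.columns[na.loc[idx]]:
            log_rows.append({"subject_id": sid, "stage": row["stage"],
                             "variable": var, "reason": "missing"})

    drop = outlier_ids | missing_ids
    retained = cohort[~cohort["subject_id"].isin(drop)].copy()
    excluded = cohort[cohort["subject_id"].isin(drop)].copy()
    if retained.empty:
        raise NoAnalyzableSubjectsError("no analyzable subjects after exclusions")
    log = pd.DataFrame(log_rows, columns=["subject_id", "stage", "variable", "reason"])
    return ExclusionResult(retained=retained, excluded=excluded, log=log,
                           thresholds=thresholds)


def write_exclusion_log(result: ExclusionResult, path) -> None:
    result.log.to_csv(path, index=False)


def read_charts(path) -> ReferenceChartSet:
    """Load a chart set from a directory of ``chart_<quantity>.csv`` files."""
    return ReferenceChartSet.from_directory(pathlib.Path(path))
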