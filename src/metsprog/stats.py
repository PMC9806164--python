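"""Group summaries, stage-change tests on the transform scale, and
Benjamini-Yekutieli false-discovery-rate adjustment.

Transform policy: every analyzed variable is log-transformed before testing
except age, Tanner stage, glucose — and BMI-z, which can be negative and is
therefore tested on the identity scale.  Two-timepoint change is tested with
a paired t-test on within-subject differences of the transformed values;
prepubertal between-group contrasts use Welch two-sample tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .charts import ReferenceChartSet
from .criteria import add_derived_measures, flag_cohort
from .errors import DegenerateTestError, DomainError, ValidationError
from .schema import ANALYSIS_VARIABLES, split_stages

IDENTITY_SCALE = {"age", "tanner", "glucose", "bmi_z"}
KNOWN_VARIABLES = set(ANALYSIS_VARIABLES) | {"age", "tanner"}

SUMMARY_VARIABLES = ["age", "tanner", "bmi", "bmi_z", "waist", "whr", "sum_sf",
                     "sbp", "dbp", "total_chol", "ldl", "hdl", "tag",
                     "glucose", "insulin", "homa_ir"]


def transform_policy(variable: str) -> str:
    """``"log"`` or ``"identity"`` for a schema variable."""
    if variable not in KNOWN_VARIABLES:
        raise ValidationError(f"unknown variable {variable!r}")
    return "identity" if variable in IDENTITY_SCALE else "log"


def _transform(values: np.ndarray, variable: str) -> np.ndarray:
    if transform_policy(variable) == "log":
        if np.any(values[~np.isnan(values)] <= 0):
            raise DomainError(f"{variable}: log transform requires positive values")
        return np.log(values)
    return values


@dataclass
class ChangeTest:
    variable: str
    scale: str
    n: int
    p_value: float
    mean_change: float       # pub - pre on the natural scale
    ratio: float | None      # geometric pub/pre ratio (log-scale variables)


def within_group_change_test(pre: np.ndarray, pub: np.ndarray, variable: str
                             ) -> ChangeTest:
    """Paired two-sided t-test of pub vs pre on the transform scale."""
    pre = np.asarray(pre, float)
    pub = np.asarray(pub, float)
    keep = ~(np.isnan(pre) | np.isnan(pub))
    pre, pub = pre[keep], pub[keep]
    if len(pre) < 3:
        raise DegenerateTestError("need >=3 complete pairs")
    scale = transform_policy(variable)
    d = _transform(pub, variable) - _transform(pre, variable)
    if np.allclose(d, d[0]) and not np.allclose(d, 0.0):
        raise DegenerateTestError("zero variance of differences")
    if np.allclose(d, 0.0):
        p = 1.0
    else:
        p = float(sps.ttest_rel(_transform(pub, variable),
                                _transform(pre, variable)).pvalue)
    ratio = float(np.exp(d.mean())) if scale == "log" else None
    return ChangeTest(variable=variable, scale=scale, n=len(pre), p_value=p,
                      mean_change=float(np.mean(pub - pre)), ratio=ratio)


def between_group_prepub_test(values_by_group: dict, variable: str) -> pd.DataFrame:
    """Pairwise Welch tests between groups on the transform scale.

    Groups with fewer than 3 values are skipped with a warning. Returns a
    DataFrame with columns group_a, group_b, n_a, n_b, p_value.
    """
    usable = {}
    for g, v in values_by_group.items():
        v = np.asarray(v, float)
        v = v[~np.isnan(v)]
        if len(v) < 3:
            warnings.warn(f"group {g!r} has <3 values; skipped", stacklevel=2)
            continue
        usable[g] = _transform(v, variable)
    rows = []
    for ga, gb in itertools.combinations(usable, 2):
        res = sps.ttest_ind(usable[ga], usable[gb], equal_var=False)
        rows.append({"group_a": ga, "group_b": gb, "n_a": len(usable[ga]),
                     "n_b": len(usable[gb]), "p_value": float(res.pvalue)})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "p_value"])


@dataclass
class AdjustedPValues:
    raw: np.ndarray
    adjusted: np.ndarray
    m: int
    c_m: float               # harmonic-number constant sum_{k<=m} 1/k
    method: str = "BY"


def benjamini_yekutieli(pvals) -> AdjustedPValues:
    """Benjamini-Yekutieli step-up adjustment (valid under any dependence)."""
    p = np.asarray(pvals, float)
    if p.ndim != 1 or len(p) == 0:
        raise DomainError("p-value vector must be 1-D and non-empty")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    adj = multipletests(p, alpha=0.05, method="fdr_by")[1]
    m = len(p)
    return AdjustedPValues(raw=p, adjusted=adj, m=m,
                           c_m=float(np.sum(1.0 / np.arange(1, m + 1))))


def group_summary(cohort: pd.DataFrame, charts: ReferenceChartSet,
                  grouping: str = "sex") -> pd.DataFrame:
    """Mean/SD/n per group, variable and stage, plus the paired change column.

    ``grouping``:
      * ``"sex"`` — total cohort plus girls/boys;
      * ``"prepub_bmi_mets"`` — prepubertal NW / OW / OB-NoMetS / OB-MetS;
      * ``"pub_mets"`` — pubertal MetS yes/no.

    Empty groups are omitted with a warning.
    """
    der = add_derived_measures(cohort)
    flags = flag_cohort(der, charts)
    pre, pub = split_stages(der)
    fpre, fpub = split_stages(flags)

    if grouping == "sex":
        labels = pre["sex"].copy()
        groups = {"total": labels.index, "girls": labels.index[labels == "girl"],
                  "boys": labels.index[labels == "boy"]}
    elif grouping == "prepub_bmi_mets":
        cat = fpre["bmi_category"]
        mets = fpre["mets"]
        groups = {"NW": cat.index[cat == "NW"], "OW": cat.index[cat == "OW"],
                  "OB-NoMetS": cat.index[(cat == "OB") & ~mets],
                  "OB-MetS": cat.index[(cat == "OB") & mets]}
    elif grouping == "pub_mets":
        mets = fpub["mets"]
        groups = {"NoMetS": mets.index[~mets], "MetS": mets.index[mets]}
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")

    rows = []
    for gname, idx in groups.items():
        if len(idx) == 0:
            warnings.warn(f"group {gname!r} is empty; omitted", stacklevel=2)
            continue
        gpre, gpub = pre.loc[idx], pub.loc[idx]
        for var in SUMMARY_VARIABLES:
            if var not in gpre.columns:
                continue
            a = gpre[var].to_numpy(float)
            b = gpub[var].to_numpy(float)
            delta = b - a
            for stage, v in (("pre", a), ("pub", b), ("delta", delta)):
                ok = ~np.isnan(v)
                rows.append({"group": gname, "variable": var, "stage": stage,
                             "mean": float(np.mean(v[ok])) if ok.any() else np.nan,
                             "sd": float(np.std(v[ok], ddof=1)) if ok.sum() > 1 else np.nan,
                             "n": int(ok.sum())})
    return pd.DataFrame(rows, columns=["group", "variable", "stage", "mean", "sd", "n"])
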