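"""Prepuberty-to-puberty transitions: BMI-category flows, component tracking
2x2 tables, and risk/odds effect estimates.

Effect estimates from a 2x2 table with layout

    exposed (altered at pre):      a (altered at pub)   b (not)
    unexposed (normal at pre):     c (altered at pub)   d (not)

Risk ratio RR = [a/(a+b)] / [c/(c+d)] with a log-normal (Wald) 95% CI; odds
ratio OR = ad/bc with the Woolf interval.  When any cell is zero the
Haldane-Anscombe +0.5 correction is applied to all four cells and the method
tag records it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .charts import ReferenceChartSet
from .criteria import add_derived_measures, flag_cohort
from .errors import DegenerateTestError, DomainError, IntegrityError, ValidationError
from .schema import split_stages

CATEGORY_ORDER = ["NW", "OW", "OB"]
TRACKABLE_COMPONENTS = ("sbp", "dbp", "tag", "hdl", "glucose", "homa_ir", "mets")

_FLAG_FOR = {"sbp": "high_sbp", "dbp": "high_dbp", "tag": "hypertriglyceridemia",
             "hdl": "low_hdl", "glucose": "hyperglycemia",
             "homa_ir": "insulin_resistance", "mets": "mets"}

Z95 = 1.959963984540054


@dataclass
class TransitionSummary:
    counts: pd.DataFrame          # 3x3, rows pre category, columns pub category
    n: int
    stayed: float                 # fraction on the diagonal
    moved_up: float               # fraction moving up >=1 category (NW<OW<OB)
    moved_down: float
    persistence: dict             # per pre-category stay rate


@dataclass
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EffectEstimate:
    measure: str                  # "risk_ratio" | "odds_ratio"
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    flagged: bool = False         # separation / degenerate-likelihood marker


def transition_summary_from_counts(counts: pd.DataFrame) -> TransitionSummary:
    """Summarize a 3x3 pre x pub category count matrix."""
    counts = counts.reindex(index=CATEGORY_ORDER, columns=CATEGORY_ORDER,
                            fill_value=0)
    m = counts.to_numpy(float)
    n = int(m.sum())
    if n == 0:
        raise DomainError("empty transition matrix")
    stayed = np.trace(m) / n
    up = sum(m[i, j] for i in range(3) for j in range(3) if j > i) / n
    down = sum(m[i, j] for i in range(3) for j in range(3) if j < i) / n
    persistence = {c: (m[i, i] / m[i].sum()) if m[i].sum() else np.nan
                   for i, c in enumerate(CATEGORY_ORDER)}
    return TransitionSummary(counts=counts.astype(int), n=n, stayed=stayed,
                             moved_up=up, moved_down=down, persistence=persistence)


def bmi_transition_matrix(cohort: pd.DataFrame, charts: ReferenceChartSet
                          ) -> TransitionSummary:
    """BMI-category transition counts for a paired cohort."""
    from .criteria import classify_bmi_category

    der = add_derived_measures(cohort)
    pre, pub = split_stages(der)
    cat_pre = np.asarray(classify_bmi_category(
        pre["bmi"].to_numpy(float), pre["sex"], pre["age"], charts))
    cat_pub = np.asarray(classify_bmi_category(
        pub["bmi"].to_numpy(float), pub["sex"], pub["age"], charts))
    counts = pd.crosstab(pd.Categorical(cat_pre, categories=CATEGORY_ORDER),
                         pd.Categorical(cat_pub, categories=CATEGORY_ORDER),
                         dropna=False)
    counts.index = CATEGORY_ORDER
    counts.columns = CATEGORY_ORDER
    return transition_summary_from_counts(counts)


def _stage_flags(cohort: pd.DataFrame, charts: ReferenceChartSet) -> pd.DataFrame:
    der = add_derived_measures(cohort)
    flags = flag_cohort(der, charts)
    return flags


def component_tracking_table(cohort: pd.DataFrame, component: str,
                             charts: ReferenceChartSet) -> ContingencyTable:
    """Cross-tabulate prepubertal vs pubertal alteration of one component."""
    if component not in TRACKABLE_COMPONENTS:
        raise ValidationError(f"unknown component {component!r}; "
                              f"expected one of {TRACKABLE_COMPONENTS}")
    flags = _stage_flags(cohort, charts)
    col = _FLAG_FOR[component]
    pre, pub = split_stages(flags)
    e = pre[col].to_numpy(bool)
    o = pub[col].to_numpy(bool)
    return ContingencyTable(a=int((e & o).sum()), b=int((e & ~o).sum()),
                            c=int((~e & o).sum()), d=int((~e & ~o).sum()))


def _maybe_correct(t: ContingencyTable):
    cells = np.array([t.a, t.b, t.c, t.d], float)
    corrected = (cells == 0).any()
    if corrected:
        cells = cells + 0.5
    return cells, corrected


def risk_ratio(table: ContingencyTable) -> EffectEstimate:
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise DegenerateTestError("risk ratio undefined: empty exposure arm")
    (a, b, c, d), corrected = _maybe_correct(table)
    rr = (a / (a + b)) / (c / (c + d))
    se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    lo, hi = np.exp(np.log(rr) - Z95 * se), np.exp(np.log(rr) + Z95 * se)
    method = "wald-log" + ("+haldane" if corrected else "")
    return EffectEstimate("risk_ratio", float(rr), float(lo), float(hi), method)


def odds_ratio(table: ContingencyTable) -> EffectEstimate:
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise DegenerateTestError("odds ratio undefined: empty exposure arm")
    (a, b, c, d), corrected = _maybe_correct(table)
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(orr) - Z95 * se), np.exp(np.log(orr) + Z95 * se)
    method = "woolf" + ("+haldane" if corrected else "")
    return EffectEstimate("odds_ratio", float(orr), float(lo), float(hi), method)


def persistence_logistic(cohort: pd.DataFrame, component: str,
                         charts: ReferenceChartSet,
                         covariates: tuple = ()) -> EffectEstimate:
    """Logistic regression of pubertal alteration on prepubertal alteration.

    ``covariates`` may include ``"sex"`` and/or ``"tanner_pub"``. Returns the
    odds ratio for the prepubertal-alteration term with a Wald 95% CI; perfect
    separation is reported as a flagged estimate with an infinite bound.
    """
    if component not in TRACKABLE_COMPONENTS:
        raise ValidationError(f"unknown component {component!r}")
    flags = _stage_flags(cohort, charts)
    col = _FLAG_FOR[component]
    fpre, fpub = split_stages(flags)
    y = fpub[col].astype(float).to_numpy()
    if y.min() == y.max():
        raise DegenerateTestError("outcome has a single class")
    X = pd.DataFrame({"pre_altered": fpre[col].astype(float).to_numpy()},
                     index=fpre.index)
    if covariates:
        cpre, cpub = split_stages(cohort)
        if "sex" in covariates:
            X["sex"] = (cpre["sex"] == "girl").astype(float)
        if "tanner_pub" in covariates:
            X["tanner_pub"] = cpub["tanner"].astype(float)
        unknown = set(covariates) - {"sex", "tanner_pub"}
        if unknown:
            raise ValidationError(f"unknown covariates {sorted(unknown)}")
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            beta = fit.params["pre_altered"]
            se = fit.bse["pre_altered"]
        except Exception:
            beta, se = np.nan, np.inf
    flagged = not np.isfinite(se) or se > 50 or not np.isfinite(beta)
    if flagged:
        est = float(np.exp(beta)) if np.isfinite(beta) else np.inf
        return EffectEstimate("odds_ratio", est, 0.0, np.inf,
                              "logistic-wald", flagged=True)
    return EffectEstimate("odds_ratio", float(np.exp(beta)),
                          float(np.exp(beta - Z95 * se)),
                          float(np.exp(beta + Z95 * se)), "logistic-wald")
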