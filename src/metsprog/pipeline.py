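"""End-to-end orchestration with a single config and reproducible seeding.

One master seed fans out to per-stage sub-seeds through a named
``SeedSequence`` counter scheme (stage name order is fixed), so individual
stages can be re-run in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .charts import ReferenceChartSet, synthetic_reference_charts
from .criteria import add_derived_measures, flag_cohort
from .errors import MetsprogError
from .fft import DEFAULT_CUES, build_fft, confusion
from .io import apply_exclusions, read_cohort, write_cohort
from .progression import (TRACKABLE_COMPONENTS, bmi_transition_matrix,
                          component_tracking_table, odds_ratio,
                          persistence_logistic, risk_ratio)
from .schema import split_stages
from .simulate import (CohortParams, default_parameters, generate_cohort,
                       inject_artifacts)
from .stats import benjamini_yekutieli, group_summary, within_group_change_test
from .validation import (CVConfig, backward_stepwise_logistic,
                         cross_validate_fft, max_vif, roc_auc)

_STAGE_NAMES = ("simulate", "inject", "exclude", "folds", "fft", "cv", "roc")


@dataclass
class RunConfig:
    out_dir: str = "metsprog_run"
    seed: int = 0
    cohort_path: str | None = None      # None -> simulate
    charts_path: str | None = None      # None -> bundled synthetic charts
    n_subjects: int = 143
    inject_outliers: int = 0
    inject_missing: int = 0
    w_ratios: tuple = (1.5, 1.2)
    cues: tuple = tuple(DEFAULT_CUES)
    max_depth: int = 4
    n_folds: int = 4
    n_repeats: int = 5
    bootstrap_factor: int = 25


def stage_seeds(master_seed: int) -> dict:
    """Derive one independent 31-bit sub-seed per pipeline stage."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGE_NAMES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(_STAGE_NAMES, children)}


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _prepub_table(cohort: pd.DataFrame, charts: ReferenceChartSet):
    """Prepubertal cue table and pubertal MetS outcome for prediction models."""
    der = add_derived_measures(cohort)
    flags = flag_cohort(der, charts)
    pre, _ = split_stages(der)
    _, fpub = split_stages(flags)
    cols = [c for c in DEFAULT_CUES if c in pre.columns]
    X = pre[cols].astype(float)
    y = fpub["mets"].to_numpy(bool)
    return X, y


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a manifest of written artifacts."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = {"seed": config.seed, "stage_seeds": seeds,
                "config_hash": _config_hash(config), "version": __version__,
                "artifacts": []}
    stage = "setup"
    try:
        charts = (ReferenceChartSet.from_directory(config.charts_path)
                  if config.charts_path else synthetic_reference_charts())

        stage = "simulate"
        if config.cohort_path:
            cohort = read_cohort(config.cohort_path)
        else:
            params = default_parameters()
            params.n_subjects = config.n_subjects
            cohort = generate_cohort(params, seed=seeds["simulate"],
                                     charts=charts).frame
            if config.inject_outliers or config.inject_missing:
                cohort, _ = inject_artifacts(cohort, config.inject_outliers,
                                             config.inject_missing,
                                             seed=seeds["inject"], charts=charts)
        write_cohort(cohort, out / "cohort.csv")
        manifest["artifacts"].append("cohort.csv")

        stage = "exclude"
        result = apply_exclusions(cohort, charts)
        cohort = result.retained
        result.log.to_csv(out / "exclusions.csv", index=False)
        manifest["artifacts"].append("exclusions.csv")

        stage = "classify"
        der = add_derived_measures(cohort)
        flags = flag_cohort(der, charts)
        flags.to_csv(out / "flags.csv", index=False)
        manifest["artifacts"].append("flags.csv")

        stage = "summarize"
        summaries = []
        for grouping in ("sex", "prepub_bmi_mets", "pub_mets"):
            s = group_summary(cohort, charts, grouping=grouping)
            s.insert(0, "grouping", grouping)
            summaries.append(s)
        summary = pd.concat(summaries, ignore_index=True)
        # within-group change tests with BY adjustment across the family
        pre, pub = split_stages(der)
        tests = []
        for var in ("bmi", "waist", "whr", "sum_sf", "sbp", "dbp", "total_chol",
                    "ldl", "hdl", "tag", "glucose", "insulin", "homa_ir"):
            t = within_group_change_test(pre[var].to_numpy(float),
                                         pub[var].to_numpy(float), var)
            tests.append({"variable": var, "scale": t.scale, "n": t.n,
                          "mean_change": t.mean_change, "p_raw": t.p_value})
        tests = pd.DataFrame(tests)
        tests["p_by"] = benjamini_yekutieli(tests["p_raw"].to_numpy()).adjusted
        summary.to_csv(out / "group_summary.csv", index=False)
        tests.to_csv(out / "change_tests.csv", index=False)
        manifest["artifacts"] += ["group_summary.csv", "change_tests.csv"]

        stage = "progress"
        trans = bmi_transition_matrix(cohort, charts)
        trans.counts.to_csv(out / "bmi_transitions.csv")
        effect_rows = []
        for comp in TRACKABLE_COMPONENTS:
            table = component_tracking_table(cohort, comp, charts)
            for fn in (risk_ratio, odds_ratio):
                try:
                    e = fn(table)
                except MetsprogError:
                    continue
                effect_rows.append({"component": comp, "measure": e.measure,
                                    "estimate": e.estimate, "ci_low": e.ci_low,
                                    "ci_high": e.ci_high, "method": e.method,
                                    "a": table.a, "b": table.b, "c": table.c,
                                    "d": table.d})
        pd.DataFrame(effect_rows).to_csv(out / "tracking_effects.csv", index=False)
        manifest["artifacts"] += ["bmi_transitions.csv", "tracking_effects.csv"]

        stage = "stepwise"
        X, y = _prepub_table(cohort, charts)
        X_sex = X.copy()
        pre_rows, _ = split_stages(cohort)
        X_sex["sex_girl"] = (pre_rows["sex"] == "girl").astype(float)
        vif = max_vif(X_sex)
        if y.any() and not y.all():
            model = backward_stepwise_logistic(X_sex, y)
            model.table.assign(max_vif=vif).to_csv(out / "stepwise.csv", index=False)
            manifest["artifacts"].append("stepwise.csv")

        stage = "fft"
        for w in config.w_ratios:
            tree = build_fft(X, y, w_ratio=w, max_depth=config.max_depth,
                             cues=[c for c in config.cues if c in X.columns])
            tag = f"w{str(w).replace('.', '_')}"
            (out / f"fft_{tag}.json").write_text(tree.to_json())
            (out / f"fft_{tag}.txt").write_text(tree.render() + "\n")
            manifest["artifacts"] += [f"fft_{tag}.json", f"fft_{tag}.txt"]

            stage = "fft-validate"
            cv = cross_validate_fft(
                X, y, CVConfig(n_folds=config.n_folds, n_repeats=config.n_repeats,
                               bootstrap_factor=config.bootstrap_factor,
                               w_ratio=w, max_depth=config.max_depth,
                               cues=[c for c in config.cues if c in X.columns],
                               seed=seeds["cv"]))
            folds = cv.folds.copy()
            agg = cv.aggregate()
            folds.loc[len(folds)] = {"repeat": -1, "fold": -1, **agg.to_dict()}
            folds.to_csv(out / f"cv_{tag}.csv", index=False)
            manifest["artifacts"].append(f"cv_{tag}.csv")

        stage = "roc"
        rocs = {v: roc_auc(X[v].to_numpy(), y) for v in ("bmi_z", "homa_ir")
                if v in X.columns}
        pd.DataFrame([rocs]).to_csv(out / "roc_auc.csv", index=False)
        manifest["artifacts"].append("roc_auc.csv")

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        (out / "INCOMPLETE").write_text(f"failed at stage {stage}: {exc}\n")
        raise MetsprogError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if "w_ratios" in d:
        d["w_ratios"] = tuple(d["w_ratios"])
    if "cues" in d:
        d["cues"] = tuple(d["cues"])
    return RunConfig(**d)
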