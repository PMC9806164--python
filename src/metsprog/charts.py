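"""Percentile reference charts used to flag altered components and BMI category.

A :class:`ReferenceChartSet` bundles one table per quantity:

``bmi``
    columns ``sex, age_lo, age_hi, ow_cutoff, ob_cutoff`` (overweight/obesity
    BMI cutoffs per sex and age band).
``waist, tag, hdl``
    columns ``sex, age_lo, age_hi, p05, p90, p95, p97``.
``sbp, dbp``
    additionally ``height_lo, height_hi`` (blood-pressure percentiles are
    height-adjusted).

Age bands are half-open ``[age_lo, age_hi)``, must not overlap, and must
jointly cover the configured age range; lookups outside coverage raise
:class:`~metsprog.errors.CoverageError` rather than extrapolating.

The bundled default charts produced by :func:`synthetic_reference_charts` are
SYNTHETIC smooth parametric curves in the broad range of published pediatric
references. They are deliberately non-authoritative: analyses of real cohorts
must load the original reference tables in this schema.
"""

from __future__ import annotations

import pathlib
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import CoverageError, SchemaError, ValidationError
from .schema import SEXES

PERCENTILE_COLUMNS = ["p05", "p90", "p95", "p97"]
QUANTITIES = ("bmi", "waist", "sbp", "dbp", "tag", "hdl")
_BP = ("sbp", "dbp")


def _required_columns(quantity: str) -> list[str]:
    base = ["sex", "age_lo", "age_hi"]
    if quantity in _BP:
        base += ["height_lo", "height_hi"]
    if quantity == "bmi":
        return base + ["ow_cutoff", "ob_cutoff"]
    return base + PERCENTILE_COLUMNS


class ReferenceChartSet:
    """Sex/age(/height) percentile tables with validated, vectorized lookups."""

    def __init__(self, charts: Mapping[str, pd.DataFrame]):
        missing = set(QUANTITIES) - set(charts)
        if missing:
            raise SchemaError(f"missing charts for: {sorted(missing)}")
        self.charts: dict[str, pd.DataFrame] = {}
        for q in QUANTITIES:
            df = charts[q].reset_index(drop=True).copy()
            cols = _required_columns(q)
            absent = [c for c in cols if c not in df.columns]
            if absent:
                raise SchemaError(f"chart {q!r} missing columns {absent}")
            self.charts[q] = df[cols]
        self._validate()

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        for q, df in self.charts.items():
            if q == "bmi":
                if not (df["ow_cutoff"] < df["ob_cutoff"]).all():
                    raise ValidationError(f"chart {q!r}: ow_cutoff must be < ob_cutoff")
            else:
                vals = df[PERCENTILE_COLUMNS].to_numpy(float)
                if not (np.diff(vals, axis=1) > 0).all():
                    raise ValidationError(
                        f"chart {q!r}: percentile columns must increase left-to-right")
            for sex in df["sex"].unique():
                sub = df[df["sex"] == sex]
                keys = ["age_lo", "age_hi"]
                if q in _BP:
                    # bands tile the (age, height) plane: check per age band
                    for (lo, hi), g in sub.groupby(["age_lo", "age_hi"]):
                        h = g.sort_values("height_lo")
                        if not (h["height_lo"].to_numpy()[1:]
                                == h["height_hi"].to_numpy()[:-1]).all():
                            raise ValidationError(
                                f"chart {q!r}: height bands overlap or leave gaps")
                    sub = sub.drop_duplicates(subset=keys)
                s = sub.sort_values("age_lo")
                if (s["age_lo"] >= s["age_hi"]).any():
                    raise ValidationError(f"chart {q!r}: empty age band")
                if (s["age_lo"].to_numpy()[1:] < s["age_hi"].to_numpy()[:-1]).any():
                    raise ValidationError(f"chart {q!r}: overlapping age bands ({sex})")
                if (s["age_lo"].to_numpy()[1:] != s["age_hi"].to_numpy()[:-1]).any():
                    raise ValidationError(f"chart {q!r}: age bands leave gaps ({sex})")

    # -- lookups ------------------------------------------------------------
    def _lookup(self, quantity: str, column: str, sex, age, height=None) -> np.ndarray:
        df = self.charts[quantity]
        sex = np.asarray(sex, dtype=object)
        age = np.asarray(age, dtype=float)
        scalar = age.ndim == 0
        sex, age = np.atleast_1d(sex), np.atleast_1d(age)
        if sex.shape != age.shape:
            sex = np.broadcast_to(sex, age.shape)
        out = np.full(age.shape, np.nan)
        if quantity in _BP:
            if height is None:
                raise ValidationError(f"{quantity} lookup requires height")
            height = np.atleast_1d(np.asarray(height, dtype=float))
        for _, row in df.iterrows():
            m = (sex == row["sex"]) & (age >= row["age_lo"]) & (age < row["age_hi"])
            if quantity in _BP:
                m &= (height >= row["height_lo"]) & (height < row["height_hi"])
            out[m] = row[column]
        if np.isnan(out).any():
            i = int(np.flatnonzero(np.isnan(out))[0])
            detail = f"sex={sex[i]}, age={age[i]:.2f}"
            if quantity in _BP:
                detail += f", height={height[i]:.1f}"
            raise CoverageError(f"no {quantity} chart row covers {detail}")
        return out[0] if scalar else out

    def percentile(self, quantity: str, column: str, sex, age, height=None):
        """Percentile value (e.g. ``column='p95'``) for each query point."""
        if quantity == "bmi":
            raise ValidationError("bmi chart holds category cutoffs, not percentiles")
        if column not in PERCENTILE_COLUMNS:
            raise ValidationError(f"unknown percentile column {column!r}")
        return self._lookup(quantity, column, sex, age, height)

    def bmi_cutoffs(self, sex, age):
        """(overweight, obesity) BMI cutoffs for each query point."""
        ow = self._lookup("bmi", "ow_cutoff", sex, age)
        ob = self._lookup("bmi", "ob_cutoff", sex, age)
        return ow, ob

    # -- serialization ------------------------------------------------------
    def to_directory(self, path) -> None:
        path = pathlib.Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for q, df in self.charts.items():
            df.to_csv(path / f"chart_{q}.csv", index=False)

    @classmethod
    def from_directory(cls, path) -> "ReferenceChartSet":
        path = pathlib.Path(path)
        charts = {}
        for q in QUANTITIES:
            f = path / f"chart_{q}.csv"
            if not f.exists():
                raise SchemaError(f"missing chart file {f}")
            charts[q] = pd.read_csv(f)
        return cls(charts)


# ---------------------------------------------------------------------------
# synthetic default charts
# ---------------------------------------------------------------------------

# piecewise-linear anchors for BMI category cutoffs (age -> cutoff), shaped
# like international child overweight/obesity curves but NOT the real tables
_BMI_ANCHORS = {
    ("boy", "ow_cutoff"): [(2, 18.4), (6, 17.6), (10, 19.8), (14, 22.6), (20, 25.6)],
    ("boy", "ob_cutoff"): [(2, 20.1), (6, 19.8), (10, 24.0), (14, 27.6), (20, 30.7)],
    ("girl", "ow_cutoff"): [(2, 18.0), (6, 17.3), (10, 19.9), (14, 23.3), (20, 25.6)],
    ("girl", "ob_cutoff"): [(2, 19.8), (6, 19.7), (10, 24.1), (14, 28.6), (20, 30.7)],
}


def expected_height(age, sex) -> np.ndarray:
    """Smooth synthetic median height (cm) by age and sex."""
    age = np.asarray(age, dtype=float)
    h = 75.0 + 6.8 * age - 0.04 * age ** 2
    bump = np.where(np.asarray(sex, dtype=object) == "boy",
                    1.5 * np.clip(age - 11.0, 0.0, 4.0) / 4.0 * 4.0, 0.0)
    return h + bump


def _interp_anchor(anchors, ages):
    xs, ys = zip(*anchors)
    return np.interp(ages, xs, ys)


def synthetic_reference_charts(age_min: float = 2.0, age_max: float = 20.0,
                               band: float = 0.5) -> ReferenceChartSet:
    """Build the bundled SYNTHETIC chart set (labelled non-authoritative)."""
    edges = np.round(np.arange(age_min, age_max + 1e-9, band), 3)
    lo, hi = edges[:-1], edges[1:]
    mid = (lo + hi) / 2.0
    charts: dict[str, pd.DataFrame] = {}

    rows = []
    for sex in SEXES:
        ow = _interp_anchor(_BMI_ANCHORS[(sex, "ow_cutoff")], mid)
        ob = _interp_anchor(_BMI_ANCHORS[(sex, "ob_cutoff")], mid)
        rows.append(pd.DataFrame({"sex": sex, "age_lo": lo, "age_hi": hi,
                                  "ow_cutoff": ow, "ob_cutoff": ob}))
    charts["bmi"] = pd.concat(rows, ignore_index=True)

    def simple_chart(p95_fn, p05_off, p90_off, p97_off):
        rows = []
        for sex in SEXES:
            p95 = p95_fn(mid, sex)
            rows.append(pd.DataFrame({
                "sex": sex, "age_lo": lo, "age_hi": hi,
                "p05": p95 + p05_off(mid), "p90": p95 + p90_off(mid),
                "p95": p95, "p97": p95 + p97_off(mid)}))
        return pd.concat(rows, ignore_index=True)

    charts["waist"] = simple_chart(
        lambda a, s: 52.0 + 2.8 * a + (1.0 if s == "boy" else 0.0),
        lambda a: -0.45 * (52 + 2.8 * a), lambda a: -2.0 - 0.05 * a, lambda a: 2.0)
    charts["tag"] = simple_chart(
        lambda a, s: np.where(a < 10, 100.0, np.minimum(100.0 + 4.0 * (a - 10), 130.0)),
        lambda a: -70.0, lambda a: -12.0, lambda a: 8.0)
    charts["hdl"] = simple_chart(
        lambda a, s: 95.0 - 0.3 * a,
        lambda a: -(57.0 - 0.35 * a),   # p05 around 38 mg/dL
        lambda a: -10.0, lambda a: 4.0)

    # blood pressure: three height bands around the synthetic median height,
    # with a +-2 mmHg adjustment per band
    def bp_chart(base, slope):
        rows = []
        for sex in SEXES:
            hmid = expected_height(mid, sex)
            for shift, (hlo, hhi) in zip(
                    (-2.0, 0.0, 2.0),
                    ((np.zeros_like(hmid), hmid - 4), (hmid - 4, hmid + 4),
                     (hmid + 4, np.full_like(hmid, 260.0)))):
                p95 = base + slope * mid + shift
                rows.append(pd.DataFrame({
                    "sex": sex, "age_lo": lo, "age_hi": hi,
                    "height_lo": hlo, "height_hi": hhi,
                    "p05": p95 - 30.0, "p90": p95 - 4.0,
                    "p95": p95, "p97": p95 + 3.0}))
        return pd.concat(rows, ignore_index=True)

    charts["sbp"] = bp_chart(102.0, 1.6)
    charts["dbp"] = bp_chart(62.0, 1.1)
    return ReferenceChartSet(charts)
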