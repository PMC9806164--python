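"""Synthetic paired prepuberty/puberty cohort generator.

The generator emulates a two-stage longitudinal pediatric cohort with the
published summary structure this package's analyses assume:

* n = 143 paired subjects (71 girls / 72 boys) by default;
* a prepubertal BMI-group mixture (normal weight / overweight / obesity
  without MetS / obesity with MetS = 43 / 31 / 56 / 13) with group-conditional
  means and SDs for every analyzed variable;
* BMI-category transitions with per-category persistence 90.7% / 61.3% /
  72.5% (overall 75.5% staying in category);
* classifier-consistent MetS status: subjects in the prepubertal MetS group
  are guaranteed obese with >=2 altered components under the bundled charts,
  obese non-MetS subjects are guaranteed <=1, so the expected classifier-
  derived prevalence is exactly 13/143 prepubertally and 17/143 at puberty;
* within-subject tracking through latent Gaussian correlations per variable;
* the HOMA-IR identity (homa = glucose x insulin / 405) holds exactly because
  HOMA-IR is derived, never drawn.

Marginals are log-normal except age, glucose, BMI-z and WHR (normal), echoing
the log-transform policy used by the downstream tests.  Group means/SDs are
re-calibrated analytically at parameter construction so the four-group
mixture reproduces the cohort-level target means and SDs exactly (the printed
group tables and printed totals disagree at the rounding level).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .charts import ReferenceChartSet, expected_height, synthetic_reference_charts
from .errors import ParameterError, ValidationError
from .schema import ANALYSIS_VARIABLES, REQUIRED_COLUMNS, SKINFOLD_COLUMNS

GROUPS = ("NW", "OW", "OBN", "OBM")  # prepubertal BMI/MetS groups
CATEGORIES = ("NW", "OW", "OB")

#: cohort-level target means/SDs: variable -> (pre_mean, pre_sd, pub_mean, pub_sd)
TABLE_TOTALS = {
    "age": (7.8, 1.8, 14.3, 1.9),
    "tanner": (0.0, 0.0, 4.3, 1.1),
    "bmi": (21.6, 4.6, 26.3, 6.3),
    "bmi_z": (1.92, 2.06, 1.63, 1.74),
    "waist": (72.0, 13.0, 85.0, 16.0),
    "whr": (0.92, 0.07, 0.86, 0.10),
    "sum_sf": (72.0, 33.0, 84.0, 26.0),
    "sbp": (104.0, 12.0, 113.0, 14.0),
    "dbp": (62.0, 9.0, 69.0, 9.0),
    "total_chol": (169.0, 33.0, 157.0, 29.0),
    "ldl": (99.0, 28.0, 91.0, 23.0),
    "hdl": (56.0, 15.0, 50.0, 12.0),
    "tag": (58.0, 28.0, 75.0, 33.0),
    "glucose": (84.0, 7.0, 85.0, 9.0),
    "insulin": (8.0, 5.9, 14.8, 9.5),
    "homa_ir": (1.67, 1.32, 3.15, 2.13),
}

#: group-conditional raw parameters per variable:
#: (pre means, pre sds, pub means, pub sds), each a 4-tuple over GROUPS
_GROUP_RAW = {
    "sbp": ((101, 105, 102, 116), (11, 9, 12, 6),
            (107, 112, 117, 121), (11, 12, 13, 23)),
    "dbp": ((62, 61, 60, 76), (7, 8, 7, 12),
            (67, 68, 68, 76), (7, 6, 9, 17)),
    "tag": ((46, 67, 55, 92), (14, 35, 23, 36),
            (67, 73, 75, 101), (29, 31, 30, 47)),
    "hdl": ((64, 57, 52, 42), (15, 16, 10, 10),
            (58, 47, 47, 41), (14, 11, 10, 9)),
    "glucose": ((84, 86, 81, 86), (7, 6, 7, 8),
                (86, 85, 84, 85), (9, 7, 9, 9)),
    "insulin": ((4.6, 8.7, 9.3, 12.2), (2.5, 5.8, 6.5, 6.9),
                (10.2, 12.6, 18.1, 21.0), (4.8, 5.8, 11.4, 10.7)),
    "ldl": ((97, 104, 96, 108), (27, 33, 27, 27),
            (90, 89, 91, 97), (25, 26, 21, 25)),
    "waist": ((58, 70, 80, 83), (5, 8, 9, 12),
              (71, 82, 94, 104), (9, 9, 14, 14)),
    "sum_sf": ((35, 77, 94, 104), (17, 22, 21, 24),
               (83, 86, 82, 93), (27, 24, 26, 21)),
    "bmi_z": ((-0.27, 1.25, 3.55, 3.73), (0.55, 0.44, 1.50, 1.96),
              (-0.10, 1.29, 2.64, 3.76), (0.70, 0.98, 1.40, 1.43)),
    "whr": ((0.88, 0.91, 0.95, 0.94), (0.06, 0.08, 0.06, 0.08),
            (0.83, 0.84, 0.90, 0.90), (0.12, 0.07, 0.08, 0.07)),
}

_NORMAL_VARS = {"glucose", "bmi_z", "whr"}  # the rest are log-normal

#: within-subject latent (Gaussian-copula) tracking correlations
_DEFAULT_RHO = {
    "bmi": 0.70, "bmi_z": 0.70, "waist": 0.60, "whr": 0.40, "sum_sf": 0.50,
    "sbp": 0.45, "dbp": 0.40, "tag": 0.45, "hdl": 0.55,
    "glucose": 0.30, "insulin": 0.45, "ldl": 0.60,
}

_COMPONENT_VARS = ["sbp", "dbp", "tag", "hdl", "glucose", "insulin"]


@dataclass
class GroupVariable:
    """Group-conditional marginal parameters for one variable."""
    dist: str                 # "lognormal" | "normal"
    pre_mean: tuple
    pre_sd: tuple
    pub_mean: tuple
    pub_sd: tuple
    rho: float                # latent pre<->pub tracking correlation


@dataclass
class CohortParams:
    """Everything :func:`generate_cohort` needs, with validated invariants."""

    n_subjects: int = 143
    girl_fraction: float = 71.0 / 143.0
    #: prepubertal group mixture weights over GROUPS (NW, OW, OB-NoMetS, OB-MetS)
    group_weights: tuple = (43 / 143, 31 / 143, 56 / 143, 13 / 143)
    #: BMI-category transition probabilities, rows NW/OW/OB over pub categories
    transition: tuple = (
        (39 / 43, 4 / 43, 0.0),
        (7 / 31, 19 / 31, 5 / 31),
        (3 / 69, 16 / 69, 50 / 69),
    )
    #: P(pubertal MetS | pubertal obesity) for prepubertal OB-MetS / OB-NoMetS
    p_pub_mets_obm: float = (4 / 13) / (50 / 69)
    p_pub_mets_obn: float = (13 / 56) / (50 / 69)
    #: per-sex prepubertal age (mean, sd) and pre->pub elapsed-time range
    age_pre: dict = field(default_factory=lambda: {
        "girl": (7.5, 1.7), "boy": (8.2, 1.8)})
    age_gap: tuple = (5.0, 8.0)
    age_clip: tuple = (3.2, 11.5)
    #: pubertal Tanner probabilities over stages 2..5
    tanner_probs: dict = field(default_factory=lambda: {
        "girl": (0.05, 0.10, 0.15, 0.70), "boy": (0.20, 0.15, 0.10, 0.55)})
    height_sd: float = 6.0
    #: BMI offsets from the category cutoffs, per stage:
    #: NW below ow_cutoff (lognormal mean, sd); OW fraction across the band
    #: (beta mean, sd); OB above ob_cutoff (lognormal mean, sd)
    bmi_offsets: dict = field(default_factory=lambda: {
        "pre": {"NW": (2.4, 1.15), "OW": (0.55, 0.18),
                "OB": (3.85, 1.3), "OBM": (5.1, 3.0)},
        "pub": {"NW": (2.8, 1.9), "OW": (0.44, 0.20),
                "OB": (3.5, 3.5), "OBM": (7.0, 5.0)},
    })
    #: latent correlation between glucose and insulin (same stage)
    glucose_insulin_corr: float = 0.30
    #: latent correlation between LDL and HDL (total cholesterol dispersion)
    ldl_hdl_corr: float = 0.15
    skinfold_alpha: tuple = (6.0, 12.0, 12.0, 10.0)
    variables: dict = field(default_factory=dict)  # name -> GroupVariable
    totals: dict = field(default_factory=lambda: dict(TABLE_TOTALS))
    max_redraws: int = 5000

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if not np.isclose(sum(self.group_weights), 1.0):
            raise ParameterError("group mixture weights must sum to 1")
        if min(self.group_weights) < 0:
            raise ParameterError("group mixture weights must be non-negative")
        for row in self.transition:
            if not np.isclose(sum(row), 1.0) or min(row) < -1e-12:
                raise ParameterError("transition rows must be probability vectors")
        for p in (self.p_pub_mets_obm, self.p_pub_mets_obn, self.girl_fraction):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("probabilities must lie in [0, 1]")
        for v in self.variables.values():
            if not -1.0 < v.rho < 1.0:
                raise ParameterError("tracking correlations must lie in (-1, 1)")


def _mixture_moments(means, sds, weights):
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    w = np.asarray(weights, float)
    m = float(w @ means)
    var = float(w @ (sds ** 2) + w @ (means - m) ** 2)
    return m, np.sqrt(var)


def _calibrate(means, sds, weights, target_mean, target_sd):
    """Shift group means and scale group SDs so the mixture hits the targets."""
    means = np.asarray(means, float).copy()
    sds = np.asarray(sds, float).copy()
    m, _ = _mixture_moments(means, sds, weights)
    means += target_mean - m
    w = np.asarray(weights, float)
    between = float(w @ (means - target_mean) ** 2)
    within = float(w @ sds ** 2)
    f2 = (target_sd ** 2 - between) / within
    f = np.sqrt(np.clip(f2, 0.25, 4.0))
    return tuple(means), tuple(sds * f)


#: post-calibration SD multipliers compensating the dispersion added by the
#: MetS-consistency rejection step (measured once with the calibration script
#: at n=50,000; see docs/methods.md)
_SD_ADJUST = {("tag", "pre"): 0.93, ("tag", "pub"): 0.96, ("insulin", "pub"): 0.97}
_MEAN_ADJUST = {("tag", "pre"): -0.7, ("tag", "pub"): -1.5}


def default_parameters() -> CohortParams:
    """Default cohort parameters, moment-calibrated against the target totals."""
    params = CohortParams()
    w = params.group_weights
    for name, (pm, ps, qm, qs) in _GROUP_RAW.items():
        t = TABLE_TOTALS[name]
        pm2, ps2 = _calibrate(pm, ps, w, t[0], t[1])
        qm2, qs2 = _calibrate(qm, qs, w, t[2], t[3])
        fp = _SD_ADJUST.get((name, "pre"), 1.0)
        fq = _SD_ADJUST.get((name, "pub"), 1.0)
        dp = _MEAN_ADJUST.get((name, "pre"), 0.0)
        dq = _MEAN_ADJUST.get((name, "pub"), 0.0)
        params.variables[name] = GroupVariable(
            dist="normal" if name in _NORMAL_VARS else "lognormal",
            pre_mean=tuple(m + dp for m in pm2), pre_sd=tuple(s * fp for s in ps2),
            pub_mean=tuple(m + dq for m in qm2), pub_sd=tuple(s * fq for s in qs2),
            rho=_DEFAULT_RHO[name])
    return params


@dataclass
class PairedCohort:
    frame: pd.DataFrame
    params: CohortParams
    seed: int
    pre_group: pd.Series | None = None  # subject_id -> generating group


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _lognormal_params(mean, sd):
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _from_latent(z, dist, mean_by_group, sd_by_group, g_idx):
    mean = np.asarray(mean_by_group, float)[g_idx]
    sd = np.asarray(sd_by_group, float)[g_idx]
    if dist == "normal":
        return mean + sd * z
    mu, sigma = _lognormal_params(mean, sd)
    return np.exp(mu + sigma * z)


def _allocate(n, weights, rng):
    """Largest-remainder integer allocation, randomly permuted over subjects."""
    weights = np.asarray(weights, float)
    raw = weights * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    if rem > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
    labels = np.repeat(np.arange(len(weights)), counts)
    return labels[rng.permutation(n)]


def _beta_ab(mean, sd):
    v = sd ** 2
    vmax = mean * (1 - mean)
    v = min(v, 0.95 * vmax)
    k = vmax / v - 1.0
    return mean * k, (1 - mean) * k


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(params: CohortParams | None = None, seed: int = 0,
                    charts: ReferenceChartSet | None = None) -> PairedCohort:
    """Draw a paired cohort; deterministic given (params, seed)."""
    if params is None:
        params = default_parameters()
    if not params.variables:
        raise ParameterError("params.variables is empty; use default_parameters()")
    if charts is None:
        charts = synthetic_reference_charts()
    rng = np.random.default_rng(seed)
    n = params.n_subjects

    sex_idx = _allocate(n, (params.girl_fraction, 1 - params.girl_fraction), rng)
    sex = np.where(sex_idx == 0, "girl", "boy").astype(object)
    g_idx = _allocate(n, params.group_weights, rng)  # 0..3 over GROUPS

    # ages, Tanner, heights -------------------------------------------------
    age_pre = np.empty(n)
    tanner_pub = np.empty(n, int)
    for s in ("girl", "boy"):
        m = sex == s
        mu, sd = params.age_pre[s]
        age_pre[m] = np.clip(mu + sd * rng.standard_normal(m.sum()), *params.age_clip)
        tanner_pub[m] = rng.choice(np.arange(2, 6), size=m.sum(),
                                   p=params.tanner_probs[s])
    age_pub = age_pre + rng.uniform(*params.age_gap, size=n)
    z_height = rng.standard_normal(n)
    height_pre = expected_height(age_pre, sex) + params.height_sd * z_height
    height_pub = expected_height(age_pub, sex) + params.height_sd * z_height

    # BMI categories and transitions ----------------------------------------
    cat_pre = np.where(g_idx == 0, "NW", np.where(g_idx == 1, "OW", "OB")).astype(object)
    cat_pre_i = np.where(g_idx == 0, 0, np.where(g_idx == 1, 1, 2))
    trans = np.asarray(params.transition, float)
    u = rng.random(n)
    cum = np.cumsum(trans[cat_pre_i], axis=1)
    cat_pub_i = (u[:, None] > cum).sum(axis=1)
    cat_pub = np.asarray(CATEGORIES, dtype=object)[cat_pub_i]

    pub_mets = np.zeros(n, bool)
    ob_pub = cat_pub == "OB"
    r = rng.random(n)
    pub_mets[(g_idx == 3) & ob_pub & (r < params.p_pub_mets_obm)] = True
    pub_mets[(g_idx == 2) & ob_pub & (r < params.p_pub_mets_obn)] = True

    # BMI from category-band offsets ----------------------------------------
    rho_bmi = _DEFAULT_RHO["bmi"]
    z_adip_pre = rng.standard_normal(n)
    z_adip_pub = rho_bmi * z_adip_pre + np.sqrt(1 - rho_bmi ** 2) * rng.standard_normal(n)

    def bmi_from_band(cat_i, age, z, stage, obm_mask):
        ow, ob = charts.bmi_cutoffs(sex, age)
        offs = params.bmi_offsets[stage]
        out = np.empty(n)
        m = cat_i == 0
        mu, sg = _lognormal_params(*offs["NW"])
        out[m] = ow[m] - np.exp(mu + sg * (-z[m]))
        m = cat_i == 1
        a, b = _beta_ab(*offs["OW"])
        out[m] = ow[m] + (ob[m] - ow[m]) * sps.beta.ppf(sps.norm.cdf(z[m]), a, b)
        for key, m in (("OB", (cat_i == 2) & ~obm_mask), ("OBM", (cat_i == 2) & obm_mask)):
            mu, sg = _lognormal_params(*offs[key])
            out[m] = ob[m] + np.exp(mu + sg * z[m])
        return np.maximum(out, 10.5)

    bmi_pre = bmi_from_band(cat_pre_i, age_pre, z_adip_pre, "pre", g_idx == 3)
    bmi_pub = bmi_from_band(cat_pub_i, age_pub, z_adip_pub, "pub", pub_mets)
    weight_pre = bmi_pre * (height_pre / 100.0) ** 2
    weight_pub = bmi_pub * (height_pub / 100.0) ** 2

    # non-component group-conditional variables ------------------------------
    def tracked_pair(var: GroupVariable, z0=None):
        z1 = rng.standard_normal(n) if z0 is None else z0
        z2 = var.rho * z1 + np.sqrt(1 - var.rho ** 2) * rng.standard_normal(n)
        return z1, z2

    vals_pre: dict[str, np.ndarray] = {}
    vals_pub: dict[str, np.ndarray] = {}
    for name in ("bmi_z", "whr", "waist", "sum_sf"):
        var = params.variables[name]
        z1, z2 = tracked_pair(var, z_adip_pre if name == "bmi_z" else None)
        vals_pre[name] = _from_latent(z1, var.dist, var.pre_mean, var.pre_sd, g_idx)
        vals_pub[name] = _from_latent(z2, var.dist, var.pub_mean, var.pub_sd, g_idx)
    vals_pre["whr"] = np.clip(vals_pre["whr"], 0.55, 1.35)
    vals_pub["whr"] = np.clip(vals_pub["whr"], 0.55, 1.35)

    # component block with MetS-consistency constraints ----------------------
    comp = _COMPONENT_VARS
    cut = {
        ("sbp", "pre"): charts.percentile("sbp", "p95", sex, age_pre, height_pre),
        ("sbp", "pub"): charts.percentile("sbp", "p95", sex, age_pub, height_pub),
        ("dbp", "pre"): charts.percentile("dbp", "p95", sex, age_pre, height_pre),
        ("dbp", "pub"): charts.percentile("dbp", "p95", sex, age_pub, height_pub),
        ("tag", "pre"): charts.percentile("tag", "p95", sex, age_pre),
        ("tag", "pub"): charts.percentile("tag", "p95", sex, age_pub),
        ("hdl", "pre"): charts.percentile("hdl", "p05", sex, age_pre),
        ("hdl", "pub"): charts.percentile("hdl", "p05", sex, age_pub),
    }

    r_gi = params.glucose_insulin_corr
    s_gi = np.sqrt(1 - r_gi ** 2)

    def comp_values(z, stage):
        out = {}
        for j, name in enumerate(comp):
            var = params.variables[name]
            zj = z[:, j]
            if name == "insulin":
                zj = r_gi * z[:, comp.index("glucose")] + s_gi * zj
            mean = var.pre_mean if stage == "pre" else var.pub_mean
            sd = var.pre_sd if stage == "pre" else var.pub_sd
            out[name] = _from_latent(zj, var.dist, mean, sd, g_idx)
        out["glucose"] = np.maximum(out["glucose"], 45.0)
        return out

    def n_altered(v, stage):
        htn = (v["sbp"] > cut[("sbp", stage)]) | (v["dbp"] > cut[("dbp", stage)])
        return (htn.astype(int)
                + (v["glucose"] > 100.0).astype(int)
                + (v["tag"] > cut[("tag", stage)]).astype(int)
                + (v["hdl"] < cut[("hdl", stage)]).astype(int))

    lo_pre = np.where(g_idx == 3, 2, 0)
    hi_pre = np.where(g_idx == 2, 1, 4)
    lo_pub = np.where(pub_mets, 2, 0)
    hi_pub = np.where(ob_pub & ~pub_mets, 1, 4)

    z_pre = rng.standard_normal((n, len(comp)))
    for _ in range(params.max_redraws):
        na = n_altered(comp_values(z_pre, "pre"), "pre")
        viol = (na < lo_pre) | (na > hi_pre)
        if not viol.any():
            break
        z_pre[viol] = rng.standard_normal((int(viol.sum()), len(comp)))
    else:
        raise ParameterError("could not satisfy prepubertal MetS constraints; "
                             "group means may be inconsistent with the charts")

    rho_vec = np.array([params.variables[c].rho for c in comp])
    eps = rng.standard_normal((n, len(comp)))
    for _ in range(params.max_redraws):
        z_pub = rho_vec * z_pre + np.sqrt(1 - rho_vec ** 2) * eps
        na = n_altered(comp_values(z_pub, "pub"), "pub")
        viol = (na < lo_pub) | (na > hi_pub)
        if not viol.any():
            break
        eps[viol] = rng.standard_normal((int(viol.sum()), len(comp)))
    else:
        raise ParameterError("could not satisfy pubertal MetS constraints")

    cvals_pre = comp_values(z_pre, "pre")
    cvals_pub = comp_values(z_pub, "pub")

    # LDL: tracked and mildly coupled to the HDL latent (total cholesterol
    # dispersion reflects lipid-fraction covariance)
    ldl = params.variables["ldl"]
    r_lh = params.ldl_hdl_corr
    s_lh = np.sqrt(1 - r_lh ** 2)
    z_hdl_pre, z_hdl_pub = z_pre[:, comp.index("hdl")], z_pub[:, comp.index("hdl")]
    zl1, zl2 = tracked_pair(ldl)
    vals_pre["ldl"] = _from_latent(r_lh * z_hdl_pre + s_lh * zl1, ldl.dist,
                                   ldl.pre_mean, ldl.pre_sd, g_idx)
    vals_pub["ldl"] = _from_latent(r_lh * z_hdl_pub + s_lh * zl2, ldl.dist,
                                   ldl.pub_mean, ldl.pub_sd, g_idx)

    # skinfolds, hip, cholesterol --------------------------------------------
    props = rng.dirichlet(params.skinfold_alpha, size=n)
    subject_id = np.array([f"S{i:05d}" for i in range(n)], dtype=object)

    def stage_frame(stage, age, height, weight_, tanner, vals, cvals):
        df = pd.DataFrame({
            "subject_id": subject_id, "sex": sex, "stage": stage,
            "age": age, "tanner": tanner,
            "weight": weight_, "height": height,
            "waist": vals["waist"], "hip": vals["waist"] / vals["whr"],
            "sbp": cvals["sbp"], "dbp": cvals["dbp"],
            "ldl": vals["ldl"], "hdl": cvals["hdl"], "tag": cvals["tag"],
            "glucose": cvals["glucose"], "insulin": cvals["insulin"],
            "bmi_z": vals["bmi_z"],
        })
        df["total_chol"] = df["ldl"] + df["hdl"] + df["tag"] / 5.0
        sf = vals["sum_sf"][:, None] * props
        for k, c in enumerate(SKINFOLD_COLUMNS):
            df[c] = sf[:, k]
        return df

    pre_df = stage_frame("pre", age_pre, height_pre, weight_pre,
                         np.zeros(n, int), vals_pre, cvals_pre)
    pub_df = stage_frame("pub", age_pub, height_pub, weight_pub,
                         tanner_pub, vals_pub, cvals_pub)
    frame = pd.concat([pre_df, pub_df], ignore_index=True)
    frame = frame[REQUIRED_COLUMNS + ["bmi_z"]]
    groups = pd.Series(np.asarray(GROUPS, dtype=object)[g_idx], index=subject_id,
                       name="pre_group")
    return PairedCohort(frame=frame, params=params, seed=seed, pre_group=groups)


# ---------------------------------------------------------------------------
# artifact injection (outliers + missingness) for exclusion-filter testing
# ---------------------------------------------------------------------------

def inject_artifacts(cohort: pd.DataFrame, n_outliers: int, n_missing: int,
                     seed: int = 0, charts: ReferenceChartSet | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant exactly ``n_outliers`` normal-weight >p99 outliers and blank one
    field for ``n_missing`` other subjects.

    So that the outlier filter flags exactly the chosen subjects, natural
    normal-weight extremes are first pulled back to the variable's 97th
    percentile (only when ``n_outliers > 0``; with 0/0 the cohort is returned
    unchanged). Returns (modified cohort, artifact log).
    """
    from .criteria import add_derived_measures, classify_bmi_category

    if charts is None:
        charts = synthetic_reference_charts()
    df = cohort.copy().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    log_rows = []
    if n_outliers == 0 and n_missing == 0:
        return df, pd.DataFrame(columns=["subject_id", "stage", "variable", "kind"])

    der = add_derived_measures(df)
    pre = der[der["stage"] == "pre"]
    nw_ids = pre.loc[np.asarray(classify_bmi_category(
        pre["bmi"].to_numpy(float), pre["sex"], pre["age"], charts)) == "NW",
        "subject_id"].to_numpy()
    if n_outliers > len(nw_ids):
        raise ParameterError("not enough normal-weight subjects for outlier injection")

    chosen = rng.choice(nw_ids, size=n_outliers, replace=False) if n_outliers else []
    others = np.setdiff1d(df["subject_id"].unique(), chosen)
    if n_missing > len(others):
        raise ParameterError("not enough subjects left for missingness injection")
    missing_ids = rng.choice(others, size=n_missing, replace=False) if n_missing else []

    # blank fields FIRST: the outlier quantiles must be computed on the final
    # missingness pattern (the filters use nan-aware quantiles)
    missing_rows = []
    blankable = [c for c in df.columns if c not in
                 ("subject_id", "sex", "stage", "age", "tanner")]
    for sid in missing_ids:
        var = rng.choice(blankable)
        stage = rng.choice(["pre", "pub"])
        m = (df["subject_id"] == sid) & (df["stage"] == stage)
        df.loc[m, var] = np.nan
        missing_rows.append({"subject_id": sid, "stage": stage, "variable": var,
                             "kind": "missing"})

    if n_outliers > 0:
        keep_nw = np.setdiff1d(nw_ids, chosen)
        mask_keep = df["subject_id"].isin(keep_nw)
        for _ in range(20):
            der = add_derived_measures(df)
            capped_any = False
            for var in ANALYSIS_VARIABLES:
                if var not in der.columns:
                    continue
                for stage in ("pre", "pub"):
                    s = der["stage"] == stage
                    vals = der.loc[s, var].astype(float)
                    p99 = np.nanquantile(vals, 0.99)
                    # pull natural extremes deep into the bulk (the median):
                    # values parked near the tail quantiles keep straddling the
                    # interpolated p99 as it is re-estimated
                    target = np.nanquantile(vals, 0.50)
                    over = s & mask_keep & (der[var] > p99)
                    if not over.any():
                        continue
                    capped_any = True
                    ratio = target / der.loc[over, var]
                    if var in df.columns:
                        df.loc[over, var] = target
                    elif var == "bmi":
                        df.loc[over, "weight"] *= ratio
                    elif var == "whr":
                        df.loc[over, "hip"] /= ratio
                    elif var == "sum_sf":
                        df.loc[over, SKINFOLD_COLUMNS] = (
                            df.loc[over, SKINFOLD_COLUMNS].mul(ratio, axis=0))
                    elif var == "homa_ir":
                        df.loc[over, "insulin"] *= ratio
            if not capped_any:
                break

    # one inflation per (variable, stage) slot at a time: stacking several
    # extremes on one slot would drag the empirical p99 above the smaller ones
    inflatable = ["waist", "sbp", "dbp", "total_chol", "ldl", "hdl", "tag",
                  "glucose", "insulin"]
    slots = [(v, s) for v in inflatable for s in ("pre", "pub")]
    if n_outliers > 2 * len(slots):
        raise ParameterError("too many outliers for the available variables")
    slot_order = list(rng.permutation(len(slots)))
    base_max = {v: float(df[v].max()) for v in inflatable}
    for k, sid in enumerate(chosen):
        var, stage = slots[slot_order[k % len(slots)]]
        m = (df["subject_id"] == sid) & (df["stage"] == stage)
        df.loc[m, var] = (2.0 + 0.5 * (k // len(slots))) * base_max[var]
        log_rows.append({"subject_id": sid, "stage": stage, "variable": var,
                         "kind": "outlier"})

    log_rows += missing_rows
    return df, pd.DataFrame(log_rows, columns=["subject_id", "stage", "variable", "kind"])


# ---------------------------------------------------------------------------
# planted-rule cohorts for structure-recovery experiments
# ---------------------------------------------------------------------------

def planted_rule_cohort(n: int = 2000, seed: int = 0, noise: float = 0.02,
                        homa_cutoff: float = 2.5, sbp_cutoff: float = 106.0
                        ) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Cue table + labels generated by a planted two-level tree.

    The positive class is exactly (HOMA-IR > homa_cutoff) AND (SBP >
    sbp_cutoff), with a small label-flip noise. Returns (X, y, truth).
    """
    rng = np.random.default_rng(seed)
    mu, sg = _lognormal_params(2.2, 1.5)
    homa = np.exp(mu + sg * rng.standard_normal(n))
    sbp = 105.0 + 12.0 * rng.standard_normal(n)
    mu2, sg2 = _lognormal_params(60.0, 25.0)
    tag = np.exp(mu2 + sg2 * rng.standard_normal(n))
    bmi_z = 1.5 + 1.8 * rng.standard_normal(n)
    y = (homa > homa_cutoff) & (sbp > sbp_cutoff)
    flip = rng.random(n) < noise
    y = y ^ flip
    X = pd.DataFrame({"homa_ir": homa, "sbp": sbp, "tag": tag, "bmi_z": bmi_z})
    truth = {"cues": ["homa_ir", "sbp"], "thresholds": [homa_cutoff, sbp_cutoff],
             "directions": ["greater", "greater"]}
    return X, y.astype(bool), truth


# ---------------------------------------------------------------------------
# parameter (de)serialization
# ---------------------------------------------------------------------------

def save_params(params: CohortParams, path) -> None:
    d = dataclasses.asdict(params)
    d["variables"] = {k: dataclasses.asdict(v) for k, v in params.variables.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(d), fh, sort_keys=False)


def load_params(path) -> CohortParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["variables"] = {k: GroupVariable(**v) for k, v in d.get("variables", {}).items()}
    for key in ("group_weights", "age_gap", "age_clip", "skinfold_alpha"):
        if key in d:
            d[key] = tuple(d[key])
    if "transition" in d:
        d["transition"] = tuple(tuple(r) for r in d["transition"])
    return CohortParams(**d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
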