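import numpy as np
import pandas as pd
import pytest

from metsprog.charts import synthetic_reference_charts
from metsprog.simulate import default_parameters, generate_cohort

BIG_N = 50_000
BIG_SEED = 101


@pytest.fixture(scope="session")
def charts():
    return synthetic_reference_charts()


@pytest.fixture(scope="session")
def big_cohort(charts):
    """One large cohort shared by the calibration/recovery tests."""
    params = default_parameters()
    params.n_subjects = BIG_N
    return generate_cohort(params, seed=BIG_SEED, charts=charts)


@pytest.fixture(scope="session")
def small_cohort(charts):
    params = default_parameters()
    params.n_subjects = 143
    return generate_cohort(params, seed=11, charts=charts)


_DEFAULTS = {
    "sex": "girl", "weight": 30.0, "height": 130.0, "waist": 60.0, "hip": 68.0,
    "sf_bicipital": 8.0, "sf_tricipital": 12.0, "sf_subscapular": 10.0,
    "sf_suprailiac": 9.0, "sbp": 95.0, "dbp": 55.0, "total_chol": 160.0,
    "ldl": 95.0, "hdl": 55.0, "tag": 60.0, "glucose": 85.0, "insulin": 5.0,
}


def make_row(subject_id="S1", stage="pre", **overrides):
    """One hand-built cohort row: a healthy normal-weight girl by default."""
    row = dict(_DEFAULTS)
    row.update({"subject_id": subject_id, "stage": stage,
                "age": 8.0 if stage == "pre" else 14.0,
                "tanner": 0 if stage == "pre" else 3})
    row.update(overrides)
    return row


def make_cohort(rows):
    return pd.DataFrame(rows)


def make_paired(n, pre_overrides=None, pub_overrides=None):
    """n subjects with identical default pre and pub rows (plus overrides)."""
    rows = []
    for i in range(n):
        rows.append(make_row(f"P{i:04d}", "pre", **(pre_overrides or {})))
        rows.append(make_row(f"P{i:04d}", "pub", **(pub_overrides or {})))
    return pd.DataFrame(rows)


@pytest.fixture
def row_factory():
    return make_row


@pytest.fixture
def paired_factory():
    return make_paired
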