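import itertools

import numpy as np
import pandas as pd
import pytest

from metsprog.errors import DegenerateTestError, ValidationError
from metsprog.progression import (ContingencyTable, bmi_transition_matrix,
                                  component_tracking_table, odds_ratio,
                                  persistence_logistic, risk_ratio,
                                  transition_summary_from_counts)

from .conftest import make_cohort, make_row

Z = 1.959963984540054


def test_all_staying_subjects(charts):
    rows = []
    for i in range(4):
        rows += [make_row(f"A{i}", "pre"), make_row(f"A{i}", "pub")]
    t = bmi_transition_matrix(make_cohort(rows), charts)
    assert t.stayed == 1.0 and t.moved_up == 0.0 and t.moved_down == 0.0


def test_overall_persistence_from_printed_counts():
    counts = pd.DataFrame([[39, 4, 0], [7, 19, 5], [3, 16, 50]],
                          index=["NW", "OW", "OB"], columns=["NW", "OW", "OB"])
    t = transition_summary_from_counts(counts)
    assert t.n == 143
    assert t.stayed == pytest.approx(108 / 143)
    assert 100 * t.stayed == pytest.approx(75.5, abs=0.05)
    assert t.persistence["NW"] == pytest.approx(0.907, abs=5e-4)
    assert t.persistence["OW"] == pytest.approx(0.613, abs=5e-4)
    assert t.persistence["OB"] == pytest.approx(0.725, abs=5e-4)
    assert t.stayed + t.moved_up + t.moved_down == pytest.approx(1.0)


def test_single_upward_move(charts):
    rows = []
    for i in range(5):
        rows += [make_row(f"B{i}", "pre"), make_row(f"B{i}", "pub")]
    df = make_cohort(rows)
    # push one subject's pubertal BMI into obesity
    m = (df["subject_id"] == "B0") & (df["stage"] == "pub")
    df.loc[m, "weight"] = 90.0
    t = bmi_transition_matrix(df, charts)
    assert t.moved_up == pytest.approx(1 / 5)


def test_transition_invariant_to_row_order(charts, small_cohort):
    base = bmi_transition_matrix(small_cohort.frame, charts)
    shuffled = small_cohort.frame.sample(frac=1.0, random_state=5)
    again = bmi_transition_matrix(shuffled, charts)
    pd.testing.assert_frame_equal(base.counts, again.counts)


def _tracking_cohort(a, b, c, d):
    """Paired cohort with controlled low-HDL alteration counts (a,b,c,d)."""
    rows = []
    low, high = 30.0, 55.0  # HDL below/above the p05 cutoff at any age
    combos = [(low, low)] * a + [(low, high)] * b + [(high, low)] * c \
        + [(high, high)] * d
    for i, (hpre, hpub) in enumerate(combos):
        rows.append(make_row(f"T{i:03d}", "pre", hdl=hpre))
        rows.append(make_row(f"T{i:03d}", "pub", hdl=hpub))
    return make_cohort(rows)


def test_component_tracking_counts(charts):
    df = _tracking_cohort(4, 9, 13, 117)
    t = component_tracking_table(df, "hdl", charts)
    assert (t.a, t.b, t.c, t.d) == (4, 9, 13, 117)


def test_no_alterations_gives_empty_table(charts):
    df = _tracking_cohort(0, 0, 0, 20)
    t = component_tracking_table(df, "hdl", charts)
    assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 20)


def test_unknown_component_rejected(charts):
    with pytest.raises(ValidationError):
        component_tracking_table(_tracking_cohort(1, 1, 1, 1), "ferritin", charts)


def test_mets_tracking_risk_ratio_printed_margins():
    """13 prepubertal and 17 pubertal cases among 143 reconstruct RR = 3.08."""
    t = ContingencyTable(a=4, b=9, c=13, d=117)
    rr = risk_ratio(t)
    assert rr.estimate == pytest.approx(3.08, abs=0.005)
    orr = odds_ratio(t)
    assert orr.estimate == pytest.approx(4.00, abs=0.005)


def test_equal_risks_give_unit_rr():
    assert risk_ratio(ContingencyTable(5, 5, 8, 8)).estimate == pytest.approx(1.0)
    assert odds_ratio(ContingencyTable(3, 3, 3, 3)).estimate == pytest.approx(1.0)


def test_zero_cell_triggers_haldane_correction():
    e = risk_ratio(ContingencyTable(0, 10, 5, 85))
    assert np.isfinite(e.estimate) and e.estimate < 1.0
    assert "haldane" in e.method
    assert "haldane" not in risk_ratio(ContingencyTable(1, 9, 5, 85)).method


def test_empty_arm_is_degenerate():
    with pytest.raises(DegenerateTestError):
        risk_ratio(ContingencyTable(0, 0, 5, 5))


def _oracle(a, b, c, d):
    """Independent closed-form RR/OR with Haldane correction and Wald CIs."""
    if (a == 0) or (b == 0) or (c == 0) or (d == 0):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    rr = (a / (a + b)) / (c / (c + d))
    se_rr = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    orr = a * d / (b * c)
    se_or = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (rr, rr * np.exp(-Z * se_rr), rr * np.exp(Z * se_rr),
            orr, orr * np.exp(-Z * se_or), orr * np.exp(Z * se_or))


def test_effect_estimates_match_enumeration_oracle():
    """Exhaustive agreement on every 2x2 table with cells <= 5."""
    for a, b, c, d in itertools.product(range(6), repeat=4):
        if a + b == 0 or c + d == 0:
            continue
        t = ContingencyTable(a, b, c, d)
        rr_o, rr_lo, rr_hi, or_o, or_lo, or_hi = _oracle(a, b, c, d)
        rr = risk_ratio(t)
        orr = odds_ratio(t)
        assert rr.estimate == pytest.approx(rr_o, rel=1e-12)
        assert rr.ci_low == pytest.approx(rr_lo, rel=1e-9)
        assert rr.ci_high == pytest.approx(rr_hi, rel=1e-9)
        assert orr.estimate == pytest.approx(or_o, rel=1e-12)
        assert orr.ci_low == pytest.approx(or_lo, rel=1e-9)
        assert orr.ci_high == pytest.approx(or_hi, rel=1e-9)
        if rr.estimate >= 1.0:
            assert orr.estimate >= rr.estimate - 1e-12


def test_persistence_logistic_matches_closed_form_or(charts):
    df = _tracking_cohort(6, 4, 5, 25)
    est = persistence_logistic(df, "hdl", charts)
    closed = odds_ratio(ContingencyTable(6, 4, 5, 25))
    assert est.estimate == pytest.approx(closed.estimate, abs=5e-4)
    assert est.ci_low == pytest.approx(closed.ci_low, rel=0.01)


def test_persistence_logistic_all_negative_outcome(charts):
    df = _tracking_cohort(0, 5, 0, 25)
    with pytest.raises(DegenerateTestError):
        persistence_logistic(df, "hdl", charts)


def test_persistence_logistic_separation_flagged(charts):
    df = _tracking_cohort(10, 0, 0, 20)  # perfect persistence: separation
    est = persistence_logistic(df, "hdl", charts)
    assert est.flagged and est.ci_high == np.inf


def test_persistence_logistic_recovers_known_odds(charts):
    """Simulated tracking with known OR ~ 3 lands inside the Wald CI."""
    rng = np.random.default_rng(12)
    n = 4000
    pre_alt = rng.random(n) < 0.25
    p = np.where(pre_alt, 0.3, 0.3 / (0.7 * 3 + 0.3))  # odds ratio 3
    pub_alt = rng.random(n) < p
    rows = []
    for i in range(n):
        rows.append(make_row(f"R{i:05d}", "pre", hdl=30.0 if pre_alt[i] else 55.0))
        rows.append(make_row(f"R{i:05d}", "pub", hdl=30.0 if pub_alt[i] else 55.0))
    est = persistence_logistic(make_cohort(rows), "hdl", charts)
    assert est.ci_low < 3.0 < est.ci_high
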