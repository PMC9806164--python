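import itertools

import numpy as np
import pandas as pd
import pytest

from metsprog.errors import DomainError, ParameterError, StratificationError
from metsprog.simulate import planted_rule_cohort
from metsprog.validation import (CVConfig, backward_stepwise_logistic,
                                 bootstrap_oversample, cross_validate_fft,
                                 max_vif, roc_auc, stratified_folds)


def test_positives_spread_evenly_across_folds():
    y = np.zeros(143, bool)
    y[:17] = True
    folds = stratified_folds(y, 4, seed=0)
    pos_counts = sorted(np.bincount(folds[y], minlength=4))
    assert pos_counts == [4, 4, 4, 5]
    sizes = sorted(np.bincount(folds, minlength=4))
    assert sizes == [35, 36, 36, 36]


def test_too_few_positives_raise():
    y = np.zeros(20, bool)
    y[0] = True
    with pytest.raises(StratificationError):
        stratified_folds(y, 4, seed=0)


def test_bootstrap_sizes_and_determinism():
    idx = np.arange(107)
    boot = bootstrap_oversample(idx, 25, seed=3)
    assert len(boot) == 2675
    assert set(boot) <= set(idx)
    np.testing.assert_array_equal(boot, bootstrap_oversample(idx, 25, seed=3))
    plain = bootstrap_oversample(idx, 1, seed=4)
    assert len(plain) == 107
    same = bootstrap_oversample(np.array([9, 9, 9]), 2, seed=5)
    assert (same == 9).all()
    with pytest.raises(DomainError):
        bootstrap_oversample([], 2, seed=0)


def _cue_table(n=143, seed=0, n_pos=17):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"homa_ir": rng.lognormal(0.4, 0.6, n),
                      "sbp": rng.normal(104, 12, n),
                      "tag": rng.lognormal(4.0, 0.4, n)})
    score = 1.2 * np.log(X["homa_ir"]) + 0.05 * X["sbp"] + rng.normal(0, 1, n)
    y = np.zeros(n, bool)
    y[np.argsort(-score.to_numpy())[:n_pos]] = True
    return X, y


def test_cv_contract_twenty_disjoint_estimates():
    X, y = _cue_table()
    cfg = CVConfig(n_folds=4, n_repeats=5, bootstrap_factor=25, seed=1)
    res = cross_validate_fft(X, y, cfg)
    assert res.n_estimates == 20
    f = res.folds
    assert ((f["sens"].between(0, 1)) & (f["spec"].between(0, 1))
            & (f["wacc"].between(0, 1))).all()
    # bootstrap enlarges the training partition 25x; test partition untouched
    assert (f["n_train"] == 25 * (len(y) - f["n_test"])).all()
    # every fold holds out at least one positive
    assert (f["tp"] + f["fn"] >= 1).all()
    agg = res.aggregate()
    assert agg["wacc"] == pytest.approx(f["wacc"].mean())


def test_cv_deterministic_given_seed():
    X, y = _cue_table(seed=2)
    cfg = CVConfig(seed=7)
    a = cross_validate_fft(X, y, cfg).folds
    b = cross_validate_fft(X, y, CVConfig(seed=7)).folds
    pd.testing.assert_frame_equal(a, b)


def test_cv_recovers_planted_rule_performance():
    """Held-out sens/spec within 5 points of the planted rule's own values."""
    X, y, truth = planted_rule_cohort(n=2000, seed=21, noise=0.02)
    # the generating rule's performance on noisy labels is the ceiling
    pred_true = (X["homa_ir"] > truth["thresholds"][0]) \
        & (X["sbp"] > truth["thresholds"][1])
    sens_pop = (pred_true & y).sum() / y.sum()
    spec_pop = (~pred_true & ~y).sum() / (~y).sum()
    cfg = CVConfig(n_folds=4, n_repeats=2, bootstrap_factor=2, seed=3,
                   max_depth=3)
    agg = cross_validate_fft(X, y, cfg).aggregate()
    assert agg["sens"] == pytest.approx(sens_pop, abs=0.05)
    assert agg["spec"] == pytest.approx(spec_pop, abs=0.05)


def test_bad_cv_config_rejected():
    with pytest.raises(ParameterError):
        CVConfig(n_folds=1)
    with pytest.raises(ParameterError):
        CVConfig(bootstrap_factor=0)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def test_roc_examples():
    assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(1.0)
    assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)
    assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == pytest.approx(0.5)
    with pytest.raises(DomainError):
        roc_auc([1, 2], [1, 1])


def _auc_pairs(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_matches_pair_counting_oracle():
    rng = np.random.default_rng(8)
    for _ in range(300):
        n = rng.integers(3, 13)
        scores = rng.integers(0, 5, n).astype(float)  # ties on purpose
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            continue
        assert roc_auc(scores, y) == pytest.approx(_auc_pairs(scores, y),
                                                   abs=1e-12)


# ---------------------------------------------------------------------------
# stepwise logistic + VIF
# ---------------------------------------------------------------------------

def _logistic_data(n, seed, beta=1.2):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"signal": rng.normal(0, 1, n),
                      "noise1": rng.normal(0, 1, n),
                      "noise2": rng.normal(0, 1, n)})
    eta = -1.0 + beta * X["signal"].to_numpy()
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    return X, y.astype(float)


def test_stepwise_retains_generative_predictor():
    X, y = _logistic_data(1500, seed=9)
    model = backward_stepwise_logistic(X, y)
    assert "signal" in model.predictors
    row = model.table.set_index("predictor").loc["signal"]
    assert row["ci_low"] < np.exp(1.2) < row["ci_high"]


def test_stepwise_drops_pure_noise():
    rng = np.random.default_rng(10)
    X = pd.DataFrame({f"n{i}": rng.normal(0, 1, 400) for i in range(4)})
    y = (rng.random(400) < 0.3).astype(float)
    model = backward_stepwise_logistic(X, y)
    assert len(model.predictors) <= 1
    assert len(model.trace) >= 3


def test_stepwise_boundary_alphas():
    X, y = _logistic_data(300, seed=11)
    full = backward_stepwise_logistic(X, y, alpha_remove=1.0)
    assert set(full.predictors) == set(X.columns)
    empty = backward_stepwise_logistic(X, y, alpha_remove=0.0)
    assert empty.predictors == []


def test_stepwise_separation_flagged_not_crashed():
    rng = np.random.default_rng(12)
    X = pd.DataFrame({"perfect": np.r_[np.zeros(20), np.ones(20)],
                      "other": rng.normal(0, 1, 40)})
    y = np.r_[np.zeros(20), np.ones(20)]
    model = backward_stepwise_logistic(X, y, alpha_remove=1.0)
    assert model.flagged


def test_vif_orthogonal_and_duplicated():
    x1 = np.tile([1.0, -1.0], 50)
    x2 = np.repeat([1.0, -1.0], 50)
    X = pd.DataFrame({"a": x1, "b": x2})
    assert max_vif(X) == pytest.approx(1.0, abs=1e-9)
    X["c"] = X["a"]
    assert max_vif(X) == np.inf


def test_vif_correlated_pair_closed_form():
    # x2 = 0.8 x1 + 0.6 e with orthonormal x1, e: R^2 = 0.64, VIF = 2.78
    x1 = np.tile([1.0, -1.0], 50)
    e = np.tile([1.0, 1.0, -1.0, -1.0], 25)
    X = pd.DataFrame({"a": x1, "b": 0.8 * x1 + 0.6 * e})
    assert max_vif(X) == pytest.approx(1 / (1 - 0.64), rel=1e-9)


def test_vif_needs_two_predictors():
    with pytest.raises(DomainError):
        max_vif(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
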