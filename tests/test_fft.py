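import itertools

import numpy as np
import pandas as pd
import pytest

from metsprog.errors import DomainError, ValidationError
from metsprog.fft import (ConfusionMetrics, CueRule, FastFrugalTreeClassifier,
                          FFTree, build_fft, confusion, optimal_cue_threshold,
                          weighted_accuracy)


@pytest.mark.parametrize("sens,spec,w,expected", [
    (1.0, 1.0, 1.5, 1.0),
    (0.8, 0.6, 1.5, 0.72),       # (1.2 + 0.6) / 2.5
    (0.8, 0.6, 1.0, 0.7),        # balanced accuracy at w = 1
    (0.0, 1.0, 1.2, 1.0 / 2.2),
])
def test_weighted_accuracy_values(sens, spec, w, expected):
    assert weighted_accuracy(sens, spec, w) == pytest.approx(expected)


def test_weighted_accuracy_domain():
    with pytest.raises(DomainError):
        weighted_accuracy(0.5, 0.5, 0.0)
    with pytest.raises(DomainError):
        weighted_accuracy(1.2, 0.5, 1.5)


def test_confusion_counts_and_rates():
    m = confusion([True] * 17 + [True] * 25 + [False] * 101,
                  [True] * 17 + [False] * 126, w_ratio=1.5)
    assert (m.tp, m.fp, m.tn, m.fn) == (17, 25, 101, 0)
    assert m.sens == pytest.approx(1.0)
    assert m.acc == pytest.approx(118 / 143)
    assert round(100 * m.acc, 1) == 82.5
    m2 = confusion([True, True], [True, False])
    assert m2.spec == 0.0
    with pytest.raises(ValidationError):
        confusion([True], [True, False])


def test_separable_data_reaches_unit_wacc():
    v = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    y = np.array([0, 0, 0, 1, 1, 1], bool)
    rule = optimal_cue_threshold(v, y, 1.5)
    assert rule.wacc == pytest.approx(1.0)
    assert rule.direction == "greater" and 3.0 < rule.threshold < 10.0


def test_threshold_requires_both_classes_and_variation():
    with pytest.raises(DomainError):
        optimal_cue_threshold([1, 2, 3], [True, True, True], 1.5)
    with pytest.raises(DomainError):
        optimal_cue_threshold([2, 2, 2], [True, False, True], 1.5)


def _brute_force_rule(v, y, w):
    """Independent exhaustive scan over midpoints and directions."""
    v, y = np.asarray(v, float), np.asarray(y, bool)
    uniq = np.unique(v)
    best = None
    for t in (uniq[:-1] + uniq[1:]) / 2:
        for direction in ("greater", "less"):
            pred = v > t if direction == "greater" else v < t
            tp = (pred & y).sum()
            tn = (~pred & ~y).sum()
            sens, spec = tp / y.sum(), tn / (~y).sum()
            wacc = (w * sens + spec) / (w + 1)
            key = (wacc, sens, -t, direction == "greater")
            if best is None or key > best:
                best = key
    return best


def test_threshold_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    for i in range(250):
        n = rng.integers(4, 31)
        v = np.round(rng.normal(0, 1, n), 2)
        y = rng.random(n) < 0.4
        if y.all() or not y.any() or len(np.unique(v)) < 2:
            continue
        w = rng.choice([1.0, 1.2, 1.5, 2.0])
        rule = optimal_cue_threshold(v, y, w)
        wacc_o, sens_o, neg_t, _ = _brute_force_rule(v, y, w)
        assert rule.wacc == pytest.approx(wacc_o, abs=1e-12)
        assert rule.sens == pytest.approx(sens_o, abs=1e-12)
        assert rule.threshold == pytest.approx(-neg_t, abs=1e-12)


def test_uninformative_cue_near_chance():
    rng = np.random.default_rng(8)
    v = rng.normal(0, 1, 4000)
    y = rng.random(4000) < 0.5
    rule = optimal_cue_threshold(v, y, 1.0)
    assert 0.5 <= rule.wacc < 0.55


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------

def _predict_oracle(rules_in_order, exits, row):
    for rule, exit_side in zip(rules_in_order, exits):
        sat = (row[rule.variable] > rule.threshold if rule.direction == "greater"
               else row[rule.variable] < rule.threshold)
        if exit_side == "both":
            return sat
        if exit_side == "positive" and sat:
            return True
        if exit_side == "negative" and not sat:
            return False
    raise AssertionError("tree did not terminate")


def _brute_force_tree_wacc(X, y, w, max_depth):
    """Exhaustive fan search: marginal ranking order, all exits, all depths."""
    rules = {c: optimal_cue_threshold(X[c].to_numpy(), y, w, variable=c)
             for c in X.columns if len(np.unique(X[c])) > 1}
    ranked = sorted(rules, key=lambda c: (-rules[c].wacc, -rules[c].sens, c))
    best = -1.0
    for depth in range(1, min(max_depth, len(ranked)) + 1):
        top = [rules[c] for c in ranked[:depth]]
        for pattern in itertools.product(("positive", "negative"),
                                         repeat=depth - 1):
            exits = list(pattern) + ["both"]
            pred = np.array([_predict_oracle(top, exits, X.iloc[i])
                             for i in range(len(X))])
            tp = (pred & y).sum()
            tn = (~pred & ~y).sum()
            wacc = (w * tp / y.sum() + tn / (~y).sum()) / (w + 1)
            best = max(best, wacc)
    return best


def test_build_matches_exhaustive_search_on_small_instances():
    rng = np.random.default_rng(9)
    checked = 0
    while checked < 120:
        n = rng.integers(8, 21)
        X = pd.DataFrame({k: np.round(rng.normal(0, 1, n), 2)
                          for k in ("a", "b", "c")})
        y = rng.random(n) < 0.4
        if y.all() or not y.any():
            continue
        w = rng.choice([1.2, 1.5])
        tree = build_fft(X, y, w_ratio=w, max_depth=3)
        assert tree.metrics.wacc == pytest.approx(
            _brute_force_tree_wacc(X, y, w, 3), abs=1e-12)
        checked += 1


def test_single_informative_cue_gives_depth_one():
    rng = np.random.default_rng(10)
    n = 200
    X = pd.DataFrame({"signal": rng.normal(0, 1, n),
                      "noise1": rng.normal(0, 1, n),
                      "noise2": rng.normal(0, 1, n)})
    y = X["signal"].to_numpy() > 0.3
    tree = build_fft(X, y, w_ratio=1.5, max_depth=3)
    assert tree.depth == 1 and tree.cues[0].variable == "signal"
    assert tree.metrics.wacc == pytest.approx(1.0)


def test_max_depth_one_reduces_to_best_cue(small_cohort, charts):
    rng = np.random.default_rng(11)
    X = pd.DataFrame({k: rng.normal(0, 1, 60) for k in ("a", "b")})
    y = (X["a"] + 0.5 * rng.normal(0, 1, 60)) > 0
    tree = build_fft(X, y, w_ratio=1.5, max_depth=1)
    best = max((optimal_cue_threshold(X[c].to_numpy(), y, 1.5, variable=c)
                for c in X.columns), key=lambda r: (r.wacc, r.sens))
    assert tree.depth == 1
    assert tree.metrics.wacc == pytest.approx(best.wacc)


def test_first_level_positive_exit_dominates():
    tree = FFTree(cues=[CueRule("a", "greater", 1.0),
                        CueRule("b", "less", 0.0)],
                  exits=["positive", "both"])
    assert tree.predict({"a": 5.0, "b": 100.0}) is True
    assert tree.predict({"a": 0.0, "b": 100.0}) is False
    assert tree.predict({"a": 0.0, "b": -1.0}) is True


def test_depth_one_greater_threshold():
    tree = FFTree(cues=[CueRule("a", "greater", 2.0)], exits=["both"])
    assert tree.predict({"a": 1.0}) is False
    assert tree.predict({"a": 3.0}) is True


def test_missing_variable_named_in_error():
    tree = FFTree(cues=[CueRule("homa_ir", "greater", 2.5)], exits=["both"])
    with pytest.raises(ValidationError, match="homa_ir"):
        tree.predict({"sbp": 100.0})


def test_training_metrics_self_consistent():
    rng = np.random.default_rng(12)
    X = pd.DataFrame({k: rng.normal(0, 1, 80) for k in ("a", "b", "c")})
    y = (X["a"] - X["b"]) > 0.2
    tree = build_fft(X, y, w_ratio=1.2, max_depth=3)
    m = confusion(tree.predict(X), y, 1.2)
    assert (m.tp, m.fp, m.tn, m.fn) == (tree.metrics.tp, tree.metrics.fp,
                                        tree.metrics.tn, tree.metrics.fn)


def test_serialization_round_trip():
    rng = np.random.default_rng(13)
    X = pd.DataFrame({k: rng.normal(0, 1, 50) for k in ("a", "b")})
    y = X["a"] > 0
    tree = build_fft(X, y, w_ratio=1.5, max_depth=2)
    again = FFTree.from_json(tree.to_json())
    Xnew = pd.DataFrame({k: rng.normal(0, 1, 200) for k in ("a", "b")})
    np.testing.assert_array_equal(tree.predict(Xnew), again.predict(Xnew))
    assert again.w_ratio == tree.w_ratio
    assert "training" in again.render()


def test_increasing_w_ratio_never_lowers_cue_sensitivity():
    """Over a fixed candidate set (all midpoints x directions of one cue) the
    w-weighted argmax moves monotonically toward higher sensitivity."""
    rng = np.random.default_rng(14)
    for _ in range(40):
        n = 60
        v = rng.normal(0, 1, n)
        y = (v + rng.normal(0, 0.8, n)) > 0.5
        if y.all() or not y.any():
            continue
        sens = [optimal_cue_threshold(v, y, w).sens
                for w in (1.0, 1.2, 1.5, 2.0, 4.0)]
        assert all(b >= a - 1e-12 for a, b in zip(sens, sens[1:]))


# ---------------------------------------------------------------------------
# sklearn estimator
# ---------------------------------------------------------------------------

def test_estimator_follows_sklearn_protocol():
    from sklearn.base import clone

    rng = np.random.default_rng(15)
    X = rng.normal(0, 1, (100, 3))
    y = (X[:, 0] > 0.2).astype(int)
    clf = FastFrugalTreeClassifier(w_ratio=1.2, max_depth=2)
    assert clone(clf).get_params()["w_ratio"] == 1.2
    clf.fit(X, y)
    assert hasattr(clf, "tree_") and clf.n_features_in_ == 3
    pred = clf.predict(X)
    assert set(np.unique(pred)) <= {0, 1}
    assert clf.score(X, y) > 0.95
    clf2 = FastFrugalTreeClassifier(cues=["x0"]).set_params(max_depth=1)
    clf2.fit(X, y)
    assert clf2.tree_.depth == 1


def test_estimator_with_dataframe_and_labels():
    rng = np.random.default_rng(16)
    X = pd.DataFrame({"homa_ir": rng.lognormal(0.5, 0.5, 150),
                      "sbp": rng.normal(105, 10, 150)})
    y = np.where(X["homa_ir"] > 2.0, "mets", "healthy")
    clf = FastFrugalTreeClassifier().fit(X, y)
    assert set(clf.predict(X)) <= {"mets", "healthy"}
    assert list(clf.feature_names_in_) == ["homa_ir", "sbp"]
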