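"""Fast-and-frugal trees (FFTs) under a weighted-accuracy objective.

An FFT is an ordered list of single-variable threshold rules ("cues"). Every
non-final level exits on exactly one side — a record either gets classified
immediately (the exit side) or falls through to the next cue; the final level
classifies both ways.  Trees are scored by weighted accuracy

    wacc = (w * sensitivity + specificity) / (w + 1)

where ``w`` (the sensitivity weight ratio) expresses how much more important
it is to catch true positives than to avoid false positives (w = 1 reduces to
balanced accuracy).

Construction is the common "fan" procedure: each candidate cue is thresholded
independently on the full training set (maximizing marginal wacc over data
midpoints, both directions), cues are ranked by marginal wacc, and for every
depth up to ``max_depth`` all 2^(depth-1) exit-side assignments of the top
cues are enumerated; the tree with the best training wacc wins.  All ties are
broken deterministically (higher sensitivity, then fewer levels, then cue
name order).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DomainError, ValidationError

DIRECTIONS = ("greater", "less")


def weighted_accuracy(sens: float, spec: float, w_ratio: float) -> float:
    """Ratio-normalized convex combination of sensitivity and specificity."""
    if w_ratio <= 0:
        raise DomainError("w_ratio must be positive")
    s, p = np.asarray(sens, float), np.asarray(spec, float)
    if np.any((s < 0) | (s > 1)) or np.any((p < 0) | (p > 1)):
        raise DomainError("sensitivity and specificity must lie in [0, 1]")
    out = (w_ratio * s + p) / (w_ratio + 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    w_ratio: float = 1.5

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sens(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def spec(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def wacc(self) -> float:
        return weighted_accuracy(self.sens, self.spec, self.w_ratio)


def confusion(predictions, labels, w_ratio: float = 1.5) -> ConfusionMetrics:
    pred = np.asarray(predictions, bool)
    y = np.asarray(labels, bool)
    if pred.shape != y.shape:
        raise ValidationError("predictions and labels differ in length")
    return ConfusionMetrics(tp=int((pred & y).sum()), fp=int((pred & ~y).sum()),
                            tn=int((~pred & ~y).sum()), fn=int((~pred & y).sum()),
                            w_ratio=w_ratio)


@dataclass
class CueRule:
    """Threshold rule predicting the positive class when satisfied."""
    variable: str
    direction: str            # "greater": positive when value > threshold
    threshold: float
    sens: float = np.nan
    spec: float = np.nan
    wacc: float = np.nan

    def satisfied(self, values) -> np.ndarray:
        v = np.asarray(values, float)
        return v > self.threshold if self.direction == "greater" else v < self.threshold


def optimal_cue_threshold(values, labels, w_ratio: float = 1.5,
                          variable: str = "cue") -> CueRule:
    """Best single-cue rule over data midpoints, both directions.

    Ties are broken toward higher sensitivity, then the lower threshold, then
    direction name order.
    """
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    if np.isnan(v).any():
        raise DomainError("cue values must not contain NaN")
    npos, nneg = int(y.sum()), int((~y).sum())
    if npos == 0 or nneg == 0:
        raise DomainError("both classes must be present")

    order = np.argsort(v, kind="mergesort")
    vs, ys = v[order], y[order]
    uniq, first = np.unique(vs, return_index=True)
    if len(uniq) == 1:
        raise DomainError("cue is constant; no threshold separates anything")
    mids = (uniq[:-1] + uniq[1:]) / 2.0

    # cumulative positives among values <= each unique value
    cpos = np.cumsum(ys)
    last = np.r_[first[1:] - 1, len(vs) - 1]
    pos_le = cpos[last][:-1]                 # positives with value <= uniq[i]
    n_le = (last + 1)[:-1].astype(float)

    # direction "greater": predict positive when v > t
    sens_g = (npos - pos_le) / npos
    spec_g = (n_le - pos_le) / nneg
    # direction "less": predict positive when v < t  (strict; v <= uniq[i])
    sens_l = pos_le / npos
    spec_l = (nneg - (n_le - pos_le)) / nneg

    best = None
    for direction, sens_arr, spec_arr in (("greater", sens_g, spec_g),
                                          ("less", sens_l, spec_l)):
        wacc_arr = (w_ratio * sens_arr + spec_arr) / (w_ratio + 1.0)
        # max wacc, then max sens, then lowest threshold
        i = np.lexsort((mids, -sens_arr, -wacc_arr))[0]
        key = (wacc_arr[i], sens_arr[i], -mids[i],
               1 if direction == "greater" else 0)
        if best is None or key > best[0]:
            best = (key, CueRule(variable, direction, float(mids[i]),
                                 float(sens_arr[i]), float(spec_arr[i]),
                                 float(wacc_arr[i])))
    return best[1]


@dataclass
class FFTree:
    """Ordered cue list with one exit side per non-final level."""
    cues: list                     # list[CueRule]
    exits: list                    # per level: "positive"/"negative"; last "both"
    w_ratio: float = 1.5
    metrics: ConfusionMetrics | None = None

    def __post_init__(self):
        if len(self.exits) != len(self.cues):
            raise ValidationError("one exit per level required")
        if self.exits and self.exits[-1] != "both":
            raise ValidationError("final level must exit both ways")
        if any(e not in ("positive", "negative") for e in self.exits[:-1]):
            raise ValidationError("non-final exits must be 'positive' or 'negative'")

    @property
    def depth(self) -> int:
        return len(self.cues)

    def predict(self, data) -> np.ndarray:
        """Classify records (DataFrame, mapping of arrays, or single dict)."""
        single = isinstance(data, dict) and not isinstance(
            next(iter(data.values()), None), (list, np.ndarray, pd.Series))
        if single:
            data = {k: [v] for k, v in data.items()}
        for rule in self.cues:
            if rule.variable not in data:
                raise ValidationError(f"record is missing variable {rule.variable!r}")
        n = len(np.asarray(data[self.cues[0].variable]))
        out = np.zeros(n, bool)
        undecided = np.ones(n, bool)
        for rule, exit_side in zip(self.cues, self.exits):
            sat = rule.satisfied(np.asarray(data[rule.variable], float))
            if exit_side == "positive":
                hit = undecided & sat
                out[hit] = True
                undecided &= ~sat
            elif exit_side == "negative":
                miss = undecided & ~sat
                out[miss] = False
                undecided &= sat
            else:  # final level: classify everything still undecided
                out[undecided] = sat[undecided]
                undecided[:] = False
        return bool(out[0]) if single else out

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        doc = {"cues": [{**asdict(c), "exit": e}
                        for c, e in zip(self.cues, self.exits)],
               "w_ratio": self.w_ratio,
               "metrics": asdict(self.metrics) if self.metrics else None}
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FFTree":
        doc = json.loads(text)
        cues, exits = [], []
        for c in doc["cues"]:
            exits.append(c.pop("exit"))
            cues.append(CueRule(**c))
        metrics = ConfusionMetrics(**doc["metrics"]) if doc.get("metrics") else None
        return cls(cues=cues, exits=exits, w_ratio=doc["w_ratio"], metrics=metrics)

    def render(self) -> str:
        """Figure-style text rendering of the decision list."""
        lines = []
        for i, (rule, exit_side) in enumerate(zip(self.cues, self.exits)):
            op = ">" if rule.direction == "greater" else "<"
            cond = f"{rule.variable} {op} {rule.threshold:g}"
            if exit_side == "both":
                lines.append(f"[{i + 1}] if {cond}: RISK else: NO RISK")
            elif exit_side == "positive":
                lines.append(f"[{i + 1}] if {cond}: RISK else: next cue")
            else:
                lines.append(f"[{i + 1}] if not {cond}: NO RISK else: next cue")
        if self.metrics is not None:
            m = self.metrics
            lines.append(f"training: sens={m.sens:.3f} spec={m.spec:.3f} "
                         f"acc={m.acc:.3f} wacc={m.wacc:.3f} "
                         f"(tp={m.tp} fp={m.fp} tn={m.tn} fn={m.fn})")
        return "\n".join(lines)


def _better(key_a, names_a, key_b, names_b) -> bool:
    """True when (key_a, names_a) beats (key_b, names_b).

    key = (wacc, sens, -depth) maximized; final tie goes to the
    lexicographically smaller cue-name tuple (reproducibility).
    """
    if key_b is None:
        return True
    if key_a != key_b:
        return key_a > key_b
    return tuple(names_a) < tuple(names_b)


def build_fft(X: pd.DataFrame, y, w_ratio: float = 1.5, max_depth: int = 4,
              cues: list | None = None) -> FFTree:
    """Build a fast-and-frugal tree maximizing training weighted accuracy."""
    y = np.asarray(y, bool)
    if y.sum() == 0 or (~y).sum() == 0:
        raise DomainError("training data must contain both classes")
    if cues is None:
        cues = [c for c in X.columns]
    if not cues:
        raise ValidationError("no candidate cues")

    rules = {}
    for c in cues:
        try:
            rules[c] = optimal_cue_threshold(X[c].to_numpy(float), y, w_ratio,
                                             variable=c)
        except DomainError:
            continue  # constant cue: unusable
    if not rules:
        raise DomainError("no usable (non-constant) cues")
    ranked = sorted(rules, key=lambda c: (-rules[c].wacc, -rules[c].sens, c))

    best_key, best_names, best_tree = None, None, None
    for depth in range(1, min(max_depth, len(ranked)) + 1):
        top = ranked[:depth]
        for pattern in product(("positive", "negative"), repeat=depth - 1):
            exits = list(pattern) + ["both"]
            tree = FFTree(cues=[rules[c] for c in top], exits=exits,
                          w_ratio=w_ratio)
            m = confusion(tree.predict(X), y, w_ratio)
            key = (round(m.wacc, 12), round(m.sens, 12), -depth)
            if _better(key, top, best_key, best_names):
                best_key, best_names, best_tree = key, top, tree
                best_tree.metrics = m
    return best_tree


#: default prepubertal candidate cues for pubertal-MetS prediction
DEFAULT_CUES = ["bmi_z", "waist", "sbp", "dbp", "tag", "hdl", "ldl",
                "glucose", "homa_ir", "age"]


class FastFrugalTreeClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn estimator wrapper around :func:`build_fft`.

    Parameters
    ----------
    w_ratio : float
        Sensitivity-to-specificity importance ratio of the weighted-accuracy
        objective.
    max_depth : int
        Maximum number of cue levels.
    cues : list of str or None
        Candidate cue columns; defaults to all columns of the training frame
        (or positional names ``x0..`` for array input).

    Attributes
    ----------
    tree_ : FFTree
        The fitted tree.
    feature_names_in_ : ndarray of str
    classes_ : ndarray
    """

    def __init__(self, w_ratio: float = 1.5, max_depth: int = 4,
                 cues: list | None = None):
        self.w_ratio = w_ratio
        self.max_depth = max_depth
        self.cues = cues

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D")
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def fit(self, X, y):
        frame = self._as_frame(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise DomainError("binary classification only")
        yb = y == self.classes_[1]
        self.tree_ = build_fft(frame, yb, w_ratio=self.w_ratio,
                               max_depth=self.max_depth, cues=self.cues)
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        frame = self._as_frame(X)
        pred = self.tree_.predict(frame)
        return np.where(pred, self.classes_[1], self.classes_[0])

    def score(self, X, y):
        """Weighted accuracy on (X, y) at the estimator's w_ratio."""
        check_is_fitted(self, "tree_")
        yb = np.asarray(y) == self.classes_[1]
        m = confusion(self.tree_.predict(self._as_frame(X)), yb, self.w_ratio)
        return m.wacc
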