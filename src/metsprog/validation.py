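"""Out-of-sample evaluation of the FFT procedure and regression baselines.

The cross-validation scheme: stratified k-fold (every fold receives held-out
positives), with within-fold bootstrap oversampling of the *training*
partition only (enlarging it ``bootstrap_factor`` times), repeated
``n_repeats`` times — k=4 folds x 5 repeats = 20 held-out estimates by
default.  Oversampling never touches the held-out partition; leaking
resampled test rows would make the held-out metrics meaningless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import (DegenerateTestError, DomainError, ParameterError,
                     StratificationError, ValidationError)
from .fft import ConfusionMetrics, FFTree, build_fft, confusion

Z95 = 1.959963984540054


@dataclass
class CVConfig:
    n_folds: int = 4
    n_repeats: int = 5
    bootstrap_factor: int = 25
    w_ratio: float = 1.5
    max_depth: int = 4
    cues: list | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ParameterError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ParameterError("n_repeats must be >= 1")
        if self.bootstrap_factor < 1:
            raise ParameterError("bootstrap_factor must be >= 1")


@dataclass
class CVResult:
    folds: pd.DataFrame           # repeat, fold, tp, fp, tn, fn, sens, spec, acc, wacc
    trees: list = field(default_factory=list)
    config: CVConfig | None = None

    @property
    def n_estimates(self) -> int:
        return len(self.folds)

    def aggregate(self) -> pd.Series:
        return self.folds[["sens", "spec", "acc", "wacc"]].mean()


def stratified_folds(labels, n_folds: int, seed: int = 0) -> np.ndarray:
    """Fold assignment partitioning positives and negatives separately."""
    y = np.asarray(labels, bool)
    if int(y.sum()) < n_folds:
        raise StratificationError(
            f"{int(y.sum())} positives cannot cover {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = k
    return assignment


def bootstrap_oversample(indices, factor: int, seed: int = 0) -> np.ndarray:
    """Sample with replacement factor x len(indices) indices."""
    idx = np.asarray(indices)
    if len(idx) == 0:
        raise DomainError("cannot resample an empty index set")
    if factor < 1:
        raise ParameterError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.choice(idx, size=factor * len(idx), replace=True)


def cross_validate_fft(X: pd.DataFrame, y, config: CVConfig) -> CVResult:
    """Stratified repeated CV of the FFT builder with bootstrap oversampling."""
    y = np.asarray(y, bool)
    if len(X) != len(y):
        raise ValidationError("X and y differ in length")
    root = np.random.SeedSequence(config.seed)
    fold_rows, trees = [], []
    for rep in range(config.n_repeats):
        rep_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        assignment = stratified_folds(y, config.n_folds, seed=rep_seed)
        for fold in range(config.n_folds):
            test_mask = assignment == fold
            train_idx = np.flatnonzero(~test_mask)
            test_idx = np.flatnonzero(test_mask)
            assert not np.intersect1d(train_idx, test_idx).size
            boot_seed = rep_seed * config.n_folds + fold + 1
            tree = None
            for retry in range(10):
                boot = bootstrap_oversample(train_idx, config.bootstrap_factor,
                                            seed=boot_seed + 7919 * retry)
                yb = y[boot]
                if yb.all() or not yb.any():
                    continue
                tree = build_fft(X.iloc[boot], yb, w_ratio=config.w_ratio,
                                 max_depth=config.max_depth, cues=config.cues)
                break
            if tree is None:
                raise DegenerateTestError(
                    "training partition single-class after bootstrap retries")
            m = confusion(tree.predict(X.iloc[test_idx]), y[test_idx],
                          config.w_ratio)
            trees.append(tree)
            fold_rows.append({
                "repeat": rep, "fold": fold, "n_train": len(boot),
                "n_test": len(test_idx), "tp": m.tp, "fp": m.fp,
                "tn": m.tn, "fn": m.fn, "sens": m.sens, "spec": m.spec,
                "acc": m.acc, "wacc": m.wacc})
    return CVResult(folds=pd.DataFrame(fold_rows), trees=trees, config=config)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (rank/Mann-Whitney with tie correction)."""
    y = np.asarray(labels, bool)
    s = np.asarray(scores, float)
    if y.all() or not y.any():
        raise DomainError("both classes must be present")
    return float(roc_auc_score(y, s))


@dataclass
class SelectedModel:
    predictors: list
    table: pd.DataFrame           # predictor, coef, or_, ci_low, ci_high, p_value
    trace: list                   # (step, removed predictor, its p-value)
    flagged: bool = False         # separation encountered


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=500)
    return fit


def backward_stepwise_logistic(X: pd.DataFrame, y, predictors: list | None = None,
                               alpha_remove: float = 0.05) -> SelectedModel:
    """Backward elimination by the largest Wald p-value above ``alpha_remove``.

    ``alpha_remove=1`` keeps the full model; ``alpha_remove=0`` empties it.
    Separation is reported via ``flagged`` with infinite-CI handling, not a
    crash.
    """
    y = np.asarray(y, float)
    if len(np.unique(y)) != 2:
        raise DomainError("outcome must have both classes")
    if predictors is None:
        predictors = list(X.columns)
    current = list(predictors)
    if X[current].isna().any().any():
        raise ValidationError("complete cases required")
    trace = []
    flagged = False
    step = 0
    while current:
        try:
            fit = _fit_logit(X[current], y)
            pvals = fit.pvalues.drop("const")
            if not np.isfinite(pvals.to_numpy()).all():
                flagged = True
                pvals = pvals.fillna(1.0)
        except Exception:
            flagged = True
            # remove deterministically on failure: last predictor
            trace.append((step, current[-1], np.nan))
            current = current[:-1]
            step += 1
            continue
        worst = pvals.idxmax()
        if pvals[worst] > alpha_remove:
            trace.append((step, worst, float(pvals[worst])))
            current.remove(worst)
            step += 1
        else:
            break

    if not current:
        table = pd.DataFrame(columns=["predictor", "coef", "or_", "ci_low",
                                      "ci_high", "p_value"])
        return SelectedModel(predictors=[], table=table, trace=trace,
                             flagged=flagged)

    fit = _fit_logit(X[current], y)
    rows = []
    for name in current:
        beta, se = fit.params[name], fit.bse[name]
        if not np.isfinite(se) or se > 50:
            flagged = True
            lo, hi = 0.0, np.inf
        else:
            lo, hi = np.exp(beta - Z95 * se), np.exp(beta + Z95 * se)
        rows.append({"predictor": name, "coef": float(beta),
                     "or_": float(np.exp(beta)), "ci_low": float(lo),
                     "ci_high": float(hi), "p_value": float(fit.pvalues[name])})
    return SelectedModel(predictors=current, table=pd.DataFrame(rows),
                         trace=trace, flagged=flagged)


def max_vif(X: pd.DataFrame, predictors: list | None = None) -> float:
    """Largest variance inflation factor VIF_j = 1/(1 - R²_j) among predictors."""
    if predictors is None:
        predictors = list(X.columns)
    if len(predictors) < 2:
        raise DomainError("VIF needs at least two predictors")
    out = 0.0
    for name in predictors:
        others = [p for p in predictors if p != name]
        yv = X[name].to_numpy(float)
        if np.allclose(yv, yv[0]):
            raise DomainError(f"predictor {name!r} is constant")
        Xo = sm.add_constant(X[others].to_numpy(float), has_constant="add")
        res = sm.OLS(yv, Xo).fit()
        r2 = min(res.rsquared, 1.0)
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out = max(out, vif)
    return float(out)
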