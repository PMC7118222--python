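"""Treatment-response metrics and leave-one-out SVM/SVR evaluation.

The reduction ratio RR = (baseline - week8) / baseline summarises symptom
improvement per PANSS domain.  Cluster-mean NH features feed (a) a
leave-one-out SVM separating patients from controls (accuracy /
sensitivity / specificity from the pooled fold predictions) and (b) a
leave-one-out epsilon-SVR predicting RR, scored by the Pearson correlation
between held-out predictions and the actual ratios against a Bonferroni
threshold (default 0.05/16: 4 regions x 4 PANSS domains).

Hyperparameters (C, gamma) are selected by a grid search nested inside
each training fold by default (no leakage into the held-out subject); a
``pooled`` mode selecting once on all data — the likelier historical
protocol, with its optimism risk — is available and labelled as such.
The soft-margin linear SVM (hinge loss + l2 penalty) is additionally
implemented directly as a small dual quadratic program; it serves as the
correctness oracle for the production libsvm path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.model_selection import GridSearchCV, LeaveOneOut, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .inference import pearson_corr

__all__ = [
    "SVMModel", "ClassifierReport", "SVRReport",
    "reduction_ratio", "confusion_metrics", "bonferroni_threshold",
    "default_grid", "loo_svm_classify", "loo_svr_predict", "train_svm_primal",
]


def default_grid(step: int = 2):
    """LIBSVM-style powers-of-two grid: C in 2^[-5, 15], gamma in 2^[-15, 3]."""
    return {"C": [2.0**e for e in range(-5, 16, step)],
            "gamma": [2.0**e for e in range(-15, 4, step)]}


def reduction_ratio(score_baseline: float, score_week8: float) -> float:
    """RR = (baseline - week8) / baseline; requires a positive baseline."""
    if score_baseline <= 0:
        raise ValueError("baseline score must be positive")
    return (score_baseline - score_week8) / score_baseline


def confusion_metrics(tp: int, fn: int, tn: int, fp: int):
    """(accuracy, sensitivity, specificity) as percentages, 2 decimals."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("each class needs at least one subject")
    acc = 100.0 * (tp + tn) / (tp + fn + tn + fp)
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return round(acc, 2), round(sens, 2), round(spec, 2)


def bonferroni_threshold(alpha: float = 0.05, m: int = 16) -> float:
    if not 0 < alpha < 1 or m < 1:
        raise ValueError("need 0 < alpha < 1 and m >= 1")
    return alpha / m


@dataclass
class ClassifierReport:
    predictions: np.ndarray
    labels: np.ndarray
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float
    grid_surface: list = field(default_factory=list)  # (C, gamma, cv accuracy)


@dataclass
class SVRReport:
    predictions: np.ndarray
    target: np.ndarray
    r: float
    p: float
    bonferroni_alpha: float
    significant: bool
    grid_surface: list = field(default_factory=list)


def _check_features(features, n_min):
    x = np.atleast_2d(np.asarray(features, float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    if x.shape[0] < n_min:
        raise ValueError(f"need at least {n_min} subjects")
    return x


def _n_combos(grid: dict) -> int:
    n = 1
    for v in grid.values():
        n *= len(v)
    return n


def _fit_with_grid(estimator_cls, x, y, grid, scoring, inner_cv):
    """Grid-searched scaler+SVM pipeline; returns fitted search object."""
    pipe = Pipeline([("scale", StandardScaler()),
                     ("svm", estimator_cls())])
    params = {f"svm__{k}": v for k, v in grid.items()}
    return GridSearchCV(pipe, params, cv=inner_cv, scoring=scoring, n_jobs=None).fit(x, y)


def _fit_single(estimator_cls, x, y, grid):
    """Degenerate one-point grid: fit directly, no inner search."""
    params = {k: v[0] for k, v in grid.items()}
    pipe = Pipeline([("scale", StandardScaler()),
                     ("svm", estimator_cls(**params))])
    return pipe.fit(x, y)


def loo_svm_classify(features, labels, grid: dict | None = None, seed: int = 0,
                     kernel: str = "rbf", mode: str = "nested",
                     inner_folds: int = 3) -> ClassifierReport:
    """Leave-one-out SVM classification of patients vs controls.

    Positive label 1 = patient, 0 = control.  Features are standardised
    with training-fold statistics; (C, gamma) are grid-searched within the
    training fold (``mode='nested'``) or once on the full sample
    (``mode='pooled'``, optimism-prone, kept for protocol comparison).
    """
    x = _check_features(features, 4)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0/1)")
    grid = grid or default_grid()
    if kernel == "linear":
        grid = {"C": grid["C"]}

    def make_inner(y_tr):
        k = min(inner_folds, int(np.bincount(y_tr).min()))
        return StratifiedKFold(n_splits=max(2, k), shuffle=True, random_state=seed)

    cls = lambda **kw: SVC(kernel=kernel, **kw)
    surface = []
    single = _n_combos(grid) == 1
    if mode == "pooled" and not single:
        search = _fit_with_grid(cls, x, y, grid, "accuracy", make_inner(y))
        best = {k.split("__")[1]: v for k, v in search.best_params_.items()}
        surface = _surface(search)
    elif mode not in ("nested", "pooled"):
        raise ValueError("mode must be 'nested' or 'pooled'")

    preds = np.empty_like(y)
    for train, test in LeaveOneOut().split(x):
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("training fold lacks a class")
        if single:
            model = _fit_single(cls, x[train], y_tr, grid)
        elif mode == "nested":
            search = _fit_with_grid(cls, x[train], y_tr, grid,
                                    "accuracy", make_inner(y_tr))
            model = search.best_estimator_
            if not surface:
                surface = _surface(search)
        else:
            model = Pipeline([("scale", StandardScaler()), ("svm", cls(**best))])
            model.fit(x[train], y_tr)
        preds[test] = model.predict(x[test])
    tp = int(((preds == 1) & (y == 1)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    acc, sens, spec = confusion_metrics(tp, fn, tn, fp)
    return ClassifierReport(preds, y, tp, fn, tn, fp, acc, sens, spec, surface)


def _surface(search) -> list:
    out = []
    for params, score in zip(search.cv_results_["params"],
                             search.cv_results_["mean_test_score"]):
        out.append((params.get("svm__C"), params.get("svm__gamma"), float(score)))
    return out


def loo_svr_predict(features, target_rr, grid: dict | None = None, seed: int = 0,
                    kernel: str = "rbf", mode: str = "nested", inner_folds: int = 3,
                    alpha: float = 0.05, m_tests: int = 16) -> SVRReport:
    """Leave-one-out epsilon-SVR of reduction ratios from baseline NH features.

    Reports Pearson r between held-out predictions and actual RR with the
    t-transform p-value, compared against the alpha/m Bonferroni threshold.
    """
    x = _check_features(features, 6)
    y = np.asarray(target_rr, float)
    if y.std() == 0:
        raise ValueError("constant target")
    grid = grid or default_grid()
    if kernel == "linear":
        grid = {"C": grid["C"]}
    cls = lambda **kw: SVR(kernel=kernel, **kw)
    inner = min(inner_folds, x.shape[0] - 2)
    surface = []
    single = _n_combos(grid) == 1
    if mode == "pooled" and not single:
        search = _fit_with_grid(cls, x, y, grid, "neg_mean_squared_error", inner)
        best = {k.split("__")[1]: v for k, v in search.best_params_.items()}
        surface = _surface(search)
    elif mode not in ("nested", "pooled"):
        raise ValueError("mode must be 'nested' or 'pooled'")
    preds = np.empty_like(y)
    for train, test in LeaveOneOut().split(x):
        if single:
            model = _fit_single(cls, x[train], y[train], grid)
        elif mode == "nested":
            search = _fit_with_grid(cls, x[train], y[train], grid,
                                    "neg_mean_squared_error", inner)
            model = search.best_estimator_
            if not surface:
                surface = _surface(search)
        else:
            model = Pipeline([("scale", StandardScaler()), ("svm", cls(**best))])
            model.fit(x[train], y[train])
        preds[test] = model.predict(x[test])
    if np.std(preds) == 0:
        # flat predictor (all targets inside the epsilon tube): no association
        r, p = 0.0, 1.0
    else:
        r, p = pearson_corr(preds, y)
    thr = bonferroni_threshold(alpha, m_tests)
    # predictive success means a POSITIVE predicted-vs-actual correlation;
    # a negative r is the hallmark of the LOO mean-prediction artifact
    # (held-out predictions shrink to the training mean, which anti-
    # correlates with the held-out target), never evidence of prediction
    return SVRReport(preds, y, r, p, thr, bool(r > 0 and p < thr), surface)


# --- reference primal/dual linear SVM -------------------------------------

@dataclass
class SVMModel:
    """Soft-margin linear SVM solution: decision(x) = sign(w.x + b)."""

    w: np.ndarray
    b: float
    C: float
    alpha: np.ndarray
    slack: np.ndarray
    objective: float
    kernel: str = "linear"
    rbf_gamma: float | None = None

    def decision(self, x):
        return np.atleast_2d(x) @ self.w + self.b

    def predict(self, x):
        return np.where(self.decision(x) >= 0, 1, -1)


def _primal_objective(w, b, x, y, C):
    margins = 1 - y * (x @ w + b)
    return 0.5 * float(w @ w) + C * float(np.clip(margins, 0, None).sum())


def train_svm_primal(features, labels, C: float = 1.0) -> SVMModel:
    """Reference soft-margin linear SVM.

    Minimises 0.5 ||w||^2 + C sum(xi) s.t. y_i (x_i.w + b) >= 1 - xi_i,
    xi >= 0 — equivalently hinge loss with an l2 penalty (lambda' <-> 1/C
    scaling).  Solved through the box-constrained dual QP (SLSQP on small
    n); the bias is recovered from on-margin support vectors, falling back
    to a direct 1-D minimisation of the primal in b.  KKT margin residuals
    are checked to 1e-6 at the optimum.
    """
    x = _check_features(features, 2)
    y = np.asarray(labels, float).ravel()
    if set(np.unique(y)) == {0.0, 1.0}:
        y = 2 * y - 1
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("labels must be binary")
    n = x.shape[0]
    q = (y[:, None] * y[None, :]) * (x @ x.T)
    q = q + 1e-10 * np.eye(n)  # regularise for the QP solver

    fun = lambda a: 0.5 * a @ q @ a - a.sum()
    jac = lambda a: q @ a - 1.0
    res = optimize.minimize(
        fun, np.full(n, min(C, 1.0) / 2), jac=jac, method="SLSQP",
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        options={"maxiter": 500, "ftol": 1e-12})
    if not res.success and res.status != 8:  # 8: positive directional derivative (flat)
        raise RuntimeError(f"SVM dual QP failed to converge: {res.message}")
    alpha = np.clip(res.x, 0.0, C)
    w = (alpha * y) @ x

    on_margin = (alpha > 1e-6 * C) & (alpha < C * (1 - 1e-6))
    if on_margin.any():
        b = float(np.mean(y[on_margin] - x[on_margin] @ w))
    else:
        cand = np.concatenate([y - x @ w, [0.0]])
        b = float(min(cand, key=lambda bb: _primal_objective(w, bb, x, y, C)))
    slack = np.clip(1 - y * (x @ w + b), 0.0, None)
    return SVMModel(w, b, C, alpha, slack, _primal_objective(w, b, x, y, C))
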