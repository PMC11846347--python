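"""Cross-validated case-vs-control classification on spectra.

Three pieces:

* L2-regularized logistic regression evaluated by stratified 10-fold
  cross-validation, with the penalty chosen per outer fold by an inner
  grid search; ROC curves are averaged vertically on a fixed FPR grid
  and the AUC distribution is summarized as mean +- SD.
* Leave-one-out linear support-vector scores — the continuous
  decision-function values used downstream by the ROC-GLM stage-effect
  regression.
* Learning curves: mean AUC at increasing class-balanced training-set
  sizes (5 repeats per size), extrapolated with the inverse power law
  AUC(n) = a - b * n^(-c), whose parameter ``a`` is the large-sample
  performance asymptote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, LeaveOneOut, StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

__all__ = [
    "CvRocResult",
    "LearningCurveFit",
    "fit_logistic_l2_cv",
    "svm_loocv_scores",
    "learning_curve",
    "fit_inverse_power_law",
]

# 7 log-spaced inverse-regularization values, 1e-3 .. 1e3
PENALTY_GRID = np.logspace(-3, 3, 7)
FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class CvRocResult:
    fold_aucs: np.ndarray
    mean_auc: float
    sd_auc: float
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray          # vertically averaged over folds
    best_c_per_fold: np.ndarray   # chosen inverse-regularization per fold


@dataclass(frozen=True)
class LearningCurveFit:
    sample_sizes: np.ndarray
    mean_aucs: np.ndarray
    a: float   # asymptotic AUC, in (0.5, 1]
    b: float
    c: float

    def predict(self, n: np.ndarray | float) -> np.ndarray | float:
        return self.a - self.b * np.asarray(n, dtype=float) ** (-self.c)


def _interp_tpr(fpr: np.ndarray, tpr: np.ndarray) -> np.ndarray:
    """Vertical interpolation of one fold's step ROC onto FPR_GRID."""
    out = np.interp(FPR_GRID, fpr, tpr)
    out[0] = 0.0
    out[-1] = 1.0
    return out


def fit_logistic_l2_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int | None = 0,
    inner_folds: int = 3,
) -> CvRocResult:
    """Outer stratified k-fold CV of an L2 logistic classifier.

    The regularization factor is selected independently per outer fold
    by an inner grid search (AUC criterion) over :data:`PENALTY_GRID`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} subjects per class for {folds}-fold stratified CV, "
            f"got {counts.min()}"
        )
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs, tprs, best_c = [], [], []
    for train, test in outer.split(X, y):
        grid = GridSearchCV(
            LogisticRegression(solver="lbfgs", max_iter=5000),  # L2 penalty, strength 1/C
            {"C": PENALTY_GRID},
            scoring="roc_auc",
            cv=StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed),
        )
        grid.fit(X[train], y[train])
        scores = grid.predict_proba(X[test])[:, 1]
        fold_aucs.append(roc_auc_score(y[test], scores))
        fpr, tpr, _ = roc_curve(y[test], scores)
        tprs.append(_interp_tpr(fpr, tpr))
        best_c.append(grid.best_params_["C"])
    fold_aucs = np.asarray(fold_aucs)
    return CvRocResult(
        fold_aucs=fold_aucs,
        mean_auc=float(fold_aucs.mean()),
        sd_auc=float(fold_aucs.std(ddof=1)),
        fpr_grid=FPR_GRID.copy(),
        mean_tpr=np.mean(tprs, axis=0),
        best_c_per_fold=np.asarray(best_c),
    )


def svm_loocv_scores(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> np.ndarray:
    """Leave-one-out decision-function scores of a linear-kernel SVM.

    Each subject is scored by a maximum-margin classifier trained on
    all other subjects; the raw (unthresholded) decision value is
    returned.  The regularization constant defaults to 1.0 and can be
    overridden.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) < 10:
        raise ValueError("need at least 10 subjects for leave-one-out scoring")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all spectra identical")
    clf = SVC(kernel="linear", C=C)
    return cross_val_predict(clf, X, y, cv=LeaveOneOut(), method="decision_function")


def learning_curve(
    X: np.ndarray,
    y: np.ndarray,
    sizes: np.ndarray,
    repeats: int = 5,
    seed: int | None = 0,
    folds: int = 10,
) -> np.ndarray:
    """Mean CV AUC per class-balanced training-subset size.

    Per size, ``repeats`` random class-balanced subsets are drawn and
    each evaluated with :func:`fit_logistic_l2_cv`; AUCs are averaged
    over repeats.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    sizes = np.asarray(sizes, dtype=int)
    if np.any(sizes < 20) or np.any(sizes > len(y)):
        raise ValueError("sizes must lie in [20, n]")
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    means = []
    for size in sizes:
        per_class = size // 2
        if per_class > min(len(idx0), len(idx1)):
            raise ValueError(f"size {size} exceeds class-balanced capacity")
        aucs = []
        for _ in range(repeats):
            sub = np.r_[
                rng.choice(idx0, per_class, replace=False),
                rng.choice(idx1, per_class, replace=False),
            ]
            res = fit_logistic_l2_cv(
                X[sub], y[sub], folds=min(folds, per_class), seed=int(rng.integers(2**31))
            )
            aucs.append(res.mean_auc)
        means.append(float(np.mean(aucs)))
    return np.asarray(means)


def fit_inverse_power_law(sizes: np.ndarray, aucs: np.ndarray) -> LearningCurveFit:
    """Nonlinear least-squares fit of AUC(n) = a - b * n^(-c).

    Bounds: a in (0.5, 1], b >= 0, c > 0.  A flat curve degenerates to
    b ~ 0 with a equal to the constant level.
    """
    sizes = np.asarray(sizes, dtype=float)
    aucs = np.asarray(aucs, dtype=float)
    if sizes.size != aucs.size or sizes.size < 3:
        raise ValueError("need at least 3 (size, AUC) points for a 3-parameter fit")

    def resid(p: np.ndarray) -> np.ndarray:
        a, b, c = p
        return a - b * sizes ** (-c) - aucs

    lo = np.array([0.5, 0.0, 1e-6])
    hi = np.array([1.0, np.inf, 10.0])
    best = None
    for c0 in (0.3, 0.6, 1.0):
        a0 = float(np.clip(aucs.max() + 0.01, 0.51, 1.0))
        b0 = max(float((a0 - aucs[0]) * sizes[0] ** c0), 1e-6)
        try:
            sol = least_squares(
                resid,
                np.clip([a0, b0, c0], lo, hi),
                bounds=(lo, hi),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("inverse power-law fit failed")
    a, b, c = best.x
    return LearningCurveFit(sizes.astype(int), aucs, float(a), float(b), float(c))
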