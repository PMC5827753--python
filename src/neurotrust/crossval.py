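"""Linear-SVM trust classification under LOOCV and stratified 10-fold CV.

Each cross-validation sample is the feature vector of one full recording.
Features are z-scored inside each training fold only (no leakage into the
held-out sample), the classifier is a linear SVM with C = 1, and the
F-score is the standard F1 with 'trustworthy' as the positive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .kta import kta_rank_features
from .labels import TRUSTWORTHY

logger = logging.getLogger(__name__)


@dataclass
class SVMReport:
    """Cross-validated accuracy/F-score with per-fold predictions."""

    accuracy: float              # percent
    f_score: float               # percent, F1 on the positive class
    cv_scheme: str
    predictions: np.ndarray      # predicted label per sample
    positive_class: object = TRUSTWORTHY


def _positive_class(y: np.ndarray):
    classes = pd.unique(y)
    if TRUSTWORTHY in classes:
        return TRUSTWORTHY
    return sorted(classes, key=str)[-1]


def _splitter(cv, y: np.ndarray, seed: int):
    if isinstance(cv, str):
        key = cv.lower()
    else:
        key = cv
    if key in ("loocv", "loo"):
        return LeaveOneOut(), "LOOCV"
    if key in ("10fold", "kfold", "10-fold", 10):
        k = 10
    elif isinstance(key, int):
        k = key
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")
    _, counts = np.unique(y, return_counts=True)
    k = min(k, counts.min())  # stratification requires >= 1 per class per fold
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed), f"{k}-fold"


def evaluate_svm(
    X,
    y,
    features: list[str] | None = None,
    cv="loocv",
    seed: int = 0,
    C: float = 1.0,
) -> SVMReport:
    """Cross-validated linear-SVM classification of the given feature subset."""
    if isinstance(X, pd.DataFrame):
        Xv = X[list(features)].to_numpy(dtype=float) if features else X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if features:
            Xv = Xv[:, list(features)]
    if Xv.ndim != 2 or Xv.shape[1] == 0:
        raise ValueError("feature subset must be non-empty")
    y = np.asarray(y)
    preds = np.empty(len(y), dtype=object)

    for attempt in range(10):
        splitter, scheme = _splitter(cv, y, seed + attempt)
        ok = True
        for train, test in splitter.split(Xv, y):
            if len(np.unique(y[train])) < 2:
                ok = False
                break
            model = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
            model.fit(Xv[train], y[train])
            preds[test] = model.predict(Xv[test])
        if ok:
            break
        logger.warning("single-class training fold; refolding with a new seed")
    else:
        raise RuntimeError("could not build folds with both classes present")

    pos = _positive_class(y)
    correct = preds == y
    accuracy = 100.0 * correct.mean()
    tp = np.sum((preds == pos) & (y == pos))
    fp = np.sum((preds == pos) & (y != pos))
    fn = np.sum((preds != pos) & (y == pos))
    f1 = 100.0 * (2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) else 0.0
    return SVMReport(
        accuracy=float(accuracy),
        f_score=float(f1),
        cv_scheme=scheme,
        predictions=preds,
        positive_class=pos,
    )


@dataclass
class SweepResult:
    """Accuracy as a function of the number of selected features."""

    curve: dict[int, float] = field(default_factory=dict)   # d -> accuracy %
    optimum: int = 0                                        # smallest d at max
    ranked: list[str] = field(default_factory=list)
    cv_scheme: str = ""
    selection_mode: str = "global"


def sweep_dimension(
    X: pd.DataFrame,
    y,
    cv="loocv",
    max_dim: int | None = None,
    seed: int = 0,
    selection_mode: str = "global",
) -> SweepResult:
    """Accuracy curve over d = 2..max_dim top-KTA features.

    ``selection_mode='global'`` ranks features once on the full dataset (the
    convention assumed when reporting a single ranked key-feature list);
    ``'per-fold'`` re-ranks inside every training fold, which removes
    selection bias at extra cost. The optimum is the smallest d achieving
    the maximum accuracy over the sweep.
    """
    y = np.asarray(y)
    p = X.shape[1]
    max_dim = p if max_dim is None else min(max_dim, p)
    if max_dim < 2:
        raise ValueError("max_dim must be at least 2")
    curve: dict[int, float] = {}
    scheme = ""
    if selection_mode == "global":
        ranked = kta_rank_features(X, y, n_select=max_dim, seed=seed).selected
        for d in range(2, max_dim + 1):
            rep = evaluate_svm(X, y, ranked[:d], cv=cv, seed=seed)
            curve[d] = rep.accuracy
            scheme = rep.cv_scheme
    elif selection_mode == "per-fold":
        ranked = kta_rank_features(X, y, n_select=max_dim, seed=seed).selected
        Xv = X.to_numpy(dtype=float)
        for d in range(2, max_dim + 1):
            splitter, scheme = _splitter(cv, y, seed)
            preds = np.empty(len(y), dtype=object)
            for train, test in splitter.split(Xv, y):
                sel = kta_rank_features(X.iloc[train], y[train], n_select=d, seed=seed).selected
                model = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
                model.fit(X.iloc[train][sel], y[train])
                preds[test] = model.predict(X.iloc[test][sel])
            curve[d] = float(100.0 * np.mean(preds == y))
    else:
        raise ValueError("selection_mode must be 'global' or 'per-fold'")
    best = max(curve.values())
    optimum = min(d for d, acc in curve.items() if acc == best)
    return SweepResult(
        curve=curve,
        optimum=optimum,
        ranked=ranked,
        cv_scheme=scheme,
        selection_mode=selection_mode,
    )
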