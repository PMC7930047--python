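"""Binary scratch / non-scratch classification of 3-s hand-movement windows.

Training follows: class balancing by random down-sampling, feature
selection with recursive feature elimination under cross-validation (a
decision tree as the ranking estimator), and a 50-tree random forest fit on
the selected features.  Performance is assessed with leave-one-subject-out
(LOSO) validation, re-running balancing and selection inside each fold so
no information from the held-out subject leaks into training.
"""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, FEATURE_SET_VERSION

SCRATCH = "scratch"
NON_SCRATCH = "non-scratch"

MODEL_FORMAT_VERSION = "1"


def balance_classes(
    y: np.ndarray | pd.Series, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Indices that down-sample the majority class to the minority count.

    Sampling is without replacement and deterministic under a fixed seed.
    Returned indices are sorted, preserving the original sample order.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(rng)
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == cls)
        if cnt > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def select_features_rfecv(
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = None,
    cv: int = 5,
    step: int = 1,
) -> np.ndarray:
    """Boolean support mask from RFE-CV with a decision-tree estimator."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < cv:
        raise ValueError(
            f"each class needs at least cv={cv} samples for RFE-CV "
            f"(smallest class has {counts.min()})"
        )
    selector = RFECV(
        estimator=DecisionTreeClassifier(random_state=seed),
        step=step,
        cv=StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed),
        scoring="accuracy",
        min_features_to_select=1,
    )
    selector.fit(X, y)
    return selector.support_


class ScratchClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest scratch classifier with in-fit balancing and RFE-CV.

    Parameters
    ----------
    n_estimators : int, default 50
        Trees in the forest.
    threshold : float, default 0.5
        A window is predicted scratch when the forest's scratch probability
        is strictly above this value.
    balance : bool, default True
        Randomly down-sample the majority class before feature selection.
    feature_selection : bool, default True
        Run RFE-CV before fitting the forest.
    cv : int, default 5
        Folds for the RFE-CV scoring.
    random_state : int or None
        Seed for balancing, selection and the forest.

    Attributes
    ----------
    classes_ : ndarray of the two class labels.
    support_ : boolean mask over the input features.
    selected_feature_names_ : names of the retained features.
    forest_ : the fitted :class:`RandomForestClassifier`.
    training_meta_ : dict with class counts, seed and feature-set version.
    """

    def __init__(
        self,
        n_estimators: int = 50,
        threshold: float = 0.5,
        balance: bool = True,
        feature_selection: bool = True,
        cv: int = 5,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.threshold = threshold
        self.balance = balance
        self.feature_selection = feature_selection
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (windows x features)")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        if feature_names is None:
            if X.shape[1] == len(FEATURE_NAMES):
                feature_names = list(FEATURE_NAMES)
            else:
                feature_names = [f"f{i}" for i in range(X.shape[1])]
        if len(feature_names) != X.shape[1]:
            raise ValueError("feature_names length mismatch")

        rng = np.random.default_rng(self.random_state)
        if self.balance:
            idx = balance_classes(y, rng)
            Xb, yb = X[idx], y[idx]
        else:
            Xb, yb = X, y

        if self.feature_selection:
            support = select_features_rfecv(
                Xb, yb, seed=self.random_state, cv=self.cv
            )
        else:
            support = np.ones(X.shape[1], dtype=bool)

        forest = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state
        )
        forest.fit(Xb[:, support], yb)

        self.classes_ = forest.classes_
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        self.support_ = support
        self.selected_feature_names_ = [
            n for n, s in zip(feature_names, support) if s
        ]
        self.forest_ = forest
        self.training_meta_ = {
            "class_counts": {str(c): int(n) for c, n in zip(classes, counts)},
            "balanced_counts": {
                str(c): int(n)
                for c, n in zip(*np.unique(yb, return_counts=True))
            },
            "random_state": self.random_state,
            "feature_set_version": FEATURE_SET_VERSION,
            "n_selected": int(support.sum()),
        }
        return self

    def _positive_index(self) -> int:
        if SCRATCH in self.classes_:
            return int(np.flatnonzero(self.classes_ == SCRATCH)[0])
        return 1

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return self.forest_.predict_proba(X[:, self.support_])

    def scratch_probability(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, self._positive_index()]

    def predict(self, X) -> np.ndarray:
        p = self.scratch_probability(X)
        pos = self.classes_[self._positive_index()]
        neg = self.classes_[1 - self._positive_index()]
        return np.where(p > self.threshold, pos, neg)


def train_scratch_classifier(
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = None,
    n_estimators: int = 50,
    feature_names: list[str] | None = None,
) -> ScratchClassifier:
    """Balance, select and fit; thin wrapper over :class:`ScratchClassifier`."""
    clf = ScratchClassifier(n_estimators=n_estimators, random_state=seed)
    return clf.fit(X, y, feature_names=feature_names)


def predict_windows(
    model: ScratchClassifier,
    features: np.ndarray,
    hand_moving: np.ndarray,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-window predictions with hand-movement gating.

    Windows without full-window hand movement are labeled non-scratch
    without invoking the classifier (probability reported as NaN).
    """
    hand_moving = np.asarray(hand_moving, dtype=bool)
    n = len(hand_moving)
    features = np.asarray(features, dtype=float)
    thr = model.threshold if threshold is None else threshold
    pred = np.full(n, NON_SCRATCH, dtype=object)
    prob = np.full(n, np.nan)
    if hand_moving.any():
        p = model.scratch_probability(features[hand_moving])
        prob[hand_moving] = p
        pred[hand_moving] = np.where(p > thr, SCRATCH, NON_SCRATCH)
    return pd.DataFrame({"hand_moving": hand_moving, "pred": pred, "probability": prob})


def loso_validate(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    seed: int | None = None,
    **clf_params,
) -> pd.DataFrame:
    """Leave-one-subject-out validation of the scratch classifier.

    For each held-out subject, balancing, feature selection and forest
    training are re-run on the remaining subjects; held-out windows are then
    predicted and summarised into per-subject accuracy, sensitivity,
    specificity, PPV, NPV and F1 (scratch as the positive class).  Subjects
    with only one class present are still predicted; undefined ratios come
    back as NaN.
    """
    from .evaluation import epoch_metrics  # local import to avoid a cycle

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    rows = []
    base = ScratchClassifier(random_state=seed, **clf_params)
    for subj in uniq:
        held = subjects == subj
        if not held.any():
            continue
        y_train = y[~held]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"training fold for subject {subj} has one class")
        clf = clone(base)
        clf.fit(X[~held], y_train)
        pred = clf.predict(X[held])
        prob = clf.scratch_probability(X[held])
        m = epoch_metrics(
            pred, y[held], positive_class=SCRATCH, scores=prob, strict=False
        )
        m["subject"] = subj
        m["n_windows"] = int(held.sum())
        rows.append(m)
    cols = [
        "subject", "n_windows", "accuracy", "sensitivity", "specificity",
        "ppv", "npv", "f1", "auc",
    ]
    return pd.DataFrame(rows)[cols].set_index("subject")


def loso_summary(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) across subjects of the LOSO metric table."""
    metrics = per_subject.drop(columns=["n_windows"])
    return pd.DataFrame({"mean": metrics.mean(), "sd": metrics.std()})


def save_model(model: ScratchClassifier, path: str | Path) -> None:
    """Persist a fitted model as a versioned archive (metadata + forest)."""
    check_is_fitted(model, "forest_")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "meta": model.training_meta_,
        "params": model.get_params(),
        "feature_names_in": list(model.feature_names_in_),
        "selected_feature_names": model.selected_feature_names_,
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> ScratchClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model archive version {payload.get('format_version')!r}"
        )
    return payload["model"]


def model_metadata(path: str | Path) -> dict:
    payload = joblib.load(path)
    return {k: v for k, v in payload.items() if k != "model"}
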