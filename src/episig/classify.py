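"""Case/control classifiers with LOOCV grid search, scored by MCC.

Three model kinds, the ones episignature studies routinely deploy:

- ``svm`` — support vector machine (linear / RBF / polynomial kernels),
  probabilities via a sigmoid fit on decision values (Platt scaling,
  calibrated within the training data);
- ``rf`` — random forest;
- ``plr`` — penalized (L2) logistic regression, liblinear solver with the
  dual formulation.

Hyperparameters are chosen by leave-one-out cross-validation: each grid
point produces one held-out prediction per training sample, the pooled
predictions are scored with the Matthews correlation coefficient, and the
best grid point (ties broken by declared grid order) is refit on the full
training data.  Predicted label is "case" iff the case probability strictly
exceeds the fixed 0.5 threshold.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import CASE, CONTROL

__all__ = [
    "MODEL_KINDS",
    "default_grid",
    "mcc",
    "EpisignatureClassifier",
    "train_classifier",
    "predict",
    "save_model",
    "load_model",
]

MODEL_KINDS = ("svm", "rf", "plr")
THRESHOLD = 0.5


def default_grid(kind: str) -> list[dict]:
    """Small declared hyperparameter grids (user-overridable)."""
    if kind == "svm":
        return (
            [{"kernel": "linear", "C": c} for c in (0.01, 0.1, 1.0, 10.0)]
            + [{"kernel": "rbf", "C": c} for c in (0.1, 1.0, 10.0)]
            + [{"kernel": "poly", "degree": d, "C": c} for d in (2, 3) for c in (0.1, 1.0)]
        )
    if kind == "rf":
        return [
            {"n_estimators": n, "max_depth": d}
            for n in (100, 300)
            for d in (None, 5, 10)
        ]
    if kind == "plr":
        return [{"C": c} for c in (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)]
    raise ValueError(f"unknown model kind {kind!r}")


def mcc(true_labels, predicted_labels, positive: str = CASE) -> float:
    """Matthews correlation coefficient from the confusion table.

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; defined as 0
    when any factor of the denominator is zero.
    """
    yt = np.asarray(true_labels)
    yp = np.asarray(predicted_labels)
    if yt.shape != yp.shape:
        raise ValueError("label vectors must have equal length")
    if yt.size == 0:
        raise ValueError("label vectors must be non-empty")
    tp = float(np.sum((yt == positive) & (yp == positive)))
    tn = float(np.sum((yt != positive) & (yp != positive)))
    fp = float(np.sum((yt != positive) & (yp == positive)))
    fn = float(np.sum((yt == positive) & (yp != positive)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def _make_estimator(kind: str, params: dict, seed: int):
    if kind == "svm":
        return SVC(random_state=seed, gamma="scale", **params)
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if kind == "plr":
        # default penalty is the L2 norm; liblinear with the dual formulation
        # (the dual coordinate-descent solver is randomized -> seed it)
        return LogisticRegression(
            solver="liblinear", dual=True, max_iter=5000, random_state=seed, **params
        )
    raise ValueError(f"unknown model kind {kind!r}")


class EpisignatureClassifier(BaseEstimator, ClassifierMixin):
    """LOOCV-grid-searched binary classifier over episignature features.

    Parameters
    ----------
    kind:
        "svm", "rf" or "plr".
    grid:
        List of hyperparameter dicts tried in order; ``None`` uses
        :func:`default_grid`.
    scale_features:
        Center/scale features before fitting.  ``None`` means the
        kind-specific default: on for svm and plr (margin / penalized
        models), off for rf.  Scaling statistics are fit inside each LOOCV
        fold from that fold's training part only; the persisted statistics
        come from the full training set.
    seed:
        Reproducibility seed for the stochastic kinds.

    Fitted attributes: ``best_params_``, ``loocv_score_``, ``classes_``,
    ``feature_names_``, ``scaler_``, ``estimator_``.
    """

    def __init__(
        self,
        kind: str = "svm",
        grid: list[dict] | None = None,
        scale_features: bool | None = None,
        seed: int = 0,
    ):
        self.kind = kind
        self.grid = grid
        self.scale_features = scale_features
        self.seed = seed

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if X.shape[1] == 0:
            raise ValueError("feature matrix has no features")
        if X.isna().to_numpy().any():
            raise ValueError("features must be free of missing values")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")

        grid = self.grid if self.grid is not None else default_grid(self.kind)
        if not grid:
            raise ValueError("hyperparameter grid is empty")
        scale = (
            self.kind in ("svm", "plr")
            if self.scale_features is None
            else self.scale_features
        )

        Xv = X.to_numpy(dtype=float)
        scores = []
        for params in grid:
            preds, _ = self._loocv(Xv, y, params, scale)
            scores.append(mcc(y, preds))

        self.cv_results_ = pd.DataFrame({"params": grid, "loocv_mcc": scores})
        self.best_index_ = int(np.argmax(scores))
        self.best_params_ = grid[self.best_index_]
        self.loocv_score_ = float(scores[self.best_index_])

        self.scaler_ = StandardScaler().fit(Xv) if scale else None
        Xfit = self.scaler_.transform(Xv) if self.scaler_ is not None else Xv
        self.estimator_ = _make_estimator(self.kind, self.best_params_, self.seed).fit(
            Xfit, y
        )
        self.classes_ = self.estimator_.classes_
        if self.kind == "svm":
            # Platt scaling on held-out LOOCV decision values at the chosen
            # hyperparameters: probabilities come from a sigmoid of the
            # decision value, calibrated within the training data.
            _, decisions = self._loocv(Xv, y, self.best_params_, scale, decision=True)
            self.platt_ = _fit_platt(decisions, y == self.classes_[1])
        self.feature_names_ = list(X.columns)
        self.threshold_ = THRESHOLD
        return self

    def _loocv(self, Xv, y, params, scale, decision: bool = False):
        """One held-out prediction (and decision value, for SVM) per sample."""
        base = _make_estimator(self.kind, params, self.seed)
        preds = np.empty(len(y), dtype=object)
        decisions = np.empty(len(y))
        for train_idx, test_idx in LeaveOneOut().split(Xv):
            Xtr, Xte = Xv[train_idx], Xv[test_idx]
            if scale:
                sc = StandardScaler().fit(Xtr)
                Xtr, Xte = sc.transform(Xtr), sc.transform(Xte)
            est = clone(base).fit(Xtr, y[train_idx])
            preds[test_idx[0]] = est.predict(Xte)[0]
            if decision:
                decisions[test_idx[0]] = est.decision_function(Xte)[0]
        return preds, decisions if decision else None

    # -- prediction --------------------------------------------------------
    def _check_schema(self, X) -> np.ndarray:
        if not hasattr(self, "estimator_"):
            raise RuntimeError("classifier is not fitted")
        X = pd.DataFrame(X)
        missing = [f for f in self.feature_names_ if f not in X.columns]
        if missing:
            raise KeyError(f"feature matrix lacks {len(missing)} schema features")
        Xv = X.loc[:, self.feature_names_].to_numpy(dtype=float)
        if self.scaler_ is not None:
            Xv = self.scaler_.transform(Xv)
        return Xv

    def predict_proba(self, X) -> np.ndarray:
        """Column order follows ``classes_`` (sklearn convention)."""
        Xv = self._check_schema(X)
        if self.kind == "svm":
            f = self.estimator_.decision_function(Xv)
            a, b = self.platt_
            p1 = expit(a * f + b)  # probability of classes_[1]
            return np.column_stack([1 - p1, p1])
        return self.estimator_.predict_proba(Xv)

    def case_probability(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        case_col = int(np.flatnonzero(self.classes_ == CASE)[0])
        return proba[:, case_col]

    def predict(self, X) -> np.ndarray:
        """"case" iff P(case) strictly exceeds 0.5 (exactly 0.5 -> control)."""
        p = self.case_probability(X)
        return np.where(p > self.threshold_, CASE, CONTROL)


def train_classifier(
    features: pd.DataFrame,
    labels: pd.Series,
    kind: str = "svm",
    grid: list[dict] | None = None,
    scale_features: bool | None = None,
    seed: int = 0,
) -> EpisignatureClassifier:
    """Fit an :class:`EpisignatureClassifier` on a sample x feature matrix."""
    labels = labels.loc[features.index]
    clf = EpisignatureClassifier(
        kind=kind, grid=grid, scale_features=scale_features, seed=seed
    )
    return clf.fit(features, labels.to_numpy())


def predict(model: EpisignatureClassifier, features: pd.DataFrame) -> pd.DataFrame:
    """Per-sample case probabilities and thresholded labels."""
    if len(features) == 0:
        return pd.DataFrame(columns=["probability", "label"])
    prob = model.case_probability(features)
    label = np.where(prob > model.threshold_, CASE, CONTROL)
    return pd.DataFrame(
        {"probability": prob, "label": label},
        index=pd.Index(features.index, name="sample_id"),
    )


# -- persistence -----------------------------------------------------------

def _fit_platt(decisions: np.ndarray, positive: np.ndarray) -> tuple[float, float]:
    """Sigmoid calibration p = expit(a*f + b) by near-unregularized logistic fit."""
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10_000)
    lr.fit(decisions.reshape(-1, 1), positive.astype(int))
    # orient so the returned pair maps decision value -> P(positive class)
    sign = 1.0 if lr.classes_[1] == 1 else -1.0
    return float(sign * lr.coef_[0, 0]), float(sign * lr.intercept_[0])


class _LinearProbabilityModel:
    """Reconstructed linear model: probabilities from persisted coefficients."""

    def __init__(self, coef, intercept, classes):
        self.coef_ = np.asarray(coef, dtype=float)
        self.intercept_ = np.asarray(intercept, dtype=float)
        self.classes_ = np.asarray(classes)

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X) @ self.coef_.ravel() + self.intercept_[0]

    def predict_proba(self, X) -> np.ndarray:
        p1 = expit(self.decision_function(X))  # probability of classes_[1]
        return np.column_stack([1 - p1, p1])


def save_model(model: EpisignatureClassifier, path: str | Path) -> None:
    """Persist a fitted model as a directory: JSON metadata + parameters.

    plr and linear-svm coefficients are stored as JSON so that probabilities
    are exactly reproducible from the serialized numbers; other kinds carry
    an opaque fitted-state payload.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    est = model.estimator_
    linear_svm = model.kind == "svm" and model.best_params_.get("kernel") == "linear"
    meta = {
        "kind": model.kind,
        "best_params": model.best_params_,
        "loocv_score": model.loocv_score_,
        "feature_names": model.feature_names_,
        "classes": [str(c) for c in model.classes_],
        "threshold": model.threshold_,
        "seed": model.seed,
        "scaling": None
        if model.scaler_ is None
        else {
            "mean": model.scaler_.mean_.tolist(),
            "scale": model.scaler_.scale_.tolist(),
        },
        "representation": "coefficients" if (model.kind == "plr" or linear_svm) else "pickle",
    }
    if model.kind == "svm":
        meta["platt"] = list(model.platt_)
    if model.kind == "plr" or linear_svm:
        meta["parameters"] = {
            "coef": est.coef_.tolist(),
            "intercept": est.intercept_.tolist(),
        }
    (path / "model.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    if meta["representation"] == "pickle":
        with open(path / "estimator.pkl", "wb") as fh:
            pickle.dump(est, fh)


def load_model(path: str | Path) -> EpisignatureClassifier:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    model = EpisignatureClassifier(kind=meta["kind"], seed=meta["seed"])
    model.best_params_ = meta["best_params"]
    model.loocv_score_ = meta["loocv_score"]
    model.feature_names_ = meta["feature_names"]
    model.classes_ = np.asarray(meta["classes"])
    model.threshold_ = meta["threshold"]
    if meta["scaling"] is None:
        model.scaler_ = None
    else:
        sc = StandardScaler()
        sc.mean_ = np.asarray(meta["scaling"]["mean"])
        sc.scale_ = np.asarray(meta["scaling"]["scale"])
        sc.var_ = sc.scale_**2
        sc.n_features_in_ = len(sc.mean_)
        model.scaler_ = sc
    if meta["kind"] == "svm":
        model.platt_ = tuple(meta["platt"])
    if meta["representation"] == "coefficients":
        params = meta["parameters"]
        model.estimator_ = _LinearProbabilityModel(
            params["coef"], params["intercept"], meta["classes"]
        )
    else:
        with open(path / "estimator.pkl", "rb") as fh:
            model.estimator_ = pickle.load(fh)
    return model
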