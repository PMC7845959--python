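"""Classifiers, stratified cross-validation and ROC analysis.

Three classifier families are exposed behind one probability-emitting
interface: a native Gaussian Naive Bayes, a linear-kernel maximum-margin
model and a bagged tree ensemble (the latter two delegate to scikit-learn).
Evaluation uses stratified 5-fold cross-validation with per-fold imputation
fitted on the training folds only, reporting accuracy (percent), a pooled
ROC curve with its AUC, and a summed confusion matrix.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureMatrix",
    "CVResult",
    "Model",
    "train_classifier",
    "cross_validate",
    "roc_auc",
    "save_model",
    "load_model",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("gaussian_nb", "linear_margin", "tree_ensemble")

MODEL_FORMAT_VERSION = 1


@dataclass
class FeatureMatrix:
    """Dense region x feature matrix with binary labels.

    ``metadata`` records provenance such as mean-imputed columns.
    """

    values: np.ndarray
    feature_names: List[str]
    labels: Optional[np.ndarray] = None
    region_ids: Optional[List[str]] = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match column count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("labels length does not match row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, names: Sequence[str]) -> "FeatureMatrix":
        index = {n: i for i, n in enumerate(self.feature_names)}
        cols = [index[n] for n in names]
        return FeatureMatrix(
            values=self.values[:, cols],
            feature_names=list(names),
            labels=self.labels,
            region_ids=self.region_ids,
            metadata=dict(self.metadata),
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.feature_names)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        if self.region_ids is not None:
            df.index = self.region_ids
        return df


class _GaussianNB:
    """Gaussian Naive Bayes with a per-feature variance floor.

    Class-conditional densities are independent Gaussians with training-fold
    means and variances; the variance floor is 1e-9 times the largest
    feature variance (or 1e-12 when all variances vanish).
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_GaussianNB":
        self.classes_ = np.unique(y)
        n, d = X.shape
        self.theta_ = np.empty((len(self.classes_), d))
        self.var_ = np.empty((len(self.classes_), d))
        self.log_prior_ = np.empty(len(self.classes_))
        for i, c in enumerate(self.classes_):
            Xc = X[y == c]
            self.theta_[i] = Xc.mean(axis=0)
            self.var_[i] = Xc.var(axis=0)
            self.log_prior_[i] = np.log(len(Xc) / n)
        vmax = self.var_.max()
        floor = 1e-9 * vmax if vmax > 0 else 1e-12
        self.var_ = np.maximum(self.var_, floor)
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        jll = np.empty((X.shape[0], len(self.classes_)))
        for i in range(len(self.classes_)):
            log_pdf = -0.5 * (
                np.log(2.0 * np.pi * self.var_[i])
                + (X - self.theta_[i]) ** 2 / self.var_[i]
            )
            jll[:, i] = self.log_prior_[i] + log_pdf.sum(axis=1)
        return jll

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        jll = self._joint_log_likelihood(np.asarray(X, dtype=float))
        jll -= jll.max(axis=1, keepdims=True)
        probs = np.exp(jll)
        return probs / probs.sum(axis=1, keepdims=True)


@dataclass
class Model:
    """A fitted classifier plus its feature-name manifest.

    Prediction refuses matrices whose feature names do not match the
    manifest (order-sensitive).
    """

    kind: str
    feature_names: List[str]
    estimator: object
    scaler: Optional[StandardScaler] = None
    impute_means: Optional[np.ndarray] = None

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        if self.impute_means is not None:
            X = np.where(np.isnan(X), self.impute_means, X)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X

    def predict_proba(self, X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            if X.feature_names != self.feature_names:
                raise ValueError(
                    "feature-name manifest mismatch: model was trained on "
                    f"{self.feature_names}, matrix has {X.feature_names}"
                )
            X = X.values
        return self.estimator.predict_proba(self._prepare(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _impute(X: np.ndarray, means: Optional[np.ndarray] = None):
    if means is None:
        means = np.nanmean(X, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
    return np.where(np.isnan(X), means, X), means


def train_classifier(
    matrix,
    labels: Optional[np.ndarray] = None,
    kind: str = "gaussian_nb",
    params: Optional[dict] = None,
    seed: int = 0,
) -> Model:
    """Fit one classifier; returns a :class:`Model` with manifest.

    ``matrix`` may be a :class:`FeatureMatrix` (labels taken from it when
    ``labels`` is None) or a plain array plus explicit labels.
    """
    params = dict(params or {})
    if isinstance(matrix, FeatureMatrix):
        X = matrix.values
        names = list(matrix.feature_names)
        if labels is None:
            labels = matrix.labels
    else:
        X = np.asarray(matrix, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    if labels is None:
        raise ValueError("labels required")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    counts = np.bincount(y)
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")
    frac = counts.max() / counts.sum()
    if frac > 0.55:
        warnings.warn(
            f"class imbalance {frac:.2f} > 0.55; accuracies may be misleading",
            stacklevel=2,
        )
    X, impute_means = _impute(X)
    scaler = None
    if kind == "gaussian_nb":
        est = _GaussianNB().fit(X, y)
    elif kind == "linear_margin":
        scaler = StandardScaler().fit(X)
        est = SVC(
            kernel="linear",
            probability=True,
            random_state=seed,
            **params,
        ).fit(scaler.transform(X), y)
    elif kind == "tree_ensemble":
        params.setdefault("n_estimators", 200)
        est = RandomForestClassifier(random_state=seed, **params).fit(X, y)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; choose {CLASSIFIER_KINDS}")
    return Model(
        kind=kind,
        feature_names=names,
        estimator=est,
        scaler=scaler,
        impute_means=impute_means,
    )


@dataclass
class CVResult:
    """Cross-validation summary: accuracies in percent, pooled ROC/AUC."""

    fold_accuracies: List[float]
    mean_accuracy: float
    sd_accuracy: float
    auc: float
    roc_curve: Tuple[np.ndarray, np.ndarray]  # (FPR, TPR)
    confusion: np.ndarray  # summed over folds; rows true, cols predicted
    seed: int
    kind: str

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "sd_accuracy": float(self.sd_accuracy),
            "auc": float(self.auc),
            "confusion": self.confusion.tolist(),
            "seed": self.seed,
            "kind": self.kind,
        }


def cross_validate(
    matrix,
    labels: Optional[np.ndarray] = None,
    k: int = 5,
    kind: str = "gaussian_nb",
    seed: int = 0,
    params: Optional[dict] = None,
) -> CVResult:
    """Stratified k-fold cross-validation with train-fold-only preprocessing."""
    if isinstance(matrix, FeatureMatrix):
        X = matrix.values
        if labels is None:
            labels = matrix.labels
    else:
        X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    class_counts = np.bincount(y)
    if (class_counts[class_counts > 0] < k).any():
        raise ValueError(f"each class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_accs: List[float] = []
    pooled_scores = np.empty(len(y))
    confusion = np.zeros((2, 2), dtype=int)
    for train_idx, test_idx in skf.split(X, y):
        model = train_classifier(X[train_idx], y[train_idx], kind=kind, seed=seed,
                                 params=params)
        probs = model.predict_proba(X[test_idx])[:, 1]
        pred = (probs >= 0.5).astype(int)
        fold_accs.append(100.0 * float(np.mean(pred == y[test_idx])))
        pooled_scores[test_idx] = probs
        for t, p in zip(y[test_idx], pred):
            confusion[t, p] += 1
    curve, auc = roc_auc(pooled_scores, y)
    return CVResult(
        fold_accuracies=fold_accs,
        mean_accuracy=float(np.mean(fold_accs)),
        sd_accuracy=float(np.std(fold_accs, ddof=1)),
        auc=auc,
        roc_curve=curve,
        confusion=confusion,
        seed=seed,
        kind=kind,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]):
    """ROC curve and AUC (ties count one half) from scores and binary labels.

    AUC equals the probability that a random positive outscores a random
    negative.  Returns ``((fpr, tpr), auc)`` with points ordered by
    decreasing threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_y = y[order]
    # group ties: cumulative TP/FP evaluated at the end of each tie group
    distinct = np.flatnonzero(np.diff(sorted_scores)) if len(scores) > 1 else np.array([], dtype=int)
    group_ends = np.r_[distinct, len(scores) - 1]
    tps = np.cumsum(sorted_y == 1)[group_ends]
    fps = np.cumsum(sorted_y == 0)[group_ends]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr), auc


def save_model(model: Model, path) -> None:
    """Persist a model as a versioned blob with its feature-name manifest."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": model.kind,
        "feature_names": model.feature_names,
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> Model:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload.get('format_version')}"
        )
    return payload["model"]
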