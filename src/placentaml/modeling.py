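"""Classifier back-ends, final-model training, and the threshold probe.

The primary model family is linear discriminant analysis (LDA) — a linear
classifier assuming class-conditional Gaussians with a pooled covariance —
with logistic regression, random forest and an RBF support-vector machine as
comparators. All families predict a probability for the positive (NC,
non-crossing) class; a probability at or above the operating threshold
(default 0.5) is discretized as NC.

Fingerprint counts are used raw: no scaling is applied by default (LDA and
trees are scale-equivariant for this purpose), though standardization can be
switched on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .metrics import NEGATIVE_LABEL, POSITIVE_LABEL, confusion, f_beta

logger = logging.getLogger(__name__)

FAMILIES = ("LDA", "LR", "RF", "SVM")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus the knobs needed to reproduce a fit."""

    family: str = "LDA"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    probability_threshold: float = 0.5
    seed: int = 0
    scale_features: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not (0.0 < self.probability_threshold < 1.0):
            raise ValueError(
                f"probability_threshold must be in (0, 1), got {self.probability_threshold}"
            )


def _backend(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    if spec.family == "LR":
        hp.setdefault("max_iter", 1000)
        return LogisticRegression(**hp)
    if spec.family == "RF":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.family == "SVM":
        hp.setdefault("kernel", "rbf")
        hp.setdefault("C", 1.0)
        return SVC(probability=True, random_state=spec.seed, **hp)
    raise AssertionError(spec.family)


class BarrierClassifier(BaseEstimator, ClassifierMixin):
    """Placental-transfer classifier with a fixed NC-probability threshold.

    A thin scikit-learn estimator over the four back-end families. ``fit``
    takes a feature table and C/NC labels; ``predict_proba`` returns the
    probability of the positive (NC) class in column order ``classes_``;
    ``predict`` discretizes at ``probability_threshold`` (boundary inclusive:
    a probability exactly at the threshold predicts NC).
    """

    def __init__(
        self,
        family: str = "LDA",
        hyperparameters: Optional[Mapping[str, object]] = None,
        probability_threshold: float = 0.5,
        seed: int = 0,
        scale_features: bool = False,
    ):
        self.family = family
        self.hyperparameters = hyperparameters
        self.probability_threshold = probability_threshold
        self.seed = seed
        self.scale_features = scale_features

    def _spec(self) -> ClassifierSpec:
        return ClassifierSpec(
            family=self.family,
            hyperparameters=dict(self.hyperparameters or {}),
            probability_threshold=self.probability_threshold,
            seed=self.seed,
            scale_features=self.scale_features,
        )

    def fit(self, X, y) -> "BarrierClassifier":
        spec = self._spec()
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=object)
        classes = set(y)
        if not classes <= {POSITIVE_LABEL, NEGATIVE_LABEL}:
            raise ValueError(f"labels must be C/NC, got {sorted(classes)}")
        if len(classes) < 2:
            raise ValueError("cannot fit on single-class labels")
        const = X.columns[(X.nunique(axis=0) <= 1)] if len(X) else []
        if len(const):
            logger.info("constant features tolerated in fit: %s", list(const))
        self.feature_names_ = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
        self.scaler_ = None
        if spec.scale_features:
            self.scaler_ = StandardScaler().fit(Xv)
            Xv = self.scaler_.transform(Xv)
        self.estimator_ = _backend(spec).fit(Xv, y)
        self.classes_ = self.estimator_.classes_
        return self

    def _proba_positive(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise ValueError(f"prediction table lacks feature(s) {missing}")
        Xv = X.loc[:, self.feature_names_].to_numpy(dtype=float)
        if self.scaler_ is not None:
            Xv = self.scaler_.transform(Xv)
        if len(Xv) == 0:
            return np.empty(0, dtype=float)
        proba = self.estimator_.predict_proba(Xv)
        pos_col = list(self.estimator_.classes_).index(POSITIVE_LABEL)
        return proba[:, pos_col]

    def predict_proba(self, X) -> np.ndarray:
        p = self._proba_positive(pd.DataFrame(X))
        out = np.empty((len(p), 2), dtype=float)
        for j, c in enumerate(self.classes_):
            out[:, j] = p if c == POSITIVE_LABEL else 1.0 - p
        return out

    def predict(self, X) -> np.ndarray:
        p = self._proba_positive(pd.DataFrame(X))
        return np.where(
            p >= self.probability_threshold, POSITIVE_LABEL, NEGATIVE_LABEL
        ).astype(object)


@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to reuse it."""

    spec: ClassifierSpec
    feature_names: list[str]
    estimator: BarrierClassifier
    training_summary: dict


def fit(spec: ClassifierSpec, table: pd.DataFrame, labels: Sequence[str]) -> TrainedModel:
    """Train one classifier on a descriptor table and C/NC labels."""
    clf = BarrierClassifier(
        family=spec.family,
        hyperparameters=dict(spec.hyperparameters),
        probability_threshold=spec.probability_threshold,
        seed=spec.seed,
        scale_features=spec.scale_features,
    )
    clf.fit(table, labels)
    y = np.asarray(labels, dtype=object)
    train_conf = confusion(y, clf.predict(table))
    summary = {
        "n_C": int(np.sum(y == NEGATIVE_LABEL)),
        "n_NC": int(np.sum(y == POSITIVE_LABEL)),
        "train_f_half": f_beta(train_conf, 0.5),
    }
    return TrainedModel(
        spec=spec,
        feature_names=list(clf.feature_names_),
        estimator=clf,
        training_summary=summary,
    )


def predict(model: TrainedModel, table: pd.DataFrame) -> pd.DataFrame:
    """Predicted labels and NC probabilities for each row of *table*."""
    proba = model.estimator._proba_positive(pd.DataFrame(table))
    labels = np.where(
        proba >= model.spec.probability_threshold, POSITIVE_LABEL, NEGATIVE_LABEL
    )
    return pd.DataFrame(
        {"probability_NC": proba, "predicted_label": labels},
        index=pd.DataFrame(table).index,
    )


def threshold_probe(
    model: TrainedModel,
    feature: str,
    values: Sequence[float],
    baseline: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Probe the decision boundary along one descriptor.

    Builds artificial samples that hold every model feature at the baseline
    (default 0) while sweeping *feature* through *values*, and reports the
    predicted label at each probe value. The result has columns
    value / probability_NC / predicted_label, with ``attrs["crossing_value"]``
    set to the probe value at the single label change, if there is exactly one.
    """
    if feature not in model.feature_names:
        raise ValueError(f"{feature!r} is not a model feature {model.feature_names}")
    base = {name: 0.0 for name in model.feature_names}
    base.update(baseline or {})
    rows = []
    for v in values:
        row = dict(base)
        row[feature] = float(v)
        rows.append(row)
    table = pd.DataFrame(rows, columns=model.feature_names)
    pred = predict(model, table)
    out = pd.DataFrame(
        {
            "value": list(values),
            "probability_NC": pred["probability_NC"].to_numpy(),
            "predicted_label": pred["predicted_label"].to_numpy(),
        }
    )
    flips = [
        i for i in range(1, len(out))
        if out["predicted_label"].iloc[i] != out["predicted_label"].iloc[i - 1]
    ]
    out.attrs["crossing_value"] = out["value"].iloc[flips[0]] if len(flips) == 1 else None
    return out


__all__ = [
    "FAMILIES",
    "ClassifierSpec",
    "BarrierClassifier",
    "TrainedModel",
    "fit",
    "predict",
    "threshold_probe",
]
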