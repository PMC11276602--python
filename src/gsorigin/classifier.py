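"""Soft-voting ensemble over origin classes.

Three base classifiers — multinomial logistic regression, a LightGBM
gradient-boosted tree model, and an RBF-kernel SVM with calibrated
probability outputs — are each tuned by stratified grid search maximizing
macro-F1, then combined by averaging their class-probability vectors (soft
voting, equal weights by default).  Features are the platform-neutral
gene-set NES values chosen by the selection step, standardized to zero
mean / unit variance with statistics learned on the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataio import DataError, OriginVocabulary
from .enrichment import EnrichmentMatrix
from .platform_select import FeatureSelection

__all__ = ["OriginModel", "OriginPrediction", "default_grid", "train", "predict", "top_k"]

MODEL_FORMAT_VERSION = 1


def default_grid() -> dict[str, dict[str, list]]:
    """Hyperparameter grid searched for each ensemble member."""
    return {
        "logistic": {"C": [0.1, 1.0, 10.0]},
        "lightgbm": {"num_leaves": [15, 31], "n_estimators": [100, 300]},
        "svm": {"C": [1.0, 10.0]},
    }


@dataclass(frozen=True)
class OriginPrediction:
    """Per-sample class-probability vector with its induced ranking.

    ``ranking`` orders the vocabulary by decreasing probability; exact ties
    keep vocabulary order.
    """

    sample: str
    vocabulary: OriginVocabulary
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.vocabulary),):
            raise DataError("probability vector length does not match vocabulary")
        if (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-9:
            raise DataError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def ranking(self) -> list[str]:
        order = np.argsort(-self.probs, kind="stable")
        return [self.vocabulary.classes[i] for i in order]

    @property
    def top1(self) -> str:
        return self.ranking[0]


@dataclass
class OriginModel:
    """Fitted soft-voting ensemble plus everything needed to reapply it."""

    vocabulary: OriginVocabulary
    features: list[str]
    scaler: StandardScaler
    members: dict[str, object]
    weights: dict[str, float]
    training_meta: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "OriginModel":
        blob = joblib.load(path)
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise DataError(f"unsupported model format version {blob.get('format_version')}")
        return blob["model"]


def _design_matrix(em: EnrichmentMatrix, features: list[str]) -> np.ndarray:
    missing = [f for f in features if f not in em.scores.index]
    if missing:
        raise DataError(f"unknown feature(s): {missing[:5]}")
    return em.scores.loc[features].to_numpy(dtype=float).T  # samples x features


def train(
    em: EnrichmentMatrix,
    sel: FeatureSelection,
    grid: dict | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    balanced: bool = False,
) -> OriginModel:
    """Fit the three members on the selected features with grid search.

    Every training sample must carry an origin_class; each class needs at
    least ``cv_folds`` samples for stratified CV.  Deterministic given
    ``seed`` (single-threaded fits, seeded CV shuffles and seeded internal
    randomness of each member).
    """
    grid = grid if grid is not None else default_grid()
    # canonical sample order: makes the fit invariant to input ordering
    # (SVC probability calibration and CV splits are order-sensitive)
    em = em.subset_samples(sorted(em.samples))
    labels = em.origin_class
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise DataError(f"sample(s) without origin_class in training data: {missing[:5]}")
    y = labels.astype(str).to_numpy()
    counts = pd.Series(y).value_counts()
    if len(counts) < 2:
        raise DataError("training data must contain at least two origin classes")
    if (counts < cv_folds).any():
        small = counts[counts < cv_folds]
        raise DataError(f"class(es) with fewer samples than cv_folds={cv_folds}: {dict(small)}")
    vocab = OriginVocabulary.from_labels(y)

    X = _design_matrix(em, list(sel.selected))
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    class_weight = "balanced" if balanced else None
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    bases = {
        "logistic": LogisticRegression(max_iter=5000, class_weight=class_weight),
        "lightgbm": LGBMClassifier(
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            verbose=-1,
            class_weight=class_weight,
        ),
        "svm": SVC(
            kernel="rbf",
            gamma="scale",
            probability=True,
            random_state=seed,
            class_weight=class_weight,
        ),
    }
    members: dict[str, object] = {}
    best_params: dict[str, dict] = {}
    for name, base in bases.items():
        search = GridSearchCV(
            base, grid.get(name, {}), scoring="f1_macro", cv=cv, n_jobs=1, refit=True
        )
        search.fit(Xs, y)
        members[name] = search.best_estimator_
        best_params[name] = search.best_params_

    return OriginModel(
        vocabulary=vocab,
        features=list(sel.selected),
        scaler=scaler,
        members=members,
        weights={name: 1.0 for name in members},
        training_meta={
            "grid": grid,
            "best_params": best_params,
            "cv_folds": cv_folds,
            "seed": seed,
            "balanced": balanced,
            "n_train": len(y),
        },
    )


def _member_proba(model: OriginModel, name: str, Xs: np.ndarray) -> np.ndarray:
    member = model.members[name]
    proba = member.predict_proba(Xs)
    # align member class order to the shared vocabulary
    aligned = np.zeros((Xs.shape[0], len(model.vocabulary)))
    for j, cls in enumerate(member.classes_):
        aligned[:, model.vocabulary.index_of(str(cls))] = proba[:, j]
    return aligned


def predict(model: OriginModel, em: EnrichmentMatrix) -> list[OriginPrediction]:
    """Soft-vote class probabilities for every sample in ``em``.

    The ensemble probability is the weight-normalized mean of the member
    probability vectors, so with equal weights it is a convex combination
    bounded by the member minima and maxima per class.
    """
    X = _design_matrix(em, model.features)
    Xs = model.scaler.transform(X)
    total_w = sum(model.weights.values())
    mixed = np.zeros((Xs.shape[0], len(model.vocabulary)))
    for name, w in model.weights.items():
        mixed += (w / total_w) * _member_proba(model, name, Xs)
    mixed = mixed / mixed.sum(axis=1, keepdims=True)
    return [
        OriginPrediction(sample=s, vocabulary=model.vocabulary, probs=mixed[i])
        for i, s in enumerate(em.samples)
    ]


def top_k(pred: OriginPrediction, k: int) -> list[str]:
    """First k classes of the prediction's probability ranking."""
    if not (1 <= k <= len(pred.vocabulary)):
        raise DataError(f"k must be in [1, {len(pred.vocabulary)}], got {k}")
    return pred.ranking[:k]


def write_predictions(preds: list[OriginPrediction], path: str | Path) -> None:
    if not preds:
        raise DataError("no predictions to write")
    vocab = preds[0].vocabulary
    rows = []
    for p in preds:
        row = {"sample_id": p.sample}
        row.update({cls: p.probs[i] for i, cls in enumerate(vocab.classes)})
        row["top1"] = p.ranking[0]
        row["top2"] = p.ranking[1] if len(vocab) > 1 else p.ranking[0]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
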