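"""Evaluation protocols: top-k accuracy, confusion matrices, stratified
k-fold CV, cross-platform transfer, band sweeps and cross-platform
correlation diagnostics.

"Weighted accuracy" here is pooled top-k accuracy — the fraction of samples
whose true class appears among the k highest-probability predictions — which
is identical to the class-support-weighted mean of per-class top-k
accuracies.  Macro-F1 is the unweighted mean of per-class F1 scores over the
classes present in the test split (classes absent from training are excluded
from the mean and logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from . import classifier as clf
from .dataio import DataError, ExpressionMatrix, OriginVocabulary
from .enrichment import EnrichmentMatrix
from .platform_select import FeatureSelection, feature_auc, select_band

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "topk_weighted_accuracy",
    "per_class_topk_accuracy",
    "confusion_matrix",
    "macro_f1",
    "cross_platform_validation",
    "kfold_cv",
    "band_sweep",
    "platform_correlation_diagnostic",
    "evaluate",
]


@dataclass
class EvaluationReport:
    confusion: pd.DataFrame
    top_k_accuracy: dict[int, float]
    per_class_topk: dict[str, float]
    macro_f1: float
    fold_scores: list[float] = field(default_factory=list)


def _truth_vector(preds: Sequence[clf.OriginPrediction], truth: Mapping[str, str]) -> list[str]:
    missing = [p.sample for p in preds if p.sample not in truth]
    if missing:
        raise DataError(f"missing truth label(s) for sample(s): {missing[:5]}")
    return [truth[p.sample] for p in preds]


def topk_weighted_accuracy(
    preds: Sequence[clf.OriginPrediction], truth: Mapping[str, str], k: int
) -> float:
    """Fraction of samples whose true class is in the top-k ranking."""
    labels = _truth_vector(preds, truth)
    hits = sum(1 for p, t in zip(preds, labels) if t in clf.top_k(p, k))
    return hits / len(preds)


def per_class_topk_accuracy(
    preds: Sequence[clf.OriginPrediction], truth: Mapping[str, str], k: int
) -> dict[str, float]:
    labels = _truth_vector(preds, truth)
    hits: dict[str, int] = {}
    totals: dict[str, int] = {}
    for p, t in zip(preds, labels):
        totals[t] = totals.get(t, 0) + 1
        hits[t] = hits.get(t, 0) + (1 if t in clf.top_k(p, k) else 0)
    return {c: hits[c] / totals[c] for c in totals}


def confusion_matrix(
    preds: Sequence[clf.OriginPrediction], truth: Mapping[str, str], vocab: OriginVocabulary
) -> pd.DataFrame:
    """Counts of (true class, top-1 predicted class); rows are truth."""
    labels = _truth_vector(preds, truth)
    mat = pd.DataFrame(0, index=list(vocab.classes), columns=list(vocab.classes), dtype=int)
    for p, t in zip(preds, labels):
        if t not in mat.index:
            raise DataError(f"truth class {t!r} outside vocabulary")
        top1 = p.top1
        if top1 not in mat.columns:
            raise DataError(f"predicted class {top1!r} outside vocabulary")
        mat.loc[t, top1] += 1
    return mat


def macro_f1(preds: Sequence[clf.OriginPrediction], truth: Mapping[str, str]) -> float:
    """Unweighted mean per-class F1 over classes present in the truth labels;
    truth classes the model cannot predict (absent from its vocabulary) are
    excluded from the mean with a warning."""
    labels = _truth_vector(preds, truth)
    model_classes = set(preds[0].vocabulary.classes)
    present = sorted(set(labels))
    scorable = [c for c in present if c in model_classes]
    skipped = [c for c in present if c not in model_classes]
    if skipped:
        logger.warning("classes absent from training excluded from macro-F1: %s", skipped)
    if not scorable:
        raise DataError("no test class overlaps the model vocabulary")
    y_pred = [p.top1 for p in preds]
    return float(f1_score(labels, y_pred, labels=scorable, average="macro", zero_division=0))


def _truth_of(em: EnrichmentMatrix) -> dict[str, str]:
    oc = em.origin_class
    if oc.isna().any():
        raise DataError("evaluation requires origin_class for every sample")
    return {s: str(c) for s, c in oc.items()}


def cross_platform_validation(
    em: EnrichmentMatrix,
    sel: FeatureSelection,
    train_platform: str,
    grid: dict | None = None,
    seed: int = 0,
    cv_folds: int = 3,
) -> float:
    """Train on one platform's samples, test on the other's; return macro-F1."""
    platforms = pd.unique(em.platform)
    if train_platform not in platforms:
        raise DataError(f"platform {train_platform!r} not present")
    if len(platforms) != 2:
        raise DataError(f"need exactly two platforms, got {list(platforms)}")
    train_ids = em.platform.index[em.platform == train_platform].tolist()
    test_ids = em.platform.index[em.platform != train_platform].tolist()
    model = clf.train(em.subset_samples(train_ids), sel, grid=grid, cv_folds=cv_folds, seed=seed)
    test_em = em.subset_samples(test_ids)
    preds = clf.predict(model, test_em)
    return macro_f1(preds, _truth_of(test_em))


def kfold_cv(
    em: EnrichmentMatrix,
    sel: FeatureSelection,
    k: int = 5,
    grid: dict | None = None,
    seed: int = 0,
    cv_folds: int = 3,
) -> list[float]:
    """Stratified shuffled k-fold top-1 accuracies, seed-deterministic."""
    truth = _truth_of(em)
    samples = np.asarray(em.samples)
    y = np.asarray([truth[s] for s in samples])
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        raise DataError(f"stratified {k}-fold split infeasible: {dict(counts[counts < k])}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(samples, y):
        model = clf.train(
            em.subset_samples(samples[train_idx]), sel, grid=grid, cv_folds=cv_folds, seed=seed
        )
        test_em = em.subset_samples(samples[test_idx])
        preds = clf.predict(model, test_em)
        scores.append(topk_weighted_accuracy(preds, truth, k=1))
    return scores


def band_sweep(
    em_train: EnrichmentMatrix,
    em_test: EnrichmentMatrix,
    deltas: Sequence[float],
    grid: dict | None = None,
    seed: int = 0,
    positive_platform: str | None = None,
    cv_folds: int = 3,
) -> pd.DataFrame:
    """Top-1 weighted accuracy on ``em_test`` for every (training cohort
    composition) x (delta band) combination.

    Compositions are each single platform of ``em_train`` plus both combined.
    AUCs are computed once on the full two-platform training matrix.  A delta
    whose band is empty yields a row marked failed; the sweep continues.
    """
    if len(deltas) == 0:
        raise DataError("deltas must be nonempty")
    platforms = list(pd.unique(em_train.platform))
    if len(platforms) != 2:
        raise DataError(f"training matrix must contain exactly two platforms, got {platforms}")
    pos = positive_platform if positive_platform is not None else platforms[0]
    aucs = feature_auc(em_train, pos)
    truth = _truth_of(em_test)
    compositions = [[platforms[0]], [platforms[1]], platforms]
    rows = []
    for delta in deltas:
        try:
            sel = select_band(aucs, delta, positive_platform=pos)
        except DataError as exc:
            for comp in compositions:
                rows.append(
                    {"delta": delta, "training_platforms": "+".join(comp), "n_features": 0,
                     "accuracy": np.nan, "failed": str(exc)}
                )
            continue
        for comp in compositions:
            ids = em_train.platform.index[em_train.platform.isin(comp)].tolist()
            try:
                model = clf.train(
                    em_train.subset_samples(ids), sel, grid=grid, cv_folds=cv_folds, seed=seed
                )
                preds = clf.predict(model, em_test)
                acc = topk_weighted_accuracy(preds, truth, k=1)
                rows.append(
                    {"delta": delta, "training_platforms": "+".join(comp),
                     "n_features": len(sel), "accuracy": acc, "failed": ""}
                )
            except DataError as exc:
                rows.append(
                    {"delta": delta, "training_platforms": "+".join(comp),
                     "n_features": len(sel), "accuracy": np.nan, "failed": str(exc)}
                )
    return pd.DataFrame(rows)


def platform_correlation_diagnostic(
    expr: ExpressionMatrix, em: EnrichmentMatrix, class_label: str
) -> tuple[float, float]:
    """Across-platform Pearson correlation of per-class mean feature vectors,
    at the gene level and at the gene-set-score level.

    A higher set-level than gene-level correlation indicates that the
    rank-based featurization absorbed the platform-specific intensity
    response that distorts raw expression.
    """
    platforms = list(pd.unique(expr.platform))
    if len(platforms) != 2:
        raise DataError(f"need exactly two platforms, got {platforms}")
    out = []
    for values, platform_ann, class_ann in (
        (expr.values, expr.platform, expr.origin_class),
        (em.scores, em.platform, em.origin_class),
    ):
        means = []
        for plat in platforms:
            mask = (platform_ann == plat) & (class_ann.astype(object) == class_label)
            ids = platform_ann.index[mask].tolist()
            if len(ids) < 2:
                raise DataError(f"class {class_label!r} has < 2 samples on platform {plat!r}")
            means.append(values[ids].mean(axis=1).to_numpy())
        a, b = means
        if np.std(a) == 0 or np.std(b) == 0:
            raise DataError("zero variance in a per-class mean vector")
        out.append(float(np.corrcoef(a, b)[0, 1]))
    return out[0], out[1]


def evaluate(
    preds: Sequence[clf.OriginPrediction],
    truth: Mapping[str, str],
    vocab: OriginVocabulary,
    ks: Sequence[int] = (1, 2),
) -> EvaluationReport:
    """Bundle the standard report: confusion, top-k accuracies, per-class
    top-max(k) accuracy, macro-F1."""
    kmax = max(ks)
    return EvaluationReport(
        confusion=confusion_matrix(preds, truth, vocab),
        top_k_accuracy={k: topk_weighted_accuracy(preds, truth, k) for k in ks},
        per_class_topk=per_class_topk_accuracy(preds, truth, kmax),
        macro_f1=macro_f1(preds, truth),
    )
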