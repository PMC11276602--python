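import numpy as np
import pandas as pd
import pytest

from gsorigin import classifier as clf
from gsorigin import enrichment, synth
from gsorigin.dataio import ExpressionMatrix
from gsorigin.platform_select import feature_auc, select_band


def small_config(**overrides) -> synth.SynthConfig:
    """A fast cohort: 300 genes, 3 classes, 8 samples/class/platform, 40 sets."""
    base = dict(
        n_genes=300,
        n_classes=3,
        samples_per_class_per_platform=8,
        n_gene_sets=40,
        set_size_range=(5, 15),
        class_effect=1.5,  # clearly separable: unit tests probe mechanics, not difficulty
        seed=11,
    )
    base.update(overrides)
    return synth.SynthConfig(**base)


FAST_GRID = {
    "logistic": {"C": [1.0]},
    "lightgbm": {"num_leaves": [15], "n_estimators": [50]},
    "svm": {"C": [1.0]},
}


@pytest.fixture(scope="session")
def fast_grid():
    return FAST_GRID


@pytest.fixture(scope="session")
def tiny_cohort():
    return synth.generate(small_config())


@pytest.fixture(scope="session")
def tiny_em(tiny_cohort):
    expr, gs, _ = tiny_cohort
    return enrichment.featurize(expr, gs)


@pytest.fixture(scope="session")
def tiny_selection(tiny_em):
    return select_band(feature_auc(tiny_em, "rnaseq"), 0.25, positive_platform="rnaseq")


@pytest.fixture(scope="session")
def tiny_model(tiny_em, tiny_selection, fast_grid):
    rnaseq = tiny_em.platform.index[tiny_em.platform == "rnaseq"].tolist()
    return clf.train(tiny_em.subset_samples(rnaseq), tiny_selection,
                     grid=fast_grid, cv_folds=3, seed=11)


def make_expression(values: np.ndarray, genes, samples, platform=None, origin=None) -> ExpressionMatrix:
    """Small hand-built ExpressionMatrix for unit tests."""
    platform = platform or ["rnaseq"] * len(samples)
    origin = origin if origin is not None else [None] * len(samples)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=list(genes), columns=list(samples), dtype=float),
        platform=pd.Series(platform, index=list(samples)),
        origin_class=pd.Series(origin, index=list(samples), dtype=object),
    )


@pytest.fixture(scope="session")
def default_pipeline():
    """The full default-condition pipeline, shared by the slower end-to-end
    tests: generate -> featurize -> platform AUCs -> delta=0.25 selection ->
    cross-platform training with and without selection."""
    from gsorigin.evaluation import topk_weighted_accuracy
    from gsorigin.platform_select import FeatureSelection

    cfg = synth.SynthConfig(seed=0)
    expr, gs, truth = synth.generate(cfg)
    em = enrichment.featurize(expr, gs)
    aucs = feature_auc(em, "rnaseq")
    sel25 = select_band(aucs, 0.25, positive_platform="rnaseq")
    sel_all = FeatureSelection(feature_auc=dict(aucs), positive_platform="rnaseq",
                               band_delta=0.5, selected=list(aucs))
    rnaseq = em.platform.index[em.platform == "rnaseq"].tolist()
    micro = em.platform.index[em.platform == "microarray"].tolist()
    truth_map = {s: str(c) for s, c in em.origin_class.items()}

    accuracy = {}
    predictions = {}
    for name, sel in (("selected", sel25), ("all_features", sel_all)):
        model = clf.train(em.subset_samples(rnaseq), sel, cv_folds=3, seed=0)
        preds = clf.predict(model, em.subset_samples(micro))
        predictions[name] = preds
        accuracy[name] = topk_weighted_accuracy(preds, truth_map, k=1)

    return {
        "cfg": cfg, "expr": expr, "gs": gs, "truth": truth, "em": em,
        "aucs": aucs, "sel25": sel25, "sel_all": sel_all,
        "accuracy": accuracy, "predictions": predictions, "truth_map": truth_map,
    }
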