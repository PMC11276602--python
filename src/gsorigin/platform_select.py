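"""Platform-neutral feature selection by single-feature ROC AUC.

Each gene-set feature is scored on how well it alone separates the two
measurement platforms (e.g. microarray vs RNA-seq cohorts).  An AUC of 0.5
means the feature carries no platform information, so the classifier built
on it cannot tell the cohorts apart — exactly the features that let the
cohorts be pooled.  Features with |AUC - 0.5| <= delta are retained.

AUC is computed with the tie-corrected rank-sum (Mann-Whitney) identity:
AUC = P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg), which the
average-rank formulation yields exactly in O(n log n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataio import DataError
from .enrichment import EnrichmentMatrix

__all__ = ["FeatureSelection", "feature_auc", "select_band", "auc_histogram"]

DEFAULT_DELTA = 0.25


@dataclass
class FeatureSelection:
    """Per-feature platform AUC and the features retained inside a delta band."""

    feature_auc: dict[str, float]
    positive_platform: str
    band_delta: float
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = [f for f in self.selected if f not in self.feature_auc]
        if unknown:
            raise DataError(f"selected features missing AUCs: {unknown[:5]}")

    def __len__(self) -> int:
        return len(self.selected)


def feature_auc(em: EnrichmentMatrix, positive_platform: str) -> dict[str, float]:
    """Single-feature ROC AUC for discriminating the two platforms.

    Returns a mapping in the enrichment-matrix feature order.  Exactly two
    platform labels must be present; ``positive_platform`` is the one whose
    higher scores count toward AUC > 0.5.
    """
    platforms = pd.unique(em.platform)
    if len(platforms) != 2:
        raise DataError(f"need exactly two platforms, got {list(platforms)}")
    if positive_platform not in platforms:
        raise DataError(f"positive platform {positive_platform!r} not present in {list(platforms)}")
    pos_mask = (em.platform == positive_platform).to_numpy()
    n_pos = int(pos_mask.sum())
    n_neg = int((~pos_mask).sum())
    ranks = rankdata(em.scores.to_numpy(), axis=1, method="average")
    r_pos = ranks[:, pos_mask].sum(axis=1)
    auc = (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return dict(zip(em.gene_sets, auc.tolist()))


def select_band(aucs: dict[str, float], delta: float, positive_platform: str = "") -> FeatureSelection:
    """Retain features with |AUC - 0.5| <= delta (boundary inclusive).

    Selection order follows the input feature order.  Nested bands are
    monotone: a smaller delta always selects a subset of a larger one.
    """
    if not (0.0 < delta <= 0.5):
        raise DataError(f"delta must be in (0, 0.5], got {delta}")
    # epsilon keeps the boundary genuinely inclusive under float rounding
    # (e.g. |0.55 - 0.5| evaluates a hair above 0.05)
    selected = [f for f, a in aucs.items() if abs(a - 0.5) <= delta + 1e-12]
    if not selected:
        raise DataError(f"no feature within the AUC band 0.5 +/- {delta}")
    return FeatureSelection(
        feature_auc=dict(aucs), positive_platform=positive_platform, band_delta=delta, selected=selected
    )


def auc_histogram(aucs: dict[str, float], bin_width: float) -> pd.DataFrame:
    """Histogram of feature AUCs over (0, 1] with half-open bins [lo, hi),
    last bin closed so AUC = 1.0 is counted."""
    if not (0.0 < bin_width <= 0.5):
        raise DataError(f"bin width must divide (0, 1] into >= 2 bins, got {bin_width}")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    values = np.fromiter(aucs.values(), dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts})


def write_selection_report(sel: FeatureSelection, path) -> None:
    chosen = set(sel.selected)
    rows = pd.DataFrame(
        {
            "gene_set": list(sel.feature_auc),
            "auc": [sel.feature_auc[f] for f in sel.feature_auc],
            "selected": [int(f in chosen) for f in sel.feature_auc],
        }
    )
    rows.to_csv(path, sep="\t", index=False, float_format="%.17g")
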