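"""Single-sample gene-set enrichment scoring.

Each sample's expression profile is reduced to a ranking of the measured gene
universe (descending expression, ties broken lexicographically by symbol).
For a gene set with m of N universe genes, the unweighted GSEA running sum —
which is exactly the two-sample Kolmogorov-Smirnov statistic on rank
positions — walks the ranking adding 1/m at members and subtracting 1/(N-m)
at non-members.  The enrichment score (ES) is the deviation of largest
magnitude: the positive peak if members concentrate at high expression, the
negative trough if they concentrate at low expression (|peak| wins ties).
ES is then normalized to an NES by dividing by the mean |ES| of random
same-size gene sets drawn uniformly from the universe, making scores
comparable across set sizes.

Because scoring is rank-based, any strictly increasing per-sample transform
of expression (log, quantile scaling, platform-specific intensity response)
leaves every score exactly unchanged — the property that makes microarray and
RNA-seq cohorts comparable at the gene-set level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .dataio import DataError, ExpressionMatrix, GeneSetCollection

__all__ = [
    "EnrichmentMatrix",
    "RankedProfile",
    "rank_genes",
    "enrichment_score",
    "normalize_score",
    "featurize",
]

DEFAULT_MIN_SET_SIZE = 5
DEFAULT_N_NULL = 100
DEFAULT_SEED = 13


@dataclass
class EnrichmentMatrix:
    """Gene-set x sample matrix of signed normalized enrichment scores."""

    scores: pd.DataFrame
    platform: pd.Series
    origin_class: pd.Series
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        from .dataio import _check_sample_annotations

        _check_sample_annotations(self.scores, self.platform, self.origin_class)

    @property
    def gene_sets(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.scores.columns.tolist()

    def subset_samples(self, samples: Iterable[str]) -> "EnrichmentMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.scores.columns]
        if missing:
            raise DataError(f"unknown samples: {missing[:5]}")
        return EnrichmentMatrix(
            scores=self.scores[samples].copy(),
            platform=self.platform[samples].copy(),
            origin_class=self.origin_class[samples].copy(),
            params=dict(self.params),
        )


@dataclass(frozen=True)
class RankedProfile:
    """One sample's gene universe ordered by decreasing expression.

    ``ranking`` is a bijection over the universe; it is invariant under any
    strictly increasing transform of the sample's expression values.
    """

    ranking: tuple[str, ...]
    tie_rule: str = "lexicographic"

    def __len__(self) -> int:
        return len(self.ranking)


def rank_genes(m: ExpressionMatrix, sample: str) -> RankedProfile:
    """Order the universe by descending expression in one sample.

    Ties are broken lexicographically by gene symbol so the ranking is a
    deterministic function of the (value, symbol) pairs.
    """
    if sample not in m.values.columns:
        raise DataError(f"unknown sample {sample!r}")
    vals = m.values[sample].to_numpy(dtype=float)
    genes = np.asarray(m.genes, dtype=object)
    lex = np.argsort(np.argsort(genes))  # lexicographic rank of each gene
    order = np.lexsort((lex, -vals))
    return RankedProfile(ranking=tuple(genes[order]))


def _es_from_sorted_positions(pos: np.ndarray, n: int) -> np.ndarray:
    """Signed ES from sorted 1-based member rank positions.

    ``pos`` has member positions along the last axis, sorted ascending.
    Vectorized over any leading axes.  The running sum just after the i-th
    member equals i/m - (pos_i - i)/(n - m); just before it equals
    (i-1)/m - (pos_i - i)/(n - m).  The walk starts and ends at 0, so the
    peak is max(after, 0) and the trough min(before, 0).
    """
    m = pos.shape[-1]
    if not (1 <= m < n):
        raise DataError(f"gene set size {m} invalid for universe of {n}")
    i = np.arange(1, m + 1, dtype=float)
    miss = (pos - i) / (n - m)
    after = i / m - miss
    before = (i - 1) / m - miss
    d_plus = np.maximum(after.max(axis=-1), 0.0)
    d_minus = np.minimum(before.min(axis=-1), 0.0)
    # tolerance makes the "peak wins exact ties" rule robust to rounding: true
    # nonzero gaps are multiples of 1/(m*(n-m)), far above 1e-12
    return np.where(d_plus >= -d_minus - 1e-12, d_plus, d_minus)


def enrichment_score(profile: RankedProfile, members: Iterable[str]) -> float:
    """Signed KS enrichment score of ``members`` against a ranked profile.

    Positive scores mean the set's genes sit unusually high in the expression
    ranking, negative unusually low; ES is always in [-1, 1].  Genes outside
    the universe are ignored; an empty intersection, or a set covering the
    whole universe, is an error (the running sum is degenerate).
    """
    universe = profile.ranking
    n = len(universe)
    member_set = set(members)
    pos = np.array([k + 1 for k, g in enumerate(universe) if g in member_set], dtype=float)
    if pos.size == 0:
        raise DataError("gene set has no members in the universe")
    if pos.size == n:
        raise DataError("gene set covers the entire universe")
    return float(_es_from_sorted_positions(pos, n))


def _null_mean_abs_es(n: int, m: int, n_null: int, seed: int) -> float:
    """Mean |ES| of ``n_null`` uniform random size-m subsets of an n-gene
    universe.  Depends only on (n, m, n_null, seed): random member positions
    are uniform regardless of the ranking itself."""
    if n_null < 1:
        raise DataError("n_null must be >= 1")
    rng = np.random.default_rng([seed, m, n])
    u = rng.random((n_null, n))
    pos = np.sort(np.argpartition(u, m - 1, axis=1)[:, :m], axis=1) + 1.0
    null = _es_from_sorted_positions(pos, n)
    mean_abs = float(np.abs(null).mean())
    if mean_abs == 0.0:
        raise RuntimeError("degenerate null: mean |ES| is zero")  # unreachable for 1 <= m < n
    return mean_abs


def normalize_score(
    es: float,
    set_size: int,
    profile: RankedProfile,
    n_null: int = DEFAULT_N_NULL,
    seed: int = DEFAULT_SEED,
) -> float:
    """NES = ES / mean(|ES|) of random same-size sets from the universe.

    The sign of ``es`` is preserved; the result is deterministic given
    (seed, n_null, universe size).
    """
    return es / _null_mean_abs_es(len(profile), set_size, n_null, seed)


def featurize(
    m: ExpressionMatrix,
    gs: GeneSetCollection,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    n_null: int = DEFAULT_N_NULL,
    seed: int = DEFAULT_SEED,
) -> EnrichmentMatrix:
    """Score every (gene set, sample) pair into a signed NES matrix.

    Gene sets are first intersected with the measured gene universe; sets
    with fewer than ``min_set_size`` surviving members are dropped and listed
    in ``params['dropped_sets']``.  Null scaling factors are computed once per
    surviving set size and reused across all samples (the universe is shared).
    Each sample's column depends only on that sample's expression profile.
    """
    genes = np.asarray(m.genes, dtype=object)
    n = len(genes)
    gene_index = {g: k for k, g in enumerate(genes)}
    lex = np.argsort(np.argsort(genes))

    surviving: list[tuple[str, np.ndarray]] = []
    dropped: list[str] = []
    for name, members in gs:
        idx = np.array([gene_index[g] for g in members if g in gene_index], dtype=int)
        if idx.size < min_set_size or idx.size >= n:
            dropped.append(name)
        else:
            surviving.append((name, idx))
    if not surviving:
        raise DataError(f"no gene set has >= {min_set_size} members in the {n}-gene universe")

    vals = m.values.to_numpy(dtype=float)
    n_samples = vals.shape[1]
    # position (1-based rank) of every gene in every sample's ranking
    pos_of_gene = np.empty((n, n_samples), dtype=float)
    rows = np.arange(1, n + 1, dtype=float)
    for j in range(n_samples):
        order = np.lexsort((lex, -vals[:, j]))
        pos_of_gene[order, j] = rows

    null_means: dict[int, float] = {}
    scores = np.empty((len(surviving), n_samples), dtype=float)
    for r, (name, idx) in enumerate(surviving):
        msize = idx.size
        if msize not in null_means:
            null_means[msize] = _null_mean_abs_es(n, msize, n_null, seed)
        p = np.sort(pos_of_gene[idx, :], axis=0).T  # samples x m
        scores[r, :] = _es_from_sorted_positions(p, n) / null_means[msize]

    df = pd.DataFrame(scores, index=[name for name, _ in surviving], columns=m.values.columns)
    params = {
        "min_set_size": min_set_size,
        "n_null": n_null,
        "seed": seed,
        "n_genes_universe": n,
        "dropped_sets": dropped,
    }
    return EnrichmentMatrix(
        scores=df, platform=m.platform.copy(), origin_class=m.origin_class.copy(), params=params
    )
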