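"""Two-platform synthetic expression cohorts with planted structure.

The generator emulates the situation the pipeline is built for: two cohorts
measured on different platforms (an "rnaseq" platform and a "microarray"
platform with a compressive intensity response), sharing class-dependent
gene-set activation but differing in per-gene scale, offset and
platform-specific artifacts.  Three kinds of gene sets are planted:

* class-informative sets, whose member genes are up-shifted in samples of
  one assigned class on **both** platforms (the biological signal);
* platform-biased sets, whose member genes are shifted on the microarray
  platform only — alternately up and down across sets, the way probe sets
  over- or under-report relative to sequencing (the technical artifact the
  AUC band is meant to remove);
* background sets with no planted signal.

Baseline expression is lognormal per gene.  Platform bias is injected at the
gene level *before* ranking so it genuinely perturbs enrichment scores, and
each platform's values are additionally passed through a monotone
scale/offset/exponent distortion that rank-based featurization must (and
does) absorb exactly.  The three set categories draw members from disjoint
gene pools so each planted effect is clean.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dataio import DataError, ExpressionMatrix, GeneSetCollection
from .enrichment import EnrichmentMatrix
from .platform_select import FeatureSelection

__all__ = ["SynthConfig", "SynthTruth", "generate", "expected_properties", "DEFAULT_CLASS_NAMES"]

DEFAULT_CLASS_NAMES = (
    "breast", "lung", "colorectal", "liver", "kidney", "stomach", "ovary",
    "pancreas", "prostate", "skin", "thyroid", "brain", "bladder", "uterus",
    "bile_duct", "head_and_neck", "adrenal_gland",
)

PLATFORM_A = "rnaseq"
PLATFORM_B = "microarray"


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic two-platform experiment.

    ``class_effect`` is the mean log-scale up-shift, in units of
    ``noise_sd``, applied to informative-set member genes in their class;
    ``platform_effect`` is the magnitude of the log-scale shift applied to
    biased-set member genes on the microarray platform only, with
    alternating sign across biased sets (default calibrated so a biased
    feature's platform AUC deviates from 0.5 by about 0.3, i.e. lands near
    0.8 or 0.2).  ``gene_response_sd`` is the SD of a fixed per-gene
    log-scale probe response on the microarray platform, emulating
    gene-specific probe efficiency: it scrambles cross-platform
    comparability at the gene level, while set-level scores, which pool
    ~m member ranks, largely absorb it.  ``platform_transform`` maps each
    platform label to a monotone distortion
    ``value -> scale * value**exponent + offset`` applied last.
    """

    n_genes: int = 2000
    n_classes: int = 6
    samples_per_class_per_platform: int = 20
    n_gene_sets: int = 300
    set_size_range: tuple[int, int] = (10, 30)
    frac_class_informative: float = 0.3
    frac_platform_biased: float = 0.3
    class_effect: float = 0.4
    platform_effect: float = 0.3
    noise_sd: float = 1.0
    gene_response_sd: float = 0.1
    platform_transform: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            PLATFORM_A: {"scale": 1.0, "offset": 0.0, "exponent": 1.0},
            PLATFORM_B: {"scale": 0.25, "offset": 30.0, "exponent": 0.15},
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 10 or self.n_classes < 2 or self.n_gene_sets < 1:
            raise DataError("config too small: need >= 10 genes, >= 2 classes, >= 1 gene set")
        if self.samples_per_class_per_platform < 1:
            raise DataError("need at least one sample per class per platform")
        lo, hi = self.set_size_range
        if not (5 <= lo <= hi):
            raise DataError(f"set sizes must be >= 5, got range {self.set_size_range}")
        if hi > self.n_genes // 10:
            # smallest pool is one half of the 20% biased-gene pool
            raise DataError("set sizes too large for the gene pools")
        for frac in (self.frac_class_informative, self.frac_platform_biased):
            if not (0.0 <= frac <= 1.0):
                raise DataError("fractions must lie in [0, 1]")
        if self.frac_class_informative + self.frac_platform_biased > 1.0:
            raise DataError("informative + biased fractions must sum to <= 1")
        if self.class_effect < 0 or self.platform_effect < 0 or self.noise_sd <= 0:
            raise DataError("effects must be >= 0 and noise_sd > 0")
        if self.gene_response_sd < 0:
            raise DataError("gene_response_sd must be >= 0")
        for plat, tf in self.platform_transform.items():
            if tf.get("scale", 1.0) <= 0 or tf.get("exponent", 1.0) <= 0:
                raise DataError(f"platform transform for {plat!r} is not strictly increasing")


@dataclass
class SynthTruth:
    """Ground truth of one generation run."""

    class_of_set: dict[str, str]
    biased_sets: list[str]
    background_sets: list[str]
    sample_labels: pd.DataFrame  # index sample_id, columns platform / origin_class
    config: SynthConfig


def generate(cfg: SynthConfig) -> tuple[ExpressionMatrix, GeneSetCollection, SynthTruth]:
    """Draw one synthetic two-platform cohort under ``cfg``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    classes = list(DEFAULT_CLASS_NAMES[: cfg.n_classes])
    if cfg.n_classes > len(DEFAULT_CLASS_NAMES):
        classes = [f"class_{i:02d}" for i in range(cfg.n_classes)]

    # disjoint gene pools: 40% informative / 20% biased / 40% background
    perm = rng.permutation(cfg.n_genes)
    n_inf_pool = int(round(0.4 * cfg.n_genes))
    n_bias_pool = int(round(0.2 * cfg.n_genes))
    bias_pool = perm[n_inf_pool : n_inf_pool + n_bias_pool]
    pools = {
        "informative": perm[:n_inf_pool],
        # biased sets alternate direction; same-direction sets share a pool so
        # every set's member shifts stay coherent
        "biased_up": bias_pool[: n_bias_pool // 2],
        "biased_down": bias_pool[n_bias_pool // 2 :],
        "background": perm[n_inf_pool + n_bias_pool :],
    }

    n_inf = int(round(cfg.frac_class_informative * cfg.n_gene_sets))
    n_bias = int(round(cfg.frac_platform_biased * cfg.n_gene_sets))
    categories = ["informative"] * n_inf
    categories += ["biased_up" if k % 2 == 0 else "biased_down" for k in range(n_bias)]
    categories += ["background"] * (cfg.n_gene_sets - len(categories))

    lo, hi = cfg.set_size_range
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    class_of_set: dict[str, str] = {}
    biased_sets: list[str] = []
    background_sets: list[str] = []
    inf_count = 0
    for k, cat in enumerate(categories):
        name = f"SET_{k:04d}"
        size = int(rng.integers(lo, hi + 1))
        members = genes[rng.choice(pools[cat], size=size, replace=False)]
        sets[name] = members.tolist()
        if cat == "informative":
            cls = classes[inf_count % cfg.n_classes]
            class_of_set[name] = cls
            descriptions[name] = f"synthetic signature activated in {cls}"
            inf_count += 1
        elif cat.startswith("biased"):
            biased_sets.append(name)
            descriptions[name] = "synthetic platform-biased signature"
        else:
            background_sets.append(name)
            descriptions[name] = "synthetic background set"
    gs = GeneSetCollection(sets=sets, descriptions=descriptions)

    # per-class / per-platform gene shift indicators
    gene_pos = {g: i for i, g in enumerate(genes)}
    class_gene_mask = np.zeros((cfg.n_classes, cfg.n_genes), dtype=bool)
    for name, cls in class_of_set.items():
        idx = [gene_pos[g] for g in sets[name]]
        class_gene_mask[classes.index(cls), idx] = True
    biased_gene_shift = np.zeros(cfg.n_genes)
    up_pool = set(pools["biased_up"].tolist())
    for name in biased_sets:
        for g in sets[name]:
            i = gene_pos[g]
            biased_gene_shift[i] = cfg.platform_effect if i in up_pool else -cfg.platform_effect

    spp = cfg.samples_per_class_per_platform
    sample_ids, platforms, labels = [], [], []
    for plat in (PLATFORM_A, PLATFORM_B):
        for cls in classes:
            for i in range(spp):
                sample_ids.append(f"{plat}_{cls}_{i:03d}")
                platforms.append(plat)
                labels.append(cls)
    n_samples = len(sample_ids)

    mu = rng.normal(2.0, 1.0, size=cfg.n_genes)  # lognormal baseline, log scale
    gene_response = cfg.gene_response_sd * rng.standard_normal(cfg.n_genes)
    z = mu[:, None] + cfg.noise_sd * rng.standard_normal((cfg.n_genes, n_samples))
    for j in range(n_samples):
        ci = classes.index(labels[j])
        z[class_gene_mask[ci], j] += cfg.class_effect * cfg.noise_sd
        if platforms[j] == PLATFORM_B:
            z[:, j] += biased_gene_shift + gene_response
    v = np.exp(z)
    for plat in (PLATFORM_A, PLATFORM_B):
        tf = cfg.platform_transform.get(plat, {})
        scale = float(tf.get("scale", 1.0))
        offset = float(tf.get("offset", 0.0))
        exponent = float(tf.get("exponent", 1.0))
        cols = [j for j, p in enumerate(platforms) if p == plat]
        v[:, cols] = scale * v[:, cols] ** exponent + offset

    values = pd.DataFrame(v, index=genes, columns=sample_ids)
    platform = pd.Series(platforms, index=sample_ids, name="platform")
    origin = pd.Series(labels, index=sample_ids, name="origin_class", dtype=object)
    expr = ExpressionMatrix(values=values, platform=platform, origin_class=origin)
    truth = SynthTruth(
        class_of_set=class_of_set,
        biased_sets=biased_sets,
        background_sets=background_sets,
        sample_labels=pd.DataFrame({"platform": platform, "origin_class": origin}),
        config=cfg,
    )
    return expr, gs, truth


def expected_properties(
    truth: SynthTruth, em: EnrichmentMatrix, sel: FeatureSelection
) -> dict[str, float]:
    """Check the planted structure against a featurized + selected run.

    Reports the fraction of planted platform-biased sets the selection
    excluded, the fraction of class-informative sets it retained, and the
    mean NES of informative sets inside vs outside their assigned class.
    """
    known = set(truth.class_of_set) | set(truth.biased_sets) | set(truth.background_sets)
    present = [s for s in em.gene_sets if s in known]
    if len(present) != len(em.gene_sets):
        raise DataError("enrichment matrix contains gene sets unknown to this truth (mismatched provenance)")
    if any(f not in known for f in sel.feature_auc):
        raise DataError("selection covers gene sets unknown to this truth (mismatched provenance)")

    selected = set(sel.selected)
    biased_present = [s for s in truth.biased_sets if s in em.scores.index]
    inf_present = [s for s in truth.class_of_set if s in em.scores.index]
    frac_biased_excluded = (
        sum(1 for s in biased_present if s not in selected) / len(biased_present)
        if biased_present else float("nan")
    )
    frac_informative_retained = (
        sum(1 for s in inf_present if s in selected) / len(inf_present)
        if inf_present else float("nan")
    )

    in_class, out_class = [], []
    origin = em.origin_class.astype(object)
    for s in inf_present:
        cls = truth.class_of_set[s]
        row = em.scores.loc[s]
        mask = (origin == cls).to_numpy()
        in_class.append(float(row.to_numpy()[mask].mean()))
        out_class.append(float(row.to_numpy()[~mask].mean()))
    return {
        "frac_biased_excluded": frac_biased_excluded,
        "frac_informative_retained": frac_informative_retained,
        "informative_in_class_mean_nes": float(np.mean(in_class)) if in_class else float("nan"),
        "informative_out_class_mean_nes": float(np.mean(out_class)) if out_class else float("nan"),
    }
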