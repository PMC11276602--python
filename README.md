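# gsorigin

Predicting the tissue of origin of a metastatic tumor from its
transcriptome, across measurement platforms.

Metastatic cancers of unknown primary (CUP) are treated far more effectively
when the organ the tumor arose in is known. Expression-based origin
classifiers exist, but the two largest public sources of labeled tumor
transcriptomes — RNA-seq consortia and legacy microarray compendia — live on
incompatible numeric scales, so models trained on one platform transfer
poorly to the other.

`gsorigin` implements a three-stage pipeline that makes the platforms
compatible before any classifier sees the data:

1. **Gene-set featurization.** Each sample's expression profile is reduced
   to a ranking of its genes, and every gene set *S* (|*S* ∩ universe| = *m*
   of *N* genes) is scored with the unweighted GSEA running sum — the
   Kolmogorov–Smirnov statistic on rank positions: walking the ranking, add
   1/*m* at members and subtract 1/(*N*−*m*) elsewhere; the enrichment score
   ES ∈ [−1, 1] is the deviation of largest magnitude, positive when members
   concentrate at high expression. ES is normalized to NES = ES / E|ES|
   under random same-size gene sets, making scores comparable across set
   sizes. Because the score depends only on within-sample ranks, any
   monotone platform response (log-like microarray compression, scale,
   offset) is absorbed exactly.
2. **Platform-neutral feature selection.** For every gene-set feature the
   single-feature ROC AUC for discriminating the two platforms is computed
   by the tie-corrected rank-sum identity. AUC ≈ 0.5 means the feature
   carries no platform signal; features with |AUC − 0.5| ≤ δ (default
   δ = 0.25) are retained, the rest — platform artifacts — are discarded.
3. **Soft-voting ensemble.** Multinomial logistic regression, LightGBM and
   an RBF SVM are each tuned by stratified grid search maximizing macro-F1
   on standardized NES features, then combined by averaging their class
   probability vectors. Predictions are rankings of candidate origin
   classes; accuracy is reported as top-*k* (truth among the *k* most
   probable classes).

A seed-deterministic synthetic-data module generates two-platform cohorts
with planted class-dependent gene-set activation, planted platform-biased
sets, a per-gene probe response and a compressive microarray transform, so
the whole pipeline is testable end to end without any downloads.

## Worked example

```python
from gsorigin import synth, featurize, feature_auc, select_band, train, predict
from gsorigin.evaluation import topk_weighted_accuracy, platform_correlation_diagnostic

expr, gene_sets, truth = synth.generate(synth.SynthConfig(seed=0))
em = featurize(expr, gene_sets)

r_gene, r_set = platform_correlation_diagnostic(expr, em, "breast")
aucs = feature_auc(em, "rnaseq")
sel = select_band(aucs, delta=0.25, positive_platform="rnaseq")

rnaseq = em.platform.index[em.platform == "rnaseq"]
micro = em.platform.index[em.platform == "microarray"]
model = train(em.subset_samples(rnaseq), sel, cv_folds=3, seed=0)
preds = predict(model, em.subset_samples(micro))
truth_map = {s: c for s, c in em.origin_class.items()}
```

prints (via the accompanying format calls):

```
cross-platform correlation  gene level: 0.786   gene-set level: 0.818
platform-neutral features: 226 / 300 inside AUC 0.5 +/- 0.25
train RNA-seq -> test microarray  top-1: 0.933   top-2: 0.967
sample microarray_breast_000: top-2 ranking ['breast', 'colorectal'], P(breast) = 0.51
```

Reading the numbers: per-class mean profiles of the two platforms agree
better at the gene-set level (0.818) than at the gene level (0.786) — the
featurization absorbed most of the platform distortion. 226 of 300 features
are platform-neutral at δ = 0.25. A model trained purely on the RNA-seq
cohort then identifies the origin of 93% of microarray samples at top-1 and
97% at top-2; for the first test sample the ensemble puts probability 0.51
on the correct organ.

The same pipeline is available as a CLI:

```bash
gsorigin synth --out-dir data --seed 0
gsorigin featurize --matrix data/expression.tsv --metadata data/metadata.tsv \
    --gmt data/gene_sets.gmt --out enrich.tsv
gsorigin select --enrichment enrich.tsv --metadata data/metadata.tsv \
    --positive-platform rnaseq --delta 0.25 --out selection.tsv
gsorigin train --enrichment enrich.tsv --metadata data/metadata.tsv \
    --selection selection.tsv --out model.joblib
gsorigin predict --model model.joblib --enrichment enrich.tsv \
    --metadata data/metadata.tsv --out predictions.tsv
gsorigin evaluate --predictions predictions.tsv --metadata data/metadata.tsv \
    --out report.json
```

All inputs and outputs are plain TSV / GMT / JSON; reruns with the same
config are byte-identical.

## Documentation

`docs/methods.md` describes the model, its assumptions, all tunable
parameters with defaults and rationale, what the synthetic generator does
and does not emulate, and the package's numerical conventions.
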