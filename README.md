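# miniabs

Absolute single-sample intrinsic-subtype classification of breast cancer
from a minimal gene panel.

## The problem

The five intrinsic breast-cancer subtypes (Basal-like, Her2E, LumA, LumB,
Normal-like) are usually assigned by nearest-centroid classifiers such as
PAM50, which require cohort-level normalization and gene centering before a
sample can be scored. The call for one patient therefore depends on the
assay platform and on the composition of the cohort it happens to be
processed with — a serious problem for clinical trials with biased subtype
enrichment and for meta-analysis across platforms. An *absolute*
single-sample classifier (SSC) must make its call from one sample's raw
measurements alone.

`miniabs` implements such a classifier and its full construction pipeline.
The features are pairwise gene expression ratios (PGER) within one sample:
for raw linear expression values *e_i*, *e_j* (RPKM/FPKM-like units) of two
panel genes,

    r_ij = log2((e_i + 1) / (e_j + 1)),   1 <= i < j <= n,

soft-thresholded by a slack margin α that treats ratios within ±α of zero
as experimental noise:

    r'_ij = 0        if |r_ij| <= α
          = r_ij − α if  r_ij  >  α
          = r_ij + α if  r_ij  < −α

An n-gene panel yields n(n−1)/2 features per sample; because every ratio is
taken within the sample, the classifier's call is exactly independent of
cohort composition and largely independent of platform scale.

The construction pipeline, all provided here:

1. **ssDEG selection** — one-vs-rest Wilcoxon rank-sum tests with BH-FDR
   (q < 0.005) rank subtype-specific differentially expressed genes per
   subtype over a gene universe (default: the PAM50 gene list).
2. **Candidate gene sets** — four clinical seed markers (ESR1, PGR, ERBB2,
   MKI67) plus the top-k ssDEGs of each subtype, for levels k = 1..5
   (8 genes at level 1, 13 at level 2 for the bundled reference ranking).
3. **Grid training** — repeated stratified 5-fold cross-validation of
   4 algorithms (random forest, RBF-SVM, CART, naive Bayes) × 7 slack
   margins (α ∈ {0, 0.01, 0.05, 0.10, 0.15, 0.20, 1.00}) per level; the
   initial model is the smallest gene set within tolerance of the best
   accuracy.
4. **Gene reduction** — random-forest mean-decrease-Gini importances are
   summed per gene over its incident pair features; genes are removed one
   at a time from the bottom of the ranking (a protected head above the
   largest importance gap is kept) and the smallest panel whose CV accuracy
   stays within tolerance wins. On the reference data this yields the
   shipped 11-gene panel {ESR1, PGR, ERBB2, MKI67, MLPH, FGFR4, CEP55,
   KRT17, FOXA1, MYBL2, SFRP1} with 55 PGER features.
5. **Slack-margin ensemble** — one classifier per α is trained on the final
   panel; a new sample is called by majority vote of the seven members,
   with tied votes reported as `Ambiguous` (scored as incorrect).

No fitted weights are shipped: the panel and construction are provided, and
models are trained on your own (or synthetic) labelled data.

## Worked example

Train an ensemble on a simulated five-class cohort (60 samples per
subtype, 8 marker genes at 2 log2-units effect, σ = 0.7 log-normal noise,
5 pure-noise genes) and classify held-out samples:

```python
from miniabs import (SimConfig, default_markers, simulate, call_ssdegs,
                     significant_ssdegs, split_train_test, MiniAbsClassifier, score)

cfg = SimConfig(
    class_sizes={"Basal-like": 60, "Her2E": 60, "LumA": 60, "LumB": 60, "Normal-like": 60},
    markers=default_markers(2.0),
    noise_gene_names=("FOXA1", "MYBL2", "GRB7", "KRT14", "FGFR4"),
    noise_sd=0.7, seed=0,
)
mat, labels = simulate(cfg)
table = call_ssdegs(mat, labels, gene_universe=list(mat.genes))
print(significant_ssdegs(table).head(5).to_string(index=False))

X = mat.to_samples_by_genes()
X_tr, y_tr, X_te, y_te = split_train_test(X, labels, 0.8, seed=0)
model = MiniAbsClassifier(
    genes=[g for g in mat.genes if g not in ("FOXA1", "MYBL2", "GRB7", "KRT14", "FGFR4")],
    algorithm="rf", folds=5, repeats=2, tune_grid_size=2, random_state=0,
).fit(X_tr, y_tr)

single = model.predict_single(X_te.iloc[0].to_dict())
print("single-sample call:", single.final.iloc[0])

print(score(model.predict_result(X_te), y_te, exclude_normal_like=True).to_text())
```

prints (abridged):

```
 gene    subtype      p_value      q_value direction  rank  passed_threshold
KRT17 Basal-like 2.851654e-31 3.707151e-30        up     1              True
 MLPH Basal-like 4.861348e-30 3.159876e-29      down     2              True
ERBB2      Her2E 6.970873e-31 9.062136e-30        up     1              True
  PGR       LumA 1.101951e-29 1.149986e-28        up     1              True
 ESR1       LumA 1.769209e-29 1.149986e-28        up     2              True

single-sample call: Basal-like

samples scored      : 48
accuracy            : 0.9375
Cohen's kappa       : 0.9184 (95% CI 0.8289-1.0078)
```

The ssDEG table recovers the planted markers as each subtype's top-ranked
genes with the planted direction; the single-sample call is made from one
sample's raw values alone (it is bit-identical to that sample's call inside
any cohort); and the held-out accuracy over the four major subtypes is
93.75% with chance-corrected agreement κ = 0.92.

The same workflow is available from the shell:

```sh
miniabs simulate --out fx --seed 0
miniabs ssdeg    --expr fx/separable_expression.tsv --labels fx/separable_labels.tsv --out ssdegs.tsv
miniabs train    --expr fx/separable_expression.tsv --labels fx/separable_labels.tsv --out model
miniabs predict  --expr fx/separable_expression.tsv --model model --out calls.tsv
miniabs evaluate --calls calls.tsv --labels fx/separable_labels.tsv --out report.tsv --exclude-normal-like
```

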