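# prognet

Network-based prognostic biomarker discovery: a log-fold-change–gated,
network-smoothed t-statistic feature selector with nested cross-validation,
followed by co-expression module detection, minimum-spanning-tree hub
refinement, and median-split survival stratification. Ships with a fully
seeded synthetic-data generator so the whole pipeline is testable offline.

## Method overview

1. **IO / harmonization** (`prognet.io`) — TSV expression matrices, phenotype
   tables (survival time canonicalized to days), edge-list networks, gene
   lists/GMT. `harmonize` aligns samples and keeps measured genes missing
   from the network as isolated nodes; `dichotomize_survival` labels samples
   −1 (event before the cutoff) / +1 (followed past it), excluding samples
   censored early.
2. **Preprocess** (`prognet.preprocess`) — additive batch removal via
   per-gene least squares with sum-to-zero batch terms and a protected class
   covariate; per-gene standardization (n−1 denominator).
3. **Smoothing** (`prognet.smoothing`) — pooled-variance t and logFC per
   gene; p-step random-walk kernel `K = (a·I − L̃)^p` on the normalized
   Laplacian (`a ≥ 2` guarantees a PSD, entrywise non-negative kernel);
   genes ranked by `K·|t|` and gated by `|logFC|`.
4. **Cross-validation** (`prognet.crossval`) — repeated stratified k-fold CV
   (default 10×5); selection and a linear SVM are fit inside each training
   fold only; rank-based AUC per fold, median over folds, consensus
   signature by selection frequency.
5. **Co-expression** (`prognet.coexpr`) — unsigned soft-threshold scan
   (scale-free fit index), topological overlap matrix, average-linkage
   clustering with a static cut, module eigengenes, eigengene–trait
   correlations.
6. **Hubs** (`prognet.hubs`) — keep the top fraction of edges by weight,
   minimum spanning forest on `d = 1 − w/max(w)`, hubs = highest forest
   degree (or betweenness), intersection with an external regulator list.
7. **Survival** (`prognet.survival`) — Kaplan–Meier product-limit curves,
   median-split grouping (ties low), Gehan–Breslow–Wilcoxon weighted
   log-rank (plain log-rank as a flag), Pearson/Spearman association.
8. **Simulate** (`prognet.simulate`) — preferential-attachment or
   stochastic-block network with a planted *connected* signature subgraph,
   block-correlated expression with a class shift on the signature (plus
   scattered decoy differential genes), optional batch shift, and
   exponential survival whose hazard grows with signature expression;
   everything is a pure function of `SimConfig`.

## CLI

```sh
prognet simulate --n-genes 500 --n-samples 200 --seed 1 --out-dir data/
prognet preprocess --expr data/X.tsv --pheno data/P.tsv --standardize --out data/Xs.tsv
prognet select --expr data/Xs.tsv --pheno data/P.tsv --net data/ppi.tsv \
    --a 2 --p 3 --top-frac 0.1 --min-logfc 0.5 \
    --out signature.txt --scores scores.tsv
prognet crossval --expr data/X.tsv --pheno data/P.tsv --net data/ppi.tsv \
    --repeats 10 --folds 5 --seed 1 --out cv.json
prognet modules --expr data/X.tsv --genes signature.txt --pheno data/P.tsv \
    --out modules.json --assignments assignments.tsv --net-out module_net.tsv
prognet hubs --net module_net.tsv --top-frac 0.3 --n-hubs 30 \
    --intersect regulators.txt --out hubs.json
prognet survive --expr data/X.tsv --pheno data/P.tsv --genes hubs.txt \
    --method gehan --out survival.tsv
```

(`python -m prognet.cli` works equally without the console script.)

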