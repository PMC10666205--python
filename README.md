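# regenne

Pathway-stratified deep learning for binary phenotype prediction from gene
expression, with canonical-correlation fusion and integrated-gradients
interpretation.

## The problem

Complex diseases are driven by coordinated dysregulation of biological
pathways, not by genes in isolation — and pathways overlap: the same gene
participates in several processes, coupling their activity. `regenne` is
for researchers who want to (i) predict a binary phenotype (tumour stage,
cancer type, survival status …) from a samples × genes expression matrix,
(ii) respect pathway structure while doing it, and (iii) get gene- and
pathway-level importance rankings out of the fitted model.

## The model

One small 1-D CNN per pathway, fused through a CCA regularizer:

1. **Gene ordering.** Within each pathway the genes are re-indexed by
   their Spearman-correlation structure: gene *j* receives the aggregate
   coefficient ρ_row_j = (∏_i |ρ_ji|)^{1/g}, and the columns are sorted so
   ρ_row_1 ≥ ρ_row_2 ≥ … — correlated genes become neighbours, which is
   what a 1-D convolution needs.
2. **Stratified CNN branches.** Each ordered block passes through two
   conv(32 filters, kernel 3, stride 1, same padding) + max-pool(÷2)
   stages and is flattened.
3. **CCA-regularized objective.** With branch features X_k, training
   minimizes
   `mean cross-entropy − λ · mean_{k<l} CanCorr_d(X_k, X_l)`,
   where CanCorr_d is the sum of the top-d canonical correlations of the
   ridge-stabilized CCA problem — pairs of pathways that share genes are
   rewarded for keeping their learned features correlated. λ = 0 is the
   plain stratified-CNN ablation.
4. **Prediction & interpretation.** A softmax head gives P(class 1);
   integrated gradients (zero baseline, midpoint Riemann sum) attribute
   predictions back to gene positions, aggregated into pathway and gene
   rankings.

The evaluation protocol ships with the package: stratified 70/30 split,
10×10-fold cross-validation (100 fold AUCs, percentile 95% CI),
500-resample stratified bootstrap CIs on the test set, per-pathway
screening (top-100 by single-branch AUC), and a permutation null
calibration. Everything is implemented in NumPy/SciPy with hand-written
backpropagation and is fully deterministic given a seed.

## Worked example

```python
import regenne as rg
from regenne.training import classifier_from_config
from regenne.evaluation import stratified_split, auc, bootstrap_ci
from regenne.attribution import attribution_report

# synthetic cohort: 20 pathways x 15 genes, n=500, 3 causal pathways,
# adjacent pathways share 5 genes
bundle = rg.simulate_bundle(rg.preset_config("medium", seed=0))
X = bundle.expression.to_dataframe()          # 500 x 215 DataFrame
y = bundle.phenotype.to_array(bundle.expression.sample_ids)

tr, te = stratified_split(y, train_frac=0.7, seed=0)
clf = rg.PathwayCNNClassifier(
    pathways=bundle.pathways, lambda_cca=0.1, epochs=100, random_state=0,
)
clf.fit(X.iloc[tr], y[tr])

scores = clf.predict_proba(X.iloc[te])[:, 1]
print("held-out AUC:", round(auc(scores, y[te]), 3))
mean, lo, hi, _ = bootstrap_ci(scores, y[te], B=500, seed=0)
print(f"bootstrap 95% CI: [{lo:.3f}, {hi:.3f}]")

report = attribution_report(clf, X.iloc[te], steps=50)
print(report.pathway_scores.head(5).to_string(index=False))
print("true causal pathways:", bundle.causal_names)
```

Output:

```
held-out AUC: 0.941
bootstrap 95% CI: [0.899, 0.973]
feature_id   level    score  rank
     PW000 pathway 0.328936     1
     PW007 pathway 0.302018     2
     PW014 pathway 0.277510     3
     PW013 pathway 0.137169     4
     PW001 pathway 0.108820     5
true causal pathways: ['PW000', 'PW007', 'PW014']
```

The held-out AUC of 0.941 matches the oracle predictor (the noiseless
linear predictor the labels were drawn from scores 0.925 on the full
cohort), and the three causal pathways occupy the top three attribution
ranks, well separated from the first non-causal one.

`PathwayCNNClassifier` follows the scikit-learn estimator protocol
(`get_params`/`set_params`, `fit`/`predict`/`predict_proba`, clonable), so
it composes with `sklearn.model_selection` utilities directly.

### Command line

```bash
regenne simulate --preset small --seed 7 --out-dir data/
regenne screen   --expr data/expression.tsv --gmt data/pathways.gmt \
                 --pheno data/phenotype.tsv --top-k 100 --out ranked.tsv
regenne train    --expr data/expression.tsv --gmt data/pathways.gmt \
                 --pheno data/phenotype.tsv --out model.npz
regenne predict  --model model.npz --expr data/expression.tsv --out probs.tsv
regenne attribute --model model.npz --expr data/expression.tsv \
                 --top-pathways 20 --top-genes 10 --out report.tsv
regenne evaluate --expr data/expression.tsv --gmt data/pathways.gmt \
                 --pheno data/phenotype.tsv --mode cv --out cv.tsv
```

Expression input is samples × genes TSV/CSV with a header of gene symbols
(`--transpose` accepts the genes × samples dialect); pathways are standard
GMT; phenotypes a two-column `sample_id  label` table. Every run writes a
JSON manifest (config, seeds, input digests, timings) beside its output.

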