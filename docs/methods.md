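# Methods

## The model

`regenne` predicts a binary phenotype from a samples × genes expression
matrix by stratifying the genes into biological pathways and giving each
pathway its own small 1-D convolutional feature extractor, then fusing the
branches through a canonical-correlation (CCA) reward in the training
objective.

### Gene ordering inside a pathway

A 1-D convolution assumes neighbouring input positions are related, which
raw gene order does not provide. For each pathway with *g* matched genes we
compute the g × g Spearman rank-correlation matrix on the training samples,
collapse each row to a single aggregate coefficient — the geometric mean of
that gene's absolute correlations with every pathway member (self included)
— and re-index the genes in non-increasing aggregate order. Genes that
co-vary strongly with the rest of the pathway end up adjacent at the front
of the block.

Numerical details: absolute correlations are floored at 1e-12 before the
log-domain product so that a single exactly-zero correlation cannot
annihilate the rest of a row; a zero-variance gene (rank correlation
undefined) is assigned correlation 0 against every other gene and kept in
place, so block shapes stay aligned with the pathway definition; ties in
the aggregate score keep the original column order (stable sort). The
geometric mean, the plain product and the product divided by *g* are
strictly increasing transforms of one another and therefore induce the
identical ordering; the geometric mean is used because it stays in a sane
numeric range for large *g*. An arithmetic-mean aggregate, which can order
differently, is available as `aggregate="arithmetic"`.

### Branch architecture

Each pathway block (samples × ordered genes) feeds a CNN branch of two
convolution + pooling stages: 1-D convolution (32 filters, kernel 3,
stride 1, zero "same" padding so convolution preserves length), ReLU, then
max-pooling with factor 2, twice. Each pooling floors a halving of the
spatial length, so a block of width *g* flattens to `32 * (g // 2 // 2)`
features. Blocks need width ≥ 4 to survive both poolings; pathways
matching fewer genes (but at least `min_genes`, default 5, configurable)
are right-padded with zero columns rather than dropped. Pool ties route
the gradient to the left position.

The branch features of all pathways are concatenated into one fully
connected layer with a two-unit softmax head; training minimizes the mean
binary cross-entropy with predicted probabilities clipped to
[1e-12, 1 − 1e-12].

### The CCA regularizer

Pathways that share genes carry correlated signal, and the fusion step
rewards branch pairs for preserving that association. For feature blocks
X₁ (n × p) and X₂ (n × q) the layer computes the sum of the top-*d*
canonical correlations of the ridge-stabilized problem: covariances
Σ₁₁ + εI, Σ₂₂ + εI and cross-covariance Σ₁₂ on centred data, the whitened
cross-operator T = Σ₁₁^{−1/2} Σ₁₂ Σ₂₂^{−1/2}, and the sum of the top-*d*
singular values of T. The optimal projection weights are recovered in
closed form at every evaluation (the whitening is recomputed, never
carried as free parameters), so the penalty always sits at the optimum of
the projection weights and is bounded above by *d*. Its analytic gradient
with respect to both feature blocks follows the chain rule through the
top-*d* singular triplets and is verified against finite differences in
the tests.

The training objective is

    mean cross-entropy  −  λ · mean over pathway pairs of CanCorr_d ,

with the mean (not sum) over the k(k−1)/2 pairs so λ keeps the same
meaning regardless of how many pathways survive screening. λ = 0 is
exactly the unregularized stratified CNN: the CCA code path is never
entered, and a hand-rolled CCA-free SGD loop reproduces the λ = 0
trajectory bit-for-bit (asserted in the tests).

**When the CCA term is evaluated.** Minibatches of 5 samples cannot carry
a usable covariance of 32–96-dimensional feature blocks, so the CCA term
is not computed per minibatch. Instead, each epoch runs the minibatch SGD
pass on the cross-entropy, then takes one full-training-set gradient
ascent step on λ × the pairwise penalty (branches only; the head does not
enter the penalty). This alternating scheme keeps the covariances well
conditioned, keeps the per-epoch cost linear in the number of pathway
pairs, and makes the logged penalty an exact full-sample quantity. It is a
deliberate design choice among several defensible readings of where in
the loop the CCA belongs.

Defaults: d = 8 (capped at the smallest branch feature dimension),
ε = 1e-3, λ = 0.1. None of the three has a canonical published value; d
and ε are stability-driven, and λ = 0.1 keeps the penalty gradient an
order of magnitude below the cross-entropy gradient so the classifier
remains the main task. The λ = 0 ablation is a first-class configuration.

### Optimization

Plain stochastic gradient descent, no momentum, learning rate 0.001,
batch size 5, 400 epochs by default, batch order reshuffled each epoch.
Weights are Glorot-uniform, seeded from `random_state`; biases start at
zero. Runs are deterministic given the seed. Non-finite losses abort with
the failing epoch. Two-unit softmax logits make the head a literal softmax
classifier (mathematically equivalent to a single sigmoid unit).

## Screening

With many pathways, fusion is preceded by per-pathway screening: each
pathway gets a single-branch CNN (no CCA term — it needs two branches),
trained on a stratified 80% of the provided samples and scored by AUC on
the remaining 20%; pathways are ranked by that AUC (ties broken by name)
and the top K (default 100) are kept. Any final test split must be held
out before screening. For cross-validation, the screen-then-fuse
composite estimator (`ScreenedPathwayCNNClassifier`, CLI
`evaluate --screen-top-k K`) performs screening inside `fit`, so wrapping
it in a CV loop screens inside each fold and the fold's holdout never
leaks into pathway selection.

## Evaluation protocol

* **AUC** via the Mann–Whitney rank statistic, tied scores half-credited.
* **Stratified 70/30 split** for train/test; class proportions in each
  part within one sample of the global proportions.
* **Repeated stratified k-fold CV**: fresh stratified fold assignment per
  repeat; 10 repeats × 10 folds yield 100 fold AUCs; the 95% CI is the
  2.5/97.5 percentile interval over them (percentile chosen over a normal
  approximation for robustness near the [0, 1] boundary). Folds are
  stratified because unstratified 10-fold on imbalanced cohorts can
  produce single-class holdouts.
* **Bootstrap CI on the test set**: 500 stratified resamples with
  replacement (resampling within each class guarantees both classes in
  every resample), percentile bounds.
* **Null calibration**: labels permuted (class counts preserved), a fresh
  split/train/test cycle per permutation, reporting the null AUC
  distribution and the fraction of permutations whose AUC exceeds the
  one-sided normal-approximation threshold of the Mann–Whitney statistic
  at α = 0.05 — the pipeline's empirical type-I error.

## Attribution

Integrated gradients against an all-zero baseline: the straight-line path
integral of ∂P(class 1)/∂input, approximated with a midpoint Riemann sum
(default 50 steps; completeness error < 1% of F(x) − F(0) at 200 steps on
trained models, asserted in the tests). Per-sample signed attributions
can be retained; rankings aggregate magnitudes: a gene's score is the mean
over samples of its absolute attribution summed over its occurrences
across pathway blocks (a `max` pooling variant exists), a pathway's score
is the mean over samples of the summed absolute attribution of its block.
Padded columns carry no gene and are excluded at gene level. Aggregating
magnitudes over all scored samples (rather than signed values, which can
cancel between classes) is a choice; signed per-sample values remain
available for inspection.

## Synthetic data

The generator produces the three structural features the model exploits:

* **Within-pathway correlation** — one standard-normal latent factor per
  pathway; gene = √w · factor + √(1−w) · noise, so two genes of one
  pathway correlate ≈ w (`within_corr`, default 0.5 — mid-range co-expression).
* **Shared genes** — consecutive pathways share
  ⌈overlap_frac · genes_per_pathway⌉ genes (chain topology for an
  interpretable truth; `random_overlap` for stress tests). A shared gene
  loads on all owning factors, normalized to keep unit marginal variance —
  exactly the between-pathway correlation the CCA layer rewards.
* **Pathway-driven outcome** — linear predictor = effect_size × sum of
  causal-pathway mean expression, plus Gaussian noise (`noise_sd`), labels
  drawn from the logistic probability. `true_linear_predictor` exposes the
  noiseless oracle.

Presets: `small` (8 pathways × 10 genes, n = 200, adjacent pathways share
5 genes, 1 causal pathway) and `medium` (20 pathways × 15 genes, n = 500,
5 shared genes per adjacent pair, 3 non-adjacent causal pathways,
effect 3.0). Effect size 3 with noise 1 puts the oracle predictor's AUC
above 0.9 — strong but not trivial signal.

What the generator does **not** emulate: real count mechanics (RSEM,
library size), heavy-tailed or zero-inflated marginals, nonlinear
gene–gene dependence, confounding covariates, and realistic pathway-size
dispersion. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated factor model, not expected
performance on cohort data.

## Problem sizes used in the shipped checks

The automated checks run the full pipeline at reduced scale, chosen as
the smallest sizes at which each property is meaningful: held-out
recovery and the λ-ablation comparison on the `medium` preset at 100
epochs over 5 seeds; repeated 10×10 CV at 25 epochs on the `small`
preset; null calibration with 20 permutations at 15 epochs, n = 300.
Default training (400 epochs) is unchanged for real use.

## Known limitations

* Binary outcomes only; one fully connected head (no deeper fusion).
* Exactly two conv+pool stages; pathways narrower than 4 matched genes
  are zero-padded rather than modelled at native width.
* The CCA step's full-training-set evaluation makes its cost quadratic in
  the number of retained pathways (hence the top-100 screening step).
* Gene identifiers are matched by upper-cased symbol equality; no
  probe-to-symbol translation is performed.
* The per-epoch alternating CE/CCA optimization is not a joint gradient
  of a single objective evaluated at one parameter point per step; the
  logged `total` recombines the two components for bookkeeping.
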