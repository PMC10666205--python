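"""scikit-learn-style estimator for the pathway-stratified CNN ensemble.

``PathwayCNNClassifier`` is a binary classifier over a samples x genes
matrix. At fit time each pathway's genes are matched against the input
columns, ordered by their mutual Spearman correlation, and handed to a
dedicated 1-D CNN branch; the concatenated branch features feed a two-unit
softmax head. The training objective is

    mean cross-entropy  -  lambda * mean over pathway pairs of CanCorr_d,

where CanCorr_d is the (ridge-stabilized) sum of the top-d canonical
correlations between two branches' feature blocks: pairs of pathways that
share genes are rewarded for keeping their learned features correlated.
Optimization is plain SGD (no momentum); the cross-entropy part is
minimized in minibatches, and the CCA term takes one full-training-set
ascent step per epoch, where its covariances are well conditioned.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from . import _nn
from .cca import mean_pairwise_penalty
from .containers import ExpressionMatrix, PathwayCollection, ValidationError
from .pathway_prep import PathwayTensorSet, blocks_for_new_data, build_pathway_tensors


class TrainingDivergedError(RuntimeError):
    pass


def _as_collection(pathways) -> PathwayCollection:
    if isinstance(pathways, PathwayCollection):
        return pathways
    if isinstance(pathways, dict):
        return PathwayCollection.from_mapping(pathways)
    raise TypeError("pathways must be a PathwayCollection or a name -> genes mapping")


class PathwayCNNClassifier(ClassifierMixin, BaseEstimator):
    """Pathway-stratified 1-D CNN ensemble with CCA-regularized training.

    Parameters
    ----------
    pathways : PathwayCollection or mapping name -> gene list
        Gene sets defining the branches. Pathways may overlap.
    gene_names : sequence of str, optional
        Column names of X when X is a bare array; ignored (taken from the
        columns) when X is a DataFrame.
    min_genes : int, default 5
        Pathways matching fewer expression columns are dropped.
    n_filters, kernel_size : CNN branch architecture (two conv+pool stages,
        stride 1, "same" padding, max-pool halving the length).
    cca_dim : int, default 8
        Number of canonical correlations summed per pathway pair; capped at
        the smallest branch feature dimension at fit time.
    cca_ridge : float, default 1e-3
        Ridge added to both covariance blocks inside the CCA term.
    lambda_cca : float, default 0.1
        Trade-off weight of the CCA reward; 0 disables the term entirely
        (the unregularized stratified-CNN ablation).
    learning_rate, epochs, batch_size : SGD schedule (defaults 0.001 / 400 / 5).
    aggregate : {"geometric", "arithmetic"}, default "geometric"
        Row-aggregation of the Spearman matrix used to order genes.
    random_state : int or None
        Seeds weight initialization and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray of the two class labels (sorted).
    pathways_ : list of OrderedPathway actually retained.
    dropped_pathways_ : list of (name, reason).
    net_ : the underlying NumPy network.
    cca_dim_ : effective projection dimension.
    cca_weights_ : dict (name_i, name_j) -> (W1, W2) final CCA projections.
    training_log_ : list of per-epoch dicts with keys
        ``cross_entropy``, ``cca_penalty``, ``total``.
    """

    def __init__(
        self,
        pathways=None,
        gene_names=None,
        min_genes: int = 5,
        n_filters: int = 32,
        kernel_size: int = 3,
        cca_dim: int = 8,
        cca_ridge: float = 1e-3,
        lambda_cca: float = 0.1,
        learning_rate: float = 0.001,
        epochs: int = 400,
        batch_size: int = 5,
        aggregate: str = "geometric",
        random_state=None,
    ):
        self.pathways = pathways
        self.gene_names = gene_names
        self.min_genes = min_genes
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.cca_dim = cca_dim
        self.cca_ridge = cca_ridge
        self.lambda_cca = lambda_cca
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.aggregate = aggregate
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _resolve_matrix(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=np.float64), [str(c).upper() for c in X.columns]
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x genes)")
        if self.gene_names is None:
            raise ValueError(
                "gene_names must be given when X is a bare array (or pass a DataFrame)"
            )
        if len(self.gene_names) != X.shape[1]:
            raise ValueError("gene_names length does not match X columns")
        return X, [str(g).upper() for g in self.gene_names]

    def fit(self, X, y):
        if self.pathways is None:
            raise ValueError("pathways must be provided")
        if self.lambda_cca < 0:
            raise ValueError("lambda_cca must be non-negative")
        values, genes = self._resolve_matrix(X)
        y = np.asarray(y)
        if values.shape[0] != len(y):
            raise ValueError("X and y disagree on the number of samples")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"binary classification only; got classes {self.classes_!r}"
            )
        y01 = (y == self.classes_[1]).astype(np.int64)
        self.n_features_in_ = values.shape[1]
        self._fit_genes = genes

        expr = ExpressionMatrix(
            sample_ids=[f"s{i}" for i in range(values.shape[0])],
            gene_ids=genes,
            values=values,
        )
        coll = _as_collection(self.pathways)
        tset = build_pathway_tensors(
            expr, coll, min_genes=self.min_genes, aggregate=self.aggregate
        )
        self.pathways_ = tset.pathways
        self.dropped_pathways_ = tset.dropped_pathways

        rng = np.random.default_rng(self.random_state)
        init_rng = np.random.default_rng(rng.integers(2**31))
        shuffle_rng = np.random.default_rng(rng.integers(2**31))
        self.net_ = _nn.EnsembleNet(
            [pw.width for pw in self.pathways_],
            self.n_filters,
            self.kernel_size,
            init_rng,
        )
        self.cca_dim_ = int(min(self.cca_dim, min(self.net_.feature_dims)))
        if self.lambda_cca > 0 and len(self.pathways_) < 2:
            warnings.warn(
                "lambda_cca > 0 with a single pathway branch: the CCA term is 0",
                RuntimeWarning,
            )
        self.training_log_ = self._train_loop(tset.blocks, y01, shuffle_rng)

        # final CCA projections for inspection / serialization
        if len(self.pathways_) >= 2 and self.lambda_cca > 0:
            feats = self.net_.branch_features(tset.blocks)
            _, _, pair_w = mean_pairwise_penalty(
                feats, self.cca_dim_, self.cca_ridge, with_grads=False
            )
            names = [pw.name for pw in self.pathways_]
            self.cca_weights_ = {
                (names[i], names[j]): w for (i, j), w in pair_w.items()
            }
        else:
            self.cca_weights_ = {}
        return self

    def _train_loop(self, blocks, y01, shuffle_rng) -> list[dict]:
        M = len(y01)
        if M < 2:
            raise ValidationError("need at least 2 training samples")
        use_cca = self.lambda_cca > 0 and len(blocks) >= 2
        prepared = self.net_.prepare_blocks(blocks)
        log: list[dict] = []
        for epoch in range(self.epochs):
            perm = shuffle_rng.permutation(M)
            ce_sum = 0.0
            for start in range(0, M, self.batch_size):
                idx = perm[start : start + self.batch_size]
                logits = self.net_.forward_prepared(prepared, idx)
                ce, dlogits = _nn.softmax_ce_grad(logits, y01[idx])
                if not np.isfinite(ce):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}"
                    )
                self.net_.backward(dlogits)
                self.net_.sgd_step(self.learning_rate)
                ce_sum += ce * len(idx)
            cca_val = 0.0
            if use_cca:
                feats = self.net_.features_from_prepared(prepared)
                cca_val, grads, _ = mean_pairwise_penalty(
                    feats, self.cca_dim_, self.cca_ridge, with_grads=True
                )
                if not np.isfinite(cca_val):
                    raise TrainingDivergedError(
                        f"non-finite CCA penalty at epoch {epoch}"
                    )
                # total loss carries -lambda * CanCorr: ascend the penalty
                self.net_.backward_branches(
                    [-self.lambda_cca * g for g in grads]
                )
                self.net_.sgd_step(self.learning_rate, include_head=False)
            epoch_ce = ce_sum / M
            log.append(
                {
                    "epoch": epoch,
                    "cross_entropy": epoch_ce,
                    "cca_penalty": cca_val,
                    "total": epoch_ce - self.lambda_cca * cca_val,
                }
            )
        return log

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise NotFittedError("this PathwayCNNClassifier is not fitted yet")

    def _blocks_for(self, X) -> list[np.ndarray]:
        self._check_fitted()
        if isinstance(X, pd.DataFrame):
            upper = X.rename(columns=lambda c: str(c).upper())
            missing = set(self._fit_genes) - set(upper.columns)
            if missing:
                raise ValueError(
                    f"X lacks {len(missing)} genes seen at fit time, "
                    f"e.g. {sorted(missing)[:3]}"
                )
            values = upper.reindex(columns=self._fit_genes).to_numpy(dtype=np.float64)
        else:
            values = np.asarray(X, dtype=np.float64)
            if values.ndim != 2 or values.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"X must have {self.n_features_in_} columns in fit-time order"
                )
        return blocks_for_new_data(self.pathways_, values)

    def predict_proba(self, X) -> np.ndarray:
        blocks = self._blocks_for(X)
        p1 = self.net_.predict_proba1(blocks)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def transform(self, X) -> np.ndarray:
        """Concatenated branch features (samples x sum of branch dims)."""
        return np.hstack(self.branch_feature_blocks(X))

    def branch_feature_blocks(self, X) -> list[np.ndarray]:
        """Per-pathway flattened CNN features, one matrix per branch."""
        return self.net_.branch_features(self._blocks_for(X))

    def loss_components(self, X, y) -> dict[str, float]:
        """Cross-entropy, CCA penalty and total objective on (X, y) at the
        current weights; total = cross_entropy - lambda * cca_penalty."""
        blocks = self._blocks_for(X)
        y = np.asarray(y)
        y01 = (y == self.classes_[1]).astype(np.int64)
        logits = self.net_.forward(blocks)
        ce = _nn.cross_entropy(y01, _nn.softmax(logits)[:, 1])
        cca_val = 0.0
        if self.lambda_cca > 0:
            if len(blocks) >= 2:
                feats = self.net_.branch_features(blocks)
                cca_val, _, _ = mean_pairwise_penalty(
                    feats, self.cca_dim_, self.cca_ridge
                )
            else:
                warnings.warn(
                    "single pathway branch: CCA term is 0", RuntimeWarning
                )
        return {
            "cross_entropy": ce,
            "cca_penalty": cca_val,
            "total": ce - self.lambda_cca * cca_val,
        }
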