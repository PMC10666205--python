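"""Training, per-pathway screening and prediction as module-level
functions over :class:`~regenne.estimator.PathwayCNNClassifier`.

Screening follows the protocol of training one single-branch CNN per
pathway, ranking pathways by individual validation AUC and keeping the top
K (default 100) for the CCA-fused ensemble. The screening AUC is computed
on an internal stratified 80/20 split of the training portion, so any
final test split is never touched here.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn
from .config import ModelConfig
from .containers import ExpressionMatrix, PathwayCollection, PhenotypeTable, ValidationError
from .estimator import PathwayCNNClassifier, _as_collection
from .evaluation import auc, stratified_split
from .io import align
from .pathway_prep import OrderedPathway


def classifier_from_config(
    pathways, config: ModelConfig, random_state: int | None = None
) -> PathwayCNNClassifier:
    return PathwayCNNClassifier(
        pathways=pathways,
        min_genes=config.min_genes,
        n_filters=config.n_filters,
        kernel_size=config.kernel_size,
        cca_dim=config.cca_dim,
        cca_ridge=config.cca_ridge,
        lambda_cca=config.lambda_cca,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        aggregate=config.aggregate,
        random_state=config.seed if random_state is None else random_state,
    )


def train(
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    pathways: PathwayCollection,
    config: ModelConfig | None = None,
) -> PathwayCNNClassifier:
    """Align, fit and return the ensemble classifier."""
    config = config or ModelConfig()
    expr, pheno = align(expr, pheno)
    pheno.require_both_classes()
    clf = classifier_from_config(pathways, config)
    clf.fit(expr.to_dataframe(), pheno.to_array(expr.sample_ids))
    return clf


def predict(clf: PathwayCNNClassifier, expr: ExpressionMatrix) -> pd.Series:
    """Per-sample probability of class 1, indexed by sample id."""
    p = clf.predict_proba(expr.to_dataframe())[:, 1]
    return pd.Series(p, index=expr.sample_ids, name="prob_class1")


@dataclass
class ScreeningResult:
    ranked: list[tuple[str, float]]  # (pathway, auc), auc non-increasing
    selected: list[str]              # top-K names

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ranked, columns=["pathway", "auc"])
        df["selected"] = df["pathway"].isin(set(self.selected))
        return df


def screen_pathways(
    X,
    y,
    pathways,
    config: ModelConfig | None = None,
    top_k: int = 100,
    val_frac: float = 0.2,
    random_state: int | None = None,
) -> ScreeningResult:
    """Rank pathways by single-branch validation AUC and select the top K.

    Each pathway gets its own unregularized single-branch CNN (the CCA term
    needs at least two branches, so lambda is irrelevant here), trained on
    80% of the provided samples and scored on the held-out 20%. Ties are
    broken by pathway name.
    """
    config = config or ModelConfig()
    coll = _as_collection(pathways)
    if isinstance(X, pd.DataFrame):
        Xdf = X
    else:
        raise TypeError("screen_pathways expects a DataFrame with gene columns")
    y = np.asarray(y)
    seed = config.seed if random_state is None else random_state
    tr_idx, val_idx = stratified_split(y, train_frac=1.0 - val_frac, seed=seed)
    results: list[tuple[str, float]] = []
    for name in coll.names:
        single = PathwayCollection.from_mapping({name: list(coll.genes(name))})
        clf = classifier_from_config(single, config, random_state=seed)
        clf.set_params(lambda_cca=0.0)
        try:
            clf.fit(Xdf.iloc[tr_idx], y[tr_idx])
        except ValidationError:
            continue  # pathway matched too few genes
        scores = clf.predict_proba(Xdf.iloc[val_idx])[:, 1]
        results.append((name, auc(scores, (y[val_idx] == clf.classes_[1]).astype(int))))
    if not results:
        raise ValidationError("no pathway could be screened")
    results.sort(key=lambda t: (-t[1], t[0]))
    selected = [name for name, _ in results[: min(top_k, len(results))]]
    return ScreeningResult(ranked=results, selected=selected)


class ScreenedPathwayCNNClassifier(ClassifierMixin, BaseEstimator):
    """Screen-then-fuse composite: rank pathways by single-branch AUC on an
    internal split of the training data, keep the top K, then fit the
    CCA-fused ensemble on the selected pathways only.

    Because screening happens inside ``fit``, wrapping this estimator in a
    cross-validation loop screens inside each fold — the fold's holdout
    never leaks into pathway selection.
    """

    def __init__(self, pathways=None, top_k: int = 100, val_frac: float = 0.2,
                 config: ModelConfig | None = None, random_state=None):
        self.pathways = pathways
        self.top_k = top_k
        self.val_frac = val_frac
        self.config = config
        self.random_state = random_state

    def fit(self, X, y):
        cfg = self.config or ModelConfig()
        seed = cfg.seed if self.random_state is None else self.random_state
        coll = _as_collection(self.pathways)
        self.screening_ = screen_pathways(
            X, y, coll, config=cfg, top_k=self.top_k,
            val_frac=self.val_frac, random_state=seed,
        )
        selected = PathwayCollection.from_mapping(
            {name: list(coll.genes(name)) for name in self.screening_.selected}
        )
        self.estimator_ = classifier_from_config(selected, cfg, random_state=seed)
        self.estimator_.fit(X, y)
        self.classes_ = self.estimator_.classes_
        return self

    def predict_proba(self, X):
        return self.estimator_.predict_proba(X)

    def predict(self, X):
        return self.estimator_.predict(X)


# ----------------------------------------------------------------------
# serialization: one .npz archive with a JSON manifest plus the weights
# ----------------------------------------------------------------------

_MANIFEST_VERSION = 1


def save_model(clf: PathwayCNNClassifier, path: str | os.PathLike) -> None:
    clf._check_fitted()
    manifest = {
        "format_version": _MANIFEST_VERSION,
        "params": {
            k: v
            for k, v in clf.get_params().items()
            if k not in ("pathways", "gene_names")
        },
        "classes": [json.loads(json.dumps(c, default=str)) for c in clf.classes_.tolist()],
        "fit_genes": clf._fit_genes,
        "cca_dim_eff": clf.cca_dim_,
        "pathways": [
            {
                "name": pw.name,
                "genes": pw.genes,
                "gene_order": pw.gene_order.tolist(),
                "row_scores": pw.row_scores.tolist(),
                "column_indices": pw.column_indices.tolist(),
                "n_padded": pw.n_padded,
            }
            for pw in clf.pathways_
        ],
        "dropped_pathways": clf.dropped_pathways_,
    }
    weights = clf.net_.get_weights()
    arrays = {f"w{i}": w for i, w in enumerate(weights)}
    np.savez(path, manifest=json.dumps(manifest), **arrays)


def load_model(path: str | os.PathLike) -> PathwayCNNClassifier:
    with np.load(path, allow_pickle=False) as npz:
        manifest = json.loads(str(npz["manifest"]))
        if manifest["format_version"] != _MANIFEST_VERSION:
            raise ValueError(
                f"unsupported model format {manifest['format_version']}"
            )
        weights = [npz[f"w{i}"] for i in range(len(npz.files) - 1)]
    clf = PathwayCNNClassifier(**manifest["params"])
    clf.classes_ = np.array(manifest["classes"])
    clf._fit_genes = list(manifest["fit_genes"])
    clf.n_features_in_ = len(clf._fit_genes)
    clf.pathways_ = [
        OrderedPathway(
            name=p["name"],
            genes=list(p["genes"]),
            gene_order=np.array(p["gene_order"], dtype=np.int64),
            row_scores=np.array(p["row_scores"], dtype=np.float64),
            column_indices=np.array(p["column_indices"], dtype=np.int64),
            n_padded=int(p["n_padded"]),
        )
        for p in manifest["pathways"]
    ]
    clf.dropped_pathways_ = [tuple(t) for t in manifest["dropped_pathways"]]
    clf.net_ = _nn.EnsembleNet(
        [pw.width for pw in clf.pathways_],
        manifest["params"]["n_filters"],
        manifest["params"]["kernel_size"],
        np.random.default_rng(0),
    )
    clf.net_.set_weights(weights)
    clf.cca_dim_ = int(manifest["cca_dim_eff"])
    clf.cca_weights_ = {}
    clf.training_log_ = []
    return clf
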