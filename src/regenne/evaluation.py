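"""Evaluation protocol: AUC, stratified 70/30 split, repeated stratified
k-fold cross-validation (10 x 10 by default, yielding 100 fold AUCs),
stratified bootstrap confidence intervals (500 resamples) and a
permutation null calibration of the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .containers import ValidationError


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic; tied
    scores receive half credit. ``labels`` must contain both classes."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC undefined: only one class present")
    if n1 + n0 != len(labels):
        raise ValueError("labels must be binary 0/1")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def stratified_split(
    labels, train_frac: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive stratified index split; class proportions in
    each part are within one sample of the global proportions."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("stratified_split needs exactly two classes")
    if counts.min() < 2:
        raise ValidationError("each class needs at least 2 samples to split")
    idx = np.arange(len(labels))
    tr, te = train_test_split(
        idx, train_size=train_frac, stratify=labels, random_state=seed
    )
    return np.sort(tr), np.sort(te)


@dataclass
class CVResult:
    auc_values: np.ndarray
    mean_auc: float
    ci_low: float
    ci_high: float
    repeats: int
    folds: int


def repeated_kfold(
    X,
    y,
    estimator_factory: Callable[[int], object],
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold CV of a fit/predict_proba estimator.

    Per repeat a fresh stratified fold assignment is drawn; per fold the
    estimator (built by ``estimator_factory(fold_seed)``) trains on the
    k-1 folds and is scored by AUC on the holdout. With 10 repeats of 10
    folds this yields 100 AUC values; the 95% CI is the 2.5/97.5 percentile
    interval over them.
    """
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValidationError(
            f"stratified {folds}-fold CV needs >= {folds} samples per class"
        )
    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    for _ in range(repeats):
        fold_seed = int(rng.integers(2**31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        for tr, te in skf.split(np.zeros(len(y)), y):
            est = estimator_factory(int(rng.integers(2**31)))
            Xtr = X.iloc[tr] if hasattr(X, "iloc") else X[tr]
            Xte = X.iloc[te] if hasattr(X, "iloc") else X[te]
            est.fit(Xtr, y[tr])
            scores = est.predict_proba(Xte)[:, 1]
            aucs.append(auc(scores, (y[te] == est.classes_[1]).astype(int)))
    values = np.array(aucs)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return CVResult(
        auc_values=values,
        mean_auc=float(values.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        repeats=repeats,
        folds=folds,
    )


def bootstrap_ci(
    scores, labels, B: int = 500, seed: int = 0
) -> tuple[float, float, float, np.ndarray]:
    """Stratified bootstrap of the test AUC: B resamples drawn with
    replacement within each class (so every resample keeps both classes),
    percentile 2.5/97.5 bounds. Returns (mean, low, high, resample AUCs)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("bootstrap needs both classes")
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        rp = rng.choice(pos, size=len(pos), replace=True)
        rn = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([rp, rn])
        vals[b] = auc(scores[idx], labels[idx])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(vals.mean()), float(lo), float(hi), vals


@dataclass
class NullCalibration:
    null_aucs: list[float] = field(default_factory=list)
    null_mean_auc: float = float("nan")
    type_i_error: float = float("nan")
    n_permutations: int = 0
    alpha: float = 0.05


def null_calibration(
    X,
    y,
    estimator_factory: Callable[[int], object],
    n_permutations: int = 20,
    seed: int = 0,
    train_frac: float = 0.7,
    alpha: float = 0.05,
) -> NullCalibration:
    """Type-I-error check of the full pipeline under permuted labels.

    Each permutation shuffles the labels (class counts preserved), does a
    fresh stratified train/test split, trains from scratch and records the
    test AUC. A permutation counts as a (false) rejection when its AUC
    exceeds the one-sided normal-approximation threshold of the
    Mann-Whitney statistic around 0.5 at level ``alpha``.
    """
    if n_permutations == 0:
        return NullCalibration(alpha=alpha)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    null_aucs: list[float] = []
    rejections = 0
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        tr, te = stratified_split(yp, train_frac=train_frac, seed=int(rng.integers(2**31)))
        est = estimator_factory(int(rng.integers(2**31)))
        Xtr = X.iloc[tr] if hasattr(X, "iloc") else X[tr]
        Xte = X.iloc[te] if hasattr(X, "iloc") else X[te]
        est.fit(Xtr, yp[tr])
        scores = est.predict_proba(Xte)[:, 1]
        yte = (yp[te] == est.classes_[1]).astype(int)
        a = auc(scores, yte)
        null_aucs.append(a)
        n1, n0 = int(yte.sum()), int(len(yte) - yte.sum())
        se0 = np.sqrt((n0 + n1 + 1) / (12.0 * n0 * n1))
        if (a - 0.5) / se0 > stats.norm.ppf(1 - alpha):
            rejections += 1
    return NullCalibration(
        null_aucs=null_aucs,
        null_mean_auc=float(np.mean(null_aucs)),
        type_i_error=rejections / n_permutations,
        n_permutations=n_permutations,
        alpha=alpha,
    )
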