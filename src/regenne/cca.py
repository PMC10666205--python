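"""Canonical correlation analysis: a classical solver and a differentiable
penalty for use inside the training loss.

``classical_cca`` solves the textbook generalized eigenproblem
Sigma_12 Sigma_22^-1 Sigma_21 a = rho^2 Sigma_11 a on centered data, with an
optional ridge on both covariance blocks. ``soft_cca_penalty`` computes the
same quantity — the sum of the top-d canonical correlations — by whitening
the cross-covariance (T = Sigma_11^{-1/2} Sigma_12 Sigma_22^{-1/2}) and
summing the top-d singular values, together with the analytic gradient of
that sum with respect to both feature matrices. The two routes are kept
independent so each can check the other.

During ensemble training the penalty is *maximized* (subtracted from the
loss, weighted by lambda): it rewards pathway pairs whose learned feature
blocks stay linearly associated, which is where shared genes between
pathways show up.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg


class CCAError(np.linalg.LinAlgError):
    pass


def _cov_blocks(X: np.ndarray, Y: np.ndarray, ridge: float):
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with a shared sample axis")
    n = X.shape[0]
    if n < 2:
        raise ValueError("covariance undefined for fewer than 2 samples")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    denom = n - 1
    S11 = Xc.T @ Xc / denom + ridge * np.eye(X.shape[1])
    S22 = Yc.T @ Yc / denom + ridge * np.eye(Y.shape[1])
    S12 = Xc.T @ Yc / denom
    return Xc, Yc, S11, S22, S12, denom


def classical_cca(
    X: np.ndarray, Y: np.ndarray, d: int, ridge: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-d canonical correlations and projection pairs of (X, Y).

    Returns ``(correlations, A, B)`` with correlations non-increasing in
    [0, 1] and projections as columns of A (p x d) and B (q x d). Solves the
    generalized symmetric eigenproblem on ridge-stabilized covariances.
    """
    _, _, S11, S22, S12, _ = _cov_blocks(X, Y, ridge)
    p, q = S11.shape[0], S22.shape[0]
    if not 1 <= d <= min(p, q):
        raise ValueError(f"d={d} must be in [1, min(p, q)={min(p, q)}]")
    try:
        S22_inv_S21 = linalg.solve(S22, S12.T, assume_a="pos")
    except np.linalg.LinAlgError as exc:
        raise CCAError(
            "rank-deficient covariance; pass ridge > 0 to stabilize"
        ) from exc
    M = S12 @ S22_inv_S21
    try:
        eigvals, eigvecs = linalg.eigh(M, S11)
    except np.linalg.LinAlgError as exc:
        raise CCAError(
            "rank-deficient covariance; pass ridge > 0 to stabilize"
        ) from exc
    order = np.argsort(eigvals)[::-1][:d]
    corrs = np.sqrt(np.clip(eigvals[order], 0.0, 1.0))
    A = eigvecs[:, order]
    # b proportional to S22^-1 S21 a, normalized to unit variance
    B = np.empty((q, d))
    for j in range(d):
        b = S22_inv_S21 @ A[:, j]
        nb = np.sqrt(b @ S22 @ b)
        B[:, j] = b / nb if nb > 0 else b
    return corrs, A, B


def _inv_sqrt_psd(S: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    w = np.maximum(w, floor)
    return (V / np.sqrt(w)) @ V.T


def soft_cca_penalty(
    X1: np.ndarray,
    X2: np.ndarray,
    d: int,
    ridge: float = 1e-3,
    with_grads: bool = False,
):
    """Sum of the top-d canonical correlations of two feature blocks, and
    (optionally) its gradient with respect to each block.

    The projections solving the whitened problem are recomputed in closed
    form at every call, so the returned value is always at the optimum of
    the projection weights; it is bounded above by d. Gradients follow the
    chain rule through T = S11^{-1/2} S12 S22^{-1/2} restricted to the
    top-d singular triplets.
    """
    Xc, Yc, S11, S22, S12, denom = _cov_blocks(X1, X2, ridge)
    p, q = S11.shape[0], S22.shape[0]
    d_eff = min(d, p, q)
    A = _inv_sqrt_psd(S11)
    B = _inv_sqrt_psd(S22)
    T = A @ S12 @ B
    U, s, Vt = np.linalg.svd(T)
    value = float(s[:d_eff].sum())
    W1 = A @ U[:, :d_eff]
    W2 = B @ Vt[:d_eff].T
    if not with_grads:
        return value, (W1, W2)
    Ud, Vd, sd = U[:, :d_eff], Vt[:d_eff].T, s[:d_eff]
    d12 = A @ Ud @ Vd.T @ B                      # d value / d S12
    d11 = -0.5 * (A @ (Ud * sd) @ Ud.T @ A)      # d value / d S11
    d22 = -0.5 * (B @ (Vd * sd) @ Vd.T @ B)      # d value / d S22
    gX1 = (2.0 * Xc @ d11 + Yc @ d12.T) / denom
    gX2 = (2.0 * Yc @ d22 + Xc @ d12) / denom
    # chain through per-column centering
    gX1 -= gX1.mean(axis=0, keepdims=True)
    gX2 -= gX2.mean(axis=0, keepdims=True)
    return value, (W1, W2), (gX1, gX2)


def mean_pairwise_penalty(
    features: list[np.ndarray],
    d: int,
    ridge: float = 1e-3,
    with_grads: bool = False,
):
    """Average ``soft_cca_penalty`` over all k(k-1)/2 feature-block pairs,
    whitening each block once and reusing it across its k-1 pairs.

    Averaging (rather than summing) keeps the meaning of the trade-off
    weight lambda independent of how many pathways survive screening.
    Returns (value, grads_per_block | None, pair_weights) where
    ``pair_weights`` maps (i, j) -> (W1, W2) projections.
    """
    k = len(features)
    if k < 2:
        return 0.0, ([np.zeros_like(f) for f in features] if with_grads else None), {}
    # whiten each block once, reuse across its k-1 pairs
    whitened, whiteners, denom = [], [], features[0].shape[0] - 1
    for F in features:
        Xc, _, S11, _, _, den = _cov_blocks(F, F, ridge)
        A = _inv_sqrt_psd(S11)
        whiteners.append(A)
        whitened.append(Xc @ A)
        denom = den
    n_pairs = k * (k - 1) // 2
    total = 0.0
    grads = [np.zeros_like(F) for F in features] if with_grads else None
    pair_weights: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for i in range(k):
        for j in range(i + 1, k):
            Zi, Zj = whitened[i], whitened[j]
            d_eff = min(d, Zi.shape[1], Zj.shape[1])
            T = Zi.T @ Zj / denom
            # top-d singular triplets of T via the symmetric eigenproblem of
            # T T^T (cheaper than a full SVD; T is small and square-ish)
            w, Q = np.linalg.eigh(T @ T.T)
            top = np.argsort(w)[::-1][:d_eff]
            sd = np.sqrt(np.maximum(w[top], 1e-30))
            Ud = Q[:, top]
            Vd = T.T @ Ud / sd
            total += float(sd.sum())
            pair_weights[(i, j)] = (whiteners[i] @ Ud, whiteners[j] @ Vd)
            if with_grads:
                # same chain rule as soft_cca_penalty, written in the
                # whitened basis: Xc @ dS11-term = Z @ (-1/2 Ud sd Ud^T) A
                g1 = ((Zj @ Vd - Zi @ (Ud * sd)) @ Ud.T) @ whiteners[i] / denom
                g2 = ((Zi @ Ud - Zj @ (Vd * sd)) @ Vd.T) @ whiteners[j] / denom
                grads[i] += (g1 - g1.mean(axis=0, keepdims=True)) / n_pairs
                grads[j] += (g2 - g2.mean(axis=0, keepdims=True)) / n_pairs
    return total / n_pairs, grads, pair_weights
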