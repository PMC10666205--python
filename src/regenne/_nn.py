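"""NumPy neural-network core with hand-written backpropagation.

The ensemble is one small CNN branch per pathway (conv - relu - pool/2 -
conv - relu - pool/2 - flatten, stride 1, "same" padding) feeding a single
dense two-unit softmax head. Because most pathway blocks share a width
(after padding), branches of equal input length are evaluated together as
one stacked tensor of shape (branches, batch, channels, length) using
batched matmuls — the loop over pathways happens inside BLAS, not Python.
Backward passes return input gradients, so the same machinery serves SGD
training and integrated-gradients attribution.
"""

from __future__ import annotations

import numpy as np


def glorot_uniform(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety."""
    z = np.asarray(z, dtype=np.float64)
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


PROB_CLIP = 1e-12


def cross_entropy(y: np.ndarray, p1: np.ndarray) -> float:
    """Mean binary cross-entropy of predicted class-1 probabilities,
    clipped to [1e-12, 1 - 1e-12]."""
    p1 = np.clip(np.asarray(p1, dtype=np.float64), PROB_CLIP, 1.0 - PROB_CLIP)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean(-y * np.log(p1) - (1.0 - y) * np.log(1.0 - p1)))


def softmax_ce_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Cross-entropy of a two-unit softmax head and its logit gradient
    (already averaged over the batch)."""
    probs = softmax(logits)
    ce = cross_entropy(y, probs[:, 1])
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
    dlogits = (probs - onehot) / len(y)
    return ce, dlogits


# ----------------------------------------------------------------------
# grouped primitive ops on (P, B, C, L) tensors
# ----------------------------------------------------------------------


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, k: int):
    """Same-padding stride-1 conv. x (P,B,C,L), W (P, C*k, O), b (P, O)
    -> out (P,B,O,L) plus the im2col cache."""
    P, B, C, L = x.shape
    p = k // 2
    xp = np.zeros((P, B, C, L + 2 * p))
    xp[..., p : p + L] = x
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=3)  # (P,B,C,L,k)
    if C == 1:
        cols = win.reshape(P, B * L, k)  # single channel: already (L, k)-ordered
    else:
        cols = win.transpose(0, 1, 3, 2, 4).reshape(P, B * L, C * k)
    out = np.matmul(cols, W) + b[:, None, :]  # (P, B*L, O)
    O = W.shape[2]
    return out.reshape(P, B, L, O).transpose(0, 1, 3, 2), (cols, x.shape)


def _conv_backward(dout: np.ndarray, W: np.ndarray, cache, k: int):
    """Gradients of _conv_forward: returns (dx, dW, db)."""
    cols, xshape = cache
    P, B, C, L = xshape
    O = W.shape[2]
    dout_r = dout.transpose(0, 1, 3, 2).reshape(P, B * L, O)
    dW = np.matmul(cols.transpose(0, 2, 1), dout_r)
    db = dout_r.sum(axis=1)
    dcols = np.matmul(dout_r, W.transpose(0, 2, 1))  # (P, B*L, C*k)
    dcols = dcols.reshape(P, B, L, C, k).transpose(0, 1, 3, 2, 4)
    p = k // 2
    dxp = np.zeros((P, B, C, L + 2 * p))
    for j in range(k):
        dxp[..., j : j + L] += dcols[..., j]
    return dxp[..., p : p + L], dW, db


def _pool_forward(x: np.ndarray):
    """Non-overlapping factor-2 max pool over the last axis; an odd tail
    position is dropped (floor division of the length). Ties route the
    gradient to the left position."""
    L = x.shape[-1]
    Lo = L // 2
    x0 = x[..., 0 : 2 * Lo : 2]
    x1 = x[..., 1 : 2 * Lo : 2]
    left = x0 >= x1
    return np.where(left, x0, x1), (left, x.shape)


def _pool_backward(dout: np.ndarray, cache):
    left, xshape = cache
    Lo = dout.shape[-1]
    dx = np.zeros(xshape)
    dx[..., 0 : 2 * Lo : 2] = np.where(left, dout, 0.0)
    dx[..., 1 : 2 * Lo : 2] = np.where(left, 0.0, dout)
    return dx


class BranchGroup:
    """All pathway branches sharing one input length, evaluated jointly."""

    def __init__(self, n_branches: int, input_length: int, n_filters: int,
                 kernel_size: int, rng: np.random.Generator):
        if input_length < 4:
            raise ValueError(
                f"branch input length {input_length} < 4; pad the pathway "
                "block so it survives two halving pools"
            )
        P, F, k = n_branches, n_filters, kernel_size
        if k % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.P, self.F, self.k = P, F, k
        self.input_length = input_length
        self.W1 = glorot_uniform(rng, (P, 1 * k, F), 1 * k, F * k)
        self.b1 = np.zeros((P, F))
        self.W2 = glorot_uniform(rng, (P, F * k, F), F * k, F * k)
        self.b2 = np.zeros((P, F))
        self.spatial_out = (input_length // 2) // 2
        self.output_dim = self.spatial_out * F
        self.dW1 = np.zeros_like(self.W1)
        self.db1 = np.zeros_like(self.b1)
        self.dW2 = np.zeros_like(self.W2)
        self.db2 = np.zeros_like(self.b2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x (P, B, L) -> features (P, B, output_dim)."""
        h = x[:, :, None, :]
        c1, self._cache_c1 = _conv_forward(h, self.W1, self.b1, self.k)
        self._mask1 = c1 > 0
        r1 = c1 * self._mask1
        p1, self._cache_p1 = _pool_forward(r1)
        c2, self._cache_c2 = _conv_forward(p1, self.W2, self.b2, self.k)
        self._mask2 = c2 > 0
        r2 = c2 * self._mask2
        p2, self._cache_p2 = _pool_forward(r2)
        P, B = p2.shape[:2]
        return p2.reshape(P, B, self.output_dim)

    def backward(self, dfeat: np.ndarray) -> np.ndarray:
        """dfeat (P, B, output_dim) -> dx (P, B, L); stores weight grads."""
        P, B = dfeat.shape[:2]
        d = dfeat.reshape(P, B, self.F, self.spatial_out)
        d = _pool_backward(d, self._cache_p2) * self._mask2
        d, self.dW2, self.db2 = _conv_backward(d, self.W2, self._cache_c2, self.k)
        d = _pool_backward(d, self._cache_p1) * self._mask1
        d, self.dW1, self.db1 = _conv_backward(d, self.W1, self._cache_c1, self.k)
        return d[:, :, 0, :]

    def param_grads(self):
        return [
            (self.W1, self.dW1),
            (self.b1, self.db1),
            (self.W2, self.dW2),
            (self.b2, self.db2),
        ]


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def param_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class EnsembleNet:
    """One CNN branch per pathway, concatenated features into a single
    dense layer with a two-unit softmax. Branches of equal input length
    are grouped for vectorized evaluation; the public interface is always
    per-branch lists in the original pathway order."""

    def __init__(self, input_lengths: list[int], n_filters: int,
                 kernel_size: int, rng: np.random.Generator):
        self.n_branches = len(input_lengths)
        if self.n_branches == 0:
            raise ValueError("at least one pathway branch is required")
        self.input_lengths = list(input_lengths)
        by_length: dict[int, list[int]] = {}
        for i, g in enumerate(input_lengths):
            by_length.setdefault(g, []).append(i)
        self.groups: list[tuple[list[int], BranchGroup]] = []
        for g in sorted(by_length):
            idxs = by_length[g]
            self.groups.append(
                (idxs, BranchGroup(len(idxs), g, n_filters, kernel_size, rng))
            )
        self.feature_dims = [0] * self.n_branches
        for idxs, grp in self.groups:
            for i in idxs:
                self.feature_dims[i] = grp.output_dim
        self.head = Dense(int(sum(self.feature_dims)), 2, rng)
        self._offsets = np.concatenate([[0], np.cumsum(self.feature_dims)])

    # -- forward ---------------------------------------------------------
    def prepare_blocks(self, blocks: list[np.ndarray]) -> list[np.ndarray]:
        """Stack per-branch blocks into one (P, n, L) array per group, so
        repeated minibatch forwards only slice the sample axis."""
        if len(blocks) != self.n_branches:
            raise ValueError(
                f"model has {self.n_branches} pathway branches but got "
                f"{len(blocks)} blocks"
            )
        for i, (blk, g) in enumerate(zip(blocks, self.input_lengths)):
            if blk.ndim != 2 or blk.shape[1] != g:
                raise ValueError(
                    f"block {i} has shape {blk.shape}, expected (n, {g})"
                )
        return [np.stack([blocks[i] for i in idxs]) for idxs, _ in self.groups]

    def features_from_prepared(
        self, prepared: list[np.ndarray], idx: np.ndarray | None = None
    ) -> list[np.ndarray]:
        feats: list[np.ndarray | None] = [None] * self.n_branches
        for (idxs, grp), stacked in zip(self.groups, prepared):
            out = grp.forward(stacked if idx is None else stacked[:, idx])
            for pos, i in enumerate(idxs):
                feats[i] = out[pos]
        return feats  # type: ignore[return-value]

    def branch_features(self, blocks: list[np.ndarray]) -> list[np.ndarray]:
        return self.features_from_prepared(self.prepare_blocks(blocks))

    def forward_prepared(
        self, prepared: list[np.ndarray], idx: np.ndarray | None = None
    ) -> np.ndarray:
        return self.head.forward(
            np.hstack(self.features_from_prepared(prepared, idx))
        )

    def forward(self, blocks: list[np.ndarray]) -> np.ndarray:
        return self.forward_prepared(self.prepare_blocks(blocks))

    def predict_proba1(self, blocks: list[np.ndarray]) -> np.ndarray:
        return softmax(self.forward(blocks))[:, 1]

    # -- backward --------------------------------------------------------
    def _split_features(self, dfeat_concat: np.ndarray) -> list[np.ndarray]:
        return [
            dfeat_concat[:, self._offsets[i] : self._offsets[i + 1]]
            for i in range(self.n_branches)
        ]

    def backward(self, dlogits: np.ndarray, need_input_grads: bool = False):
        dfeat = self.head.backward(dlogits)
        dfeats = self._split_features(dfeat)
        dxs = self.backward_branches(dfeats, need_input_grads=need_input_grads)
        return dxs if need_input_grads else None

    def backward_branches(
        self, dfeats: list[np.ndarray], need_input_grads: bool = False
    ):
        """Backprop per-branch feature gradients through the branches only
        (the head is untouched); used by the CCA ascent step."""
        input_grads: list[np.ndarray | None] = [None] * self.n_branches
        for idxs, grp in self.groups:
            stacked = np.stack([dfeats[i] for i in idxs])
            dx = grp.backward(stacked)
            if need_input_grads:
                for pos, i in enumerate(idxs):
                    input_grads[i] = dx[pos]
        return input_grads if need_input_grads else None

    # -- parameters ------------------------------------------------------
    def param_grads(self, include_head: bool = True):
        out = []
        for _, grp in self.groups:
            out.extend(grp.param_grads())
        if include_head:
            out.extend(self.head.param_grads())
        return out

    def sgd_step(self, lr: float, include_head: bool = True) -> None:
        for p, g in self.param_grads(include_head=include_head):
            p -= lr * g

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.param_grads()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        pgs = self.param_grads()
        if len(weights) != len(pgs):
            raise ValueError("weight list does not match the architecture")
        for (p, _), w in zip(pgs, weights):
            if p.shape != w.shape:
                raise ValueError("weight shapes do not match the architecture")
            p[...] = w
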