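"""Dual-scale convolution + spatial attention network over embedded DNA.

Architecture, for an embedded sequence E (d channels x N positions):

* two parallel 1D valid convolutions (kernel widths 10 and 12 by default,
  1024 filters each) + ReLU, whose outputs are concatenated along the
  *spatial* axis ("dual-scale fusion": channel count is preserved, spatial
  lengths add);
* a spatial attention gate: per-position mean and max over channels form a
  2 x L descriptor, a width-7 same-padded convolution + sigmoid turns it into
  a gating vector S in (0,1)^L, which multiplies every channel;
* global max-pooling over positions and a single dense layer with 2-way
  softmax.

Everything here is plain numpy (float32) with hand-written gradients, sized
for 1D genomic inputs.  Public single-instance functions take feature
matrices in channels x positions layout; the batched training path uses
(batch, positions, channels) internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

ABLATION_VARIANTS = ("-SS1", "-SS2", "-SA", "-SS1-SS2-SA")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ConvBranchParams:
    """One single-scale convolution branch: M filters of width k over C_in channels."""

    weights: np.ndarray  # (M, C_in, k)
    bias: np.ndarray  # (M,)

    @property
    def kernel_size(self) -> int:
        return self.weights.shape[2]

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "ConvBranchParams":
        return ConvBranchParams(self.weights.copy(), self.bias.copy())


@dataclass
class AttentionParams:
    """Spatial-attention convolution: 2 pooled channels -> 1 gating channel."""

    weights: np.ndarray  # (1, 2, kernel)
    bias: np.ndarray  # (1,)

    @property
    def kernel_size(self) -> int:
        return self.weights.shape[2]

    def copy(self) -> "AttentionParams":
        return AttentionParams(self.weights.copy(), self.bias.copy())


@dataclass
class HeadParams:
    """Dense 2-way classification head on the max-pooled feature vector."""

    weights: np.ndarray  # (2, M)
    bias: np.ndarray  # (2,)

    def copy(self) -> "HeadParams":
        return HeadParams(self.weights.copy(), self.bias.copy())


@dataclass
class ModelParams:
    """All network weights plus the ablation switches.

    ``use_branches[b]`` disables a convolution branch without removing its
    weights; ``use_attention`` toggles the gate; ``bypass_conv`` routes the
    raw embedding straight into max-pool + head (the no-conv, no-attention
    ablation), in which case the head consumes d inputs instead of M.
    """

    branches: list[ConvBranchParams]
    attention: AttentionParams | None
    head: HeadParams
    use_branches: tuple[bool, ...] = ()
    use_attention: bool = True
    bypass_conv: bool = False

    def __post_init__(self) -> None:
        if not self.use_branches:
            self.use_branches = tuple(True for _ in self.branches)
        if not self.bypass_conv and not any(self.use_branches):
            raise ValueError("at least one convolution branch must be enabled")

    @property
    def enabled_branches(self) -> list[ConvBranchParams]:
        return [b for b, on in zip(self.branches, self.use_branches) if on]

    @property
    def kernel_sizes(self) -> tuple[int, ...]:
        return tuple(b.kernel_size for b in self.branches)

    def copy(self) -> "ModelParams":
        return ModelParams(
            branches=[b.copy() for b in self.branches],
            attention=self.attention.copy() if self.attention is not None else None,
            head=self.head.copy(),
            use_branches=self.use_branches,
            use_attention=self.use_attention,
            bypass_conv=self.bypass_conv,
        )


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def init_params(
    embedding_dim: int = 20,
    kernel_sizes: Sequence[int] = (10, 12),
    n_filters: int = 1024,
    attention_kernel: int = 7,
    use_attention: bool = True,
    bypass_conv: bool = False,
    seed: int = 0,
) -> ModelParams:
    """Seeded fan-in-scaled uniform initialization of all weights."""
    if attention_kernel % 2 != 1:
        raise ValueError("attention kernel width must be odd for symmetric padding")
    rng = np.random.default_rng(seed)
    branches = [
        ConvBranchParams(
            weights=_uniform_init(rng, (n_filters, embedding_dim, k), embedding_dim * k),
            bias=np.zeros(n_filters, dtype=np.float32),
        )
        for k in kernel_sizes
    ]
    attention = AttentionParams(
        weights=_uniform_init(rng, (1, 2, attention_kernel), 2 * attention_kernel),
        bias=np.zeros(1, dtype=np.float32),
    )
    head_in = embedding_dim if bypass_conv else n_filters
    head = HeadParams(
        weights=_uniform_init(rng, (2, head_in), head_in),
        bias=np.zeros(2, dtype=np.float32),
    )
    return ModelParams(
        branches=branches,
        attention=attention,
        head=head,
        use_attention=use_attention,
        bypass_conv=bypass_conv,
    )


def make_ablation(params: ModelParams, variant: str, seed: int = 0) -> ModelParams:
    """Return a copy of ``params`` with one standard ablation applied.

    ``-SS1`` / ``-SS2`` disable the first / second convolution branch,
    ``-SA`` removes the attention gate, and ``-SS1-SS2-SA`` bypasses both
    convolutions and attention so the head (re-initialized to embedding_dim
    inputs, seeded) consumes the per-channel spatial max of the raw
    embedding.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown ablation variant {variant!r}; choose from {ABLATION_VARIANTS}")
    out = params.copy()
    if variant == "-SS1":
        out.use_branches = (False,) + out.use_branches[1:]
    elif variant == "-SS2":
        out.use_branches = out.use_branches[:1] + (False,) + out.use_branches[2:]
    elif variant == "-SA":
        out.use_attention = False
    else:  # -SS1-SS2-SA
        out.bypass_conv = True
        out.use_attention = False
        d = out.branches[0].weights.shape[1]
        rng = np.random.default_rng(seed)
        out.head = HeadParams(
            weights=_uniform_init(rng, (2, d), d),
            bias=np.zeros(2, dtype=np.float32),
        )
    if not out.bypass_conv and not any(out.use_branches):
        raise ValueError("ablation would disable every branch")
    return out


# ---------------------------------------------------------------------------
# batched forward / backward (internal layout: batch x positions x channels)


def _windows(X: np.ndarray, k: int) -> np.ndarray:
    """Strided sliding-window view (B, N, C) -> (B, N-k+1, k, C)."""
    B, N, C = X.shape
    s0, s1, s2 = X.strides
    return np.lib.stride_tricks.as_strided(
        X, shape=(B, N - k + 1, k, C), strides=(s0, s1, s1, s2), writeable=False
    )


def _branch_forward(X: np.ndarray, p: ConvBranchParams) -> tuple[np.ndarray, np.ndarray]:
    """Valid 1D convolution + ReLU.  Returns (activation, pre-activation windows)."""
    B, N, C = X.shape
    k = p.kernel_size
    if N < k:
        raise ValueError(f"input length {N} shorter than kernel width {k}")
    win = np.ascontiguousarray(_windows(X, k)).reshape(B * (N - k + 1), k * C)
    Wmat = p.weights.transpose(2, 1, 0).reshape(k * C, p.n_filters)  # (j,c) -> m
    Z = (win @ Wmat).reshape(B, N - k + 1, p.n_filters) + p.bias
    return np.maximum(Z, 0.0), win


def _attention_forward(
    F: np.ndarray, p: AttentionParams
) -> tuple[np.ndarray, dict]:
    """Spatial attention on F (B, L, M).  Returns (F_hat, cache)."""
    B, L, M = F.shape
    k = p.kernel_size
    pad = k // 2
    mean = F.mean(axis=2)
    argc = F.argmax(axis=2)
    mx = np.take_along_axis(F, argc[:, :, None], axis=2)[:, :, 0]
    D = np.stack([mean, mx], axis=2)  # (B, L, 2): [avg, max]
    Dp = np.pad(D, ((0, 0), (pad, pad), (0, 0)))
    win = np.ascontiguousarray(_windows(Dp, k))  # (B, L, k, 2)
    s_logit = np.einsum("bljc,cj->bl", win, p.weights[0]) + p.bias[0]
    S = 1.0 / (1.0 + np.exp(-s_logit))
    F_hat = F * S[:, :, None]
    cache = {"S": S, "win": win, "argc": argc, "F": F, "pad": pad}
    return F_hat, cache


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def batch_forward(X: np.ndarray, params: ModelParams, train: bool = False):
    """Forward pass on a batch of embedded sequences X (B, N, d).

    Returns class probabilities (B, 2) with column 0 the positive class;
    with ``train=True`` additionally returns the cache needed by
    :func:`batch_backward`.
    """
    X = np.asarray(X, dtype=np.float32)
    cache: dict = {"X": X}
    if params.bypass_conv:
        argp = X.argmax(axis=1)  # (B, d)
        v = np.take_along_axis(X, argp[:, None, :], axis=1)[:, 0, :]
        cache.update(F_hat=None, argp=argp)
    else:
        acts, wins = [], []
        for b in params.enabled_branches:
            A, win = _branch_forward(X, b)
            acts.append(A)
            wins.append(win)
        F = np.concatenate(acts, axis=1)  # (B, L, M)
        cache.update(acts=acts, wins=wins, F=F)
        if params.use_attention and params.attention is not None:
            F_hat, att_cache = _attention_forward(F, params.attention)
            cache["att"] = att_cache
        else:
            F_hat = F
            cache["att"] = None
        argp = F_hat.argmax(axis=1)  # (B, M)
        v = np.take_along_axis(F_hat, argp[:, None, :], axis=1)[:, 0, :]
        cache.update(F_hat=F_hat, argp=argp)
    logits = v @ params.head.weights.T + params.head.bias
    probs = _softmax(logits)
    cache.update(v=v, probs=probs)
    if train:
        return probs, cache
    return probs


def batch_backward(cache: dict, y_idx: np.ndarray, params: ModelParams) -> dict:
    """Gradients of the mean cross-entropy w.r.t. every trainable array.

    ``y_idx`` holds 0 for positive-class samples, 1 for negative.  Embeddings
    are fixed inputs, so no gradient flows into X.  Returns a flat dict
    keyed like ``branch0.weights``, ``attention.bias``, ``head.weights``.
    """
    probs, v = cache["probs"], cache["v"]
    B = probs.shape[0]
    dlogits = probs.copy()
    dlogits[np.arange(B), y_idx] -= 1.0
    dlogits /= B

    grads: dict[str, np.ndarray] = {
        "head.weights": dlogits.T @ v,
        "head.bias": dlogits.sum(axis=0),
    }
    if params.bypass_conv:
        return grads

    dv = dlogits @ params.head.weights  # (B, M)
    F_hat = cache["F_hat"]
    dF_hat = np.zeros_like(F_hat)
    np.put_along_axis(dF_hat, cache["argp"][:, None, :], dv[:, None, :], axis=1)

    att = cache["att"]
    if att is not None:
        S, win, argc, F, pad = att["S"], att["win"], att["argc"], att["F"], att["pad"]
        Bn, L, M = F.shape
        dF = dF_hat * S[:, :, None]
        dS = (dF_hat * F).sum(axis=2)
        dls = dS * S * (1.0 - S)  # through the sigmoid
        grads["attention.weights"] = np.einsum("bl,bljc->cj", dls, win)[None, :, :]
        grads["attention.bias"] = np.array([dls.sum()], dtype=np.float64)
        k = params.attention.kernel_size
        dDp = np.zeros((Bn, L + 2 * pad, 2), dtype=np.float64)
        for j in range(k):
            dDp[:, j : j + L, :] += dls[:, :, None] * params.attention.weights[0, :, j]
        dD = dDp[:, pad : pad + L, :]
        dF += dD[:, :, 0:1] / M  # mean-pool path, spread over channels
        # max-pool path: route to the per-position argmax channel
        flat = dF.reshape(Bn * L, M)
        np.add.at(flat, (np.arange(Bn * L), argc.ravel()), dD[:, :, 1].ravel())
        dF_hat = dF
    dF = dF_hat

    # split the fused gradient back to the enabled branches along the spatial axis
    offset = 0
    enabled_idx = [i for i, on in enumerate(params.use_branches) if on]
    for slot, (i, A, win) in enumerate(zip(enabled_idx, cache["acts"], cache["wins"])):
        p = params.branches[i]
        L_b = A.shape[1]
        dA = dF[:, offset : offset + L_b, :]
        offset += L_b
        dZ = np.where(A > 0, dA, 0.0)
        dZ_flat = dZ.reshape(-1, p.n_filters)
        dWmat = win.T @ dZ_flat  # (k*C, M)
        k, C = p.kernel_size, p.weights.shape[1]
        grads[f"branch{i}.weights"] = dWmat.reshape(k, C, p.n_filters).transpose(2, 1, 0)
        grads[f"branch{i}.bias"] = dZ_flat.sum(axis=0)
    return grads


def trainable_arrays(params: ModelParams) -> dict[str, np.ndarray]:
    """Flat name -> array view of every trainable tensor (ablation-aware)."""
    out: dict[str, np.ndarray] = {
        "head.weights": params.head.weights,
        "head.bias": params.head.bias,
    }
    if params.bypass_conv:
        return out
    for i, (b, on) in enumerate(zip(params.branches, params.use_branches)):
        if on:
            out[f"branch{i}.weights"] = b.weights
            out[f"branch{i}.bias"] = b.bias
    if params.use_attention and params.attention is not None:
        out["attention.weights"] = params.attention.weights
        out["attention.bias"] = params.attention.bias
    return out


class Adam:
    """Standard Adam over a named dict of float32 arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, arrays: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, arr in arrays.items():
            g = grads[name].astype(np.float32)
            if name not in self.m:
                self.m[name] = np.zeros_like(arr)
                self.v[name] = np.zeros_like(arr)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            m_hat = self.m[name] / (1 - b1**self.t)
            v_hat = self.v[name] / (1 - b2**self.t)
            arr -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(np.float32)


# ---------------------------------------------------------------------------
# public single-instance operations (channels x positions layout)


def conv1d_valid(E: np.ndarray, p: ConvBranchParams) -> np.ndarray:
    """Valid (no padding, stride 1) 1D convolution of E (C_in x N) -> M x (N-k+1).

    out[m, t] = bias_m + sum_{c,j} weights[m, c, j] * E[c, t + j].
    """
    E = np.asarray(E, dtype=np.float32)
    X = E.T[None]  # (1, N, C)
    k = p.kernel_size
    if E.shape[1] < k:
        raise ValueError(f"spatial length {E.shape[1]} shorter than kernel width {k}")
    win = np.ascontiguousarray(_windows(X, k)).reshape(-1, k * E.shape[0])
    Wmat = p.weights.transpose(2, 1, 0).reshape(k * E.shape[0], p.n_filters)
    Z = win @ Wmat + p.bias
    return Z.T  # (M, N-k+1)


def dual_scale_fusion(E: np.ndarray, params: ModelParams) -> np.ndarray:
    """ReLU conv outputs of every enabled branch, concatenated along positions."""
    enabled = params.enabled_branches
    if not enabled:
        raise ValueError("no enabled convolution branch")
    return np.concatenate(
        [np.maximum(conv1d_valid(E, b), 0.0) for b in enabled], axis=1
    )


def attention_descriptor(F: np.ndarray) -> np.ndarray:
    """Channel-pooled 2 x L descriptor of F (M x L): row 0 mean, row 1 max."""
    F = np.asarray(F)
    return np.stack([F.mean(axis=0), F.max(axis=0)])


def spatial_attention(F: np.ndarray, p: AttentionParams) -> tuple[np.ndarray, np.ndarray]:
    """Attention gate on F (M x L): returns (S: 1 x L, F_hat: M x L)."""
    F = np.asarray(F, dtype=np.float32)
    F_hat, cache = _attention_forward(F.T[None], p)
    return cache["S"].reshape(1, -1), F_hat[0].T


def forward(E: np.ndarray, params: ModelParams) -> tuple[float, float]:
    """Full forward pass on one embedded sequence E (d x N) -> (p_pos, p_neg)."""
    probs = batch_forward(np.asarray(E, dtype=np.float32).T[None], params)
    return float(probs[0, 0]), float(probs[0, 1])


def cross_entropy(probs: Sequence[Sequence[float]], labels: Sequence[int]) -> float:
    """Mean negative log-probability of the true class over a batch.

    ``labels`` are class indices into each probability pair.  Probabilities
    are clamped at 1e-12 before the log.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.size == 0:
        raise ValueError("empty batch")
    p_true = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.maximum(p_true, 1e-12))))


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(params: ModelParams, path: str | Path, extra_meta: dict | None = None) -> None:
    """Write all weight arrays (.npz) plus a JSON sidecar of hyperparameters."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {
        "head.weights": params.head.weights,
        "head.bias": params.head.bias,
    }
    for i, b in enumerate(params.branches):
        arrays[f"branch{i}.weights"] = b.weights
        arrays[f"branch{i}.bias"] = b.bias
    if params.attention is not None:
        arrays["attention.weights"] = params.attention.weights
        arrays["attention.bias"] = params.attention.bias
    np.savez(path, **arrays)
    meta = {
        "kernel_sizes": list(params.kernel_sizes),
        "n_filters": params.branches[0].n_filters if params.branches else 0,
        "embedding_dim": params.branches[0].weights.shape[1] if params.branches else
        params.head.weights.shape[1],
        "use_branches": list(params.use_branches),
        "use_attention": params.use_attention,
        "bypass_conv": params.bypass_conv,
    }
    meta.update(extra_meta or {})
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_checkpoint(path: str | Path) -> tuple[ModelParams, dict]:
    path = Path(path)
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    branches = []
    i = 0
    while f"branch{i}.weights" in arrays:
        branches.append(ConvBranchParams(arrays[f"branch{i}.weights"], arrays[f"branch{i}.bias"]))
        i += 1
    attention = None
    if "attention.weights" in arrays:
        attention = AttentionParams(arrays["attention.weights"], arrays["attention.bias"])
    params = ModelParams(
        branches=branches,
        attention=attention,
        head=HeadParams(arrays["head.weights"], arrays["head.bias"]),
        use_branches=tuple(meta.get("use_branches", [True] * len(branches))),
        use_attention=meta.get("use_attention", True),
        bypass_conv=meta.get("bypass_conv", False),
    )
    return params, meta
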