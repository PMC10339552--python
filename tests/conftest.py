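"""Shared fixtures and independent brute-force oracles.

The oracles re-derive every network operation with explicit loops so the
vectorized implementations are checked against code that shares nothing with
them.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from enhancerscan.model_core import ModelParams


# ---------------------------------------------------------------------------
# brute-force oracles (loop-level re-derivations, float64)


def oracle_conv1d(E: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Triple-loop valid convolution: out[m,t] = b_m + sum_{c,j} w[m,c,j] E[c,t+j]."""
    M, C, k = weights.shape
    N = E.shape[1]
    out = np.zeros((M, N - k + 1))
    for m in range(M):
        for t in range(N - k + 1):
            acc = float(bias[m])
            for c in range(C):
                for j in range(k):
                    acc += float(weights[m, c, j]) * float(E[c, t + j])
            out[m, t] = acc
    return out


def oracle_attention(F: np.ndarray, weights: np.ndarray, bias: float):
    """Per-position mean/max pooling, padded convolution, sigmoid, product."""
    M, L = F.shape
    k = weights.shape[2]
    pad = k // 2
    D = np.zeros((2, L))
    for t in range(L):
        D[0, t] = sum(F[m, t] for m in range(M)) / M
        D[1, t] = max(F[m, t] for m in range(M))
    Dp = np.zeros((2, L + 2 * pad))
    Dp[:, pad : pad + L] = D
    S = np.zeros(L)
    for t in range(L):
        acc = float(bias)
        for c in range(2):
            for j in range(k):
                acc += float(weights[0, c, j]) * Dp[c, t + j]
        S[t] = 1.0 / (1.0 + math.exp(-acc))
    F_hat = np.zeros_like(F, dtype=float)
    for m in range(M):
        for t in range(L):
            F_hat[m, t] = F[m, t] * S[t]
    return S, F_hat


def oracle_forward(E: np.ndarray, params: ModelParams) -> tuple[float, float]:
    """Composition of the loop oracles plus explicit max-pool and softmax."""
    pieces = []
    for b in params.enabled_branches:
        A = oracle_conv1d(E, b.weights, b.bias)
        pieces.append(np.maximum(A, 0.0))
    F = np.concatenate(pieces, axis=1)
    if params.use_attention and params.attention is not None:
        _, F_hat = oracle_attention(F, params.attention.weights, float(params.attention.bias[0]))
    else:
        F_hat = F
    v = F_hat.max(axis=1)
    logits = params.head.weights @ v + params.head.bias
    z = logits - logits.max()
    e = np.exp(z)
    p = e / e.sum()
    return float(p[0]), float(p[1])


def oracle_auc(scores, labels, positive="positive") -> float:
    """O(n^2) Mann-Whitney pair counting; tied scores count one half."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def tiny_embedder():
    """A quickly trained embedding shared by tests that only need lookups."""
    from enhancerscan import SkipgramEmbedder

    rng = np.random.default_rng(42)
    seqs = [random_dna(rng, 60) for _ in range(40)]
    return SkipgramEmbedder(epochs=3, random_state=0).fit(seqs)


@pytest.fixture(scope="session")
def ident_sim_small():
    """Small identification-mode synthetic dataset (planted 10/12-nt motifs)."""
    from enhancerscan import SimConfig, generate_dataset

    return generate_dataset(SimConfig(n_per_class=40, length=60, seed=7))
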