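"""3-mer tokenization and skip-gram word embeddings for DNA sequences.

A DNA sequence is treated as a sentence and every overlapping window of three
consecutive nucleotides as a word, so a K-nt sequence yields N = K - 2 words.
Word vectors are trained with the skip-gram objective and negative sampling;
the trainer is a compact numpy implementation of the classic word2vec
algorithm (sub-sampling of frequent words, shrunk context windows, a 3/4-power
unigram noise distribution and a linearly decaying learning rate), restricted
to what a 64-word DNA vocabulary needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass(frozen=True)
class TokenSequence:
    """An ordered list of overlapping n-mer words from one sequence."""

    words: tuple[str, ...]

    @property
    def n_words(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)

    def __len__(self) -> int:
        return len(self.words)


def tokenize(seq: str, n: int = 3) -> TokenSequence:
    """Split a sequence into all overlapping n-mers, in order.

    For the default n=3 a K-nt sequence yields K - 2 words, consecutive words
    overlapping by two nucleotides (e.g. ATCGG -> ATC, TCG, CGG).
    """
    if len(seq) < n:
        raise ValueError(f"sequence of length {len(seq)} shorter than n={n}")
    return TokenSequence(tuple(seq[i : i + n] for i in range(len(seq) - n + 1)))


@dataclass
class Vocab:
    """Dense word -> index mapping with corpus counts."""

    index: dict[str, int]
    counts: np.ndarray  # per-index corpus count

    @property
    def words(self) -> list[str]:
        out = [""] * len(self.index)
        for w, i in self.index.items():
            out[i] = w
        return out

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, word: str) -> bool:
        return word in self.index


def build_vocab(corpus: Sequence[TokenSequence], min_count: int = 1) -> Vocab:
    """Count words over the corpus and retain those with count >= min_count."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    counts: dict[str, int] = {}
    for sent in corpus:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    kept = sorted(w for w, c in counts.items() if c >= min_count)
    index = {w: i for i, w in enumerate(kept)}
    return Vocab(index=index, counts=np.array([counts[w] for w in kept], dtype=np.int64))


@dataclass
class SkipgramConfig:
    """Skip-gram training configuration.

    Defaults follow the word2vec setup used throughout this package: 20-d
    vectors, context window 5, minimum count 1, initial learning rate 0.025,
    51 epochs, 5 negative samples per positive pair and a 1e-3 frequent-word
    down-sampling threshold.
    """

    vector_size: int = 20
    window: int = 5
    min_count: int = 1
    initial_lr: float = 0.025
    min_lr: float = 1e-4
    epochs: int = 51
    negatives: int = 5
    downsample: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        for name in ("vector_size", "window", "min_count", "epochs", "negatives"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.initial_lr <= 0 or self.downsample <= 0:
            raise ValueError("initial_lr and downsample must be positive")


@dataclass
class EmbeddingTable:
    """Input and output (context) vectors for every vocabulary word."""

    vocab: Vocab
    vectors: np.ndarray  # (W, d) input vectors e_w
    out_vectors: np.ndarray  # (W, d) output vectors e'_w
    config: SkipgramConfig

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.vocab.index[word]]

    def save_word2vec(self, path: str | Path) -> None:
        """Serialize input vectors in the word2vec text format."""
        words = self.vocab.words
        with open(path, "w") as fh:
            fh.write(f"{len(words)} {self.dim}\n")
            for w in words:
                vec = " ".join(f"{x:.9g}" for x in self.vector(w))  # float32 round-trips
                fh.write(f"{w} {vec}\n")

    @classmethod
    def load_word2vec(cls, path: str | Path, config: SkipgramConfig | None = None) -> "EmbeddingTable":
        with open(path) as fh:
            header = fh.readline().split()
            n_words, dim = int(header[0]), int(header[1])
            words, rows = [], []
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                words.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(words) != n_words or any(len(r) != dim for r in rows):
            raise ValueError("malformed word2vec text file")
        vocab = Vocab(index={w: i for i, w in enumerate(words)},
                      counts=np.ones(len(words), dtype=np.int64))
        vectors = np.asarray(rows, dtype=np.float32)
        cfg = config or SkipgramConfig(vector_size=dim)
        return cls(vocab=vocab, vectors=vectors,
                   out_vectors=np.zeros_like(vectors), config=cfg)


def skipgram_softmax_prob(center: str, context: str, table: EmbeddingTable) -> float:
    """Full-softmax probability p(context | center) under the embedding model.

    p = exp(e'_context . e_center) / sum_j exp(e'_j . e_center), normalized
    over the whole vocabulary.
    """
    for w in (center, context):
        if w not in table.vocab:
            raise KeyError(f"word {w!r} not in vocabulary")
    e_center = table.vectors[table.vocab.index[center]].astype(np.float64)
    scores = table.out_vectors.astype(np.float64) @ e_center
    scores -= scores.max()  # numerical stability; cancels in the ratio
    expd = np.exp(scores)
    return float(expd[table.vocab.index[context]] / expd.sum())


def _keep_probability(counts: np.ndarray, threshold: float) -> np.ndarray:
    """word2vec frequent-word sub-sampling keep probability, clipped to 1."""
    freq = counts / counts.sum()
    with np.errstate(divide="ignore"):
        p = (np.sqrt(freq / threshold) + 1.0) * (threshold / freq)
    return np.minimum(p, 1.0)


def _noise_cdf(counts: np.ndarray) -> np.ndarray:
    """Cumulative unigram^(3/4) noise distribution for negative sampling."""
    weights = counts.astype(np.float64) ** 0.75
    return np.cumsum(weights / weights.sum())


def _epoch_pairs(
    sentences: list[np.ndarray],
    keep_prob: np.ndarray,
    window: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate (center, context) index pairs for one epoch.

    Each word is retained with its sub-sampling probability, then each
    retained center draws a shrunk window b ~ U{1..window}; windows never span
    sentence boundaries.
    """
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for sent in sentences:
        kept = sent[rng.random(len(sent)) < keep_prob[sent]]
        n = len(kept)
        if n < 2:
            continue
        b = rng.integers(1, window + 1, size=n)
        pos = np.arange(n)
        for off in range(-window, window + 1):
            if off == 0:
                continue
            j = pos + off
            mask = (j >= 0) & (j < n) & (np.abs(off) <= b)
            if mask.any():
                centers.append(kept[pos[mask]])
                contexts.append(kept[j[mask]])
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def _scatter_add(out: np.ndarray, idx: np.ndarray, updates: np.ndarray) -> None:
    """out[idx[i]] += updates[i], deterministic, via per-dimension bincount."""
    W, d = out.shape
    for j in range(d):
        out[:, j] += np.bincount(idx, weights=updates[:, j], minlength=W)


def train_skipgram(
    corpus: Sequence[TokenSequence],
    cfg: SkipgramConfig | None = None,
    batch_pairs: int = 512,
) -> EmbeddingTable:
    """Train skip-gram word vectors with negative sampling on a token corpus.

    Mini-batches of (center, context) pairs receive a joint SGD update with
    ``cfg.negatives`` noise words per pair; the learning rate decays linearly
    from ``cfg.initial_lr`` to ``cfg.min_lr`` over the whole run.  The batch
    size is kept small relative to the 64-word DNA vocabulary so accumulated
    per-word updates stay close to sequential SGD.  Training is
    single-threaded and bit-reproducible from ``cfg.seed``.
    """
    cfg = cfg or SkipgramConfig()
    cfg.validate()
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    vocab = build_vocab(corpus, min_count=cfg.min_count)
    W, d = len(vocab), cfg.vector_size
    rng = np.random.default_rng(cfg.seed)

    # word2vec-style init: small uniform input vectors, zero output vectors
    U = ((rng.random((W, d)) - 0.5) / d).astype(np.float64)
    V = np.zeros((W, d), dtype=np.float64)

    sentences = [
        np.array([vocab.index[w] for w in sent if w in vocab], dtype=np.int64)
        for sent in corpus
    ]
    keep_prob = _keep_probability(vocab.counts, cfg.downsample)
    noise_cdf = _noise_cdf(vocab.counts)

    for epoch in range(cfg.epochs):
        centers, contexts = _epoch_pairs(sentences, keep_prob, cfg.window, rng)
        n_pairs = len(centers)
        for start in range(0, n_pairs, batch_pairs):
            progress = (epoch + start / max(n_pairs, 1)) / cfg.epochs
            lr = cfg.initial_lr + (cfg.min_lr - cfg.initial_lr) * progress
            c_idx = centers[start : start + batch_pairs]
            t_idx = contexts[start : start + batch_pairs]
            B = len(c_idx)
            neg = np.searchsorted(noise_cdf, rng.random((B, cfg.negatives)))
            targets = np.concatenate([t_idx[:, None], neg], axis=1)  # (B, 1+neg)
            labels = np.zeros((B, 1 + cfg.negatives))
            labels[:, 0] = 1.0

            Uc, Vt = U[c_idx], V[targets]
            u = np.einsum("bd,bjd->bj", Uc, Vt)
            g = expit(u) - labels  # d loss / d u
            # a noise draw that collides with the true context carries no signal
            g[:, 1:][neg == t_idx[:, None]] = 0.0

            dU = np.einsum("bj,bjd->bd", g, Vt)
            dV = (g[:, :, None] * Uc[:, None, :]).reshape(-1, d)
            _scatter_add(U, c_idx, -lr * dU)
            _scatter_add(V, targets.ravel(), -lr * dV)

    return EmbeddingTable(
        vocab=vocab,
        vectors=U.astype(np.float32),
        out_vectors=V.astype(np.float32),
        config=cfg,
    )


def complete_dna_vocab(table: EmbeddingTable, n: int = 3) -> EmbeddingTable:
    """Extend a table to the full closed DNA n-mer vocabulary (4^n words).

    Words absent from the training corpus receive small deterministic
    word2vec-style init vectors (zero output vectors), so every valid DNA
    sequence is embeddable while untrained words carry no learned signal.
    """
    from itertools import product

    all_words = ["".join(t) for t in product("ACGT", repeat=n)]
    missing = [w for w in all_words if w not in table.vocab]
    if not missing:
        return table
    d = table.dim
    extra = np.empty((len(missing), d), dtype=np.float32)
    for i, w in enumerate(missing):
        word_rng = np.random.default_rng([table.config.seed, all_words.index(w)])
        extra[i] = ((word_rng.random(d) - 0.5) / d).astype(np.float32)
    index = dict(table.vocab.index)
    for w in missing:
        index[w] = len(index)
    vocab = Vocab(index=index,
                  counts=np.concatenate([table.vocab.counts,
                                         np.zeros(len(missing), dtype=np.int64)]))
    return EmbeddingTable(
        vocab=vocab,
        vectors=np.vstack([table.vectors, extra]),
        out_vectors=np.vstack([table.out_vectors, np.zeros_like(extra)]),
        config=table.config,
    )


def embed_sequence(tokens: TokenSequence, table: EmbeddingTable) -> np.ndarray:
    """Map a token sequence to its d x N embedding matrix (one column per word)."""
    try:
        idx = [table.vocab.index[w] for w in tokens]
    except KeyError as exc:
        raise KeyError(f"token {exc.args[0]!r} not in vocabulary") from None
    return table.vectors[idx].T.copy()


class SkipgramEmbedder(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: DNA strings -> skip-gram embedding matrices.

    ``fit`` tokenizes the training sequences into overlapping n-mers and
    trains the embedding table on them alone; ``transform`` returns one
    float32 array of shape (vector_size, K - n + 1) per input sequence.

    Parameters mirror :class:`SkipgramConfig`.
    """

    def __init__(
        self,
        n: int = 3,
        vector_size: int = 20,
        window: int = 5,
        min_count: int = 1,
        initial_lr: float = 0.025,
        epochs: int = 51,
        negatives: int = 5,
        downsample: float = 1e-3,
        random_state: int = 0,
    ):
        self.n = n
        self.vector_size = vector_size
        self.window = window
        self.min_count = min_count
        self.initial_lr = initial_lr
        self.epochs = epochs
        self.negatives = negatives
        self.downsample = downsample
        self.random_state = random_state

    def _config(self) -> SkipgramConfig:
        return SkipgramConfig(
            vector_size=self.vector_size,
            window=self.window,
            min_count=self.min_count,
            initial_lr=self.initial_lr,
            epochs=self.epochs,
            negatives=self.negatives,
            downsample=self.downsample,
            seed=self.random_state,
        )

    def fit(self, X: Sequence[str], y=None) -> "SkipgramEmbedder":
        corpus = [tokenize(seq, self.n) for seq in X]
        # the DNA n-mer vocabulary is closed: complete it so prediction-time
        # sequences containing n-mers unseen in training remain embeddable
        self.table_ = complete_dna_vocab(train_skipgram(corpus, self._config()), self.n)
        self.n_words_ = len(self.table_.vocab)
        return self

    def transform(self, X: Sequence[str]) -> list[np.ndarray]:
        if not hasattr(self, "table_"):
            raise RuntimeError("SkipgramEmbedder is not fitted")
        return [embed_sequence(tokenize(seq, self.n), self.table_) for seq in X]
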