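"""Training and evaluation protocols for the enhancer classifier.

Covers the full experimental protocol: Adam on mean cross-entropy with
mini-batches and best-validation-epoch checkpointing, the standard enhancer
benchmark metrics (ACC, SN, SP, MCC, AUC), stratified k-fold cross-validation
with a per-fold retrained embedding (no test token ever enters embedding
training), multi-seed stability summaries, and the two-layer cascade that
first identifies enhancers and then grades their strength.

The central object is :class:`DualScaleAttentionClassifier`, an sklearn-style
estimator over raw DNA strings; the module-level functions are thin protocol
drivers around it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import roc_auc_score
from threadpoolctl import threadpool_limits

from .embedding import EmbeddingTable, SkipgramEmbedder, embed_sequence, tokenize
from .model_core import (
    Adam,
    ModelParams,
    batch_backward,
    batch_forward,
    cross_entropy,
    init_params,
    load_checkpoint,
    make_ablation,
    save_checkpoint,
    trainable_arrays,
)
from .sequence_io import Dataset, POSITIVE, NEGATIVE, split_folds

# internal class indices: forward's probability column 0 is the positive class
_POS_IDX, _NEG_IDX = 0, 1


@dataclass
class TrainConfig:
    """Optimization settings for one network training run."""

    batch_size: int = 64
    epochs: int = 50
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    patience: int | None = None  # early stopping on validation loss; None = off
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size/epochs must be >= 1 and learning_rate > 0")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")


class DivergedError(RuntimeError):
    """Training loss became non-finite."""


def _stratified_holdout(y_idx: np.ndarray, fraction: float, rng: np.random.Generator):
    """Per-class holdout indices of ~`fraction` of the data (at least 1 each)."""
    val: list[int] = []
    for cls in np.unique(y_idx):
        members = np.flatnonzero(y_idx == cls)
        n_val = max(1, int(round(fraction * len(members))))
        if n_val >= len(members):
            n_val = len(members) - 1
        val.extend(rng.permutation(members)[:n_val].tolist())
    val_idx = np.array(sorted(val), dtype=int)
    train_idx = np.setdiff1d(np.arange(len(y_idx)), val_idx)
    return train_idx, val_idx


def train_network(
    X: np.ndarray,
    y_idx: np.ndarray,
    params: ModelParams,
    cfg: TrainConfig,
) -> tuple[ModelParams, dict]:
    """Adam / cross-entropy training of ``params`` in place.

    ``X`` is the embedded batch (n, N, d); ``y_idx`` uses 0 = positive,
    1 = negative.  Returns the weights with the best validation loss (final
    weights when ``validation_fraction`` is 0) and the loss history.  BLAS is
    pinned to one thread for the duration so the run is a bit-reproducible
    pure function of (X order, cfg.seed) across machines.
    """
    with threadpool_limits(limits=1):
        return _train_network_impl(X, y_idx, params, cfg)


def _train_network_impl(
    X: np.ndarray,
    y_idx: np.ndarray,
    params: ModelParams,
    cfg: TrainConfig,
) -> tuple[ModelParams, dict]:
    cfg.validate()
    if len(np.unique(y_idx)) < 2:
        raise ValueError("training requires both classes present")
    rng = np.random.default_rng(cfg.seed)

    if cfg.validation_fraction > 0:
        train_idx, val_idx = _stratified_holdout(y_idx, cfg.validation_fraction, rng)
    else:
        train_idx, val_idx = np.arange(len(y_idx)), np.empty(0, dtype=int)
    X_tr, y_tr = X[train_idx], y_idx[train_idx]
    X_val, y_val = X[val_idx], y_idx[val_idx]

    opt = Adam(lr=cfg.learning_rate)
    arrays = trainable_arrays(params)
    history: dict = {"train_loss": [], "val_loss": [], "steps": 0}
    best: ModelParams | None = None
    best_val = math.inf
    since_best = 0

    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(X_tr))
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(perm), cfg.batch_size):
            sel = perm[start : start + cfg.batch_size]
            probs, cache = batch_forward(X_tr[sel], params, train=True)
            loss = cross_entropy(probs, y_tr[sel])
            if not math.isfinite(loss):
                raise DivergedError(
                    f"non-finite loss {loss} at epoch {epoch + 1}; "
                    f"lr={cfg.learning_rate}, batch={cfg.batch_size}"
                )
            grads = batch_backward(cache, y_tr[sel], params)
            opt.step(arrays, grads)
            history["steps"] += 1
            epoch_loss += loss * len(sel)
            seen += len(sel)
        history["train_loss"].append(epoch_loss / max(seen, 1))

        if len(val_idx):
            val_probs = batch_forward(X_val, params)
            val_loss = cross_entropy(val_probs, y_val)
            history["val_loss"].append(val_loss)
            if val_loss < best_val:
                best_val, best, since_best = val_loss, params.copy(), 0
            else:
                since_best += 1
                if cfg.patience is not None and since_best >= cfg.patience:
                    break
    final = best if best is not None else params
    return final, history


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """Confusion counts and the five benchmark metrics for one evaluation.

    ``acc``, ``sn``, ``sp`` and ``auc`` are stored as fractions in [0, 1]
    (conventionally reported as percentages); ``mcc`` lies in [-1, 1].
    """

    counts: ConfusionCounts
    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.counts.tp, "fp": self.counts.fp,
            "tn": self.counts.tn, "fn": self.counts.fn,
            "acc_pct": round(100 * self.acc, 2),
            "sn_pct": round(100 * self.sn, 2),
            "sp_pct": round(100 * self.sp, 2),
            "mcc": round(self.mcc, 3),
        }
        if self.auc is not None:
            d["auc_pct"] = round(100 * self.auc, 2)
        return d

    def __str__(self) -> str:
        parts = [
            f"ACC {100 * self.acc:.2f}%", f"MCC {self.mcc:.3f}",
            f"SN {100 * self.sn:.2f}%", f"SP {100 * self.sp:.2f}%",
        ]
        if self.auc is not None:
            parts.append(f"AUC {100 * self.auc:.2f}%")
        return "  ".join(parts)


def confusion(
    scores: Sequence[float],
    labels: Sequence[str],
    threshold: float = 0.5,
    positive_label: str = POSITIVE,
) -> ConfusionCounts:
    """Tally a confusion table; a score exactly at the threshold predicts positive."""
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    if len(scores) == 0:
        raise ValueError("empty input")
    tp = fp = tn = fn = 0
    for s, lab in zip(scores, labels):
        pred_pos = s >= threshold
        is_pos = lab == positive_label
        if pred_pos and is_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif is_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> EvalReport:
    """ACC, SN, SP and MCC from confusion counts.

    ACC = (TP+TN)/total; SN = TP/(TP+FN); SP = TN/(TN+FP);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0
    whenever a denominator factor vanishes.  SN/SP are 0 when their class is
    absent.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    acc = (c.tp + c.tn) / c.total
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    return EvalReport(counts=c, acc=acc, sn=sn, sp=sp, mcc=mcc)


def auc(scores: Sequence[float], labels: Sequence[str], positive_label: str = POSITIVE) -> float:
    """Area under the ROC curve (trapezoidal; equals the tie-corrected
    Mann-Whitney rank statistic)."""
    y = np.asarray([1 if lab == positive_label else 0 for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[str],
    threshold: float = 0.5,
    positive_label: str = POSITIVE,
) -> EvalReport:
    """Confusion counts + all five metrics from continuous positive-class scores."""
    rep = metrics(confusion(scores, labels, threshold, positive_label))
    try:
        rep.auc = auc(scores, labels, positive_label)
    except ValueError:
        rep.auc = None
    return rep


# ---------------------------------------------------------------------------
# the estimator


class DualScaleAttentionClassifier(ClassifierMixin, BaseEstimator):
    """Enhancer sequence classifier: 3-mer skip-gram embedding, dual-scale
    convolution fusion, spatial attention, max-pool + softmax head.

    ``fit`` takes raw DNA strings (all of one length) and their class labels,
    trains the word embedding on the training sequences only, freezes it, and
    trains the network with Adam on cross-entropy.  ``predict_proba`` accepts
    sequences of any admissible length (the network is fully convolutional).

    Parameters
    ----------
    kernel_sizes : filter widths of the parallel convolution branches.
    n_filters : filters per branch (the reference architecture uses 1024).
    ablation : one of ``-SS1``, ``-SS2``, ``-SA``, ``-SS1-SS2-SA`` or None.
    embedding : optional pre-fitted :class:`SkipgramEmbedder` or
        :class:`EmbeddingTable` to share one table across models; when None a
        fresh embedding is trained on the fit data.
    positive_label : label treated as the positive class; defaults to
        ``"positive"`` when present, else the lexicographically larger class.
    Remaining parameters mirror :class:`TrainConfig` and
    :class:`~enhancerscan.embedding.SkipgramConfig`.
    """

    def __init__(
        self,
        kernel_sizes: tuple[int, ...] = (10, 12),
        n_filters: int = 1024,
        attention_kernel: int = 7,
        use_attention: bool = True,
        ablation: str | None = None,
        embedding_dim: int = 20,
        skipgram_epochs: int = 51,
        skipgram_window: int = 5,
        embedding=None,
        batch_size: int = 64,
        epochs: int = 50,
        learning_rate: float = 1e-3,
        validation_fraction: float = 0.1,
        patience: int | None = None,
        positive_label: str | None = None,
        random_state: int = 0,
    ):
        self.kernel_sizes = kernel_sizes
        self.n_filters = n_filters
        self.attention_kernel = attention_kernel
        self.use_attention = use_attention
        self.ablation = ablation
        self.embedding_dim = embedding_dim
        self.skipgram_epochs = skipgram_epochs
        self.skipgram_window = skipgram_window
        self.embedding = embedding
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.positive_label = positive_label
        self.random_state = random_state

    # -- embedding handling -------------------------------------------------

    def _resolve_table(self, X: Sequence[str]) -> EmbeddingTable:
        if isinstance(self.embedding, EmbeddingTable):
            return self.embedding
        if isinstance(self.embedding, SkipgramEmbedder):
            if not hasattr(self.embedding, "table_"):
                raise ValueError("a pre-supplied SkipgramEmbedder must be fitted")
            return self.embedding.table_
        if self.embedding is not None:
            raise TypeError("embedding must be an EmbeddingTable, a fitted "
                            "SkipgramEmbedder, or None")
        embedder = SkipgramEmbedder(
            vector_size=self.embedding_dim,
            window=self.skipgram_window,
            epochs=self.skipgram_epochs,
            random_state=self.random_state,
        ).fit(X)
        return embedder.table_

    def _embed_stack(self, X: Sequence[str]) -> np.ndarray:
        lengths = {len(s) for s in X}
        if len(lengths) != 1:
            raise ValueError("all sequences in one embedded batch must share a length")
        mats = [embed_sequence(tokenize(s), self.embedding_table_) for s in X]
        return np.stack([m.T for m in mats]).astype(np.float32)  # (B, N, d)

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X: Sequence[str], y: Sequence[str]) -> "DualScaleAttentionClassifier":
        X = list(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y differ in length")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes, got {self.classes_!r}")
        if self.positive_label is not None:
            pos = self.positive_label
            if pos not in self.classes_:
                raise ValueError(f"positive_label {pos!r} not among classes {self.classes_!r}")
        else:
            pos = POSITIVE if POSITIVE in self.classes_ else self.classes_[1]
        self.positive_label_ = pos

        self.embedding_table_ = self._resolve_table(X)
        self.n_corpus_sequences_ = None if self.embedding is not None else len(X)
        X_emb = self._embed_stack(X)
        y_idx = np.where(y == pos, _POS_IDX, _NEG_IDX)

        min_len = X_emb.shape[1]
        if not self.ablation == "-SS1-SS2-SA" and min_len < max(self.kernel_sizes):
            raise ValueError(
                f"tokenized length {min_len} shorter than widest kernel "
                f"{max(self.kernel_sizes)}"
            )

        params = init_params(
            embedding_dim=self.embedding_dim,
            kernel_sizes=self.kernel_sizes,
            n_filters=self.n_filters,
            attention_kernel=self.attention_kernel,
            use_attention=self.use_attention,
            seed=self.random_state,
        )
        if self.ablation is not None:
            params = make_ablation(params, self.ablation, seed=self.random_state)

        cfg = TrainConfig(
            batch_size=self.batch_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            validation_fraction=self.validation_fraction,
            patience=self.patience,
            seed=self.random_state,
        )
        self.params_, self.history_ = train_network(X_emb, y_idx, params, cfg)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("classifier is not fitted")

    def decision_scores(self, X: Sequence[str]) -> np.ndarray:
        """Positive-class probabilities, accepting mixed sequence lengths."""
        self._check_fitted()
        X = list(X)
        out = np.empty(len(X), dtype=float)
        by_len: dict[int, list[int]] = {}
        for i, s in enumerate(X):
            by_len.setdefault(len(s), []).append(i)
        with threadpool_limits(limits=1):  # bit-reproducible scoring
            for idx in by_len.values():
                emb = self._embed_stack([X[i] for i in idx])
                probs = batch_forward(emb, self.params_)
                out[idx] = probs[:, _POS_IDX]
        return out

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        p_pos = self.decision_scores(X)
        proba = np.empty((len(p_pos), 2), dtype=float)
        pos_col = int(np.flatnonzero(self.classes_ == self.positive_label_)[0])
        proba[:, pos_col] = p_pos
        proba[:, 1 - pos_col] = 1.0 - p_pos
        return proba

    def predict(self, X: Sequence[str]) -> np.ndarray:
        p_pos = self.decision_scores(X)
        neg = [c for c in self.classes_ if c != self.positive_label_][0]
        return np.where(p_pos >= 0.5, self.positive_label_, neg)

    def evaluate(self, X: Sequence[str], y: Sequence[str]) -> EvalReport:
        return evaluate_scores(self.decision_scores(X), list(y),
                               positive_label=self.positive_label_)

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Self-describing checkpoint: weights (.npz + .json) and the embedding
        table in word2vec text format."""
        self._check_fitted()
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_checkpoint(
            self.params_,
            directory / "model.npz",
            extra_meta={
                "classes": [str(c) for c in self.classes_],
                "positive_label": str(self.positive_label_),
                "estimator_params": {
                    k: v for k, v in self.get_params().items()
                    if isinstance(v, (int, float, str, bool, tuple, list, type(None)))
                },
            },
        )
        self.embedding_table_.save_word2vec(directory / "embedding.w2v")

    @classmethod
    def load(cls, directory: str | Path) -> "DualScaleAttentionClassifier":
        directory = Path(directory)
        params, meta = load_checkpoint(directory / "model.npz")
        est_params = dict(meta.get("estimator_params", {}))
        est_params.pop("embedding", None)
        if "kernel_sizes" in est_params:
            est_params["kernel_sizes"] = tuple(est_params["kernel_sizes"])
        obj = cls(**est_params)
        obj.params_ = params
        obj.classes_ = np.asarray(meta["classes"])
        obj.positive_label_ = meta["positive_label"]
        obj.embedding_table_ = EmbeddingTable.load_word2vec(directory / "embedding.w2v")
        obj.history_ = {}
        return obj


def train(
    ds: Dataset,
    table: EmbeddingTable,
    arch: ModelParams,
    cfg: TrainConfig,
) -> ModelParams:
    """Protocol-level training: dataset + fixed embedding table -> weights."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    X = np.stack(
        [embed_sequence(tokenize(r.seq), table).T for r in ds.records]
    ).astype(np.float32)
    y_idx = np.where(np.asarray(ds.labels) == POSITIVE, _POS_IDX, _NEG_IDX)
    fitted, _ = train_network(X, y_idx, arch, cfg)
    return fitted


# ---------------------------------------------------------------------------
# protocols


@dataclass
class CVReport:
    folds: list[EvalReport]

    @property
    def mean(self) -> dict[str, float]:
        out = {
            "acc": float(np.mean([f.acc for f in self.folds])),
            "sn": float(np.mean([f.sn for f in self.folds])),
            "sp": float(np.mean([f.sp for f in self.folds])),
            "mcc": float(np.mean([f.mcc for f in self.folds])),
        }
        aucs = [f.auc for f in self.folds if f.auc is not None]
        if aucs:
            out["auc"] = float(np.mean(aucs))
        return out


def cross_validate(
    ds: Dataset,
    clf: DualScaleAttentionClassifier,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> CVReport:
    """k-fold cross-validation with a leakage guard.

    Each fold trains a fresh clone of ``clf`` on the other k-1 parts; because
    the clone fits its own embedding on its training sequences, no held-out
    token ever enters embedding training.  Record ids must be unique so fold
    provenance can be asserted.
    """
    assignment = split_folds(ds, k=k, seed=seed, stratified=stratified)
    ids = [r.id for r in ds.records]
    if len(set(ids)) != len(ids):
        raise ValueError("cross-validation requires unique record ids")
    folds: list[EvalReport] = []
    for fold in range(1, k + 1):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        train_ds, test_ds = ds.subset(train_idx), ds.subset(test_idx)
        if {r.id for r in train_ds.records} & {r.id for r in test_ds.records}:
            raise AssertionError("fold leakage: a record appears on both sides")
        fold_clf = clone(clf)
        if fold_clf.embedding is None:
            # embedding is retrained per fold on the training portion only
            pass
        fold_clf.fit(train_ds.sequences, train_ds.labels)
        folds.append(fold_clf.evaluate(test_ds.sequences, test_ds.labels))
    return CVReport(folds=folds)


def seed_stability(
    ds_train: Dataset,
    ds_test: Dataset,
    clf: DualScaleAttentionClassifier,
    seeds: Sequence[int],
    population_variance: bool = True,
) -> dict:
    """Train once per seed, evaluate on the fixed test set, summarize spread.

    Returns per-seed reports plus mean and (population, by default) variance
    of ACC and MCC.
    """
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds")
    reports: list[EvalReport] = []
    for s in seeds:
        run = clone(clf)
        run.set_params(random_state=int(s))
        run.fit(ds_train.sequences, ds_train.labels)
        reports.append(run.evaluate(ds_test.sequences, ds_test.labels))
    ddof = 0 if population_variance else 1
    accs = np.array([r.acc for r in reports])
    mccs = np.array([r.mcc for r in reports])

    def _var(x: np.ndarray) -> float:
        # shift-invariant form: exactly 0 when all runs coincide
        return float((x - x[0]).var(ddof=ddof))

    return {
        "seeds": list(map(int, seeds)),
        "reports": reports,
        "acc_mean": float(accs.mean()),
        "acc_var": _var(accs),
        "mcc_mean": float(mccs.mean()),
        "mcc_var": _var(mccs),
    }


LAYER1_POS, LAYER1_NEG = "enhancer", "non-enhancer"
LAYER2_POS, LAYER2_NEG = "strong enhancer", "weak enhancer"


def two_layer_predict(
    sequences: Sequence[str],
    model1: DualScaleAttentionClassifier,
    model2: DualScaleAttentionClassifier,
) -> list[str]:
    """Cascade prediction: classifier I gates enhancers, classifier II grades
    the gated ones as strong or weak.

    Returns one of {"non-enhancer", "weak enhancer", "strong enhancer"} per
    sequence.  Per-layer isolated evaluation is simply ``model.evaluate`` on
    the corresponding labeled set.
    """
    sequences = list(sequences)
    d1 = model1.embedding_table_.dim
    d2 = model2.embedding_table_.dim
    if d1 != d2:
        raise ValueError(f"incompatible embedding dimensions: {d1} vs {d2}")
    out = [LAYER1_NEG] * len(sequences)
    gate = model1.decision_scores(sequences) >= 0.5
    passed = [i for i, g in enumerate(gate) if g]
    if passed:
        strong = model2.decision_scores([sequences[i] for i in passed]) >= 0.5
        for i, is_strong in zip(passed, strong):
            out[i] = LAYER2_POS if is_strong else LAYER2_NEG
    return out
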