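"""Reading, validating, writing and partitioning labeled DNA sequence sets.

Sequences are plain FASTA over the {A, C, G, T} alphabet.  Class labels are
not carried in-band by the benchmark-style data this package targets, so they
are supplied per file (one FASTA per class) or, as a fallback, as a
``label=<tag>`` token in the FASTA header.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import KFold, StratifiedKFold

ALPHABET = "ACGT"

#: Shortest admissible sequence: 3-mer tokenization yields K - 2 words and the
#: widest default convolution filter spans 12 words, so K >= 14.
MIN_LENGTH = 14

POSITIVE = "positive"
NEGATIVE = "negative"

Layer = Literal["identification", "classification"]


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled DNA sequence."""

    id: str
    seq: str
    label: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Dataset:
    """A labeled collection of sequences for one classification layer.

    ``layer`` records which biological question the labels answer:
    ``identification`` (enhancer vs. non-enhancer) or ``classification``
    (strong vs. weak enhancer).  Class counts are always recomputed from the
    records, never cached.
    """

    records: list[SequenceRecord]
    layer: Layer = "identification"

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(collections.Counter(r.label for r in self.records))

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, indices: Iterable[int]) -> "Dataset":
        idx = list(indices)
        return Dataset([self.records[i] for i in idx], layer=self.layer)


class InvalidSequenceError(ValueError):
    """A sequence violates the ACGT alphabet or the minimum-length contract."""


def read_fasta(path: str | Path, label: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into records, optionally assigning one class label.

    The header token up to the first whitespace becomes the record id.  When
    ``label`` is None, a ``label=<tag>`` key in the header description is used
    as a fallback label source.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_label = label
        if rec_label is None:
            for token in rec.description.split():
                if token.startswith("label="):
                    rec_label = token[len("label="):]
                    break
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), label=rec_label))
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as standard FASTA with 60-column line wrapping."""
    bio_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=f"label={r.label}" if r.label else "")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(bio_records)


def validate_record(
    rec: SequenceRecord,
    policy: str = "reject",
    seed: int | None = None,
) -> SequenceRecord:
    """Return a record satisfying the alphabet and length invariants.

    Lower-case letters are upper-cased.  Characters outside {A,C,G,T} either
    raise (``policy="reject"``) or are replaced by a uniformly drawn base
    (``policy="resample"``, reproducible from ``seed``).
    """
    seq = rec.seq.upper()
    bad = [i for i, ch in enumerate(seq) if ch not in ALPHABET]
    if bad:
        if policy == "reject":
            raise InvalidSequenceError(
                f"record {rec.id!r}: non-ACGT character {seq[bad[0]]!r} "
                f"at position {bad[0] + 1}"
            )
        elif policy == "resample":
            rng = np.random.default_rng(seed)
            chars = list(seq)
            for i in bad:
                chars[i] = ALPHABET[rng.integers(4)]
            seq = "".join(chars)
        else:
            raise ValueError(f"unknown policy {policy!r}")
    if len(seq) < MIN_LENGTH:
        raise InvalidSequenceError(
            f"record {rec.id!r}: length {len(seq)} < minimum {MIN_LENGTH}"
        )
    return replace(rec, seq=seq)


def validate_dataset(ds: Dataset, policy: str = "reject", seed: int | None = None) -> Dataset:
    return Dataset(
        [validate_record(r, policy=policy, seed=seed) for r in ds.records],
        layer=ds.layer,
    )


def split_folds(
    ds: Dataset,
    k: int,
    seed: int = 0,
    stratified: bool = True,
) -> np.ndarray:
    """Assign each record to one of ``k`` cross-validation folds (1..k).

    Folds are disjoint, cover all records and differ in size by at most one
    (per class when ``stratified``).  The assignment is a pure function of
    ``(ds, k, seed, stratified)``.
    """
    n = len(ds)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    assignment = np.zeros(n, dtype=int)
    if stratified:
        labels = np.asarray(ds.labels)
        counts = collections.Counter(labels.tolist())
        if min(counts.values()) < k:
            raise ValueError("every class needs at least k members for stratified folds")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        index_iter = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        index_iter = splitter.split(np.zeros(n))
    for fold, (_, test_idx) in enumerate(index_iter, start=1):
        assignment[test_idx] = fold
    return assignment


def train_test_split_dataset(
    ds: Dataset, test_fraction: float, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Stratified train/test split, deterministic in ``seed``."""
    k = max(2, round(1.0 / test_fraction))
    folds = split_folds(ds, k=k, seed=seed, stratified=True)
    test_idx = np.flatnonzero(folds == 1)
    train_idx = np.flatnonzero(folds != 1)
    return ds.subset(train_idx), ds.subset(test_idx)


def write_predictions(
    path: str | Path,
    ids: Sequence[str],
    scores: Sequence[float],
    predicted: Sequence[str],
) -> None:
    """Tab-separated prediction file: one row per sequence (id, score, class)."""
    with open(path, "w") as fh:
        fh.write("id\tscore\tpredicted_class\n")
        for i, s, p in zip(ids, scores, predicted):
            fh.write(f"{i}\t{s:.6f}\t{p}\n")
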