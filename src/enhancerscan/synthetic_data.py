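"""Synthetic enhancer-like sequence datasets with planted motifs.

The generator emulates the layout of the two-layer enhancer benchmark —
balanced classes of fixed-length (200 nt) sequences — while giving exact
ground truth: negatives are pure i.i.d. background, positives carry motif
instances sampled column-wise from position-weight matrices (PWMs) at known
locations.  The strong/weak distinction of the second layer is modelled as a
dosage-and-fidelity difference: strong sequences receive two faithful motif
instances, weak sequences a single instance from a noise-flattened PWM.

Motif lengths default to 10 and 12 nt, matching the two receptive-field
scales of the classifier, with an 8-nt fixture available for filter-size
experiments (transcription-factor binding motifs typically span 5-30 bp).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .sequence_io import ALPHABET, Dataset, NEGATIVE, POSITIVE, SequenceRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class MotifSpec:
    """A motif as a 4 x length position-weight matrix (rows A, C, G, T)."""

    name: str
    pwm: np.ndarray

    def __post_init__(self):
        pwm = np.asarray(self.pwm, dtype=float)
        if pwm.shape[0] != 4 or pwm.shape[1] < 4:
            raise ValueError("PWM must be 4 x length with length >= 4")
        if not np.allclose(pwm.sum(axis=0), 1.0):
            raise ValueError("PWM columns must sum to 1")
        if (pwm < 0).any():
            raise ValueError("PWM entries must be nonnegative")
        object.__setattr__(self, "pwm", pwm)

    @property
    def length(self) -> int:
        return self.pwm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.pwm.argmax(axis=0))

    @classmethod
    def from_consensus(cls, name: str, consensus: str, fidelity: float = 0.95) -> "MotifSpec":
        """PWM that emits the consensus base with probability ``fidelity`` and
        the three alternatives uniformly otherwise."""
        if not 0.25 <= fidelity <= 1.0:
            raise ValueError("fidelity must be in [0.25, 1]")
        L = len(consensus)
        pwm = np.full((4, L), (1.0 - fidelity) / 3.0)
        for j, ch in enumerate(consensus.upper()):
            pwm[ALPHABET.index(ch), j] = fidelity
        return cls(name=name, pwm=pwm)

    def flattened(self, alpha: float) -> "MotifSpec":
        """Mix the PWM with the uniform distribution: (1-alpha)*pwm + alpha/4."""
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        return MotifSpec(
            name=f"{self.name}_flat{alpha:g}",
            pwm=(1.0 - alpha) * self.pwm + alpha * 0.25,
        )

    @classmethod
    def from_text(cls, name: str, path: str | Path) -> "MotifSpec":
        """Load a PWM from a whitespace-separated 4 x length text matrix."""
        pwm = np.loadtxt(path)
        return cls(name=name, pwm=pwm)


def builtin_motifs() -> dict[str, MotifSpec]:
    """Small fixture motifs at the three studied lengths (8, 10, 12 nt)."""
    return {
        "cre8": MotifSpec.from_consensus("cre8", "TGACGTCA"),
        "ets10": MotifSpec.from_consensus("ets10", "CCGGAAGTGA"),
        "ebox12": MotifSpec.from_consensus("ebox12", "GGCCACGTGGCC"),
        "gata10": MotifSpec.from_consensus("gata10", "AGATAAGATC"),
    }


def default_motif_set() -> list[MotifSpec]:
    """The default planted families: one 10-nt and one 12-nt motif."""
    m = builtin_motifs()
    return [m["ets10"], m["ebox12"]]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the benchmark layout: balanced classes of 200-nt
    sequences over a uniform background, 1484 sequences per class in
    identification mode (742 strong + 742 weak in classification mode uses
    ``n_per_class=742``).
    """

    n_per_class: int = 1484
    length: int = 200
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motifs: list[MotifSpec] = field(default_factory=default_motif_set)
    positive_insertions: int = 1  # identification mode dosage
    strong_insertions: int = 2  # classification mode: strong dosage
    weak_insertions: int = 1  # classification mode: weak dosage
    weak_noise: float = 0.3  # PWM flattening for the weak class
    disjoint_families: bool = False  # each motif family in its own half of positives
    reverse_complement: bool = False  # plant the reverse complement w.p. 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        comp = np.asarray(self.background, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or not np.isclose(comp.sum(), 1.0):
            raise ValueError("background composition must be 4 nonnegative values summing to 1")
        if any(m.length > self.length for m in self.motifs):
            raise ValueError("motif longer than sequence length")


@dataclass(frozen=True)
class MotifPlacement:
    """Ground-truth interval of one planted motif, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    motif: str


@dataclass
class SimResult:
    dataset: Dataset
    truth: list[MotifPlacement]
    config: SimConfig
    leakage_rate: float  # fraction of negatives containing a motif consensus

    def write(self, fasta_path: str | Path, truth_path: str | Path | None = None,
              config_path: str | Path | None = None) -> None:
        from .sequence_io import write_fasta

        write_fasta(self.dataset.records, fasta_path)
        if truth_path is not None:
            write_truth_tsv(self.truth, truth_path)
        if config_path is not None:
            with open(config_path, "w") as fh:
                json.dump(config_to_dict(self.config), fh, indent=2)


def sample_background(length: int, comp: Sequence[float], rng: np.random.Generator) -> str:
    """i.i.d. background sequence of the given length and base composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    comp = np.asarray(comp, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or not np.isclose(comp.sum(), 1.0):
        raise ValueError("invalid base composition")
    idx = rng.choice(4, size=length, p=comp / comp.sum())
    return "".join(ALPHABET[i] for i in idx)


def plant_motif(
    seq: str,
    motif: MotifSpec,
    rng: np.random.Generator,
    reverse_complement: bool = False,
    forbidden: Sequence[tuple[int, int]] = (),
) -> tuple[str, int]:
    """Replace a uniformly chosen window of ``seq`` with a PWM sample.

    Returns the modified sequence and the 0-based start position.  Windows
    overlapping any ``forbidden`` interval are rejected (used to keep
    multiple insertions disjoint); if no admissible position exists after
    exhausting candidates an error is raised.
    """
    L, m = len(seq), motif.length
    if m > L:
        raise ValueError(f"motif length {m} exceeds sequence length {L}")
    candidates = [
        p for p in range(L - m + 1)
        if all(p + m <= a or p >= b for a, b in forbidden)
    ]
    if not candidates:
        raise ValueError("no admissible insertion position left")
    pos = int(candidates[rng.integers(len(candidates))])
    instance = "".join(
        ALPHABET[rng.choice(4, p=motif.pwm[:, j])] for j in range(m)
    )
    if reverse_complement and rng.random() < 0.5:
        instance = instance.translate(_COMPLEMENT)[::-1]
    return seq[:pos] + instance + seq[pos + m:], pos


def _measure_leakage(negatives: list[SequenceRecord], motifs: Sequence[MotifSpec]) -> float:
    if not negatives:
        return 0.0
    hits = sum(
        1 for r in negatives if any(m.consensus in r.seq for m in motifs)
    )
    return hits / len(negatives)


def generate_dataset(
    cfg: SimConfig,
    layer: Literal["identification", "classification"] = "identification",
) -> SimResult:
    """Generate a balanced labeled dataset with exact motif ground truth.

    ``identification``: positives carry ``positive_insertions`` faithful
    motif instances, negatives are pure background.  ``classification``:
    positives are *strong* (``strong_insertions`` faithful instances),
    negatives are *weak* (``weak_insertions`` instances from the
    noise-flattened PWM).  Byte-identical output for identical config.
    """
    cfg.validate()
    if not cfg.motifs:
        raise ValueError("motif set must not be empty")
    rng = np.random.default_rng(cfg.seed)
    records: list[SequenceRecord] = []
    truth: list[MotifPlacement] = []

    def pick_motif(i_positive: int, pool: Sequence[MotifSpec]) -> MotifSpec:
        if cfg.disjoint_families and len(pool) > 1:
            family = 0 if i_positive < (cfg.n_per_class + 1) // 2 else 1
            return pool[family]
        return pool[rng.integers(len(pool))]

    def build(label: str, i: int, n_insert: int, pool: Sequence[MotifSpec]) -> SequenceRecord:
        sid = f"{layer[:5]}_{label}_{i:05d}"
        seq = sample_background(cfg.length, cfg.background, rng)
        placed: list[tuple[int, int]] = []
        for _ in range(n_insert):
            motif = pick_motif(i, pool)
            seq, pos = plant_motif(
                seq, motif, rng,
                reverse_complement=cfg.reverse_complement,
                forbidden=placed,
            )
            placed.append((pos, pos + motif.length))
            truth.append(MotifPlacement(sid, pos, pos + motif.length, motif.name))
        return SequenceRecord(id=sid, seq=seq, label=label)

    if layer == "identification":
        pos_pool = cfg.motifs
        for i in range(cfg.n_per_class):
            records.append(build(POSITIVE, i, cfg.positive_insertions, pos_pool))
        for i in range(cfg.n_per_class):
            records.append(build(NEGATIVE, i, 0, cfg.motifs))
    elif layer == "classification":
        weak_pool = [m.flattened(cfg.weak_noise) for m in cfg.motifs]
        for i in range(cfg.n_per_class):
            records.append(build(POSITIVE, i, cfg.strong_insertions, cfg.motifs))
        for i in range(cfg.n_per_class):
            records.append(build(NEGATIVE, i, cfg.weak_insertions, weak_pool))
    else:
        raise ValueError(f"unknown layer {layer!r}")

    negatives = [r for r in records if r.label == NEGATIVE] if layer == "identification" else []
    leakage = _measure_leakage(negatives, cfg.motifs)
    return SimResult(
        dataset=Dataset(records, layer=layer),
        truth=truth,
        config=cfg,
        leakage_rate=leakage,
    )


def write_truth_tsv(truth: Sequence[MotifPlacement], path: str | Path) -> None:
    """BED-like ground truth: sequence id, start, end (0-based half-open), motif."""
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.seq_id}\t{t.start}\t{t.end}\t{t.motif}\n")


def config_to_dict(cfg: SimConfig) -> dict:
    return {
        "n_per_class": cfg.n_per_class,
        "length": cfg.length,
        "background": list(cfg.background),
        "motifs": [
            {"name": m.name, "consensus": m.consensus, "length": m.length}
            for m in cfg.motifs
        ],
        "positive_insertions": cfg.positive_insertions,
        "strong_insertions": cfg.strong_insertions,
        "weak_insertions": cfg.weak_insertions,
        "weak_noise": cfg.weak_noise,
        "disjoint_families": cfg.disjoint_families,
        "reverse_complement": cfg.reverse_complement,
        "seed": cfg.seed,
    }
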