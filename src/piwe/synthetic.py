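"""Synthetic labeled sequence sets with controllable class signal.

The generator emulates the gross statistics of transposon-derived piRNA
collections without any download: short sequences (16-35 nt, lengths peaked
at 30), a 5'-uridine bias in the positive class, one enriched sequence motif,
and a mild first-order compositional autocorrelation in positives (the
analogue of the U/A-richness of real piRNAs). A toy transposon library that
contains every generated sequence as an exact substring is emitted alongside,
so the dataset-builder's <=3-mismatch transposon filter passes by
construction.

Setting ``motif_prob=0``, ``markov_bias=0`` and equal 5' probabilities yields
the null condition: no channel separates the classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError
from .seqio import LabeledDataset, Sequence

BASES = "ACGT"
MIN_LEN, MAX_LEN = 16, 35


def peaked_length_probs(peak: int = 30, sd: float = 3.0) -> np.ndarray:
    """Discretized Gaussian over [16, 35], the piRNA-like length profile."""
    lengths = np.arange(MIN_LEN, MAX_LEN + 1)
    p = np.exp(-0.5 * ((lengths - peak) / sd) ** 2)
    return p / p.sum()


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; the defaults define the standard study condition."""

    n_pos: int = 500
    n_neg: int = 500
    length_probs: np.ndarray = field(default_factory=peaked_length_probs)
    five_prime_u_pos: float = 0.8
    five_prime_u_neg: float = 0.25
    motif: str = "TGCAT"
    motif_prob: float = 0.7
    markov_bias: float = 0.18   # positive-class self-transition excess
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    transposon_chunk: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lp = np.asarray(self.length_probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if lp.shape != (MAX_LEN - MIN_LEN + 1,) or np.any(lp < 0) or not np.isclose(lp.sum(), 1):
            raise ValidationError("length_probs must be a distribution over [16, 35]")
        if bg.shape != (4,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1):
            raise ValidationError("background must be a distribution over A,C,G,T")
        for name in ("five_prime_u_pos", "five_prime_u_neg", "motif_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.markov_bias <= 0.75:
            raise ValidationError("markov_bias must be in [0, 0.75]")
        if set(self.motif) - set(BASES):
            raise ValidationError("motif must be over A,C,G,T")
        object.__setattr__(self, "length_probs", lp)
        object.__setattr__(self, "background", bg)


def null_spec(**overrides) -> SyntheticSpec:
    """The no-signal control: all class-discriminating channels switched off."""
    base = SyntheticSpec(motif_prob=0.0, markov_bias=0.0,
                         five_prime_u_pos=0.25, five_prime_u_neg=0.25)
    return replace(base, **overrides)


def _markov_matrix(background: np.ndarray, bias: float) -> np.ndarray:
    """Self-transition excess `bias` on top of the background, rows normalized."""
    T = np.tile(background, (4, 1))
    T += bias * np.eye(4)
    T -= bias / 3 * (1 - np.eye(4)) * (background > 0)
    T = np.clip(T, 1e-9, None)
    return T / T.sum(axis=1, keepdims=True)


def _draw_sequence(
    rng: np.random.Generator,
    length: int,
    five_prime_u: float,
    background: np.ndarray,
    transition: np.ndarray | None,
) -> str:
    letters = np.empty(length, dtype=int)
    if rng.uniform() < five_prime_u:
        letters[0] = 3  # T (the DNA representation of 5' U)
    else:
        non_t = background[:3] / background[:3].sum()
        letters[0] = rng.choice(3, p=non_t)
    for i in range(1, length):
        p = transition[letters[i - 1]] if transition is not None else background
        letters[i] = rng.choice(4, p=p)
    return "".join(BASES[c] for c in letters)


def _insert_motif(rng: np.random.Generator, residues: str, motif: str) -> str:
    # keep position 1 intact so the 5' channel stays independent of the motif
    lo, hi = 1, len(residues) - len(motif)
    if hi < lo:
        return residues
    start = int(rng.integers(lo, hi + 1))
    return residues[:start] + motif + residues[start + len(motif):]


def generate_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, list[Sequence]]:
    """Generate the labeled dataset and its covering toy transposon library."""
    rng = np.random.default_rng(spec.rng_seed)
    lengths = np.arange(MIN_LEN, MAX_LEN + 1)
    transition = _markov_matrix(spec.background, spec.markov_bias) \
        if spec.markov_bias > 0 else None

    sequences: list[Sequence] = []
    labels = []
    for i in range(spec.n_pos):
        L = int(rng.choice(lengths, p=spec.length_probs))
        res = _draw_sequence(rng, L, spec.five_prime_u_pos, spec.background, transition)
        if rng.uniform() < spec.motif_prob:
            res = _insert_motif(rng, res, spec.motif)
        sequences.append(Sequence(f"pos_{i + 1:05d}", res))
        labels.append(1)
    for i in range(spec.n_neg):
        L = int(rng.choice(lengths, p=spec.length_probs))
        res = _draw_sequence(rng, L, spec.five_prime_u_neg, spec.background, None)
        sequences.append(Sequence(f"neg_{i + 1:05d}", res))
        labels.append(0)

    # transposon library: concatenate all residues into ~transposon_chunk-nt
    # records so every sequence is an exact substring of some record
    transposons: list[Sequence] = []
    buf: list[str] = []
    size = 0
    for seq in sequences:
        buf.append(seq.residues)
        size += len(seq)
        if size >= spec.transposon_chunk:
            transposons.append(Sequence(f"tn_{len(transposons) + 1:03d}", "".join(buf)))
            buf, size = [], 0
    if buf:
        transposons.append(Sequence(f"tn_{len(transposons) + 1:03d}", "".join(buf)))

    return LabeledDataset(sequences, np.array(labels)), transposons
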