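"""Sequence-derived feature encoders for short non-coding RNA classification.

Each encoder maps a DNA sequence onto a fixed-length real vector. The default
catalog holds 22 feature families, indexed in a fixed order that also defines
the base-learner index of the ensemble:

==========  =====================================  =========
family      parameters (defaults)                  dimension
==========  =====================================  =========
spectrum    k = 1..5                               4^k
mismatch    (k, m) = (3,1), (4,1), (5,1)           4^k
subsequence (k, w) = (3,1), (4,1), (5,1)           4^k
revckmer    k = 1..5                               see below
pse         PC/SC di-/trinucleotide, lam=1, w=0.1  16+lam, 64+lam,
                                                   16+6*lam, 64+12*lam
sparse      d = 35                                 5*d
pssm        d = 35                                 d
==========  =====================================  =========

Occurrence profiles (spectrum, mismatch, subsequence, revckmer) are
frequency-normalized so variable-length sequences are comparable. k-mers are
indexed lexicographically with A<C<G<T; the one-hot letter order is
(A, C, G, T, E) where E is the null padding letter of the fixed-length
encodings.

The reverse-complement k-mer dimension is the equivalence-class count
(4^k + 4^{k/2})/2 for even k and 4^k/2 for odd k (2, 10, 32, 136, 512 for
k = 1..5).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence as TSequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    ParameterError,
    ValidationError,
)
from .seqio import Sequence

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# tuned defaults: max mismatches, gap penalty, correlation rank, fixed length
DEFAULT_M = 1
DEFAULT_W = 1.0
DEFAULT_LAMBDA = 1
DEFAULT_D = 35
DEFAULT_PSE_WEIGHT = 0.1

FamilyName = Literal[
    "spectrum", "mismatch", "subsequence", "revckmer",
    "pc_pse_dnc", "pc_pse_tnc", "sc_pse_dnc", "sc_pse_tnc",
    "sparse", "pssm",
]


def _encode(residues: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in residues), dtype=np.int64,
                       count=len(residues))


def kmer_list(k: int) -> list[str]:
    """All k-mers in lexicographic A<C<G<T order."""
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def revc_kmer_dimension(k: int) -> int:
    """Number of {kmer, revcomp} equivalence classes."""
    if k % 2 == 0:
        return (4**k + 4 ** (k // 2)) // 2
    return 4**k // 2


# ---------------------------------------------------------------------------
# Feature specs and the default 22-family catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """One encoder family plus its parameters and declared output dimension."""

    name: str
    family: FamilyName
    k: int = 0
    m: int = 0
    w: float = DEFAULT_W
    lam: int = DEFAULT_LAMBDA
    d: int = DEFAULT_D
    pse_weight: float = DEFAULT_PSE_WEIGHT
    dimension: int = 0

    def __post_init__(self) -> None:
        if self.family == "mismatch" and not self.m < self.k:
            raise ParameterError(f"{self.name}: need m < k, got m={self.m} k={self.k}")
        if self.family == "subsequence" and not 0.0 <= self.w <= 1.0:
            raise ParameterError(f"{self.name}: gap penalty w must be in [0,1]")
        if self.lam < 1:
            raise ParameterError(f"{self.name}: lam must be >= 1")
        expected = _expected_dimension(self)
        if self.dimension == 0:
            object.__setattr__(self, "dimension", expected)
        elif self.dimension != expected:
            raise ParameterError(
                f"{self.name}: declared dimension {self.dimension} != "
                f"closed-form {expected}"
            )


def _expected_dimension(spec: FeatureSpec) -> int:
    fam = spec.family
    if fam in ("spectrum", "mismatch", "subsequence"):
        return 4**spec.k
    if fam == "revckmer":
        return revc_kmer_dimension(spec.k)
    if fam == "pc_pse_dnc":
        return 16 + spec.lam
    if fam == "pc_pse_tnc":
        return 64 + spec.lam
    if fam == "sc_pse_dnc":
        return 16 + 6 * spec.lam
    if fam == "sc_pse_tnc":
        return 64 + 12 * spec.lam
    if fam == "sparse":
        return 5 * spec.d
    if fam == "pssm":
        return spec.d
    raise ParameterError(f"unknown family {fam!r}")


def default_catalog(
    m: int = DEFAULT_M,
    w: float = DEFAULT_W,
    lam: int = DEFAULT_LAMBDA,
    d: int = DEFAULT_D,
    pse_weight: float = DEFAULT_PSE_WEIGHT,
) -> list[FeatureSpec]:
    """The 22-family default catalog; list order defines base-learner index."""
    specs: list[FeatureSpec] = []
    for k in range(1, 6):
        specs.append(FeatureSpec(f"spectrum{k}", "spectrum", k=k))
    for k in range(3, 6):
        specs.append(FeatureSpec(f"mismatch{k}_{m}", "mismatch", k=k, m=m))
    for k in range(3, 6):
        specs.append(FeatureSpec(f"subseq{k}_w{w:g}", "subsequence", k=k, w=w))
    for k in range(1, 6):
        specs.append(FeatureSpec(f"revckmer{k}", "revckmer", k=k))
    specs.append(FeatureSpec("pc_pse_dnc", "pc_pse_dnc", lam=lam, pse_weight=pse_weight))
    specs.append(FeatureSpec("pc_pse_tnc", "pc_pse_tnc", lam=lam, pse_weight=pse_weight))
    specs.append(FeatureSpec("sc_pse_dnc", "sc_pse_dnc", lam=lam, pse_weight=pse_weight))
    specs.append(FeatureSpec("sc_pse_tnc", "sc_pse_tnc", lam=lam, pse_weight=pse_weight))
    specs.append(FeatureSpec("sparse", "sparse", d=d))
    specs.append(FeatureSpec("pssm", "pssm", d=d))
    names = [s.name for s in specs]
    assert len(names) == len(set(names)) == 22
    return specs


def feature_names(spec: FeatureSpec) -> list[str]:
    """Column labels for one spec's matrix, e.g. 'spectrum3:ACG'."""
    fam = spec.family
    if fam in ("spectrum", "mismatch", "subsequence"):
        labels = kmer_list(spec.k)
    elif fam == "revckmer":
        labels = _revc_classes(spec.k)[1]
    elif fam in ("pc_pse_dnc", "pc_pse_tnc", "sc_pse_dnc", "sc_pse_tnc"):
        t = 2 if "dnc" in fam else 3
        labels = kmer_list(t) + [f"theta{j}" for j in range(1, spec.dimension - 4**t + 1)]
    elif fam == "sparse":
        labels = [f"pos{i + 1}:{c}" for i in range(spec.d) for c in "ACGTE"]
    elif fam == "pssm":
        labels = [f"pos{i + 1}" for i in range(spec.d)]
    else:  # pragma: no cover
        raise ParameterError(fam)
    return [f"{spec.name}:{lab}" for lab in labels]


# ---------------------------------------------------------------------------
# Occurrence profiles
# ---------------------------------------------------------------------------

def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of each length-k window under base-4 lexicographic order."""
    L = len(codes)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows @ powers if L >= k else np.empty(0, dtype=np.int64)


def _normalize(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total <= 0:
        return np.zeros_like(counts, dtype=float)
    return counts / total


def spectrum_profile(seq: Sequence | str, k: int) -> np.ndarray:
    """k-mer occurrence frequencies over the L-k+1 windows (sum to 1)."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if not 1 <= k <= len(residues):
        raise DegenerateInputError(
            f"k={k} outside [1, {len(residues)}] for sequence of length "
            f"{len(residues)}"
        )
    counts = np.bincount(_kmer_codes(_encode(residues), k), minlength=4**k)
    return _normalize(counts.astype(float))


@lru_cache(maxsize=None)
def _hamming_ball(k: int, m: int) -> tuple[np.ndarray, ...]:
    """For each k-mer code, the codes within Hamming distance <= m."""
    codes = np.arange(4**k, dtype=np.int64)
    neighbours: list[set[int]] = [set() for _ in range(4**k)]
    digits = np.array([(codes // 4**p) % 4 for p in range(k - 1, -1, -1)]).T
    for code in codes:
        ball = {int(code)}
        frontier = {int(code)}
        for _ in range(m):
            nxt = set()
            for c in frontier:
                for pos in range(k):
                    place = 4 ** (k - 1 - pos)
                    cur = (c // place) % 4
                    for b in range(4):
                        if b != cur:
                            nxt.add(c + (b - cur) * place)
            ball |= nxt
            frontier = nxt
        neighbours[code] = ball
    return tuple(np.fromiter(sorted(b), dtype=np.int64) for b in neighbours)


def mismatch_profile(seq: Sequence | str, k: int, m: int) -> np.ndarray:
    """(k, m)-mismatch frequencies: each window credits its Hamming-<=m ball."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if m >= k:
        raise ParameterError(f"mismatch profile needs m < k (got m={m}, k={k})")
    if k > len(residues):
        raise DegenerateInputError(f"k={k} > sequence length {len(residues)}")
    ball = _hamming_ball(k, m)
    counts = np.zeros(4**k)
    window_codes, window_mult = np.unique(_kmer_codes(_encode(residues), k),
                                          return_counts=True)
    for code, mult in zip(window_codes, window_mult):
        counts[ball[code]] += mult
    return _normalize(counts)


def subsequence_profile(seq: Sequence | str, k: int, w: float) -> np.ndarray:
    """(k, w)-subsequence frequencies over all (possibly gapped) index tuples.

    Every index tuple i1 < ... < ik contributes weight w**g to its k-mer,
    where g = (ik - i1 + 1) - k is the total gap length (0**0 == 1, so w = 0
    reduces to the contiguous spectrum). Computed by a prefix-sum dynamic
    programme over positions; the gap weight factorizes over consecutive
    picks as w**(i_{j+1} - i_j - 1).
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if not 0.0 <= w <= 1.0:
        raise ParameterError(f"gap penalty w={w} outside [0, 1]")
    if k > len(residues):
        raise DegenerateInputError(f"k={k} > sequence length {len(residues)}")
    codes = _encode(residues)
    L = len(codes)
    # D[i, u]: total gap-weight of length-t subsequences ending at i spelling u
    D = np.zeros((L, 4))
    D[np.arange(L), codes] = 1.0
    for _t in range(2, k + 1):
        width = D.shape[1]
        newD = np.zeros((L, width * 4))
        prefix = np.zeros(width)
        for i in range(L):
            if i > 0:
                prefix = w * prefix + D[i - 1]
            newD[i].reshape(width, 4)[:, codes[i]] = prefix
        D = newD
    return _normalize(D.sum(axis=0))


@lru_cache(maxsize=None)
def _revc_classes(k: int) -> tuple[np.ndarray, tuple[str, ...]]:
    """Map each k-mer code to its {kmer, revcomp} class index.

    The class representative is the lexicographic minimum of the pair;
    class indices follow the sorted order of representatives.
    """
    kmers = kmer_list(k)
    reps = sorted({min(s, reverse_complement(s)) for s in kmers})
    rep_index = {r: i for i, r in enumerate(reps)}
    mapping = np.array(
        [rep_index[min(s, reverse_complement(s))] for s in kmers], dtype=np.int64
    )
    return mapping, tuple(reps)


def revc_kmer_profile(seq: Sequence | str, k: int) -> np.ndarray:
    """Strand-insensitive k-mer frequencies pooled over revcomp pairs."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if k > len(residues):
        raise DegenerateInputError(f"k={k} > sequence length {len(residues)}")
    mapping, reps = _revc_classes(k)
    counts = np.bincount(_kmer_codes(_encode(residues), k), minlength=4**k)
    pooled = np.zeros(len(reps))
    np.add.at(pooled, mapping, counts)
    return _normalize(pooled)


# ---------------------------------------------------------------------------
# Pseudo nucleotide composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyTable:
    """Standardized physicochemical values per di- or trinucleotide.

    ``values`` has shape (4**tuple_size, n_properties); each property column
    is z-scored over all tuples (zero mean, unit variance). The bundled
    default tables are deterministic synthetic stand-ins spanning plausible
    physical ranges for the named helix-step / trimer properties (exact
    published scales are not redistributed here); only a fixed standardized
    table is required downstream.
    """

    tuple_size: int
    property_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (4**self.tuple_size, len(self.property_names)):
            raise ConfigurationError(
                f"property table shape {vals.shape} inconsistent with "
                f"{4 ** self.tuple_size} tuples x {len(self.property_names)} properties"
            )
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_tsv(cls, path: str | Path, tuple_size: int) -> "PropertyTable":
        """Load a (tuple, property, value) TSV and z-score each property."""
        df = pd.read_csv(path, sep="\t")
        tuples = kmer_list(tuple_size)
        pivot = df.pivot(index="tuple", columns="property", values="value")
        missing = set(tuples) - set(pivot.index)
        if missing:
            raise ConfigurationError(f"property table misses tuples {sorted(missing)[:4]}")
        mat = pivot.loc[tuples].to_numpy(dtype=float)
        mat = (mat - mat.mean(axis=0)) / mat.std(axis=0)
        return cls(tuple_size, tuple(pivot.columns), mat)


@lru_cache(maxsize=None)
def default_property_table(tuple_size: int) -> PropertyTable:
    """Bundled default tables: 6 dinucleotide / 12 trinucleotide properties."""
    fname = {
        2: "dinucleotide_properties_synthetic.tsv",
        3: "trinucleotide_properties_synthetic.tsv",
    }[tuple_size]
    with resources.as_file(resources.files("piwe.data") / fname) as p:
        table = PropertyTable.from_tsv(p, tuple_size)
    expected = {2: 6, 3: 12}[tuple_size]
    if len(table.property_names) != expected:  # pragma: no cover
        raise ConfigurationError(
            f"default table has {len(table.property_names)} properties, "
            f"expected {expected}"
        )
    return table


PseVariant = Literal["pc_dnc", "pc_tnc", "sc_dnc", "sc_tnc"]


def pse_composition(
    seq: Sequence | str,
    variant: PseVariant,
    lam: int = DEFAULT_LAMBDA,
    pse_weight: float = DEFAULT_PSE_WEIGHT,
    props: PropertyTable | None = None,
) -> np.ndarray:
    """Parallel/series pseudo di-/trinucleotide composition.

    The first 4**t entries are tuple frequencies f_u / (1 + w * sum(theta));
    the tail entries are w * theta_j / (1 + w * sum(theta)), where for the
    parallel variants theta_j is the lag-j mean squared property difference
    averaged over properties, and for the series variants one theta per
    (lag, property) pair is the lag-j mean product of that property's
    standardized values. The vector always sums to 1.
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if variant not in ("pc_dnc", "pc_tnc", "sc_dnc", "sc_tnc"):
        raise ParameterError(f"unknown pse variant {variant!r}")
    t = 2 if variant.endswith("dnc") else 3
    L = len(residues)
    if lam < 1:
        raise ParameterError("lam must be >= 1")
    if lam > L - t:
        raise ParameterError(
            f"lam={lam} too large for sequence length {L} (max {L - t})"
        )
    if pse_weight < 0:
        raise ParameterError("pse_weight must be >= 0")
    if props is None:
        props = default_property_table(t)
    if props.tuple_size != t:
        raise ConfigurationError(
            f"property table is for {props.tuple_size}-tuples, variant needs {t}"
        )

    codes = _kmer_codes(_encode(residues), t)
    freqs = _normalize(np.bincount(codes, minlength=4**t).astype(float))
    P = props.values[codes]  # (n_tuples, n_props)

    thetas: list[float] = []
    parallel = variant.startswith("pc")
    for j in range(1, lam + 1):
        a, b = P[:-j], P[j:]
        if parallel:
            thetas.append(float(np.mean((a - b) ** 2)))  # mean over pairs & props
        else:
            thetas.extend(np.mean(a * b, axis=0).tolist())  # one per property
    theta = np.asarray(thetas)
    denom = 1.0 + pse_weight * theta.sum()
    return np.concatenate([freqs / denom, pse_weight * theta / denom])


# ---------------------------------------------------------------------------
# Fixed-length encodings: sparse profile and PSSM
# ---------------------------------------------------------------------------

NULL_LETTER = "E"
_SPARSE_ORDER = "ACGT" + NULL_LETTER


def fix_length(seq: Sequence | str, d: int) -> str:
    """Truncate to the first d residues or pad with the null letter E."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if d < 1:
        raise ParameterError("d must be >= 1")
    if len(residues) >= d:
        return residues[:d]
    return residues + NULL_LETTER * (d - len(residues))


def sparse_profile(seq: Sequence | str, d: int = DEFAULT_D) -> np.ndarray:
    """Positionwise one-hot over (A,C,G,T,E) after fixing length to d."""
    fixed = fix_length(seq, d)
    out = np.zeros((d, 5))
    for i, letter in enumerate(fixed):
        out[i, _SPARSE_ORDER.index(letter)] = 1.0
    return out.ravel()


@dataclass(frozen=True)
class PSSMModel:
    """Per-column log-odds scores m(R) learned from fixed-length positives.

    m(R) = log2(((count_c(R) + 0.25) / (n_c + 1)) / 0.25), where n_c counts
    non-null letters at column c; the null letter E always scores 0.
    """

    d: int
    scores: np.ndarray  # (d, 4) for A,C,G,T
    n_training: int

    def __post_init__(self) -> None:
        if np.asarray(self.scores).shape != (self.d, 4):
            raise ConfigurationError("PSSM score matrix must be (d, 4)")


def build_pssm(positives: TSequence[Sequence | str], d: int = DEFAULT_D) -> PSSMModel:
    """Estimate the PSSM from positive training sequences only."""
    if not positives:
        raise ValidationError("cannot build a PSSM from an empty training set")
    counts = np.zeros((d, 4))
    for seq in positives:
        fixed = fix_length(seq, d)
        for c, letter in enumerate(fixed):
            if letter != NULL_LETTER:
                counts[c, _BASE_INDEX[letter]] += 1
    n_c = counts.sum(axis=1, keepdims=True)  # non-E letters per column
    scores = np.log2(((counts + 0.25) / (n_c + 1.0)) / 0.25)
    return PSSMModel(d=d, scores=scores, n_training=len(positives))


def pssm_profile(seq: Sequence | str, model: PSSMModel) -> np.ndarray:
    """Score a sequence columnwise; padded positions (E) score exactly 0."""
    fixed = fix_length(seq, model.d)
    out = np.zeros(model.d)
    for c, letter in enumerate(fixed):
        if letter != NULL_LETTER:
            out[c] = model.scores[c, _BASE_INDEX[letter]]
    return out


# ---------------------------------------------------------------------------
# Dataset-level encoding
# ---------------------------------------------------------------------------

def _min_length(spec: FeatureSpec) -> int:
    fam = spec.family
    if fam in ("spectrum", "mismatch", "subsequence", "revckmer"):
        return spec.k
    if fam in ("pc_pse_dnc", "sc_pse_dnc"):
        return spec.lam + 2
    if fam in ("pc_pse_tnc", "sc_pse_tnc"):
        return spec.lam + 3
    return 1  # sparse / pssm accept any non-empty sequence


def encode_sequence(
    seq: Sequence | str, spec: FeatureSpec, pssm: PSSMModel | None = None
) -> np.ndarray:
    """Encode one sequence for one spec; too-short sequences yield zero vectors."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    fam = spec.family
    if len(residues) < _min_length(spec):
        logger.warning(
            "%s: sequence of length %d below minimum %d; emitting zero vector",
            spec.name, len(residues), _min_length(spec),
        )
        return np.zeros(spec.dimension)
    if fam == "spectrum":
        return spectrum_profile(residues, spec.k)
    if fam == "mismatch":
        return mismatch_profile(residues, spec.k, spec.m)
    if fam == "subsequence":
        return subsequence_profile(residues, spec.k, spec.w)
    if fam == "revckmer":
        return revc_kmer_profile(residues, spec.k)
    if fam in ("pc_pse_dnc", "pc_pse_tnc", "sc_pse_dnc", "sc_pse_tnc"):
        variant = {"pc_pse_dnc": "pc_dnc", "pc_pse_tnc": "pc_tnc",
                   "sc_pse_dnc": "sc_dnc", "sc_pse_tnc": "sc_tnc"}[fam]
        return pse_composition(residues, variant, spec.lam, spec.pse_weight)
    if fam == "sparse":
        return sparse_profile(residues, spec.d)
    if fam == "pssm":
        if pssm is None:
            raise ConfigurationError("catalog contains pssm but no model given")
        return pssm_profile(residues, pssm)
    raise ParameterError(f"unknown family {fam!r}")  # pragma: no cover


def encode_dataset(
    seqs: TSequence[Sequence],
    catalog: TSequence[FeatureSpec],
    pssm: PSSMModel | None = None,
) -> dict[str, np.ndarray]:
    """One (n_sequences x spec.dimension) matrix per spec, rows in seq order."""
    needs_pssm = any(s.family == "pssm" for s in catalog)
    if needs_pssm and pssm is None:
        raise ConfigurationError("catalog contains the pssm spec but pssm is None")
    out: dict[str, np.ndarray] = {}
    for spec in catalog:
        mat = np.empty((len(seqs), spec.dimension))
        for i, seq in enumerate(seqs):
            mat[i] = encode_sequence(seq, spec, pssm)
        out[spec.name] = mat
    return out


def matrices_to_frame(
    matrices: dict[str, np.ndarray], catalog: TSequence[FeatureSpec]
) -> pd.DataFrame:
    """Concatenate per-spec matrices into one labeled DataFrame (TSV-ready)."""
    cols: list[str] = []
    blocks: list[np.ndarray] = []
    for spec in catalog:
        cols.extend(feature_names(spec))
        blocks.append(matrices[spec.name])
    return pd.DataFrame(np.hstack(blocks), columns=cols)
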