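"""Construction of positive and pseudo-piRNA negative sets.

The negative ("pseudo piRNA") class is built from non-piRNA ncRNAs: sequences
shorter than 16 nt are dropped, sequences longer than 35 nt are cut to a
fragment whose length is drawn from the empirical length distribution of the
real piRNAs, and only fragments that match a transposon within a small number
of mismatches (default 3) are kept — mirroring how the positive class is
restricted to transposon-matched piRNAs. Matching is an exhaustive
sliding-window Hamming scan over both strands.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence as TSequence

import numpy as np

from .exceptions import ConfigurationError, ValidationError
from .seqio import LabeledDataset, Sequence
from .features import reverse_complement, _encode

logger = logging.getLogger(__name__)

MIN_PIRNA_LEN = 16
MAX_PIRNA_LEN = 35


@dataclass(frozen=True)
class MatchPolicy:
    """Transposon-matching policy: mismatch budget and strand handling."""

    max_mismatches: int = 3
    search_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValidationError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class LengthDistribution:
    """Probability per integer length on the piRNA support [16, 35]."""

    lengths: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=int)
        probs = np.asarray(self.probs, dtype=float)
        if lengths.shape != probs.shape:
            raise ValidationError("lengths and probs must align")
        if np.any((lengths < MIN_PIRNA_LEN) | (lengths > MAX_PIRNA_LEN)):
            raise ValidationError(
                f"support must lie within [{MIN_PIRNA_LEN}, {MAX_PIRNA_LEN}]"
            )
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValidationError("probabilities must be >= 0 and sum to 1")
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "probs", probs)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.choice(self.lengths, size=size, p=self.probs)


def min_mismatches(
    query: Sequence | str, target: Sequence | str, policy: MatchPolicy = MatchPolicy()
) -> int | None:
    """Minimum Hamming distance of the query over all target windows.

    Scans every length-|query| window of the target (and of its reverse
    complement when the policy asks) and returns the smallest mismatch count,
    or None when the query is longer than the target.
    """
    q = query.residues if isinstance(query, Sequence) else query
    t = target.residues if isinstance(target, Sequence) else target
    if len(q) > len(t):
        logger.debug("query longer than target (%d > %d): no window", len(q), len(t))
        return None
    strands = [t]
    if policy.search_reverse_complement:
        strands.append(reverse_complement(t))
    qc = _encode(q)
    best = len(q)
    for strand in strands:
        tc = _encode(strand)
        windows = np.lib.stride_tricks.sliding_window_view(tc, len(q))
        dists = (windows != qc).sum(axis=1)
        best = min(best, int(dists.min()))
        if best == 0:
            break
    return best


def filter_matched(
    queries: TSequence[Sequence],
    transposons: TSequence[Sequence],
    policy: MatchPolicy = MatchPolicy(),
) -> list[Sequence]:
    """Keep queries within policy.max_mismatches of any transposon (order-stable)."""
    if not transposons:
        raise ConfigurationError("transposon library is empty")
    kept: list[Sequence] = []
    for q in queries:
        for t in transposons:
            d = min_mismatches(q, t, policy)
            if d is not None and d <= policy.max_mismatches:
                kept.append(q)
                break
    return kept


def empirical_length_distribution(positives: TSequence[Sequence]) -> LengthDistribution:
    """Empirical length frequencies of the real piRNAs."""
    if not positives:
        raise ValidationError("no positive sequences given")
    lens = np.array([len(s) for s in positives])
    if np.any((lens < MIN_PIRNA_LEN) | (lens > MAX_PIRNA_LEN)):
        raise ValidationError(
            f"positive lengths must lie within [{MIN_PIRNA_LEN}, {MAX_PIRNA_LEN}]"
        )
    values, counts = np.unique(lens, return_counts=True)
    return LengthDistribution(values, counts / counts.sum())


def cut_to_distribution(
    ncrnas: TSequence[Sequence], dist: LengthDistribution, rng_seed: int
) -> list[Sequence]:
    """Trim candidate ncRNAs into the piRNA length range.

    Sequences shorter than 16 are dropped; lengths 16-35 pass unchanged;
    longer sequences are replaced by one fragment whose length is drawn from
    ``dist`` and whose start offset is uniform over valid positions.
    """
    rng = np.random.default_rng(rng_seed)
    out: list[Sequence] = []
    for seq in ncrnas:
        L = len(seq)
        if L < MIN_PIRNA_LEN:
            continue
        if L <= MAX_PIRNA_LEN:
            out.append(seq)
            continue
        frag_len = int(dist.sample(rng))
        start = int(rng.integers(0, L - frag_len + 1))
        out.append(Sequence(f"{seq.id}|frag{start + 1}-{start + frag_len}",
                            seq.residues[start : start + frag_len]))
    return out


def _dedupe(seqs: TSequence[Sequence]) -> list[Sequence]:
    """Drop exact duplicate residue strings, keeping first occurrence."""
    seen: set[str] = set()
    out = []
    for s in seqs:
        if s.residues not in seen:
            seen.add(s.residues)
            out.append(s)
    return out


def assemble_dataset(
    positives: TSequence[Sequence],
    negatives: TSequence[Sequence],
    mode: str = "balanced",
    rng_seed: int = 0,
) -> LabeledDataset:
    """Assemble a labeled dataset, deduplicating each class first.

    balanced: all positives plus a seeded uniform sample (without
    replacement) of the same number of negatives. imbalanced: all of both.
    """
    if mode not in ("balanced", "imbalanced"):
        raise ValidationError(f"mode must be balanced|imbalanced, got {mode!r}")
    pos = _dedupe(positives)
    neg = _dedupe(negatives)
    if mode == "balanced":
        if len(neg) < len(pos):
            raise ValidationError(
                f"balanced mode needs >= {len(pos)} negatives, have {len(neg)}"
            )
        rng = np.random.default_rng(rng_seed)
        idx = rng.choice(len(neg), size=len(pos), replace=False)
        neg = [neg[i] for i in sorted(idx)]
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return LabeledDataset(list(pos) + list(neg), labels)


def build_pseudo_pirna_set(
    positives: TSequence[Sequence],
    ncrnas: TSequence[Sequence],
    transposons: TSequence[Sequence],
    policy: MatchPolicy = MatchPolicy(),
    mode: str = "balanced",
    rng_seed: int = 0,
) -> tuple[LabeledDataset, dict]:
    """Full pipeline: match positives, cut ncRNAs, match fragments, assemble.

    Returns the dataset plus a JSON-serializable run manifest.
    """
    matched_pos = filter_matched(positives, transposons, policy)
    if not matched_pos:
        raise ValidationError("no positive sequence matches the transposon library")
    dist = empirical_length_distribution(matched_pos)
    fragments = cut_to_distribution(ncrnas, dist, rng_seed)
    matched_neg = filter_matched(fragments, transposons, policy)
    dataset = assemble_dataset(matched_pos, matched_neg, mode, rng_seed)
    manifest = {
        "seed": rng_seed,
        "mode": mode,
        "policy": {
            "max_mismatches": policy.max_mismatches,
            "search_reverse_complement": policy.search_reverse_complement,
        },
        "counts": {
            "positives_in": len(positives),
            "positives_matched": len(matched_pos),
            "ncrnas_in": len(ncrnas),
            "fragments": len(fragments),
            "negatives_matched": len(matched_neg),
            "dataset": len(dataset),
        },
    }
    return dataset, manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
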