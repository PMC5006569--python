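"""FASTA and label-file I/O with alphabet canonicalization.

Sequences are DNA strings over {A,C,G,T}. RNA deposits are common for small
non-coding RNAs, so U/u is silently mapped to T on input; any other ambiguity
code (N, R, Y, ...) rejects the record. Record ids are kept verbatim up to the
first whitespace of the FASTA title line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence as TSequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .exceptions import ParseError, ValidationError

CANONICAL_ALPHABET = "ACGT"
_CANON_TABLE = str.maketrans("acgtuU", "ACGTTT")
_VALID = frozenset(CANONICAL_ALPHABET)


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over the canonical {A,C,G,T} alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: empty residues")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValidationError(
                f"sequence {self.id!r}: invalid residues {sorted(bad)} "
                f"(alphabet is A,C,G,T after canonicalization)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Sequences with binary labels (1 = real piRNA, 0 = pseudo piRNA)."""

    sequences: list[Sequence]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels):
            raise ValidationError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if self.labels.size and not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.sequences)


def canonicalize(residues: str, record_id: str = "?") -> str:
    """Uppercase and map U->T; reject any letter outside {A,C,G,T,U} cases."""
    canon = residues.translate(_CANON_TABLE)
    bad = set(canon) - _VALID
    if bad:
        raise ValidationError(
            f"record {record_id!r}: residue(s) {sorted(bad)} outside the "
            f"DNA/RNA alphabet"
        )
    return canon


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into canonicalized :class:`Sequence` records.

    Raises :class:`ParseError` naming the offending line for content before
    the first header, and :class:`ValidationError` naming the record id for
    residues outside {A,C,G,T,U} (either case).
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ParseError(
                f"{path}: line {lineno}: expected FASTA header '>' before "
                f"sequence data"
            )
        break
    out: list[Sequence] = []
    with io.StringIO(text) as handle:
        for title, residues in SimpleFastaParser(handle):
            rec_id = title.split()[0] if title.split() else title
            out.append(Sequence(rec_id, canonicalize(residues, rec_id)))
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as wrapped FASTA; round-trips ids and residues."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (id, 0/1) into an id->label mapping."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 'id<TAB>label'")
        rec_id, raw = parts[0], parts[1].strip()
        if raw not in {"0", "1"}:
            raise ParseError(f"{path}: line {lineno}: label must be 0 or 1")
        labels[rec_id] = int(raw)
    return labels


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for seq, lab in zip(dataset.sequences, dataset.labels):
            fh.write(f"{seq.id}\t{int(lab)}\n")


def attach_labels(seqs: TSequence[Sequence], labels: dict[str, int]) -> LabeledDataset:
    """Pair sequences with labels by id; every sequence must be labeled."""
    missing = [s.id for s in seqs if s.id not in labels]
    if missing:
        raise ValidationError(f"no label for record(s): {missing[:5]}")
    return LabeledDataset(list(seqs), np.array([labels[s.id] for s in seqs]))
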