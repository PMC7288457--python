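"""Reading, validating, and one-hot encoding fixed-length RNA windows.

Sequences are windows over the alphabet {A, C, G, U}. DNA-style input is
accepted: ``T`` is silently normalized to ``U`` and lowercase letters are
upper-cased. Each valid residue maps to a 4-dimensional indicator vector in
the fixed channel order A, C, G, U, so a window of length L becomes an
(L, 4) binary matrix with unit row sums (channels-last orientation).

Ambiguous residues (e.g. ``N``) are rejected by default; a permissive mode
encodes them as an all-zero row instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGU"
CHANNELS: dict[str, int] = {nt: i for i, nt in enumerate(ALPHABET)}

#: Canonical model input length in nucleotides.
WINDOW_LENGTH = 51

#: 0-based index of the central position of a 51-nt window (the adenosine
#: position for genuine m6A windows).
CENTER_INDEX = WINDOW_LENGTH // 2


class SequenceError(ValueError):
    """A sequence failed alphabet or length validation."""


class FastaError(ValueError):
    """A FASTA file could not be parsed into usable records."""


@dataclass(frozen=True)
class RnaSequence:
    """A normalized RNA window with a free-text identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Upper-case and map T -> U. No alphabet check is performed here."""
    return raw.upper().replace("T", "U")


def validate_sequence(
    seq: RnaSequence,
    required_length: int = WINDOW_LENGTH,
    *,
    permissive: bool = False,
    require_central_a: bool = False,
) -> RnaSequence:
    """Check alphabet and length; return the sequence unchanged on success.

    Parameters
    ----------
    seq
        Sequence to validate (already normalized by construction).
    required_length
        Exact length the sequence must have; ``None`` skips the check.
    permissive
        If True, residues outside {A,C,G,U} are tolerated (they will encode
        to an all-zero row). Off by default.
    require_central_a
        If True, additionally require an A at the central window position.

    Raises
    ------
    SequenceError
        On the first offending position (0-based) or on a length mismatch.
    """
    if required_length is not None and len(seq) != required_length:
        raise SequenceError(
            f"sequence {seq.id!r}: length {len(seq)} != required {required_length}"
        )
    if not permissive:
        for pos, nt in enumerate(seq.residues):
            if nt not in CHANNELS:
                raise SequenceError(
                    f"sequence {seq.id!r}: invalid residue {nt!r} at position {pos}"
                )
    if require_central_a:
        center = len(seq) // 2
        if seq.residues[center] != "A":
            raise SequenceError(
                f"sequence {seq.id!r}: central position {center} is "
                f"{seq.residues[center]!r}, expected 'A'"
            )
    return seq


def one_hot_encode(seq: RnaSequence | str, *, permissive: bool = False) -> np.ndarray:
    """Encode a sequence as an (L, 4) binary matrix, channel order A,C,G,U.

    In permissive mode unknown residues become all-zero rows; otherwise they
    raise :class:`SequenceError`.
    """
    residues = seq.residues if isinstance(seq, RnaSequence) else normalize_residues(seq)
    mat = np.zeros((len(residues), 4), dtype=np.float64)
    for pos, nt in enumerate(residues):
        ch = CHANNELS.get(nt)
        if ch is None:
            if not permissive:
                raise SequenceError(f"invalid residue {nt!r} at position {pos}")
            continue
        mat[pos, ch] = 1.0
    return mat


def one_hot_decode(mat: np.ndarray, *, permissive: bool = False) -> str:
    """Invert :func:`one_hot_encode`. All-zero rows decode to 'N' in
    permissive mode and are an error otherwise."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError(f"expected an (L, 4) matrix, got shape {mat.shape}")
    out = []
    for pos, row in enumerate(mat):
        total = row.sum()
        if total == 0:
            if permissive:
                out.append("N")
                continue
            raise ValueError(f"row {pos} sums to 0 (not one-hot)")
        if total != 1 or not np.isin(row, (0.0, 1.0)).all():
            raise ValueError(f"row {pos} is not a one-hot indicator: {row}")
        out.append(ALPHABET[int(np.argmax(row))])
    return "".join(out)


@dataclass
class LabeledDataset:
    """An ordered collection of (sequence, binary label) records.

    Label 1 marks the methylated (positive) class, 0 the non-methylated
    (negative) class. All sequences must share one length.
    """

    records: list[tuple[RnaSequence, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s, _ in self.records}
        if len(lengths) > 1:
            raise SequenceError(f"mixed sequence lengths in dataset: {sorted(lengths)}")
        bad = {lab for _, lab in self.records if lab not in (0, 1)}
        if bad:
            raise ValueError(f"labels must be 0/1, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[RnaSequence, int]]:
        return iter(self.records)

    @property
    def n_positive(self) -> int:
        return sum(lab for _, lab in self.records)

    @property
    def n_negative(self) -> int:
        return len(self) - self.n_positive

    @property
    def sequence_length(self) -> int:
        if not self.records:
            raise ValueError("empty dataset has no sequence length")
        return len(self.records[0][0])

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.records], dtype=np.int64)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in indices])

    def merge(self, other: "LabeledDataset") -> "LabeledDataset":
        return LabeledDataset(self.records + other.records)

    def encode(self, *, permissive: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """One-hot encode every record; returns (X, y) with X of shape
        (n, L, 4) and y of shape (n,)."""
        X = np.stack(
            [one_hot_encode(s, permissive=permissive) for s, _ in self.records]
        )
        return X, self.labels


def read_fasta(
    path: str | Path,
    label: int,
    required_length: int | None = WINDOW_LENGTH,
    *,
    permissive: bool = False,
    require_central_a: bool = False,
) -> LabeledDataset:
    """Read a FASTA file and attach one binary label to every record.

    Residues are upper-cased and T is normalized to U. Each record is
    validated (length + alphabet) unless disabled via the flags.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"no such file: {path}")
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = RnaSequence(id=rec.id, residues=str(rec.seq))
        validate_sequence(
            seq,
            required_length,
            permissive=permissive,
            require_central_a=require_central_a,
        )
        records.append((seq, label))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return LabeledDataset(records)


def read_tsv(
    path: str | Path,
    required_length: int | None = WINDOW_LENGTH,
    *,
    permissive: bool = False,
) -> LabeledDataset:
    """Read a two-column (sequence, label) tab-separated file."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            residues, lab_str = parts
            try:
                lab = int(lab_str)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad label {lab_str!r}") from exc
            seq = RnaSequence(id=f"row{lineno}", residues=residues)
            validate_sequence(seq, required_length, permissive=permissive)
            records.append((seq, lab))
    if not records:
        raise ValueError(f"no records found in {path}")
    return LabeledDataset(records)


def write_fasta(records: Iterable[RnaSequence], path: str | Path) -> None:
    """Write sequences as plain multi-record FASTA (unwrapped lines)."""
    with open(path, "w") as fh:
        for seq in records:
            fh.write(f">{seq.id}\n{seq.residues}\n")
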