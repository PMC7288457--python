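"""Synthetic labeled-sequence generation.

Emulates the structure of the benchmark datasets — balanced sets of 51-nt
RNA windows, one positive (methylated) and one negative (non-methylated)
class — with a planted, DRACH-like consensus motif in the positives so
learnability is controllable. Negatives are i.i.d. background with chance
occurrences of the motif *at the planted offset* rejected (occurrences
elsewhere are allowed, keeping the signal localized).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_encoding import ALPHABET, LabeledDataset, RnaSequence, normalize_residues


@dataclass(frozen=True)
class MotifModel:
    """Planted-motif model for positive-class windows.

    The default GGACU motif at offset 24 places its A at the central
    position (index 25, 0-based) of a 51-nt window.
    """

    motif: str = "GGACU"
    offset: int = 24
    insertion_probability: float = 1.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif", normalize_residues(self.motif))
        if any(nt not in ALPHABET for nt in self.motif):
            raise ValueError(f"motif contains non-ACGU residues: {self.motif!r}")
        if not 0.0 <= self.insertion_probability <= 1.0:
            raise ValueError("insertion_probability must be in [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ValueError("background must be a probability vector over A,C,G,U")


def _random_window(rng: np.random.Generator, length: int, background) -> str:
    idx = rng.choice(4, size=length, p=background)
    return "".join(ALPHABET[i] for i in idx)


def generate_dataset(
    n_pos: int,
    n_neg: int,
    length: int = 51,
    model: MotifModel | None = None,
    seed: int = 0,
) -> LabeledDataset:
    """Balanced-style synthetic dataset with a planted motif in positives.

    Positives carry the motif at ``model.offset`` with probability
    ``model.insertion_probability`` (remaining positions i.i.d. background);
    negatives are pure background re-drawn until the motif is absent at the
    offset. Deterministic for a given seed.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos and n_neg must be non-negative")
    model = model or MotifModel()
    if model.offset + len(model.motif) > length:
        raise ValueError(
            f"motif (offset {model.offset}, length {len(model.motif)}) "
            f"exceeds window length {length}"
        )
    rng = np.random.default_rng(seed)
    records: list[tuple[RnaSequence, int]] = []
    end = model.offset + len(model.motif)
    for i in range(n_pos):
        window = _random_window(rng, length, model.background)
        if rng.random() < model.insertion_probability:
            window = window[: model.offset] + model.motif + window[end:]
        records.append((RnaSequence(id=f"pos_{i}", residues=window), 1))
    for i in range(n_neg):
        while True:
            window = _random_window(rng, length, model.background)
            if window[model.offset : end] != model.motif:
                break
        records.append((RnaSequence(id=f"neg_{i}", residues=window), 0))
    return LabeledDataset(records)


def generate_null_dataset(n: int, length: int = 51, seed: int = 0) -> LabeledDataset:
    """Negative control: background sequences with labels assigned
    independently of content (a random half of the records get label 1)."""
    if n % 2 != 0:
        raise ValueError(f"n must be even for an exactly balanced null, got {n}")
    rng = np.random.default_rng(seed)
    background = (0.25, 0.25, 0.25, 0.25)
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.choice(n, size=n // 2, replace=False)] = 1
    records = [
        (RnaSequence(id=f"null_{i}", residues=_random_window(rng, length, background)), int(labels[i]))
        for i in range(n)
    ]
    return LabeledDataset(records)


def write_dataset_fasta(
    dataset: LabeledDataset,
    out_dir: str | Path,
    *,
    stem: str = "dataset",
    manifest: dict | None = None,
) -> tuple[Path, Path]:
    """Emit the dataset as two FASTA files (positives, negatives) plus a
    TSV manifest recording generation parameters."""
    from .io_encoding import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos_path = out_dir / f"{stem}_pos.fasta"
    neg_path = out_dir / f"{stem}_neg.fasta"
    write_fasta((s for s, lab in dataset if lab == 1), pos_path)
    write_fasta((s for s, lab in dataset if lab == 0), neg_path)
    manifest_path = out_dir / f"{stem}_manifest.tsv"
    rows = {
        "n_positive": dataset.n_positive,
        "n_negative": dataset.n_negative,
        "length": dataset.sequence_length,
    }
    if manifest:
        rows.update(manifest)
    with open(manifest_path, "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in rows.items():
            fh.write(f"{key}\t{value}\n")
    return pos_path, neg_path
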