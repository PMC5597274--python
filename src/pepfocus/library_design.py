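"""Tripeptide enumeration and position-resolved physicochemical encoding.

The complete tripeptide space over the 20 standard amino acids holds
20**3 = 8000 sequences.  Each peptide is encoded as a 39-dimensional vector:
13 amino-acid indices evaluated at each of the 3 sequence positions, counted
from the N-terminus.  Feature labels follow the "{p}A-{i}" convention —
"1A-7" is index 7 (hydropathy) at the first residue.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .aaindex import AMINO_ACIDS, IndexTable

PEPTIDE_LENGTH = 3


class EncodingError(ValueError):
    """Raised when a peptide cannot be encoded against an index table."""


def enumerate_tripeptides() -> list[str]:
    """All 8000 tripeptides in lexicographic order ('AAA' first, 'YYY' last)."""
    return ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=PEPTIDE_LENGTH)]


def feature_labels(n_indices: int = 13) -> list[str]:
    """Position-major labels '1A-1' ... '3A-{n}': all indices of position 1 first."""
    return [
        f"{pos}A-{ix}"
        for pos in range(1, PEPTIDE_LENGTH + 1)
        for ix in range(1, n_indices + 1)
    ]


@dataclass(frozen=True)
class FeatureMatrix:
    """Peptides-by-features matrix of physicochemical descriptor values."""

    peptides: tuple[str, ...]
    labels: tuple[str, ...]
    values: np.ndarray  # shape (n_peptides, n_features)
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.peptides), len(self.labels)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.peptides)} peptides x {len(self.labels)} labels"
            )

    @property
    def n_features(self) -> int:
        return len(self.labels)

    def row(self, peptide: str) -> np.ndarray:
        return self.values[self.peptides.index(peptide)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.peptides), columns=list(self.labels)
        )

    def to_tsv(self, stream: TextIO) -> None:
        df = self.to_frame()
        df.index.name = "peptide"
        df.to_csv(stream, sep="\t")


def validate_peptide(seq: str) -> None:
    if len(seq) != PEPTIDE_LENGTH or any(c not in AMINO_ACIDS for c in seq):
        raise EncodingError(
            f"invalid tripeptide {seq!r}: must be 3 uppercase residues from "
            f"{AMINO_ACIDS}"
        )


def encode(peptides: Sequence[str], table: IndexTable) -> FeatureMatrix:
    """Encode peptides as position-resolved index values (unscaled).

    Cell for peptide q at label "{p}A-{i}" is the value of index i for the
    residue at position p, position 1 being the N-terminus.  Columns are
    position-major: all 13 indices of position 1, then position 2, then 3.
    """
    if len(table) == 0:
        raise ValueError("index table is empty")
    lut = np.array(
        [[ix.values[aa] for ix in table] for aa in AMINO_ACIDS]
    )  # 20 x n_indices
    res_pos = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    n_ix = len(table)
    out = np.empty((len(peptides), PEPTIDE_LENGTH * n_ix))
    for r, pep in enumerate(peptides):
        validate_peptide(pep)
        for p, aa in enumerate(pep):
            out[r, p * n_ix : (p + 1) * n_ix] = lut[res_pos[aa]]
    return FeatureMatrix(
        peptides=tuple(peptides),
        labels=tuple(feature_labels(n_ix)),
        values=out,
        scaled=False,
    )


def scale(matrix: FeatureMatrix, atol: float = 1e-12) -> FeatureMatrix:
    """Z-score every column to mean 0, SD 1 (population SD).

    Idempotent up to floating-point error.  Raises on a zero-variance column,
    naming the offending feature label.
    """
    mu = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0)
    dead = np.flatnonzero(sd <= atol)
    if dead.size:
        labels = [matrix.labels[i] for i in dead]
        raise ValueError(f"cannot scale zero-variance feature column(s): {labels}")
    return replace(matrix, values=(matrix.values - mu) / sd, scaled=True)


def write_peptides_txt(peptides: Iterable[str], stream: TextIO) -> None:
    for pep in peptides:
        stream.write(pep + "\n")


def write_peptides_fasta(peptides: Iterable[str], stream: TextIO) -> None:
    """FASTA export with the sequence itself as record identifier."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(p), id=p, description="") for p in peptides]
    seqio_write(records, stream, "fasta")
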