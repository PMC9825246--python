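"""Amino-acid sequence featurization: BLOSUM50 encoding, standardization, padding.

A sequence of N residues becomes a 20×N real matrix whose j-th column is the
BLOSUM50 substitution row of residue j against the 20 canonical amino acids.
Features are standardized with a scaler fitted on training columns only, then
right-padded with zero columns to a fixed per-role width N_max, so that pad
columns coincide with the post-standardization feature mean.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

#: The 20 canonical amino acids, alphabetical by one-letter code. This fixed
#: ordering defines the feature axis of every encoded matrix.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
N_FEATURES = len(CANONICAL_RESIDUES)

#: Default floor for zero-variance features when standardizing.
SCALE_FLOOR = 1e-8


class Role(str, Enum):
    """The part a sequence plays in an interaction record."""

    PEPTIDE = "peptide"
    CDR3A = "cdr3a"
    CDR3B = "cdr3b"
    MHC_PSEUDO = "mhc_pseudo"


def _blosum50_table() -> np.ndarray:
    """20×20 BLOSUM50 restricted to canonical residues (row i = residue i
    against all 20, in CANONICAL_RESIDUES order)."""
    m = substitution_matrices.load("BLOSUM50")
    idx = [m.alphabet.index(a) for a in CANONICAL_RESIDUES]
    return np.asarray(m)[np.ix_(idx, idx)].astype(np.float64)


BLOSUM50 = _blosum50_table()


def load_substitution_matrix(path_or_handle) -> np.ndarray:
    """Parse an NCBI-format substitution matrix file into the canonical 20×20
    layout used by :func:`blosum50_encode`."""
    if isinstance(path_or_handle, (str,)):
        with open(path_or_handle) as fh:
            m = substitution_matrices.read(fh)
    else:
        m = substitution_matrices.read(path_or_handle)
    missing = [a for a in CANONICAL_RESIDUES if a not in m.alphabet]
    if missing:
        raise ValueError(f"matrix lacks canonical residues: {missing}")
    idx = [m.alphabet.index(a) for a in CANONICAL_RESIDUES]
    return np.asarray(m)[np.ix_(idx, idx)].astype(np.float64)


@dataclass(frozen=True)
class AminoAcidSequence:
    """A validated amino-acid string with its role in the record.

    Raises ValueError at construction for any character outside the 20
    canonical residues (non-canonical letters such as B/J/O/U/X/Z are
    rejected, not imputed) and for empty strings — a missing sequence is an
    absent record field, never an empty one.
    """

    residues: str
    role: Role

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty sequence; absence must be a missing field")
        for pos, ch in enumerate(self.residues):
            if ch not in CANONICAL_RESIDUES:
                raise ValueError(
                    f"non-canonical residue {ch!r} at position {pos} "
                    f"in {self.role.value} sequence"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class EncodedSequence:
    """A standardized, zero-padded 20×N_max feature matrix."""

    features: np.ndarray
    true_length: int
    role: Role

    def __post_init__(self):
        f = self.features
        if f.shape[0] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} feature rows, got {f.shape[0]}")
        if self.true_length > f.shape[1]:
            raise ValueError("true_length exceeds matrix width")


def blosum50_encode(seq: AminoAcidSequence, matrix: np.ndarray | None = None) -> np.ndarray:
    """Encode a sequence as a 20×N matrix of substitution rows.

    Column j is the full 20-dimensional BLOSUM50 row of residue j (its
    substitution score against each canonical residue).
    """
    table = BLOSUM50 if matrix is None else matrix
    cols = [CANONICAL_RESIDUES.index(ch) for ch in seq.residues]
    return table[cols].T.copy()  # (20, N)


@dataclass
class FeatureScaler:
    """Per-feature standardization fitted on training (non-pad) columns only."""

    mean_: np.ndarray = field(default=None)  # (20,)
    scale_: np.ndarray = field(default=None)  # (20,), strictly positive

    @property
    def is_fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, encodings: Iterable[np.ndarray], floor: float = SCALE_FLOOR) -> "FeatureScaler":
        mats = [np.asarray(e, dtype=np.float64) for e in encodings]
        if not mats:
            raise ValueError("no encodings to fit the scaler on")
        cols = np.concatenate(mats, axis=1)  # (20, total_columns)
        if cols.shape[1] < 2:
            raise ValueError("need at least 2 columns to fit a scaler")
        self.mean_ = cols.mean(axis=1)
        std = cols.std(axis=1)  # population std, matching variance-1 on the fit set
        self.scale_ = np.maximum(std, floor)
        return self

    def transform(self, raw: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return (raw - self.mean_[:, None]) / self.scale_[:, None]

    def inverse_transform(self, std: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return std * self.scale_[:, None] + self.mean_[:, None]

    def _check_fitted(self):
        if not self.is_fitted:
            raise ValueError("scaler is not fitted")

    def to_dict(self) -> dict:
        self._check_fitted()
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(mean_=np.asarray(d["mean"]), scale_=np.asarray(d["scale"]))


def fit_scaler(training_encodings: Iterable[np.ndarray], floor: float = SCALE_FLOOR) -> FeatureScaler:
    """Fit a :class:`FeatureScaler` on raw (unpadded) training encodings."""
    return FeatureScaler().fit(training_encodings, floor=floor)


def standardize_and_pad(
    raw: np.ndarray, scaler: FeatureScaler, n_max: int, role: Role = Role.PEPTIDE
) -> EncodedSequence:
    """Standardize a raw 20×N encoding and right-pad with zeros to 20×N_max."""
    raw = np.asarray(raw, dtype=np.float64)
    n = raw.shape[1]
    if n > n_max:
        raise ValueError(f"sequence length {n} exceeds N_max {n_max}")
    out = np.zeros((N_FEATURES, n_max), dtype=np.float64)
    out[:, :n] = scaler.transform(raw)
    return EncodedSequence(features=out, true_length=n, role=role)


def read_fasta(path_or_handle) -> list[str]:
    """Read plain sequence strings from a FASTA file ('>' headers, wrapped lines)."""
    if isinstance(path_or_handle, str):
        records = list(SeqIO.parse(path_or_handle, "fasta"))
    else:
        records = list(SeqIO.parse(path_or_handle, "fasta"))
    return [str(r.seq).upper() for r in records]
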