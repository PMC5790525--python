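"""Matrix-based MHC class I binding prediction and multi-predictor consensus.

The in-repo predictor is an additive position-scoring matrix in the
stabilized-matrix-method family:

    log10(IC50 / nM) = intercept + sum_i weights[residue_i, i]

for a peptide of the matrix's length, with the result clamped to
[0.01, 1e7] nM.  Several predictors (each a matrix file) score every
candidate, and the consensus IC50 is the geometric mean of the
per-predictor IC50s — i.e. the arithmetic mean on the log10 scale, the
natural scale for an additive model whose outputs span orders of
magnitude.  An arithmetic-mean consensus is available for sensitivity
checks.  Externally produced IC50 tables can be merged through the same
``BindingPrediction`` records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .epitopes import PeptideCandidate
from .sequence import AMINO_ACIDS

IC50_FLOOR_NM = 0.01
IC50_CEIL_NM = 1e7

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class MatrixFormatError(ValueError):
    """Raised when a scoring-matrix file is malformed."""


@dataclass(frozen=True)
class ScoringMatrix:
    """A 20 x k table of log10-IC50 contributions plus an intercept."""

    allele: str
    length: int
    weights: np.ndarray  # shape (20, length)
    intercept: float
    predictor_id: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (20, self.length):
            raise MatrixFormatError(
                f"weights shape {w.shape} != (20, {self.length})"
            )
        if not np.all(np.isfinite(w)) or not np.isfinite(self.intercept):
            raise MatrixFormatError("non-finite matrix entries")
        object.__setattr__(self, "weights", w)


def predict_ic50(matrix: ScoringMatrix, peptide: str) -> float:
    """Score one peptide: IC50 in nM, clamped to [0.01, 1e7]."""
    if len(peptide) != matrix.length:
        raise ValueError(
            f"peptide length {len(peptide)} != matrix length {matrix.length}"
        )
    try:
        rows = [_AA_INDEX[aa] for aa in peptide]
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r} in peptide") from exc
    log_ic50 = matrix.intercept + float(
        matrix.weights[rows, np.arange(matrix.length)].sum()
    )
    return float(np.clip(10.0**log_ic50, IC50_FLOOR_NM, IC50_CEIL_NM))


def predict_ic50_many(matrix: ScoringMatrix, peptides: Sequence[str]) -> np.ndarray:
    """Vectorised scoring of many same-length peptides."""
    if not peptides:
        return np.empty(0)
    idx = np.array(
        [[_AA_INDEX[aa] for aa in p] for p in peptides], dtype=np.intp
    )
    if idx.shape[1] != matrix.length:
        raise ValueError("peptide length != matrix length")
    log_ic50 = matrix.intercept + matrix.weights[
        idx, np.arange(matrix.length)
    ].sum(axis=1)
    return np.clip(10.0**log_ic50, IC50_FLOOR_NM, IC50_CEIL_NM)


@dataclass(frozen=True)
class BindingPrediction:
    """One predictor's IC50 (nM) for one candidate."""

    candidate: PeptideCandidate
    predictor_id: str
    ic50_nM: float

    def __post_init__(self) -> None:
        if not IC50_FLOOR_NM <= self.ic50_nM <= IC50_CEIL_NM:
            raise ValueError(
                f"ic50 {self.ic50_nM} outside [{IC50_FLOOR_NM}, {IC50_CEIL_NM}] nM"
            )


@dataclass(frozen=True)
class ConsensusResult:
    """Per-predictor IC50s and their consensus for one candidate."""

    candidate: PeptideCandidate
    per_predictor: tuple[BindingPrediction, ...]
    consensus_ic50_nM: float


def consensus_ic50(
    predictions: Sequence[BindingPrediction], scale: str = "log"
) -> float:
    """Combine per-predictor IC50s into one consensus value.

    ``scale='log'`` (default) takes the geometric mean — the arithmetic mean
    of log10 IC50s, exponentiated; ``scale='linear'`` takes the plain
    arithmetic mean.  Either way the result lies within [min, max] of the
    inputs.  All predictions must refer to the same candidate.
    """
    if not predictions:
        raise ValueError("consensus requires at least one prediction")
    first = predictions[0].candidate
    if any(p.candidate is not first for p in predictions[1:]):
        raise ValueError("predictions mix different candidates")
    values = np.array([p.ic50_nM for p in predictions], dtype=float)
    if scale == "log":
        geo = 10.0 ** np.mean(np.log10(values))
        # exponentiation round-trip can land a hair outside [min, max]
        return float(np.clip(geo, values.min(), values.max()))
    if scale == "linear":
        return float(np.mean(values))
    raise ValueError(f"unknown consensus scale {scale!r}")


def build_consensus(
    candidate: PeptideCandidate,
    predictions: Sequence[BindingPrediction],
    scale: str = "log",
) -> ConsensusResult:
    return ConsensusResult(
        candidate=candidate,
        per_predictor=tuple(predictions),
        consensus_ic50_nM=consensus_ic50(predictions, scale=scale),
    )


# ---------------------------------------------------------------------------
# Matrix file format
# ---------------------------------------------------------------------------
#
#   #allele=H-2Kb
#   #length=8
#   #intercept=4.5
#   #predictor=smm1
#   A<TAB>w1 ... w8        (20 rows, residues in fixed alphabetical order)


def write_scoring_matrix(matrix: ScoringMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#allele={matrix.allele}\n")
        fh.write(f"#length={matrix.length}\n")
        fh.write(f"#intercept={matrix.intercept!r}\n")
        fh.write(f"#predictor={matrix.predictor_id}\n")
        for i, aa in enumerate(AMINO_ACIDS):
            row = "\t".join(repr(float(v)) for v in matrix.weights[i])
            fh.write(f"{aa}\t{row}\n")


def load_scoring_matrix(path: str | Path) -> ScoringMatrix:
    """Load a matrix TSV, validating shape, residue order, and numerics."""
    header: dict[str, str] = {}
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise MatrixFormatError(f"{path} line {line_no}: bad header line")
                key, value = line[1:].split("=", 1)
                header[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            aa = fields[0]
            if aa not in _AA_INDEX:
                raise MatrixFormatError(
                    f"{path} line {line_no}: unknown residue row {aa!r}"
                )
            if aa in rows:
                raise MatrixFormatError(f"{path} line {line_no}: duplicate row {aa}")
            try:
                rows[aa] = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise MatrixFormatError(
                    f"{path} line {line_no}: non-numeric cell ({exc})"
                ) from exc
    for key in ("allele", "length", "intercept", "predictor"):
        if key not in header:
            raise MatrixFormatError(f"{path}: missing header #{key}=")
    length = int(header["length"])
    missing = [aa for aa in AMINO_ACIDS if aa not in rows]
    if missing:
        raise MatrixFormatError(f"{path}: missing residue row(s) {missing}")
    weights = np.empty((20, length))
    for aa, values in rows.items():
        if len(values) != length:
            raise MatrixFormatError(
                f"{path}: row {aa} has {len(values)} columns, expected {length}"
            )
        weights[_AA_INDEX[aa]] = values
    return ScoringMatrix(
        allele=header["allele"],
        length=length,
        weights=weights,
        intercept=float(header["intercept"]),
        predictor_id=header["predictor"],
    )


class PredictorRegistry:
    """A set of matrix predictors keyed by (predictor_id, allele, length)."""

    def __init__(self, matrices: Iterable[ScoringMatrix] = ()) -> None:
        self._matrices: dict[tuple[str, str, int], ScoringMatrix] = {}
        for m in matrices:
            self.add(m)

    def add(self, matrix: ScoringMatrix) -> None:
        key = (matrix.predictor_id, matrix.allele, matrix.length)
        if key in self._matrices:
            raise ValueError(f"duplicate matrix for {key}")
        self._matrices[key] = matrix

    @classmethod
    def from_paths(cls, paths: Iterable[str | Path]) -> "PredictorRegistry":
        return cls(load_scoring_matrix(p) for p in sorted(str(p) for p in paths))

    @property
    def predictor_ids(self) -> list[str]:
        return sorted({pid for pid, _, _ in self._matrices})

    def matrices_for(self, allele: str, length: int) -> list[ScoringMatrix]:
        out = [
            m
            for (pid, a, k), m in sorted(self._matrices.items())
            if a == allele and k == length
        ]
        return out

    def predict_candidate(
        self, candidate: PeptideCandidate, scale: str = "log"
    ) -> ConsensusResult:
        matrices = self.matrices_for(
            candidate.allele.name, len(candidate.mutant_peptide)
        )
        if not matrices:
            raise ValueError(
                f"no matrices for allele {candidate.allele.name} "
                f"length {len(candidate.mutant_peptide)}"
            )
        preds = [
            BindingPrediction(
                candidate=candidate,
                predictor_id=m.predictor_id,
                ic50_nM=predict_ic50(m, candidate.mutant_peptide),
            )
            for m in matrices
        ]
        return build_consensus(candidate, preds, scale=scale)
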