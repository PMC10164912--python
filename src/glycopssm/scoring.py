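"""Position-specific scoring matrix: data type, TSV I/O, and prediction.

A matrix assigns a real score to each of 18 amino acids (the canonical 20
minus the rare W and C) at each non-center offset of an odd-length window;
for the default 39-mer this is the 18 x 38 table. A window's score is the
sum of the matrix cells selected by its flanking residues. W, C, X and the
terminal pad '-' contribute exactly zero, and the center S/T itself is
unscored — any S-versus-T preference must come from the neighbors.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import MATRIX_AA, MATRIX_AA_INDEX
from .seqio import ProteinRecord
from .windows import (
    DEFAULT_WINDOW_LENGTH,
    LabeledPeptideSet,
    PeptideWindow,
    extract_windows,
)

__all__ = [
    "ScoringMatrix",
    "PredictionThresholds",
    "DEFAULT_THRESHOLDS",
    "SitePrediction",
    "score_window",
    "score_set",
    "predict_sites",
    "read_matrix",
    "write_matrix",
    "write_predictions",
]


def _offsets(length: int) -> list[int]:
    flank = (length - 1) // 2
    return [o for o in range(-flank, flank + 1) if o != 0]


@dataclass
class ScoringMatrix:
    """Scores per (amino acid, position offset), center offset excluded.

    ``values`` has shape (18, L-1); rows follow :data:`MATRIX_AA`
    (alphabetical one-letter order), columns follow offsets
    -(L-1)/2..-1, +1..+(L-1)/2.
    """

    length: int
    values: np.ndarray
    name: str = "matrix"

    def __post_init__(self) -> None:
        if self.length < 3 or self.length % 2 == 0:
            raise ValueError(f"matrix length must be odd >= 3, got {self.length}")
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(MATRIX_AA), self.length - 1)
        if self.values.shape != expected:
            raise ValueError(
                f"matrix values must have shape {expected}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")

    @classmethod
    def zeros(cls, length: int = DEFAULT_WINDOW_LENGTH, name: str = "zero") -> "ScoringMatrix":
        return cls(length, np.zeros((len(MATRIX_AA), length - 1)), name=name)

    @property
    def offsets(self) -> list[int]:
        return _offsets(self.length)

    def cell(self, residue: str, offset: int) -> float:
        col = self.offsets.index(offset)
        return float(self.values[MATRIX_AA_INDEX[residue], col])

    def row_means(self) -> dict[str, float]:
        """Mean score of each residue across all offsets — the summary used
        to read compositional preferences off a trained matrix."""
        means = self.values.mean(axis=1)
        return {aa: float(means[i]) for i, aa in enumerate(MATRIX_AA)}


@dataclass(frozen=True)
class PredictionThresholds:
    """Low/medium/high score cutoffs for calling a site positive.

    Defaults correspond to the stringency tiers used for benchmark
    evaluation of the trained 39-mer matrix; "high" favors precision over
    sensitivity. A site is called at a tier when score >= threshold.
    """

    low: float = 123.0
    medium: float = 148.0
    high: float = 160.0

    def __post_init__(self) -> None:
        if not self.low <= self.medium <= self.high:
            raise ValueError(
                f"thresholds must satisfy low <= medium <= high, got "
                f"{self.low}, {self.medium}, {self.high}"
            )


DEFAULT_THRESHOLDS = PredictionThresholds()


@dataclass(frozen=True)
class SitePrediction:
    parent_id: str
    center_position: int
    center_residue: str
    score: float
    call_low: bool
    call_medium: bool
    call_high: bool


def _window_index_vector(matrix: ScoringMatrix, window: str) -> np.ndarray:
    """Per-column row index into the matrix, -1 for unscorable residues."""
    flank = (matrix.length - 1) // 2
    flanks = window[:flank] + window[flank + 1 :]
    return np.array([MATRIX_AA_INDEX.get(aa, -1) for aa in flanks], dtype=int)


def score_window(matrix: ScoringMatrix, window: PeptideWindow | str) -> float:
    """Sum matrix cells over the window's flanking residues.

    W, C, X and '-' contribute zero; the center residue is not scored.
    """
    wstr = window.window if isinstance(window, PeptideWindow) else window
    if len(wstr) != matrix.length:
        raise ValueError(
            f"window length {len(wstr)} does not match matrix length "
            f"{matrix.length}"
        )
    idx = _window_index_vector(matrix, wstr)
    cols = np.nonzero(idx >= 0)[0]
    return float(matrix.values[idx[cols], cols].sum())


def score_set(matrix: ScoringMatrix, pset: LabeledPeptideSet) -> list[float]:
    """Score every window of a set, preserving order."""
    out = []
    for i, w in enumerate(pset.windows):
        try:
            out.append(score_window(matrix, w))
        except ValueError as exc:
            raise ValueError(f"window {i} of set {pset.name!r}: {exc}") from exc
    return out


def predict_sites(
    matrix: ScoringMatrix,
    protein: ProteinRecord,
    thresholds: PredictionThresholds = DEFAULT_THRESHOLDS,
) -> list[SitePrediction]:
    """Score every S/T site of a protein and call it at each threshold."""
    preds = []
    for w in extract_windows(protein, matrix.length):
        s = score_window(matrix, w)
        preds.append(
            SitePrediction(
                parent_id=w.parent_id,
                center_position=w.center_position,
                center_residue=w.center_residue,
                score=s,
                call_low=s >= thresholds.low,
                call_medium=s >= thresholds.medium,
                call_high=s >= thresholds.high,
            )
        )
    return preds


def write_matrix(matrix: ScoringMatrix, path: str | Path) -> None:
    """Write as TSV: header of signed offsets, one row per amino acid."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["aa"] + [f"{o:+d}" for o in matrix.offsets])
        for i, aa in enumerate(MATRIX_AA):
            writer.writerow([aa] + [repr(float(v)) for v in matrix.values[i]])


def read_matrix(path: str | Path, name: str | None = None) -> ScoringMatrix:
    """Read a matrix TSV.

    Tolerant of amino-acid rows in any order and of an extra offset-0
    column, which is ignored with a warning (some matrix dialects carry a
    center column even though the center residue is never scored).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    header = rows[0]
    if header[0].lower() not in ("aa", "residue", ""):
        raise ValueError(f"{path}: first header cell must label the residue column")
    try:
        offsets = [int(tok) for tok in header[1:]]
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer offset in header: {exc}") from exc
    keep = [i for i, o in enumerate(offsets) if o != 0]
    if len(keep) < len(offsets):
        warnings.warn(
            f"{path}: offset-0 column present; ignored (center is unscored)",
            stacklevel=2,
        )
    kept_offsets = [offsets[i] for i in keep]
    length = len(kept_offsets) + 1
    if sorted(kept_offsets) != _offsets(length):
        raise ValueError(
            f"{path}: offsets {kept_offsets} do not form a contiguous "
            "symmetric non-center range"
        )
    values = np.zeros((len(MATRIX_AA), length - 1))
    seen: set[str] = set()
    for r, row in enumerate(rows[1:], start=2):
        if not row or not "".join(row).strip():
            continue
        aa = row[0].strip().upper()
        if aa not in MATRIX_AA_INDEX:
            raise ValueError(f"{path}: line {r}: unexpected residue row {aa!r}")
        if aa in seen:
            raise ValueError(f"{path}: line {r}: duplicate row for {aa!r}")
        seen.add(aa)
        cells = [row[1 + i] for i in keep]
        for o, cell in zip(kept_offsets, cells):
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: line {r}: non-numeric cell {cell!r} for "
                    f"residue {aa} offset {o:+d}"
                ) from None
            values[MATRIX_AA_INDEX[aa], _offsets(length).index(o)] = v
    missing = set(MATRIX_AA) - seen
    if missing:
        raise ValueError(f"{path}: missing residue row(s) {sorted(missing)}")
    return ScoringMatrix(length, values, name=name or path.stem)


def write_predictions(preds: Sequence[SitePrediction], path: str | Path) -> None:
    """Predictions TSV: parent_id, position, residue, score, three calls."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["parent_id", "position", "residue", "score",
             "call_low", "call_medium", "call_high"]
        )
        for p in preds:
            writer.writerow(
                [p.parent_id, p.center_position, p.center_residue,
                 f"{p.score:.6f}", int(p.call_low), int(p.call_medium),
                 int(p.call_high)]
            )
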