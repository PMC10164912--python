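"""Matrix training: the MAS objective and randomized hill climbing.

The matrix assessment score (MAS) measures how well a scoring matrix
separates a positive from a negative peptide set:

    MAS = (P - Pstd - N - Nstd) / P

where P and N are the medians and Pstd/Nstd the sample standard deviations
of the two score distributions. The numerator is the gap between the lower
edge of the positive distribution and the upper edge of the negative one;
dividing by P makes the objective invariant to a uniform rescaling of the
matrix, so training cannot inflate MAS by simply multiplying all scores.
An alternative sign convention that *adds* Nstd is available behind
``literal_nstd=True`` for comparison; it rewards a wider negative
distribution and is not the default because the training goal is
separation.

Training is pure accept-if-better hill climbing: each iteration perturbs
one uniformly chosen matrix cell by +/- step_size and keeps the change iff
the objective strictly increases. While the positive median is not yet
positive the MAS ratio is not a meaningful separation measure, so the
optimizer ranks such states below every P > 0 state and orders them by the
raw numerator; once P > 0 the objective is MAS itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .alphabet import MATRIX_AA, MATRIX_AA_INDEX
from .scoring import ScoringMatrix
from .windows import DEFAULT_WINDOW_LENGTH, LabeledPeptideSet

__all__ = [
    "MASReport",
    "OptimizerConfig",
    "Trajectory",
    "TrajectoryStep",
    "mas",
    "optimize_matrix",
    "write_trajectory",
]


@dataclass(frozen=True)
class MASReport:
    """Score-distribution summary behind one MAS evaluation."""

    P: float
    N: float
    Pstd: float
    Nstd: float
    mas: float


def _median_std(scores: np.ndarray) -> tuple[float, float]:
    med = float(np.median(scores))
    std = 0.0 if scores.size == 1 else float(np.std(scores, ddof=1))
    return med, std


def mas(
    positive_scores: Sequence[float],
    negative_scores: Sequence[float],
    *,
    literal_nstd: bool = False,
) -> MASReport:
    """Matrix assessment score of two score distributions.

    Medians use the mean of the middle two values for even-length input;
    standard deviations are the sample (n-1) kind, zero for singletons.
    Raises when either list is empty or when the positive median is zero
    (the normalized objective is undefined there).
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("MAS requires non-empty positive and negative score lists")
    P, Pstd = _median_std(pos)
    N, Nstd = _median_std(neg)
    numerator = P - Pstd - N + (Nstd if literal_nstd else -Nstd)
    if P == 0.0:
        raise ValueError("MAS undefined: positive median is zero")
    return MASReport(P=P, N=N, Pstd=Pstd, Nstd=Nstd, mas=numerator / P)


@dataclass(frozen=True)
class OptimizerConfig:
    """Hill-climbing run parameters.

    Identical config and datasets give a bitwise-identical trained matrix:
    one seeded generator drives initialization, cell choice and step sign.
    ``init="uniform"`` draws initial cells from uniform(-init_range,
    +init_range); an all-zero start is available but is a fixed point of
    single-cell hill climbing (no single step can beat the zero matrix's
    objective, because medians stay at zero while the spreads grow), so
    random initialization is the default.
    """

    seed: int
    iterations: int = 100_000
    step_size: float = 1.0
    init: Literal["zero", "uniform"] = "uniform"
    init_range: float = 1.0
    literal_nstd: bool = False
    report_every: int = 1000

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.init not in ("zero", "uniform"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.init_range <= 0:
            raise ValueError("init_range must be positive")
        if self.report_every < 1:
            raise ValueError("report_every must be >= 1")


@dataclass(frozen=True)
class TrajectoryStep:
    iteration: int
    mas: float  # -inf while the normalized objective is undefined (P <= 0)
    accepted: bool


@dataclass
class Trajectory:
    """Per-iteration record of a training run."""

    steps: list[TrajectoryStep] = field(default_factory=list)
    initial_mas: float = float("-inf")

    def accepted_mas(self) -> list[float]:
        return [s.mas for s in self.steps if s.accepted]

    @property
    def final_mas(self) -> float:
        accepted = self.accepted_mas()
        return accepted[-1] if accepted else self.initial_mas


def _flank_index_array(pset: LabeledPeptideSet, length: int) -> np.ndarray:
    """(n_windows, L-1) matrix-row indices; -1 for unscorable residues."""
    flank = (length - 1) // 2
    rows = []
    for w in pset.windows:
        flanks = w.window[:flank] + w.window[flank + 1 :]
        rows.append([MATRIX_AA_INDEX.get(aa, -1) for aa in flanks])
    return np.asarray(rows, dtype=np.int64)


def _objective(
    pos_scores: np.ndarray, neg_scores: np.ndarray, literal_nstd: bool
) -> tuple[tuple[int, float], float]:
    """Lexicographic objective key plus the MAS value (-inf when P <= 0)."""
    P, Pstd = _median_std(pos_scores)
    N, Nstd = _median_std(neg_scores)
    numerator = P - Pstd - N + (Nstd if literal_nstd else -Nstd)
    if P > 0:
        m = numerator / P
        return (1, m), m
    return (0, numerator), float("-inf")


def optimize_matrix(
    positive: LabeledPeptideSet,
    negative: LabeledPeptideSet,
    config: OptimizerConfig,
) -> tuple[ScoringMatrix, Trajectory]:
    """Train a scoring matrix by randomized hill climbing on MAS.

    Each iteration perturbs one uniformly chosen cell by +/- step_size
    (equal probability) and keeps the change iff the objective strictly
    increases, so the accepted-step MAS sequence is strictly increasing and
    the returned matrix attains the maximum objective seen.
    """
    if len(positive) == 0 or len(negative) == 0:
        raise ValueError("both peptide sets must be non-empty")
    if positive.length != negative.length:
        raise ValueError(
            f"window length mismatch: positive {positive.length}, "
            f"negative {negative.length}"
        )
    length = positive.length or DEFAULT_WINDOW_LENGTH
    n_aa, n_cols = len(MATRIX_AA), length - 1

    rng = np.random.default_rng(config.seed)
    if config.init == "zero":
        values = np.zeros((n_aa, n_cols))
    else:
        values = config.init_range * rng.uniform(-1.0, 1.0, size=(n_aa, n_cols))

    pos_idx = _flank_index_array(positive, length)
    neg_idx = _flank_index_array(negative, length)

    def set_scores(idx: np.ndarray) -> np.ndarray:
        scores = np.zeros(idx.shape[0])
        for j in range(n_cols):
            valid = idx[:, j] >= 0
            scores[valid] += values[idx[valid, j], j]
        return scores

    pos_scores = set_scores(pos_idx)
    neg_scores = set_scores(neg_idx)
    key, m = _objective(pos_scores, neg_scores, config.literal_nstd)

    traj = Trajectory(initial_mas=m)
    n_cells = n_aa * n_cols
    for it in range(config.iterations):
        cell = int(rng.integers(n_cells))
        row, col = divmod(cell, n_cols)
        delta = config.step_size if rng.integers(2) else -config.step_size

        pos_mask = pos_idx[:, col] == row
        neg_mask = neg_idx[:, col] == row
        new_pos = pos_scores + delta * pos_mask
        new_neg = neg_scores + delta * neg_mask
        new_key, new_m = _objective(new_pos, new_neg, config.literal_nstd)

        accepted = new_key > key
        if accepted:
            values[row, col] += delta
            pos_scores, neg_scores = new_pos, new_neg
            key, m = new_key, new_m
        traj.steps.append(TrajectoryStep(iteration=it, mas=m, accepted=accepted))

    matrix = ScoringMatrix(length, values, name=f"trained-seed{config.seed}")
    return matrix, traj


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Trajectory TSV: iteration, mas (current best; -inf before P > 0),
    accepted flag."""
    with open(path, "w", newline="") as fh:
        fh.write("iteration\tmas\taccepted\n")
        for s in traj.steps:
            fh.write(f"{s.iteration}\t{s.mas!r}\t{int(s.accepted)}\n")
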