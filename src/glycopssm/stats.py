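"""Dataset diagnostics and evaluation metrics.

Covers positional amino-acid frequency matrices of window sets,
whole-dataset compositional bias (exact binomial upper tail against a
background composition, after Harrison & Gerstein), amino-acid composition
summaries, confusion-matrix metrics over a protein's S/T sites, and a
Pearson-correlation helper.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

from .alphabet import CANONICAL_AA, PAD, UNKNOWN
from .seqio import ProteinRecord
from .windows import LabeledPeptideSet

__all__ = [
    "FrequencyMatrix",
    "BiasResult",
    "ConfusionSummary",
    "positional_frequency",
    "compositional_bias",
    "binomial_upper_tail",
    "background_from_sequences",
    "composition",
    "evaluate_predictions",
    "pearson",
    "write_frequency_tsv",
    "write_bias_tsv",
    "format_confusion_report",
]


@dataclass
class FrequencyMatrix:
    """Per-offset amino-acid frequencies of a window set.

    ``frequencies`` is a (20, L) array over the canonical alphabet and all
    offsets including the center (offset 0); pads and X are excluded from
    both numerator and denominator. ``counts`` holds the number of scorable
    residues per offset.
    """

    length: int
    frequencies: np.ndarray
    counts: np.ndarray

    @property
    def offsets(self) -> list[int]:
        flank = (self.length - 1) // 2
        return list(range(-flank, flank + 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.frequencies, index=list(CANONICAL_AA), columns=self.offsets
        )

    def frequency(self, residue: str, offset: int) -> float:
        return float(
            self.frequencies[CANONICAL_AA.index(residue),
                             self.offsets.index(offset)]
        )


def positional_frequency(pset: LabeledPeptideSet) -> FrequencyMatrix:
    """Column-normalized residue frequencies at every window offset.

    By the window invariant the center column is 100% S+T for any valid
    set. Frequencies are count ratios, so duplicating the set leaves the
    matrix unchanged.
    """
    if len(pset) == 0:
        raise ValueError("cannot compute frequencies of an empty set")
    length = pset.length
    counts = np.zeros((len(CANONICAL_AA), length), dtype=np.int64)
    aa_index = {aa: i for i, aa in enumerate(CANONICAL_AA)}
    for w in pset.windows:
        for j, aa in enumerate(w.window):
            if aa not in (PAD, UNKNOWN):
                counts[aa_index[aa], j] += 1
    col_totals = counts.sum(axis=0)
    freqs = np.zeros_like(counts, dtype=float)
    nonzero = col_totals > 0
    freqs[:, nonzero] = counts[:, nonzero] / col_totals[nonzero]
    return FrequencyMatrix(length=length, frequencies=freqs, counts=col_totals)


@dataclass(frozen=True)
class BiasResult:
    """Compositional-bias statistic for one residue.

    ``p_bias`` is the exact binomial upper tail P(X >= observed_count) with
    X ~ Binomial(total_residues, background_frequency): the probability of
    seeing at least this many copies of the residue under the background
    composition. ``log10_p`` carries the magnitude when the tail underflows
    a double.
    """

    residue: str
    observed_count: int
    total_residues: int
    background_frequency: float
    p_bias: float
    log10_p: float


def binomial_upper_tail(k: int, n: int, p: float) -> tuple[float, float]:
    """P(X >= k) for X ~ Binomial(n, p), with its log10.

    Summed in log space over per-count log-pmf terms, so far-tail
    magnitudes (1e-264 and beyond the double-precision floor) keep full
    relative precision in the returned log10.
    """
    if k <= 0:
        return 1.0, 0.0
    if k > n:
        return 0.0, -math.inf
    ks = np.arange(k, n + 1)
    logsf = float(logsumexp(sps.binom.logpmf(ks, n, p)))
    logsf = min(logsf, 0.0)  # guard against rounding past certainty
    return math.exp(logsf), logsf / math.log(10.0)


def background_from_sequences(
    sequences: Iterable[ProteinRecord],
) -> dict[str, float]:
    """Pooled canonical-residue composition of a sequence collection."""
    counts = {aa: 0 for aa in CANONICAL_AA}
    total = 0
    for rec in sequences:
        for aa in rec.sequence:
            if aa in counts:
                counts[aa] += 1
                total += 1
    if total == 0:
        raise ValueError("no canonical residues in input sequences")
    return {aa: counts[aa] / total for aa in CANONICAL_AA}


def _check_background(background: Mapping[str, float]) -> None:
    missing = set(CANONICAL_AA) - set(background)
    if missing:
        raise ValueError(f"background missing residue(s) {sorted(missing)}")
    if any(background[aa] <= 0 or background[aa] >= 1 for aa in CANONICAL_AA):
        raise ValueError("background frequencies must lie strictly in (0, 1)")
    total = sum(background[aa] for aa in CANONICAL_AA)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"background frequencies sum to {total}, not 1")


def compositional_bias(
    sequences: Sequence[ProteinRecord],
    background: Mapping[str, float],
) -> list[BiasResult]:
    """Whole-set compositional bias of every canonical residue.

    Counts are pooled over the given sequences — for window datasets built
    by exhaustive S/T windowing, pass the underlying region sequences
    rather than the overlapping windows, otherwise each residue is counted
    up to L times and the bias is wildly overstated.
    """
    if not sequences:
        raise ValueError("sequences must be non-empty")
    _check_background(background)
    counts = {aa: 0 for aa in CANONICAL_AA}
    total = 0
    for rec in sequences:
        for aa in rec.sequence:
            if aa in counts:
                counts[aa] += 1
                total += 1
    results = []
    for aa in CANONICAL_AA:
        p, log10p = binomial_upper_tail(counts[aa], total, background[aa])
        results.append(
            BiasResult(
                residue=aa,
                observed_count=counts[aa],
                total_residues=total,
                background_frequency=background[aa],
                p_bias=p,
                log10_p=log10p,
            )
        )
    return results


def composition(protein: ProteinRecord) -> dict[str, float]:
    """Fraction of each canonical residue in one sequence."""
    counts = {aa: 0 for aa in CANONICAL_AA}
    total = 0
    for aa in protein.sequence:
        if aa in counts:
            counts[aa] += 1
            total += 1
    if total == 0:
        raise ValueError(f"{protein.id!r}: no canonical residues")
    return {aa: counts[aa] / total for aa in CANONICAL_AA}


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/FP/TN/FN counts over a protein's S/T sites with derived rates.

    Rates are None when their denominator is zero. ``precision`` is the
    fraction of predicted sites that are verified known sites.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    @property
    def precision(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    def percent(self, metric: str) -> int | None:
        """Metric as a whole percent (benchmark-table display precision)."""
        value = getattr(self, metric)
        return None if value is None else round(100 * value)


def evaluate_predictions(
    predicted_positive: set[int],
    known_positive: set[int],
    all_sites: set[int],
) -> ConfusionSummary:
    """Confusion summary of called sites against verified sites.

    ``all_sites`` is the full S/T site universe of the test protein; sites
    in neither the predicted nor the known set count as true negatives.
    """
    stray_pred = predicted_positive - all_sites
    stray_known = known_positive - all_sites
    if stray_pred or stray_known:
        raise ValueError(
            f"positions outside the site universe: "
            f"predicted {sorted(stray_pred)}, known {sorted(stray_known)}"
        )
    tp = len(predicted_positive & known_positive)
    fp = len(predicted_positive - known_positive)
    fn = len(known_positive - predicted_positive)
    tn = len(all_sites) - tp - fp - fn
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t distribution
    on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs two equal-length lists of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def write_frequency_tsv(fm: FrequencyMatrix, path: str | Path) -> None:
    fm.to_frame().to_csv(path, sep="\t", index_label="aa", float_format="%.6f")


def write_bias_tsv(results: Sequence[BiasResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["residue", "observed_count", "total_residues",
             "background_frequency", "p_bias", "log10_p"]
        )
        for r in results:
            writer.writerow(
                [r.residue, r.observed_count, r.total_residues,
                 f"{r.background_frequency:.6f}", f"{r.p_bias:.6e}",
                 f"{r.log10_p:.3f}"]
            )


def format_confusion_report(summary: ConfusionSummary) -> str:
    """Human-readable block mirroring a predictor-benchmark table row."""

    def pct(metric: str) -> str:
        v = summary.percent(metric)
        return "n/a" if v is None else f"{v}%"

    lines = [
        f"Positive sites found\t{summary.tp}",
        f"Total sites found\t{summary.tp + summary.fp}",
        f"Predicted sites verified\t{pct('precision')}",
        f"Sensitivity\t{pct('sensitivity')}",
        f"Specificity\t{pct('specificity')}",
        f"Accuracy\t{pct('accuracy')}",
    ]
    return "\n".join(lines)
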