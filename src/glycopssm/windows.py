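"""Fixed-length peptide windows centered on serine/threonine residues.

Windows are the unit of both training data and prediction: every S/T in a
sequence yields exactly one window, with '-' padding where the window runs
past a terminus, so terminus-adjacent sites are never dropped. The default
length of 39 (19 flanking residues per side) reflects the observation that
OGT's compositional preferences extend far beyond the catalytic-site
footprint.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

from .alphabet import CENTER_AA, PAD, WINDOW_AA
from .seqio import ProteinRecord

__all__ = [
    "DEFAULT_WINDOW_LENGTH",
    "PeptideWindow",
    "LabeledPeptideSet",
    "extract_windows",
    "windows_from_site_list",
    "read_window_tsv",
    "write_window_tsv",
]

DEFAULT_WINDOW_LENGTH = 39

_WINDOW_CHARS = set(WINDOW_AA)


def _check_length(length: int) -> None:
    if length < 3 or length % 2 == 0:
        raise ValueError(f"window length must be odd and >= 3, got {length}")


@dataclass(frozen=True)
class PeptideWindow:
    """An odd-length peptide window centered on an S or T residue."""

    parent_id: str
    center_position: int  # 1-based, parent numbering when known
    window: str

    def __post_init__(self) -> None:
        _check_length(len(self.window))
        bad = set(self.window) - _WINDOW_CHARS
        if bad:
            raise ValueError(f"illegal window character(s) {sorted(bad)!r}")
        if self.center_residue not in CENTER_AA:
            raise ValueError(
                f"window center must be S or T, got {self.center_residue!r}"
            )
        core = self.window.strip(PAD)
        if PAD in core:
            raise ValueError(
                f"pad characters must be confined to the window ends: "
                f"{self.window!r}"
            )

    @property
    def flank(self) -> int:
        return (len(self.window) - 1) // 2

    @property
    def center_residue(self) -> str:
        return self.window[(len(self.window) - 1) // 2]

    def __len__(self) -> int:
        return len(self.window)


@dataclass
class LabeledPeptideSet:
    """A named collection of equal-length windows with a class label.

    Duplicates and overlapping windows are retained as-is: the negative
    training sets produced by exhaustive S/T windowing of short IDRs are
    intrinsically overlapping and deduplication would distort composition.
    """

    name: str
    label: Literal["positive", "negative"]
    windows: list[PeptideWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive|negative, got {self.label!r}")
        lengths = {len(w) for w in self.windows}
        if len(lengths) > 1:
            raise ValueError(
                f"set {self.name!r}: mixed window lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int | None:
        return len(self.windows[0]) if self.windows else None

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[PeptideWindow]:
        return iter(self.windows)


def _window_at(sequence: str, idx0: int, flank: int) -> str:
    """Window around 0-based index, '-'-padded past either terminus."""
    left = max(0, idx0 - flank)
    right = min(len(sequence), idx0 + flank + 1)
    return (
        PAD * (flank - (idx0 - left))
        + sequence[left:right]
        + PAD * (flank - (right - 1 - idx0))
    )


def extract_windows(
    protein: ProteinRecord, length: int = DEFAULT_WINDOW_LENGTH
) -> list[PeptideWindow]:
    """One window per S/T residue, in order of position along the sequence.

    Center positions are reported in parent numbering when the record
    carries region metadata, otherwise in local numbering.
    """
    _check_length(length)
    flank = (length - 1) // 2
    offset = protein.numbering_offset
    out = []
    for i, aa in enumerate(protein.sequence):
        if aa in CENTER_AA:
            out.append(
                PeptideWindow(
                    parent_id=protein.parent_id or protein.id,
                    center_position=offset + i + 1,
                    window=_window_at(protein.sequence, i, flank),
                )
            )
    return out


def windows_from_site_list(
    protein: ProteinRecord,
    sites: Sequence[int],
    length: int = DEFAULT_WINDOW_LENGTH,
) -> list[PeptideWindow]:
    """Windows around known modified positions (record's own numbering).

    Each listed site must carry S or T; anything else is a validation error
    naming the position, since a mispositioned site list usually means the
    wrong isoform or numbering scheme.
    """
    _check_length(length)
    flank = (length - 1) // 2
    offset = protein.numbering_offset
    out = []
    for pos in sites:
        aa = protein.residue_at(pos)
        if aa not in CENTER_AA:
            raise ValueError(
                f"site {pos} in {protein.id!r} is {aa!r}, not S/T"
            )
        out.append(
            PeptideWindow(
                parent_id=protein.parent_id or protein.id,
                center_position=pos,
                window=_window_at(protein.sequence, pos - offset - 1, flank),
            )
        )
    return out


_TSV_FIELDS = ("parent_id", "center_position", "window", "label")


def write_window_tsv(pset: LabeledPeptideSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_FIELDS)
        for w in pset.windows:
            writer.writerow([w.parent_id, w.center_position, w.window, pset.label])


def read_window_tsv(path: str | Path, name: str | None = None) -> LabeledPeptideSet:
    """Read a window TSV written by :func:`write_window_tsv`.

    All rows must share one label; the set name defaults to the file stem.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TSV_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        rows = list(reader)
    labels = {r["label"] for r in rows}
    if len(labels) > 1:
        raise ValueError(f"{path}: mixed labels {sorted(labels)}")
    label = labels.pop() if labels else "positive"
    windows = [
        PeptideWindow(
            parent_id=r["parent_id"],
            center_position=int(r["center_position"]),
            window=r["window"],
        )
        for r in rows
    ]
    return LabeledPeptideSet(name=name or path.stem, label=label, windows=windows)
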