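"""Protein sequence I/O, region slicing, and point-mutation handling.

Coordinates are 1-based and inclusive throughout, following residue
numbering conventions in the structural/IDR literature ("aa 1-214" means
residues 1 through 214). A record sliced out of a parent keeps the parent
identifier and its residue span, so window centers and mutation positions
can always be reported in parent numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import SEQUENCE_AA

__all__ = [
    "ProteinRecord",
    "PointMutation",
    "FixtureRegistry",
    "DEFAULT_REGISTRY",
    "FUS_MUT_A",
    "FUS_MUT_B",
    "FUS_MUT_C",
    "FUS_MUT_D",
    "FUS_MUT_E",
    "FUS_MUT_F",
    "read_fasta",
    "write_fasta",
    "slice_region",
    "apply_mutations",
    "parse_mutations",
]

_SEQUENCE_CHARS = set(SEQUENCE_AA)


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA or illegal residues."""


class CoordinateError(ValueError):
    """Raised for out-of-range residue coordinates."""


class MutationError(ValueError):
    """Raised for inconsistent point-mutation specifications."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein (or protein region) with 1-based provenance coordinates.

    Parameters
    ----------
    id:
        Free-text identifier (FASTA header token before first whitespace).
    sequence:
        Uppercase one-letter sequence over the 20 canonical residues plus
        ``X`` for unknown.
    parent_id:
        Identifier of the parent protein when this record is a subregion.
    region_start, region_end:
        1-based inclusive residue span of this record in the parent.
    """

    id: str
    sequence: str
    parent_id: str | None = None
    region_start: int | None = None
    region_end: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not self.sequence.isupper():
            raise ValueError(f"record {self.id!r}: sequence must be uppercase")
        bad = set(self.sequence) - _SEQUENCE_CHARS
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: illegal residue character(s) "
                f"{sorted(bad)!r}; allowed alphabet is {SEQUENCE_AA!r}"
            )
        if (self.region_start is None) != (self.region_end is None):
            raise ValueError(
                f"record {self.id!r}: region_start and region_end must be "
                "given together"
            )
        if self.region_start is not None:
            if self.region_start < 1:
                raise CoordinateError(
                    f"record {self.id!r}: region_start must be >= 1"
                )
            span = self.region_end - self.region_start + 1
            if span != len(self.sequence):
                raise CoordinateError(
                    f"record {self.id!r}: region {self.region_start}-"
                    f"{self.region_end} spans {span} residues but sequence "
                    f"has {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def numbering_offset(self) -> int:
        """Parent-numbering position of residue 1 of this record, minus 1."""
        return (self.region_start - 1) if self.region_start else 0

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position in this record's own numbering
        (parent numbering when region coordinates are present)."""
        local = position - self.numbering_offset
        if not 1 <= local <= len(self.sequence):
            raise CoordinateError(
                f"position {position} outside {self.id!r} "
                f"(numbering {self.numbering_offset + 1}-"
                f"{self.numbering_offset + len(self.sequence)})"
            )
        return self.sequence[local - 1]


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class PointMutation:
    """Single-residue substitution in compact ``G34A`` notation."""

    wt_residue: str
    position: int
    mut_residue: str

    def __post_init__(self) -> None:
        for res, role in ((self.wt_residue, "wild-type"), (self.mut_residue, "mutant")):
            if res not in _SEQUENCE_CHARS:
                raise MutationError(f"{role} residue {res!r} is not an amino acid")
        if self.position < 1:
            raise MutationError(f"position {self.position} must be >= 1")
        if self.wt_residue == self.mut_residue:
            raise MutationError(
                f"{self}: wild-type and mutant residues are identical"
            )

    @classmethod
    def parse(cls, token: str) -> "PointMutation":
        m = _MUTATION_RE.match(token.strip().upper())
        if not m:
            raise MutationError(
                f"cannot parse mutation {token!r}; expected e.g. 'G34A'"
            )
        return cls(m.group(1), int(m.group(2)), m.group(3))

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"


def parse_mutations(text: str) -> list[PointMutation]:
    """Parse a comma/whitespace-separated list of ``G34A`` tokens."""
    tokens = [t for t in re.split(r"[,\s]+", text.strip()) if t]
    return [PointMutation.parse(t) for t in tokens]


# Compositional mutation sets designed to raise the OGT-substrate character
# of the FUS N-terminal low-complexity region: glycines and glutamines
# swapped for alanine/threonine/proline, serines for threonines, one
# aspartate for threonine. Positions are FUS parent numbering.
FUS_MUT_A = parse_mutations("Q31T G34A Q36A G40T Q43P D46T G49A")
FUS_MUT_B = parse_mutations("G67A Q69T G74A G76P G79A G80P G82A S83T Q85P")
FUS_MUT_C = parse_mutations("G99A G101T S107T S108T G111A G114A S115T")
FUS_MUT_D = FUS_MUT_A + FUS_MUT_B
FUS_MUT_E = FUS_MUT_B + FUS_MUT_C
FUS_MUT_F = FUS_MUT_A + FUS_MUT_B + FUS_MUT_C


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    parent_accession: str
    region_start: int | None
    region_end: int | None
    sequence: str | None = None


class FixtureRegistry:
    """Named protein regions used as benchmark substrates.

    The registry records accessions and residue spans only; sequences are
    user-supplied (``attach_sequence``) because bundling database sequences
    would freeze a particular release. Operations needing a sequence fail
    cleanly when none is attached.
    """

    def __init__(self, entries: Iterable[RegistryEntry] = ()) -> None:
        self._entries: dict[str, RegistryEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: RegistryEntry) -> None:
        if entry.name in self._entries:
            raise ValueError(f"duplicate registry entry {entry.name!r}")
        self._entries[entry.name] = entry

    def names(self) -> list[str]:
        return list(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def entry(self, name: str) -> RegistryEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise KeyError(
                f"no registry entry {name!r}; known: {sorted(self._entries)}"
            ) from None

    def attach_sequence(self, name: str, sequence: str) -> None:
        e = self.entry(name)
        if e.region_start is not None:
            span = e.region_end - e.region_start + 1
            if len(sequence) != span:
                raise CoordinateError(
                    f"{name}: sequence length {len(sequence)} does not match "
                    f"region span {span}"
                )
        self._entries[name] = replace(e, sequence=sequence.upper())

    def record(self, name: str) -> ProteinRecord:
        """Materialize an entry as a ProteinRecord; requires a sequence."""
        e = self.entry(name)
        if e.sequence is None:
            raise ValueError(
                f"registry entry {name!r} has no attached sequence; use "
                "attach_sequence() with the accession "
                f"{e.parent_accession!r} residues "
                f"{e.region_start}-{e.region_end}"
            )
        return ProteinRecord(
            id=name,
            sequence=e.sequence,
            parent_id=e.parent_accession,
            region_start=e.region_start,
            region_end=e.region_end,
        )


def _default_registry() -> FixtureRegistry:
    # Lamin A ships without a span: the isoform numbering used in published
    # site tables is not pinned down, so the full-length record is the
    # conservative choice and the ambiguity is left to the caller.
    rows = [
        ("EWS_LCRN", "UniProt:Q01844", 1, 264),
        ("FUS_LCRN", "UniProt:P35637", 1, 214),
        ("TAF15_LCRN", "UniProt:Q92804", 1, 210),
        ("SARA_IDR", "UniProt:O95405", 766, 822),
        ("DDX4_IDR_MOUSE", "UniProt:Q61496", 1, 236),
        ("CFTR_RDOMAIN", "UniProt:P13569", 654, 838),
        ("FMRP_IDR", "UniProt:Q06787", 445, 632),
        ("CBP_ID1", "UniProt:Q92793", 1, 344),
        ("CBP_ID3", "UniProt:Q92793", 676, 1080),
        ("CBP_ID4", "UniProt:Q92793", 1851, 2057),
        ("CBP_ID5", "UniProt:Q92793", 2124, 2442),
        ("LAMIN_A", "UniProt:P02545", None, None),
        ("RPB1_CTD", "UniProt:P24928", 1586, 1970),
    ]
    return FixtureRegistry(
        RegistryEntry(name, acc, start, end) for name, acc, start, end in rows
    )


DEFAULT_REGISTRY = _default_registry()

#: Regions whose S/T-centered windows form the experimentally verified
#: negative training set (IDRs shown by intact MS to resist glycosylation).
NEGATIVE_SET_REGIONS = (
    "TAF15_LCRN",
    "CFTR_RDOMAIN",
    "DDX4_IDR_MOUSE",
    "FMRP_IDR",
    "SARA_IDR",
)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords.

    The header token before the first whitespace becomes the id; sequences
    are uppercased; a trailing ``*`` stop character is stripped. Residues
    outside the 21-letter alphabet (20 canonical + X) are a parse error.
    """
    path = Path(path)
    # Pre-scan for a sequence line before any header: Biopython silently
    # skips such garbage, but it signals a corrupt file.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before any '>' header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as unwrapped single-line FASTA."""
    bio = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(bio)


def slice_region(protein: ProteinRecord, start: int, end: int) -> ProteinRecord:
    """Extract the inclusive 1-based span ``start``-``end`` as a new record.

    The result carries ``parent_id = protein.id`` and region coordinates in
    the *parent's own* local numbering, so slices compose.
    """
    if not (1 <= start <= end <= len(protein.sequence)):
        raise CoordinateError(
            f"span {start}-{end} out of range for {protein.id!r} "
            f"(length {len(protein.sequence)})"
        )
    return ProteinRecord(
        id=f"{protein.id}:{start}-{end}",
        sequence=protein.sequence[start - 1 : end],
        parent_id=protein.id,
        region_start=start,
        region_end=end,
    )


def apply_mutations(
    protein: ProteinRecord, mutations: Sequence[PointMutation]
) -> ProteinRecord:
    """Apply point mutations, validating the wild-type residue at each site.

    Positions use the record's own numbering (parent numbering when region
    metadata is present). The input record is unchanged; an empty mutation
    list returns an identical sequence. Duplicate positions are rejected,
    which makes application order-independent.
    """
    positions = [m.position for m in mutations]
    dupes = {p for p in positions if positions.count(p) > 1}
    if dupes:
        raise MutationError(f"duplicate mutation positions: {sorted(dupes)}")
    seq = list(protein.sequence)
    offset = protein.numbering_offset
    for m in mutations:
        found = protein.residue_at(m.position)
        if found != m.wt_residue:
            raise MutationError(
                f"mutation {m}: expected {m.wt_residue!r} at position "
                f"{m.position} but found {found!r}"
            )
        seq[m.position - offset - 1] = m.mut_residue
    suffix = "+".join(str(m) for m in mutations)
    new_id = f"{protein.id}|{suffix}" if mutations else protein.id
    return ProteinRecord(
        id=new_id,
        sequence="".join(seq),
        parent_id=protein.parent_id,
        region_start=protein.region_start,
        region_end=protein.region_end,
    )
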