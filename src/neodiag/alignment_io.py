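"""Reading and validating aligned FASTA loci and specimen metadata.

The pipeline works on per-locus multiple sequence alignments over the IUPAC
DNA alphabet (plus ``-`` for gaps) together with a specimen table assigning
each individual to a species and, optionally, a form variant below the
species level.  Species and form are collapsed into a single opaque *group*
key (``species`` or ``species|form``) so that every downstream stage —
distances, mismatch distributions, diagnostic characters — only ever sees
flat group labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GROUP_SEPARATOR = "|"

#: IUPAC nucleotide codes mapped to the set of bases they may stand for.
#: ``N`` is fully ambiguous; the gap character carries no state at all.
IUPAC_STATE_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset(),
}

ALPHABET: frozenset[str] = frozenset(IUPAC_STATE_SETS)

#: The four unambiguous bases.
BASES: tuple[str, ...] = ("A", "C", "G", "T")

#: Two-fold ambiguity codes, used to encode electropherogram double peaks.
TWOFOLD_CODES: tuple[str, ...] = ("R", "Y", "S", "W", "K", "M")


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment (e.g. unequal lengths)."""


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC DNA alphabet."""


class MetadataError(ValueError):
    """The specimen metadata table is malformed."""


def iupac_states(char: str) -> frozenset[str]:
    """Return the set of bases an alignment character may represent.

    ``A``/``C``/``G``/``T`` map to singletons, ambiguity codes to their
    standard base sets, ``N`` to all four bases and the gap ``-`` to the
    empty set.  Input is case-insensitive and ``U`` is treated as ``T``.
    """
    c = char.upper()
    if c == "U":
        c = "T"
    try:
        return IUPAC_STATE_SETS[c]
    except KeyError:
        raise AlphabetError(f"character {char!r} is not an IUPAC DNA code or gap") from None


@dataclass(frozen=True)
class SpecimenRecord:
    """One collected individual with its species / form labels."""

    specimen_id: str
    species: str
    form: str = ""

    @property
    def group(self) -> str:
        """Group key: the species, or ``species|form`` when a form is set."""
        if self.form:
            return f"{self.species}{GROUP_SEPARATOR}{self.form}"
        return self.species


@dataclass
class AlignedLocus:
    """One marker region: equal-length IUPAC sequences keyed by specimen."""

    locus_name: str
    length: int
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if len(seq) != self.length:
                raise AlignmentError(
                    f"locus {self.locus_name!r}: sequence {sid!r} has length "
                    f"{len(seq)}, alignment length is {self.length}"
                )
            for pos, ch in enumerate(seq):
                if ch not in ALPHABET:
                    raise AlphabetError(
                        f"locus {self.locus_name!r}: sequence {sid!r} has "
                        f"illegal character {ch!r} at column {pos + 1}"
                    )

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class Dataset:
    """All loci plus the specimen table; a specimen may miss some loci."""

    specimens: list[SpecimenRecord]
    loci: dict[str, AlignedLocus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise MetadataError(f"duplicate specimen_id(s): {sorted(dupes)}")
        known = set(ids)
        for locus in self.loci.values():
            orphans = sorted(set(locus.sequences) - known)
            if orphans:
                raise MetadataError(
                    f"locus {locus.locus_name!r} has sequences with no metadata "
                    f"record: {orphans}"
                )

    @property
    def group_of(self) -> dict[str, str]:
        return {s.specimen_id: s.group for s in self.specimens}

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.specimens:
            seen.setdefault(s.group, None)
        return list(seen)


def _canonical(seq: str) -> str:
    """Uppercase and map RNA-style U to T."""
    return seq.upper().replace("U", "T")


def read_fasta_alignment(path: str | Path, locus_name: str) -> AlignedLocus:
    """Read one aligned FASTA file into an :class:`AlignedLocus`.

    Record IDs (first whitespace-delimited token of the header) become
    specimen IDs.  All records must have the same length; characters are
    validated against the IUPAC alphabet and stored uppercase.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    sequences: dict[str, str] = {}
    length = len(records[0].seq)
    for rec in records:
        if rec.id in sequences:
            raise AlignmentError(f"{path}: duplicate record ID {rec.id!r}")
        seq = _canonical(str(rec.seq))
        if len(seq) != length:
            raise AlignmentError(
                f"{path}: record {rec.id!r} has length {len(seq)}, "
                f"expected {length} (alignment must be flush)"
            )
        sequences[rec.id] = seq
    return AlignedLocus(locus_name=locus_name, length=length, sequences=sequences)


def write_fasta_alignment(locus: AlignedLocus, path: str | Path) -> None:
    """Write an :class:`AlignedLocus` back to FASTA (uppercase)."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in locus.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


REQUIRED_METADATA_COLUMNS = ("specimen_id", "species", "form")


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read the specimen table (TSV: specimen_id, species, form)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing column(s) {missing}")
    ids = df["specimen_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise MetadataError(f"{path}: duplicate specimen_id(s) {dupes}")
    return [
        SpecimenRecord(row.specimen_id, row.species, row.form)
        for row in df.itertuples(index=False)
    ]


def write_metadata(specimens: Iterable[SpecimenRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.specimen_id, s.species, s.form) for s in specimens],
        columns=list(REQUIRED_METADATA_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def build_dataset(
    loci: Iterable[AlignedLocus], specimens: Iterable[SpecimenRecord]
) -> Dataset:
    """Cross-reference loci against metadata and log per-group coverage."""
    specimens = list(specimens)
    loci = list(loci)
    if not loci:
        warnings.warn("building a dataset with zero loci", stacklevel=2)
    ds = Dataset(specimens=specimens, loci={l.locus_name: l for l in loci})
    group_of = ds.group_of
    for locus in ds.loci.values():
        counts: dict[str, int] = {}
        for sid in locus.sequences:
            g = group_of[sid]
            counts[g] = counts.get(g, 0) + 1
        logger.info("locus %s: %d sequences, groups %s", locus.locus_name, len(locus), counts)
        if len(counts) < 2:
            warnings.warn(
                f"locus {locus.locus_name!r} covers {len(counts)} group(s); "
                "between-group analyses need at least 2",
                stacklevel=2,
            )
    return ds
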