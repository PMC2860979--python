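"""Character-based diagnosis: pure/private diagnostic sites and assignment.

Instead of summarising divergence into a single distance, the character-based
approach asks which alignment columns carry group-diagnostic states.  Two
filters are applied first:

* columns where any individual carries an IUPAC ambiguity code (a coded
  electropherogram double peak) are deleted outright, and
* columns whose variation is carried by fewer than two individuals are
  dropped, since a lone deviant is indistinguishable from a sequencing error.

Each retained column is then classified per group:

* **PURE** — every member of the group shares one base there, and that base
  occurs in no other group: the site identifies any member unambiguously.
* **PRIVATE** — some base occurs only in this group, but not in all of its
  members: evidence of distinctness, unusable for identification alone.
* **NONE** — neither holds.

Specimen assignment votes a query's base at every PURE column and returns
the group with strictly most matches.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment_io import (
    AlignedLocus,
    AlignmentError,
    BASES,
    SpecimenRecord,
    iupac_states,
)


class SiteStatus(str, Enum):
    PURE = "PURE"
    PRIVATE = "PRIVATE"
    NONE = "NONE"


@dataclass(frozen=True)
class GroupSiteState:
    """Observed unambiguous bases of one group at one column, with status."""

    state_set: frozenset[str]
    status: SiteStatus


@dataclass(frozen=True)
class SiteClassification:
    """Per-group classification of one retained alignment column (1-based)."""

    column: int
    per_group: Mapping[str, GroupSiteState]

    @property
    def informative(self) -> bool:
        return any(g.status is not SiteStatus.NONE for g in self.per_group.values())

    def pure_groups(self) -> list[str]:
        return [g for g, s in self.per_group.items() if s.status is SiteStatus.PURE]


@dataclass
class DiagnosticSiteTable:
    """All retained, classified columns of one locus plus exclusion counts."""

    locus_name: str
    length: int
    groups: list[str]
    retained_columns: list[SiteClassification]
    n_excluded_ambiguous: int
    n_excluded_rare: int

    @property
    def columns(self) -> list[int]:
        return [c.column for c in self.retained_columns]

    @property
    def n_retained(self) -> int:
        return len(self.retained_columns)

    def noninformative_columns(self) -> list[int]:
        return [c.column for c in self.retained_columns if not c.informative]


def ambiguity_filter(locus: AlignedLocus) -> set[int]:
    """Columns (1-based) to delete because any individual has a double peak.

    A column is excluded iff any sequence carries a non-ACGT, non-gap
    character there; gaps are not double peaks and do not trigger exclusion.
    """
    excluded: set[int] = set()
    for seq in locus.sequences.values():
        for pos, ch in enumerate(seq):
            if ch not in "ACGT-":
                excluded.add(pos + 1)
    return excluded


def variable_site_filter(
    locus: AlignedLocus,
    min_variant_carriers: int = 2,
    candidate_columns: Iterable[int] | None = None,
) -> set[int]:
    """Columns (1-based) whose variation is carried by ≥ ``min_variant_carriers``.

    Gaps are ignored when counting carriers.  A column is retained iff the
    number of sequences not carrying the modal base is at least the
    threshold; under a modal tie this retains exactly the columns where
    every tied state has enough carriers.
    """
    if candidate_columns is None:
        candidate_columns = range(1, locus.length + 1)
    seqs = list(locus.sequences.values())
    retained: set[int] = set()
    for col in candidate_columns:
        counts = Counter(
            s[col - 1] for s in seqs if s[col - 1] in BASES
        )
        if not counts:
            continue
        non_modal = sum(counts.values()) - max(counts.values())
        if non_modal >= min_variant_carriers:
            retained.add(col)
    return retained


def _classify_column(
    states_by_group: Mapping[str, frozenset[str]]
) -> dict[str, GroupSiteState]:
    """Apply the PURE / PRIVATE / NONE rules to one column's state sets."""
    out: dict[str, GroupSiteState] = {}
    for group, states in states_by_group.items():
        others: set[str] = set()
        for other, s in states_by_group.items():
            if other != group:
                others |= s
        if not states:
            status = SiteStatus.NONE
        elif len(states) == 1 and not (states & others):
            status = SiteStatus.PURE
        elif any(b not in others for b in states) and len(states) > 1:
            status = SiteStatus.PRIVATE
        else:
            status = SiteStatus.NONE
        out[group] = GroupSiteState(state_set=states, status=status)
    return out


def classify_sites(
    locus: AlignedLocus,
    specimens: Sequence[SpecimenRecord],
    min_variant_carriers: int = 2,
    apply_filters: bool = True,
) -> DiagnosticSiteTable:
    """Filter columns and classify each retained one per group.

    Filters run in order (ambiguity deletion, then the ≥2-carrier rule),
    matching how diagnostic-site figures are conventionally built.
    ``apply_filters=False`` classifies every column (ambiguous characters
    then contribute nothing to state sets), for exploratory use.
    """
    group_of = {s.specimen_id: s.group for s in specimens}
    members: dict[str, list[str]] = {}
    for sid in locus.sequences:
        members.setdefault(group_of[sid], []).append(sid)
    groups = list(members)
    if len(groups) < 2:
        raise ValueError(
            f"locus {locus.locus_name!r}: need ≥2 groups to classify sites, "
            f"have {groups}"
        )

    if apply_filters:
        ambiguous = ambiguity_filter(locus)
        candidates = [c for c in range(1, locus.length + 1) if c not in ambiguous]
        retained = variable_site_filter(locus, min_variant_carriers, candidates)
        n_rare = len(candidates) - len(retained)
        n_amb = len(ambiguous)
    else:
        retained = set(range(1, locus.length + 1))
        n_rare = n_amb = 0

    classifications: list[SiteClassification] = []
    for col in sorted(retained):
        states_by_group = {
            g: frozenset(
                locus.sequences[sid][col - 1]
                for sid in members[g]
                if locus.sequences[sid][col - 1] in BASES
            )
            for g in groups
        }
        classifications.append(
            SiteClassification(column=col, per_group=_classify_column(states_by_group))
        )
    return DiagnosticSiteTable(
        locus_name=locus.locus_name,
        length=locus.length,
        groups=groups,
        retained_columns=classifications,
        n_excluded_ambiguous=n_amb,
        n_excluded_rare=n_rare,
    )


def count_pure_differences(
    table: DiagnosticSiteTable, group_a: str, group_b: str
) -> int:
    """Retained columns where the two groups' state sets are disjoint.

    Disjoint non-empty state sets mean every member of one group differs
    from every member of the other at that column — a fixed character
    difference between the groups.
    """
    for g in (group_a, group_b):
        if g not in table.groups:
            raise KeyError(f"group {g!r} not in table (groups: {table.groups})")
    n = 0
    for site in table.retained_columns:
        sa = site.per_group[group_a].state_set
        sb = site.per_group[group_b].state_set
        if sa and sb and not (sa & sb):
            n += 1
    return n


UNASSIGNED = None


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of diagnostic-site voting for one query sequence."""

    group: str | None  # None = UNASSIGNED
    tally: Mapping[str, int] = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return self.group is not None


def assign_specimen(query: str, table: DiagnosticSiteTable) -> AssignmentResult:
    """Assign an aligned query to a group by voting over PURE columns.

    At every column that is PURE for some group, the query's character votes
    for each group whose pure state it could represent (an ambiguity code
    votes iff the pure state is among its possible bases).  Gaps and the
    fully ambiguous ``N`` carry no information and never vote.  The group
    with strictly most votes wins; ties and empty tallies return UNASSIGNED.
    """
    if len(query) != table.length:
        raise AlignmentError(
            f"query length {len(query)} does not match alignment length "
            f"{table.length} of locus {table.locus_name!r}"
        )
    tally: dict[str, int] = {}
    for site in table.retained_columns:
        pure = site.pure_groups()
        if not pure:
            continue
        states = iupac_states(query[site.column - 1])
        if not states or len(states) == 4:
            continue
        for g in pure:
            (pure_state,) = site.per_group[g].state_set
            if pure_state in states:
                tally[g] = tally.get(g, 0) + 1
    if not tally:
        return AssignmentResult(UNASSIGNED, {})
    best = max(tally.values())
    winners = [g for g, v in tally.items() if v == best]
    group = winners[0] if len(winners) == 1 else UNASSIGNED
    return AssignmentResult(group, tally)


# ---------------------------------------------------------------------------
# writers

def table_to_frame(table: DiagnosticSiteTable) -> pd.DataFrame:
    """Long-format frame: one row per (column, group) with states and status."""
    rows = []
    for site in table.retained_columns:
        for g in table.groups:
            st = site.per_group[g]
            rows.append(
                (
                    table.locus_name,
                    site.column,
                    g,
                    "".join(sorted(st.state_set)),
                    st.status.value,
                    site.informative,
                )
            )
    return pd.DataFrame(
        rows, columns=["locus", "column", "group", "states", "status", "informative"]
    )


def write_site_table(table: DiagnosticSiteTable, path: str | Path) -> None:
    table_to_frame(table).to_csv(path, sep="\t", index=False)


def render_site_alignment(
    table: DiagnosticSiteTable,
    locus: AlignedLocus,
    specimens: Sequence[SpecimenRecord],
) -> str:
    """Text rendering of the retained sites: rows = specimens, cols = sites.

    Column headers are zero-padded 1-based site labels printed vertically;
    sites PURE for the row's group are bracketed, private states are marked
    with ``*``.
    """
    group_of = {s.specimen_id: s.group for s in specimens}
    cols = table.columns
    width = max((len(str(table.length)), 3))
    labels = [str(c).zfill(width) for c in cols]
    id_w = max(len(sid) for sid in locus.sequences) + 2
    lines = []
    for row in range(width):
        lines.append(" " * id_w + " ".join(lab[row] for lab in labels))
    lines.append("")
    for sid, seq in locus.sequences.items():
        g = group_of[sid]
        body = " ".join(seq[c - 1] for c in cols)
        marks = " ".join(
            "="
            if table.retained_columns[k].per_group[g].status is SiteStatus.PURE
            else "*"
            if table.retained_columns[k].per_group[g].status is SiteStatus.PRIVATE
            else " "
            for k in range(len(cols))
        )
        lines.append(f"{sid:<{id_w}}{body}   {g}")
        lines.append(f"{'':<{id_w}}{marks}")
    lines.append("")
    lines.append("= site PURE for the row's group; * state PRIVATE to it")
    return "\n".join(lines)
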