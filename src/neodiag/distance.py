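"""Uncorrected p-distances with pairwise deletion, and group summaries.

The p-distance between two aligned sequences is the proportion of compared
columns at which they differ.  A column enters a pair's comparison only when
both characters are unambiguous bases: gaps and IUPAC ambiguity codes (coded
electropherogram double peaks) are ignored for the affected comparison
(*pairwise deletion*), never for the whole alignment.  A pair with no
comparable column has an *undefined* distance, which propagates as missing —
never as zero.

Group-level summaries report the mean and standard deviation of p over all
pairs between (or within) groups, the layout in which multi-marker barcode
studies conventionally tabulate divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .alignment_io import (
    AlignedLocus,
    AlignmentError,
    Dataset,
    SpecimenRecord,
    iupac_states,
)

#: Sentinel in encoded sequence arrays for "not an unambiguous base".
_EXCLUDED = np.uint8(255)

_ENCODE = np.full(256, _EXCLUDED, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_ENCODE[ord("U")] = _ENCODE[ord("T")]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned sequence as uint8: A,C,G,T → 0..3, all else → 255."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PairwiseDistance:
    """p-distance for one sequence pair after pairwise deletion."""

    p: float
    n_compared: int

    @property
    def defined(self) -> bool:
        return self.n_compared > 0

    @property
    def mismatches(self) -> int:
        return int(round(self.p * self.n_compared)) if self.defined else 0


def pairwise_p(seq_a: str, seq_b: str) -> PairwiseDistance:
    """p-distance between two aligned sequences with pairwise deletion.

    Columns where either character is a gap or any ambiguity code are
    excluded; p is the mismatch proportion over the retained columns.  When
    nothing is comparable the distance is flagged undefined (p = NaN).
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a, b = encode_sequence(seq_a), encode_sequence(seq_b)
    valid = (a != _EXCLUDED) & (b != _EXCLUDED)
    n = int(valid.sum())
    if n == 0:
        return PairwiseDistance(p=float("nan"), n_compared=0)
    mismatches = int(((a != b) & valid).sum())
    return PairwiseDistance(p=mismatches / n, n_compared=n)


@dataclass
class DistanceMatrix:
    """All pairwise p-distances for one locus.

    ``p`` is a symmetric float matrix (NaN = undefined pair) and
    ``n_compared`` the matching matrix of retained-column counts; rows and
    columns follow ``specimen_ids``.
    """

    locus_name: str
    specimen_ids: list[str]
    p: np.ndarray
    n_compared: np.ndarray

    def index_of(self, specimen_id: str) -> int:
        return self.specimen_ids.index(specimen_id)

    def get(self, id_a: str, id_b: str) -> PairwiseDistance:
        i, j = self.index_of(id_a), self.index_of(id_b)
        return PairwiseDistance(float(self.p[i, j]), int(self.n_compared[i, j]))

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)


def distance_matrix(locus: AlignedLocus) -> DistanceMatrix:
    """Compute the full symmetric p-distance matrix for one locus."""
    ids = locus.specimen_ids
    if len(ids) < 2:
        raise AlignmentError(
            f"locus {locus.locus_name!r}: need at least 2 sequences, have {len(ids)}"
        )
    coded = np.stack([encode_sequence(locus.sequences[i]) for i in ids])
    n = len(ids)
    p = np.zeros((n, n), dtype=float)
    nc = np.full((n, n), locus.length, dtype=int)
    for i in range(n):
        valid_i = coded[i] != _EXCLUDED
        nc[i, i] = int(valid_i.sum())
        for j in range(i + 1, n):
            valid = valid_i & (coded[j] != _EXCLUDED)
            m = int(valid.sum())
            nc[i, j] = nc[j, i] = m
            if m == 0:
                p[i, j] = p[j, i] = np.nan
            else:
                d = int(((coded[i] != coded[j]) & valid).sum()) / m
                p[i, j] = p[j, i] = d
    return DistanceMatrix(locus.locus_name, list(ids), p, nc)


@dataclass(frozen=True)
class GroupDistanceSummary:
    """Mean/SD of p over the pair set of one group pair at one locus."""

    locus_name: str
    group_a: str
    group_b: str
    mean_p: float
    sd_p: float
    n_pairs: int
    n_undefined: int = 0

    @property
    def within(self) -> bool:
        return self.group_a == self.group_b


SDEstimator = Literal["sample", "population"]


def _pair_indices(
    matrix: DistanceMatrix,
    group_of: dict[str, str],
    group_a: str,
    group_b: str,
) -> list[tuple[int, int]]:
    members_a = [i for i, s in enumerate(matrix.specimen_ids) if group_of.get(s) == group_a]
    members_b = [i for i, s in enumerate(matrix.specimen_ids) if group_of.get(s) == group_b]
    if group_a == group_b:
        return list(combinations(members_a, 2))
    return [(i, j) for i in members_a for j in members_b]


def group_summary(
    matrix: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
    group_a: str,
    group_b: str,
    sd_estimator: SDEstimator = "sample",
) -> GroupDistanceSummary:
    """Summarise p over all pairs between ``group_a`` and ``group_b``.

    With ``group_a == group_b`` the within-group pair set (n·(n−1)/2 pairs)
    is used.  Undefined pairs are skipped and counted.  The SD defaults to
    the sample estimator (n−1 denominator); ``sd_estimator="population"``
    switches to the n denominator for sensitivity checks.
    """
    group_of = {s.specimen_id: s.group for s in specimens}
    pairs = _pair_indices(matrix, group_of, group_a, group_b)
    if not pairs:
        raise ValueError(
            f"no pairs for groups {group_a!r} vs {group_b!r} in locus "
            f"{matrix.locus_name!r}"
        )
    values = np.array([matrix.p[i, j] for i, j in pairs], dtype=float)
    defined = values[~np.isnan(values)]
    n_undef = len(values) - len(defined)
    if len(defined) == 0:
        mean = sd = float("nan")
    else:
        mean = float(defined.mean())
        if len(defined) == 1:
            sd = 0.0
        else:
            sd = float(defined.std(ddof=1 if sd_estimator == "sample" else 0))
    return GroupDistanceSummary(
        locus_name=matrix.locus_name,
        group_a=group_a,
        group_b=group_b,
        mean_p=mean,
        sd_p=sd,
        n_pairs=len(pairs),
        n_undefined=n_undef,
    )


def all_group_summaries(
    dataset: Dataset,
    sd_estimator: SDEstimator = "sample",
) -> list[GroupDistanceSummary]:
    """Every between-group and within-group summary for every locus.

    Loci with fewer than two sequences, and groups too small for a pair set,
    are skipped with a warning.
    """
    out: list[GroupDistanceSummary] = []
    group_of = dataset.group_of
    for locus in dataset.loci.values():
        if len(locus) < 2:
            warnings.warn(
                f"locus {locus.locus_name!r}: fewer than 2 sequences, skipped",
                stacklevel=2,
            )
            continue
        matrix = distance_matrix(locus)
        present: dict[str, int] = {}
        for sid in locus.sequences:
            g = group_of[sid]
            present[g] = present.get(g, 0) + 1
        groups = [g for g in dataset.groups if g in present]
        if len(groups) < 2:
            warnings.warn(
                f"locus {locus.locus_name!r}: only {len(groups)} group(s); "
                "between-group summaries unavailable",
                stacklevel=2,
            )
        for ga, gb in combinations(groups, 2):
            out.append(group_summary(matrix, dataset.specimens, ga, gb, sd_estimator))
        for g in groups:
            if present[g] >= 2:
                out.append(group_summary(matrix, dataset.specimens, g, g, sd_estimator))
            else:
                warnings.warn(
                    f"group {g!r} has a single member at locus "
                    f"{locus.locus_name!r}; within-group summary skipped",
                    stacklevel=2,
                )
    return out


# ---------------------------------------------------------------------------
# writers

def write_phylip(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write a square PHYLIP-style distance matrix (NaN for undefined)."""
    with open(path, "w") as fh:
        fh.write(f"{matrix.n_specimens}\n")
        for i, sid in enumerate(matrix.specimen_ids):
            row = " ".join(f"{v:.6f}" for v in matrix.p[i])
            fh.write(f"{sid:<12s}{row}\n")


def write_long_tsv(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write one row per unordered pair: specimen_i, specimen_j, p, n_compared."""
    rows = []
    for i, j in combinations(range(matrix.n_specimens), 2):
        rows.append(
            (
                matrix.specimen_ids[i],
                matrix.specimen_ids[j],
                matrix.p[i, j],
                matrix.n_compared[i, j],
            )
        )
    pd.DataFrame(
        rows, columns=["specimen_i", "specimen_j", "p", "n_compared"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def summaries_to_frame(summaries: Iterable[GroupDistanceSummary]) -> pd.DataFrame:
    """Long-format DataFrame of group summaries."""
    return pd.DataFrame(
        [
            (
                s.locus_name,
                s.group_a,
                s.group_b,
                s.mean_p,
                s.sd_p,
                s.n_pairs,
                s.n_undefined,
            )
            for s in summaries
        ],
        columns=[
            "locus",
            "group_a",
            "group_b",
            "mean_p",
            "sd_p",
            "n_pairs",
            "n_undefined",
        ],
    )


def write_summary_table(
    summaries: Iterable[GroupDistanceSummary], path: str | Path
) -> pd.DataFrame:
    """Write a divergence table: rows = group pairs, columns = loci.

    Cells hold ``mean (SD)`` with five / five decimal places, mirroring the
    conventional multi-marker layout.  Between-group rows come first, then
    within-group rows.  Returns the pivoted frame.
    """
    df = summaries_to_frame(summaries)
    df["comparison"] = [
        f"within {a}" if a == b else f"{a} VS {b}"
        for a, b in zip(df.group_a, df.group_b)
    ]
    df["cell"] = [
        "NA" if np.isnan(m) else f"{m:.5f} ({s:.5f})"
        for m, s in zip(df.mean_p, df.sd_p)
    ]
    between = df.loc[df.group_a != df.group_b, "comparison"].drop_duplicates()
    within = df.loc[df.group_a == df.group_b, "comparison"].drop_duplicates()
    order = list(dict.fromkeys([*between, *within]))
    wide = df.pivot_table(
        index="comparison", columns="locus", values="cell", aggfunc="first"
    ).reindex(order)
    wide.to_csv(path, sep="\t")
    return wide
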