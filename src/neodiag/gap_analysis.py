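"""Mismatch distributions and barcoding-gap detection.

A *mismatch distribution* is the histogram of pairwise p-distances split by
comparison category (within each group, and between each pair of groups).
A *barcoding gap* between two groups exists when every between-group
distance exceeds every within-group distance (both groups' within-distances
pooled): identification by a distance threshold is then possible.  Gap
detection always works on the raw distances, never on the binned histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import SpecimenRecord
from .distance import DistanceMatrix, _pair_indices


@dataclass
class MismatchHistogram:
    """Binned pairwise p-distances for one comparison category."""

    locus_name: str
    category: str
    bin_width: float
    counts: dict[int, int]
    n_undefined: int = 0

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())

    def bin_edges(self, index: int) -> tuple[float, float]:
        return index * self.bin_width, (index + 1) * self.bin_width


def _categories(
    matrix: DistanceMatrix, specimens: Sequence[SpecimenRecord]
) -> dict[str, list[tuple[int, int]]]:
    """Partition all unordered pairs into within/between categories."""
    group_of = {s.specimen_id: s.group for s in specimens}
    order: dict[str, None] = {}
    for s in specimens:
        order.setdefault(s.group, None)
    groups = [g for g in order if any(group_of.get(sid) == g for sid in matrix.specimen_ids)]
    cats: dict[str, list[tuple[int, int]]] = {}
    for g in groups:
        cats[f"within {g}"] = _pair_indices(matrix, group_of, g, g)
    for ga, gb in combinations(groups, 2):
        cats[f"{ga} VS {gb}"] = _pair_indices(matrix, group_of, ga, gb)
    return cats


def mismatch_distribution(
    matrix: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
    bin_width: float = 0.005,
) -> list[MismatchHistogram]:
    """Histogram p for every within- and between-group category.

    Bins are half-open ``[k·w, (k+1)·w)``, so a distance exactly on an edge
    falls in the upper bin.  Every defined pair lands in exactly one
    category and one bin; undefined pairs are counted separately.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    out: list[MismatchHistogram] = []
    for category, pairs in _categories(matrix, specimens).items():
        counts: dict[int, int] = {}
        n_undef = 0
        for i, j in pairs:
            p = matrix.p[i, j]
            if np.isnan(p):
                n_undef += 1
                continue
            k = int(np.floor(p / bin_width))
            counts[k] = counts.get(k, 0) + 1
        if not pairs:
            warnings.warn(f"category {category!r} has no pairs", stacklevel=2)
        out.append(
            MismatchHistogram(
                locus_name=matrix.locus_name,
                category=category,
                bin_width=bin_width,
                counts=dict(sorted(counts.items())),
                n_undefined=n_undef,
            )
        )
    return out


@dataclass(frozen=True)
class GapResult:
    """Barcoding-gap verdict for one group pair at one locus."""

    locus_name: str
    group_a: str
    group_b: str
    max_intra: float
    min_inter: float
    n_intra: int
    n_inter: int
    n_undefined: int = 0

    @property
    def gap_size(self) -> float:
        return self.min_inter - self.max_intra

    @property
    def has_gap(self) -> bool:
        return self.gap_size > 0


def barcoding_gap(
    matrix: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
    group_a: str,
    group_b: str,
) -> GapResult:
    """Compare pooled within-distances of two groups against their between-distances.

    Both groups need ≥2 members (for within-pairs); the verdict uses raw
    distances, so it is independent of any histogram binning.  Undefined
    pairs are skipped and counted.
    """
    group_of = {s.specimen_id: s.group for s in specimens}
    sizes = {
        g: sum(1 for sid in matrix.specimen_ids if group_of.get(sid) == g)
        for g in (group_a, group_b)
    }
    for g, n in sizes.items():
        if n < 2:
            raise ValueError(
                f"group {g!r} has {n} member(s) in locus {matrix.locus_name!r}; "
                "barcoding-gap analysis needs ≥2 per group"
            )
    intra_pairs = _pair_indices(matrix, group_of, group_a, group_a) + _pair_indices(
        matrix, group_of, group_b, group_b
    )
    inter_pairs = _pair_indices(matrix, group_of, group_a, group_b)
    intra = np.array([matrix.p[i, j] for i, j in intra_pairs], dtype=float)
    inter = np.array([matrix.p[i, j] for i, j in inter_pairs], dtype=float)
    n_undef = int(np.isnan(intra).sum() + np.isnan(inter).sum())
    intra = intra[~np.isnan(intra)]
    inter = inter[~np.isnan(inter)]
    if len(intra) == 0 or len(inter) == 0:
        raise ValueError(
            f"no defined intra or inter distances for {group_a!r} vs {group_b!r}"
        )
    return GapResult(
        locus_name=matrix.locus_name,
        group_a=group_a,
        group_b=group_b,
        max_intra=float(intra.max()),
        min_inter=float(inter.min()),
        n_intra=len(intra),
        n_inter=len(inter),
        n_undefined=n_undef,
    )


# ---------------------------------------------------------------------------
# writers / plotting

def histograms_to_frame(histograms: Sequence[MismatchHistogram]) -> pd.DataFrame:
    rows = []
    for h in histograms:
        for k, c in h.counts.items():
            lo, hi = h.bin_edges(k)
            rows.append((h.locus_name, h.category, lo, hi, c))
    return pd.DataFrame(rows, columns=["locus", "category", "bin_lo", "bin_hi", "count"])


def write_histograms(histograms: Sequence[MismatchHistogram], path: str | Path) -> None:
    histograms_to_frame(histograms).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def gap_results_to_frame(results: Sequence[GapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.locus_name,
                r.group_a,
                r.group_b,
                r.max_intra,
                r.min_inter,
                r.gap_size,
                r.has_gap,
                r.n_intra,
                r.n_inter,
                r.n_undefined,
            )
            for r in results
        ],
        columns=[
            "locus",
            "group_a",
            "group_b",
            "max_intra",
            "min_inter",
            "gap_size",
            "has_gap",
            "n_intra",
            "n_inter",
            "n_undefined",
        ],
    )


def plot_mismatch(
    histograms: Sequence[MismatchHistogram], path: str | Path, title: str | None = None
) -> None:
    """Stacked-bar mismatch distribution for one locus (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not histograms:
        raise ValueError("no histograms to plot")
    w = histograms[0].bin_width
    max_bin = max((max(h.counts, default=0) for h in histograms), default=0)
    bins = np.arange(max_bin + 2)
    bottom = np.zeros(len(bins))
    fig, ax = plt.subplots(figsize=(8, 4))
    cmap = plt.get_cmap("tab10")
    for idx, h in enumerate(histograms):
        heights = np.array([h.counts.get(int(k), 0) for k in bins], dtype=float)
        ax.bar(
            bins * w,
            heights,
            width=w,
            bottom=bottom,
            align="edge",
            label=h.category,
            color=cmap(idx % 10),
        )
        bottom += heights
    ax.set_xlabel("pairwise distance (p)")
    ax.set_ylabel("number of pairs")
    ax.set_title(title or histograms[0].locus_name)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)
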