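"""Shared fixtures and tiny alignment factories."""

from __future__ import annotations

import numpy as np
import pytest

from neodiag.alignment_io import AlignedLocus, SpecimenRecord


def make_locus(seqs: dict[str, str] | list[str], name: str = "locus") -> AlignedLocus:
    """Build an AlignedLocus from a dict or an auto-ID'd list of sequences."""
    if isinstance(seqs, list):
        seqs = {f"s{i + 1}": s for i, s in enumerate(seqs)}
    length = len(next(iter(seqs.values())))
    return AlignedLocus(locus_name=name, length=length, sequences=dict(seqs))


def make_specimens(groups: dict[str, list[str]]) -> list[SpecimenRecord]:
    """Specimen records from {group_label: [specimen_ids]}; label may be
    'species' or 'species|form'."""
    out = []
    for group, ids in groups.items():
        species, _, form = group.partition("|")
        out.extend(SpecimenRecord(i, species, form) for i in ids)
    return out


def random_alignment(
    rng: np.random.Generator,
    n_seqs: int,
    n_cols: int,
    n_groups: int,
    ambiguity_frac: float = 0.05,
    gap_frac: float = 0.05,
) -> tuple[AlignedLocus, list[SpecimenRecord]]:
    """Random small alignment with mixed IUPAC/gap content and group labels."""
    alphabet = np.array(list("ACGT"))
    extras = np.array(list("RYSWKMBDHVN"))
    rows = []
    for _ in range(n_seqs):
        seq = alphabet[rng.integers(0, 4, n_cols)]
        mask = rng.random(n_cols) < ambiguity_frac
        seq[mask] = extras[rng.integers(0, len(extras), int(mask.sum()))]
        gaps = rng.random(n_cols) < gap_frac
        seq[gaps] = "-"
        rows.append("".join(seq))
    locus = make_locus(rows)
    group_ids: dict[str, list[str]] = {f"g{k}": [] for k in range(n_groups)}
    for i, sid in enumerate(locus.specimen_ids):
        group_ids[f"g{rng.integers(0, n_groups) if i >= n_groups else i}"].append(sid)
    # guarantee every group has at least one member
    specimens = make_specimens({g: ids for g, ids in group_ids.items() if ids})
    return locus, specimens


@pytest.fixture(scope="session")
def default_sim():
    """One simulated study-condition dataset, shared across tests."""
    from neodiag.synthetic_data import default_paper_config, simulate_dataset

    return simulate_dataset(default_paper_config(seed=0))
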