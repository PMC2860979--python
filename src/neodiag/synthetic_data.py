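"""Synthetic multi-locus barcode datasets on the fixed four-group topology.

The generator emulates the statistical structure of a multi-marker copepod
barcoding study: four groups related as
``(cristatus, (plumchrus, (flemingeri-large, flemingeri-small)))``, four
loci with strongly unequal divergence scales (COI ≫ 12S ≫ ITS ≈ 28S), low
within-group diversity, and sporadic two-fold IUPAC ambiguity codes standing
in for electropherogram double peaks.

Sequence change is parameterised by the Jukes–Cantor (JC69) model, the
simplest process with a closed-form relation between divergence ``d``
(expected substitutions per site) and the expected proportion of differing
sites,

    p_diff(d) = (3/4) · (1 − exp(−4d/3)),

which serves as the recovery oracle throughout the test-suite.
:func:`evolve_jc` implements the unconditioned process (independent
per-site Bernoulli substitution) and is what the closed-form checks
exercise.

:func:`simulate_dataset` itself realises the tree under a *no-multiple-hit*
conditioning: per-branch substitution budgets are solved additively on the
mismatch-proportion scale from the configured tip-to-tip divergences, and
every substitution event hits a column not yet touched anywhere in the
locus (columns drawn from one shuffled per-locus pool).  With no repeated
hits, realised pairwise mismatch proportions are exactly additive along
tree paths, so every realised group divergence equals its configured target
up to stochastic rounding of the branch budgets (±1 site).  An
unconditioned realisation would instead inherit the binomial noise of each
shared internal branch — SD √(p(1−p)/L) ≈ 0.014 per site proportion for a
COI-scale species pair — swamping the narrow divergence hierarchy the
generator exists to reproduce.  The cost is mild: saturation (multiple
hits) is not represented, which at these divergences (≤ 0.17
substitutions/site) shifts nothing the pipeline measures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .alignment_io import (
    AlignedLocus,
    Dataset,
    GROUP_SEPARATOR,
    SpecimenRecord,
    build_dataset,
    write_fasta_alignment,
    write_metadata,
)

# The four groups of the fixed rooted topology
# (cristatus, (plumchrus, (flemingeri-large, flemingeri-small))).
CRISTATUS = "N. cristatus"
PLUMCHRUS = "N. plumchrus"
FLEM_LARGE = f"N. flemingeri{GROUP_SEPARATOR}large"
FLEM_SMALL = f"N. flemingeri{GROUP_SEPARATOR}small"
GROUPS: tuple[str, ...] = (CRISTATUS, PLUMCHRUS, FLEM_SMALL, FLEM_LARGE)

_ID_PREFIX = {CRISTATUS: "Ncr", PLUMCHRUS: "Npl", FLEM_SMALL: "Nfs", FLEM_LARGE: "Nfl"}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: two-fold IUPAC codes containing each base (double peak = true base + one more)
_TWOFOLD_FOR_BASE = {"A": "RWM", "C": "YSM", "G": "RSK", "T": "YWK"}


def jc_expected_p(d: float) -> float:
    """Expected proportion of differing sites after divergence ``d`` (JC69)."""
    if d < 0:
        raise ValueError(f"divergence must be non-negative, got {d}")
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def jc_divergence(p: float) -> float:
    """Invert :func:`jc_expected_p`; defined for ``0 ≤ p < 0.75``."""
    if not 0 <= p < 0.75:
        raise ValueError(f"p must be in [0, 0.75) for JC inversion, got {p}")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def evolve_jc(seq: str, d: float, rng: np.random.Generator) -> str:
    """Evolve a sequence for divergence ``d`` under JC69.

    Each site independently substitutes with probability ``p_diff(d)`` to a
    uniformly chosen different base.  Non-ACGT characters are left untouched.
    """
    p = jc_expected_p(d)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    is_base = np.isin(arr, _BASES)
    hit = (rng.random(arr.size) < p) & is_base
    idx = np.flatnonzero(hit)
    if idx.size:
        arr[idx] = _substitute(arr[idx], rng)
    return arr.tobytes().decode("ascii")


def _substitute(bases: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace each base by a uniformly chosen *different* base."""
    # index of current base in ACGT (byte codes are already sorted), shift 1..3 mod 4
    cur = np.searchsorted(_BASES, bases)
    shift = rng.integers(1, 4, size=bases.size)
    return _BASES[(cur + shift) % 4]


def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    k = int(x)
    return k + (1 if rng.random() < x - k else 0)


class _SitePool:
    """Shuffled column indices of one locus, handed out without replacement.

    Guarantees the no-multiple-hit conditioning: every substitution event in
    the locus lands on a distinct column.
    """

    def __init__(self, length: int, rng: np.random.Generator) -> None:
        self._sites = rng.permutation(length)
        self._cursor = 0

    def take(self, k: int) -> np.ndarray:
        if self._cursor + k > self._sites.size:
            raise ValueError(
                "configured divergences require more substituted columns than "
                "the locus has: increase length or lower divergences"
            )
        out = self._sites[self._cursor : self._cursor + k]
        self._cursor += k
        return out


def _branch_realise(
    parent: np.ndarray,
    mismatch_budget: float,
    pool: _SitePool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """One branch: substitute stochastic-round(L·budget) fresh columns.

    Each substituted column flips to a uniformly chosen different base.
    Returns (child sequence, realised substitution count).
    """
    k = _stochastic_round(parent.size * mismatch_budget, rng)
    child = parent.copy()
    if k:
        pos = pool.take(k)
        child[pos] = _substitute(child[pos], rng)
    return child, k


@dataclass
class LocusSpec:
    """Length, divergence targets, within-group diversity and ambiguity rate.

    ``pairwise_divergence`` maps each unordered group pair to the expected
    *specimen-level* (tip-to-tip) substitutions/site; within-group depth is
    subtracted when branch lengths are solved.
    """

    length: int
    pairwise_divergence: dict[frozenset, float]
    intra_diversity: float
    ambiguity_rate: float

    def divergence(self, group_a: str, group_b: str) -> float:
        return self.pairwise_divergence[frozenset((group_a, group_b))]

    def validate(self) -> None:
        if self.length < 1:
            raise ValueError(f"locus length must be ≥1, got {self.length}")
        for key in (self.intra_diversity, self.ambiguity_rate):
            if key < 0:
                raise ValueError("rates must be non-negative")
        needed = {frozenset(p) for p in
                  [(a, b) for i, a in enumerate(GROUPS) for b in GROUPS[i + 1:]]}
        if set(self.pairwise_divergence) != needed:
            raise ValueError("pairwise_divergence must cover all 6 group pairs")
        if any(v < 0 for v in self.pairwise_divergence.values()):
            raise ValueError("divergences must be non-negative")


def solve_branch_lengths(spec: LocusSpec) -> dict[str, float]:
    """Solve per-branch mismatch budgets of the fixed topology from a LocusSpec.

    Configured tip-to-tip divergences (substitutions/site) are mapped to
    expected mismatch proportions through the JC closed form, reduced to
    ancestor-to-ancestor separations by subtracting each group's
    within-group mismatch depth (clipping at zero), and solved additively
    on the tree — exact under the generator's no-multiple-hit realisation.
    The two flemingeri forms' divergences to an outside group are averaged,
    since they share the same path above their common ancestor.  Raises
    when the divergence hierarchy is not realisable on the topology.
    """
    intra = jc_expected_p(spec.intra_diversity)

    def anc(a: str, b: str) -> float:
        return max(jc_expected_p(spec.divergence(a, b)) - intra, 0.0)

    d_ls = anc(FLEM_LARGE, FLEM_SMALL)
    d_fp = 0.5 * (anc(FLEM_LARGE, PLUMCHRUS) + anc(FLEM_SMALL, PLUMCHRUS))
    d_fc = 0.5 * (anc(FLEM_LARGE, CRISTATUS) + anc(FLEM_SMALL, CRISTATUS))
    d_pc = anc(PLUMCHRUS, CRISTATUS)

    r = 0.5 * (d_pc + d_fc - d_fp)  # root to cristatus plus root to node1
    q = 0.5 * (d_pc - d_fc + d_fp)  # node1 to plumchrus
    m = d_fp - q - 0.5 * d_ls       # node1 to node2

    tol = 1e-12
    if q < -tol:
        raise ValueError(
            "unrealizable divergences: d(flemingeri,cristatus) exceeds "
            "d(plumchrus,cristatus) + d(flemingeri,plumchrus)"
        )
    if r < -tol:
        raise ValueError(
            "unrealizable divergences: d(flemingeri,plumchrus) exceeds "
            "d(plumchrus,cristatus) + d(flemingeri,cristatus)"
        )
    if m < -tol:
        raise ValueError(
            "unrealizable divergences: d(large,small) must not exceed "
            "the flemingeri-to-plumchrus divergence "
            "(d(large,small) ≤ d(flemingeri,plumchrus) is required)"
        )
    return {
        "root->cristatus": max(r, 0.0) / 2,
        "root->node1": max(r, 0.0) / 2,
        "node1->plumchrus": max(q, 0.0),
        "node1->node2": max(m, 0.0),
        "node2->large": 0.5 * d_ls,
        "node2->small": 0.5 * d_ls,
    }


DEFAULT_GROUP_SIZES: dict[str, int] = {
    CRISTATUS: 8,
    PLUMCHRUS: 8,
    FLEM_SMALL: 16,
    FLEM_LARGE: 5,
}


@dataclass
class SimulationConfig:
    """Everything needed to generate one multi-locus dataset reproducibly."""

    seed: int
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    locus_specs: dict[str, LocusSpec] = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.group_sizes) != set(GROUPS):
            raise ValueError(f"group_sizes must cover exactly {GROUPS}")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be ≥1")
        n_spec = sum(self.group_sizes.values())
        for name, spec in self.locus_specs.items():
            spec.validate()
            budgets = solve_branch_lengths(spec)  # raises on unrealizable hierarchy
            expected_columns = spec.length * (
                sum(budgets.values())
                + n_spec * jc_expected_p(spec.intra_diversity) / 2
            )
            # rounding can add one column per branch/tip draw
            if expected_columns + len(budgets) + n_spec > spec.length:
                raise ValueError(
                    f"locus {name!r}: divergences need ~{expected_columns:.0f} "
                    f"substituted columns, more than length {spec.length} allows "
                    "under the no-multiple-hit realisation"
                )

    # -- JSON round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "group_sizes": dict(self.group_sizes),
            "locus_specs": {
                name: {
                    "length": s.length,
                    "intra_diversity": s.intra_diversity,
                    "ambiguity_rate": s.ambiguity_rate,
                    "pairwise_divergence": {
                        " VS ".join(sorted(pair)): v
                        for pair, v in s.pairwise_divergence.items()
                    },
                }
                for name, s in self.locus_specs.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        specs = {
            name: LocusSpec(
                length=s["length"],
                intra_diversity=s["intra_diversity"],
                ambiguity_rate=s["ambiguity_rate"],
                pairwise_divergence={
                    frozenset(k.split(" VS ")): v
                    for k, v in s["pairwise_divergence"].items()
                },
            )
            for name, s in data["locus_specs"].items()
        }
        return cls(
            seed=int(data["seed"]),
            group_sizes=dict(data["group_sizes"]),
            locus_specs=specs,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SimulatedDataset:
    """A generated dataset plus its generating truth."""

    dataset: Dataset
    truth: SimulationConfig
    branch_substitutions: dict[str, dict[str, int]]


#: Published mean between-group p-distances the default config targets,
#: per locus: (large vs small, flemingeri vs plumchrus,
#: flemingeri vs cristatus, cristatus vs plumchrus).
TARGET_MEAN_P: dict[str, dict[frozenset, float]] = {
    "COI": {
        frozenset((FLEM_LARGE, FLEM_SMALL)): 0.03586,
        frozenset((FLEM_LARGE, PLUMCHRUS)): 0.15379,
        frozenset((FLEM_SMALL, PLUMCHRUS)): 0.15379,
        frozenset((FLEM_LARGE, CRISTATUS)): 0.16190,
        frozenset((FLEM_SMALL, CRISTATUS)): 0.16190,
        frozenset((CRISTATUS, PLUMCHRUS)): 0.16151,
    },
    "12S": {
        frozenset((FLEM_LARGE, FLEM_SMALL)): 0.00451,
        frozenset((FLEM_LARGE, PLUMCHRUS)): 0.06703,
        frozenset((FLEM_SMALL, PLUMCHRUS)): 0.06703,
        frozenset((FLEM_LARGE, CRISTATUS)): 0.08559,
        frozenset((FLEM_SMALL, CRISTATUS)): 0.08559,
        frozenset((CRISTATUS, PLUMCHRUS)): 0.07596,
    },
    "ITS": {
        frozenset((FLEM_LARGE, FLEM_SMALL)): 0.00058,
        frozenset((FLEM_LARGE, PLUMCHRUS)): 0.00533,
        frozenset((FLEM_SMALL, PLUMCHRUS)): 0.00533,
        frozenset((FLEM_LARGE, CRISTATUS)): 0.00430,
        frozenset((FLEM_SMALL, CRISTATUS)): 0.00430,
        frozenset((CRISTATUS, PLUMCHRUS)): 0.00659,
    },
    "28S": {
        frozenset((FLEM_LARGE, FLEM_SMALL)): 0.00000,
        frozenset((FLEM_LARGE, PLUMCHRUS)): 0.00813,
        frozenset((FLEM_SMALL, PLUMCHRUS)): 0.00813,
        frozenset((FLEM_LARGE, CRISTATUS)): 0.00811,
        frozenset((FLEM_SMALL, CRISTATUS)): 0.00811,
        frozenset((CRISTATUS, PLUMCHRUS)): 0.01081,
    },
}

#: locus lengths (bp of the analysed alignment)
DEFAULT_LENGTHS = {"COI": 658, "12S": 500, "ITS": 900, "28S": 400}

#: within-group diversity (expected substitutions/site between two members):
#: mitochondrial markers are the most variable (within-COI < 0.010,
#: within-12S < 0.005), nuclear ITS barely variable (< 0.002) and 28S
#: invariant within groups.
DEFAULT_INTRA = {"COI": 0.006, "12S": 0.003, "ITS": 0.001, "28S": 0.0}

#: per-base probability of a coded double peak
DEFAULT_AMBIGUITY_RATE = 0.002


def default_paper_config(seed: int) -> SimulationConfig:
    """The study-condition configuration: 8/8/16/5 specimens, four loci.

    Divergence targets are the published between-group mean p-distances,
    inverted through the JC closed form to substitutions/site.
    """
    specs = {}
    for locus, targets in TARGET_MEAN_P.items():
        specs[locus] = LocusSpec(
            length=DEFAULT_LENGTHS[locus],
            pairwise_divergence={
                pair: jc_divergence(p) for pair, p in targets.items()
            },
            intra_diversity=DEFAULT_INTRA[locus],
            ambiguity_rate=DEFAULT_AMBIGUITY_RATE,
        )
    return SimulationConfig(seed=seed, locus_specs=specs)


def _inject_ambiguity(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> str:
    """Replace bases by a containing two-fold IUPAC code with prob ``rate``."""
    out = seq.tobytes().decode("ascii")
    if rate <= 0:
        return out
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if not hits.size:
        return out
    chars = list(out)
    for i in hits:
        options = _TWOFOLD_FOR_BASE[chars[i]]
        chars[i] = options[rng.integers(0, len(options))]
    return "".join(chars)


def _specimen_records(group_sizes: Mapping[str, int]) -> list[SpecimenRecord]:
    records = []
    for group in GROUPS:
        species, _, form = group.partition(GROUP_SEPARATOR)
        for k in range(group_sizes[group]):
            records.append(
                SpecimenRecord(f"{_ID_PREFIX[group]}{k + 1:02d}", species, form)
            )
    return records


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full multi-locus dataset from ``config``.

    Per locus: a uniform-random root sequence is evolved along the fixed
    topology with solved per-branch mismatch budgets under the
    no-multiple-hit conditioning (each substitution event hits a fresh
    column); every specimen is its group ancestor evolved by half the
    within-group diversity (star phylogeny within groups); finally each
    base is independently replaced by a containing two-fold IUPAC code with
    probability ``ambiguity_rate``.  Byte-identical output for identical
    configs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    specimens = _specimen_records(config.group_sizes)
    by_group: dict[str, list[str]] = {g: [] for g in GROUPS}
    for s in specimens:
        by_group[s.group].append(s.specimen_id)

    loci: list[AlignedLocus] = []
    branch_counts: dict[str, dict[str, int]] = {}
    for locus_name, spec in config.locus_specs.items():
        branches = solve_branch_lengths(spec)
        L = spec.length
        pool = _SitePool(L, rng)
        root = _BASES[rng.integers(0, 4, size=L)]
        counts: dict[str, int] = {}

        def step(parent: np.ndarray, branch: str) -> np.ndarray:
            child, k = _branch_realise(parent, branches[branch], pool, rng)
            counts[branch] = k
            return child

        crist_anc = step(root, "root->cristatus")
        node1 = step(root, "root->node1")
        plum_anc = step(node1, "node1->plumchrus")
        node2 = step(node1, "node1->node2")
        large_anc = step(node2, "node2->large")
        small_anc = step(node2, "node2->small")
        ancestors = {
            CRISTATUS: crist_anc,
            PLUMCHRUS: plum_anc,
            FLEM_SMALL: small_anc,
            FLEM_LARGE: large_anc,
        }

        sequences: dict[str, str] = {}
        tip_budget = jc_expected_p(spec.intra_diversity) / 2
        for group in GROUPS:
            for sid in by_group[group]:
                tip, k = _branch_realise(ancestors[group], tip_budget, pool, rng)
                counts[f"tip:{sid}"] = k
                sequences[sid] = _inject_ambiguity(tip, spec.ambiguity_rate, rng)
        loci.append(AlignedLocus(locus_name=locus_name, length=L, sequences=sequences))
        branch_counts[locus_name] = counts

    dataset = build_dataset(loci, specimens)
    return SimulatedDataset(
        dataset=dataset, truth=config, branch_substitutions=branch_counts
    )


def write_simulated(
    sim: SimulatedDataset, outdir: str | Path
) -> dict[str, Path]:
    """Write FASTA per locus, metadata TSV and the truth config JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, locus in sim.dataset.loci.items():
        path = outdir / f"{name}.fasta"
        write_fasta_alignment(locus, path)
        written[f"fasta:{name}"] = path
    meta = outdir / "specimens.tsv"
    write_metadata(sim.dataset.specimens, meta)
    written["metadata"] = meta
    truth = outdir / "truth.json"
    sim.truth.to_json(truth)
    written["truth"] = truth
    return written
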