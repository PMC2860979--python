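"""Independent brute-force oracles, deliberately naive.

Everything here is written as plain per-column Python loops with its own
IUPAC table, so the implementations under test share no code path with it.
"""

from __future__ import annotations

import math

ORACLE_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"}, "-": set(),
}


def oracle_pairwise_p(a: str, b: str) -> tuple[float, int]:
    """(p, n_compared) by a naive per-column loop with pairwise deletion."""
    n = mism = 0
    for x, y in zip(a, b):
        sx, sy = ORACLE_IUPAC[x], ORACLE_IUPAC[y]
        if len(sx) == 1 and len(sy) == 1:
            n += 1
            if sx != sy:
                mism += 1
    return (mism / n if n else math.nan), n


def oracle_classify(
    sequences: dict[str, str],
    group_of: dict[str, str],
    min_variant_carriers: int = 2,
) -> dict[int, dict[str, tuple[frozenset, str]]]:
    """Filter and classify every column by direct set comparison.

    Returns {1-based column: {group: (state_set, status)}} for retained
    columns only, with status in {"PURE", "PRIVATE", "NONE"}.
    """
    ids = list(sequences)
    length = len(sequences[ids[0]])
    groups = sorted({group_of[i] for i in ids})
    out: dict[int, dict[str, tuple[frozenset, str]]] = {}
    for col in range(length):
        chars = [sequences[i][col] for i in ids]
        if any(c not in "ACGT-" for c in chars):
            continue  # double-peak column deleted
        bases = [c for c in chars if c != "-"]
        if not bases:
            continue
        top = max(bases.count(b) for b in set(bases))
        if len(bases) - top < min_variant_carriers:
            continue  # variation carried by too few individuals
        sets = {
            g: frozenset(
                sequences[i][col]
                for i in ids
                if group_of[i] == g and sequences[i][col] != "-"
            )
            for g in groups
        }
        verdicts: dict[str, tuple[frozenset, str]] = {}
        for g in groups:
            others = set().union(*(sets[h] for h in groups if h != g))
            mine = sets[g]
            if len(mine) == 1 and not (mine & others):
                status = "PURE"
            elif len(mine) > 1 and any(b not in others for b in mine):
                status = "PRIVATE"
            else:
                status = "NONE"
            verdicts[g] = (mine, status)
        out[col + 1] = verdicts
    return out
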