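"""Pairwise and multi-set gene-list comparison.

Statistics per pair (against a stated universe): upper-tail hypergeometric
p (P(X >= overlap), the observed count included), BH-adjusted p across the
emitted family, Jaccard index, fold enrichment by the explicit ORA formula
(a/b)/((c-a)/(d-b)) with a = overlap, b = |B|, c = |A|, d = |universe|, and
percentage overlap relative to the smaller set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import pandas as pd
from scipy import stats

from .diffexpr import adjust_pvalues
from .exceptions import StressmetaError

__all__ = [
    "OverlapResult",
    "pairwise_overlap",
    "multiset_partition",
    "MultisetPartition",
    "overlap_matrix",
    "fold_enrichment",
    "hypergeom_upper_tail",
]


def hypergeom_upper_tail(n_overlap: int, n_universe: int, n_a: int, n_b: int) -> float:
    """P(X >= n_overlap) for X ~ Hypergeometric(N, K=n_a, n=n_b)."""
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))


def fold_enrichment(a: int, b: int, c: int, d: int) -> float:
    """(a/b) / ((c - a)/(d - b)); 0 when a = 0, +inf when c = a > 0."""
    if b == 0 or d - b <= 0:
        return float("nan")
    if a == 0:
        return 0.0
    if c - a == 0:
        return float("inf")
    return (a / b) / ((c - a) / (d - b))


@dataclass(frozen=True)
class OverlapResult:
    set_a: str
    set_b: str
    n_a: int
    n_b: int
    n_universe: int
    n_overlap: int
    p_hyper: float
    jaccard: float
    fold_enrichment: float
    pct_overlap: float
    p_adj: float = float("nan")

    def as_row(self) -> dict:
        return {
            "set_A": self.set_a, "set_B": self.set_b,
            "n_A": self.n_a, "n_B": self.n_b,
            "n_universe": self.n_universe, "n_overlap": self.n_overlap,
            "p_hyper": self.p_hyper, "p_adj": self.p_adj,
            "jaccard": self.jaccard, "fold_enrichment": self.fold_enrichment,
            "pct_overlap": self.pct_overlap,
        }


def pairwise_overlap(name_a: str, set_a, name_b: str, set_b, universe) -> OverlapResult:
    """All pairwise overlap statistics for two gene sets against a universe."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not universe:
        raise StressmetaError("universe must be non-empty")
    for name, s in ((name_a, set_a), (name_b, set_b)):
        stray = s - universe
        if stray:
            raise StressmetaError(
                f"set {name!r}: element {sorted(stray)[0]!r} outside the universe")
    inter = set_a & set_b
    n_a, n_b, n_u, n_o = len(set_a), len(set_b), len(universe), len(inter)
    union = n_a + n_b - n_o
    jaccard = n_o / union if union else 0.0
    smaller = min(n_a, n_b)
    pct = 100.0 * n_o / smaller if smaller else 0.0
    return OverlapResult(
        set_a=name_a, set_b=name_b, n_a=n_a, n_b=n_b, n_universe=n_u,
        n_overlap=n_o,
        p_hyper=hypergeom_upper_tail(n_o, n_u, n_a, n_b),
        jaccard=jaccard,
        fold_enrichment=fold_enrichment(n_o, n_b, n_a, n_u),
        pct_overlap=pct,
    )


@dataclass
class MultisetPartition:
    """Membership table, Venn-region counts, shared (>= k) and unique sets."""

    membership: pd.DataFrame  # genes x set-names, bool
    venn_counts: dict[frozenset, int]
    shared: set[str]
    unique: dict[str, set[str]]
    k: int


def multiset_partition(sets: Mapping[str, set], k: int = 2) -> MultisetPartition:
    """Decompose named gene sets into Venn regions, shared and unique genes."""
    if len(sets) < 2:
        raise StressmetaError("multiset_partition needs >= 2 sets")
    names = list(sets)
    genes = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {name: [g in sets[name] for g in genes] for name in names},
        index=pd.Index(genes, name="gene_id"),
    )
    counts = membership.sum(axis=1)
    venn: dict[frozenset, int] = {}
    for _, row in membership.iterrows():
        region = frozenset(n for n in names if row[n])
        venn[region] = venn.get(region, 0) + 1
    shared = set(membership.index[counts >= k])
    unique = {
        name: set(membership.index[(counts == 1) & membership[name]])
        for name in names
    }
    return MultisetPartition(membership=membership, venn_counts=venn,
                             shared=shared, unique=unique, k=k)


def overlap_matrix(
    sets: Mapping[str, Mapping[str, set]] | Mapping[str, set],
    universe,
) -> pd.DataFrame:
    """All-pairs overlap table with BH adjustment across the emitted family.

    ``sets`` is either a flat ``{name: set}`` mapping (one family) or a
    nested ``{group: {name: set}}`` mapping (one sub-family per direction
    group; pairs are formed within groups, BH spans all emitted rows).
    ``universe`` is a single set, or ``{name: tested-universe}`` in which
    case each pair is scored against the intersection of the two members'
    tested universes (sets restricted accordingly).
    """
    first = next(iter(sets.values()))
    groups: Mapping[str, Mapping[str, set]]
    if isinstance(first, Mapping):
        groups = sets  # type: ignore[assignment]
    else:
        groups = {"all": sets}  # type: ignore[dict-item]

    rows = []
    for group, members in groups.items():
        if len(members) < 2:
            raise StressmetaError(f"group {group!r} needs >= 2 sets")
        for name_a, name_b in combinations(members, 2):
            if isinstance(universe, Mapping):
                pair_universe = set(universe[name_a]) & set(universe[name_b])
                set_a = set(members[name_a]) & pair_universe
                set_b = set(members[name_b]) & pair_universe
            else:
                pair_universe = universe
                set_a, set_b = members[name_a], members[name_b]
            res = pairwise_overlap(name_a, set_a, name_b, set_b, pair_universe)
            row = res.as_row()
            row["group"] = group
            rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_pvalues(out["p_hyper"].to_numpy())
    return out
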