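"""Hypergeometric over-representation of result gene sets.

Functional stand-in for web GO tools: each gene set in a user-supplied
collection (GMT) is tested for over-representation in a query set with the
one-sided hypergeometric upper tail against a declared background
universe, followed by Benjamini-Hochberg adjustment across the collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .expression import benjamini_hochberg

__all__ = ["GeneSet", "GeneSetCollection", "CompositionError",
           "hypergeom_test", "enrich"]


class CompositionError(ValueError):
    """Query or set members fall outside the declared universe."""


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} is empty")


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against.

    Members outside the universe are dropped at harmonisation; sets left
    empty afterwards are removed.
    """

    sets: list[GeneSet]
    universe: frozenset[str]

    @classmethod
    def from_dict(cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str],
                  descriptions: Mapping[str, str] | None = None) -> "GeneSetCollection":
        uni = frozenset(universe)
        out = []
        for sid, members in sets.items():
            kept = frozenset(members) & uni
            if kept:
                desc = (descriptions or {}).get(sid, "")
                out.append(GeneSet(sid, desc, kept))
        return cls(sets=out, universe=uni)

    def __len__(self) -> int:
        return len(self.sets)


def hypergeom_test(query: Iterable[str], gene_set: Iterable[str],
                   universe: Iterable[str]) -> float:
    """Upper-tail hypergeometric p-value for the query/set overlap.

    With universe size N, set size K and query size n, returns
    P(overlap >= k) for the observed overlap k. The query must be a subset
    of the universe.
    """
    uni = set(universe)
    q = set(query)
    outside = q - uni
    if outside:
        raise CompositionError(
            f"{len(outside)} query gene(s) outside universe, e.g. {sorted(outside)[:5]}"
        )
    s = set(gene_set) & uni
    k = len(q & s)
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, len(uni), len(s), len(q)))


def enrich(query: Iterable[str], collection: GeneSetCollection,
           fdr_cutoff: float = 0.05, p_cutoff: float | None = None,
           jaccard_groups: bool = False) -> pd.DataFrame:
    """Over-representation of the query against every set in the collection.

    Returns one row per gene set passing the filters: overlap counts,
    hypergeometric p, BH q computed across all sets in the collection,
    and the overlapping members; sorted by (q, p, set_id). ``fdr_cutoff``
    filters on q (<=); ``p_cutoff`` optionally filters on the raw p (<)
    as a separate flag. ``jaccard_groups`` adds a crude relatedness
    grouping: sets are greedily clustered at Jaccard overlap >= 0.5 on
    their query-overlap members.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    q = set(query)
    rows = []
    for gs in collection.sets:
        overlap = q & gs.members
        p = hypergeom_test(q, gs.members, collection.universe)
        rows.append({
            "set_id": gs.set_id,
            "description": gs.description,
            "set_size": len(gs.members),
            "query_size": len(q),
            "overlap": len(overlap),
            "universe_size": len(collection.universe),
            "p_value": p,
            "members": ";".join(sorted(overlap)),
        })
    df = pd.DataFrame(rows)
    df["fdr_q"] = benjamini_hochberg(df["p_value"].values)
    df = df.sort_values(["fdr_q", "p_value", "set_id"], kind="stable").reset_index(drop=True)
    if jaccard_groups:
        df["jaccard_group"] = _jaccard_groups(df)
    if p_cutoff is not None:
        df = df[df["p_value"] < p_cutoff]
    if fdr_cutoff is not None:
        df = df[df["fdr_q"] <= fdr_cutoff]
    return df.reset_index(drop=True)


def _jaccard_groups(df: pd.DataFrame, threshold: float = 0.5) -> list[int]:
    members = [set(m.split(";")) if m else set() for m in df["members"]]
    group = [-1] * len(df)
    next_group = 0
    for i in range(len(df)):
        if group[i] >= 0:
            continue
        group[i] = next_group
        for j in range(i + 1, len(df)):
            if group[j] >= 0 or not members[i] or not members[j]:
                continue
            jac = len(members[i] & members[j]) / len(members[i] | members[j])
            if jac >= threshold:
                group[j] = next_group
        next_group += 1
    return group
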