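"""Overlapping community detection by the clique percolation method (CPM).

Communities are node-unions of connected components of the k-clique
adjacency graph, where two k-cliques are adjacent iff they share exactly
k-1 nodes.  k defaults to 3, the setting used for microsynteny communities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class Community:
    community_id: str
    members: frozenset[str]
    k: int

    def __len__(self) -> int:
        return len(self.members)


def _k_cliques(graph: nx.Graph, k: int) -> set[frozenset[str]]:
    """All k-cliques, obtained by decomposing maximal cliques into their
    k-subsets."""
    cliques: set[frozenset[str]] = set()
    for maximal in nx.find_cliques(graph):
        if len(maximal) >= k:
            for sub in itertools.combinations(sorted(maximal), k):
                cliques.add(frozenset(sub))
    return cliques


def find_communities(graph: nx.Graph, k: int = 3) -> list[Community]:
    """Clique percolation at clique size ``k``.

    Adjacency requires sharing exactly k-1 nodes (two distinct k-cliques
    can never share k).  Communities are ordered by (size descending,
    lexicographically smallest member ascending) and labelled C1, C2, ...
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    cliques = sorted(_k_cliques(graph, k), key=sorted)
    # union-find over cliques keyed by shared (k-1)-subsets
    parent = list(range(len(cliques)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    by_subset: dict[frozenset[str], int] = {}
    for idx, clique in enumerate(cliques):
        for drop in clique:
            key = clique - {drop}
            if key in by_subset:
                union(by_subset[key], idx)
            else:
                by_subset[key] = idx
    groups: dict[int, set[str]] = {}
    for idx, clique in enumerate(cliques):
        groups.setdefault(find(idx), set()).update(clique)
    ordered = sorted(
        groups.values(), key=lambda m: (-len(m), min(m))
    )
    return [
        Community(community_id=f"C{n}", members=frozenset(m), k=k)
        for n, m in enumerate(ordered, 1)
    ]


def community_membership_table(
    communities: Sequence[Community],
    family_ids: Iterable[str],
) -> pd.DataFrame:
    """Per-gene table of community ids; multi-membership ';'-joined in
    community-id order, unclustered genes labelled 'none'."""
    membership: dict[str, list[str]] = {g: [] for g in family_ids}
    for com in communities:
        for g in sorted(com.members):
            membership.setdefault(g, []).append(com.community_id)
    rows = [
        {"gene_id": g, "communities": ";".join(ids) if ids else "none"}
        for g, ids in sorted(membership.items())
    ]
    return pd.DataFrame(rows)


def communities_table(communities: Sequence[Community]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"community_id": c.community_id, "size": len(c),
             "members": ";".join(sorted(c.members))}
            for c in communities
        ]
    )
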