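"""Synteny-network assembly and family subnetwork extraction.

The global network has one node per gene appearing in any collinear block
and one unweighted edge per unordered anchor pair; an edge anchored in
several blocks carries all supporting block ids as annotation.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .collinearity import CollinearBlock
from .core_io import GeneRecord

logger = logging.getLogger(__name__)


def build_network(
    blocks: Sequence[CollinearBlock],
    genes: Sequence[GeneRecord] | None = None,
) -> nx.Graph:
    """One edge per unordered anchor pair; block support merged into the
    ``blocks`` edge attribute.  Node ``species`` attributes come from the
    gene table when given (error if an anchor gene is missing from it)."""
    species: Mapping[str, str] | None = None
    if genes is not None:
        species = {g.gene_id: g.species for g in genes}
    graph = nx.Graph()
    for blk in blocks:
        for anchor in blk.anchors:
            a, b = anchor.gene_a, anchor.gene_b
            if a == b:
                continue
            for g in (a, b):
                if species is not None and g not in species:
                    raise KeyError(f"anchor gene {g} absent from gene table")
                if g not in graph:
                    graph.add_node(
                        g,
                        species=species[g] if species is not None
                        else g.split("|", 1)[0],
                    )
            if graph.has_edge(a, b):
                if blk.block_id not in graph.edges[a, b]["blocks"]:
                    graph.edges[a, b]["blocks"].append(blk.block_id)
            else:
                graph.add_edge(a, b, blocks=[blk.block_id])
    return graph


def extract_family_subnetwork(
    network: nx.Graph,
    family_ids: Iterable[str],
    genes: Sequence[GeneRecord] | None = None,
) -> nx.Graph:
    """Induced subgraph on the family's genes.

    Family members without any syntenic partner are retained as degree-0
    nodes (their species taken from ``genes`` when provided); if no family
    gene is syntenic at all a warning is logged.
    """
    fam = set(family_ids)
    if not fam:
        raise ValueError("family_ids is empty")
    present = fam & set(network.nodes)
    if not present:
        logger.warning("no family gene has any syntenic relationship")
    sub = nx.Graph(network.subgraph(present).copy())
    if genes is not None:
        for g in genes:
            if g.gene_id in fam and g.gene_id not in sub:
                sub.add_node(g.gene_id, species=g.species)
    return sub


def block_context(
    blocks: Sequence[CollinearBlock],
    family_ids: Iterable[str],
) -> dict[str, list[tuple[str, str]]]:
    """All anchor pairs of every block containing at least one family
    anchor, grouped by block id."""
    fam = set(family_ids)
    out: dict[str, list[tuple[str, str]]] = {}
    for blk in blocks:
        if any(a.gene_a in fam or a.gene_b in fam for a in blk.anchors):
            out[blk.block_id] = [(a.gene_a, a.gene_b) for a in blk.anchors]
    return out


def edge_table(network: nx.Graph) -> pd.DataFrame:
    rows = [
        {"node1": min(a, b), "node2": max(a, b),
         "block_ids": ";".join(sorted(data.get("blocks", [])))}
        for a, b, data in network.edges(data=True)
    ]
    return pd.DataFrame(rows).sort_values(
        ["node1", "node2"], ignore_index=True
    ) if rows else pd.DataFrame(columns=["node1", "node2", "block_ids"])


def node_table(network: nx.Graph) -> pd.DataFrame:
    rows = [
        {"node": n, "species": network.nodes[n].get("species", ""),
         "degree": network.degree[n]}
        for n in sorted(network.nodes)
    ]
    return pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["node", "species", "degree"]
    )
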