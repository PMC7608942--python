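"""Pairwise collinear block detection by dynamic-programming anchor chaining.

Anchors are homologous gene pairs placed at (rank_i, rank_j) on a chromosome
pair.  Blocks are extracted greedily: the maximum-score monotone chain
(forward or inverted) is found by DP, emitted if long enough, its anchors
removed, and the search repeated.  Scoring is
``m * match_score + gap_penalty * sum((di-1) + (dj-1))`` with rank-gap
extensions capped at ``max_gaps`` in both genomes, mirroring the documented
defaults of the standard collinearity tool (50 / -1 / 5 / 25).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core_io import GeneRecord, HomologyHit, index_by_id

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    i: int
    j: int
    weight: float = 0.0


@dataclass(frozen=True)
class ChainParams:
    match_score: float = 50.0
    gap_penalty: float = -1.0
    match_size: int = 5
    max_gaps: int = 25

    def __post_init__(self) -> None:
        if self.match_size < 2:
            raise ValueError("match_size must be >= 2")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")
        if self.gap_penalty > 0:
            raise ValueError("gap_penalty must be <= 0")


#: chromosome-pair key: ((species_a, chrom_a), (species_b, chrom_b)), sorted
PairKey = tuple[tuple[str, str], tuple[str, str]]


@dataclass
class CollinearBlock:
    species_a: str
    chrom_a: str
    species_b: str
    chrom_b: str
    anchors: list[Anchor]
    orientation: str  # "forward" | "inverted"
    score: float
    block_id: str = ""

    def __len__(self) -> int:
        return len(self.anchors)


def build_anchor_sets(
    genes: Sequence[GeneRecord],
    hits: Iterable[HomologyHit],
) -> dict[PairKey, list[Anchor]]:
    """Group homology hits into anchors per unordered chromosome pair.

    Intra-species (and intra-chromosome) comparisons are included; on a
    chromosome self-comparison each unordered anchor appears once with
    i < j, so the trivial self-diagonal never exists.
    """
    idx = index_by_id(genes)
    groups: dict[PairKey, list[Anchor]] = {}
    for hit in hits:
        ga = idx.get(hit.query_id)
        gb = idx.get(hit.subject_id)
        if ga is None or gb is None:
            missing = [
                g for g, r in ((hit.query_id, ga), (hit.subject_id, gb)) if r is None
            ]
            raise KeyError(f"hit endpoint(s) missing from gene table: {missing}")
        if ga.gene_id == gb.gene_id:
            continue
        ka, kb = (ga.species, ga.chrom), (gb.species, gb.chrom)
        if (kb, gb.rank, gb.gene_id) < (ka, ga.rank, ga.gene_id):
            ga, gb = gb, ga
            ka, kb = kb, ka
        groups.setdefault((ka, kb), []).append(
            Anchor(gene_a=ga.gene_id, gene_b=gb.gene_id, i=ga.rank, j=gb.rank,
                   weight=hit.bitscore)
        )
    for key in groups:
        groups[key].sort(key=lambda a: (a.i, a.j, a.gene_a, a.gene_b))
    return groups


def _best_chain(
    anchors: Sequence[Anchor], params: ChainParams, orientation: str
) -> tuple[float, list[int]] | None:
    """Maximum-score monotone chain by DP over anchors sorted by (i, j).

    Ties break toward the longer chain, then the smaller start i, then the
    smaller start j.  Returns (score, anchor indices) or None.
    """
    order = sorted(
        range(len(anchors)), key=lambda k: (anchors[k].i, anchors[k].j)
    )
    if not order:
        return None
    inverted = orientation == "inverted"
    ms, gp, mg = params.match_score, params.gap_penalty, params.max_gaps
    # per anchor: (score, length, -start_i, -start_j), maximized lexically
    best_key: dict[int, tuple[float, int, int, int]] = {}
    pred: dict[int, int | None] = {}
    for pos, c in enumerate(order):
        ac = anchors[c]
        cand: tuple[float, int, int, int] = (ms, 1, -ac.i, -ac.j)
        cand_pred: int | None = None
        for p in order[:pos]:
            ap = anchors[p]
            if ap.i >= ac.i:
                continue
            gap_i = ac.i - ap.i - 1
            if gap_i > mg:
                continue
            if inverted:
                if ap.j <= ac.j:
                    continue
                gap_j = ap.j - ac.j - 1
            else:
                if ap.j >= ac.j:
                    continue
                gap_j = ac.j - ap.j - 1
            if gap_j > mg:
                continue
            ps, pl, psi, psj = best_key[p]
            key = (ps + ms + gp * (gap_i + gap_j), pl + 1, psi, psj)
            if key > cand:
                cand = key
                cand_pred = p
        best_key[c] = cand
        pred[c] = cand_pred
    end = max(best_key, key=lambda k: best_key[k])
    score = best_key[end][0]
    chain: list[int] = []
    node: int | None = end
    while node is not None:
        chain.append(node)
        node = pred[node]
    chain.reverse()
    return score, chain


def best_chain_score(anchors: Sequence[Anchor], params: ChainParams) -> float:
    """Best chain score over both orientations (no minimum-length cut);
    0.0 for an empty anchor set."""
    best = 0.0
    for orientation in ("forward", "inverted"):
        res = _best_chain(anchors, params, orientation)
        if res is not None:
            best = max(best, res[0])
    return best


def chain_anchors(
    anchors: Sequence[Anchor],
    params: ChainParams | None = None,
    species_a: str = "",
    chrom_a: str = "",
    species_b: str = "",
    chrom_b: str = "",
) -> list[CollinearBlock]:
    """Greedy best-chain extraction for one chromosome pair.

    Repeatedly finds the maximum-score chain (both orientations; forward
    preferred on exact ties), emits it as a block when it has at least
    ``match_size`` anchors, removes its anchors, and stops when the best
    remaining chain is shorter than ``match_size``.
    """
    params = params or ChainParams()
    remaining = list(anchors)
    blocks: list[CollinearBlock] = []
    k = 0
    while remaining:
        candidates = []
        for orientation in ("forward", "inverted"):
            res = _best_chain(remaining, params, orientation)
            if res is not None:
                score, chain = res
                a0 = remaining[chain[0]]
                candidates.append(
                    ((score, len(chain), -a0.i, -a0.j, orientation == "forward"),
                     orientation, chain)
                )
        if not candidates:
            break
        _, orientation, chain = max(candidates)
        if len(chain) < params.match_size:
            break
        chosen = [remaining[c] for c in chain]
        score = params.match_score * len(chosen) + params.gap_penalty * sum(
            (b.i - a.i - 1) + abs(b.j - a.j) - 1
            for a, b in zip(chosen, chosen[1:])
        )
        k += 1
        blocks.append(
            CollinearBlock(
                species_a=species_a, chrom_a=chrom_a,
                species_b=species_b, chrom_b=chrom_b,
                anchors=chosen, orientation=orientation, score=score,
                block_id=f"{species_a}.{chrom_a}-{species_b}.{chrom_b}#{k}",
            )
        )
        chain_set = set(chain)
        remaining = [a for idx, a in enumerate(remaining) if idx not in chain_set]
    return blocks


def validate_block(block: CollinearBlock, params: ChainParams) -> None:
    """Check the block invariants; raises ValueError on violation."""
    if len(block.anchors) < params.match_size:
        raise ValueError(f"{block.block_id}: fewer than match_size anchors")
    for a, b in zip(block.anchors, block.anchors[1:]):
        if b.i <= a.i:
            raise ValueError(f"{block.block_id}: i not strictly increasing")
        if block.orientation == "forward" and b.j <= a.j:
            raise ValueError(f"{block.block_id}: j not strictly increasing")
        if block.orientation == "inverted" and b.j >= a.j:
            raise ValueError(f"{block.block_id}: j not strictly decreasing")
        if b.i - a.i - 1 > params.max_gaps or abs(b.j - a.j) - 1 > params.max_gaps:
            raise ValueError(f"{block.block_id}: rank gap exceeds max_gaps")


def detect_tandems(
    genes: Sequence[GeneRecord],
    hits: Iterable[HomologyHit],
    window: int = 1,
) -> list[tuple[str, ...]]:
    """Tandem arrays: connected chains of homologous same-chromosome gene
    pairs whose rank difference is at most ``window``.

    Returns one tuple per array, members sorted by rank.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    idx = index_by_id(genes)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    members: set[str] = set()
    for hit in hits:
        ga, gb = idx.get(hit.query_id), idx.get(hit.subject_id)
        if ga is None or gb is None or ga.gene_id == gb.gene_id:
            continue
        if (ga.species, ga.chrom) != (gb.species, gb.chrom):
            continue
        if abs(ga.rank - gb.rank) <= window:
            parent.setdefault(ga.gene_id, ga.gene_id)
            parent.setdefault(gb.gene_id, gb.gene_id)
            union(ga.gene_id, gb.gene_id)
            members.update((ga.gene_id, gb.gene_id))
    arrays: dict[str, list[str]] = {}
    for g in members:
        arrays.setdefault(find(g), []).append(g)
    return sorted(
        tuple(sorted(v, key=lambda g: idx[g].rank)) for v in arrays.values()
    )


def run_all_pairs(
    genomes: dict[str, Sequence[GeneRecord]],
    hits: Iterable[HomologyHit],
    params: ChainParams | None = None,
) -> tuple[list[CollinearBlock], pd.DataFrame]:
    """Chain every unordered genome pair including self-comparisons —
    n(n+1)/2 comparisons — and return all blocks plus a manifest."""
    params = params or ChainParams()
    species = sorted(genomes)
    if len(species) != len(set(species)):
        raise ValueError("duplicate species identifiers")
    all_genes = [g for sp in species for g in genomes[sp]]
    groups = build_anchor_sets(all_genes, hits)
    blocks: list[CollinearBlock] = []
    counts: dict[tuple[str, str], int] = {}
    for a_idx, sp_a in enumerate(species):
        for sp_b in species[a_idx:]:
            counts[(sp_a, sp_b)] = 0
    for ((sp_a, ch_a), (sp_b, ch_b)), anchors in sorted(groups.items()):
        pair = (sp_a, sp_b) if sp_a <= sp_b else (sp_b, sp_a)
        if pair not in counts:
            continue
        found = chain_anchors(
            anchors, params,
            species_a=sp_a, chrom_a=ch_a, species_b=sp_b, chrom_b=ch_b,
        )
        for blk in found:
            validate_block(blk, params)
        counts[pair] += len(found)
        blocks.extend(found)
    manifest = pd.DataFrame(
        [
            {"species_a": a, "species_b": b, "n_blocks": n}
            for (a, b), n in sorted(counts.items())
        ]
    )
    return blocks, manifest


def write_collinearity(blocks: Sequence[CollinearBlock], path) -> None:
    """Plain-text collinearity file: one '## block' header per block, then
    one tab-separated anchor pair per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for blk in blocks:
            fh.write(
                f"## block {blk.block_id} orientation={blk.orientation} "
                f"score={blk.score:g} n={len(blk)}\n"
            )
            for a in blk.anchors:
                fh.write(f"{a.gene_a}\t{a.gene_b}\t{a.i}\t{a.j}\n")
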