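"""Phylogenomic synteny profiling: community x species matrices ordered by
a species tree, per-species copy numbers, and per-community exon summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from .communities import Community
from .core_io import GeneRecord, tree_leaf_order

logger = logging.getLogger(__name__)


def build_profile(
    communities: Sequence[Community],
    genes: Sequence[GeneRecord],
    tree: dendropy.Tree,
    family_ids: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Community x species count matrix plus its presence/absence variant.

    Rows are community ids plus a ``none`` row for unclustered family genes;
    columns follow the species-tree leaf order.  Genes in several
    communities are counted in each, so column sums over all rows equal the
    per-species family copy number plus multi-membership.
    """
    order = tree_leaf_order(tree)
    species_of = {g.gene_id: g.species for g in genes}
    fam = set(family_ids) if family_ids is not None else set(species_of)
    missing = sorted({species_of[g] for g in fam if g in species_of} - set(order))
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    clustered: set[str] = set()
    rows: dict[str, dict[str, int]] = {}
    for com in communities:
        counts = {sp: 0 for sp in order}
        for g in com.members:
            sp = species_of.get(g)
            if sp is None:
                raise KeyError(f"community member {g} absent from gene table")
            counts[sp] += 1
            clustered.add(g)
        rows[com.community_id] = counts
    none_counts = {sp: 0 for sp in order}
    for g in fam - clustered:
        if g in species_of:
            none_counts[species_of[g]] += 1
    rows["none"] = none_counts
    profile = pd.DataFrame.from_dict(rows, orient="index", columns=order)
    presence = (profile > 0).astype(int)
    return profile, presence


def copy_number_table(
    genes: Sequence[GeneRecord],
    family_ids: Iterable[str],
) -> pd.DataFrame:
    """Per-species family copy counts; species without a copy report 0."""
    fam = set(family_ids)
    counts: dict[str, int] = {}
    for g in genes:
        counts.setdefault(g.species, 0)
        if g.gene_id in fam:
            counts[g.species] += 1
    return pd.DataFrame(
        [{"species": sp, "copies": n} for sp, n in sorted(counts.items())]
    )


@dataclass(frozen=True)
class ExonSummary:
    group: str
    n: int
    mean: float
    median: float
    mode: int
    histogram: dict[int, int]


def exon_summary(
    communities: Sequence[Community],
    genes: Sequence[GeneRecord],
    family_ids: Iterable[str] | None = None,
) -> list[ExonSummary]:
    """Exon-count summary + histogram per community (and for unclustered
    genes under ``none``).  Modal ties report the smallest modal value."""
    exon_of = {
        g.gene_id: g.exon_count for g in genes if g.exon_count is not None
    }
    if not exon_of:
        raise ValueError(
            "no exon counts available; provide GFF3-derived gene records"
        )
    fam = set(family_ids) if family_ids is not None else None
    clustered: set[str] = set()
    groups: list[tuple[str, list[str]]] = []
    for com in communities:
        groups.append((com.community_id, sorted(com.members)))
        clustered.update(com.members)
    if fam is not None:
        groups.append(("none", sorted(fam - clustered)))
    out: list[ExonSummary] = []
    for name, members in groups:
        values = sorted(exon_of[g] for g in members if g in exon_of)
        if not values:
            logger.warning("group %s has no exon counts; excluded", name)
            continue
        hist: dict[int, int] = {}
        for v in values:
            hist[v] = hist.get(v, 0) + 1
        top = max(hist.values())
        mode = min(v for v, c in hist.items() if c == top)
        s = pd.Series(values)
        out.append(
            ExonSummary(
                group=name, n=len(values), mean=float(s.mean()),
                median=float(s.median()), mode=mode, histogram=hist,
            )
        )
    return out


def exon_summary_tables(
    summaries: Sequence[ExonSummary],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(summary, histogram) data frames for serialization."""
    summary = pd.DataFrame(
        [
            {"group": s.group, "n": s.n, "mean": s.mean,
             "median": s.median, "mode": s.mode}
            for s in summaries
        ]
    )
    hist = pd.DataFrame(
        [
            {"group": s.group, "exon_count": v, "n_genes": c}
            for s in summaries
            for v, c in sorted(s.histogram.items())
        ]
    )
    return summary, hist
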