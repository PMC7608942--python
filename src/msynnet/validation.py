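"""Self-validation experiments: planted-block recovery, NG86 estimator
recovery, and end-to-end scenario analyses with known ground truth.

These run the pipeline on data from the bundled simulator and measure how
well each stage recovers what was planted; both the test suite and the
reproduction script build on them.
"""

from __future__ import annotations

import random
import numpy as np

from .collinearity import Anchor, ChainParams, chain_anchors, run_all_pairs
from .communities import find_communities
from .molevo import CodonAlignment, group_ks, ng86
from .network import build_network, extract_family_subnetwork
from .profiling import exon_summary
from .simulate import (
    SimResult,
    evolve_cds,
    mammal_scenario,
    plant_scenario,
    random_cds,
    simulate_dataset,
)


# ---------------------------------------------------------------------------
# planted collinear blocks


def planted_anchor_case(
    rng: random.Random, params: ChainParams
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """One chromosome pair: 1-3 planted collinear runs of 5-20 anchors
    (forward or inverted, rank steps 1-3) plus ~5% uniform noise anchors.

    Noise anchors are rejected when they fall inside a planted run's
    max_gaps corridor — an anchor collinear with and adjacent to a planted
    run is legitimately part of the chain, so leaving it in would make
    anchor-exact recovery ill-defined rather than hard.
    Returns (planted, noise) rank-pair lists.
    """
    n_blocks = rng.randrange(1, 4)
    planted: list[tuple[int, int]] = []
    used_i: set[int] = set()
    used_j: set[int] = set()
    corridors: list[tuple[int, int, int, int]] = []
    base_i = base_j = 0
    for _ in range(n_blocks):
        length = rng.randrange(5, 21)
        base_i += rng.randrange(30, 60)
        base_j += rng.randrange(30, 60)
        sign = rng.choice([1, -1])
        run = []
        i = base_i
        j = base_j if sign == 1 else base_j + 3 * length + 10
        for _ in range(length):
            i += 1 + rng.randrange(0, 3)
            j += sign * (1 + rng.randrange(0, 3))
            run.append((i, j))
        planted.extend(run)
        corridors.append(
            (min(x for x, _ in run), max(x for x, _ in run),
             min(y for _, y in run), max(y for _, y in run))
        )
        used_i.update(x for x, _ in run)
        used_j.update(y for _, y in run)
        base_i = max(x for x, _ in run)
        base_j = max(y for _, y in run)
    n_noise = max(1, int(0.05 * len(planted)))
    noise: list[tuple[int, int]] = []
    margin = params.max_gaps + 1
    while len(noise) < n_noise:
        x = rng.randrange(0, base_i + 100)
        y = rng.randrange(0, base_j + 100)
        if x in used_i or y in used_j:
            continue
        if any(
            lo_i - margin <= x <= hi_i + margin
            and lo_j - margin <= y <= hi_j + margin
            for lo_i, hi_i, lo_j, hi_j in corridors
        ):
            continue
        noise.append((x, y))
        used_i.add(x)
        used_j.add(y)
    return planted, noise


def planted_block_recovery(
    n_cases: int, seed: int, params: ChainParams | None = None
) -> tuple[float, float]:
    """Anchor-level (precision, recall) of chaining on planted runs."""
    params = params or ChainParams()
    rng = random.Random(seed)
    tp = fp = fn = 0
    for _ in range(n_cases):
        planted, noise = planted_anchor_case(rng, params)
        anchors = [
            Anchor(f"a{i}", f"b{j}", i, j)
            for i, j in sorted(set(planted) | set(noise))
        ]
        found = {
            (a.i, a.j)
            for blk in chain_anchors(anchors, params)
            for a in blk.anchors
        }
        tp += len(found & set(planted))
        fp += len(found - set(planted))
        fn += len(set(planted) - found)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return precision, recall


# ---------------------------------------------------------------------------
# NG86 estimator recovery


def ks_recovery(
    true_distance: float,
    n_pairs: int,
    seed: int,
    n_codons: int = 300,
) -> dict:
    """Evolve ``n_pairs`` parent/child CDS pairs to a known synonymous
    distance and re-estimate it with NG86; returns the mean estimate, its
    mean relative error and the saturation count."""
    rng = np.random.default_rng([seed, int(true_distance * 1000)])
    estimates = []
    n_saturated = 0
    for _ in range(n_pairs):
        parent = random_cds(rng, n_codons)
        child = evolve_cds(parent, true_distance, rng)
        est = ng86(CodonAlignment("parent", "child", parent, child))
        if est.Ks is None:
            n_saturated += 1
        else:
            estimates.append(est.Ks)
    mean = float(np.mean(estimates)) if estimates else float("nan")
    return {
        "true": true_distance,
        "mean_ks": mean,
        "rel_error": (mean - true_distance) / true_distance,
        "n_saturated": n_saturated,
        "n_pairs": n_pairs,
    }


# ---------------------------------------------------------------------------
# end-to-end scenarios


def _family_communities(sim: SimResult, k: int = 3):
    blocks, _ = run_all_pairs(sim.genomes, sim.hits)
    net = build_network(blocks, sim.all_genes())
    fam = sim.focal_family_ids()
    sub = extract_family_subnetwork(net, fam, sim.all_genes())
    return find_communities(sub, k=k), fam, blocks


def _species_of(gene_id: str) -> str:
    return gene_id.split("|", 1)[0]


def mammal_scenario_analysis(seed: int) -> dict:
    """Run the mammal scenario end to end and measure the community
    structure, exon histograms and per-community Ks."""
    sim = simulate_dataset(mammal_scenario(seed))
    communities, fam, _ = _family_communities(sim)
    outgroup_genes = [g for g in fam if _species_of(g) == "outg"]
    out_memberships = [
        c.community_id for c in communities
        if any(g in c.members for g in outgroup_genes)
    ]
    with_out = next(
        (c for c in communities if any(_species_of(g) == "outg" for g in c.members)),
        None,
    )
    without_out = next(
        (c for c in communities if all(_species_of(g) != "outg" for g in c.members)),
        None,
    )
    result = {
        "n_communities": len(communities),
        "community_sizes": sorted((len(c) for c in communities), reverse=True),
        "outgroup_n_copies": len(outgroup_genes),
        "outgroup_n_communities": len(out_memberships),
    }
    summaries = {
        s.group: s for s in exon_summary(communities, sim.all_genes(), fam)
    }
    if with_out is not None and without_out is not None:
        conserved, transposed = with_out, without_out
        ks, _ = group_ks(
            {
                "conserved": sorted(conserved.members),
                "transposed": sorted(transposed.members),
            },
            sim.cds,
        )
        by = ks.set_index("group")
        hist_t = summaries[transposed.community_id].histogram
        hist_c = summaries[conserved.community_id].histogram
        result.update(
            {
                "conserved_mean_ks": float(by.loc["conserved", "mean_Ks"]),
                "transposed_mean_ks": float(by.loc["transposed", "mean_Ks"]),
                "conserved_pct_9_exons": 100.0 * hist_c.get(9, 0) / sum(hist_c.values()),
                "transposed_pct_1_2_exons": 100.0
                * (hist_t.get(1, 0) + hist_t.get(2, 0))
                / sum(hist_t.values()),
            }
        )
    return result


def plant_scenario_analysis(seed: int) -> dict:
    """Run the plant scenario end to end and classify communities by the
    species they span."""
    sim = simulate_dataset(plant_scenario(seed))
    communities, fam, _ = _family_communities(sim)
    all_species = set(sim.genomes)
    transposed_species = {
        _species_of(g)
        for g in fam
        if sim.truth.contexts[g].startswith("ctx_transposed")
    }
    spanning = [
        c for c in communities
        if {_species_of(g) for g in c.members} == all_species
    ]
    restricted = [
        c for c in communities
        if set() < {_species_of(g) for g in c.members} <= transposed_species
        and c not in spanning
    ]
    return {
        "n_communities": len(communities),
        "n_species": len(all_species),
        "n_superclusters": len(spanning),
        "supercluster_n_species": len(
            {_species_of(g) for g in spanning[0].members}
        ) if spanning else 0,
        "n_restricted_communities": len(restricted),
        "restricted_species": sorted(
            {_species_of(g) for c in restricted for g in c.members}
        ),
        "transposed_lineage": sorted(transposed_species),
    }
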