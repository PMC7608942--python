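"""End-to-end orchestration: simulate (optional) -> collinearity ->
network -> family subnetwork -> communities -> profiling -> group Ks.

Configured either from a :class:`PipelineConfig` built in code or from an
INI-style ``key = value`` config file (see :func:`load_config`).
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, core_io
from .collinearity import ChainParams, run_all_pairs, detect_tandems, write_collinearity
from .communities import (
    communities_table,
    community_membership_table,
    find_communities,
)
from .molevo import group_ks
from .network import (
    block_context,
    build_network,
    edge_table,
    extract_family_subnetwork,
    node_table,
)
from .profiling import build_profile, copy_number_table, exon_summary, exon_summary_tables
from .simulate import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Either ``sim`` (a simulation scenario) or real-input paths; never both."""

    outdir: Path
    sim: SimConfig | None = None
    # real inputs
    gff3: dict[str, Path] = field(default_factory=dict)  # species -> path
    bed: dict[str, Path] = field(default_factory=dict)
    cds_fasta: list[Path] = field(default_factory=list)
    hits_path: Path | None = None
    family_path: Path | None = None
    tree_path: Path | None = None
    # stage options
    chain: ChainParams = field(default_factory=ChainParams)
    k: int = 3
    evalue_max: float = 1e-10
    max_hits: int = 20
    tandem_window: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        real = bool(self.gff3 or self.bed)
        if self.sim is not None and real:
            raise ValueError("provide either a simulation config or real inputs, not both")
        if self.sim is None and not real:
            raise ValueError("no inputs configured")


def load_config(path: str | Path) -> PipelineConfig:
    """INI config: [inputs]/[simulate]/[chain]/[communities]/[kaks]/[output]
    sections of ``key = value`` pairs (see the README for the schema)."""
    parser = configparser.ConfigParser()
    with open(path, encoding="utf-8") as fh:
        parser.read_file(fh)
    base = Path(path).parent
    out = Path(parser.get("output", "outdir", fallback="msynnet_out"))
    outdir = out if out.is_absolute() else base / out
    seed = parser.getint("output", "seed", fallback=0)
    chain = ChainParams(
        match_score=parser.getfloat("chain", "match_score", fallback=50.0),
        gap_penalty=parser.getfloat("chain", "gap_penalty", fallback=-1.0),
        match_size=parser.getint("chain", "match_size", fallback=5),
        max_gaps=parser.getint("chain", "max_gaps", fallback=25),
    )
    k = parser.getint("communities", "k", fallback=3)
    evalue_max = parser.getfloat("inputs", "evalue_max", fallback=1e-10)
    max_hits = parser.getint("inputs", "max_hits", fallback=20)
    if parser.has_section("simulate"):
        sim_kwargs: dict = {"species_tree": parser.get("simulate", "species_tree")}
        for key_name, get in (
            ("n_chromosomes", parser.getint), ("genes_per_chromosome", parser.getint),
            ("loss_rate", parser.getfloat), ("tandem_rate", parser.getfloat),
            ("transposition_rate", parser.getfloat), ("inversion_rate", parser.getfloat),
            ("rna_fraction", parser.getfloat), ("ks_rate", parser.getfloat),
            ("relaxed_multiplier", parser.getfloat), ("n_codons", parser.getint),
            ("family_of_interest", parser.get), ("focal_exon_count", parser.getint),
        ):
            if parser.has_option("simulate", key_name):
                sim_kwargs[key_name] = get("simulate", key_name)
        if parser.has_option("simulate", "wgd_events"):
            sim_kwargs["wgd_events"] = tuple(
                (b, int(m), float(r))
                for b, m, r in (
                    item.split(":")
                    for item in parser.get("simulate", "wgd_events").split(",")
                    if item.strip()
                )
            )
        if parser.has_option("simulate", "targeted_events"):
            sim_kwargs["targeted_events"] = tuple(
                tuple(item.split(":"))
                for item in parser.get("simulate", "targeted_events").split(",")
                if item.strip()
            )
        sim_kwargs["seed"] = seed
        return PipelineConfig(outdir=outdir, sim=SimConfig(**sim_kwargs),
                              chain=chain, k=k, seed=seed,
                              evalue_max=evalue_max, max_hits=max_hits)
    gff3 = {}
    bed = {}
    if parser.has_option("inputs", "gff3"):
        for item in parser.get("inputs", "gff3").split(","):
            sp, p = item.split(":")
            gff3[sp.strip()] = base / p.strip()
    if parser.has_option("inputs", "bed"):
        for item in parser.get("inputs", "bed").split(","):
            sp, p = item.split(":")
            bed[sp.strip()] = base / p.strip()
    cds = [base / p.strip()
           for p in parser.get("inputs", "cds", fallback="").split(",") if p.strip()]
    return PipelineConfig(
        outdir=outdir, gff3=gff3, bed=bed, cds_fasta=cds,
        hits_path=base / parser.get("inputs", "hits"),
        family_path=base / parser.get("inputs", "family"),
        tree_path=base / parser.get("inputs", "tree"),
        chain=chain, k=k, seed=seed,
        evalue_max=evalue_max, max_hits=max_hits,
    )


def _config_hash(config: PipelineConfig) -> str:
    # outdir excluded: the same analysis written elsewhere is the same run
    payload = {k: repr(v) for k, v in vars(config).items() if k != "outdir"}
    return hashlib.sha256(repr(sorted(payload.items())).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write stage outputs under ``config.outdir`` and
    return the manifest (also written as ``manifest.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    # --- inputs
    if config.sim is not None:
        sim = simulate_dataset(config.sim)
        sim.write(out / "simulated")
        genomes = sim.genomes
        cds = sim.cds
        hits = sim.hits
        # pass the emitted hits through the same filters real hits would see
        family_ids = sim.focal_family_ids()
        tree = core_io.read_tree(config.sim.species_tree)
        manifest["stages"]["simulate"] = {
            "species": len(genomes),
            "genes": sum(len(g) for g in genomes.values()),
            "hits": len(hits),
        }
    else:
        genomes = {}
        for sp, path in sorted(config.gff3.items()):
            genomes[sp] = core_io.read_gff3(path, sp)
        for sp, path in sorted(config.bed.items()):
            if sp not in genomes:
                genomes[sp] = core_io.read_bed(path, sp)
        known = {g.gene_id for recs in genomes.values() for g in recs}
        hits = core_io.read_homology_table(
            config.hits_path, evalue_max=config.evalue_max,
            max_hits=config.max_hits, known_ids=known,
        )
        family_ids = [
            line.strip()
            for line in Path(config.family_path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        cds = {}
        for path in config.cds_fasta:
            cds.update(core_io.read_fasta(path))
        tree = core_io.read_tree(config.tree_path)
    if not family_ids:
        raise ValueError("family list is empty")
    all_genes = [g for sp in sorted(genomes) for g in genomes[sp]]

    # --- collinearity (n(n+1)/2 comparisons) + tandems
    blocks, comparisons = run_all_pairs(genomes, hits, config.chain)
    write_collinearity(blocks, out / "collinearity.txt")
    core_io.write_tsv(comparisons, out / "comparisons.tsv")
    tandems = detect_tandems(all_genes, hits, window=config.tandem_window)
    core_io.write_tsv(
        pd.DataFrame({"array": [";".join(t) for t in tandems]}),
        out / "tandem_arrays.tsv",
    )
    manifest["stages"]["collinearity"] = {
        "comparisons": len(comparisons),
        "blocks": len(blocks),
        "tandem_arrays": len(tandems),
    }

    # --- network + family subnetwork
    net = build_network(blocks, all_genes)
    core_io.write_tsv(edge_table(net), out / "network_edges.tsv")
    core_io.write_tsv(node_table(net), out / "network_nodes.tsv")
    sub = extract_family_subnetwork(net, family_ids, all_genes)
    core_io.write_tsv(edge_table(sub), out / "family_edges.tsv")
    context = block_context(blocks, family_ids)
    core_io.write_tsv(
        pd.DataFrame(
            [{"block_id": b, "gene_a": a, "gene_b": c}
             for b, pairs in sorted(context.items()) for a, c in pairs]
        ),
        out / "family_block_context.tsv",
    )
    manifest["stages"]["network"] = {
        "nodes": net.number_of_nodes(), "edges": net.number_of_edges(),
        "family_nodes": sub.number_of_nodes(),
        "family_edges": sub.number_of_edges(),
    }

    # --- communities
    coms = find_communities(sub, k=config.k)
    core_io.write_tsv(communities_table(coms), out / "communities.tsv")
    core_io.write_tsv(
        community_membership_table(coms, family_ids), out / "membership.tsv"
    )
    manifest["stages"]["communities"] = {
        "n": len(coms), "sizes": [len(c) for c in coms],
    }

    # --- profiling
    profile, presence = build_profile(coms, all_genes, tree, family_ids)
    core_io.write_tsv(profile.reset_index(names="community"), out / "profile_counts.tsv")
    core_io.write_tsv(presence.reset_index(names="community"), out / "profile_presence.tsv")
    core_io.write_tsv(copy_number_table(all_genes, family_ids), out / "copy_number.tsv")
    try:
        summaries = exon_summary(coms, all_genes, family_ids)
        s_df, h_df = exon_summary_tables(summaries)
        core_io.write_tsv(s_df, out / "exon_summary.tsv")
        core_io.write_tsv(h_df, out / "exon_histogram.tsv")
        manifest["stages"]["profiling"] = {"exon_groups": len(summaries)}
    except ValueError:
        logger.warning("no exon counts available; exon summary skipped")
        manifest["stages"]["profiling"] = {"exon_groups": 0}

    # --- group Ks
    groups = {c.community_id: sorted(c.members) for c in coms}
    have_cds = {g for g, s in cds.items() if s}
    usable = {
        name: members for name, members in groups.items()
        if all(m in have_cds for m in members)
    }
    ks_summary, ks_pairs = group_ks(usable, cds)
    core_io.write_tsv(ks_summary, out / "ks_summary.tsv")
    core_io.write_tsv(ks_pairs, out / "ks_pairs.tsv")
    manifest["stages"]["kaks"] = {
        "groups": int(len(ks_summary)),
        "pairs": int(len(ks_pairs)),
    }

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
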