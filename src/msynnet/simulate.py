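"""Genome-evolution simulator: gene orders, exon structures and coding
sequences evolved along a species tree.

Supported events: gene loss, tandem duplication, DNA/RNA transposition of a
duplicate into a new genomic context (RNA copies become intronless),
segmental inversion, and whole-genome duplication/triplication followed by
fractionation (independent loss of each duplicate gene).  Coding sequences
accumulate synonymous-only substitutions at a controlled rate, with an
optional relaxation multiplier for transposed copies, so the true pairwise
synonymous distance of every gene pair is known exactly from the gene
genealogy.

Homology hits are emitted from family labels (bitscore a monotone decreasing
transform of true distance) rather than recomputed from sequences: the
all-against-all search stage of the real pipeline is an input boundary here,
which keeps runs fully deterministic and offline.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import core_io
from .core_io import GeneRecord, HomologyHit
from .molevo import (
    CODON_TO_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    SYN_SITES,
)

__all__ = [
    "SimConfig",
    "SimEvent",
    "SimResult",
    "TruthTables",
    "apply_event",
    "evolve_cds",
    "simulate_dataset",
    "mammal_scenario",
    "plant_scenario",
]


# ---------------------------------------------------------------------------
# synonymous substitution machinery

#: codon -> tuple of codons reachable by one synonymous non-stop change
SYN_CHANGES: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    _alts = []
    for _pos in range(3):
        for _nt in NUCLEOTIDES:
            if _nt == _c[_pos]:
                continue
            _alt = _c[:_pos] + _nt + _c[_pos + 1 :]
            if _alt not in STOP_CODONS and CODON_TO_AA[_alt] == CODON_TO_AA[_c]:
                _alts.append(_alt)
    SYN_CHANGES[_c] = tuple(_alts)


def evolve_cds(parent_cds: str, elapsed_distance: float, rng: np.random.Generator) -> str:
    """Evolve a CDS by synonymous-only substitution.

    Applies ``Poisson(elapsed_distance * S_true)`` substitutions, where
    ``S_true`` is the NG86 synonymous-site count of the input sequence; each
    substitution is drawn uniformly among the synonymous single-nucleotide
    changes of the current sequence.  The amino-acid sequence is invariant.
    """
    if elapsed_distance < 0:
        raise ValueError("elapsed_distance must be >= 0")
    if len(parent_cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    codons = [parent_cds[k : k + 3] for k in range(0, len(parent_cds), 3)]
    for c in codons:
        if c in STOP_CODONS:
            raise ValueError("internal stop codon in parent CDS")
        if c not in CODON_TO_AA:
            raise ValueError(f"invalid codon {c!r}")
    if elapsed_distance == 0:
        return parent_cds
    s_true = sum(SYN_SITES[c] for c in codons)
    n_sub = int(rng.poisson(elapsed_distance * s_true))
    counts = np.array([len(SYN_CHANGES[c]) for c in codons], dtype=float)
    for _ in range(n_sub):
        total = counts.sum()
        if total == 0:
            break
        r = rng.random() * total
        ci = int(np.searchsorted(np.cumsum(counts), r, side="right"))
        alts = SYN_CHANGES[codons[ci]]
        codons[ci] = alts[int(rng.integers(0, len(alts)))]
        counts[ci] = len(SYN_CHANGES[codons[ci]])
    return "".join(codons)


def random_cds(rng: np.random.Generator, n_codons: int = 300) -> str:
    """Uniform sense codons (no stops)."""
    idx = rng.integers(0, len(SENSE_CODONS), n_codons)
    return "".join(SENSE_CODONS[int(i)] for i in idx)


def translate(cds: str) -> str:
    return "".join(CODON_TO_AA[cds[k : k + 3]] for k in range(0, len(cds), 3))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """Scenario description for :func:`simulate_dataset`.

    Rates are per gene per unit branch length.  ``wgd_events`` pins
    whole-genome duplications (multiplicity 2) or triplications (3) with a
    duplicate-retention probability to named branches; ``targeted_events``
    pins single deterministic events (``tandem``, ``transposition_dna``,
    ``transposition_rna``, ``loss``) acting on one gene of a named family —
    the device used to replay a specific historical event such as a
    duplication plus retro-transposition on a clade stem.  Branch names are
    the child node labels of the newick tree (``root`` addresses the root
    stem edge).
    """

    species_tree: str
    n_chromosomes: int = 3
    genes_per_chromosome: int = 40
    loss_rate: float = 0.0
    tandem_rate: float = 0.0
    transposition_rate: float = 0.0
    inversion_rate: float = 0.0
    rna_fraction: float = 0.5
    wgd_events: tuple[tuple[str, int, float], ...] = ()
    targeted_events: tuple[tuple[str, str, str], ...] = ()
    family_of_interest: str = "famFOCAL"
    focal_exon_count: int = 9
    ks_rate: float = 0.1
    relaxed_multiplier: float = 2.0
    n_codons: int = 300
    exon_count_range: tuple[int, int] = (2, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_rate", "tandem_rate", "transposition_rate",
                     "inversion_rate", "ks_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.rna_fraction <= 1.0:
            raise ValueError("rna_fraction must be in [0, 1]")
        if self.relaxed_multiplier < 1.0:
            raise ValueError("relaxed_multiplier must be >= 1")
        for branch, multiplicity, retention in self.wgd_events:
            if multiplicity not in (2, 3):
                raise ValueError("WGD multiplicity must be 2 or 3")
            if not 0.0 < retention <= 1.0:
                raise ValueError("retention_prob must be in (0, 1]")


@dataclass(frozen=True)
class SimEvent:
    """One structural event; ``kind`` in {loss, tandem, transposition,
    inversion, wgd}."""

    kind: str
    mode: str = "dna"  # transposition only
    multiplicity: int = 2  # wgd only
    retention_prob: float = 1.0  # wgd only
    family: str | None = None  # restrict the affected gene to this family


# ---------------------------------------------------------------------------
# internal genome model


@dataclass
class _SimGene:
    uid: int
    family: str
    context: str
    exon_count: int
    cds: str
    strand: str
    relaxed: bool
    gnode: int


class _SimState:
    """Shared counters and the gene genealogy (node -> parent, depth)."""

    def __init__(self) -> None:
        self.next_uid = 0
        self.next_gnode = 0
        self.next_context = 0
        self.next_chrom_copy = 0
        self.parent: dict[int, int | None] = {}
        self.depth: dict[int, float] = {}

    def new_gnode(self, parent: int | None, dist: float) -> int:
        node = self.next_gnode
        self.next_gnode += 1
        self.parent[node] = parent
        self.depth[node] = (0.0 if parent is None else self.depth[parent]) + dist
        return node

    def new_uid(self) -> int:
        self.next_uid += 1
        return self.next_uid - 1

    def new_context(self) -> str:
        self.next_context += 1
        return f"ctx_transposed{self.next_context}"


class Genome:
    """Ordered gene lists per chromosome plus shared simulator state."""

    def __init__(self, state: _SimState) -> None:
        self.chroms: dict[str, list[_SimGene]] = {}
        self.state = state

    def copy(self) -> "Genome":
        out = Genome(self.state)
        for chrom, genes in self.chroms.items():
            out.chroms[chrom] = [replace(g) for g in genes]
        return out

    def gene_count(self) -> int:
        return sum(len(genes) for genes in self.chroms.values())

    def all_genes(self) -> list[tuple[str, int, _SimGene]]:
        return [
            (chrom, pos, g)
            for chrom in self.chroms
            for pos, g in enumerate(self.chroms[chrom])
        ]


def _pick_gene(
    genome: Genome, rng: np.random.Generator, family: str | None
) -> tuple[str, int, _SimGene] | None:
    pool = genome.all_genes()
    if family is not None:
        pool = [t for t in pool if t[2].family == family]
    if not pool:
        return None
    return pool[int(rng.integers(0, len(pool)))]


def _duplicate(gene: _SimGene, state: _SimState) -> _SimGene:
    return _SimGene(
        uid=state.new_uid(), family=gene.family, context=gene.context,
        exon_count=gene.exon_count, cds=gene.cds, strand=gene.strand,
        relaxed=gene.relaxed, gnode=state.new_gnode(gene.gnode, 0.0),
    )


def apply_event(genome: Genome, event: SimEvent, rng: np.random.Generator) -> Genome:
    """Apply one structural event in place (the genome is also returned).

    loss removes a gene and closes ranks; tandem inserts a copy at rank+1 on
    the same chromosome; transposition inserts a copy at a uniform position
    on a uniform chromosome under a fresh context label (RNA mode makes the
    copy intronless); inversion reverses a contiguous rank window and flips
    strands; wgd duplicates every chromosome and deletes each duplicate gene
    independently with probability 1 - retention_prob.
    """
    state = genome.state
    if event.kind == "loss":
        picked = _pick_gene(genome, rng, event.family)
        if picked is not None:
            chrom, pos, _ = picked
            del genome.chroms[chrom][pos]
    elif event.kind == "tandem":
        picked = _pick_gene(genome, rng, event.family)
        if picked is not None:
            chrom, pos, gene = picked
            genome.chroms[chrom].insert(pos + 1, _duplicate(gene, state))
    elif event.kind == "transposition":
        picked = _pick_gene(genome, rng, event.family)
        if picked is not None:
            _, _, gene = picked
            copy = _duplicate(gene, state)
            copy.context = state.new_context()
            copy.relaxed = True
            if event.mode == "rna":
                copy.exon_count = 1
            chroms = sorted(genome.chroms)
            dest = chroms[int(rng.integers(0, len(chroms)))]
            at = int(rng.integers(0, len(genome.chroms[dest]) + 1))
            genome.chroms[dest].insert(at, copy)
    elif event.kind == "inversion":
        chroms = sorted(c for c in genome.chroms if genome.chroms[c])
        if chroms:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            genes = genome.chroms[chrom]
            a = int(rng.integers(0, len(genes)))
            b = int(rng.integers(a, len(genes)))
            if b + 1 > len(genes):
                raise ValueError("inversion window outside chromosome")
            window = genes[a : b + 1][::-1]
            for g in window:
                g.strand = "-" if g.strand == "+" else "+"
            genome.chroms[chrom] = genes[:a] + window + genes[b + 1 :]
    elif event.kind == "wgd":
        for chrom in sorted(genome.chroms):
            originals = genome.chroms[chrom]
            for m in range(2, event.multiplicity + 1):
                state.next_chrom_copy += 1
                name = f"{chrom}_w{state.next_chrom_copy}"
                kept = []
                for gene in originals:
                    retained = rng.random() < event.retention_prob
                    if retained:
                        kept.append(_duplicate(gene, state))
                genome.chroms[name] = kept
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")
    return genome


# ---------------------------------------------------------------------------
# tree traversal


def _branch_rng(seed: int, branch_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(branch_id.encode())])
    )


def _branch_ids(tree: dendropy.Tree) -> dict[int, str]:
    """Stable branch names: child taxon/node label, or a deterministic
    preorder fallback; the root stem edge is 'root'."""
    names: dict[int, str] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            names[id(node)] = "root"
        elif node.taxon is not None:
            names[id(node)] = node.taxon.label
        elif node.label:
            names[id(node)] = node.label
        else:
            names[id(node)] = f"node{counter}"
        counter += 1
    return names


def _make_root_genome(config: SimConfig, state: _SimState) -> Genome:
    rng = _branch_rng(config.seed, "__root_genome__")
    genome = Genome(state)
    lo, hi = config.exon_count_range
    focal_chrom = "chr1"
    focal_pos = config.genes_per_chromosome // 2
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        genes = []
        for pos in range(config.genes_per_chromosome):
            focal = chrom == focal_chrom and pos == focal_pos
            genes.append(
                _SimGene(
                    uid=state.new_uid(),
                    family=config.family_of_interest if focal else f"fam_{chrom}_{pos}",
                    context=f"ctx_{chrom}",
                    exon_count=config.focal_exon_count
                    if focal
                    else int(rng.integers(lo, hi + 1)),
                    cds=random_cds(rng, config.n_codons),
                    strand="+" if rng.random() < 0.5 else "-",
                    relaxed=False,
                    gnode=state.new_gnode(None, 0.0),
                )
            )
        genome.chroms[chrom] = genes
    return genome


def _evolve_branch(
    genome: Genome,
    branch_id: str,
    length: float,
    config: SimConfig,
    log: list[dict],
) -> None:
    rng = _branch_rng(config.seed, branch_id)
    state = genome.state

    def record(event: SimEvent, note: str = "") -> None:
        log.append({"branch": branch_id, "event": event.kind,
                    "mode": event.mode if event.kind == "transposition" else "",
                    "note": note})

    for branch, kind, family in config.targeted_events:
        if branch != branch_id:
            continue
        if kind in ("transposition_dna", "transposition_rna"):
            event = SimEvent("transposition", mode=kind.rsplit("_", 1)[1],
                             family=family)
        else:
            event = SimEvent(kind, family=family)
        apply_event(genome, event, rng)
        record(event, f"targeted:{family}")
    for branch, multiplicity, retention in config.wgd_events:
        if branch == branch_id:
            event = SimEvent("wgd", multiplicity=multiplicity,
                             retention_prob=retention)
            apply_event(genome, event, rng)
            record(event, f"retention={retention}")
    n_genes = genome.gene_count()
    background = []
    for kind, rate in (
        ("loss", config.loss_rate),
        ("tandem", config.tandem_rate),
        ("transposition", config.transposition_rate),
        ("inversion", config.inversion_rate),
    ):
        count = int(rng.poisson(rate * length * n_genes))
        background.extend([kind] * count)
    rng.shuffle(background)
    for kind in background:
        mode = "rna" if (kind == "transposition"
                         and rng.random() < config.rna_fraction) else "dna"
        event = SimEvent(kind, mode=mode)
        apply_event(genome, event, rng)
        record(event)
    # synonymous divergence + genealogy checkpoint at branch end
    for chrom in sorted(genome.chroms):
        for gene in genome.chroms[chrom]:
            mult = config.relaxed_multiplier if gene.relaxed else 1.0
            dist = length * config.ks_rate * mult
            if dist > 0:
                gene.cds = evolve_cds(gene.cds, dist, rng)
            gene.gnode = state.new_gnode(gene.gnode, dist)


# ---------------------------------------------------------------------------
# outputs


@dataclass
class TruthTables:
    """Ground truth: family/context labels, event log, and the gene
    genealogy from which exact pairwise synonymous distances derive."""

    families: dict[str, str]
    contexts: dict[str, str]
    event_log: pd.DataFrame
    gnode_of: dict[str, int]
    parent: dict[int, int | None]
    depth: dict[int, float]

    def true_distance(self, gene_a: str, gene_b: str) -> float:
        na, nb = self.gnode_of[gene_a], self.gnode_of[gene_b]
        ancestors: dict[int, float] = {}
        node: int | None = na
        while node is not None:
            ancestors[node] = self.depth[node]
            node = self.parent[node]
        node = nb
        while node is not None:
            if node in ancestors:
                return (self.depth[na] - self.depth[node]) + (
                    self.depth[nb] - self.depth[node]
                )
            node = self.parent[node]
        raise KeyError(f"{gene_a} and {gene_b} share no ancestor")

    def family_members(self, family: str) -> list[str]:
        return sorted(g for g, f in self.families.items() if f == family)

    def pairwise_distances(self, family: str | None = None) -> pd.DataFrame:
        families: dict[str, list[str]] = {}
        for g, f in self.families.items():
            if family is None or f == family:
                families.setdefault(f, []).append(g)
        rows = []
        for fam in sorted(families):
            for a, b in itertools.combinations(sorted(families[fam]), 2):
                rows.append(
                    {"family": fam, "gene_a": a, "gene_b": b,
                     "distance": self.true_distance(a, b)}
                )
        return pd.DataFrame(rows)


@dataclass
class SimResult:
    config: SimConfig
    genomes: dict[str, list[GeneRecord]]
    cds: dict[str, str]
    proteins: dict[str, str]
    hits: list[HomologyHit]
    truth: TruthTables
    exon_layouts: dict[str, dict[str, list[tuple[int, int]]]]

    def all_genes(self) -> list[GeneRecord]:
        return [g for sp in sorted(self.genomes) for g in self.genomes[sp]]

    def focal_family_ids(self) -> list[str]:
        return self.truth.family_members(self.config.family_of_interest)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in sorted(self.genomes):
            records = self.genomes[sp]
            core_io.write_gff3(
                records, outdir / f"{sp}.gff3", exon_layout=self.exon_layouts[sp]
            )
            core_io.write_bed(records, outdir / f"{sp}.bed")
            ids = [r.gene_id for r in records]
            core_io.write_fasta(
                {g: self.cds[g] for g in ids}, outdir / f"{sp}.cds.fasta"
            )
            core_io.write_fasta(
                {g: self.proteins[g] for g in ids}, outdir / f"{sp}.pep.fasta"
            )
        core_io.write_homology_table(self.hits, outdir / "homology.tsv")
        core_io.write_tsv(
            pd.DataFrame(
                [{"gene_id": g, "family": f, "context": self.truth.contexts[g]}
                 for g, f in sorted(self.truth.families.items())]
            ),
            outdir / "truth_genes.tsv",
        )
        core_io.write_tsv(self.truth.pairwise_distances(),
                          outdir / "truth_distances.tsv")
        core_io.write_tsv(self.truth.event_log, outdir / "truth_events.tsv")
        (outdir / "focal_family.txt").write_text(
            "\n".join(self.focal_family_ids()) + "\n", encoding="utf-8"
        )
        (outdir / "species_tree.nwk").write_text(
            self.config.species_tree.strip() + "\n", encoding="utf-8"
        )


def _emit_species(
    species: str,
    genome: Genome,
    config: SimConfig,
    result_genomes: dict[str, list[GeneRecord]],
    cds: dict[str, str],
    proteins: dict[str, str],
    truth_families: dict[str, str],
    truth_contexts: dict[str, str],
    gnode_of: dict[str, int],
    exon_layouts: dict[str, dict[str, list[tuple[int, int]]]],
) -> None:
    intron, spacer = 100, 500
    records: list[GeneRecord] = []
    layout: dict[str, list[tuple[int, int]]] = {}
    counter = 0
    for chrom in sorted(genome.chroms):
        cursor = 0
        for gene in genome.chroms[chrom]:
            gid = f"{species}|g{counter:04d}"
            counter += 1
            cds_len = len(gene.cds)
            n_ex = max(1, gene.exon_count)
            base, extra = divmod(cds_len, n_ex)
            exons = []
            pos = cursor
            for e in range(n_ex):
                size = base + (1 if e < extra else 0)
                exons.append((pos, pos + size))
                pos += size + intron
            end = exons[-1][1]
            records.append(
                GeneRecord(
                    gene_id=gid, species=species, chrom=chrom,
                    start=cursor, end=end, strand=gene.strand,
                    exon_count=n_ex,
                )
            )
            layout[gid] = exons
            cds[gid] = gene.cds
            proteins[gid] = translate(gene.cds)
            truth_families[gid] = gene.family
            truth_contexts[gid] = gene.context
            gnode_of[gid] = gene.gnode
            cursor = end + spacer
    result_genomes[species] = core_io.assign_ranks(records)
    exon_layouts[species] = layout


def _emit_hits(
    truth: TruthTables, rng: np.random.Generator
) -> list[HomologyHit]:
    """Within-family pairs with bitscore decreasing in true distance and
    evalue a monotone transform of the bitscore."""
    hits: list[HomologyHit] = []
    families: dict[str, list[str]] = {}
    for g, f in truth.families.items():
        families.setdefault(f, []).append(g)
    for fam in sorted(families):
        for a, b in itertools.combinations(sorted(families[fam]), 2):
            d = truth.true_distance(a, b)
            bitscore = round(500.0 * float(np.exp(-d)), 1)
            evalue = 10.0 ** (-bitscore / 10.0)
            hits.append(HomologyHit(query_id=a, subject_id=b,
                                    bitscore=bitscore, evalue=evalue))
    return hits


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full simulation and return pipeline inputs + ground truth.

    Deterministic for a fixed config (per-branch RNG substreams are derived
    from (seed, branch name), so results do not depend on traversal order).
    """
    tree = core_io.read_tree(config.species_tree)
    names = _branch_ids(tree)
    state = _SimState()
    log: list[dict] = []
    root_genome = _make_root_genome(config, state)
    seed_len = tree.seed_node.edge.length or 0.0
    _evolve_branch(root_genome, "root", seed_len, config, log)
    genomes_at: dict[int, Genome] = {id(tree.seed_node): root_genome}
    result_genomes: dict[str, list[GeneRecord]] = {}
    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    families: dict[str, str] = {}
    contexts: dict[str, str] = {}
    gnode_of: dict[str, int] = {}
    exon_layouts: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            genome = genomes_at[id(node)]
        else:
            genome = genomes_at[id(node.parent_node)].copy()
            _evolve_branch(genome, names[id(node)], node.edge.length or 0.0,
                           config, log)
            genomes_at[id(node)] = genome
        if node.is_leaf():
            _emit_species(
                names[id(node)], genome, config, result_genomes,
                cds, proteins, families, contexts, gnode_of, exon_layouts,
            )
    truth = TruthTables(
        families=families, contexts=contexts,
        event_log=pd.DataFrame(log, columns=["branch", "event", "mode", "note"]),
        gnode_of=gnode_of, parent=state.parent, depth=state.depth,
    )
    hits = _emit_hits(truth, _branch_rng(config.seed, "__hits__"))
    return SimResult(
        config=config, genomes=result_genomes, cds=cds, proteins=proteins,
        hits=hits, truth=truth, exon_layouts=exon_layouts,
    )


# ---------------------------------------------------------------------------
# scenario presets


def mammal_scenario(seed: int = 0) -> SimConfig:
    """Single-copy outgroup; focal-gene duplication by RNA transposition on
    the stem of a six-species ingroup clade; transposed copies intronless
    and evolving at twice the synonymous rate.

    Mirrors a family whose ancestral-context copies stay syntenic across
    the whole clade (outgroup included) while the transposed copies form a
    second, ingroup-only syntenic community with elevated Ks.
    """
    tree = (
        "(((m1:1,m2:1)e1:1,((m3:1,m4:1)e2:0.5,(m5:1,m6:1)e3:0.5)e4:0.5)stem:1,"
        "outg:3)root;"
    )
    return SimConfig(
        species_tree=tree,
        n_chromosomes=3,
        genes_per_chromosome=40,
        targeted_events=(("stem", "transposition_rna", "famFOCAL"),),
        family_of_interest="famFOCAL",
        focal_exon_count=9,
        ks_rate=0.12,
        relaxed_multiplier=2.0,
        seed=seed,
    )


def plant_scenario(seed: int = 0) -> SimConfig:
    """Whole-genome triplication with fractionation on the root stem of
    eight species, plus a lineage-specific DNA transposition of the focal
    gene on the stem of a four-species clade.

    Mirrors a family with one ancestral-context supercluster spanning all
    species (including WGT-retained duplicates) and one lineage-restricted
    transposed community.
    """
    tree = (
        "(((p1:1,p2:1)c1:1,(p3:1,p4:1)c2:1)c3:1,"
        "((p5:1,p6:1)c4:1,(p7:1,p8:1)c5:1)c6:1)root:1;"
    )
    return SimConfig(
        species_tree=tree,
        n_chromosomes=3,
        genes_per_chromosome=40,
        wgd_events=(("root", 3, 0.25),),
        targeted_events=(("c6", "transposition_dna", "famFOCAL"),),
        family_of_interest="famFOCAL",
        focal_exon_count=9,
        ks_rate=0.08,
        relaxed_multiplier=1.5,
        seed=seed,
    )
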