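"""Readers/writers for the standard formats the pipeline touches and the
in-memory gene table.

Internal coordinates are 0-based half-open; GFF3's 1-based closed intervals
are converted exactly once at the file boundary.  Gene order ("rank") — not
base-pair position — is the coordinate used by the collinearity stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)


@dataclass
class GeneRecord:
    """One gene: where it sits and how many exons its longest isoform has.

    ``rank`` is the 0-based position of the gene among the genes of its
    chromosome ordered by start (ties by gene_id); it is assigned by
    :func:`assign_ranks`, not by the parsers.
    """

    gene_id: str
    species: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int = -1
    exon_count: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class HomologyHit:
    """An unordered homologous gene pair surviving the hit filters."""

    query_id: str
    subject_id: str
    bitscore: float
    evalue: float


@dataclass(frozen=True)
class FeatureConfig:
    """GFF3 feature/attribute vocabulary."""

    gene_type: str = "gene"
    transcript_types: tuple[str, ...] = ("mRNA", "transcript")
    exon_type: str = "exon"
    cds_type: str = "CDS"


def assign_ranks(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Assign per-chromosome ranks by (start, gene_id); returns the records
    sorted by (species, chrom, rank)."""
    out = sorted(records, key=lambda r: (r.species, r.chrom, r.start, r.gene_id))
    rank = 0
    prev = None
    for rec in out:
        key = (rec.species, rec.chrom)
        if key != prev:
            rank = 0
            prev = key
        rec.rank = rank
        rank += 1
    return out


def index_by_id(records: Iterable[GeneRecord]) -> dict[str, GeneRecord]:
    idx: dict[str, GeneRecord] = {}
    for rec in records:
        if rec.gene_id in idx:
            raise ValueError(f"duplicate gene_id {rec.gene_id}")
        idx[rec.gene_id] = rec
    return idx


# ---------------------------------------------------------------------------
# GFF3


def _check_orphan_exons(path: str | Path, cfg: FeatureConfig) -> None:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 9 and cols[2] == cfg.exon_type and "Parent=" not in cols[8]:
                raise ValueError(
                    f"{path}: exon without resolvable Parent at line {lineno}"
                )


def read_gff3(
    path: str | Path,
    species: str,
    feature_config: FeatureConfig | None = None,
) -> list[GeneRecord]:
    """Parse a GFF3 into one GeneRecord per gene.

    The representative isoform is the transcript with the greatest summed
    CDS length (falling back to summed exon length when it has no CDS);
    ties break on the lexicographically smallest transcript ID.
    ``exon_count`` is the number of exon features of that isoform.  1-based
    closed GFF3 coordinates become 0-based half-open.
    """
    cfg = feature_config or FeatureConfig()
    _check_orphan_exons(path, cfg)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    records: list[GeneRecord] = []
    for gene in db.features_of_type(cfg.gene_type, order_by=("seqid", "start")):
        best: tuple[float, str, int] | None = None  # (-length, tx_id, exon_count)
        for tx in db.children(gene, level=1):
            if tx.featuretype not in cfg.transcript_types:
                continue
            cds_len = sum(
                c.end - c.start + 1 for c in db.children(tx, featuretype=cfg.cds_type)
            )
            exons = list(db.children(tx, featuretype=cfg.exon_type))
            exon_len = sum(e.end - e.start + 1 for e in exons)
            length = cds_len if cds_len > 0 else exon_len
            key = (-length, tx.id)
            if best is None or key < (best[0], best[1]):
                best = (-length, tx.id, len(exons))
        if best is None:
            logger.warning("gene %s has no transcript; excluded", gene.id)
            continue
        records.append(
            GeneRecord(
                gene_id=gene.id,
                species=species,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                exon_count=best[2] if best[2] > 0 else None,
            )
        )
    return assign_ranks(records)


def write_gff3(
    records: Sequence[GeneRecord],
    path: str | Path,
    exon_layout: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    source: str = "msynnet",
) -> None:
    """Write gene/mRNA/exon/CDS features (0-based half-open -> 1-based closed).

    ``exon_layout`` optionally maps gene_id to 0-based half-open exon
    intervals; without it each gene gets a single exon spanning the gene.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.start, r.gene_id)):
            local = rec.gene_id.split("|", 1)[-1]
            g1, g2 = rec.start + 1, rec.end
            fh.write(
                f"{rec.chrom}\t{source}\tgene\t{g1}\t{g2}\t.\t{rec.strand}\t.\t"
                f"ID={rec.gene_id}\n"
            )
            tx = f"{rec.gene_id}.t1"
            fh.write(
                f"{rec.chrom}\t{source}\tmRNA\t{g1}\t{g2}\t.\t{rec.strand}\t.\t"
                f"ID={tx};Parent={rec.gene_id}\n"
            )
            exons = (
                exon_layout.get(rec.gene_id)
                if exon_layout is not None
                else None
            ) or [(rec.start, rec.end)]
            for k, (es, ee) in enumerate(exons, 1):
                for ftype, suffix in (("exon", "exon"), ("CDS", "cds")):
                    fh.write(
                        f"{rec.chrom}\t{source}\t{ftype}\t{es + 1}\t{ee}\t.\t"
                        f"{rec.strand}\t{'0' if ftype == 'CDS' else '.'}\t"
                        f"ID={local}.{suffix}{k};Parent={tx}\n"
                    )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, species: str) -> list[GeneRecord]:
    """Read BED4/BED6 gene positions (column 4 = gene_id); already 0-based
    half-open, taken as-is.  Exon counts are absent in BED."""
    records: list[GeneRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            start, end = int(cols[1]), int(cols[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "+"
            records.append(
                GeneRecord(
                    gene_id=cols[3], species=species, chrom=cols[0],
                    start=start, end=end, strand=strand,
                )
            )
    if not records:
        logger.warning("%s: empty BED file", path)
    return assign_ranks(records)


def write_bed(records: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in sorted(records, key=lambda r: (r.chrom, r.start, r.gene_id)):
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.gene_id}\t0\t{rec.strand}\n"
            )


# ---------------------------------------------------------------------------
# Homology hits (12-column, blast outfmt-6 dialect)


def filter_hits(
    hits: Iterable[tuple[str, str, float, float]],
    evalue_max: float = 1e-10,
    max_hits: int = 20,
) -> list[tuple[str, str, float, float]]:
    """Directed-hit filter: drop self hits and hits above ``evalue_max``,
    then keep the top ``max_hits`` per query by bitscore (ties by
    subject_id).  Idempotent."""
    by_query: dict[str, list[tuple[str, str, float, float]]] = {}
    for q, s, ev, bs in hits:
        if q == s or ev > evalue_max:
            continue
        by_query.setdefault(q, []).append((q, s, ev, bs))
    out: list[tuple[str, str, float, float]] = []
    for q in sorted(by_query):
        ranked = sorted(by_query[q], key=lambda h: (-h[3], h[1]))
        out.extend(ranked[:max_hits])
    return out


def symmetrize(
    directed: Iterable[tuple[str, str, float, float]],
) -> list[HomologyHit]:
    """Collapse directed hits to unordered pairs (best bitscore, best evalue)
    so the edge set is independent of search direction."""
    pairs: dict[tuple[str, str], tuple[float, float]] = {}
    for q, s, ev, bs in directed:
        key = (q, s) if q <= s else (s, q)
        if key in pairs:
            ev0, bs0 = pairs[key]
            pairs[key] = (min(ev, ev0), max(bs, bs0))
        else:
            pairs[key] = (ev, bs)
    return [
        HomologyHit(query_id=a, subject_id=b, evalue=ev, bitscore=bs)
        for (a, b), (ev, bs) in sorted(pairs.items())
    ]


def read_homology_table(
    path: str | Path,
    evalue_max: float = 1e-10,
    max_hits: int = 20,
    known_ids: set[str] | None = None,
    on_unknown: str = "warn",
) -> list[HomologyHit]:
    """Read 12-column tabular hits (cols 1,2,11,12 = query, subject, evalue,
    bitscore), filter and symmetrize.

    ``known_ids`` enables the unknown-gene policy: ``on_unknown`` is
    ``"warn"`` (skip with a warning) or ``"error"``.
    """
    if on_unknown not in {"warn", "error"}:
        raise ValueError("on_unknown must be 'warn' or 'error'")
    directed: list[tuple[str, str, float, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns")
            q, s = cols[0], cols[1]
            if known_ids is not None and (q not in known_ids or s not in known_ids):
                unknown = [g for g in (q, s) if g not in known_ids]
                if on_unknown == "error":
                    raise ValueError(
                        f"{path}:{lineno}: unknown gene id(s) {unknown}"
                    )
                logger.warning("%s:%d: skipping unknown gene id(s) %s", path, lineno, unknown)
                continue
            directed.append((q, s, float(cols[10]), float(cols[11])))
    return symmetrize(filter_hits(directed, evalue_max=evalue_max, max_hits=max_hits))


def write_homology_table(hits: Sequence[HomologyHit], path: str | Path) -> None:
    """Write unordered hits back out in the 12-column dialect (one direction
    per pair; the unused alignment columns are zero-filled)."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:g}\t{h.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / TSV / newick


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; the id is the token before the first
    whitespace; duplicate ids are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated UTF-8 with a single '#'-commented header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        return pd.read_csv(fh, sep="\t", names=header, header=None)


def gene_table(records: Sequence[GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "species": [r.species for r in records],
            "chrom": [r.chrom for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "strand": [r.strand for r in records],
            "rank": [r.rank for r in records],
            "exon_count": [r.exon_count for r in records],
        }
    )


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a newick species tree from a path or a newick string."""
    text = None
    p = Path(str(source))
    if p.exists():
        text = p.read_text(encoding="utf-8")
    else:
        text = str(source)
    tree = dendropy.Tree.get(data=text, schema="newick")
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(leaves) != len(set(leaves)):
        raise ValueError("species tree has duplicate leaf names")
    return tree


def tree_leaf_order(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]
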