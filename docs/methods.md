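# Methods

This note documents the models, algorithmic choices and parameter defaults
behind `msynnet`, and what the bundled simulator does and does not emulate.

## Gene tables and coordinates

Internal coordinates are 0-based half-open; GFF3's 1-based closed intervals
are converted exactly once at the file boundary, so a GFF3 → internal →
GFF3 round trip restores the original intervals.  The coordinate used by
all synteny computations is the **gene rank**: the 0-based position of a
gene among the genes of its chromosome ordered by start (ties broken by
gene id).  Rank-based chaining is robust to assembly-scale differences in
intergenic distance and matches the conventions of standard collinearity
tools.

The representative isoform of a gene is the transcript with the greatest
summed CDS length (falling back to summed exon length when no CDS is
annotated), ties broken by the lexicographically smallest transcript id.
CDS length is preferred because the downstream Ks stage operates on coding
sequence.  The exon count of a gene is the exon count of that isoform.

Homology input is 12-column tabular (query, subject, ..., evalue,
bitscore).  Self hits are removed, hits with evalue above `evalue_max`
(default 1e-10) are dropped, and each query keeps its best `max_hits`
(default 20) hits by bitscore, matching search protocols that cap the
reported hit list at 20 alignments per query.  No e-value threshold is
universally standard between an all-vs-all search and block detection, so
both values are exposed as configuration.  The directed filter is
idempotent; filtered hits are then symmetrized to unordered pairs so the
anchor set does not depend on search direction.

## Collinear block detection

Anchors for a chromosome pair are chained by dynamic programming over
anchors sorted by (i, j).  A chain of m anchors scores
`m·match_score + gap_penalty·Σ[(Δi−1) + (Δj−1)]`; extensions require
strictly increasing i and strictly monotone j (increasing = forward,
decreasing = inverted) with both rank gaps ≤ `max_gaps`.  DP ties break
toward the longer chain, then the smaller start i, then the smaller start
j; on an exact score tie between orientations, forward wins.  Blocks are
extracted greedily: emit the best chain if it has ≥ `match_size` anchors,
remove its anchors, repeat; extraction stops when the best remaining chain
is shorter than `match_size`.  Greedy removal resolves overlapping chains
deterministically; no anchor appears in two blocks of the same chromosome
pair.

Defaults `match_score=50, gap_penalty=-1, match_size=5, max_gaps=25` mirror
the published defaults of the reference collinearity tool.  No statistical
block e-value is computed.  Tandem arrays (mutually homologous genes within
a rank window, default 1, joined transitively) are reported but not
collapsed before chaining — collapsing is a destructive normalisation the
input data may not warrant, and the reported arrays let users do it
explicitly if desired.

Self-comparisons are included (n(n+1)/2 comparisons for n genomes); on a
chromosome self-comparison each unordered anchor is listed once with
i < j, which excludes the trivial self-diagonal.

## Synteny network and communities

The network has one node per gene occurring in a block and one unweighted
edge per unordered anchor pair; an edge supported by several blocks carries
all block ids as annotation but still counts once — community detection
operates on the unweighted simple graph.  The family subnetwork is the
induced subgraph on the family's gene ids, with members lacking any
syntenic partner retained as degree-0 nodes so copy-number accounting never
silently loses genes.

Communities are found by clique percolation: all k-cliques (obtained by
decomposing maximal cliques into k-subsets), adjacency iff two k-cliques
share exactly k−1 nodes, communities = node-unions of the connected
components of the clique-adjacency graph.  k defaults to 3.  Family
subnetworks are small (tens to a few hundred nodes), so the worst-case cost
of clique decomposition is acceptable.  Output order is deterministic:
size descending, then smallest member; ids C1, C2, ... are assigned in that
order.  Overlap is a feature of the method: a gene may appear in several
communities and is counted in each.

## Profiling

The profile matrix has one row per community plus a `none` row for
unclustered family genes, and one column per species in species-tree leaf
order; cells are gene counts, with a presence/absence variant also emitted
(figures in this literature use both conventions).  Column sums over all
rows equal per-species family copy number (plus multi-membership, when
communities overlap).  Exon summaries report n, mean, median, mode (ties →
smallest modal value) and the full histogram per community.

## NG86 Ka/Ks

Protein pairs are aligned globally (Needleman–Wunsch, BLOSUM62, affine
gaps: open 10, extend 0.5) via Biopython's pairwise aligner, taking its
first optimal traceback (deterministic for fixed inputs), then
back-translated: residue → its codon, gap → `---`, with one terminal stop
codon stripped and translation verified.  Only gap-free, unambiguous codon
columns enter the counts.

Sites: per codon, s = Σ over positions of (synonymous one-step changes)/3;
changes creating a stop count as nonsynonymous; S is averaged between the
two sequences and N = 3·(compared codons) − S, exactly.  Differences
between codons are averaged over all minimal substitution pathways with
equal weights, excluding pathways through stop codons (if every pathway is
excluded, the average falls back to all pathways).  Jukes–Cantor
correction K = −(3/4)·ln(1 − (4/3)p) is applied to both proportions; a
non-positive log argument marks the pair saturated, Ks/Ka undefined.
Saturated pairs are excluded from group means and quartiles but always
counted, so the exclusion is visible.  Quartiles use linear interpolation
between order statistics.  Only the standard genetic code is supported;
model choice beyond NG86 (ML codon models, model averaging) is out of
scope.

## The simulator

The simulator evolves a root genome (by default 3 chromosomes × 40 genes,
each gene a family of its own, random 2–12 exon structure, 300 random
sense codons) along a newick species tree.  Branch events:

* **loss** — remove a uniform gene, closing ranks;
* **tandem** — insert a copy at rank+1 on the same chromosome;
* **transposition** — insert a copy at a uniform position on a uniform
  chromosome under a *fresh context label*; RNA-mediated copies get
  exon_count 1 (retro-copy), and all transposed copies switch to a relaxed
  synonymous rate (`relaxed_multiplier` × `ks_rate`) from the event onward;
* **inversion** — reverse a contiguous rank window and flip strands;
* **wgd** — duplicate every chromosome (multiplicity 2 or 3), then delete
  each duplicate gene independently with probability 1 − `retention_prob`
  (fractionation); duplicated copies keep their ancestral context label.

Background event counts per branch are Poisson(rate × branch length × gene
count), applied in shuffled draw order; each branch uses an RNG substream
derived from (seed, branch name), so results are independent of traversal
order and byte-identical across runs.  Deterministic `targeted_events`
(e.g. "RNA-transpose one copy of the focal family on this stem") replay
specific historical events; `wgd_events` pin polyploidies to named
branches.

Coding sequences evolve by synonymous-only substitution:
Poisson(d × S_true) substitutions, each drawn uniformly among the
synonymous single-nucleotide changes of the current sequence, so the
protein is invariant and the true synonymous distance of every gene pair
is exact, computed from the gene genealogy (symmetric and additive along
the generating tree path).  Homology hits are emitted from family labels —
bitscore 500·e^(−d), evalue 10^(−bitscore/10) — rather than recomputed
from sequences: the all-vs-all search tool is an input boundary of the
pipeline, and label-derived hits keep runs deterministic and offline.

What the simulator does **not** emulate: nonsynonymous evolution, codon
usage bias, alternative genetic codes, chromosome fission/fusion,
annotation noise, assembly fragmentation, and missing data.  Passing tests
therefore demonstrate correctness of the pipeline's inference machinery
under clean, fully-controlled histories — not robustness to the annotation
artifacts of real genomes.

### Scenario presets

*Mammal-style* (`mammal_scenario`): seven species — six ingroup, one
outgroup at depth 3 — with a single targeted RNA transposition of the
nine-exon focal gene on the ingroup stem, `ks_rate 0.12`,
`relaxed_multiplier 2`, no background events (the preset isolates the
focal historical event; background rates remain available in `SimConfig`).
With these rates the conserved group's expected mean pairwise Ks is
4.1 × 0.12 ≈ 0.49 and the transposed group's about twice that — chosen so
the scaled-down scenario produces group means in the same regime as the
motivating full-genome analyses (≈0.5 vs ≈1).  Expected outcome: two
communities, the ancestral-context one containing the outgroup, the
transposed one intronless and faster-evolving.

*Plant-style* (`plant_scenario`): eight species, a whole-genome
triplication with retention 0.25 on the root stem, and a targeted DNA
transposition of the focal gene on one four-species stem.  Expected
outcome: one supercluster spanning all eight species (absorbing any
retained WGT duplicates, which stay syntenic to the ancestral context)
plus one community restricted to the transposed lineage.

Scenario parameters reproduce qualitative topology (community counts and
memberships), not the absolute numbers of any real genome set; problem
sizes (7–8 species, ~120–180 genes per genome, 300-codon CDSs) were chosen
as the smallest at which every stage is exercised with comfortable margins.

## Validation experiments

`msynnet.validation` packages the recurring experiments:

* **Planted-block recovery** — chromosome pairs with 1–3 planted collinear
  runs (5–20 anchors, forward or inverted, rank steps 1–3) plus ~5%
  uniform noise anchors; noise falling inside a planted run's max_gaps
  corridor is rejected during generation, because an anchor collinear and
  adjacent to a run is genuinely part of the chain and anchor-exact
  recovery would otherwise be ill-defined.  Recovery is measured as
  anchor-level precision and recall.
* **NG86 estimator recovery** — parent/child CDS pairs evolved to known
  synonymous distance d and re-estimated.  Recovery is excellent at low
  divergence (≈ +1% at d = 0.1, ≈ +5% at d = 0.5).  At d = 1.0 the
  estimate runs ≈ +16% high asymptotically: at two-fold degenerate sites
  the difference/site contribution saturates at 1.5 while the Jukes–Cantor
  inversion assumes 0.75, so the pooled correction over-corrects;
  finite-length convexity of the correction adds ≈ +2% more.  This is an
  intrinsic property of NG86 counting with a pooled JC correction under
  synonymous-only evolution, documented here rather than hidden by tuning
  the generator.
* **Scenario analyses** — the two presets run end to end, reporting
  community structure, exon histograms and per-group Ks against the
  simulator's ground truth.

The brute-force oracles used by the test suite (exhaustive monotone-chain
search; k-clique enumeration with pairwise-intersection percolation) live
with the tests and share no code with the implementations they check; the
clique percolation implementation is additionally cross-checked against
the graph library's independent routine.
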