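import filecmp

import numpy as np
import pytest

from msynnet.molevo import translate_cds
from msynnet.simulate import (
    SimConfig,
    SimEvent,
    _make_root_genome,
    _SimState,
    apply_event,
    evolve_cds,
    mammal_scenario,
    random_cds,
    simulate_dataset,
)

THREE_SPECIES = "((A:1,B:1)ab:1,C:2)root;"


def _small_config(**kwargs):
    defaults = dict(
        species_tree=THREE_SPECIES, n_chromosomes=2, genes_per_chromosome=10,
        n_codons=60, ks_rate=0.0, seed=1,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


def _toy_genome(n_genes=10, seed=0):
    state = _SimState()
    cfg = _small_config(genes_per_chromosome=n_genes)
    return _make_root_genome(cfg, state)


def _ranks_ok(genome):
    for chrom, genes in genome.chroms.items():
        assert len({g.uid for g in genes}) == len(genes)


class TestEvents:
    def test_loss_closes_ranks(self):
        g = _toy_genome()
        before = g.gene_count()
        apply_event(g, SimEvent("loss"), np.random.default_rng(0))
        assert g.gene_count() == before - 1

    def test_tandem_inserts_adjacent_copy(self):
        g = _toy_genome()
        rng = np.random.default_rng(1)
        apply_event(g, SimEvent("tandem"), rng)
        chrom = next(c for c in g.chroms if len(g.chroms[c]) == 11)
        genes = g.chroms[chrom]
        pos = next(
            k for k, gene in enumerate(genes[:-1])
            if genes[k + 1].family == gene.family
        )
        copy = genes[pos + 1]
        assert copy.context == genes[pos].context
        _ranks_ok(g)

    def test_rna_transposition_makes_intronless_copy(self):
        g = _toy_genome()
        before = {gene.uid for _, _, gene in g.all_genes()}
        apply_event(g, SimEvent("transposition", mode="rna"),
                    np.random.default_rng(2))
        (copy,) = [gene for _, _, gene in g.all_genes() if gene.uid not in before]
        assert copy.exon_count == 1
        assert copy.relaxed
        assert copy.context.startswith("ctx_transposed")

    def test_dna_transposition_preserves_exons(self):
        g = _toy_genome()
        before = {gene.uid for _, _, gene in g.all_genes()}
        exon_of = {gene.uid: gene.exon_count for _, _, gene in g.all_genes()}
        fam_of = {gene.uid: gene.family for _, _, gene in g.all_genes()}
        apply_event(g, SimEvent("transposition", mode="dna"),
                    np.random.default_rng(3))
        (copy,) = [gene for _, _, gene in g.all_genes() if gene.uid not in before]
        donor_uid = next(u for u, f in fam_of.items() if f == copy.family)
        assert copy.exon_count == exon_of[donor_uid]

    def test_inversion_reverses_order_and_flips_strands(self):
        class ScriptedRng:
            """Yields a fixed sequence from integers(): chromosome index 0,
            window start 0, window end len-1 (full-chromosome inversion)."""

            def __init__(self, values):
                self.values = list(values)

            def integers(self, lo, hi):
                return self.values.pop(0)

        g = _toy_genome()
        chrom = sorted(g.chroms)[0]
        before = [(gene.uid, gene.strand) for gene in g.chroms[chrom]]
        rng = ScriptedRng([0, 0, len(before) - 1])
        apply_event(g, SimEvent("inversion"), rng)
        after = [(gene.uid, gene.strand) for gene in g.chroms[chrom]]
        assert [u for u, _ in after] == [u for u, _ in reversed(before)]
        assert all(s1 != s2 for (_, s1), (_, s2) in zip(reversed(before), after))

    def test_wgd_with_full_retention_doubles_gene_count(self):
        g = _toy_genome()
        before = g.gene_count()
        apply_event(g, SimEvent("wgd", multiplicity=2, retention_prob=1.0),
                    np.random.default_rng(4))
        assert g.gene_count() == 2 * before

    def test_wgd_retention_follows_binomial_law(self):
        """Duplicate retention at p=0.5 over 1000 genes stays within three
        binomial standard deviations of the mean."""
        state = _SimState()
        cfg = SimConfig(species_tree=THREE_SPECIES, n_chromosomes=1,
                        genes_per_chromosome=1000, n_codons=3, seed=9)
        g = _make_root_genome(cfg, state)
        apply_event(g, SimEvent("wgd", multiplicity=2, retention_prob=0.5),
                    np.random.default_rng(7))
        retained = g.gene_count() - 1000
        sigma = (1000 * 0.25) ** 0.5
        assert abs(retained - 500) <= 3 * sigma

    def test_wgt_adds_two_chromosome_copies(self):
        g = _toy_genome()
        n_chroms = len(g.chroms)
        apply_event(g, SimEvent("wgd", multiplicity=3, retention_prob=1.0),
                    np.random.default_rng(5))
        assert len(g.chroms) == 3 * n_chroms

    def test_unknown_event_kind(self):
        with pytest.raises(ValueError, match="unknown event"):
            apply_event(_toy_genome(), SimEvent("fusion"), np.random.default_rng(0))

    def test_invalid_multiplicity_rejected_by_config(self):
        with pytest.raises(ValueError, match="multiplicity"):
            _small_config(wgd_events=(("root", 4, 0.5),))


class TestEvolveCds:
    def test_zero_distance_is_identity(self):
        rng = np.random.default_rng(0)
        cds = random_cds(rng, 50)
        assert evolve_cds(cds, 0.0, rng) == cds

    def test_translation_invariant(self):
        rng = np.random.default_rng(1)
        for d in (0.1, 0.5, 2.0):
            cds = random_cds(rng, 80)
            child = evolve_cds(cds, d, rng)
            assert translate_cds(child) == translate_cds(cds)
            assert child != cds  # divergence actually happened

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            evolve_cds("ATGTAGAAA", 0.1, np.random.default_rng(0))


class TestSimulateDataset:
    def test_no_event_limit(self):
        """With all rates zero every species carries the root gene order
        and family content."""
        sim = simulate_dataset(_small_config())
        families = {
            sp: [sim.truth.families[r.gene_id] for r in recs]
            for sp, recs in sim.genomes.items()
        }
        base = families["A"]
        assert families["B"] == base and families["C"] == base
        assert len(base) == 20

    def test_wgd_with_full_retention_doubles_descendants(self):
        sim = simulate_dataset(
            _small_config(wgd_events=(("ab", 2, 1.0),))
        )
        assert len(sim.genomes["A"]) == 40
        assert len(sim.genomes["C"]) == 20

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = _small_config(ks_rate=0.05, tandem_rate=0.002, loss_rate=0.002)
        for run in ("r1", "r2"):
            simulate_dataset(cfg).write(tmp_path / run)
        names = sorted(p.name for p in (tmp_path / "r1").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "r1", tmp_path / "r2", names, shallow=False
        )
        assert mismatch == [] and errors == []

    def test_zero_length_branch_has_no_events(self):
        sim = simulate_dataset(
            _small_config(
                species_tree="((A:0,B:0)ab:0,C:0)root;",
                loss_rate=5.0, tandem_rate=5.0,
            )
        )
        assert all(len(recs) == 20 for recs in sim.genomes.values())

    def test_hits_are_exactly_within_family_pairs(self):
        sim = simulate_dataset(_small_config(ks_rate=0.05))
        fams = sim.truth.families
        for hit in sim.hits:
            assert fams[hit.query_id] == fams[hit.subject_id]
        # bitscore decreases with true distance
        import itertools

        scored = [
            (sim.truth.true_distance(h.query_id, h.subject_id), h.bitscore)
            for h in sim.hits
        ]
        for (d1, b1), (d2, b2) in itertools.combinations(scored[:50], 2):
            if d1 < d2:
                assert b1 >= b2

    def test_protein_fasta_is_translation_of_cds(self):
        sim = simulate_dataset(_small_config())
        for gid, cds in list(sim.cds.items())[:10]:
            assert sim.proteins[gid] == translate_cds(cds)

    def test_rank_permutation_invariant_after_event_storm(self):
        """Heavy background event rates never corrupt the rank structure of
        emitted gene tables."""
        sim = simulate_dataset(
            _small_config(
                loss_rate=0.02, tandem_rate=0.02, transposition_rate=0.01,
                inversion_rate=0.01, ks_rate=0.01,
            )
        )
        for sp, recs in sim.genomes.items():
            for chrom in {r.chrom for r in recs}:
                ranks = sorted(r.rank for r in recs if r.chrom == chrom)
                assert ranks == list(range(len(ranks)))


class TestMammalScenarioTruth:
    def test_two_contexts_inside_clade_outgroup_shares_one(self, mammal_sim):
        """The focal family occupies exactly two genomic contexts within the
        ingroup; the outgroup's single copy shares the ancestral one."""
        truth = mammal_sim.truth
        fam = mammal_sim.focal_family_ids()
        ingroup = {g for g in fam if not g.startswith("outg|")}
        outgroup = {g for g in fam if g.startswith("outg|")}
        clade_contexts = {truth.contexts[g] for g in ingroup}
        assert len(clade_contexts) == 2
        assert len(outgroup) == 1
        assert {truth.contexts[g] for g in outgroup} < clade_contexts

    def test_relaxed_copies_diverge_faster_in_truth(self, mammal_sim):
        import itertools

        truth = mammal_sim.truth
        fam = mammal_sim.focal_family_ids()
        conserved = [g for g in fam
                     if not truth.contexts[g].startswith("ctx_transposed")]
        relaxed = [g for g in fam
                   if truth.contexts[g].startswith("ctx_transposed")]
        mean = lambda genes: np.mean(
            [truth.true_distance(a, b)
             for a, b in itertools.combinations(genes, 2)]
        )
        assert mean(relaxed) > mean(conserved)

    def test_true_distance_is_symmetric_and_additive(self, mammal_sim):
        truth = mammal_sim.truth
        fam = mammal_sim.focal_family_ids()
        a, b = fam[0], fam[1]
        assert truth.true_distance(a, b) == pytest.approx(truth.true_distance(b, a))
        # conserved ingroup pair distance = 2 * (path to MRCA) * ks_rate
        m1 = next(g for g in fam if g.startswith("m1|")
                  and not truth.contexts[g].startswith("ctx_transposed"))
        m2 = next(g for g in fam if g.startswith("m2|")
                  and not truth.contexts[g].startswith("ctx_transposed"))
        ks = mammal_sim.config.ks_rate
        assert truth.true_distance(m1, m2) == pytest.approx(2 * 1.0 * ks)
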