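import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msynnet import core_io
from msynnet.core_io import FeatureConfig, GeneRecord, HomologyHit

GFF3_TWO_ISOFORMS = """##gff-version 3
chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\tsrc\texon\t101\t150\t.\t+\t.\tID=g1.t1.e1;Parent=g1.t1
chr1\tsrc\texon\t161\t200\t.\t+\t.\tID=g1.t1.e2;Parent=g1.t1
chr1\tsrc\tCDS\t101\t150\t.\t+\t0\tID=g1.t1.c1;Parent=g1.t1
chr1\tsrc\tCDS\t161\t200\t.\t+\t0\tID=g1.t1.c2;Parent=g1.t1
chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=g1.t2;Parent=g1
chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=g1.t2.e1;Parent=g1.t2
chr1\tsrc\tCDS\t101\t200\t.\t+\t0\tID=g1.t2.c1;Parent=g1.t2
chr1\tsrc\tgene\t301\t400\t.\t-\t.\tID=g2
chr1\tsrc\tmRNA\t301\t400\t.\t-\t.\tID=g2.t1;Parent=g2
chr1\tsrc\texon\t301\t330\t.\t-\t.\tID=g2.t1.e1;Parent=g2.t1
chr1\tsrc\texon\t341\t370\t.\t-\t.\tID=g2.t1.e2;Parent=g2.t1
chr1\tsrc\texon\t381\t400\t.\t-\t.\tID=g2.t1.e3;Parent=g2.t1
"""


class TestGff3:
    def test_longest_isoform_and_exon_count(self, tmp_path):
        """The isoform with the greatest summed CDS length wins; its exon
        features are counted."""
        path = tmp_path / "x.gff3"
        path.write_text(GFF3_TWO_ISOFORMS)
        records = {r.gene_id: r for r in core_io.read_gff3(path, "sp")}
        # g1.t2 has a single 100-nt CDS vs t1's 90 -> one exon counted
        assert records["g1"].exon_count == 1
        assert records["g2"].exon_count == 3

    def test_coordinate_conversion(self, tmp_path):
        """1-based closed GFF3 columns become 0-based half-open."""
        path = tmp_path / "x.gff3"
        path.write_text(GFF3_TWO_ISOFORMS)
        records = {r.gene_id: r for r in core_io.read_gff3(path, "sp")}
        assert (records["g1"].start, records["g1"].end) == (100, 200)
        assert records["g2"].strand == "-"

    def test_orphan_exon_is_an_error(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text(
            "chr1\ts\tgene\t1\t10\t.\t+\t.\tID=g\n"
            "chr1\ts\texon\t1\t10\t.\t+\t.\tID=e1\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            core_io.read_gff3(path, "sp")

    def test_gene_without_transcript_excluded(self, tmp_path, caplog):
        path = tmp_path / "x.gff3"
        path.write_text("chr1\ts\tgene\t1\t10\t.\t+\t.\tID=lonely\n")
        with caplog.at_level("WARNING"):
            records = core_io.read_gff3(path, "sp")
        assert records == []
        assert "lonely" in caplog.text

    def test_round_trip_restores_closed_intervals(self, tmp_path):
        """write_gff3(read_gff3(x)) preserves the 1-based closed intervals."""
        src = tmp_path / "a.gff3"
        src.write_text(GFF3_TWO_ISOFORMS)
        records = core_io.read_gff3(src, "sp")
        dst = tmp_path / "b.gff3"
        core_io.write_gff3(records, dst)
        again = core_io.read_gff3(dst, "sp")
        assert [(r.gene_id, r.start, r.end, r.strand) for r in again] == [
            (r.gene_id, r.start, r.end, r.strand) for r in records
        ]


class TestBed:
    def test_basic_parse(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t0\t500\tg1\t0\t+\n")
        (rec,) = core_io.read_bed(path, "sp")
        assert (rec.start, rec.end, rec.strand, rec.exon_count) == (0, 500, "+", None)

    def test_rank_follows_start_not_file_order(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t10\t20\ta\n" "chr1\t5\t9\tb\n")
        recs = {r.gene_id: r for r in core_io.read_bed(path, "sp")}
        assert recs["b"].rank == 0 and recs["a"].rank == 1

    def test_invalid_interval(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t9\t5\ta\n")
        with pytest.raises(ValueError, match=":1"):
            core_io.read_bed(path, "sp")

    def test_empty_file_warns(self, tmp_path, caplog):
        path = tmp_path / "x.bed"
        path.write_text("")
        with caplog.at_level("WARNING"):
            assert core_io.read_bed(path, "sp") == []
        assert "empty" in caplog.text


class TestRanks:
    def test_rank_order_equals_start_then_id_order(self):
        """Sorting by rank is the same as sorting by (start, gene_id) on
        every chromosome."""
        rng = random.Random(7)
        records = []
        for n in range(60):
            start = rng.randrange(0, 500)
            records.append(
                GeneRecord(
                    gene_id=f"g{n}", species="sp", chrom=f"chr{n % 3}",
                    start=start, end=start + 1 + rng.randrange(50), strand="+",
                )
            )
        ranked = core_io.assign_ranks(records)
        for chrom in {"chr0", "chr1", "chr2"}:
            sub = [r for r in ranked if r.chrom == chrom]
            by_rank = sorted(sub, key=lambda r: r.rank)
            by_pos = sorted(sub, key=lambda r: (r.start, r.gene_id))
            assert [r.gene_id for r in by_rank] == [r.gene_id for r in by_pos]
            assert sorted(r.rank for r in sub) == list(range(len(sub)))


class TestHomology:
    def _write(self, path, rows):
        path.write_text(
            "".join(
                f"{q}\t{s}\t0\t0\t0\t0\t0\t0\t0\t0\t{ev}\t{bs}\n"
                for q, s, ev, bs in rows
            )
        )

    def test_self_hits_and_weak_hits_dropped(self, tmp_path):
        path = tmp_path / "h.tsv"
        self._write(path, [("g1", "g1", 0.0, 500), ("g1", "g2", 1e-3, 90),
                           ("g1", "g3", 1e-30, 200)])
        hits = core_io.read_homology_table(path, evalue_max=1e-10)
        assert [(h.query_id, h.subject_id) for h in hits] == [("g1", "g3")]

    def test_per_query_cap(self, tmp_path):
        """25 hits for one query are capped to the 20 best by bitscore."""
        path = tmp_path / "h.tsv"
        self._write(
            path, [("q", f"s{n:02d}", 1e-40, 100 + n) for n in range(25)]
        )
        hits = core_io.read_homology_table(path, max_hits=20)
        assert len(hits) == 20
        assert min(h.bitscore for h in hits) == 105  # the 5 weakest dropped

    def test_filter_idempotent(self):
        rng = random.Random(3)
        raw = [
            (f"g{rng.randrange(8)}", f"g{rng.randrange(8)}",
             10.0 ** -rng.randrange(5, 40), float(rng.randrange(60, 400)))
            for _ in range(300)
        ]
        once = core_io.filter_hits(raw, evalue_max=1e-10, max_hits=5)
        twice = core_io.filter_hits(once, evalue_max=1e-10, max_hits=5)
        assert once == twice

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([f"g{n}" for n in range(6)]),
                st.sampled_from([f"g{n}" for n in range(6)]),
                st.floats(min_value=0.0, max_value=1e-5),
                st.floats(min_value=1.0, max_value=500.0),
            ),
            max_size=60,
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_filter_idempotent_property(self, raw):
        once = core_io.filter_hits(raw, evalue_max=1e-8, max_hits=4)
        assert core_io.filter_hits(once, evalue_max=1e-8, max_hits=4) == once

    def test_symmetrize_is_direction_independent(self):
        fwd = [("a", "b", 1e-20, 100.0), ("b", "a", 1e-25, 120.0)]
        rev = [tuple(x) for x in reversed(fwd)]
        assert core_io.symmetrize(fwd) == core_io.symmetrize(rev)
        (hit,) = core_io.symmetrize(fwd)
        assert (hit.bitscore, hit.evalue) == (120.0, 1e-25)

    def test_unknown_id_policy(self, tmp_path):
        path = tmp_path / "h.tsv"
        self._write(path, [("g1", "gX", 1e-30, 200)])
        assert core_io.read_homology_table(path, known_ids={"g1"}) == []
        with pytest.raises(ValueError, match="gX"):
            core_io.read_homology_table(path, known_ids={"g1"}, on_unknown="error")


class TestFastaTsv:
    def test_fasta_round_trip_and_id_token(self, tmp_path):
        path = tmp_path / "x.fa"
        path.write_text(">g1 some description\nATG\nCCC\n>g2\nTTT\n")
        assert core_io.read_fasta(path) == {"g1": "ATGCCC", "g2": "TTT"}
        out = tmp_path / "y.fa"
        core_io.write_fasta({"g1": "ATGCCC", "g2": "TTT"}, out)
        assert core_io.read_fasta(out) == {"g1": "ATGCCC", "g2": "TTT"}

    def test_duplicate_fasta_id(self, tmp_path):
        path = tmp_path / "x.fa"
        path.write_text(">g1 a\nAT\n>g1 b\nCC\n")
        with pytest.raises(ValueError, match="duplicate"):
            core_io.read_fasta(path)

    def test_tsv_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({"a": [1, 2, 3], "b": ["x", "y", "z"]})
        path = tmp_path / "t.tsv"
        core_io.write_tsv(df, path)
        assert path.read_text().startswith("#a\tb\n")
        back = core_io.read_tsv(path)
        assert back.equals(df)
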