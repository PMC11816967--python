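"""Format readers/writers: parsing semantics, invariants, round trips."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from equiprio import io as eio
from equiprio.core import GenomicInterval, ScoreTrack, ValidationError, point
from equiprio.prioritize import LDPair

from conftest import random_chain


class TestBed:
    def test_zero_based_half_open(self):
        (iv,) = eio.read_intervals("chr1\t0\t10")
        assert (iv.chrom, iv.start, iv.end, iv.strand) == ("chr1", 0, 10, ".")

    def test_strand_column(self):
        (iv,) = eio.read_intervals("chr2\t5\t6\tx\t0\t-")
        assert len(iv) == 1 and iv.strand == "-"

    def test_empty_interval_rejected(self):
        with pytest.raises(ValidationError):
            eio.read_intervals("chr1\t7\t7")

    def test_malformed_line_names_line_number(self):
        with pytest.raises(eio.ParseError, match="line 2"):
            eio.read_intervals("chr1\t0\t10\nchr1\t5")

    def test_round_trip(self):
        ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 5, 6, "-")]
        assert eio.read_intervals(eio.write_intervals(ivs)) == ivs


class TestScoreTrack:
    def test_single_base_score(self):
        track = eio.read_score_track("chr1\t99\t100\t3.87")
        assert track.value_at("chr1", 99) == 3.87
        assert track.value_at("chr1", 100) is None

    def test_empty_track(self):
        assert len(eio.read_score_track("")) == 0

    def test_overlap_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            eio.read_score_track("chr1\t0\t10\t1.0\nchr1\t5\t6\t2.0")

    def test_non_numeric_score(self):
        with pytest.raises(eio.ParseError):
            eio.read_score_track("chr1\t0\t10\tNaN?")

    def test_round_trip(self):
        text = "chr1\t5\t9\t-0.5\nchr1\t9\t12\t2.25\nchr2\t0\t1\t4.91\n"
        track = eio.read_score_track(text)
        assert eio.write_score_track(track) == text


class TestChain:
    MINIMAL = (
        "chain 100 chrS 5000 + 0 1000 chrT 6000 + 500 1500 1\n"
        "1000\n\n"
    )

    def test_minimal_chain(self):
        (c,) = eio.read_chain(self.MINIMAL)
        assert c.blocks == ((1000, 0, 0),)
        assert c.source == GenomicInterval("chrS", 0, 1000)

    def test_two_chains_in_file_order(self):
        chains = eio.read_chain(self.MINIMAL + self.MINIMAL.replace(" 1\n", " 2\n", 1))
        assert [c.chain_id for c in chains] == [1, 2]

    def test_block_sum_mismatch_rejected(self):
        bad = self.MINIMAL.replace("1000\n\n", "999\n\n")
        with pytest.raises(ValidationError):
            eio.read_chain(bad)

    def test_random_valid_chains_round_trip(self):
        rng = random.Random(11)
        for i in range(50):
            chain = random_chain(rng, i + 1)
            text = eio.write_chain([chain], {chain.source.chrom: 100_000})
            (parsed,) = eio.read_chain(text)
            assert parsed == chain

    def test_corrupted_block_sums_always_raise(self):
        rng = random.Random(12)
        for i in range(30):
            chain = random_chain(rng, i + 1)
            text = eio.write_chain([chain], {chain.source.chrom: 100_000})
            lines = text.splitlines()
            # bump one block size by one: both span sums break
            for ln, line in enumerate(lines):
                parts = line.split()
                if line and not line.startswith("chain") and parts[0].isdigit():
                    parts[0] = str(int(parts[0]) + 1)
                    lines[ln] = " ".join(parts)
                    break
            with pytest.raises(ValidationError):
                eio.read_chain("\n".join(lines))


class TestTables:
    def test_manifest_positions_are_one_based(self):
        text = "marker_id\trs_id\tchrom\tpos\tref\talt\nM1\trs1\tchr1\t100\tA\tG\n"
        (v,) = eio.read_tables(text, "manifest")
        assert (v.pos, v.site.end) == (99, 100)
        assert v.marker_id == "M1"

    def test_ld_pair_value(self):
        (p,) = eio.read_tables("snp_a\tsnp_b\tr2\nm1\ts9\t0.955\n", "ld")
        assert p == LDPair("m1", "s9", 0.955)

    def test_mirna_fasta(self):
        (m,) = eio.read_tables(">mir-x\nUAGCUUAUCAGACUGAUGUUGA\n", "mirna_fasta")
        assert m.mirna_id == "mir-x" and len(m.sequence) == 22

    def test_missing_column_lists_names(self):
        with pytest.raises(eio.SchemaError, match="r2"):
            eio.read_tables("snp_a\tsnp_b\nx\ty\n", "ld")

    @pytest.mark.parametrize("dialect,rows", [
        ("ld", [LDPair("a", "b", 0.97), LDPair("c", "d", 1.0)]),
        ("polya", [GenomicInterval("chr1", 10, 20)]),
        ("tfbs", {"rs1": {"Gain of TFBS", "Score Change"}}),
    ])
    def test_write_read_round_trip(self, dialect, rows):
        assert eio.read_tables(eio.write_table(rows, dialect), dialect) == rows

    @given(p=st.integers(min_value=1, max_value=10**9))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_coordinate_round_trip_one_based(self, p):
        # internal [p-1, p) converts back to the declared 1-based position p
        text = f"rs_id\tchrom\tpos\tref\talt\nrs1\tchr1\t{p}\tA\tG\n"
        (v,) = eio.read_tables(text, "wgs")
        assert v.pos == p - 1
        assert eio.write_table([v], "wgs") == text


class TestGff3:
    def test_gene_model_round_trip(self):
        from conftest import make_gene

        genes = [make_gene(strand="+"),
                 make_gene(chrom="chr2", origin=50, strand="-", gene_id="g2")]
        parsed = eio.read_gene_models(eio.write_gene_models(genes))
        assert len(parsed) == 2
        for got, want in zip(sorted(parsed, key=lambda g: g.span.chrom),
                             sorted(genes, key=lambda g: g.span.chrom)):
            assert got.span == want.span
            assert got.transcripts[0].exons == want.transcripts[0].exons
            assert got.transcripts[0].cds == want.transcripts[0].cds
            assert got.transcripts[0].utr3 == want.transcripts[0].utr3


class TestFixture:
    def test_row_and_gene_counts(self):
        table = eio.read_final_table_fixture()
        assert len(table.rows) == 31
        assert len({r.gene_symbol for r in table.rows}) == 19

    def test_conserved_intronic_example_row(self):
        table = eio.read_final_table_fixture()
        (row,) = [r for r in table.rows if r.rs_id == "rs68623490"]
        assert row.gerp == 4.91
        assert row.constrained
        assert row.gene_symbol == "PDLIM5"

    def test_bracketed_ids_become_anchors(self):
        table = eio.read_final_table_fixture()
        (row,) = [r for r in table.rows if r.rs_id == "rs397216526"]
        assert row.type == "LD"
        assert row.anchor_ids == ("BIEC2_307086",) and row.marker_ids == ()
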