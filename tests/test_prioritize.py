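"""LD expansion, criterion filter, QTL-ortholog filter, final table."""

import random

import pytest

from equiprio.annotate import AnnotationRecord
from equiprio.core import GenomicInterval, Thresholds, Variant, point
from equiprio.genes import ConsequenceCall
from equiprio.prioritize import (
    LDPair,
    OrthologRow,
    PrioritizedTable,
    QTLRecord,
    build_final_table,
    expand_by_ld,
    passes_any,
    propagate_to_markers,
    qtl_gene_filter,
)


def marker(rs, marker_id, pos=100):
    return Variant(rs, point("chr1", pos), "A", "G", marker_id=marker_id)


def wgs(rs, pos=200):
    return Variant(rs, point("chr1", pos), "C", "T")


def record(rs="rsX", gene="g1", terms=("intron_variant",), **kw):
    defaults = dict(
        constrained=False, gerp=None, gerp_high=False, tf_effect=frozenset(),
        regulatory={}, cpg=False, mirna_hits=(), polya=False,
    )
    defaults.update(kw)
    return AnnotationRecord(
        rs_id=rs, gene_id=gene, consequence=ConsequenceCall(frozenset(terms)),
        **defaults,
    )


class TestExpandByLd:
    M = [marker("rs1m", "M1"), marker("rs2m", "M2", pos=110)]
    W = [wgs("rs9s", 200), wgs("rs8s", 210)]

    def test_partner_above_threshold_included(self):
        variants, _, _ = expand_by_ld(self.M, self.W, [LDPair("M1", "rs9s", 0.955)])
        ld = [v for v in variants if v.provenance == "ld_partner"]
        assert [(v.rs_id, v.anchor_marker_ids) for v in ld] == [("rs9s", ("M1",))]

    def test_exact_threshold_excluded(self):
        variants, _, _ = expand_by_ld(self.M, self.W, [LDPair("M1", "rs9s", 0.95)])
        assert all(v.provenance == "direct_marker" for v in variants)

    def test_marker_marker_pair_side_channel(self):
        variants, side, _ = expand_by_ld(self.M, self.W, [LDPair("M1", "M2", 1.0)])
        assert side == [LDPair("M1", "M2", 1.0)]
        assert {v.rs_id for v in variants} == {"rs1m", "rs2m"}

    def test_dangling_id_warns_and_skips(self):
        variants, _, warnings = expand_by_ld(self.M, self.W, [LDPair("M1", "rsNO", 0.99)])
        assert len(warnings) == 1 and "rsNO" in warnings[0]
        assert all(v.provenance == "direct_marker" for v in variants)

    def test_direct_provenance_wins_on_dedup(self):
        shared = marker("rsBOTH", "M3", pos=300)
        also_wgs = Variant("rsBOTH", point("chr1", 300), "A", "G")
        variants, _, _ = expand_by_ld(
            [shared, *self.M], [also_wgs], [LDPair("M1", "rsBOTH", 0.99)]
        )
        (v,) = [x for x in variants if x.rs_id == "rsBOTH"]
        assert v.provenance == "direct_marker"

    def test_multiple_anchors_union(self):
        pairs = [LDPair("M1", "rs9s", 0.99), LDPair("M2", "rs9s", 0.97)]
        variants, _, _ = expand_by_ld(self.M, self.W, pairs)
        (v,) = [x for x in variants if x.rs_id == "rs9s"]
        assert v.anchor_marker_ids == ("M1", "M2")

    def test_raising_threshold_never_adds_variants(self):
        rng = random.Random(5)
        pairs = [LDPair("M1", w.rs_id, round(rng.uniform(0.9, 1.0), 3)) for w in self.W]
        prev = None
        for cutoff in (0.9, 0.95, 0.97, 0.99, 1.0):
            variants, _, _ = expand_by_ld(self.M, self.W, pairs, cutoff)
            rs = {v.rs_id for v in variants}
            if prev is not None:
                assert rs <= prev
            prev = rs


class TestPassesAny:
    def test_all_false_record_fails(self):
        assert not passes_any(record())

    def test_tfbs_alone_passes(self):
        assert passes_any(record(tf_effect=frozenset({"Gain of TFBS"})))

    def test_high_gerp_alone_passes(self):
        assert passes_any(record(gerp=4.91, gerp_high=True))

    def test_severe_alone_passes_and_is_switchable(self):
        rec = record(terms=("missense_variant",))
        assert passes_any(rec)
        assert not passes_any(rec, Thresholds(severe_is_criterion=False))

    def test_cpg_off_by_default_on_by_switch(self):
        rec = record(cpg=True)
        assert not passes_any(rec)
        assert passes_any(rec, Thresholds(cpg_is_criterion=True))

    def test_enabling_a_criterion_is_monotone(self):
        recs = [record(cpg=True), record(), record(polya=True),
                record(terms=("missense_variant",), cpg=True)]
        base = {r.rs_id for r in recs if passes_any(r, Thresholds())}
        wider = {r.rs_id for r in recs if passes_any(r, Thresholds(cpg_is_criterion=True))}
        assert base <= wider


class TestPropagate:
    def test_partner_pass_brackets_marker(self):
        partner = Variant("rsL", point("chr1", 5), "A", "G",
                          provenance="ld_partner", anchor_marker_ids=("M1",))
        ids, rows = propagate_to_markers([partner])
        assert ids == {"M1"} and rows == [("rsL", ("M1",))]

    def test_direct_pass_is_marker_row(self):
        ids, rows = propagate_to_markers([marker("rs1m", "M1")])
        assert ids == {"M1"} and rows == [("rs1m", ())]

    def test_nothing_passes_nothing_propagates(self):
        assert propagate_to_markers([]) == (set(), [])


class TestQtlFilter:
    ORTH = [OrthologRow("g1", "cattle", "T1", GenomicInterval("bta1", 10_000, 12_000))]

    def _qtl(self, start, end, trait_class="Meat and Carcass"):
        return QTLRecord("cattle", "t", trait_class, GenomicInterval("bta1", start, end))

    def test_ortholog_inside_qtl(self):
        assert qtl_gene_filter(["g1"], [self._qtl(9000, 13_000)], self.ORTH) == {"g1"}

    def test_reachable_only_through_flank(self):
        # QTL starts 4,999 bp after the ortholog ends: brute-force expansion check
        qtl = self._qtl(12_000 + 4999, 20_000)
        assert qtl_gene_filter(["g1"], [qtl], self.ORTH, flank=5000) == {"g1"}
        assert qtl_gene_filter(["g1"], [qtl], self.ORTH, flank=4998) == set()

    def test_gene_without_ortholog_dropped(self):
        assert qtl_gene_filter(["g2"], [self._qtl(0, 50_000)], self.ORTH) == set()

    def test_trait_class_allow_list(self):
        qtl = self._qtl(9000, 13_000, trait_class="Exterior")
        assert qtl_gene_filter(["g1"], [qtl], self.ORTH) == set()

    def test_species_must_match(self):
        qtl = QTLRecord("pig", "t", "Meat and Carcass",
                        GenomicInterval("bta1", 9000, 13_000))
        assert qtl_gene_filter(["g1"], [qtl], self.ORTH) == set()


def _passing_pairs():
    out = []
    for i, gene in enumerate(["g2", "g1", "g1"]):
        rs = f"rs{i}"
        if i == 2:
            v = Variant(rs, point("chr1", 300 + i), "A", "G",
                        provenance="ld_partner", anchor_marker_ids=("M9",))
        else:
            v = marker(rs, f"M{i}", pos=300 + i)
        out.append((v, record(rs=rs, gene=gene, gerp=3.0, gerp_high=True)))
    return out


class TestFinalTable:
    def test_summary_identity_and_sorting(self):
        table = build_final_table(_passing_pairs(), {"g1": "B", "g2": "A"},
                                  {"g1", "g2"})
        s = table.summary
        assert s.n_direct + s.n_ld == s.n_snps == 3
        assert [r.gene_symbol for r in table.rows] == ["A", "B", "B"]
        assert table.rows[2].anchor_ids == ("M9",)

    def test_qtl_restriction(self):
        table = build_final_table(_passing_pairs(), {"g1": "B", "g2": "A"}, {"g2"})
        assert [r.rs_id for r in table.rows] == ["rs0"]

    def test_empty_input(self):
        table = build_final_table([], {}, set())
        s = table.summary
        assert (s.n_snps, s.n_genes, s.n_markers, s.n_direct, s.n_ld) == (0,) * 5

    def test_order_invariance_byte_identical(self):
        pairs = _passing_pairs()
        t1 = build_final_table(pairs, {"g1": "B", "g2": "A"}, {"g1", "g2"})
        t2 = build_final_table(list(reversed(pairs)), {"g1": "B", "g2": "A"},
                               {"g1", "g2"})
        assert t1.to_tsv() == t2.to_tsv()

    def test_tsv_round_trip_identity(self):
        table = build_final_table(_passing_pairs(), {"g1": "B", "g2": "A"},
                                  {"g1", "g2"})
        text = table.to_tsv()
        assert PrioritizedTable.from_tsv(text).to_tsv() == text
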