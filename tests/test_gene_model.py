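"""Consequence classification against gene models."""

import random

import pytest

from equiprio import _reference as ref
from equiprio.core import GenomicInterval, ReferenceMismatchError, ValidationError, point, revcomp
from equiprio.genes import (
    GeneModel,
    Transcript,
    classify_consequence,
    expand_region,
    genes_for_variant,
)

from conftest import make_gene, make_genome, variant_at


class TestExpandRegion:
    def test_symmetric_expansion(self):
        iv = GenomicInterval("chr1", 10_000, 12_000)
        assert expand_region(iv, 5000) == GenomicInterval("chr1", 5000, 17_000)

    def test_clamped_at_origin(self):
        iv = GenomicInterval("chr1", 2000, 3000)
        assert expand_region(iv, 5000) == GenomicInterval("chr1", 0, 8000)

    def test_zero_flank_identity(self):
        iv = GenomicInterval("chr1", 5, 9, "-")
        assert expand_region(iv, 0) == iv


class TestGenesForVariant:
    def test_overlapping_spans_both_reported_sorted(self, genome):
        g1 = make_gene(origin=1000)
        g2 = GeneModel("g0", "G0", GenomicInterval("chr1", 1200, 1400, "+"),
                       g1.transcripts)
        v = variant_at(genome, "chr1", 1300)
        assert genes_for_variant(v, [g1, g2], 0) == ["g0", "g1"]

    def test_outside_all_flanks(self, gene):
        genome = make_genome(10_000)
        v = variant_at(genome, "chr1", 1000 + 700 + 5000)  # first base past the flank
        assert genes_for_variant(v, [gene], 5000) == []
        just_inside = variant_at(genome, "chr1", 1000 + 700 + 4999)
        assert genes_for_variant(just_inside, [gene], 5000) == ["g1"]

    def test_expanded_start_boundary_inclusive(self, gene):
        # brute-force scan across the boundary region agrees with the query
        genome = make_genome(20_000)
        flank = 500
        for pos in range(400, 610):
            v = variant_at(genome, "chr1", pos)
            brute = 1000 - flank <= pos < 1000 + 700 + flank
            assert (genes_for_variant(v, [gene], flank) == ["g1"]) == brute


def _patch(genome, chrom, pos, base):
    s = genome[chrom]
    genome[chrom] = s[:pos] + base + s[pos + 1 :]


class TestClassify:
    def test_upstream_of_plus_strand_gene(self, genome, gene):
        v = variant_at(genome, "chr1", 1000 - 300)
        call = classify_consequence(v, gene, genome)
        assert call.terms == {"upstream_gene_variant"}
        assert not call.severe

    def test_downstream_of_plus_strand_gene(self, genome, gene):
        v = variant_at(genome, "chr1", 1000 + 700 + 10)
        assert classify_consequence(v, gene, genome).terms == {"downstream_gene_variant"}

    def test_utr_terms(self, genome, gene):
        v5 = variant_at(genome, "chr1", 1000 + 50)
        v3 = variant_at(genome, "chr1", 1000 + 560)
        assert classify_consequence(v5, gene, genome).terms == {"5_prime_UTR_variant"}
        assert classify_consequence(v3, gene, genome).terms == {"3_prime_UTR_variant"}

    def test_start_codon_third_base_missense(self, genome, gene):
        # ATG -> ATA is Met -> Ile
        for off, base in enumerate("ATG"):
            _patch(genome, "chr1", 1150 + off, base)
        v = variant_at(genome, "chr1", 1152, alt="A")
        call = classify_consequence(v, gene, genome)
        assert call.terms == {"missense_variant"}
        assert call.severe

    def test_polypyrimidine_window_matches_brute_force(self):
        # every intronic base, both strands: the tract is ranks 3-17 from
        # the acceptor end of the intron
        for strand in "+-":
            genome = make_genome(20_000, seed=3)
            gene = make_gene(strand=strand)
            tx = gene.transcripts[0]
            for intron in tx.introns():
                positions = list(range(intron.start, intron.end))
                ranked = list(reversed(positions)) if strand == "+" else positions
                for pos in positions:
                    v = variant_at(genome, "chr1", pos)
                    call = classify_consequence(v, gene, genome)
                    expect_tract = 3 <= ranked.index(pos) + 1 <= 17
                    assert ("splice_polypyrimidine_tract_variant" in call.terms) == expect_tract
                    assert "intron_variant" in call.terms

    def test_reference_mismatch_raises(self, genome, gene):
        base = genome["chr1"][1350]
        wrong = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        from equiprio.core import Variant

        v = Variant("rsX", point("chr1", 1350), wrong, base)
        with pytest.raises(ReferenceMismatchError):
            classify_consequence(v, gene, genome)

    def test_outside_flank_raises(self, genome, gene):
        v = variant_at(genome, "chr1", 100)
        with pytest.raises(ValidationError, match="flank"):
            classify_consequence(v, gene, genome, flank=200)

    def test_exactly_one_locational_class_per_transcript(self, genome, gene):
        locational = [
            {"upstream_gene_variant"},
            {"downstream_gene_variant"},
            {"intron_variant", "splice_polypyrimidine_tract_variant"},
            {"5_prime_UTR_variant"},
            {"3_prime_UTR_variant"},
            {"synonymous_variant", "missense_variant", "stop_lost", "stop_gained"},
        ]
        for pos in range(900, 1810, 7):
            v = variant_at(genome, "chr1", pos)
            terms = classify_consequence(v, gene, genome).terms
            assert sum(bool(terms & cls) for cls in locational) == 1


class TestStrandFlip:
    def test_reverse_complement_reflection_preserves_terms(self):
        """Mirroring gene and genome through revcomp leaves terms unchanged."""
        length = 4000
        genome = make_genome(length, seed=5)
        gene = make_gene(origin=1000, strand="+")
        flipped_genome = {"chr1": revcomp(genome["chr1"])}

        def mirror_iv(iv):
            return GenomicInterval(iv.chrom, length - iv.end, length - iv.start, "-")

        tx = gene.transcripts[0]
        flipped = GeneModel(
            "g1", "G1", mirror_iv(gene.span),
            (Transcript(
                "tx1",
                exons=tuple(sorted((mirror_iv(e) for e in tx.exons), key=lambda i: i.start)),
                cds=tuple(sorted((mirror_iv(c) for c in tx.cds), key=lambda i: i.start)),
                utr5=tuple(mirror_iv(u) for u in tx.utr5),
                utr3=tuple(mirror_iv(u) for u in tx.utr3),
            ),),
        )
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for pos in range(950, 1760, 13):
            v = variant_at(genome, "chr1", pos)
            fv = variant_at(flipped_genome, "chr1", length - 1 - pos,
                            alt=comp[v.alt])
            t1 = classify_consequence(v, gene, genome).terms
            t2 = classify_consequence(fv, flipped, flipped_genome).terms
            assert t1 == t2, f"pos {pos}: {t1} != {t2}"


class TestCodingOracle:
    def test_matches_full_mrna_translation_oracle(self):
        """Codon-local classification equals rebuild-whole-protein comparison."""
        rng = random.Random(42)
        for strand in "+-":
            genome = make_genome(20_000, seed=9)
            gene = make_gene(strand=strand)
            cds_positions = [
                p for c in gene.transcripts[0].cds for p in range(c.start, c.end)
            ]
            for _ in range(300):
                pos = rng.choice(cds_positions)
                alt = rng.choice([b for b in "ACGT" if b != genome["chr1"][pos]])
                v = variant_at(genome, "chr1", pos, alt=alt)
                got = classify_consequence(v, gene, genome).terms
                want = ref.consequence_terms(v, gene, genome)
                assert got == want, f"{strand}{pos}{alt}: {got} != {want}"
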