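"""Per-variant criteria annotation."""

import random
from dataclasses import replace

from equiprio.annotate import (
    AnnotationSources,
    build_record,
    gerp_annotate,
    overlap_flag,
    polya_flag,
    tfbs_annotate,
)
from equiprio.core import GenomicInterval, ScoreTrack, Thresholds, point
from equiprio.crosslift import RegulatoryBuild, RegulatoryFeature
from equiprio.mirna import Mirna, seeds_for

from conftest import make_gene, make_genome, simple_chain_args, variant_at


class TestOverlapFlag:
    def test_end_exclusive_containment(self, genome):
        v = variant_at(genome, "chr1", 99)
        assert overlap_flag(v, [GenomicInterval("chr1", 90, 100)])

    def test_boundary_excluded(self, genome):
        v = variant_at(genome, "chr1", 100)
        assert not overlap_flag(v, [GenomicInterval("chr1", 90, 100)])

    def test_empty_list(self, genome):
        assert not overlap_flag(variant_at(genome, "chr1", 5), [])

    def test_agrees_with_all_pairs_scan(self, genome):
        rng = random.Random(17)
        ivs = []
        for _ in range(400):
            s = rng.randrange(0, 4800)
            ivs.append(GenomicInterval("chr1", s, s + rng.randrange(1, 60)))
        for _ in range(300):
            pos = rng.randrange(0, 4999)
            v = variant_at(genome, "chr1", pos)
            brute = any(iv.start <= pos < iv.end for iv in ivs)
            assert overlap_flag(v, ivs) == brute


class TestGerp:
    def _track(self, pos, score):
        return ScoreTrack([(point("chr1", pos), score)])

    def test_high_score(self, genome):
        v = variant_at(genome, "chr1", 42)
        assert gerp_annotate(v, self._track(42, 4.91)) == (4.91, True)

    def test_threshold_inclusive(self, genome):
        v = variant_at(genome, "chr1", 42)
        assert gerp_annotate(v, self._track(42, 2.0)) == (2.0, True)

    def test_uncovered_is_missing_not_zero(self, genome):
        v = variant_at(genome, "chr1", 42)
        assert gerp_annotate(v, self._track(43, 9.0)) == (None, False)

    def test_monotone_in_threshold(self, genome):
        rng = random.Random(23)
        for _ in range(100):
            score = rng.uniform(-5, 8)
            v = variant_at(genome, "chr1", 10)
            flags = [gerp_annotate(v, self._track(10, score), t)[1]
                     for t in (0.5, 2.0, 4.0, 8.0)]
            # raising the cutoff can only turn the flag off
            assert flags == sorted(flags, reverse=True)


class TestPolya:
    CLUSTER = [GenomicInterval("chr1", 200, 210)]

    def test_within_symmetric_extension(self, genome):
        assert polya_flag(variant_at(genome, "chr1", 160), self.CLUSTER, 50)

    def test_boundary_of_extension(self, genome):
        assert not polya_flag(variant_at(genome, "chr1", 149), self.CLUSTER, 50)
        assert polya_flag(variant_at(genome, "chr1", 150), self.CLUSTER, 50)

    def test_zero_flank_inside_cluster(self, genome):
        assert polya_flag(variant_at(genome, "chr1", 205), self.CLUSTER, 50)

    def test_one_sided_extension_follows_strand(self, genome):
        v_up, v_down = variant_at(genome, "chr1", 190), variant_at(genome, "chr1", 220)
        assert polya_flag(v_up, self.CLUSTER, 50, "+", symmetric=False)
        assert not polya_flag(v_down, self.CLUSTER, 50, "+", symmetric=False)
        assert not polya_flag(v_up, self.CLUSTER, 50, "-", symmetric=False)
        assert polya_flag(v_down, self.CLUSTER, 50, "-", symmetric=False)


class TestTfbs:
    TABLE = {
        "rs68895977": {"Gain of TFBS"},
        "rs69065907": {"Loss of TFBS", "Score Change", "Gain of TFBS"},
    }

    def test_single_effect(self, genome):
        v = variant_at(genome, "chr1", 5, rs="rs68895977")
        assert tfbs_annotate(v, self.TABLE) == {"Gain of TFBS"}

    def test_multiple_effects_union(self, genome):
        v = variant_at(genome, "chr1", 5, rs="rs69065907")
        assert tfbs_annotate(v, self.TABLE) == {
            "Loss of TFBS", "Score Change", "Gain of TFBS"
        }

    def test_absent_id_empty(self, genome):
        assert tfbs_annotate(variant_at(genome, "chr1", 5, rs="rsZ"), self.TABLE) == set()


def _full_sources(genome, gene, pos):
    """Sources where the variant at ``pos`` satisfies every criterion."""
    chains = simple_chain_args(genome)
    lifted = pos + 500  # the chain below shifts by +500
    mirna = Mirna("mir-t", "U" + "A" * 20)  # seed TTTTTT; engineered separately
    return AnnotationSources(
        genome=genome,
        constrained=[point("chr1", pos).expand(5)],
        gerp_track=ScoreTrack([(point("chr1", pos), 3.5)]),
        tfbs={"rsT": {"Gain of TFBS"}},
        species={
            "human": (
                chains,
                RegulatoryBuild(
                    [RegulatoryFeature(GenomicInterval("chrT", lifted - 2, lifted + 3),
                                       "enhancer")]
                ),
            )
        },
        cpg_islands=[point("chr1", pos).expand(8)],
        polya_clusters=[GenomicInterval("chr1", pos + 20, pos + 30)],
        mirna_seeds=seeds_for([mirna]),
    )


class TestBuildRecord:
    def test_empty_tracks_all_flags_false(self, genome, gene):
        v = variant_at(genome, "chr1", 1250)  # intronic
        rec = build_record(v, gene, AnnotationSources(genome=genome))
        assert rec.consequence.terms == {"intron_variant"}
        assert not rec.constrained and rec.gerp is None and not rec.gerp_high
        assert rec.tf_effect == frozenset() and rec.regulatory == {}
        assert not rec.cpg and not rec.polya and rec.mirna_hits == ()

    def test_criteria_independence_under_mutation(self, genome, gene):
        """Clearing one input source changes only its own record field."""
        pos = 1250
        v = variant_at(genome, "chr1", pos)
        sources = _full_sources(genome, gene, pos)
        base = build_record(v, gene, sources)
        assert base.constrained and base.gerp_high and base.tf_effect
        assert base.human_reg and base.cpg and base.polya

        mutations = {
            "constrained": replace(sources, constrained=[]),
            "gerp": replace(sources, gerp_track=ScoreTrack()),
            "tf_effect": replace(sources, tfbs={}),
            "regulatory": replace(sources, species={}),
            "cpg": replace(sources, cpg_islands=[]),
            "polya": replace(sources, polya_clusters=[]),
        }
        fields = ["constrained", "gerp", "gerp_high", "tf_effect", "regulatory",
                  "cpg", "polya", "mirna_hits"]
        coupled = {"gerp": {"gerp", "gerp_high"}}
        for name, mutated in mutations.items():
            rec = build_record(v, gene, mutated)
            changed = {f for f in fields if getattr(rec, f) != getattr(base, f)}
            assert changed == coupled.get(name, {name}), (name, changed)

    def test_gerp_and_tfbs_combination(self, genome, gene):
        v = variant_at(genome, "chr1", 1250, rs="rs782859809")
        sources = AnnotationSources(
            genome=genome,
            gerp_track=ScoreTrack([(point("chr1", 1250), 3.87)]),
            tfbs={"rs782859809": {"Loss of TFBS"}},
        )
        rec = build_record(v, gene, sources)
        assert rec.gerp == 3.87 and rec.gerp_high
        assert rec.tf_effect == {"Loss of TFBS"}

    def test_mirna_gated_on_utr3(self, genome, gene):
        """Seed scanning runs only for 3' UTR SNPs of the gene in question."""
        utr3_pos, intron_pos = 1600, 1250
        # engineer a seed site over the UTR3 position
        s = genome["chr1"]
        genome["chr1"] = s[:utr3_pos - 2] + "AATAAG" + s[utr3_pos + 4:]
        v = variant_at(genome, "chr1", utr3_pos, alt="C")
        seeds = {"mir-x": "AATAAG"}  # matches the planted site over the center
        sources = AnnotationSources(genome=genome, mirna_seeds=seeds)
        rec = build_record(v, gene, sources, Thresholds())
        assert rec.mirna_hits == (("mir-x", "disrupted"),)
        v2 = variant_at(genome, "chr1", intron_pos)
        rec2 = build_record(v2, gene, sources)
        assert rec2.mirna_hits == ()
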