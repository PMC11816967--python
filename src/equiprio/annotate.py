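"""Per-variant annotation: the criteria vector behind prioritization.

Each (variant, gene) pair receives one :class:`AnnotationRecord` combining
the consequence call, constrained-element overlap, the GERP score at the
base, transcription-factor binding effects from a precomputed effect
table, cross-species regulatory overlap (via liftover), CpG-island
overlap, miRNA seed-site changes (3' UTR SNPs only), and proximity to
polyadenylation clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core import GenomicInterval, ScoreTrack, Thresholds, Variant
from .crosslift import ChainAlignment, RegulatoryBuild, lift_point, regulatory_overlap
from .genes import ConsequenceCall, GeneModel, classify_consequence
from .mirna import scan_sites, windows_for_variant

TF_EFFECTS = ("Gain of TFBS", "Loss of TFBS", "Score Change")


@dataclass(frozen=True)
class AnnotationRecord:
    rs_id: str
    gene_id: str
    consequence: ConsequenceCall
    constrained: bool
    gerp: Optional[float]
    gerp_high: bool
    tf_effect: frozenset[str]
    regulatory: Mapping[str, frozenset[str]]  # species -> feature classes
    cpg: bool
    mirna_hits: tuple[tuple[str, str], ...]
    polya: bool

    @property
    def human_reg(self) -> frozenset[str]:
        return self.regulatory.get("human", frozenset())

    @property
    def mouse_reg(self) -> frozenset[str]:
        return self.regulatory.get("mouse", frozenset())


def overlap_flag(v: Variant, ivs: Iterable[GenomicInterval]) -> bool:
    """True iff some interval contains the variant base (half-open)."""
    return any(iv.contains(v.chrom, v.pos) for iv in ivs)


def gerp_annotate(
    v: Variant, track: ScoreTrack, gerp_min: float = 2.0
) -> tuple[Optional[float], bool]:
    """(score or None, conserved-flag) at the variant base.

    Uncovered positions stay missing and never count as conserved; a
    missing score is not zero.
    """
    score = track.value_at(v.chrom, v.pos)
    return score, score is not None and score >= gerp_min


def polya_flag(
    v: Variant,
    clusters: Iterable[GenomicInterval],
    flank: int = 50,
    gene_strand: str = ".",
    symmetric: bool = True,
) -> bool:
    """True iff the variant falls within ``flank`` bp of a polyA cluster.

    Default is symmetric extension on both sides (the superset reading of
    "upstream or downstream"). With ``symmetric=False`` only the 5' side
    relative to ``gene_strand`` is extended.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    for c in clusters:
        if symmetric or gene_strand == ".":
            start, end = c.start - flank, c.end + flank
        elif gene_strand == "+":
            start, end = c.start - flank, c.end
        else:
            start, end = c.start, c.end + flank
        if v.chrom == c.chrom and max(0, start) <= v.pos < end:
            return True
    return False


def tfbs_annotate(v: Variant, table: Mapping[str, set[str]]) -> frozenset[str]:
    """Effect labels recorded for this rsID; empty when absent.

    ``table`` maps rs_id -> set of effect labels (duplicates already
    collapsed by construction of the mapping).
    """
    return frozenset(table.get(v.rs_id, set()))


@dataclass
class AnnotationSources:
    """Everything build_record needs besides the variant and gene."""

    genome: Mapping[str, str]
    constrained: Sequence[GenomicInterval] = field(default_factory=list)
    gerp_track: ScoreTrack = field(default_factory=ScoreTrack)
    tfbs: Mapping[str, set[str]] = field(default_factory=dict)
    # species -> (chains, regulatory build)
    species: Mapping[str, tuple[Sequence[ChainAlignment], RegulatoryBuild]] = field(
        default_factory=dict
    )
    cpg_islands: Sequence[GenomicInterval] = field(default_factory=list)
    polya_clusters: Sequence[GenomicInterval] = field(default_factory=list)
    mirna_seeds: Mapping[str, str] = field(default_factory=dict)


def build_record(
    v: Variant,
    gene: GeneModel,
    sources: AnnotationSources,
    thresholds: Optional[Thresholds] = None,
) -> AnnotationRecord:
    """Compose the full criteria vector for one variant/gene pair."""
    th = thresholds or Thresholds()
    try:
        consequence = classify_consequence(v, gene, sources.genome, th.flank_bp)
        constrained = overlap_flag(v, sources.constrained)
        gerp, gerp_high = gerp_annotate(v, sources.gerp_track, th.gerp_min)
        tf_effect = tfbs_annotate(v, sources.tfbs)
        regulatory = {}
        for species, (chains, build) in sources.species.items():
            lr = lift_point(chains, v.chrom, v.pos)
            regulatory[species] = frozenset(regulatory_overlap(lr, build))
        cpg = overlap_flag(v, sources.cpg_islands)
        polya = polya_flag(
            v, sources.polya_clusters, th.polya_flank_bp, gene.strand, th.polya_symmetric
        )
        mirna_hits: tuple[tuple[str, str], ...] = ()
        if "3_prime_UTR_variant" in consequence.terms and sources.mirna_seeds:
            ref_w, alt_w, center = windows_for_variant(
                v, sources.genome, gene.strand, th.mirna_window_bp
            )
            mirna_hits = tuple(scan_sites(ref_w, alt_w, center, sources.mirna_seeds))
    except Exception as exc:
        raise type(exc)(f"while annotating {v.rs_id} against {gene.gene_id}: {exc}") from exc
    return AnnotationRecord(
        rs_id=v.rs_id,
        gene_id=gene.gene_id,
        consequence=consequence,
        constrained=constrained,
        gerp=gerp,
        gerp_high=gerp_high,
        tf_effect=tf_effect,
        regulatory=regulatory,
        cpg=cpg,
        mirna_hits=mirna_hits,
        polya=polya,
    )
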