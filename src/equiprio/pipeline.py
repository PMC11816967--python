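"""End-to-end orchestration: load a data bundle, annotate, prioritize.

A *bundle* is a directory of plain-text files with fixed names:

    genome.fa             reference sequence (FASTA)
    genes.gff3            candidate gene models
    chip_manifest.tsv     chip markers (1-based positions)
    wgs_snps.tsv          WGS variants available for LD expansion
    ld_pairs.tsv          pairwise R^2 values
    constrained.bed       constrained elements
    gerp.bedgraph         per-base conservation scores
    tfbs.tsv              rsID -> TF-binding effect rows
    cpg_islands.bed       CpG islands
    polya_clusters.tsv    polyadenylation clusters (BED-like)
    mirna.fa              mature miRNA sequences
    qtl.tsv               cross-species QTLs
    orthologs.tsv         horse gene -> ortholog locations
    chain_<species>.chain + regulatory_<species>.gff3   one pair per proxy species
    config.yaml           (optional) threshold overrides

Every file may also be gzip-compressed (``.gz`` suffix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import io as eio
from .annotate import AnnotationRecord, AnnotationSources, build_record
from .core import GenomicInterval, ScoreTrack, Thresholds, Variant
from .crosslift import ChainAlignment, RegulatoryBuild
from .genes import GeneModel, genes_for_variant
from .mirna import Mirna, seeds_for
from .prioritize import (
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


@dataclass
class PipelineInputs:
    genome: Mapping[str, str]
    genes: Sequence[GeneModel]
    markers: Sequence[Variant]
    wgs_snps: Sequence[Variant]
    ld_pairs: Sequence[LDPair]
    constrained: Sequence[GenomicInterval] = field(default_factory=list)
    gerp_track: ScoreTrack = field(default_factory=ScoreTrack)
    tfbs: Mapping[str, set[str]] = field(default_factory=dict)
    species: Mapping[str, tuple[Sequence[ChainAlignment], RegulatoryBuild]] = field(
        default_factory=dict
    )
    cpg_islands: Sequence[GenomicInterval] = field(default_factory=list)
    polya_clusters: Sequence[GenomicInterval] = field(default_factory=list)
    mirnas: Sequence[Mirna] = field(default_factory=list)
    qtls: Sequence[QTLRecord] = field(default_factory=list)
    orthologs: Sequence[OrthologRow] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)


@dataclass
class PipelineResult:
    table: PrioritizedTable
    funnel: dict[str, int]
    marker_marker_pairs: list[LDPair]
    warnings: list[str]
    records: list[tuple[Variant, AnnotationRecord]]
    passing: list[tuple[Variant, AnnotationRecord]]
    prioritized_marker_ids: set[str]


def run_pipeline(inputs: PipelineInputs) -> PipelineResult:
    th = inputs.thresholds
    chrom_lengths = {c: len(s) for c, s in inputs.genome.items()}
    genes_by_id = {g.gene_id: g for g in inputs.genes}
    gene_symbols = {g.gene_id: g.symbol for g in inputs.genes}

    variants, mm_pairs, warnings = expand_by_ld(
        inputs.markers, inputs.wgs_snps, inputs.ld_pairs, th.r2_min
    )

    sources = AnnotationSources(
        genome=inputs.genome,
        constrained=inputs.constrained,
        gerp_track=inputs.gerp_track,
        tfbs=inputs.tfbs,
        species=inputs.species,
        cpg_islands=inputs.cpg_islands,
        polya_clusters=inputs.polya_clusters,
        mirna_seeds=seeds_for(list(inputs.mirnas)),
    )

    records: list[tuple[Variant, AnnotationRecord]] = []
    for v in variants:
        for gene_id in genes_for_variant(v, inputs.genes, th.flank_bp, chrom_lengths):
            records.append((v, build_record(v, genes_by_id[gene_id], sources, th)))

    passing = [(v, rec) for v, rec in records if passes_any(rec, th)]
    passing_variants = {v.rs_id: v for v, _ in passing}
    marker_ids, _ = propagate_to_markers(passing_variants.values())

    pass_gene_ids = {rec.gene_id for _, rec in passing}
    qtl_genes = qtl_gene_filter(
        pass_gene_ids, inputs.qtls, inputs.orthologs, th.flank_bp
    )

    marker_ids_by_rs: dict[str, list[str]] = {}
    for m in inputs.markers:
        if m.marker_id:
            marker_ids_by_rs.setdefault(m.rs_id, []).append(m.marker_id)

    table = build_final_table(passing, gene_symbols, qtl_genes, marker_ids_by_rs)

    # conservation checks: every final row passed and survived the gene filter
    final_rs = {r.rs_id for r in table.rows}
    assert final_rs <= set(passing_variants), "final table contains a non-passing rsID"
    summ = table.summary
    assert summ.n_direct + summ.n_ld == summ.n_snps

    funnel = {
        "chip_probes": len(inputs.markers),
        "chip_snps": len({m.rs_id for m in inputs.markers}),
        "after_ld_expansion": len(variants),
        "annotated_pairs": len(records),
        "passing_snps": len(passing_variants),
        "passing_genes": len(pass_gene_ids),
        "qtl_supported_genes": len(qtl_genes),
        "final_snps": summ.n_snps,
        "final_genes": summ.n_genes,
        "final_markers": summ.n_markers,
    }
    return PipelineResult(
        table=table,
        funnel=funnel,
        marker_marker_pairs=mm_pairs,
        warnings=warnings,
        records=records,
        passing=passing,
        prioritized_marker_ids=marker_ids,
    )


def _find(bundle: Path, name: str) -> Optional[Path]:
    for cand in (bundle / name, bundle / f"{name}.gz"):
        if cand.exists():
            return cand
    return None


def thresholds_from_yaml(text: str) -> Thresholds:
    data = yaml.safe_load(text) or {}
    return Thresholds(**data)


def load_bundle(bundle_dir: str | Path) -> PipelineInputs:
    """Read a bundle directory into pipeline inputs."""
    bundle = Path(bundle_dir)

    def req(name: str) -> Path:
        p = _find(bundle, name)
        if p is None:
            raise FileNotFoundError(f"bundle is missing {name}")
        return p

    species: dict[str, tuple[list[ChainAlignment], RegulatoryBuild]] = {}
    for chain_path in sorted(bundle.glob("chain_*.chain*")):
        sp = chain_path.name.split("chain_", 1)[1].split(".chain")[0]
        reg_path = _find(bundle, f"regulatory_{sp}.gff3")
        features = eio.load_regulatory_features(reg_path) if reg_path else []
        species[sp] = (eio.load_chain(chain_path), RegulatoryBuild(features))

    cfg = _find(bundle, "config.yaml")
    thresholds = thresholds_from_yaml(cfg.read_text()) if cfg else Thresholds()

    def opt(name: str, loader, default):
        p = _find(bundle, name)
        return loader(p) if p else default

    return PipelineInputs(
        genome=eio.load_genome(req("genome.fa")),
        genes=eio.load_gene_models(req("genes.gff3")),
        markers=eio.load_tables(req("chip_manifest.tsv"), "manifest"),
        wgs_snps=opt("wgs_snps.tsv", lambda p: eio.load_tables(p, "wgs"), []),
        ld_pairs=opt("ld_pairs.tsv", lambda p: eio.load_tables(p, "ld"), []),
        constrained=opt("constrained.bed", eio.load_intervals, []),
        gerp_track=opt("gerp.bedgraph", eio.load_score_track, ScoreTrack()),
        tfbs=opt("tfbs.tsv", lambda p: eio.load_tables(p, "tfbs"), {}),
        species=species,
        cpg_islands=opt("cpg_islands.bed", eio.load_intervals, []),
        polya_clusters=opt("polya_clusters.tsv", lambda p: eio.load_tables(p, "polya"), []),
        mirnas=opt("mirna.fa", lambda p: eio.load_tables(p, "mirna_fasta"), []),
        qtls=opt("qtl.tsv", lambda p: eio.load_tables(p, "qtl"), []),
        orthologs=opt("orthologs.tsv", lambda p: eio.load_tables(p, "ortholog"), []),
        thresholds=thresholds,
    )


def run_bundle(bundle_dir: str | Path) -> PipelineResult:
    return run_pipeline(load_bundle(bundle_dir))
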