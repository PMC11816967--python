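"""Self-consistent synthetic data bundles with ground-truth manifests.

The generator builds a toy genome with spaced-out candidate genes, plants
chip markers and WGS SNPs in them, and constructs every annotation input
(conservation track, constrained elements, liftover chains, regulatory
builds, TFBS table, CpG islands, polyA clusters, mature miRNAs, QTLs and
orthologs) so that chosen SNPs satisfy chosen criteria by construction.

The expected outcome of the full pipeline is computed through the
straight-line reference code in :mod:`equiprio._reference`, never through
the pipeline modules themselves, so recovery tests are a genuine oracle
comparison. Gene placement keeps flank-expanded spans disjoint (one gene
per SNP) and SNPs at least 50 bp apart, so planted signals cannot bleed
into neighbours.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from . import _reference as ref
from . import io as eio
from .core import (
    GenomicInterval,
    ScoreTrack,
    Thresholds,
    ValidationError,
    Variant,
    point,
    revcomp,
)
from .crosslift import ChainAlignment, RegulatoryBuild, RegulatoryFeature
from .genes import GeneModel, Transcript, terms_from_display
from .mirna import Mirna
from .pipeline import PipelineInputs
from .prioritize import LDPair, OrthologRow, PrioritizedTable, QTLRecord

GENE_SPAN = 2400
SLOT = 15000

_DEFAULT_PLANTED = {
    "severe": 2,
    "mirna": 2,
    "constrained": 3,
    "gerp": 3,
    "human_reg": 2,
    "mouse_reg": 2,
    "tfbs": 2,
    "polya": 2,
    "cpg": 2,
}


class ConfigError(ValidationError):
    pass


@dataclass
class SynthConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 60000
    n_genes: int = 12
    n_chip_markers: int = 24
    n_wgs_snps: int = 30
    planted: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_PLANTED))
    qtl_gene_fraction: float = 0.6
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        if self.chrom_length < 10_000:
            raise ConfigError("chromosome length must be >= 10 kb")
        if self.n_genes > self.n_chromosomes * (self.chrom_length // SLOT):
            raise ConfigError("too many genes for the genome size")
        if self.n_chip_markers < self.n_genes:
            raise ConfigError("need at least one chip marker per gene")
        if sum(self.planted.values()) > self.n_chip_markers + self.n_wgs_snps:
            raise ConfigError("more planted positives than SNPs")
        unknown = set(self.planted) - set(_DEFAULT_PLANTED)
        if unknown:
            raise ConfigError(f"unknown planted criteria: {sorted(unknown)}")


@dataclass
class SynthBundle:
    genome: dict[str, str]
    genes: list[GeneModel]
    markers: list[Variant]
    wgs_snps: list[Variant]
    ld_pairs: list[LDPair]
    constrained: list[GenomicInterval]
    gerp_track: ScoreTrack
    tfbs: dict[str, set[str]]
    chains: dict[str, list[ChainAlignment]]
    regulatory: dict[str, list[RegulatoryFeature]]
    cpg_islands: list[GenomicInterval]
    polya_clusters: list[GenomicInterval]
    mirnas: list[Mirna]
    qtls: list[QTLRecord]
    orthologs: list[OrthologRow]
    thresholds: Thresholds

    def to_inputs(self) -> PipelineInputs:
        species = {
            sp: (self.chains[sp], RegulatoryBuild(self.regulatory.get(sp, [])))
            for sp in sorted(self.chains)
        }
        return PipelineInputs(
            genome=self.genome,
            genes=self.genes,
            markers=self.markers,
            wgs_snps=self.wgs_snps,
            ld_pairs=self.ld_pairs,
            constrained=self.constrained,
            gerp_track=self.gerp_track,
            tfbs=self.tfbs,
            species=species,
            cpg_islands=self.cpg_islands,
            polya_clusters=self.polya_clusters,
            mirnas=self.mirnas,
            qtls=self.qtls,
            orthologs=self.orthologs,
            thresholds=self.thresholds,
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sizes = {c: len(s) for c, s in self.genome.items()}
        (out / "genome.fa").write_text(eio.write_genome(self.genome))
        (out / "genes.gff3").write_text(eio.write_gene_models(self.genes))
        (out / "chip_manifest.tsv").write_text(eio.write_table(self.markers, "manifest"))
        (out / "wgs_snps.tsv").write_text(eio.write_table(self.wgs_snps, "wgs"))
        (out / "ld_pairs.tsv").write_text(eio.write_table(self.ld_pairs, "ld"))
        (out / "constrained.bed").write_text(eio.write_intervals(self.constrained))
        (out / "gerp.bedgraph").write_text(eio.write_score_track(self.gerp_track))
        (out / "tfbs.tsv").write_text(eio.write_table(self.tfbs, "tfbs"))
        (out / "cpg_islands.bed").write_text(eio.write_intervals(self.cpg_islands))
        (out / "polya_clusters.tsv").write_text(eio.write_table(self.polya_clusters, "polya"))
        (out / "mirna.fa").write_text(eio.write_mirna_fasta(self.mirnas))
        (out / "qtl.tsv").write_text(eio.write_table(self.qtls, "qtl"))
        (out / "orthologs.tsv").write_text(eio.write_table(self.orthologs, "ortholog"))
        for sp in sorted(self.chains):
            (out / f"chain_{sp}.chain").write_text(eio.write_chain(self.chains[sp], sizes))
            (out / f"regulatory_{sp}.gff3").write_text(
                eio.write_regulatory_features(self.regulatory.get(sp, []))
            )


@dataclass
class TruthManifest:
    """Ground truth: intended flags, expected pass set, expected final rows."""

    flags: dict[str, dict]
    expected_pass: set[str]
    expected_rows: list[dict]

    def to_json(self) -> str:
        return json.dumps(
            {
                "flags": self.flags,
                "expected_pass": sorted(self.expected_pass),
                "expected_rows": self.expected_rows,
            },
            indent=1,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# gene construction

def _mirror(iv: tuple[int, int]) -> tuple[int, int]:
    a, b = iv
    return (GENE_SPAN - b, GENE_SPAN - a)


_TEMPLATE = {
    "exons": [(0, 300), (1000, 1300), (2000, 2400)],
    "cds": [(100, 300), (1000, 1300), (2000, 2100)],
    "utr5": [(0, 100)],
    "utr3": [(2100, 2400)],
}


def _build_gene(idx: int, chrom: str, origin: int, strand: str) -> GeneModel:
    feats = {}
    for key, ivs in _TEMPLATE.items():
        rel = ivs if strand == "+" else sorted(_mirror(iv) for iv in ivs)
        feats[key] = tuple(
            GenomicInterval(chrom, origin + a, origin + b, strand) for a, b in rel
        )
    gene_id = f"gene{idx:02d}"
    tx = Transcript(
        transcript_id=f"{gene_id}.t1",
        exons=feats["exons"],
        cds=feats["cds"],
        utr5=feats["utr5"],
        utr3=feats["utr3"],
    )
    return GeneModel(
        gene_id=gene_id,
        symbol=gene_id.upper(),
        span=GenomicInterval(chrom, origin, origin + GENE_SPAN, strand),
        transcripts=(tx,),
    )


def _cds_positions(gene: GeneModel) -> list[int]:
    """Genomic CDS positions in transcription order (single transcript)."""
    positions: list[int] = []
    for c in gene.transcripts[0].cds:
        positions.extend(range(c.start, c.end))
    positions.sort(reverse=(gene.strand == "-"))
    return positions


def _set_codon(seq: list[str], positions: list[int], codon: str, strand: str) -> None:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for p, base in zip(positions, codon):
        seq[p] = base if strand == "+" else comp[base]


@dataclass
class _Slots:
    intron: list[int]
    cds: list[int]  # transcription-order CDS indices of codon starts
    utr3: list[int]


def _gene_slots(gene: GeneModel) -> _Slots:
    tx = gene.transcripts[0]
    exons = tx.exons
    intron_slots = []
    for a, b in zip(exons, exons[1:]):
        s, e = a.end, b.start
        intron_slots.extend(range(s + 50, e - 150 + 1, 100))
    utr = tx.utr3[0]
    return _Slots(
        intron=intron_slots,
        cds=[300, 309],  # codon starts inside the middle CDS segment
        utr3=[utr.start + 50, utr.start + 100],
    )


# ---------------------------------------------------------------------------
# generation

def generate(cfg: SynthConfig) -> tuple[SynthBundle, TruthManifest]:
    rng = random.Random(cfg.seed)
    th = cfg.thresholds

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    seq: dict[str, list[str]] = {
        c: [rng.choice("ACGT") for _ in range(cfg.chrom_length)] for c in chroms
    }

    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        chrom = chroms[i % cfg.n_chromosomes]
        slot_index = i // cfg.n_chromosomes
        origin = slot_index * SLOT + 6000
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _build_gene(i, chrom, origin, strand)
        genes.append(gene)
        cds_pos = _cds_positions(gene)
        _set_codon(seq[chrom], cds_pos[:3], "ATG", strand)
        _set_codon(seq[chrom], cds_pos[-3:], "TAA", strand)

    slots = {g.gene_id: _gene_slots(g) for g in genes}
    genes_by_id = {g.gene_id: g for g in genes}

    # --- roles ------------------------------------------------------------
    n_linked = sum(1 for i in range(cfg.n_wgs_snps) if i % 10 < 7)
    effective = [("chip", i) for i in range(cfg.n_chip_markers)] + [
        ("wgs", i) for i in range(cfg.n_wgs_snps) if i % 10 < 7
    ]
    roles_list = [r for r, n in sorted(cfg.planted.items()) for _ in range(n)]
    if len(roles_list) > len(effective):
        raise ConfigError("not enough prioritizable SNPs for the planted counts")
    rng.shuffle(effective)
    role_of: dict[tuple[str, int], str] = {
        key: role for key, role in zip(effective, roles_list)
    }

    # --- placement --------------------------------------------------------
    @dataclass
    class Placement:
        kind: str
        index: int
        role: Optional[str]
        gene: GeneModel
        pos: int
        alt_override: Optional[str] = None

    placements: list[Placement] = []
    counter = 0
    for kind, n in (("chip", cfg.n_chip_markers), ("wgs", cfg.n_wgs_snps)):
        for i in range(n):
            role = role_of.get((kind, i))
            gene = genes[counter % cfg.n_genes]
            s = slots[gene.gene_id]
            counter += 1
            try:
                if role == "severe":
                    cds_idx = s.cds.pop(0)
                    cds_pos = _cds_positions(gene)
                    codon_pos = cds_pos[cds_idx : cds_idx + 3]
                    _set_codon(seq[gene.span.chrom], codon_pos, "GAA", gene.strand)
                    # GAA -> CAA is Glu -> Gln, guaranteed missense
                    alt = "C" if gene.strand == "+" else "G"
                    placements.append(
                        Placement(kind, i, role, gene, codon_pos[0], alt_override=alt)
                    )
                    continue
                if role == "mirna":
                    pos = s.utr3.pop(0)
                else:
                    pos = s.intron.pop(0)
            except IndexError as exc:
                raise ConfigError(
                    f"infeasible planting: gene {gene.gene_id} ran out of "
                    f"{role or 'intron'} slots"
                ) from exc
            placements.append(Placement(kind, i, role, gene, pos))

    # --- variants ---------------------------------------------------------
    markers: list[Variant] = []
    wgs_snps: list[Variant] = []
    by_key: dict[tuple[str, int], Placement] = {}
    for p in placements:
        by_key[(p.kind, p.index)] = p
        chrom = p.gene.span.chrom
        ref_base = seq[chrom][p.pos]
        alt = p.alt_override or rng.choice([b for b in "ACGT" if b != ref_base])
        if p.kind == "chip":
            rs = f"rs1{p.index:05d}"
            markers.append(
                Variant(rs, point(chrom, p.pos), ref_base, alt, marker_id=f"SYN_{p.index:04d}")
            )
        else:
            rs = f"rs2{p.index:05d}"
            wgs_snps.append(Variant(rs, point(chrom, p.pos), ref_base, alt))
    # a second probe for the first chip SNP (multi-probe markers exist on chips)
    markers.append(replace(markers[0], marker_id="SYN_DUP_0000"))

    # --- LD pairs ---------------------------------------------------------
    marker_for_gene: dict[str, Variant] = {}
    for m, p in zip(markers[:-1], placements):
        marker_for_gene.setdefault(p.gene.gene_id, m)
    ld_pairs: list[LDPair] = []
    for v, p in zip(wgs_snps, (q for q in placements if q.kind == "wgs")):
        anchor = marker_for_gene[p.gene.gene_id]
        if p.index % 10 < 7:
            r2 = round(rng.uniform(0.955, 0.999), 3)
        elif p.index % 10 == 7:
            r2 = th.r2_min  # exactly at the cutoff: excluded by strictness
        else:
            r2 = round(rng.uniform(0.5, 0.9), 3)
        ld_pairs.append(LDPair(v.rs_id, anchor.marker_id, r2))
    # give one linked WGS SNP a second anchor when possible
    linked = [pr for pr in ld_pairs if pr.r2 > th.r2_min]
    if linked and len(markers) > 1:
        first = linked[0]
        other = next(
            (m for m in markers if m.marker_id and m.marker_id != first.snp_b), None
        )
        if other is not None:
            ld_pairs.append(LDPair(first.snp_a, other.marker_id, 0.97))
    # marker-marker pair (side report) and a dangling id (warning path)
    if len(markers) >= 3:
        ld_pairs.append(LDPair(markers[1].marker_id, markers[2].marker_id, 1.0))
    ld_pairs.append(LDPair("rs9unknown", markers[0].marker_id, 0.99))

    # --- criterion inputs --------------------------------------------------
    genome = {c: "".join(s) for c, s in seq.items()}
    planted_by_role: dict[str, list[tuple[Variant, Placement]]] = {}
    all_variants = markers[:-1] + wgs_snps  # unique placements
    for v, p in zip(all_variants, placements):
        if p.role:
            planted_by_role.setdefault(p.role, []).append((v, p))

    constrained = [
        point(v.chrom, v.pos).expand(10)
        for v, _ in planted_by_role.get("constrained", [])
    ]
    cpg_islands = [
        point(v.chrom, v.pos).expand(15) for v, _ in planted_by_role.get("cpg", [])
    ]
    polya_clusters = [
        GenomicInterval(v.chrom, v.pos + 20, v.pos + 30)
        for v, _ in planted_by_role.get("polya", [])
    ]

    gerp_entries: dict[tuple[str, int], float] = {}
    for v, _ in planted_by_role.get("gerp", []):
        gerp_entries[(v.chrom, v.pos)] = round(rng.uniform(th.gerp_min, th.gerp_min + 4), 2)
    for i, v in enumerate(all_variants):
        key = (v.chrom, v.pos)
        if key not in gerp_entries and i % 2 == 0:
            gerp_entries[key] = round(rng.uniform(-3.0, th.gerp_min - 0.1), 2)
    gerp_track = ScoreTrack(
        [(point(c, p), s) for (c, p), s in sorted(gerp_entries.items())]
    )

    tfbs: dict[str, set[str]] = {}
    labels = ["Gain of TFBS", "Loss of TFBS", "Score Change"]
    for v, _ in planted_by_role.get("tfbs", []):
        tfbs[v.rs_id] = set(rng.sample(labels, rng.choice([1, 2])))

    # --- chains and regulatory builds --------------------------------------
    chains: dict[str, list[ChainAlignment]] = {}
    regulatory: dict[str, list[RegulatoryFeature]] = {}
    chain_id = 1
    for si, sp in enumerate(("human", "mouse")):
        sp_chains = []
        for ci, chrom in enumerate(chroms):
            blocks = []
            remaining = cfg.chrom_length
            gap_total = 0
            while remaining > 0:
                size = min(remaining, rng.randrange(5000, 9001))
                remaining -= size
                gap_t = rng.randrange(0, 501) if remaining > 0 else 0
                gap_total += gap_t
                blocks.append((size, 0, gap_t))
            target_span = cfg.chrom_length + gap_total
            strand = "-" if ci == 1 else "+"
            sp_chains.append(
                ChainAlignment(
                    chain_id=chain_id,
                    score=1000 + chain_id,
                    source=GenomicInterval(chrom, 0, cfg.chrom_length),
                    target_chrom=f"{sp}_{chrom}",
                    target_size=target_span + 1000,
                    target_start=0,
                    target_end=target_span,
                    target_strand=strand,
                    blocks=tuple(blocks),
                )
            )
            chain_id += 1
        chains[sp] = sp_chains
        feats = []
        role = "human_reg" if sp == "human" else "mouse_reg"
        for v, _ in planted_by_role.get(role, []):
            lifted = ref.lift(sp_chains, v.chrom, v.pos)
            assert lifted is not None  # source gaps are never used above
            t_chrom, t_pos, _strand = lifted
            cls = rng.choice(["enhancer", "promoter", "open_chromatin"])
            feats.append(
                RegulatoryFeature(GenomicInterval(t_chrom, t_pos - 3, t_pos + 4), cls)
            )
        regulatory[sp] = feats

    # --- miRNAs -------------------------------------------------------------
    mirnas: list[Mirna] = []
    for k, (v, p) in enumerate(planted_by_role.get("mirna", [])):
        chrom_seq = genome[v.chrom]
        lo, hi = v.pos - 5, v.pos + 6
        ref_win = chrom_seq[lo:hi]
        center = 5
        alt_win = ref_win[:center] + v.alt + ref_win[center + 1 :]
        if p.gene.strand == "-":
            ref_win, alt_win = revcomp(ref_win), revcomp(alt_win)
            center = len(ref_win) - 1 - center
        # pick a site overlapping the SNP from the ref window (disrupted)
        # or from the alt window (created), alternating
        source_win, other_win = (ref_win, alt_win) if k % 2 == 0 else (alt_win, ref_win)
        site = None
        for start in range(center, center - 6, -1):
            if start < 0 or start + 6 > len(source_win):
                continue
            cand = source_win[start : start + 6]
            collide = any(
                other_win[s : s + 6] == cand
                for s in range(max(0, center - 5), min(center, len(other_win) - 6) + 1)
            )
            if not collide:
                site = cand
                break
        if site is None:  # pragma: no cover - needs pathological repeats
            raise ConfigError(f"could not engineer a seed site at {v.rs_id}")
        mature = "U" + revcomp(site).replace("T", "U") + "".join(
            rng.choice("ACGU") for _ in range(14)
        )
        mirnas.append(Mirna(f"syn-mir-{k + 1}", mature))
    # decoys that should match nothing in particular
    for k in range(2):
        mirnas.append(
            Mirna(f"syn-decoy-{k + 1}", "".join(rng.choice("ACGU") for _ in range(21)))
        )

    # --- QTLs and orthologs --------------------------------------------------
    n_supported = round(cfg.qtl_gene_fraction * cfg.n_genes)
    supported = set(rng.sample([g.gene_id for g in genes], n_supported))
    qtls: list[QTLRecord] = []
    orthologs: list[OrthologRow] = []
    for j, g in enumerate(genes):
        t_chrom = f"bta{j + 1}"
        t0 = 10_000
        if g.gene_id in supported:
            orthologs.append(
                OrthologRow(g.gene_id, "cattle", f"ENSBTAG{j:05d}",
                            GenomicInterval(t_chrom, t0, t0 + 2000))
            )
            # QTL 500 bp past the ortholog: only reachable through the flank
            qtls.append(
                QTLRecord("cattle", "meat tenderness", "Meat and Carcass",
                          GenomicInterval(t_chrom, t0 + 2500, t0 + 3500))
            )
        elif j % 2 == 0:
            orthologs.append(
                OrthologRow(g.gene_id, "cattle", f"ENSBTAG{j:05d}",
                            GenomicInterval(t_chrom, t0, t0 + 2000))
            )
            qtls.append(
                QTLRecord("cattle", "distant trait", "Meat and Carcass",
                          GenomicInterval(t_chrom, t0 + 20_000, t0 + 21_000))
            )
            qtls.append(
                QTLRecord("cattle", "coat colour", "Exterior",
                          GenomicInterval(t_chrom, t0 + 1000, t0 + 1500))
            )
        # remaining unsupported genes simply have no ortholog rows

    bundle = SynthBundle(
        genome=genome,
        genes=genes,
        markers=markers,
        wgs_snps=wgs_snps,
        ld_pairs=ld_pairs,
        constrained=constrained,
        gerp_track=gerp_track,
        tfbs=tfbs,
        chains=chains,
        regulatory=regulatory,
        cpg_islands=cpg_islands,
        polya_clusters=polya_clusters,
        mirnas=mirnas,
        qtls=qtls,
        orthologs=orthologs,
        thresholds=th,
    )
    manifest = compute_truth(bundle)
    return bundle, manifest


# ---------------------------------------------------------------------------
# ground truth through the reference path

def compute_truth(bundle: SynthBundle) -> TruthManifest:
    th = bundle.thresholds
    chip_ids: dict[str, str] = {}
    marker_ids_by_rs: dict[str, set[str]] = {}
    for m in bundle.markers:
        if m.marker_id:
            chip_ids[m.marker_id] = m.marker_id
            marker_ids_by_rs.setdefault(m.rs_id, set()).add(m.marker_id)
        chip_ids.setdefault(m.rs_id, m.marker_id or m.rs_id)
    wgs_by_rs = {v.rs_id: v for v in bundle.wgs_snps}

    anchors = ref.ld_partners(
        bundle.ld_pairs, chip_ids, set(wgs_by_rs), th.r2_min
    )

    included: dict[str, tuple[Variant, str, tuple[str, ...]]] = {}
    for m in bundle.markers:
        if m.rs_id not in included:
            included[m.rs_id] = (m, "Marker", ())
    for rs, anchor_ids in anchors.items():
        if rs not in included:
            included[rs] = (wgs_by_rs[rs], "LD", tuple(sorted(anchor_ids)))

    mirna_seqs = {m.mirna_id: m.sequence for m in bundle.mirnas}
    gerp_entries = list(bundle.gerp_track.items())

    flags: dict[str, dict] = {}
    expected_pass: set[str] = set()
    rows: list[dict] = []
    for rs, (v, vtype, anchor_ids) in sorted(included.items()):
        for g in bundle.genes:
            lo = max(0, g.span.start - th.flank_bp)
            hi = g.span.end + th.flank_bp
            if not (g.span.chrom == v.chrom and lo <= v.pos < hi):
                continue
            terms = ref.consequence_terms(v, g, bundle.genome)
            severe = bool(terms & ref.SEVERE)
            constrained = ref.contains_any(bundle.constrained, v.chrom, v.pos)
            gerp = ref.score_at(gerp_entries, v.chrom, v.pos)
            gerp_high = gerp is not None and gerp >= th.gerp_min
            tf = sorted(bundle.tfbs.get(rs, set()))
            human = sorted(
                ref.regulatory_classes(
                    bundle.chains.get("human", []), bundle.regulatory.get("human", []),
                    v.chrom, v.pos,
                )
            )
            mouse = sorted(
                ref.regulatory_classes(
                    bundle.chains.get("mouse", []), bundle.regulatory.get("mouse", []),
                    v.chrom, v.pos,
                )
            )
            cpg = ref.contains_any(bundle.cpg_islands, v.chrom, v.pos)
            polya = ref.polya_near(
                bundle.polya_clusters, v.chrom, v.pos, th.polya_flank_bp
            )
            mirna_hits = (
                ref.seed_effects(bundle.genome, v, g.strand, mirna_seqs, th.mirna_window_bp)
                if "3_prime_UTR_variant" in terms
                else []
            )
            passes = any(
                [
                    th.severe_is_criterion and severe,
                    constrained,
                    gerp_high,
                    bool(human),
                    bool(mouse),
                    bool(tf),
                    bool(mirna_hits),
                    polya,
                    th.cpg_is_criterion and cpg,
                ]
            )
            flags[rs] = {
                "gene": g.gene_id,
                "terms": sorted(terms),
                "severe": severe,
                "constrained": constrained,
                "gerp": gerp,
                "gerp_high": gerp_high,
                "tfbs": tf,
                "human_reg": human,
                "mouse_reg": mouse,
                "cpg": cpg,
                "polya": polya,
                "mirna": [list(h) for h in mirna_hits],
                "passes": passes,
            }
            if passes:
                expected_pass.add(rs)
                rows.append(
                    {
                        "gene_symbol": g.symbol,
                        "gene_id": g.gene_id,
                        "type": vtype,
                        "rs_id": rs,
                        "marker_ids": sorted(marker_ids_by_rs.get(rs, set()))
                        if vtype == "Marker"
                        else [],
                        "anchors": list(anchor_ids),
                        "terms": sorted(terms),
                        "constrained": constrained,
                        "gerp": gerp,
                        "tf": tf,
                        "human_reg": human,
                        "mouse_reg": mouse,
                        "mirna": sorted(h[0] for h in mirna_hits),
                    }
                )

    supported = ref.qtl_supported_genes(
        sorted({r["gene_id"] for r in rows}),
        bundle.qtls,
        bundle.orthologs,
        th.flank_bp,
        ["Meat and Carcass"],
    )
    final_rows = [
        {k: v for k, v in r.items() if k != "gene_id"}
        for r in rows
        if r["gene_id"] in supported
    ]
    final_rows.sort(key=lambda r: (r["gene_symbol"], r["rs_id"]))
    return TruthManifest(flags=flags, expected_pass=expected_pass, expected_rows=final_rows)


def canonical_rows(table: PrioritizedTable) -> list[dict]:
    """Project a pipeline table onto the manifest's row schema."""
    out = []
    for r in table.rows:
        out.append(
            {
                "gene_symbol": r.gene_symbol,
                "type": r.type,
                "rs_id": r.rs_id,
                "marker_ids": sorted(r.marker_ids),
                "anchors": sorted(r.anchor_ids),
                "terms": sorted(terms_from_display(r.consequence)),
                "constrained": r.constrained,
                "gerp": r.gerp,
                "tf": sorted(r.tf_effect),
                "human_reg": sorted(r.human_reg),
                "mouse_reg": sorted(r.mouse_reg),
                "mirna": sorted(r.mirna),
            }
        )
    return out
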