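"""A synthetic input bundle that reproduces the packaged final report.

This builds a small artificial genome with one gene per reported symbol
and plants every input signal (conservation scores, constrained elements,
TFBS effect rows, liftover chains with regulatory features, miRNA seeds,
LD pairs and QTL-supported orthologs) so that running the full pipeline
reproduces each row of the packaged prioritized-variant table: the same
consequence terms, flags and scores per rsID.

It is an end-to-end smoke fixture. The coordinates are invented; nothing
here claims to reproduce the real genomic context of the reported SNPs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .core import GenomicInterval, ScoreTrack, Thresholds, Variant, point, revcomp
from .crosslift import ChainAlignment, RegulatoryFeature
from .genes import GeneModel, Transcript
from .mirna import Mirna
from .prioritize import LDPair, OrthologRow, QTLRecord
from .synth import GENE_SPAN, SLOT, SynthBundle, _TEMPLATE, _mirror

_SEED = 14_00533  # fixed: the bundle is a deterministic artifact, not a simulation

# Worked-example marker-marker LD table: chip markers inside key muscle
# genes form one near-perfect pair (MYH2) and four perfect-LD groups
# (NEB, MSTN, the PRUNE2 trio, MSN). Used by the demonstration checks.
REPORTED_LD_PAIRS: list[LDPair] = [
    LDPair("rs68820687", "rs68820688", 0.955),  # MYH2
    LDPair("rs69127149", "rs69127154", 1.0),    # NEB
    LDPair("rs69126368", "rs69126372", 1.0),    # MSTN
    LDPair("rs69434178", "rs69434180", 1.0),    # PRUNE2
    LDPair("rs69434178", "rs69434182", 1.0),
    LDPair("rs69434180", "rs69434182", 1.0),
    LDPair("rs69607214", "rs69607215", 1.0),    # MSN
]


@dataclass
class _Snp:
    rs: str
    rel: int  # position relative to the gene origin
    marker: Optional[str] = None  # own chip marker id (Marker rows)
    anchors: tuple[str, ...] = ()  # LD anchor marker ids (LD rows)
    gerp: Optional[float] = None
    constrained: bool = False
    tf: tuple[str, ...] = ()
    human: bool = False
    mouse: bool = False
    mirna: tuple[str, ...] = ()  # miRNA ids to engineer as seed hits
    codon: Optional[str] = None  # patch this codon at rel (CDS rows)
    alt: Optional[str] = None


@dataclass
class _Gene:
    symbol: str
    strand: str = "+"
    shape: str = "standard"  # standard | got1 | sdhb | raver2
    snps: list[_Snp] = field(default_factory=list)
    extra_markers: list[tuple[str, int]] = field(default_factory=list)  # anchors to park


def _std_transcripts(tid: str, chrom: str, origin: int, strand: str) -> list[Transcript]:
    feats = {}
    for key, ivs in _TEMPLATE.items():
        rel = ivs if strand == "+" else sorted(_mirror(iv) for iv in ivs)
        feats[key] = tuple(
            GenomicInterval(chrom, origin + a, origin + b, strand) for a, b in rel
        )
    return [
        Transcript(tid, exons=feats["exons"], cds=feats["cds"],
                   utr5=feats["utr5"], utr3=feats["utr3"])
    ]


def _ivs(chrom, origin, strand, pairs):
    return tuple(GenomicInterval(chrom, origin + a, origin + b, strand) for a, b in pairs)


def _shape_transcripts(g: _Gene, chrom: str, origin: int) -> tuple[list[Transcript], int]:
    """Transcripts plus the gene span length for each shape."""
    s = g.strand
    if g.shape == "standard":
        return _std_transcripts(f"{g.symbol}.t1", chrom, origin, s), GENE_SPAN
    if g.shape == "got1":
        # one SNP at rel 250 reads upstream / 5' UTR / intronic across transcripts
        t_up = Transcript(
            f"{g.symbol}.t1",
            exons=_ivs(chrom, origin, s, [(300, 600), (1000, 1300)]),
            cds=_ivs(chrom, origin, s, [(360, 600), (1000, 1120)]),
            utr5=_ivs(chrom, origin, s, [(300, 360)]),
            utr3=_ivs(chrom, origin, s, [(1120, 1300)]),
        )
        t_utr = Transcript(
            f"{g.symbol}.t2",
            exons=_ivs(chrom, origin, s, [(200, 500), (1000, 1300)]),
            cds=_ivs(chrom, origin, s, [(380, 500), (1000, 1120)]),
            utr5=_ivs(chrom, origin, s, [(200, 380)]),
            utr3=_ivs(chrom, origin, s, [(1120, 1300)]),
        )
        t_int = Transcript(
            f"{g.symbol}.t3",
            exons=_ivs(chrom, origin, s, [(0, 100), (400, 700), (1000, 1300)]),
            cds=_ivs(chrom, origin, s, [(40, 100), (400, 700), (1000, 1120)]),
            utr5=_ivs(chrom, origin, s, [(0, 40)]),
            utr3=_ivs(chrom, origin, s, [(1120, 1300)]),
        )
        return [t_up, t_utr, t_int], 1300
    if g.shape == "sdhb":
        t_up = Transcript(
            f"{g.symbol}.t1",
            exons=_ivs(chrom, origin, s, [(300, 600), (1000, 1300)]),
            cds=_ivs(chrom, origin, s, [(360, 600), (1000, 1120)]),
            utr5=_ivs(chrom, origin, s, [(300, 360)]),
            utr3=_ivs(chrom, origin, s, [(1120, 1300)]),
        )
        t_int = Transcript(
            f"{g.symbol}.t2",
            exons=_ivs(chrom, origin, s, [(0, 100), (400, 700), (1000, 1300)]),
            cds=_ivs(chrom, origin, s, [(40, 100), (400, 700), (1000, 1120)]),
            utr5=_ivs(chrom, origin, s, [(0, 40)]),
            utr3=_ivs(chrom, origin, s, [(1120, 1300)]),
        )
        return [t_up, t_int], 1300
    if g.shape == "raver2":
        # t1: SNP at rel 2060 is coding (engineered synonymous);
        # t2: the same base sits in a long 3' UTR
        t1 = _std_transcripts(f"{g.symbol}.t1", chrom, origin, s)[0]
        t2 = Transcript(
            f"{g.symbol}.t2",
            exons=_ivs(chrom, origin, s, [(0, 300), (1000, 1300), (2000, 2400)]),
            cds=_ivs(chrom, origin, s, [(100, 300), (1000, 1148)]),
            utr5=_ivs(chrom, origin, s, [(0, 100)]),
            utr3=_ivs(chrom, origin, s, [(1148, 1300), (2000, 2400)]),
        )
        return [t1, t2], GENE_SPAN
    raise ValueError(g.shape)


_GAIN, _LOSS, _SCORE = "Gain of TFBS", "Loss of TFBS", "Score Change"

_GENES: list[_Gene] = [
    _Gene("ACYP2", snps=[
        _Snp("rs397216526", 500, anchors=("BIEC2_307086",), gerp=-0.446, human=True),
        _Snp("rs69086544", 600, anchors=("BIEC2_307086",), gerp=-0.446, human=True),
    ], extra_markers=[("BIEC2_307086", 820)]),
    _Gene("AHNAK", snps=[
        _Snp("rs69004899", 1100, marker="12-26376598-G-A", codon="GAA", alt="C"),
    ]),
    _Gene("ALB", snps=[
        _Snp("rs68643854", 500, marker="BIEC2_825788", gerp=-0.108, constrained=True),
        _Snp("rs68643900", -300, anchors=("BIEC2_785750",), gerp=-3.12, tf=(_GAIN,)),
    ], extra_markers=[("BIEC2_785750", 820)]),
    _Gene("ALDOA", snps=[
        _Snp("rs69014980", 500, marker="BIEC2_215098", gerp=-0.27, constrained=True),
        _Snp("rs782859809", 620, marker="13-20698094-G-C", gerp=3.87, tf=(_LOSS,)),
    ]),
    _Gene("ASNS", snps=[
        _Snp("rs69611459", 2200, marker="BIEC2-860417", mirna=("miR-329b",)),
    ]),
    _Gene("CS", strand="-", snps=[
        _Snp("rs1143598220", 1500, anchors=("BIEC2_1184909",), mouse=True),
    ], extra_markers=[("BIEC2_1184909", 1600)]),
    _Gene("GOT1", shape="got1", snps=[
        _Snp("rs68640585", 250, marker="BIEC2_13411", gerp=-1.05, mouse=True),
    ]),
    _Gene("MACROD1", snps=[
        _Snp("rs68893372", 420, marker="BIEC2_195029", gerp=-5.12, human=True, mouse=True),
        _Snp("rs68893379", 520, marker="BIEC2_195036", mouse=True),
        _Snp("rs69007205", 620, marker="BIEC2_195018", gerp=-0.807, constrained=True, mouse=True),
    ]),
    _Gene("MTHFD1", snps=[
        _Snp("rs69302674", 500, marker="BIEC2_632816", gerp=-0.303, constrained=True),
        _Snp("rs782854427", 1100, anchors=("BIEC2_632813",), gerp=-1.43,
             constrained=True, codon="GAA", alt="C"),
    ], extra_markers=[("BIEC2_632813", 820)]),
    _Gene("MYL11", snps=[
        _Snp("rs69065907", -300, marker="BIEC2_214942", gerp=-1.72,
             tf=(_LOSS, _SCORE, _GAIN)),
    ]),
    _Gene("MYOM1", snps=[
        _Snp("rs1142180487", 420, anchors=("BIEC2_1047070",), gerp=0.206, constrained=True),
        _Snp("rs1150182996", 500, anchors=("BIEC2_1047100",), gerp=2.04, human=True),
        _Snp("rs396225196", 580, anchors=("BIEC2_1047096",), gerp=0.623, human=True),
        _Snp("rs68759950", 660, marker="BIEC2_1047096", gerp=-0.836, mouse=True),
    ], extra_markers=[("BIEC2_1047070", 820), ("BIEC2_1047100", 900)]),
    _Gene("PDLIM5", snps=[
        _Snp("rs68623490", 500, marker="BIEC2_818877", gerp=4.91, constrained=True),
    ]),
    _Gene("PHGDH", snps=[
        _Snp("rs394992807", 500, anchors=("BIEC2_908679",), mouse=True),
        _Snp("rs395235076", 600, anchors=("BIEC2_908679",), mouse=True),
    ], extra_markers=[("BIEC2_908679", 820)]),
    _Gene("PLIN1", snps=[
        _Snp("rs397479732", 1100, marker="CUHSNP00113433", gerp=-0.63, mouse=True,
             codon="GAA", alt="C"),
    ]),
    _Gene("PYGM", strand="-", snps=[
        _Snp("rs68895977", 2700, marker="BIEC2_195234", gerp=0.644, tf=(_GAIN,)),
    ]),
    _Gene("RAVER2", shape="raver2", snps=[
        _Snp("rs69522601", 2060, marker="BIEC2_978964", gerp=-4.36, constrained=True,
             codon="CTG", alt="A",
             mirna=("miR-217", "miR-509a-5p", "miR-8924", "miR-1388", "miR-9065", "miR-9124")),
    ]),
    _Gene("RYR3", snps=[
        _Snp("rs1142172760", 500, anchors=("BIEC2_65875",), gerp=-8.78, mouse=True),
        _Snp("rs1148992878", 560, anchors=("BIEC2_65875",), mouse=True),
        _Snp("rs68480423", 990, marker="BIEC2_66277", gerp=-5.06),
    ], extra_markers=[("BIEC2_65875", 820)]),
    _Gene("SDHB", shape="sdhb", snps=[
        _Snp("rs68545902", 250, anchors=("BIEC2_471516",), gerp=-1.79, tf=(_SCORE,)),
    ], extra_markers=[("BIEC2_471516", 320)]),
    _Gene("TNNT3", snps=[
        _Snp("rs68882259", 2700, marker="BIEC2_200114", human=True),
    ]),
]


def demo_bundle() -> SynthBundle:
    """Build the demonstration bundle (deterministic; no configuration)."""
    rng = random.Random(_SEED)
    chrom = "chr1"
    length = len(_GENES) * SLOT + 10_000
    seq = [rng.choice("ACGT") for _ in range(length)]

    genes: list[GeneModel] = []
    origins: dict[str, int] = {}
    for j, g in enumerate(_GENES):
        origin = j * SLOT + 6000
        origins[g.symbol] = origin
        transcripts, span_len = _shape_transcripts(g, chrom, origin)
        genes.append(
            GeneModel(
                gene_id=g.symbol,
                symbol=g.symbol,
                span=GenomicInterval(chrom, origin, origin + span_len, g.strand),
                transcripts=tuple(transcripts),
            )
        )

    # codon patches before any ref allele is read
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for g in _GENES:
        for snp in g.snps:
            if snp.codon:
                p0 = origins[g.symbol] + snp.rel
                # GAA patches put the SNP at the first codon base (G->C is
                # Glu->Gln, missense); the CTG patch puts it at the wobble
                # base (G->A is Leu->Leu, synonymous)
                start = p0 if snp.codon == "GAA" else p0 - 2
                for k, base in enumerate(snp.codon):
                    b = base if g.strand == "+" else comp[base]
                    seq[start + k] = b

    genome = {chrom: "".join(seq)}

    markers: list[Variant] = []
    wgs: list[Variant] = []
    ld_pairs: list[LDPair] = []
    constrained: list[GenomicInterval] = []
    gerp_entries: list[tuple[GenomicInterval, float]] = []
    tfbs: dict[str, set[str]] = {}
    human_sites: list[int] = []
    mouse_sites: list[int] = []
    mirnas: list[Mirna] = []

    for g in _GENES:
        origin = origins[g.symbol]
        for snp in g.snps:
            pos = origin + snp.rel
            ref = genome[chrom][pos]
            alt = snp.alt or rng.choice([b for b in "ACGT" if b != ref])
            if snp.marker:
                markers.append(Variant(snp.rs, point(chrom, pos), ref, alt, marker_id=snp.marker))
            else:
                wgs.append(Variant(snp.rs, point(chrom, pos), ref, alt))
                for anchor in snp.anchors:
                    ld_pairs.append(LDPair(snp.rs, anchor, 0.96))
            if snp.constrained:
                constrained.append(point(chrom, pos).expand(10))
            if snp.gerp is not None:
                gerp_entries.append((point(chrom, pos), snp.gerp))
            if snp.tf:
                tfbs[snp.rs] = set(snp.tf)
            if snp.human:
                human_sites.append(pos)
            if snp.mouse:
                mouse_sites.append(pos)
            if snp.mirna:
                mirnas.extend(_engineer_mirnas(genome[chrom], pos, alt, g.strand, snp.mirna, rng))
        for marker_id, rel in g.extra_markers:
            pos = origin + rel
            ref = genome[chrom][pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            markers.append(
                Variant(f"rs9{len(markers):05d}", point(chrom, pos), ref, alt, marker_id=marker_id)
            )

    # one ungapped chain per proxy species, offset into a renamed assembly
    chains: dict[str, list[ChainAlignment]] = {}
    regulatory: dict[str, list[RegulatoryFeature]] = {}
    for cid, (sp, offset, sites) in enumerate(
        (("human", 1000, human_sites), ("mouse", 2000, mouse_sites)), start=1
    ):
        chains[sp] = [
            ChainAlignment(
                chain_id=cid,
                score=1000.0,
                source=GenomicInterval(chrom, 0, length),
                target_chrom=f"{sp}_chr1",
                target_size=length + offset + 1000,
                target_start=offset,
                target_end=offset + length,
                target_strand="+",
                blocks=((length, 0, 0),),
            )
        ]
        regulatory[sp] = [
            RegulatoryFeature(GenomicInterval(f"{sp}_chr1", p + offset - 3, p + offset + 4),
                              "enhancer")
            for p in sorted(sites)
        ]

    qtls: list[QTLRecord] = []
    orthologs: list[OrthologRow] = []
    for j, g in enumerate(_GENES):
        t_chrom = f"bta{j + 1}"
        orthologs.append(
            OrthologRow(g.symbol, "cattle", f"ENSBTAG{j:05d}",
                        GenomicInterval(t_chrom, 10_000, 12_000))
        )
        qtls.append(
            QTLRecord("cattle", "meat tenderness", "Meat and Carcass",
                      GenomicInterval(t_chrom, 12_500, 13_500))
        )

    return SynthBundle(
        genome=genome,
        genes=genes,
        markers=markers,
        wgs_snps=wgs,
        ld_pairs=ld_pairs,
        constrained=constrained,
        gerp_track=ScoreTrack(gerp_entries),
        tfbs=tfbs,
        chains=chains,
        regulatory=regulatory,
        cpg_islands=[],
        polya_clusters=[],
        mirnas=mirnas,
        qtls=qtls,
        orthologs=orthologs,
        thresholds=Thresholds(),
    )


def _engineer_mirnas(chrom_seq, pos, alt, strand, mirna_ids, rng) -> list[Mirna]:
    """Mature miRNAs whose seed site overlaps the SNP in the ref window only."""
    ref_win = chrom_seq[pos - 5 : pos + 6]
    center = 5
    alt_win = ref_win[:center] + alt + ref_win[center + 1 :]
    if strand == "-":
        ref_win, alt_win = revcomp(ref_win), revcomp(alt_win)
        center = len(ref_win) - 1 - center
    site = None
    for start in range(center, center - 6, -1):
        if start < 0 or start + 6 > len(ref_win):
            continue
        cand = ref_win[start : start + 6]
        collide = any(
            alt_win[s : s + 6] == cand
            for s in range(max(0, center - 5), min(center, len(alt_win) - 6) + 1)
        )
        if not collide:
            site = cand
            break
    assert site is not None, "pathological sequence context"
    out = []
    for mid in mirna_ids:
        tail = "".join(rng.choice("ACGU") for _ in range(14))
        out.append(Mirna(mid, "U" + revcomp(site).replace("T", "U") + tail))
    return out
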