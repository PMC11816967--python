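"""Straight-line reference computations for synthetic-data ground truth.

This module deliberately re-derives every pipeline decision with the
dumbest correct algorithm available — full-mRNA rebuild and translation
for coding effects, per-base chain expansion for liftover, all-pairs
containment scans for overlaps, exhaustive placement scans for seed
sites — and shares no logic with the pipeline modules. The synthetic-data
recovery tests compare pipeline output against these computations, so any
shortcut taken by the pipeline has an independent check.

Only plain data containers (GenomicInterval, Variant, GeneModel, ...) are
imported; no pipeline operation is.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .core import GenomicInterval, Variant
from .crosslift import ChainAlignment, RegulatoryFeature
from .genes import GeneModel, Transcript
from .prioritize import LDPair, OrthologRow, QTLRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# consequence via full-mRNA rebuild

def _tx_positions(tx: Transcript, which: str, strand: str) -> list[int]:
    """Genomic positions of a feature class in transcription order."""
    ivs = {"exon": tx.exons, "cds": tx.cds}[which]
    positions = []
    for iv in ivs:
        positions.extend(range(iv.start, iv.end))
    positions.sort(reverse=(strand == "-"))
    return positions


def consequence_terms(
    v: Variant, gene: GeneModel, genome: Mapping[str, str]
) -> set[str]:
    terms: set[str] = set()
    for tx in gene.transcripts:
        terms |= _tx_terms(v, tx, gene.strand, genome)
    return terms


def _tx_terms(v: Variant, tx: Transcript, strand: str, genome: Mapping[str, str]) -> set[str]:
    span_start = min(e.start for e in tx.exons)
    span_end = max(e.end for e in tx.exons)
    pos = v.pos
    if pos < span_start or pos >= span_end:
        left = pos < span_start
        if strand == "+":
            return {"upstream_gene_variant" if left else "downstream_gene_variant"}
        return {"downstream_gene_variant" if left else "upstream_gene_variant"}

    exonic = any(e.start <= pos < e.end for e in tx.exons)
    if not exonic:
        terms = {"intron_variant"}
        # polypyrimidine tract: rank intron bases from the acceptor end
        exons = sorted(tx.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if not (a.end <= pos < b.start):
                continue
            intron = list(range(a.end, b.start))
            ranked = list(reversed(intron)) if strand == "+" else intron
            rank = ranked.index(pos) + 1
            if 3 <= rank <= 17:
                terms.add("splice_polypyrimidine_tract_variant")
        return terms

    if any(u.start <= pos < u.end for u in tx.utr5):
        return {"5_prime_UTR_variant"}
    if any(u.start <= pos < u.end for u in tx.utr3):
        return {"3_prime_UTR_variant"}
    if any(c.start <= pos < c.end for c in tx.cds):
        cds_positions = _tx_positions(tx, "cds", strand)
        ref_mrna, alt_mrna = [], []
        for p in cds_positions:
            base = genome[v.chrom][p].upper()
            alt_base = v.alt if p == pos else base
            if strand == "-":
                base, alt_base = _COMP[base], _COMP[alt_base]
            ref_mrna.append(base)
            alt_mrna.append(alt_base)
        ref_prot = str(Seq("".join(ref_mrna)).translate())
        alt_prot = str(Seq("".join(alt_mrna)).translate())
        idx = cds_positions.index(pos) // 3
        ref_aa, alt_aa = ref_prot[idx], alt_prot[idx]
        if ref_aa == alt_aa:
            return {"synonymous_variant"}
        if ref_aa == "*":
            return {"stop_lost"}
        if alt_aa == "*":
            return {"stop_gained"}
        return {"missense_variant"}
    # exonic but unannotated relative to the CDS
    if tx.cds:
        cds_positions = _tx_positions(tx, "cds", strand)
        first = cds_positions[0]
        before = pos < first if strand == "+" else pos > first
        return {"5_prime_UTR_variant" if before else "3_prime_UTR_variant"}
    return {"intron_variant"}


SEVERE = {"missense_variant", "stop_lost", "stop_gained",
          "splice_polypyrimidine_tract_variant"}


# ---------------------------------------------------------------------------
# liftover via explicit per-base expansion

def expand_chain(chain: ChainAlignment) -> dict[int, tuple[str, int, str]]:
    """Source position -> (target chrom, target pos, strand) for one chain."""
    mapping: dict[int, tuple[str, int, str]] = {}
    s = chain.source.start
    t = chain.target_start
    for size, gap_s, gap_t in chain.blocks:
        for k in range(size):
            t_reading = t + k
            if chain.target_strand == "-":
                tpos = chain.target_size - 1 - t_reading
            else:
                tpos = t_reading
            mapping[s + k] = (chain.target_chrom, tpos, chain.target_strand)
        s += size + gap_s
        t += size + gap_t
    return mapping


def lift(chains: Sequence[ChainAlignment], chrom: str, pos: int) -> Optional[tuple[str, int, str]]:
    best = None
    for c in chains:
        if c.source.chrom == chrom and c.source.start <= pos < c.source.end:
            if best is None or (c.score, -c.chain_id) > (best.score, -best.chain_id):
                best = c
    if best is None:
        return None
    return expand_chain(best).get(pos)


def regulatory_classes(
    chains: Sequence[ChainAlignment],
    features: Sequence[RegulatoryFeature],
    chrom: str,
    pos: int,
) -> set[str]:
    lifted = lift(chains, chrom, pos)
    if lifted is None:
        return set()
    t_chrom, t_pos, _ = lifted
    return {
        f.feature_class
        for f in features
        if f.interval.chrom == t_chrom and f.interval.start <= t_pos < f.interval.end
    }


# ---------------------------------------------------------------------------
# simple scans

def contains_any(ivs: Sequence[GenomicInterval], chrom: str, pos: int) -> bool:
    return any(iv.chrom == chrom and iv.start <= pos < iv.end for iv in ivs)


def score_at(entries: Sequence[tuple[GenomicInterval, float]], chrom: str, pos: int):
    for iv, score in entries:
        if iv.chrom == chrom and iv.start <= pos < iv.end:
            return score
    return None


def polya_near(
    clusters: Sequence[GenomicInterval], chrom: str, pos: int, flank: int
) -> bool:
    for c in clusters:
        if c.chrom == chrom and c.start - flank <= pos < c.end + flank:
            return True
    return False


def seed_effects(
    genome: Mapping[str, str],
    v: Variant,
    gene_strand: str,
    mirna_seqs: Mapping[str, str],
    w: int = 5,
) -> list[tuple[str, str]]:
    """Exhaustive placement scan of every miRNA seed around the SNP."""
    chrom_seq = genome[v.chrom]
    lo, hi = max(0, v.pos - w), min(len(chrom_seq), v.pos + w + 1)
    ref_win = chrom_seq[lo:hi].upper()
    center = v.pos - lo
    alt_win = ref_win[:center] + v.alt + ref_win[center + 1 :]
    if gene_strand == "-":
        ref_win, alt_win = _revcomp(ref_win), _revcomp(alt_win)
        center = len(ref_win) - 1 - center
    hits = []
    for mid, seq in mirna_seqs.items():
        rna = seq.upper().replace("T", "U")
        seed = _revcomp(rna[1:7].replace("U", "T"))
        ref_hit = alt_hit = False
        for start in range(0, len(ref_win) - 6 + 1):
            if not (start <= center < start + 6):
                continue
            if ref_win[start : start + 6] == seed:
                ref_hit = True
            if alt_win[start : start + 6] == seed:
                alt_hit = True
        if ref_hit and not alt_hit:
            hits.append((mid, "disrupted"))
        elif alt_hit and not ref_hit:
            hits.append((mid, "created"))
    return sorted(hits)


# ---------------------------------------------------------------------------
# QTL-ortholog gene filter

def qtl_supported_genes(
    gene_ids: Sequence[str],
    qtls: Sequence[QTLRecord],
    orthologs: Sequence[OrthologRow],
    flank: int,
    trait_classes: Sequence[str],
) -> set[str]:
    kept = set()
    for gid in gene_ids:
        for o in orthologs:
            if o.horse_gene_id != gid:
                continue
            for q in qtls:
                if q.species != o.species or q.trait_class not in trait_classes:
                    continue
                q_start = max(0, q.interval.start - flank)
                q_end = q.interval.end + flank
                if (
                    q.interval.chrom == o.interval.chrom
                    and o.interval.start < q_end
                    and q_start < o.interval.end
                ):
                    kept.add(gid)
    return kept


def ld_partners(
    pairs: Sequence[LDPair],
    chip_ids: Mapping[str, str],
    wgs_rs: set[str],
    r2_min: float,
) -> dict[str, set[str]]:
    """WGS rsID -> anchor chip marker ids, via a plain pair scan.

    ``chip_ids`` maps every id a chip marker answers to (marker id or
    rsID) onto its marker id.
    """
    anchors: dict[str, set[str]] = {}
    for p in pairs:
        if not p.r2 > r2_min:
            continue
        for a, b in ((p.snp_a, p.snp_b), (p.snp_b, p.snp_a)):
            if a in chip_ids and b in wgs_rs and b not in chip_ids:
                anchors.setdefault(b, set()).add(chip_ids[a])
    return anchors
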