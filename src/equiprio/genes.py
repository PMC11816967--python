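"""Gene structures and variant consequence classification.

A deliberately small consequence classifier covering the term set that
matters for regulatory-variant prioritization: upstream/downstream calls
within a configurable flank, UTR and intron placement, codon-level coding
effects (synonymous / missense / stop gained / stop lost), and the splice
polypyrimidine tract (intronic positions 3-17 counted from the acceptor
end of each intron, the standard VEP window).

Multi-transcript genes report the union of per-transcript terms, which is
why a single SNP can legitimately be e.g. "upstream gene variant, 5' UTR
variant, intron variant" at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .core import (
    GenomicInterval,
    ReferenceMismatchError,
    SEVERE_TERMS,
    ValidationError,
    Variant,
    revcomp,
)

# VEP's polypyrimidine tract: intron bases ranked 3..17 from the acceptor,
# where the two acceptor bases (the AG dinucleotide) are ranks 1-2.
POLYPYRIMIDINE_RANKS = range(3, 18)


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons {a} / {b}"
                )
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", tuple(sorted(self.cds, key=lambda c: c.start)))
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in exons):
                raise ValidationError(
                    f"{self.transcript_id}: CDS {c} not nested in any exon"
                )
        for u in tuple(self.utr5) + tuple(self.utr3):
            if any(u.overlaps(c) for c in self.cds):
                raise ValidationError(
                    f"{self.transcript_id}: UTR {u} overlaps CDS"
                )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom, self.exons[0].start, self.exons[-1].end
        )

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end < b.start:
                out.append(GenomicInterval(a.chrom, a.end, b.start))
        return out


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    span: GenomicInterval
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: gene must be stranded")

    @property
    def strand(self) -> str:
        return self.span.strand


TERM_ORDER = (
    "upstream_gene_variant",
    "5_prime_UTR_variant",
    "synonymous_variant",
    "missense_variant",
    "stop_gained",
    "stop_lost",
    "splice_polypyrimidine_tract_variant",
    "intron_variant",
    "3_prime_UTR_variant",
    "downstream_gene_variant",
)

TERM_NAMES = {
    "upstream_gene_variant": "upstream gene variant",
    "downstream_gene_variant": "downstream gene variant",
    "intron_variant": "intron variant",
    "synonymous_variant": "synonymous variant",
    "missense_variant": "missense variant",
    "stop_lost": "stop lost",
    "stop_gained": "stop gained",
    "5_prime_UTR_variant": "5' UTR variant",
    "3_prime_UTR_variant": "3' UTR variant",
    "splice_polypyrimidine_tract_variant": "splice polypyrimidine tract variant",
}

DISPLAY_TO_TERM = {v: k for k, v in TERM_NAMES.items()}


def terms_from_display(text: str) -> frozenset[str]:
    """Inverse of :meth:`ConsequenceCall.display`."""
    parts = [p.strip() for p in text.split(",") if p.strip()]
    unknown = [p for p in parts if p not in DISPLAY_TO_TERM]
    if unknown:
        raise ValidationError(f"unknown consequence names: {unknown}")
    return frozenset(DISPLAY_TO_TERM[p] for p in parts)


@dataclass(frozen=True)
class ConsequenceCall:
    terms: frozenset[str]

    @property
    def severe(self) -> bool:
        return bool(self.terms & SEVERE_TERMS)

    def display(self) -> str:
        """Human-readable term list in a canonical order."""
        return ", ".join(TERM_NAMES[t] for t in TERM_ORDER if t in self.terms)


def expand_region(
    iv: GenomicInterval, flank: int, chrom_length: Optional[int] = None
) -> GenomicInterval:
    """Extend an interval ``flank`` bp both ways, clamped to the chromosome."""
    return iv.expand(flank, chrom_length)


def genes_for_variant(
    v: Variant,
    genes: Sequence[GeneModel],
    flank: int,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> list[str]:
    """Gene ids whose flank-expanded span contains the variant, sorted."""
    hits = []
    for g in genes:
        length = chrom_lengths.get(g.span.chrom) if chrom_lengths else None
        if expand_region(g.span, flank, length).contains(v.chrom, v.pos):
            hits.append(g.gene_id)
    return sorted(hits)


def _check_reference(v: Variant, genome: Mapping[str, str]) -> None:
    try:
        base = genome[v.chrom][v.pos].upper()
    except (KeyError, IndexError) as exc:
        raise ValidationError(f"{v.rs_id}: position {v.chrom}:{v.pos} not in genome") from exc
    if base != v.ref:
        raise ReferenceMismatchError(
            f"{v.rs_id}: genome has {base} at {v.chrom}:{v.pos}, variant declares ref {v.ref}"
        )


def _coding_terms(v: Variant, tx: Transcript, strand: str, genome: Mapping[str, str]) -> set[str]:
    """Translate the affected codon for ref and alt alleles (strand-aware)."""
    chrom_seq = genome[v.chrom]
    segments = list(tx.cds) if strand == "+" else list(reversed(tx.cds))
    offset = None
    consumed = 0
    for seg in segments:
        if seg.contains(v.chrom, v.pos):
            within = (v.pos - seg.start) if strand == "+" else (seg.end - 1 - v.pos)
            offset = consumed + within
        consumed += len(seg)
    if offset is None:  # pragma: no cover - guarded by caller
        raise ValidationError(f"{v.rs_id}: not in CDS of {tx.transcript_id}")
    codon_start = (offset // 3) * 3
    if codon_start + 3 > consumed:
        raise ValidationError(
            f"{tx.transcript_id}: CDS length {consumed} leaves an incomplete codon"
        )
    # materialize only the affected codon from the genome
    cds_seq_parts = []
    for seg in segments:
        s = chrom_seq[seg.start : seg.end].upper()
        cds_seq_parts.append(s if strand == "+" else revcomp(s))
    cds_seq = "".join(cds_seq_parts)
    ref_codon = cds_seq[codon_start : codon_start + 3]
    pos_in_codon = offset - codon_start
    ref_base = v.ref if strand == "+" else revcomp(v.ref)
    alt_base = v.alt if strand == "+" else revcomp(v.alt)
    if ref_codon[pos_in_codon] != ref_base:  # pragma: no cover - genome checked earlier
        raise ReferenceMismatchError(f"{v.rs_id}: codon/reference disagreement")
    alt_codon = ref_codon[:pos_in_codon] + alt_base + ref_codon[pos_in_codon + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return {"synonymous_variant"}
    if ref_aa == "*":
        return {"stop_lost"}
    if alt_aa == "*":
        return {"stop_gained"}
    return {"missense_variant"}


def _transcript_terms(
    v: Variant, tx: Transcript, strand: str, genome: Mapping[str, str]
) -> set[str]:
    span = tx.span
    if v.pos < span.start:
        return {"upstream_gene_variant" if strand == "+" else "downstream_gene_variant"}
    if v.pos >= span.end:
        return {"downstream_gene_variant" if strand == "+" else "upstream_gene_variant"}

    in_exon = any(e.contains(v.chrom, v.pos) for e in tx.exons)
    if in_exon:
        if any(u.contains(v.chrom, v.pos) for u in tx.utr5):
            return {"5_prime_UTR_variant"}
        if any(u.contains(v.chrom, v.pos) for u in tx.utr3):
            return {"3_prime_UTR_variant"}
        if any(c.contains(v.chrom, v.pos) for c in tx.cds):
            return _coding_terms(v, tx, strand, genome)
        # exonic but unannotated: place relative to the CDS in transcription order
        if tx.cds:
            cds_start = tx.cds[0].start if strand == "+" else tx.cds[-1].end
            before = v.pos < cds_start if strand == "+" else v.pos >= cds_start
            return {"5_prime_UTR_variant" if before else "3_prime_UTR_variant"}
        return {"intron_variant"}  # non-coding transcripts: out of scope, coarse call

    terms = {"intron_variant"}
    for intron in tx.introns():
        if not intron.contains(v.chrom, v.pos):
            continue
        # acceptor is the intron end abutting the next exon in transcription order
        rank = intron.end - v.pos if strand == "+" else v.pos - intron.start + 1
        if rank in POLYPYRIMIDINE_RANKS:
            terms.add("splice_polypyrimidine_tract_variant")
    return terms


def classify_consequence(
    v: Variant,
    gene: GeneModel,
    genome: Mapping[str, str],
    flank: int = 5000,
) -> ConsequenceCall:
    """Union of per-transcript consequence terms for one variant/gene pair."""
    _check_reference(v, genome)
    if not expand_region(gene.span, flank).contains(v.chrom, v.pos):
        raise ValidationError(
            f"{v.rs_id}: outside the {flank} bp flank of {gene.gene_id}"
        )
    terms: set[str] = set()
    for tx in gene.transcripts:
        terms |= _transcript_terms(v, tx, gene.strand, genome)
    return ConsequenceCall(frozenset(terms))
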