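"""Shared fixtures: small deterministic genomes, genes, and random chains."""

from __future__ import annotations

import random

import pytest

from equiprio.core import GenomicInterval, Variant, point
from equiprio.crosslift import ChainAlignment
from equiprio.genes import GeneModel, Transcript


def make_genome(length: int = 5000, seed: int = 7, chrom: str = "chr1") -> dict[str, str]:
    rng = random.Random(seed)
    return {chrom: "".join(rng.choice("ACGT") for _ in range(length))}


def make_gene(chrom: str = "chr1", origin: int = 1000, strand: str = "+",
              gene_id: str = "g1") -> GeneModel:
    """Three-exon coding gene: UTR5, split CDS (201 bp), UTR3."""
    ivs = lambda pairs: tuple(
        GenomicInterval(chrom, origin + a, origin + b, strand) for a, b in pairs
    )
    tx = Transcript(
        f"{gene_id}.tx1",
        exons=ivs([(0, 200), (300, 400), (500, 700)]),
        cds=ivs([(150, 200), (300, 400), (500, 551)]),
        utr5=ivs([(0, 150)]),
        utr3=ivs([(551, 700)]),
    )
    return GeneModel(
        gene_id, gene_id.upper(),
        GenomicInterval(chrom, origin, origin + 700, strand), (tx,)
    )


def variant_at(genome: dict[str, str], chrom: str, pos: int, alt: str | None = None,
               rs: str = "rsT", **kw) -> Variant:
    ref = genome[chrom][pos]
    if alt is None:
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
    return Variant(rs, point(chrom, pos), ref, alt, **kw)


def random_chain(rng: random.Random, chain_id: int, chrom: str = "chrS") -> ChainAlignment:
    """A valid random chain (< 10 kb source span) with gaps and both strands."""
    n = rng.randrange(1, 6)
    blocks = []
    for i in range(n):
        size = rng.randrange(1, 300)
        last = i == n - 1
        gs = 0 if last else rng.randrange(0, 120)
        gt = 0 if last else rng.randrange(0, 120)
        blocks.append((size, gs, gt))
    src_span = sum(s + gs for s, gs, _ in blocks)
    tgt_span = sum(s + gt for s, _, gt in blocks)
    src_start = rng.randrange(0, 400)
    t_start = rng.randrange(0, 400)
    return ChainAlignment(
        chain_id=chain_id,
        score=rng.randrange(100, 100_000),
        source=GenomicInterval(chrom, src_start, src_start + src_span),
        target_chrom="chrT",
        target_size=t_start + tgt_span + rng.randrange(1, 400),
        target_start=t_start,
        target_end=t_start + tgt_span,
        target_strand=rng.choice("+-"),
        blocks=tuple(blocks),
    )


def simple_chain_args(genome: dict[str, str]) -> list[ChainAlignment]:
    """One ungapped chain lifting all of chr1 to chrT with a +500 offset."""
    length = len(genome["chr1"])
    return [
        ChainAlignment(
            chain_id=1, score=100.0,
            source=GenomicInterval("chr1", 0, length),
            target_chrom="chrT", target_size=length + 2000,
            target_start=500, target_end=500 + length,
            target_strand="+", blocks=((length, 0, 0),),
        )
    ]


@pytest.fixture
def genome():
    return make_genome()


@pytest.fixture
def gene():
    return make_gene()
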