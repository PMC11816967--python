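"""Single-base coordinate liftover through UCSC chain alignments.

A chain describes a blockwise gapped alignment between a source ("target"
in UCSC's own header vocabulary, here: the horse assembly) and a
destination assembly. Lifting a point walks the blocks of the best-scoring
chain covering it: inside an aligned block the offset carries over, inside
a source gap the point is unmapped. Minus-strand destination chains use
reversed coordinates, which are reflected back to forward-strand
positions, exactly as the UCSC liftOver tool does for single bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .core import GenomicInterval, ValidationError


@dataclass(frozen=True)
class ChainAlignment:
    """One chain: header spans plus (size, gap_source, gap_target) blocks.

    Coordinates follow the chain file: ``source`` is in forward-strand
    coordinates; ``target_start``/``target_end`` are in reading direction,
    i.e. on ``target_strand == '-'`` they count from the far end of the
    target chromosome (``target_size`` is needed to reflect them back).
    """

    chain_id: int
    score: float
    source: GenomicInterval
    target_chrom: str
    target_size: int
    target_start: int
    target_end: int
    target_strand: str
    blocks: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.target_strand not in ("+", "-"):
            raise ValidationError(f"chain {self.chain_id}: bad target strand")
        if self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0:
            raise ValidationError(f"chain {self.chain_id}: final block must have zero gaps")
        src_span = sum(size + gs for size, gs, _ in self.blocks)
        tgt_span = sum(size + gt for size, _, gt in self.blocks)
        if src_span != len(self.source):
            raise ValidationError(
                f"chain {self.chain_id}: blocks cover {src_span} source bp, "
                f"header spans {len(self.source)}"
            )
        if tgt_span != self.target_end - self.target_start:
            raise ValidationError(
                f"chain {self.chain_id}: blocks cover {tgt_span} target bp, "
                f"header spans {self.target_end - self.target_start}"
            )


@dataclass(frozen=True)
class LiftResult:
    status: str  # "mapped" | "unmapped"
    chrom: Optional[str] = None
    pos: Optional[int] = None
    strand: Optional[str] = None

    @property
    def mapped(self) -> bool:
        return self.status == "mapped"


UNMAPPED = LiftResult("unmapped")


@dataclass(frozen=True)
class RegulatoryFeature:
    interval: GenomicInterval
    feature_class: str

    def __post_init__(self) -> None:
        if not self.feature_class:
            raise ValidationError("regulatory feature class must be non-empty")


def lift_point(chains: Sequence[ChainAlignment], chrom: str, pos: int) -> LiftResult:
    """Lift a single 0-based source position; unmapped when no chain covers it."""
    if pos < 0:
        raise ValidationError("position must be non-negative")
    covering = [c for c in chains if c.source.contains(chrom, pos)]
    if not covering:
        return UNMAPPED
    # highest score wins; ties broken by lowest chain id
    chain = min(covering, key=lambda c: (-c.score, c.chain_id))
    s_cur = chain.source.start
    t_cur = chain.target_start
    for size, gap_s, gap_t in chain.blocks:
        if s_cur <= pos < s_cur + size:
            t_reading = t_cur + (pos - s_cur)
            if chain.target_strand == "-":
                return LiftResult(
                    "mapped", chain.target_chrom,
                    chain.target_size - 1 - t_reading, "-",
                )
            return LiftResult("mapped", chain.target_chrom, t_reading, "+")
        if s_cur + size <= pos < s_cur + size + gap_s:
            return UNMAPPED  # inside a source gap
        s_cur += size + gap_s
        t_cur += size + gap_t
    return UNMAPPED  # pragma: no cover - header span guarantees coverage


class RegulatoryBuild:
    """Indexed set of regulatory features for point-overlap queries."""

    def __init__(self, features: Iterable[RegulatoryFeature]):
        self.features = list(features)
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features:
            tree = self._trees.setdefault(f.interval.chrom, IntervalTree())
            tree.addi(f.interval.start, f.interval.end, f.feature_class)

    def classes_at(self, chrom: str, pos: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.at(pos)}


def regulatory_overlap(
    lr: LiftResult, features: "RegulatoryBuild | Iterable[RegulatoryFeature]"
) -> set[str]:
    """Feature classes containing a lifted position; empty when unmapped."""
    if not lr.mapped:
        return set()
    build = features if isinstance(features, RegulatoryBuild) else RegulatoryBuild(features)
    return build.classes_at(lr.chrom, lr.pos)
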