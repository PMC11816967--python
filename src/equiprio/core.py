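"""Core domain types shared across the pipeline.

All genomic coordinates inside the package are 0-based half-open
(``[start, end)``), the BED convention. Formats that use 1-based inclusive
coordinates (GFF3, chip manifests, QTL tables) are converted at the I/O
boundary and converted back on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

VALID_STRANDS = ("+", "-", ".")
DNA_BASES = ("A", "C", "G", "T")

# Sequence Ontology terms the consequence classifier can emit.
CONSEQUENCE_TERMS = frozenset(
    {
        "upstream_gene_variant",
        "downstream_gene_variant",
        "intron_variant",
        "synonymous_variant",
        "missense_variant",
        "stop_lost",
        "stop_gained",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "splice_polypyrimidine_tract_variant",
    }
)

# Terms treated as functionally severe on their own.
SEVERE_TERMS = frozenset(
    {
        "missense_variant",
        "stop_lost",
        "stop_gained",
        "splice_polypyrimidine_tract_variant",
    }
)


class ValidationError(ValueError):
    """Raised when parsed data violates a format or domain invariant."""


class ReferenceMismatchError(ValidationError):
    """Genome base at a variant position disagrees with its declared ref allele."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def expand(self, flank: int, chrom_length: Optional[int] = None) -> "GenomicInterval":
        """Extend by ``flank`` bp both ways, clamped to [0, chrom_length]."""
        if flank < 0:
            raise ValidationError("flank must be non-negative")
        start = max(0, self.start - flank)
        end = self.end + flank
        if chrom_length is not None:
            end = min(end, chrom_length)
        return replace(self, start=start, end=end)


def point(chrom: str, pos: int, strand: str = ".") -> GenomicInterval:
    """Width-1 interval covering the single base at 0-based ``pos``."""
    return GenomicInterval(chrom, pos, pos + 1, strand)


PROVENANCE_DIRECT = "direct_marker"
PROVENANCE_LD = "ld_partner"


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant (indels are out of scope)."""

    rs_id: str
    site: GenomicInterval
    ref: str
    alt: str
    provenance: str = PROVENANCE_DIRECT
    anchor_marker_ids: tuple[str, ...] = field(default_factory=tuple)
    marker_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.site) != 1:
            raise ValidationError(f"{self.rs_id}: variant site must have width 1")
        if self.ref not in DNA_BASES or self.alt not in DNA_BASES:
            raise ValidationError(
                f"{self.rs_id}: alleles must be single bases "
                f"(got {self.ref!r}/{self.alt!r}; indels are unsupported)"
            )
        if self.ref == self.alt:
            raise ValidationError(f"{self.rs_id}: ref and alt alleles are identical")
        if self.provenance not in (PROVENANCE_DIRECT, PROVENANCE_LD):
            raise ValidationError(f"{self.rs_id}: bad provenance {self.provenance!r}")

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.start


@dataclass
class Thresholds:
    """Tunable cutoffs of the prioritization pipeline.

    flank_bp
        Gene-region expansion (and upstream/downstream window) in bp.
    r2_min
        Strict lower bound on R² for linkage-disequilibrium partners.
    gerp_min
        Minimum GERP rejected-substitution score counted as conserved.
    polya_flank_bp
        Extension around polyadenylation clusters.
    mirna_window_bp
        Half-width of the sequence window around a 3' UTR SNP.
    seed_len
        miRNA seed length (reverse complement of mature positions 2-7).
    """

    flank_bp: int = 5000
    r2_min: float = 0.95
    gerp_min: float = 2.0
    polya_flank_bp: int = 50
    mirna_window_bp: int = 5
    seed_len: int = 6
    # criterion switches
    cpg_is_criterion: bool = False
    severe_is_criterion: bool = True
    polya_symmetric: bool = True

    def __post_init__(self) -> None:
        for name in ("flank_bp", "r2_min", "gerp_min", "polya_flank_bp",
                     "mirna_window_bp", "seed_len"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")


class ScoreTrack:
    """Run-length encoded per-base score track (bedGraph semantics).

    Intervals within a chromosome must be non-overlapping; they are kept
    sorted and queried by bisection. Uncovered positions have no score.
    """

    def __init__(self, entries: Optional[list[tuple[GenomicInterval, float]]] = None):
        self._by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, score in entries or []:
            self.add(iv, score)
        self._sorted = False

    def add(self, iv: GenomicInterval, score: float) -> None:
        import math

        if not math.isfinite(score):
            raise ValidationError(f"non-finite score at {iv.chrom}:{iv.start}")
        self._by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, score))
        self._sorted = False

    def _ensure_sorted(self) -> None:
        if self._sorted:
            return
        for chrom, runs in self._by_chrom.items():
            runs.sort()
            for (s1, e1, _), (s2, _e2, _2) in zip(runs, runs[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"overlapping score intervals on {chrom}: "
                        f"[{s1},{e1}) and [{s2},{_e2})"
                    )
        self._sorted = True

    def value_at(self, chrom: str, pos: int) -> Optional[float]:
        """Score covering 0-based ``pos``, or None when uncovered."""
        from bisect import bisect_right

        self._ensure_sorted()
        runs = self._by_chrom.get(chrom)
        if not runs:
            return None
        i = bisect_right(runs, (pos, float("inf"), float("inf"))) - 1
        if i >= 0:
            start, end, score = runs[i]
            if start <= pos < end:
                return score
        return None

    def items(self):
        """Yield (GenomicInterval, score) in sorted order."""
        self._ensure_sorted()
        for chrom in sorted(self._by_chrom):
            for start, end, score in self._by_chrom[chrom]:
                yield GenomicInterval(chrom, start, end), score

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScoreTrack):
            return NotImplemented
        return list(self.items()) == list(other.items())


COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]
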