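"""miRNA seed-site scanning around 3' UTR SNPs.

A putative binding site is the 6-base DNA reverse complement of mature
miRNA positions 2-7 (the seed). An 11-nt sense-strand window (+/-5 bp) is
extracted around the SNP, in gene orientation, and every 6-mer placement
that overlaps the variant base is compared between the reference and
alternate windows: a site present only with the reference allele is
*disrupted*, one present only with the alternate allele is *created*.
Placements that do not overlap the SNP cannot change and are not scanned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .core import ValidationError, Variant, revcomp

SEED_LEN = 6

EFFECT_CREATED = "created"
EFFECT_DISRUPTED = "disrupted"


@dataclass(frozen=True)
class Mirna:
    mirna_id: str
    sequence: str  # mature sequence over A/C/G/U

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if len(seq) < 7:
            raise ValidationError(
                f"{self.mirna_id}: mature sequence must be >= 7 nt (positions 2-7 required)"
            )
        if set(seq) - set("ACGU"):
            raise ValidationError(f"{self.mirna_id}: non-ACGU characters in sequence")
        object.__setattr__(self, "sequence", seq)


def seed_of(m: Mirna) -> str:
    """DNA reverse complement of mature positions 2-7 (1-based)."""
    seed_rna = m.sequence[1:7]
    return revcomp(seed_rna.replace("U", "T"))


def windows_for_variant(
    v: Variant,
    genome: Mapping[str, str],
    gene_strand: str,
    w: int = 5,
) -> tuple[str, str, int]:
    """Sense-strand ref/alt windows of +/- ``w`` bp and the center index.

    Windows are truncated at chromosome ends; for minus-strand genes both
    windows are reverse complemented so the scan runs in gene orientation.
    """
    chrom_seq = genome[v.chrom]
    if chrom_seq[v.pos].upper() != v.ref:
        raise ValidationError(
            f"{v.rs_id}: genome base {chrom_seq[v.pos].upper()} != ref {v.ref}"
        )
    lo = max(0, v.pos - w)
    hi = min(len(chrom_seq), v.pos + w + 1)
    context = chrom_seq[lo:hi].upper()
    center = v.pos - lo
    ref_win = context
    alt_win = context[:center] + v.alt + context[center + 1 :]
    if gene_strand == "-":
        ref_win, alt_win = revcomp(ref_win), revcomp(alt_win)
        center = len(context) - 1 - center
    return ref_win, alt_win, center


def _matches_over_center(window: str, center: int, seed: str) -> bool:
    """True when ``seed`` occurs at a placement overlapping ``center``."""
    k = len(seed)
    for start in range(max(0, center - k + 1), min(center, len(window) - k) + 1):
        if window[start : start + k] == seed:
            return True
    return False


def scan_sites(
    ref_window: str,
    alt_window: str,
    center: int,
    seeds: Mapping[str, str],
) -> list[tuple[str, str]]:
    """Created/disrupted seed sites, one entry per miRNA id.

    ``seeds`` maps miRNA id -> 6-base DNA seed site. Windows must differ
    only at ``center``.
    """
    if len(ref_window) != len(alt_window):
        raise ValidationError("ref and alt windows differ in length")
    diffs = [i for i, (a, b) in enumerate(zip(ref_window, alt_window)) if a != b]
    if diffs != [center]:
        raise ValidationError(
            f"windows must differ exactly at the center index {center}, differ at {diffs}"
        )
    hits = []
    for mirna_id, seed in seeds.items():
        if len(seed) != SEED_LEN:
            raise ValidationError(f"{mirna_id}: seed must be {SEED_LEN} bases")
        in_ref = _matches_over_center(ref_window, center, seed)
        in_alt = _matches_over_center(alt_window, center, seed)
        if in_ref and not in_alt:
            hits.append((mirna_id, EFFECT_DISRUPTED))
        elif in_alt and not in_ref:
            hits.append((mirna_id, EFFECT_CREATED))
    return sorted(hits)


def seeds_for(mirnas: Mapping[str, Mirna] | list[Mirna]) -> dict[str, str]:
    """Map miRNA id -> seed site for a collection of mature miRNAs."""
    items = mirnas.values() if isinstance(mirnas, Mapping) else mirnas
    return {m.mirna_id: seed_of(m) for m in items}
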