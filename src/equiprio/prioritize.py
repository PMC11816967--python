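"""LD expansion, criterion filtering, and the prioritized variant report.

The pipeline's decision logic lives here:

* chip markers are expanded with whole-genome-sequencing SNPs in strong
  linkage disequilibrium (strictly R^2 > 0.95 by default), so a marker can
  be prioritized through evidence on a linked variant it tags;
* a variant passes when it meets *at least one* enabled criterion
  (severe consequence, constrained element, high GERP, cross-species
  regulatory overlap, TFBS effect, miRNA seed-site change, polyA
  proximity, optionally CpG island);
* genes are retained only when an ortholog in another species falls in a
  flank-expanded QTL for an allowed trait class;
* the surviving rows are formatted like the final report table, with LD
  partners carrying their anchor chip markers in brackets.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotate import AnnotationRecord
from .core import (
    GenomicInterval,
    PROVENANCE_DIRECT,
    PROVENANCE_LD,
    Thresholds,
    ValidationError,
    Variant,
)


@dataclass(frozen=True)
class LDPair:
    snp_a: str
    snp_b: str
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(f"R^2 must be in [0,1], got {self.r2}")

    def key(self) -> tuple[str, str]:
        """Unordered-pair identity."""
        return tuple(sorted((self.snp_a, self.snp_b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class QTLRecord:
    species: str
    trait: str
    trait_class: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.trait_class:
            raise ValidationError("QTL trait_class must be non-empty")


@dataclass(frozen=True)
class OrthologRow:
    horse_gene_id: str
    species: str
    target_gene_id: str
    interval: GenomicInterval


DEFAULT_TRAIT_CLASSES = ("Meat and Carcass",)


def expand_by_ld(
    markers: Sequence[Variant],
    wgs_snps: Sequence[Variant],
    pairs: Sequence[LDPair],
    r2_min: float = 0.95,
) -> tuple[list[Variant], list[LDPair], list[str]]:
    """Chip markers plus their LD partners above the (strict) R^2 cutoff.

    Returns (variants, marker_marker_pairs, warnings). Pair ids resolve
    against chip marker ids and rsIDs, and against WGS rsIDs; marker-marker
    pairs above the cutoff go to a side report instead of adding variants.
    Variants are deduplicated by rsID with direct-marker provenance
    winning over LD-partner provenance.
    """
    chip_by_id: dict[str, Variant] = {}
    for m in markers:
        if m.marker_id:
            chip_by_id[m.marker_id] = m
        chip_by_id.setdefault(m.rs_id, m)
    wgs_by_id = {s.rs_id: s for s in wgs_snps}

    out: dict[str, Variant] = {}
    for m in markers:
        if m.rs_id not in out:
            out[m.rs_id] = m
    anchors: dict[str, set[str]] = {}
    marker_marker: dict[tuple[str, str], LDPair] = {}
    warnings: list[str] = []

    for pair in pairs:
        if not pair.r2 > r2_min:
            continue
        a_chip, b_chip = pair.snp_a in chip_by_id, pair.snp_b in chip_by_id
        a_wgs, b_wgs = pair.snp_a in wgs_by_id, pair.snp_b in wgs_by_id
        if a_chip and b_chip:
            marker_marker.setdefault(pair.key(), pair)
        elif (a_chip and b_wgs) or (b_chip and a_wgs):
            chip = chip_by_id[pair.snp_a if a_chip else pair.snp_b]
            wgs = wgs_by_id[pair.snp_b if a_chip else pair.snp_a]
            if wgs.rs_id not in out or out[wgs.rs_id].provenance == PROVENANCE_LD:
                anchors.setdefault(wgs.rs_id, set()).add(chip.marker_id or chip.rs_id)
        elif a_wgs and b_wgs:
            continue  # no chip anchor on either side
        else:
            dangling = pair.snp_a if not (a_chip or a_wgs) else pair.snp_b
            warnings.append(f"LD pair ({pair.snp_a}, {pair.snp_b}): unknown id {dangling}; skipped")

    from dataclasses import replace

    for rs_id, anchor_ids in anchors.items():
        if rs_id in out and out[rs_id].provenance == PROVENANCE_DIRECT:
            continue  # direct marker wins
        out[rs_id] = replace(
            wgs_by_id[rs_id],
            provenance=PROVENANCE_LD,
            anchor_marker_ids=tuple(sorted(anchor_ids)),
        )
    variants = sorted(out.values(), key=lambda v: (v.chrom, v.pos, v.rs_id))
    side = [marker_marker[k] for k in sorted(marker_marker)]
    return variants, side, warnings


def passes_any(rec: AnnotationRecord, thresholds: Optional[Thresholds] = None) -> bool:
    """True iff at least one enabled prioritization criterion holds."""
    th = thresholds or Thresholds()
    checks = [
        th.severe_is_criterion and rec.consequence.severe,
        rec.constrained,
        rec.gerp_high,
        any(bool(classes) for classes in rec.regulatory.values()),
        bool(rec.tf_effect),
        bool(rec.mirna_hits),
        rec.polya,
        th.cpg_is_criterion and rec.cpg,
    ]
    return any(checks)


def propagate_to_markers(
    passing: Iterable[Variant],
) -> tuple[set[str], list[tuple[str, tuple[str, ...]]]]:
    """Prioritized chip-marker ids and (rs_id, anchors) per passing variant.

    A chip marker is prioritized when it passes itself or when any of its
    LD partners passes; passing LD partners carry their anchors.
    """
    marker_ids: set[str] = set()
    rows: list[tuple[str, tuple[str, ...]]] = []
    for v in passing:
        if v.provenance == PROVENANCE_DIRECT:
            if v.marker_id:
                marker_ids.add(v.marker_id)
            rows.append((v.rs_id, ()))
        else:
            if not v.anchor_marker_ids:
                raise ValidationError(f"{v.rs_id}: LD partner without anchor markers")
            marker_ids.update(v.anchor_marker_ids)
            rows.append((v.rs_id, v.anchor_marker_ids))
    return marker_ids, rows


def qtl_gene_filter(
    horse_gene_ids: Iterable[str],
    qtls: Sequence[QTLRecord],
    orthologs: Sequence[OrthologRow],
    flank: int = 5000,
    trait_classes: Sequence[str] = DEFAULT_TRAIT_CLASSES,
) -> set[str]:
    """Horse genes whose ortholog intersects a flank-expanded QTL."""
    allowed = set(trait_classes)
    expanded: dict[str, list[GenomicInterval]] = {}
    for q in qtls:
        if q.trait_class in allowed:
            expanded.setdefault(q.species, []).append(q.interval.expand(flank))
    wanted = set(horse_gene_ids)
    kept: set[str] = set()
    for row in orthologs:
        if row.horse_gene_id not in wanted or row.horse_gene_id in kept:
            continue
        for qiv in expanded.get(row.species, []):
            if row.interval.overlaps(qiv):
                kept.add(row.horse_gene_id)
                break
    return kept


@dataclass(frozen=True)
class PrioritizedRow:
    gene_symbol: str
    type: str  # "Marker" | "LD"
    rs_id: str
    marker_ids: tuple[str, ...]  # own marker ids (Marker rows)
    anchor_ids: tuple[str, ...]  # bracketed LD anchors (LD rows)
    consequence: str
    constrained: bool
    gerp: Optional[float]
    tf_effect: tuple[str, ...]
    human_reg: tuple[str, ...]
    mouse_reg: tuple[str, ...]
    mirna: tuple[str, ...]

    def marker_display(self) -> str:
        parts = list(self.marker_ids) + [f"({a})" for a in self.anchor_ids]
        return ", ".join(parts)

    def normalized_marker_ids(self) -> set[str]:
        return set(self.marker_ids) | set(self.anchor_ids)


@dataclass
class TableSummary:
    n_snps: int
    n_genes: int
    n_markers: int
    n_direct: int
    n_ld: int


@dataclass
class PrioritizedTable:
    rows: list[PrioritizedRow] = field(default_factory=list)

    @property
    def summary(self) -> TableSummary:
        markers: set[str] = set()
        for r in self.rows:
            markers |= r.normalized_marker_ids()
        n_direct = sum(1 for r in self.rows if r.type == "Marker")
        n_ld = sum(1 for r in self.rows if r.type == "LD")
        assert n_direct + n_ld == len(self.rows)
        return TableSummary(
            n_snps=len(self.rows),
            n_genes=len({r.gene_symbol for r in self.rows}),
            n_markers=len(markers),
            n_direct=n_direct,
            n_ld=n_ld,
        )

    COLUMNS = (
        "gene_symbol", "type", "rs_id", "marker_id", "consequence",
        "constrained", "gerp", "tf_binding", "human_reg", "mouse_reg", "mirna",
    )

    def to_dataframe(self) -> pd.DataFrame:
        data = []
        for r in self.rows:
            data.append(
                {
                    "gene_symbol": r.gene_symbol,
                    "type": r.type,
                    "rs_id": r.rs_id,
                    "marker_id": r.marker_display(),
                    "consequence": r.consequence,
                    "constrained": "Yes" if r.constrained else "",
                    "gerp": "" if r.gerp is None else format(r.gerp, "g"),
                    "tf_binding": ", ".join(r.tf_effect),
                    "human_reg": ", ".join(r.human_reg),
                    "mouse_reg": ", ".join(r.mouse_reg),
                    "mirna": ", ".join(r.mirna),
                }
            )
        return pd.DataFrame(data, columns=list(self.COLUMNS))

    def to_tsv(self) -> str:
        buf = _io.StringIO()
        self.to_dataframe().to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "PrioritizedTable":
        df = pd.read_csv(_io.StringIO(text), sep="\t", dtype=str).fillna("")
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"table missing columns: {sorted(missing)}")
        rows = []
        for _, rec in df.iterrows():
            own, anchors = [], []
            for token in filter(None, (t.strip() for t in rec["marker_id"].split(","))):
                if token.startswith("(") and token.endswith(")"):
                    anchors.append(token[1:-1])
                else:
                    own.append(token)
            split = lambda s: tuple(t.strip() for t in s.split(",") if t.strip())
            rows.append(
                PrioritizedRow(
                    gene_symbol=rec["gene_symbol"],
                    type=rec["type"],
                    rs_id=rec["rs_id"],
                    marker_ids=tuple(own),
                    anchor_ids=tuple(anchors),
                    consequence=rec["consequence"],
                    constrained=rec["constrained"] == "Yes",
                    gerp=float(rec["gerp"]) if rec["gerp"] != "" else None,
                    tf_effect=split(rec["tf_binding"]),
                    human_reg=split(rec["human_reg"]),
                    mouse_reg=split(rec["mouse_reg"]),
                    mirna=split(rec["mirna"]),
                )
            )
        return cls(rows)


def build_final_table(
    passing: Sequence[tuple[Variant, AnnotationRecord]],
    gene_symbols: Mapping[str, str],
    qtl_genes: set[str],
    marker_ids_by_rs: Optional[Mapping[str, Sequence[str]]] = None,
) -> PrioritizedTable:
    """Assemble the final report from passing (variant, record) pairs.

    Rows are restricted to genes surviving the QTL-ortholog filter and
    sorted lexicographically by (gene symbol, rsID); the output is
    independent of input order.
    """
    rows = []
    seen: set[tuple[str, str]] = set()
    for v, rec in passing:
        if rec.gene_id not in qtl_genes:
            continue
        key = (rec.gene_id, v.rs_id)
        if key in seen:
            continue
        seen.add(key)
        if v.provenance == PROVENANCE_DIRECT:
            own = tuple(marker_ids_by_rs.get(v.rs_id, ())) if marker_ids_by_rs else ()
            if not own and v.marker_id:
                own = (v.marker_id,)
            row_type, anchors = "Marker", ()
        else:
            row_type, own, anchors = "LD", (), v.anchor_marker_ids
        rows.append(
            PrioritizedRow(
                gene_symbol=gene_symbols.get(rec.gene_id, rec.gene_id),
                type=row_type,
                rs_id=v.rs_id,
                marker_ids=tuple(sorted(own)),
                anchor_ids=tuple(sorted(anchors)),
                consequence=rec.consequence.display(),
                constrained=rec.constrained,
                gerp=rec.gerp,
                tf_effect=tuple(sorted(rec.tf_effect)),
                human_reg=tuple(sorted(rec.human_reg)),
                mouse_reg=tuple(sorted(rec.mouse_reg)),
                mirna=tuple(m for m, _ in rec.mirna_hits),
            )
        )
    rows.sort(key=lambda r: (r.gene_symbol, r.rs_id))
    return PrioritizedTable(rows)
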