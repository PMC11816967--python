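"""Readers and writers for every external format the pipeline touches.

All coordinates are normalized to the internal 0-based half-open
convention at this boundary: BED/bedGraph and chain files are native;
GFF3, chip manifests, WGS SNP tables and QTL/ortholog tables declare
1-based coordinates and are shifted on read (and shifted back on write).
Readers accept either literal text (``read_*``) or a path, optionally
gzip-compressed (``load_*``).
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import gffutils
import pandas as pd
from Bio import SeqIO

from .core import (
    GenomicInterval,
    ScoreTrack,
    ValidationError,
    Variant,
    point,
)
from .crosslift import ChainAlignment, RegulatoryFeature
from .genes import GeneModel, Transcript
from .mirna import Mirna
from .prioritize import LDPair, OrthologRow, PrioritizedTable, QTLRecord


class ParseError(ValidationError):
    pass


class SchemaError(ValidationError):
    pass


def _read_path(path: Union[str, Path]) -> str:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return fh.read()
    return path.read_text()


# ---------------------------------------------------------------------------
# BED intervals

def read_intervals(text: str) -> list[GenomicInterval]:
    """Parse BED (3-6 column) content; 0-based half-open, column 6 = strand."""
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"BED line {lineno}: fewer than 3 tab-separated fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"BED line {lineno}: non-integer coordinates") from exc
        strand = fields[5] if len(fields) >= 6 else "."
        try:
            out.append(GenomicInterval(fields[0], start, end, strand))
        except ValidationError as exc:
            raise ValidationError(f"BED line {lineno}: {exc}") from exc
    return out


def write_intervals(ivs: Iterable[GenomicInterval]) -> str:
    lines = []
    for iv in ivs:
        if iv.strand == ".":
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}")
        else:
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def load_intervals(path: Union[str, Path]) -> list[GenomicInterval]:
    return read_intervals(_read_path(path))


# ---------------------------------------------------------------------------
# bedGraph score tracks

def read_score_track(text: str) -> ScoreTrack:
    """Parse bedGraph content into a run-length score track."""
    track = ScoreTrack()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"bedGraph line {lineno}: expected 4 columns")
        try:
            start, end, score = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(f"bedGraph line {lineno}: numeric parse failure") from exc
        track.add(GenomicInterval(fields[0], start, end), score)
    track._ensure_sorted()  # surfaces overlap violations eagerly
    return track


def write_score_track(track: ScoreTrack) -> str:
    lines = [f"{iv.chrom}\t{iv.start}\t{iv.end}\t{format(score, 'g')}"
             for iv, score in track.items()]
    return "\n".join(lines) + ("\n" if lines else "")


def load_score_track(path: Union[str, Path]) -> ScoreTrack:
    return read_score_track(_read_path(path))


# ---------------------------------------------------------------------------
# UCSC chain files

def read_chain(text: str) -> list[ChainAlignment]:
    """Parse UCSC chain content; block-sum invariants are checked per chain."""
    chains: list[ChainAlignment] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if not line.startswith("chain"):
            raise ParseError(f"chain line {i}: expected 'chain' header, got {line!r}")
        parts = line.split()
        if len(parts) != 13:
            raise ParseError(f"chain line {i}: header needs 13 fields")
        (_, score, t_name, _t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = parts
        if t_strand != "+":
            raise ParseError(f"chain {chain_id}: source strand must be '+'")
        blocks: list[tuple[int, int, int]] = []
        while i < len(lines):
            row = lines[i].strip()
            i += 1
            if not row:
                break
            nums = row.split()
            if len(nums) == 1:
                blocks.append((int(nums[0]), 0, 0))
                break
            if len(nums) != 3:
                raise ParseError(f"chain {chain_id}: malformed block line {row!r}")
            blocks.append((int(nums[0]), int(nums[1]), int(nums[2])))
        if not blocks:
            raise ParseError(f"chain {chain_id}: no alignment blocks")
        chains.append(
            ChainAlignment(
                chain_id=int(chain_id),
                score=float(score),
                source=GenomicInterval(t_name, int(t_start), int(t_end)),
                target_chrom=q_name,
                target_size=int(q_size),
                target_start=int(q_start),
                target_end=int(q_end),
                target_strand=q_strand,
                blocks=tuple(blocks),
            )
        )
    return chains


def write_chain(chains: Sequence[ChainAlignment], source_sizes: dict[str, int]) -> str:
    out = []
    for c in chains:
        out.append(
            f"chain {format(c.score, 'g')} {c.source.chrom} "
            f"{source_sizes[c.source.chrom]} + {c.source.start} {c.source.end} "
            f"{c.target_chrom} {c.target_size} {c.target_strand} "
            f"{c.target_start} {c.target_end} {c.chain_id}"
        )
        for size, gs, gt in c.blocks[:-1]:
            out.append(f"{size} {gs} {gt}")
        out.append(str(c.blocks[-1][0]))
        out.append("")
    return "\n".join(out) + ("\n" if out else "")


def load_chain(path: Union[str, Path]) -> list[ChainAlignment]:
    return read_chain(_read_path(path))


# ---------------------------------------------------------------------------
# FASTA

def read_genome(text: str) -> dict[str, str]:
    """FASTA content -> {chrom: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(_io.StringIO(text), "fasta")
    }


def write_genome(genome: dict[str, str], width: int = 70) -> str:
    parts = []
    for chrom in sorted(genome):
        parts.append(f">{chrom}")
        seq = genome[chrom]
        parts.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(parts) + "\n"


def load_genome(path: Union[str, Path]) -> dict[str, str]:
    return read_genome(_read_path(path))


# ---------------------------------------------------------------------------
# GFF3 gene models and regulatory builds

def read_gene_models(text: str) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS/UTR features into gene models."""
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        symbol = g.attributes.get("Name", [g.id])[0]
        transcripts = []
        for tx in db.children(g, featuretype="mRNA"):
            def ivs(ftype: str) -> tuple[GenomicInterval, ...]:
                return tuple(
                    GenomicInterval(f.seqid, f.start - 1, f.end, g.strand)
                    for f in db.children(tx, featuretype=ftype)
                )
            transcripts.append(
                Transcript(
                    transcript_id=tx.id,
                    exons=ivs("exon"),
                    cds=ivs("CDS"),
                    utr5=ivs("five_prime_UTR"),
                    utr3=ivs("three_prime_UTR"),
                )
            )
        if not transcripts:
            continue
        genes.append(
            GeneModel(
                gene_id=g.id,
                symbol=symbol,
                span=GenomicInterval(g.seqid, g.start - 1, g.end, g.strand),
                transcripts=tuple(transcripts),
            )
        )
    return sorted(genes, key=lambda x: (x.span.chrom, x.span.start, x.gene_id))


def load_gene_models(path: Union[str, Path]) -> list[GeneModel]:
    return read_gene_models(_read_path(path))


def write_gene_models(genes: Sequence[GeneModel]) -> str:
    """Serialize gene models back to GFF3 (1-based inclusive on write)."""

    def line(chrom, ftype, iv, attrs, strand):
        return (
            f"{chrom}\t.\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\t{attrs}"
        )

    out = ["##gff-version 3"]
    for g in genes:
        chrom, strand = g.span.chrom, g.strand
        out.append(line(chrom, "gene", g.span, f"ID={g.gene_id};Name={g.symbol}", strand))
        for tx in g.transcripts:
            out.append(line(chrom, "mRNA", tx.span,
                            f"ID={tx.transcript_id};Parent={g.gene_id}", strand))
            for ftype, ivs in (
                ("exon", tx.exons), ("CDS", tx.cds),
                ("five_prime_UTR", tx.utr5), ("three_prime_UTR", tx.utr3),
            ):
                for k, iv in enumerate(ivs):
                    out.append(line(chrom, ftype, iv,
                                    f"ID={tx.transcript_id}.{ftype}.{k};"
                                    f"Parent={tx.transcript_id}", strand))
    return "\n".join(out) + "\n"


def read_regulatory_features(text: str) -> list[RegulatoryFeature]:
    """GFF3 with the feature class in column 3 (Ensembl regulatory build style)."""
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"regulatory GFF line {lineno}: fewer than 5 columns")
        try:
            start, end = int(fields[3]) - 1, int(fields[4])
        except ValueError as exc:
            raise ParseError(f"regulatory GFF line {lineno}: bad coordinates") from exc
        out.append(RegulatoryFeature(GenomicInterval(fields[0], start, end), fields[2]))
    return out


def load_regulatory_features(path: Union[str, Path]) -> list[RegulatoryFeature]:
    return read_regulatory_features(_read_path(path))


def write_regulatory_features(features: Sequence[RegulatoryFeature]) -> str:
    lines = [
        f"{f.interval.chrom}\t.\t{f.feature_class}\t{f.interval.start + 1}"
        f"\t{f.interval.end}\t.\t.\t.\t."
        for f in features
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# TSV dialects

_SCHEMAS = {
    "manifest": ["marker_id", "rs_id", "chrom", "pos", "ref", "alt"],
    "wgs": ["rs_id", "chrom", "pos", "ref", "alt"],
    "ld": ["snp_a", "snp_b", "r2"],
    "tfbs": ["rs_id", "effect"],
    "polya": ["chrom", "start", "end"],
    "qtl": ["species", "trait", "trait_class", "chrom", "start", "end"],
    "ortholog": ["horse_gene_id", "species", "target_gene_id", "chrom", "start", "end"],
}


def _check_schema(df: pd.DataFrame, dialect: str) -> None:
    missing = [c for c in _SCHEMAS[dialect] if c not in df.columns]
    if missing:
        raise SchemaError(f"{dialect} table missing required columns: {missing}")


def read_tables(source: str, dialect: str):
    """Parse one of the pipeline's TSV dialects (or a mature-miRNA FASTA).

    Chip-manifest, WGS, QTL and ortholog coordinates are declared 1-based
    in the files and converted to the internal 0-based convention here.
    """
    if dialect == "mirna_fasta":
        return [
            Mirna(rec.id, str(rec.seq))
            for rec in SeqIO.parse(_io.StringIO(source), "fasta")
        ]
    if dialect not in _SCHEMAS:
        raise SchemaError(f"unknown table dialect {dialect!r}")
    df = pd.read_csv(_io.StringIO(source), sep="\t", dtype=str).fillna("")
    _check_schema(df, dialect)

    if dialect == "manifest":
        return [
            Variant(
                rs_id=r.rs_id, site=point(r.chrom, int(r.pos) - 1),
                ref=r.ref, alt=r.alt, marker_id=r.marker_id,
            )
            for r in df.itertuples()
        ]
    if dialect == "wgs":
        return [
            Variant(rs_id=r.rs_id, site=point(r.chrom, int(r.pos) - 1),
                    ref=r.ref, alt=r.alt)
            for r in df.itertuples()
        ]
    if dialect == "ld":
        return [LDPair(r.snp_a, r.snp_b, float(r.r2)) for r in df.itertuples()]
    if dialect == "tfbs":
        table: dict[str, set[str]] = {}
        for r in df.itertuples():
            table.setdefault(r.rs_id, set()).add(r.effect)
        return table
    if dialect == "polya":
        # BED-like: already 0-based half-open
        return [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]
    if dialect == "qtl":
        return [
            QTLRecord(r.species, r.trait, r.trait_class,
                      GenomicInterval(r.chrom, int(r.start) - 1, int(r.end)))
            for r in df.itertuples()
        ]
    if dialect == "ortholog":
        rows = [
            OrthologRow(r.horse_gene_id, r.species, r.target_gene_id,
                        GenomicInterval(r.chrom, int(r.start) - 1, int(r.end)))
            for r in df.itertuples()
        ]
        seen = set()
        for row in rows:
            key = (row.horse_gene_id, row.species, row.target_gene_id)
            if key in seen:
                raise ValidationError(f"duplicate ortholog row {key}")
            seen.add(key)
        return rows
    raise AssertionError("unreachable")


def load_tables(path: Union[str, Path], dialect: str):
    return read_tables(_read_path(path), dialect)


def write_table(rows, dialect: str) -> str:
    """Inverse of read_tables for the TSV dialects (round-trip identity)."""
    if dialect == "manifest":
        df = pd.DataFrame(
            [(v.marker_id, v.rs_id, v.chrom, v.pos + 1, v.ref, v.alt) for v in rows],
            columns=_SCHEMAS["manifest"],
        )
    elif dialect == "wgs":
        df = pd.DataFrame(
            [(v.rs_id, v.chrom, v.pos + 1, v.ref, v.alt) for v in rows],
            columns=_SCHEMAS["wgs"],
        )
    elif dialect == "ld":
        df = pd.DataFrame(
            [(p.snp_a, p.snp_b, format(p.r2, "g")) for p in rows],
            columns=_SCHEMAS["ld"],
        )
    elif dialect == "tfbs":
        flat = [(rs, eff) for rs, effs in sorted(rows.items()) for eff in sorted(effs)]
        df = pd.DataFrame(flat, columns=_SCHEMAS["tfbs"])
    elif dialect == "polya":
        df = pd.DataFrame(
            [(iv.chrom, iv.start, iv.end) for iv in rows], columns=_SCHEMAS["polya"]
        )
    elif dialect == "qtl":
        df = pd.DataFrame(
            [(q.species, q.trait, q.trait_class, q.interval.chrom,
              q.interval.start + 1, q.interval.end) for q in rows],
            columns=_SCHEMAS["qtl"],
        )
    elif dialect == "ortholog":
        df = pd.DataFrame(
            [(o.horse_gene_id, o.species, o.target_gene_id, o.interval.chrom,
              o.interval.start + 1, o.interval.end) for o in rows],
            columns=_SCHEMAS["ortholog"],
        )
    else:
        raise SchemaError(f"unknown table dialect {dialect!r}")
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def write_mirna_fasta(mirnas: Sequence[Mirna]) -> str:
    return "".join(f">{m.mirna_id}\n{m.sequence}\n" for m in mirnas)


# ---------------------------------------------------------------------------
# Packaged final-report fixture

FIXTURE_NAME = "prioritized_snps.tsv"
FIXTURE_ROWS = 31


def read_final_table_fixture() -> PrioritizedTable:
    """The packaged prioritized-variant report (checksum- and count-verified)."""
    text = resources.files("equiprio.data").joinpath(FIXTURE_NAME).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("# sha256:"):
        raise ValidationError("fixture is missing its checksum header")
    expected = lines[0].split(":", 1)[1].strip()
    body = "\n".join(lines[1:]) + "\n"
    digest = hashlib.sha256(body.encode()).hexdigest()
    if digest != expected:
        raise ValidationError("fixture checksum mismatch: file has been altered")
    table = PrioritizedTable.from_tsv(body)
    if len(table.rows) != FIXTURE_ROWS:
        raise ValidationError(
            f"fixture row count {len(table.rows)} != packaged value {FIXTURE_ROWS}"
        )
    return table
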