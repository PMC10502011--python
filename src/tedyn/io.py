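"""Readers and writers for the standard formats used by the pipeline.

FASTA is handled through Biopython, tabular formats through pandas.  GFF3 is
1-based closed on disk and converted to the internal 0-based half-open
convention on read (and back on write).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CompartmentMap,
    Contig,
    GeneFeature,
    GenomeAssembly,
    HitRecord,
    Interval,
    TECopy,
    ValidationError,
)

#: Column names of the 12-column tabular hit dialect (BLAST outfmt 6).  A
#: 13th ``qlen`` column, when present, is used to derive the gapless query
#: coverage (qend - qstart + 1) / qlen; without it coverage is NaN.
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, Contig]:
    contigs: dict[str, Contig] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ParseError(f"{path}: duplicate contig id {rec.id}")
        contigs[rec.id] = Contig(rec.id, str(rec.seq).upper())
    return contigs


def write_fasta(contigs: dict[str, Contig], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="")
        for c in contigs.values()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (genes in, TE annotations out)

def read_genes_gff3(path: str | os.PathLike) -> list[GeneFeature]:
    """Parse gene features from a GFF3 file.

    The optional evolutionary-stratum label is read from a ``stratum``
    attribute (case-insensitive key).
    """
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}:{lineno}: bad coordinates {start1}..{end1}")
            attr_map = _parse_attributes(attrs, path, lineno)
            gene_id = attr_map.get("ID") or attr_map.get("id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene without ID attribute")
            stratum = None
            for key, val in attr_map.items():
                if key.lower() == "stratum":
                    stratum = val
            genes.append(
                GeneFeature(
                    Interval(seqid, start1 - 1, end1, strand if strand in "+-" else "."),
                    gene_id=gene_id,
                    stratum_label=stratum,
                )
            )
    return genes


def _parse_attributes(attrs: str, path, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attrs.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ParseError(f"{path}:{lineno}: malformed attribute {part!r}")
        key, val = part.split("=", 1)
        out[key] = val
    return out


def write_genes_gff3(genes: Iterable[GeneFeature], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.interval.contig_id, g.interval.start)):
            attrs = f"ID={g.gene_id}"
            if g.stratum_label is not None:
                attrs += f";stratum={g.stratum_label}"
            fh.write(
                "\t".join(
                    [
                        g.interval.contig_id, "tedyn", "gene",
                        str(g.interval.start + 1), str(g.interval.end), ".",
                        g.interval.strand if g.interval.strand != "." else ".",
                        ".", attrs,
                    ]
                )
                + "\n"
            )


def write_te_gff3(copies: Iterable[TECopy], path: str | os.PathLike) -> None:
    """Write annotated TE copies with a ``category=`` attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in sorted(copies, key=lambda c: (c.interval.contig_id, c.interval.start)):
            attrs = f"ID={c.copy_id};category={','.join(c.categories)}"
            if c.family_id is not None:
                attrs += f";family={c.family_id}"
            if c.compartment is not None:
                attrs += f";compartment={c.compartment}"
            fh.write(
                "\t".join(
                    [
                        c.interval.contig_id, "tedyn", "transposable_element",
                        str(c.interval.start + 1), str(c.interval.end), ".",
                        c.interval.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


def read_te_gff3(path: str | os.PathLike) -> list[TECopy]:
    copies: list[TECopy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "transposable_element":
                continue
            attr_map = _parse_attributes(attrs, path, lineno)
            copies.append(
                TECopy(
                    copy_id=attr_map["ID"],
                    interval=Interval(seqid, int(start) - 1, int(end),
                                      strand if strand in "+-" else "."),
                    categories=attr_map.get("category", "unclassified").split(","),
                    family_id=attr_map.get("family"),
                    compartment=attr_map.get("compartment"),
                )
            )
    return copies


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | os.PathLike) -> list[Interval]:
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                intervals.append(Interval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike,
              names: Optional[Iterable[str]] = None) -> None:
    rows = list(intervals)
    name_list = list(names) if names is not None else [""] * len(rows)
    order = sorted(range(len(rows)), key=lambda i: (rows[i].contig_id, rows[i].start))
    with open(path, "w") as fh:
        for i in order:
            iv = rows[i]
            line = f"{iv.contig_id}\t{iv.start}\t{iv.end}"
            if name_list[i]:
                line += f"\t{name_list[i]}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Tabular hit format

def read_hit_table(path: str | os.PathLike) -> list[HitRecord]:
    """Read a 12-column tabular hit file (percent identity converted to a
    fraction; rows preserved in input order).  A 13th column is interpreted
    as the query length and used to compute the gapless query coverage."""
    try:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                            float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    if frame.shape[1] not in (12, 13):
        raise ParseError(f"{path}: expected 12 or 13 columns, got {frame.shape[1]}")
    names = HIT_COLUMNS + (["qlen"] if frame.shape[1] == 13 else [])
    frame.columns = names
    numeric = [c for c in names if c not in ("qseqid", "sseqid")]
    for col in numeric:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ParseError(f"{path}: non-numeric value in column {col}, row {row}")
        frame[col] = converted
    records: list[HitRecord] = []
    for row in frame.itertuples(index=False):
        sstart, send = int(row.sstart), int(row.send)
        strand = "+" if sstart <= send else "-"
        lo, hi = min(sstart, send), max(sstart, send)
        if frame.shape[1] == 13 and row.qlen > 0:
            coverage = (row.qend - row.qstart + 1) / row.qlen
        else:
            coverage = float("nan")
        records.append(
            HitRecord(
                query_id=str(row.qseqid),
                subject_contig=str(row.sseqid),
                identity=row.pident / 100.0,
                aln_length=int(row.length),
                gapless_query_coverage=coverage,
                evalue=float(row.evalue),
                subject_interval=Interval(str(row.sseqid), lo - 1, hi, strand),
            )
        )
    return records


def write_hit_table(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# assemblies and result sets

def read_assembly(fasta_path, gff_path=None, bed_paths: Optional[dict] = None) -> GenomeAssembly:
    """Load contigs, genes and optional BED feature layers into one assembly.

    Raises a validation error when a feature extends beyond its contig.
    """
    contigs = read_fasta(fasta_path)
    genes = read_genes_gff3(gff_path) if gff_path is not None else []
    layers = {
        name: read_bed(path) for name, path in (bed_paths or {}).items()
    }
    return GenomeAssembly(contigs=contigs, genes=genes, bed_layers=layers)


def write_assembly(assembly: GenomeAssembly, fasta_path, gff_path=None) -> None:
    write_fasta(assembly.contigs, fasta_path)
    if gff_path is not None:
        write_genes_gff3(assembly.genes, gff_path)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | os.PathLike,
                  compartments: Optional[CompartmentMap] = None) -> list[Path]:
    """Write result tables as TSV (deterministic column order) and the
    compartment map as BED; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        path = out / f"{name}.tsv"
        tables[name].to_csv(path, sep="\t", index=False)
        written.append(path)
    if compartments is not None:
        path = out / "compartments.bed"
        frame = compartments.to_frame().sort_values(["contig", "start"])
        with open(path, "w") as fh:
            for row in frame.itertuples(index=False):
                fh.write(f"{row.contig}\t{row.start}\t{row.end}\t{row.label}\n")
        written.append(path)
    return written
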