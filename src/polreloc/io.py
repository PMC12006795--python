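"""Readers and writers for the standard genomics text formats.

GFF3 is 1-based closed on disk and converted to the package's 0-based
half-open coordinates exactly once on read (and back once on write). BED,
narrowPeak, and bedGraph are already 0-based half-open and pass through.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    flag_rp_genes,
)


class FormatError(ValueError):
    """A format violation, reporting the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _open(source, mode: str = "r") -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, mode)
    return source


# ---------------------------------------------------------------------------
# GFF3

_GENE_TYPES = {"gene", "mRNA", "tRNA", "tRNA_gene", "snRNA", "ncRNA", "rRNA"}
_TYPE_TO_BIOTYPE = {
    "gene": "mRNA",
    "mRNA": "mRNA",
    "tRNA": "tRNA",
    "tRNA_gene": "tRNA",
    "snRNA": "snRNA",
    "ncRNA": "ncRNA",
    "rRNA": "rRNA",
}
_BIOTYPE_TO_TYPE = {
    "mRNA": "gene",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "ncRNA": "ncRNA",
    "rRNA": "rRNA",
    "other": "gene",
}


def _parse_attributes(field: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for item in field.rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"malformed GFF3 attribute {item!r}", lineno)
        k, v = item.split("=", 1)
        attrs[k] = v
    return attrs


def load_annotation(
    gff_source, rp_gene_ids: Iterable[str] = (), chrom_lengths: dict | None = None
) -> GenomeAnnotation:
    """Load a GFF3 annotation into a :class:`GenomeAnnotation`.

    Gene-level features (types gene/mRNA/tRNA/snRNA/ncRNA/rRNA) become
    :class:`GeneModel` rows; CDS features attach to their gene via the
    ``Parent`` attribute. Chromosome lengths come from ``##sequence-region``
    pragmas unless supplied explicitly. 1-based closed GFF coordinates are
    converted to 0-based half-open. Genes listed in ``rp_gene_ids`` are
    flagged ``is_rp``; ids absent from the file produce a warning.
    """
    handle = _open(gff_source)
    lengths: dict[str, int] = dict(chrom_lengths or {})
    genes: dict[str, GeneModel] = {}
    cds_parts: dict[str, list[tuple[int, int, str]]] = {}
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise FormatError("malformed ##sequence-region pragma", lineno)
                lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"expected 9 tab-separated columns, got {len(cols)}", lineno
                )
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attr = cols
            try:
                start1, end1 = int(start1), int(end1)
            except ValueError:
                raise FormatError("non-integer coordinates", lineno) from None
            if start1 < 1 or end1 < start1:
                raise FormatError(
                    f"invalid 1-based coordinates {start1}..{end1}", lineno
                )
            attrs = _parse_attributes(attr, lineno)
            start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
            if ftype in _GENE_TYPES:
                gid = attrs.get("ID") or attrs.get("Name")
                if gid is None:
                    raise FormatError("gene feature lacks ID attribute", lineno)
                if gid in genes:
                    raise FormatError(f"duplicate gene_id {gid!r}", lineno)
                if strand not in ("+", "-"):
                    raise FormatError(f"gene {gid!r}: invalid strand {strand!r}", lineno)
                biotype = attrs.get("biotype", _TYPE_TO_BIOTYPE[ftype])
                genes[gid] = GeneModel(
                    gene_id=gid,
                    interval=Interval(chrom, start, end),
                    strand=strand,
                    biotype=biotype,
                )
            elif ftype == "CDS":
                parent = attrs.get("Parent") or attrs.get("ID")
                if parent is None:
                    raise FormatError("CDS lacks Parent attribute", lineno)
                cds_parts.setdefault(parent, []).append((start, end, chrom))
    finally:
        if isinstance(gff_source, (str, Path)):
            handle.close()

    models = []
    for gid, g in genes.items():
        parts = cds_parts.get(gid)
        if parts:
            s = min(p[0] for p in parts)
            e = max(p[1] for p in parts)
            g = GeneModel(
                gene_id=g.gene_id,
                interval=g.interval,
                strand=g.strand,
                biotype=g.biotype,
                cds=Interval(parts[0][2], s, e),
            )
        models.append(g)
    models = flag_rp_genes(models, rp_gene_ids)
    if not lengths:
        # fall back to covering intervals when no pragmas are present
        for g in models:
            c = g.interval.chrom
            lengths[c] = max(lengths.get(c, 0), g.interval.end)
    return GenomeAnnotation(chrom_lengths=lengths, genes=models)


def write_gff3(annotation: GenomeAnnotation, dest) -> None:
    """Write an annotation as GFF3 (coordinates back to 1-based closed)."""
    handle = _open(dest, "w")
    try:
        handle.write("##gff-version 3\n")
        for chrom, length in annotation.chrom_lengths.items():
            handle.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in annotation.genes:
            ftype = _BIOTYPE_TO_TYPE.get(g.biotype, "gene")
            iv = g.interval
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            if g.is_rp:
                attrs += ";rp=true"
            handle.write(
                f"{iv.chrom}\tpolreloc\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            if g.cds is not None:
                handle.write(
                    f"{g.cds.chrom}\tpolreloc\tCDS\t{g.cds.start + 1}\t{g.cds.end}"
                    f"\t.\t{g.strand}\t0\tParent={g.gene_id}\n"
                )
    finally:
        if isinstance(dest, (str, Path)):
            handle.close()


# ---------------------------------------------------------------------------
# BED6 / narrowPeak / bedGraph

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_COLUMNS = BED6_COLUMNS + ["signalValue", "pValue", "qValue", "peak"]


def read_bed6(source) -> pd.DataFrame:
    df = pd.read_csv(
        source, sep="\t", header=None, comment="#", dtype={0: str}
    )
    if df.shape[1] < 3:
        raise FormatError(f"BED needs >=3 columns, got {df.shape[1]}")
    df = df.reindex(columns=range(6))
    df.columns = BED6_COLUMNS
    df["name"] = df["name"].fillna(".")
    df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(0)
    df["strand"] = df["strand"].fillna(".")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed6(df: pd.DataFrame, dest) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(dest, sep="\t", header=False, index=False)


def read_narrowpeak(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] != 10:
        raise FormatError(
            f"narrowPeak requires 10 columns, got {df.shape[1]}"
        )
    df.columns = NARROWPEAK_COLUMNS
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_narrowpeak(df: pd.DataFrame, dest) -> None:
    df.loc[:, NARROWPEAK_COLUMNS].to_csv(dest, sep="\t", header=False, index=False)


def read_bedgraph(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] != 4:
        raise FormatError(f"bedGraph requires 4 columns, got {df.shape[1]}")
    df.columns = ["chrom", "start", "end", "value"]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bedgraph(df: pd.DataFrame, dest) -> None:
    df.loc[:, ["chrom", "start", "end", "value"]].to_csv(
        dest, sep="\t", header=False, index=False
    )


def intervals_to_bed(intervals: Sequence, names: Sequence[str] | None = None) -> pd.DataFrame:
    rows = []
    for i, iv in enumerate(intervals):
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": names[i] if names is not None else f"region_{i}",
                "score": 0,
                "strand": ".",
            }
        )
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def bed_to_intervals(df: pd.DataFrame) -> list[Interval]:
    return [Interval(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# FASTA / plain lists / TSV

def read_fasta(source) -> dict[str, str]:
    handle = _open(source)
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if isinstance(source, (str, Path)):
            handle.close()


def write_fasta(sequences: dict[str, str], dest) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    handle = _open(dest, "w")
    try:
        SeqIO.write(records, handle, "fasta")
    finally:
        if isinstance(dest, (str, Path)):
            handle.close()


def read_gene_list(source) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    handle = _open(source)
    try:
        return {
            line.strip()
            for line in handle
            if line.strip() and not line.startswith("#")
        }
    finally:
        if isinstance(source, (str, Path)):
            handle.close()


def read_counts_tsv(source) -> pd.DataFrame:
    """Gene x sample integer count table (first column = gene_id index)."""
    df = pd.read_csv(source, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError("counts must be non-negative")
    return df


def read_design_tsv(source) -> pd.DataFrame:
    """Design table with columns sample, condition, replicate."""
    df = pd.read_csv(source, sep="\t")
    required = {"sample", "condition"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"design requires columns {sorted(required)}, got {list(df.columns)}"
        )
    return df
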