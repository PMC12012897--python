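"""Readers and writers for the plain-text formats the pipeline consumes.

Internal coordinates are 0-based half-open; GFF3 input (1-based inclusive)
is converted on read so BED files round-trip bit-exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .intervals import GeneModel, GenomicInterval, TEFeature

PathLike = Union[str, Path]


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6; extra columns are ignored, strand kept when present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_peak_bed(path: PathLike) -> list[tuple[GenomicInterval, float]]:
    """Read a narrowPeak-like BED: chrom, start, end, name, read count."""
    out: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            count = float(parts[4]) if len(parts) > 4 else float(parts[3])
            out.append((GenomicInterval(parts[0], int(parts[1]), int(parts[2])), count))
    return out


def write_peak_bed(
    peaks: Iterable[tuple[GenomicInterval, float]], path: PathLike, name_prefix: str = "peak"
) -> None:
    with open(path, "w") as fh:
        for i, (iv, count) in enumerate(peaks):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_prefix}{i}\t{count:g}\n")


def read_te_bed(path: PathLike) -> list[TEFeature]:
    """TE BED: chrom, start, end [, class]."""
    out: list[TEFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            te_class = parts[3] if len(parts) > 3 else "unknown"
            out.append(TEFeature(GenomicInterval(parts[0], int(parts[1]), int(parts[2])), te_class))
    return out


def write_te_bed(tes: Iterable[TEFeature], path: PathLike) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.te_class}\n")


def _gff3_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for item in raw.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3_genes(path: PathLike) -> list[GeneModel]:
    """Read ``gene`` features from GFF3 (1-based inclusive -> half-open)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = _gff3_attributes(parts[8])
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"gene feature without ID attribute: {line!r}")
            strand = parts[6] if parts[6] in ("+", "-") else "."
            iv = GenomicInterval(parts[0], int(parts[3]) - 1, int(parts[4]), strand)
            genes.append(GeneModel(gene_id, iv))
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(
                f"{iv.chrom}\tallohybrid\tgene\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_homolog_pairs(path: PathLike) -> list[tuple[str, str]]:
    """Two-column TSV (A_gene_id, C_gene_id), optional header starting with '#'."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, c = line.split("\t")[:2]
            pairs.append((a, c))
    return pairs


def write_homolog_pairs(pairs: Iterable[tuple[str, str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#A_gene_id\tC_gene_id\n")
        for a, c in pairs:
            fh.write(f"{a}\t{c}\n")


def read_counts_tsv(path: PathLike) -> pd.DataFrame:
    """Gene-count table: gene_id, length, then one column per sample replicate."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise ValueError("counts table must have a 'length' column")
    return df


def write_counts_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


CX_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]


def read_cx_report(path: PathLike) -> pd.DataFrame:
    """CX-report-style per-cytosine calls: chrom, pos(0-based), strand, context,
    methylated count, unmethylated count."""
    df = pd.read_csv(path, sep="\t", names=CX_COLUMNS, comment="#")
    bad = ~df["context"].isin(["CG", "CHG", "CHH"])
    if bad.any():
        raise ValueError(f"unknown methylation context(s): {sorted(df.loc[bad, 'context'].unique())}")
    return df


def write_cx_report(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=CX_COLUMNS)


def read_srna_bed(path: PathLike) -> pd.DataFrame:
    """sRNA mapped reads: chrom, start, end, length(nt) columns."""
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "length"], comment="#"
    )
    return df


def write_srna_bed(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(
        path, sep="\t", header=False, index=False, columns=["chrom", "start", "end", "length"]
    )
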