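"""Gene models and annotation IO.

A gene set is represented as a :class:`pandas.DataFrame` with columns
``gene_id``, ``chrom``, ``tss``, ``strand``, ``body_end``.  Coordinates are
0-based; ``tss`` is the strand-aware 5' end of the transcript, so for a
minus-strand gene ``tss > body_end``.  Transcript offsets are measured from
the TSS with downstream positive on both strands.
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "body_end"]


class AnnotationError(ValueError):
    pass


def validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Check the gene table invariants; return the (unchanged) table."""
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise AnnotationError(f"gene table lacks columns: {missing}")
    bad_strand = genes.loc[~genes["strand"].isin(["+", "-"]), "gene_id"]
    if len(bad_strand):
        raise AnnotationError(f"invalid strand for genes: {list(bad_strand[:5])}")
    plus = genes["strand"] == "+"
    bad = genes.loc[(plus & (genes["tss"] >= genes["body_end"]))
                    | (~plus & (genes["tss"] <= genes["body_end"])), "gene_id"]
    if len(bad):
        raise AnnotationError(
            f"tss/body_end violate strand orientation for genes: {list(bad[:5])}")
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].unique()
        raise AnnotationError(f"duplicate gene ids: {list(dups[:5])}")
    return genes


def body_length(genes: pd.DataFrame) -> pd.Series:
    """Transcript length in bp (always positive)."""
    return (genes["body_end"] - genes["tss"]).abs()


# ---------------------------------------------------------------------------
# readers


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read genes from BED6 (0-based half-open; TSS = strand-aware 5' end)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end", "name", "score", "strand"],
                      usecols=range(6),
                      dtype={"chrom": str, "name": str, "strand": str})
    plus = bed["strand"] == "+"
    tss = bed["start"].where(plus, bed["end"] - 1)
    body_end = bed["end"].where(plus, bed["start"] - 1)
    genes = pd.DataFrame({"gene_id": bed["name"], "chrom": bed["chrom"],
                          "tss": tss.astype(int), "strand": bed["strand"],
                          "body_end": body_end.astype(int)})
    return validate_genes(genes)


def read_genes_gff3(path: str | Path) -> pd.DataFrame:
    """Read ``gene`` records from GFF3 (1-based inclusive, converted to 0-based)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or fields[2] != "gene":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = fields
            gene_id = None
            for item in attrs.split(";"):
                key, _, value = item.partition("=")
                if key.strip() in ("ID", "gene_id", "Name") and gene_id is None:
                    gene_id = value.strip()
            if gene_id is None:
                gene_id = f"gene_at_{chrom}_{start}"
            start0, end0 = int(start) - 1, int(end) - 1  # inclusive ends
            if strand == "-":
                tss, body_end = end0, start0 - 1
            else:
                tss, body_end = start0, end0 + 1
            rows.append((gene_id, chrom, tss, strand, body_end))
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return validate_genes(genes)


def read_genes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return read_genes_gff3(path)
    return read_genes_bed(path)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV (name, length) -> dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    return sizes


# ---------------------------------------------------------------------------
# writers


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def _gene_interval(row) -> tuple[int, int]:
    """0-based half-open genomic interval of a gene body."""
    if row.strand == "+":
        return int(row.tss), int(row.body_end)
    return int(row.body_end) + 1, int(row.tss) + 1


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """BED6 writer; interval is the gene body, score 0."""
    buf = io.StringIO()
    for row in genes.itertuples(index=False):
        start, end = _gene_interval(row)
        buf.write(f"{row.chrom}\t{start}\t{end}\t{row.gene_id}\t0\t{row.strand}\n")
    Path(path).write_text(buf.getvalue())


def write_genes_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Minimal GFF3 writer (one ``gene`` record per gene, 1-based inclusive)."""
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for row in genes.itertuples(index=False):
        start, end = _gene_interval(row)
        buf.write(f"{row.chrom}\tnucorg\tgene\t{start + 1}\t{end}\t.\t"
                  f"{row.strand}\t.\tID={row.gene_id}\n")
    Path(path).write_text(buf.getvalue())
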