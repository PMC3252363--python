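"""Readers and writers for the plain-text genomic formats used by the pipeline.

Everything here is deliberately simple: BED is tab-separated text with 0-based
half-open coordinates, chromosome sizes are two-column TSV, and the GTF writer
emits only ``exon`` features carrying ``gene_id``/``transcript_id``/
``exon_number`` attributes (the subset the annotation model needs).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_fragments_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    """Write fragment intervals as BED6 (name/score filled with placeholders)."""
    df = fragments.copy()
    if "name" not in df:
        df["name"] = "."
    if "score" not in df:
        df["score"] = 0
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file; the strand column (6th) defaults to '.' if absent."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    df.columns = BED6_COLUMNS[:ncol]
    if "strand" not in df:
        df["strand"] = "."
    return df[["chrom", "start", "end", "strand"]]


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_annotation_gtf(exons: pd.DataFrame, path: str | Path) -> None:
    """Write exon features as GTF (1-based inclusive coordinates on output)."""
    with open(path, "w") as fh:
        for row in exons.itertuples(index=False):
            attrs = (
                f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}"; '
                f'exon_number "{row.exon_number}"; exon_id "{row.exon_id}";'
            )
            fh.write(
                f"{row.chrom}\tsynthetic\texon\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_annotation_gtf(path: str | Path) -> pd.DataFrame:
    """Read exon features back into the internal annotation frame (0-based)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[2] != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            rows.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[3]) - 1,
                    "end": int(fields[4]),
                    "strand": fields[6],
                    "gene_id": attrs["gene_id"],
                    "transcript_id": attrs["transcript_id"],
                    "exon_number": int(attrs["exon_number"]),
                    "exon_id": attrs.get("exon_id", ""),
                }
            )
    return pd.DataFrame(rows)


def write_table_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
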