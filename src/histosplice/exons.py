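"""Exon selection, inclusion-level labeling and decision-table assembly.

The decision system treats exons as objects, the binarized (mark, region)
calls as condition attributes, and the inclusion class as decision. An exon
enters the table only if it is internal in every transcript, at least 50 bp
long, flanked by at least 360 bp without another annotated exon, overlaps no
other exon, belongs to a gene below the top-20% expression cut, has an
inclusion level in one of the two class windows, and shows at least one
modification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CLASSES, INCLUDED, SPLICED_OUT

logger = logging.getLogger(__name__)

MIN_EXON_LENGTH = 50
MIN_INTRON_LENGTH = 360
TOP_GENE_FRACTION = 0.2
SPLICED_OUT_MAX = 0.4
INCLUDED_WINDOW = (0.9, 1.1)
UNLABELED = "unlabeled"


def select_internal_exons(
    exons: pd.DataFrame,
    min_length: int = MIN_EXON_LENGTH,
    min_intron: int = MIN_INTRON_LENGTH,
    return_audit: bool = False,
):
    """Apply the positional exon filters and measure flanking intron lengths.

    Retained exons are first or last in *no* transcript, come from
    multi-exon genes, overlap no other annotated exon, are at least
    ``min_length`` bp long and lie at least ``min_intron`` bp from the
    nearest other exon boundary on both sides (measured genome-wide, which
    makes the guarantee conservative for overlapping transcript structures).

    With ``return_audit=True`` a second frame mapping every excluded exon
    interval to its first exclusion reason is returned.
    """
    required = {"chrom", "start", "end", "strand", "gene_id", "transcript_id",
                "exon_number"}
    missing = required - set(exons.columns)
    if missing:
        raise ValueError(f"annotation is missing columns: {sorted(missing)}")

    for (tid, _), grp in exons.groupby(["transcript_id", "gene_id"], sort=False):
        grp = grp.sort_values("exon_number")
        numbers = grp["exon_number"].to_numpy()
        if not np.array_equal(numbers, np.arange(1, len(grp) + 1)):
            raise ValueError(f"transcript {tid!r} has non-consecutive exon numbers")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        strand = grp["strand"].iloc[0]
        ordered = starts if strand == "+" else starts[::-1]
        ordered_ends = ends if strand == "+" else ends[::-1]
        if np.any(np.diff(ordered) <= 0) or np.any(ordered_ends[:-1] > ordered[1:]):
            raise ValueError(f"transcript {tid!r} has unordered or overlapping exons")

    df = exons.copy()
    if "exon_id" not in df:
        df["exon_id"] = (
            df["chrom"].astype(str) + ":" + df["start"].astype(str)
            + "-" + df["end"].astype(str)
        )

    # one row per distinct exon interval per gene
    key_cols = ["chrom", "start", "end", "strand", "gene_id"]
    reasons: dict[tuple, str] = {}

    terminal_keys = set()
    for (_, gid), grp in exons.groupby(["transcript_id", "gene_id"], sort=False):
        lo = grp.loc[grp["exon_number"].idxmin()]
        hi = grp.loc[grp["exon_number"].idxmax()]
        for row in (lo, hi):
            terminal_keys.add((row["chrom"], row["start"], row["end"], row["strand"],
                               gid))

    uniq = df.drop_duplicates(subset=key_cols).reset_index(drop=True)

    gene_sizes = exons.groupby("gene_id")["exon_number"].max()
    single_exon_genes = set(gene_sizes.index[gene_sizes < 2])

    # overlap detection across all distinct intervals (any gene)
    intervals = uniq[["chrom", "start", "end"]].drop_duplicates().sort_values(
        ["chrom", "start", "end"]).reset_index(drop=True)
    overlapping = set()
    for chrom, grp in intervals.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        max_end = 0
        for i in range(len(grp)):
            if i > 0 and starts[i] < max_end:
                overlapping.add((chrom, starts[i], ends[i]))
                j = i - 1
                while j >= 0 and ends[j] > starts[i]:
                    overlapping.add((chrom, starts[j], ends[j]))
                    j -= 1
            max_end = max(max_end, ends[i])

    # nearest other exon boundary, genome-wide
    bounds = {}
    for chrom, grp in intervals.groupby("chrom", sort=False):
        bounds[chrom] = (
            np.sort(grp["start"].to_numpy()),
            np.sort(grp["end"].to_numpy()),
        )

    rows = []
    for row in uniq.itertuples(index=False):
        key = (row.chrom, row.start, row.end, row.strand, row.gene_id)
        interval = (row.chrom, row.start, row.end)
        if key in terminal_keys:
            reasons.setdefault(key, "terminal")
            continue
        if row.gene_id in single_exon_genes:
            reasons.setdefault(key, "single_exon_gene")
            continue
        if interval in overlapping:
            reasons.setdefault(key, "overlap")
            continue
        length = row.end - row.start
        if length < min_length:
            reasons.setdefault(key, "too_short")
            continue
        all_starts, all_ends = bounds[row.chrom]
        # gap to the nearest exon end at or left of this start (excluding self)
        i = np.searchsorted(all_ends, row.start, "right") - 1
        left_gap = row.start - all_ends[i] if i >= 0 else math.inf
        j = np.searchsorted(all_starts, row.end, "left")
        while j < len(all_starts) and all_starts[j] == row.start:
            j += 1
        right_gap = all_starts[j] - row.end if j < len(all_starts) else math.inf
        upstream, downstream = (
            (left_gap, right_gap) if row.strand == "+" else (right_gap, left_gap)
        )
        if upstream < min_intron or downstream < min_intron:
            reasons.setdefault(key, "short_intron")
            continue
        rows.append(
            {
                "exon_id": row.exon_id,
                "gene_id": row.gene_id,
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "strand": row.strand,
                "length": length,
                "upstream_intron": upstream,
                "downstream_intron": downstream,
            }
        )
    selected = pd.DataFrame(
        rows,
        columns=["exon_id", "gene_id", "chrom", "start", "end", "strand",
                 "length", "upstream_intron", "downstream_intron"],
    )
    if return_audit:
        audit = pd.DataFrame(
            [
                {"chrom": k[0], "start": k[1], "end": k[2], "strand": k[3],
                 "gene_id": k[4], "reason": v}
                for k, v in reasons.items()
            ]
        )
        return selected, audit
    return selected


def gene_expression(exon_expressions, top_n: int = 10) -> float:
    """Gene expression as the mean of the ``min(top_n, n)`` highest exons."""
    values = np.asarray(exon_expressions, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute gene expression from zero exons")
    k = min(top_n, values.size)
    return float(np.sort(values)[-k:].mean())


def gene_expression_table(expression: pd.DataFrame, top_n: int = 10) -> pd.Series:
    """Per-gene expression from an (exon_id, gene_id, expression) table."""
    return expression.groupby("gene_id")["expression"].apply(
        lambda v: gene_expression(v, top_n)
    )


def filter_top_genes(gene_expr: pd.Series, fraction: float = TOP_GENE_FRACTION
                     ) -> pd.Series:
    """Drop the ``ceil(fraction * N)`` highest-expressed genes.

    Ties at the cut are broken by gene id so the removal count is exact and
    deterministic even when many genes share an expression value.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    n_drop = math.ceil(fraction * len(gene_expr))
    if n_drop == 0:
        return gene_expr
    order = gene_expr.sort_index().sort_values(ascending=False, kind="stable")
    return order.iloc[n_drop:].sort_index()


def label_exons(exon_expression: pd.Series, gene_expression: pd.Series
                ) -> pd.DataFrame:
    """Inclusion levels and class labels for exons.

    Both inputs are indexed by exon id; ``gene_expression`` holds the
    expression of each exon's gene. Inclusion = exon / gene expression;
    'spliced out' below 0.4 (strict), 'included' within [0.9, 1.1]
    (closed), otherwise unlabeled.
    """
    gene_expression = gene_expression.reindex(exon_expression.index)
    if (gene_expression <= 0).any() or gene_expression.isna().any():
        bad = exon_expression.index[(gene_expression <= 0) | gene_expression.isna()]
        raise ValueError(f"non-positive gene expression for exon {bad[0]!r}")
    level = exon_expression / gene_expression
    label = pd.Series(UNLABELED, index=level.index, dtype=object)
    label[level < SPLICED_OUT_MAX] = SPLICED_OUT
    label[(level >= INCLUDED_WINDOW[0]) & (level <= INCLUDED_WINDOW[1])] = INCLUDED
    return pd.DataFrame({"inclusion_level": level, "label": label})


@dataclass
class DecisionTable:
    """Exons x binary attributes with a two-valued decision.

    ``attributes`` is a 0/1 integer frame indexed by exon id; ``decision``
    is an aligned series with values 'spliced_out' / 'included'.
    """

    attributes: pd.DataFrame
    decision: pd.Series

    def __post_init__(self):
        if not self.attributes.index.equals(self.decision.index):
            raise ValueError("attributes and decision must share an index")
        values = self.attributes.to_numpy()
        if values.size and not np.isin(values, [0, 1]).all():
            raise ValueError("attribute values must be 0/1")
        if self.attributes.columns.duplicated().any():
            raise ValueError("attribute names must be unique")
        unknown = set(self.decision.unique()) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown decision values: {sorted(unknown)}")
        self.attributes = self.attributes.astype(np.uint8)

    @property
    def n_objects(self) -> int:
        return len(self.attributes)

    @property
    def attribute_names(self) -> list[str]:
        return list(self.attributes.columns)

    def class_counts(self) -> dict[str, int]:
        counts = self.decision.value_counts()
        return {c: int(counts.get(c, 0)) for c in CLASSES}

    def subset(self, index) -> "DecisionTable":
        return DecisionTable(self.attributes.loc[index],
                             self.decision.loc[index])

    def iloc(self, positions) -> "DecisionTable":
        return DecisionTable(self.attributes.iloc[positions],
                             self.decision.iloc[positions])

    def select_attributes(self, names) -> "DecisionTable":
        return DecisionTable(self.attributes[list(names)], self.decision)

    def to_tsv(self, path: str | Path) -> None:
        df = self.attributes.copy()
        df["decision"] = self.decision
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DecisionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.drop(columns=["decision"]), df["decision"])


def drop_no_modification(table: DecisionTable) -> DecisionTable:
    """Remove exons whose attribute vector is all zero."""
    keep = table.attributes.to_numpy().sum(axis=1) > 0
    if not keep.any():
        logger.warning("all %d exons have no modification present; table is empty",
                       table.n_objects)
    return table.iloc(np.flatnonzero(keep))


def build_decision_table(labels: pd.Series, attributes: pd.DataFrame
                         ) -> DecisionTable:
    """Join class labels with the attribute matrix, keeping labeled exons only."""
    labeled = labels[labels.isin(CLASSES)]
    common = labeled.index.intersection(attributes.index)
    return DecisionTable(attributes.loc[common], labeled.loc[common])
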