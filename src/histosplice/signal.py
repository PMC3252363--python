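"""Fragment pileups and Poisson present/absent binarization of mark signals.

A ChIP-seq mark is reduced, per exon, to three binary attributes: is the mark
significantly enriched over the intronic region preceding the exon, over the
exon body, and over the succeeding intronic region. Enrichment is a one-sided
Poisson test of the fragment count in the region against the genome-wide
expected rate for that mark, so the effective cut-off automatically scales
with each mark's sequencing depth.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

DEFAULT_FRAGMENT_LENGTH = 150
DEFAULT_FLANK = 180
DEFAULT_JUNCTION_EXCLUSION = 20
DEFAULT_ALPHA = 0.05
DEFAULT_MAPPABLE_FRACTION = 0.8

REGION_SUFFIX = {"preceding": "prec", "exon": "exon", "succeeding": "succ"}


class SignalError(ValueError):
    """Raised for malformed fragments or degenerate track parameters."""


def extend_fragments(
    reads: pd.DataFrame,
    target_length: int = DEFAULT_FRAGMENT_LENGTH,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Extend (or truncate) reads to ``target_length``, anchored at the 5' end.

    Plus-strand reads keep their start; minus-strand reads keep their end.
    Reads already longer than the target are truncated from the 3' side. A
    read shorter than the target must carry a strand, otherwise the 5' end is
    ambiguous and an error naming the record is raised. When ``chrom_sizes``
    is given, fragments are clamped to ``[0, chrom_length)`` (the only case in
    which an output fragment may be shorter than ``target_length``).
    """
    start = reads["start"].to_numpy(np.int64)
    end = reads["end"].to_numpy(np.int64)
    strand = reads["strand"].to_numpy(dtype=object)
    length = end - start
    if np.any(length <= 0):
        bad = reads.index[length <= 0][0]
        raise SignalError(f"read {bad!r} has non-positive length")

    needs_strand = (length != target_length) & ~np.isin(strand, ["+", "-"])
    if needs_strand.any():
        bad = reads.index[needs_strand][0]
        raise SignalError(
            f"read {bad!r} has length != {target_length} but no strand; "
            "cannot anchor the 5' end"
        )

    minus = strand == "-"
    new_start = np.where(minus, end - target_length, start)
    new_end = new_start + target_length

    out = reads.copy()
    out["start"] = new_start
    out["end"] = new_end
    if chrom_sizes is not None:
        sizes = out["chrom"].map(chrom_sizes).to_numpy(np.int64)
        out["start"] = np.maximum(out["start"], 0)
        out["end"] = np.minimum(out["end"], sizes)
    return out


@dataclass
class PileupTrack:
    """Per-chromosome fragment pileup for one mark.

    Stores the raw fragment endpoints (for per-base coverage, computed
    lazily) and the sorted fragment midpoints used by the enrichment test.
    """

    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    midpoints: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    total_fragments: int
    genome_size: int
    mappable_fraction: float = DEFAULT_MAPPABLE_FRACTION
    _coverage: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def background_rate(self) -> float:
        """Genome-wide expected fragments per mappable bp."""
        mappable = self.genome_size * self.mappable_fraction
        if mappable <= 0:
            raise SignalError("zero mappable genome; cannot estimate the Poisson rate")
        return self.total_fragments / mappable

    def coverage(self, chrom: str) -> np.ndarray:
        """Per-base fragment coverage for one chromosome (computed on demand)."""
        if chrom not in self._coverage:
            size = self.chrom_sizes[chrom]
            diff = np.zeros(size + 1, dtype=np.int64)
            np.add.at(diff, self.starts.get(chrom, np.empty(0, np.int64)), 1)
            np.add.at(diff, self.ends.get(chrom, np.empty(0, np.int64)), -1)
            self._coverage[chrom] = np.cumsum(diff[:-1])
        return self._coverage[chrom]

    def count_midpoints(self, chrom: str, start, end):
        """Number of fragment midpoints falling in [start, end) (vectorized)."""
        mids = self.midpoints.get(chrom, np.empty(0, np.int64))
        return np.searchsorted(mids, end, "left") - np.searchsorted(mids, start, "left")

    def coverage_sum(self, chrom: str, start: int, end: int) -> int:
        cov = self.coverage(chrom)
        return int(cov[max(start, 0) : max(end, 0)].sum())

    def mean_fragment_length(self) -> float:
        total = sum((e - s).sum() for s, e in zip(self.starts.values(), self.ends.values()))
        return total / max(self.total_fragments, 1)


def build_pileup(
    fragments: pd.DataFrame,
    chrom_sizes: dict[str, int],
    mappable_fraction: float = DEFAULT_MAPPABLE_FRACTION,
) -> PileupTrack:
    """Assemble a :class:`PileupTrack` from extended fragments.

    Conservation holds by construction: the summed coverage equals the summed
    fragment lengths. Fragments extending beyond the declared chromosome
    length are an error.
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    midpoints: dict[str, np.ndarray] = {}
    for chrom, grp in fragments.groupby("chrom", sort=True):
        chrom = str(chrom)
        if chrom not in chrom_sizes:
            raise SignalError(f"fragment on unknown chromosome {chrom!r}")
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        if np.any(s < 0) or np.any(e > chrom_sizes[chrom]):
            raise SignalError(
                f"fragment outside [0, {chrom_sizes[chrom]}) on {chrom!r}"
            )
        if np.any(s >= e):
            raise SignalError(f"empty fragment interval on {chrom!r}")
        order = np.argsort(s, kind="stable")
        starts[chrom] = s[order]
        ends[chrom] = e[order]
        midpoints[chrom] = np.sort((s + e) // 2)
    return PileupTrack(
        starts=starts,
        ends=ends,
        midpoints=midpoints,
        chrom_sizes=dict(chrom_sizes),
        total_fragments=int(len(fragments)),
        genome_size=int(sum(chrom_sizes.values())),
        mappable_fraction=mappable_fraction,
    )


@dataclass(frozen=True)
class RegionTriplet:
    """The three enrichment-test regions anchored on one exon.

    ``preceding`` and ``succeeding`` follow transcription direction: the 5'
    intronic flank precedes the exon regardless of genomic orientation.
    """

    preceding: tuple[int, int]
    exon_body: tuple[int, int]
    succeeding: tuple[int, int]

    def items(self):
        return (
            ("preceding", self.preceding),
            ("exon", self.exon_body),
            ("succeeding", self.succeeding),
        )


def define_regions(
    start: int,
    end: int,
    strand: str,
    flank: int = DEFAULT_FLANK,
    junction_exclusion: int = DEFAULT_JUNCTION_EXCLUSION,
) -> RegionTriplet:
    """Region triplet for one exon.

    The searched intronic flank is the closest ``flank`` bp of intron with the
    ``junction_exclusion`` bp nearest the junction removed (so 160 bp net at
    the defaults); the exon body is trimmed by the exclusion at both ends.
    """
    start, end = int(start), int(end)
    if end - start <= 2 * junction_exclusion:
        raise SignalError(
            f"exon [{start},{end}) too short to trim {junction_exclusion} bp "
            "junction exclusions at both ends"
        )
    left = (start - flank, start - junction_exclusion)
    body = (start + junction_exclusion, end - junction_exclusion)
    right = (end + junction_exclusion, end + flank)
    if strand == "-":
        return RegionTriplet(preceding=right, exon_body=body, succeeding=left)
    return RegionTriplet(preceding=left, exon_body=body, succeeding=right)


def poisson_present(
    count: int,
    region_length: int,
    track: PileupTrack | None = None,
    alpha: float = DEFAULT_ALPHA,
    rate: float | None = None,
) -> bool:
    """Upper-tail Poisson call: present iff P(X >= count) < alpha.

    X ~ Poisson(rate * region_length) with the rate taken from the track's
    genome-wide totals unless given explicitly. The inequality is strict, so
    a count of 0 is always absent (the tail probability is 1).
    """
    if region_length <= 0:
        raise SignalError("region_length must be positive")
    if rate is None:
        if track is None:
            raise SignalError("either a track or an explicit rate is required")
        rate = track.background_rate()
    lam = rate * region_length
    return bool(poisson.sf(count - 1, lam) < alpha)


def attribute_names(marks) -> list[str]:
    """Column names in ``<mark>.<prec|exon|succ>`` order for the given marks."""
    return [f"{m}.{REGION_SUFFIX[r]}" for m in marks for r in REGION_SUFFIX]


def binarize_exons(
    exons: pd.DataFrame,
    tracks: dict[str, PileupTrack],
    alpha: float = DEFAULT_ALPHA,
    flank: int = DEFAULT_FLANK,
    junction_exclusion: int = DEFAULT_JUNCTION_EXCLUSION,
    statistic: str = "midpoint",
) -> pd.DataFrame:
    """Binary attribute matrix (exons x 3*n_marks) from per-mark tracks.

    ``exons`` needs columns exon_id/chrom/start/end/strand. The default
    enrichment statistic counts fragment midpoints in each region, which keeps
    counts independent across disjoint regions; ``statistic="pileup"`` instead
    converts the summed per-base coverage into fragment equivalents (coverage
    divided by the mark's mean fragment length) before the same Poisson test.
    Regions are clipped to chromosome bounds, with the test length clipped
    accordingly.
    """
    if statistic not in ("midpoint", "pileup"):
        raise SignalError(f"unknown statistic {statistic!r}")

    marks = list(tracks)
    n = len(exons)
    columns = attribute_names(marks)
    values = np.zeros((n, len(columns)), dtype=np.uint8)

    # Region bounds are strand-dependent only through the preceding/succeeding
    # role assignment; compute the three genomic intervals per exon once.
    region_rows = {"preceding": [], "exon": [], "succeeding": []}
    for row in exons.itertuples(index=False):
        triplet = define_regions(
            int(row.start), int(row.end), row.strand, flank, junction_exclusion
        )
        for role, (a, b) in triplet.items():
            region_rows[role].append((row.chrom, a, b))

    for j_mark, mark in enumerate(marks):
        track = tracks[mark]
        rate = track.background_rate()
        mean_len = track.mean_fragment_length() if statistic == "pileup" else None
        for j_role, role in enumerate(REGION_SUFFIX):
            col = j_mark * 3 + j_role
            rows = region_rows[role]
            chroms = np.array([r[0] for r in rows], dtype=object)
            a = np.array([r[1] for r in rows], dtype=np.int64)
            b = np.array([r[2] for r in rows], dtype=np.int64)
            counts = np.zeros(n, dtype=np.float64)
            lengths = np.zeros(n, dtype=np.int64)
            for chrom in np.unique(chroms):
                m = chroms == chrom
                size = track.chrom_sizes.get(str(chrom), 0)
                ca = np.clip(a[m], 0, size)
                cb = np.clip(b[m], 0, size)
                lengths[m] = cb - ca
                if statistic == "midpoint":
                    counts[m] = track.count_midpoints(str(chrom), ca, cb)
                else:
                    cov = track.coverage(str(chrom))
                    csum = np.concatenate([[0], np.cumsum(cov)])
                    counts[m] = (csum[cb] - csum[ca]) / mean_len
            ok = lengths > 0
            pvals = np.ones(n)
            pvals[ok] = poisson.sf(np.ceil(counts[ok]) - 1, rate * lengths[ok])
            values[:, col] = (pvals < alpha).astype(np.uint8)

    return pd.DataFrame(values, index=pd.Index(exons["exon_id"], name="exon_id"),
                        columns=columns)


def binarize_exon(
    exon: pd.Series,
    tracks: dict[str, PileupTrack],
    **kwargs,
) -> pd.Series:
    """Attribute vector for a single exon (see :func:`binarize_exons`)."""
    df = binarize_exons(exon.to_frame().T, tracks, **kwargs)
    return df.iloc[0]
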