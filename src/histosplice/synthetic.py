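"""Synthetic gene models, exon expression and ChIP-seq fragments with planted rules.

The generator emulates the study conditions of the real pipeline closely
enough that every downstream stage is testable without external data:

* gene models whose internal exons pass the length (>= 50 bp) and flanking
  intron (>= 360 bp) filters;
* exon expression constructed so that the downstream inclusion-level
  computation (exon expression over the top-10-exon gene mean) lands exactly
  in the 'spliced out' (< 0.4) or 'included' ([0.9, 1.1]) windows;
* per-mark fragment sets drawn from a homogeneous Poisson background, with
  planted combinatorial rules expressed as region-level enrichment tied to
  the exon class label with configurable penetrance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .signal import (
    DEFAULT_FLANK,
    DEFAULT_FRAGMENT_LENGTH,
    DEFAULT_JUNCTION_EXCLUSION,
    REGION_SUFFIX,
    define_regions,
)

SPLICED_OUT = "spliced_out"
INCLUDED = "included"
CLASSES = (SPLICED_OUT, INCLUDED)

REGIONS = tuple(REGION_SUFFIX)  # ("preceding", "exon", "succeeding")
STATES = ("present", "absent")


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration violates a stated minimum."""


@dataclass(frozen=True)
class PlantedRule:
    """A ground-truth combinatorial rule tying mark patterns to an exon class.

    ``conditions`` is a list of (mark, region, required_state) triples; for
    each exon of ``target_class`` the pattern is planted with probability
    ``penetrance``: 'present' regions are drawn at the enriched rate,
    'absent' regions stay at background.
    """

    conditions: tuple[tuple[str, str, str], ...]
    target_class: str = SPLICED_OUT
    penetrance: float = 1.0

    def __post_init__(self):
        conds = tuple(tuple(c) for c in self.conditions)
        object.__setattr__(self, "conditions", conds)
        if not conds:
            raise ConfigurationError("a planted rule needs at least one condition")
        pairs = [(m, r) for m, r, _ in conds]
        if len(set(pairs)) != len(pairs):
            raise ConfigurationError("duplicate (mark, region) pair in planted rule")
        for mark, region, state in conds:
            if region not in REGIONS:
                raise ConfigurationError(f"unknown region {region!r}")
            if state not in STATES:
                raise ConfigurationError(f"unknown state {state!r}")
        if self.target_class not in CLASSES:
            raise ConfigurationError(f"unknown class {self.target_class!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigurationError("penetrance must be in [0, 1]")

    def attribute_conditions(self) -> tuple[tuple[str, int], ...]:
        """The rule in decision-table terms: (attribute name, 0/1) pairs."""
        return tuple(
            sorted(
                (f"{mark}.{REGION_SUFFIX[region]}", 1 if state == "present" else 0)
                for mark, region, state in self.conditions
            )
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Ranges are inclusive (lo, hi) bounds of uniform draws. Defaults mirror
    the real pipeline's constants where they exist (150 bp fragments, 50 bp
    exon minimum, 360 bp intron minimum) and otherwise describe a compact but
    realistic locus: ~100-200 bp exons, 400-800 bp introns, a lognormal gene
    expression distribution, and a 0.02 fragments/bp background.
    """

    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (80, 200)
    intron_length: tuple[int, int] = (400, 800)
    n_marks: int = 6
    mark_names: tuple[str, ...] | None = None
    planted_rules: tuple[PlantedRule, ...] = ()
    background_rate: float = 0.02
    enrichment_fold: float = 20.0
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH
    spliced_out_fraction: float = 0.5
    expression_sigma: float = 0.0
    gene_expression_median: float = 100.0
    gene_expression_log_sd: float = 1.0
    intergenic_gap: tuple[int, int] = (1500, 2500)
    flank: int = DEFAULT_FLANK
    junction_exclusion: int = DEFAULT_JUNCTION_EXCLUSION
    seed: int = 0

    def __post_init__(self):
        def _range(name, lohi, minimum):
            lo, hi = lohi
            if lo > hi:
                raise ConfigurationError(f"{name}: lower bound exceeds upper bound")
            if lo < minimum:
                raise ConfigurationError(
                    f"{name}: minimum support {lo} below required {minimum}"
                )

        _range("exons_per_gene", self.exons_per_gene, 3)
        if self.exons_per_gene[1] > 10:
            raise ConfigurationError(
                "exons_per_gene above 10 breaks the exact inclusion-ratio "
                "construction (gene expression = mean of the top-10 exons)"
            )
        _range("exon_length", self.exon_length, 50)
        _range("intron_length", self.intron_length, 360)
        _range("intergenic_gap", self.intergenic_gap, 2 * self.flank)
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.background_rate <= 0:
            raise ConfigurationError("background_rate must be > 0")
        if self.enrichment_fold <= 1:
            raise ConfigurationError("enrichment_fold must be > 1")
        if not 0 <= self.spliced_out_fraction <= 1:
            raise ConfigurationError("spliced_out_fraction must be in [0, 1]")
        marks = self.marks()
        if len(marks) != self.n_marks or len(set(marks)) != len(marks):
            raise ConfigurationError("mark_names must be n_marks unique names")
        for rule in self.planted_rules:
            for mark, _, _ in rule.conditions:
                if mark not in marks:
                    raise ConfigurationError(f"planted rule uses unknown mark {mark!r}")

    def marks(self) -> tuple[str, ...]:
        if self.mark_names is not None:
            return tuple(self.mark_names)
        return tuple(f"M{i + 1:02d}" for i in range(self.n_marks))

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


def planted_recovery_config(seed: int = 0, penetrance: float = 0.9) -> SyntheticConfig:
    """The reference end-to-end study: one planted 3-condition 'spliced out' rule.

    The conditions are sized by a closed-form power analysis so that exact
    recovery of the planted condition set by object-relative reducts is a
    high-probability event rather than a coin flip: exact recovery needs, for
    every pair of planted attributes, at least one included-class exon
    carrying both by chance, so the included class must be large enough that
    the expected pair count N * fp^2 is ~6 at the Poisson test's achievable
    false-positive rate. The background rate (0.0185/bp; lambda = 2.96 over
    the uniform 160 bp regions) and the 24-26 kb intergenic gaps keep the
    enrichment mass from pushing the per-mark rate estimate past the cutoff
    plateau boundary (lambda ~ 3.285), which would collapse that
    false-positive rate; 'spliced out' is the minority class so the balanced
    repeats subsample the included class, which decorrelates the repeats.
    """
    rule = PlantedRule(
        conditions=(
            ("M01", "preceding", "present"),
            ("M02", "exon", "present"),
            ("M03", "succeeding", "present"),
        ),
        target_class=SPLICED_OUT,
        penetrance=penetrance,
    )
    return SyntheticConfig(
        n_genes=2400,
        exons_per_gene=(6, 6),
        exon_length=(200, 200),
        intron_length=(400, 800),
        n_marks=6,
        planted_rules=(rule,),
        background_rate=0.0185,
        enrichment_fold=20.0,
        spliced_out_fraction=0.23,
        intergenic_gap=(24000, 26000),
        seed=seed,
    )


def null_calibration_config(seed: int = 0) -> SyntheticConfig:
    """Study conditions for checking the size of the Poisson present/absent test.

    No planted rules; uniform 160 bp regions (200 bp exons minus the
    junction exclusions, 160 bp net flanks) and a background rate of
    0.14/bp, chosen from the closed-form Poisson tails so the discrete
    test's achievable size (0.0490 at lambda = 22.4) sits close to the
    nominal 0.05; at small lambda the achievable size can dip to ~0.02 and
    would measure discreteness rather than correctness.
    """
    return SyntheticConfig(
        n_genes=210,
        exons_per_gene=(6, 6),
        exon_length=(200, 200),
        intron_length=(400, 800),
        n_marks=4,
        planted_rules=(),
        background_rate=0.14,
        intergenic_gap=(1500, 2500),
        seed=seed,
    )


@dataclass
class GeneModels:
    """Generated annotation: exon table plus chromosome sizes."""

    exons: pd.DataFrame
    chrom_sizes: dict[str, int]


def generate_annotation(config: SyntheticConfig) -> GeneModels:
    """Lay out single-transcript gene models along one synthetic chromosome.

    Exons are non-overlapping within and across genes by construction
    (sequential layout with intergenic gaps). Deterministic given the config
    seed. Exon numbering follows transcription order, so exon 1 of a minus
    strand gene is the rightmost.
    """
    rng = np.random.default_rng([config.seed, 0])
    rows = []
    cursor = 1000  # left margin so flanks never leave the chromosome
    chrom = "chr1"
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:04d}"
        transcript_id = f"{gene_id}.T1"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_ex)
        in_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, n_ex - 1
        )
        strand = "+" if rng.random() < 0.5 else "-"
        starts = []
        pos = cursor
        for i in range(n_ex):
            starts.append(pos)
            pos += int(ex_lens[i])
            if i < n_ex - 1:
                pos += int(in_lens[i])
        for i, s in enumerate(starts):
            number = i + 1 if strand == "+" else n_ex - i
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(s + ex_lens[i]),
                    "strand": strand,
                    "gene_id": gene_id,
                    "transcript_id": transcript_id,
                    "exon_number": int(number),
                    "exon_id": f"{gene_id}.E{number:02d}",
                }
            )
        cursor = pos + int(
            rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1)
        )
    exons = pd.DataFrame(rows)
    return GeneModels(exons=exons, chrom_sizes={chrom: cursor + 1000})


def assign_labels_and_expression(
    models: GeneModels, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw class labels for internal exons and construct matching expression.

    Internal exons get 'spliced out' with probability
    ``spliced_out_fraction`` and a target inclusion ratio drawn from
    [0.10, 0.35] ('spliced out') or [0.92, 1.08] ('included'). Terminal exons
    receive the ratio that makes the gene's top-min(10, n) exon-expression
    mean equal the gene base expression, so the downstream recomputation of
    inclusion levels reproduces the drawn ratios exactly when
    ``expression_sigma`` is 0.
    """
    label_rows = []
    expr_rows = []
    for gene_id, grp in models.exons.groupby("gene_id", sort=True):
        grp = grp.sort_values("exon_number")
        n = len(grp)
        gene_base = config.gene_expression_median * float(
            np.exp(rng.normal(0.0, config.gene_expression_log_sd))
        )
        internal = grp.iloc[1:-1]
        ratios = {}
        for row in internal.itertuples(index=False):
            if rng.random() < config.spliced_out_fraction:
                label, ratio = SPLICED_OUT, float(rng.uniform(0.10, 0.35))
            else:
                label, ratio = INCLUDED, float(rng.uniform(0.92, 1.08))
            ratios[row.exon_id] = ratio
            label_rows.append(
                {"exon_id": row.exon_id, "gene_id": gene_id, "label": label}
            )
        # terminal-exon ratio solving mean(all n ratios) == 1 (n <= 10)
        t = (n - sum(ratios.values())) / 2.0
        for row in grp.itertuples(index=False):
            ratio = ratios.get(row.exon_id, t)
            noise = (
                float(np.exp(rng.normal(0.0, config.expression_sigma)))
                if config.expression_sigma > 0
                else 1.0
            )
            expr_rows.append(
                {
                    "exon_id": row.exon_id,
                    "gene_id": gene_id,
                    "expression": gene_base * ratio * noise,
                }
            )
    return pd.DataFrame(label_rows), pd.DataFrame(expr_rows)


def _planted_regions(
    models: GeneModels, labels: pd.DataFrame, config: SyntheticConfig,
    rng: np.random.Generator,
) -> dict[str, list[tuple[str, int, int]]]:
    """Enriched (mark -> genomic interval) assignments from the planted rules."""
    exon_info = models.exons.set_index("exon_id")
    enriched: dict[str, list[tuple[str, int, int]]] = {m: [] for m in config.marks()}
    for rule in config.planted_rules:
        eligible = labels.loc[labels["label"] == rule.target_class, "exon_id"]
        for exon_id in eligible:
            if rng.random() >= rule.penetrance:
                continue
            row = exon_info.loc[exon_id]
            triplet = define_regions(
                int(row["start"]), int(row["end"]), row["strand"],
                config.flank, config.junction_exclusion,
            )
            regions = dict(triplet.items())
            for mark, region, state in rule.conditions:
                if state != "present":
                    continue  # 'absent' regions stay at background
                a, b = regions[region]
                enriched[mark].append((row["chrom"], max(a, 0), b))
    return enriched


def generate_fragments(
    models: GeneModels,
    labels: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Per-mark fragment sets: Poisson background plus planted enrichment.

    Fragment midpoints arrive as a homogeneous Poisson process at
    ``background_rate`` per bp; each planted 'present' region receives
    additional midpoints at ``(enrichment_fold - 1) * background_rate`` so
    the total rate inside the region is the enriched rate. Fragments have
    length ``fragment_length``, clamped at chromosome boundaries, with a
    random strand (the pileup is strand-blind).
    """
    enriched = _planted_regions(models, labels, config, rng)
    frag_len = config.fragment_length
    half = frag_len // 2
    out = {}
    for mark in config.marks():
        mids = []
        chroms = []
        for chrom, size in models.chrom_sizes.items():
            n_bg = rng.poisson(config.background_rate * size)
            mids.append(rng.integers(0, size, n_bg))
            chroms.append(np.repeat(chrom, n_bg))
        for chrom, a, b in enriched[mark]:
            extra_rate = (config.enrichment_fold - 1.0) * config.background_rate
            n_extra = rng.poisson(extra_rate * (b - a))
            mids.append(rng.integers(a, b, n_extra))
            chroms.append(np.repeat(chrom, n_extra))
        mid = np.concatenate(mids)
        chrom_arr = np.concatenate(chroms)
        start = mid - half
        end = start + frag_len
        df = pd.DataFrame(
            {
                "chrom": chrom_arr,
                "start": start,
                "end": end,
                "strand": rng.choice(np.array(["+", "-"]), len(mid)),
            }
        )
        sizes = df["chrom"].map(models.chrom_sizes).to_numpy(np.int64)
        df["start"] = np.maximum(df["start"], 0)
        df["end"] = np.minimum(df["end"], sizes)
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        out[mark] = df
    return out


def reads_from_fragments(
    fragments: pd.DataFrame, read_length: int = 36
) -> pd.DataFrame:
    """Truncate fragments to 5'-anchored short reads (for the extension path)."""
    df = fragments.copy()
    minus = df["strand"].to_numpy(dtype=object) == "-"
    start = df["start"].to_numpy(np.int64)
    end = df["end"].to_numpy(np.int64)
    df["start"] = np.where(minus, end - read_length, start)
    df["end"] = df["start"] + read_length
    return df


@dataclass
class SyntheticDataset:
    """A fully generated dataset: annotation, labels, expression, fragments."""

    config: SyntheticConfig
    gene_models: GeneModels
    labels: pd.DataFrame
    expression: pd.DataFrame
    fragments: dict[str, pd.DataFrame]

    @classmethod
    def generate(cls, config: SyntheticConfig) -> "SyntheticDataset":
        models = generate_annotation(config)
        labels, expression = assign_labels_and_expression(
            models, config, np.random.default_rng([config.seed, 1])
        )
        fragments = generate_fragments(
            models, labels, config, np.random.default_rng([config.seed, 2])
        )
        return cls(config, models, labels, expression, fragments)

    def write(self, directory: str | Path) -> None:
        """Write the dataset as plain-text files (GTF, TSV, BED6 per mark)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        hio.write_annotation_gtf(self.gene_models.exons, directory / "annotation.gtf")
        hio.write_chrom_sizes(self.gene_models.chrom_sizes, directory / "chrom.sizes")
        hio.write_table_tsv(self.expression, directory / "expression.tsv")
        hio.write_table_tsv(self.labels, directory / "truth_labels.tsv")
        for mark, frags in self.fragments.items():
            hio.write_fragments_bed(frags, directory / f"{mark}.fragments.bed")
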