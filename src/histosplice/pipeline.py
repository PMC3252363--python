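"""End-to-end drivers tying the stages together.

``run_synthetic_pipeline`` exercises the whole method on generated data:
annotation -> expression/labels -> fragment tracks -> Poisson binarization ->
exon filters and inclusion labels -> decision table -> MCFS attribute
selection -> rule induction with balanced repeats and cross-validation.
The same stage functions accept real data read from BED/GTF/TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import InductionParams, MergedModel, repeat_and_merge
from .exons import (
    DecisionTable,
    build_decision_table,
    drop_no_modification,
    filter_top_genes,
    gene_expression_table,
    label_exons,
    select_internal_exons,
)
from .mcfs import MCFSParams, permutation_significance, rank_attributes, select_top
from .signal import PileupTrack, build_pileup, binarize_exons
from .synthetic import SyntheticConfig, SyntheticDataset


@dataclass
class PipelineResult:
    """Everything the synthetic end-to-end run produces."""

    dataset: SyntheticDataset
    tracks: dict[str, PileupTrack]
    internal_exons: pd.DataFrame
    labels: pd.DataFrame
    table: DecisionTable
    ranking: pd.DataFrame
    selected_attributes: list[str]
    model: MergedModel
    stage_counts: dict[str, int]


def build_synthetic_table(
    dataset: SyntheticDataset,
    alpha: float = 0.05,
    statistic: str = "midpoint",
) -> tuple[DecisionTable, pd.DataFrame, pd.DataFrame, dict[str, PileupTrack]]:
    """Decision table (and intermediates) from a generated dataset.

    The synthetic genome carries no unmappable regions, so the Poisson rate
    uses the whole genome (mappable fraction 1).
    """
    config = dataset.config
    models = dataset.gene_models
    tracks = {
        mark: build_pileup(frags, models.chrom_sizes, mappable_fraction=1.0)
        for mark, frags in dataset.fragments.items()
    }
    internal = select_internal_exons(models.exons)

    per_gene = gene_expression_table(dataset.expression)
    kept_genes = filter_top_genes(per_gene)
    internal = internal[internal["gene_id"].isin(kept_genes.index)].reset_index(
        drop=True)

    expr = dataset.expression.set_index("exon_id")
    exon_expr = expr.loc[internal["exon_id"], "expression"]
    exon_gene = expr.loc[internal["exon_id"], "gene_id"].map(kept_genes)
    labeled = label_exons(exon_expr, exon_gene)

    attributes = binarize_exons(
        internal, tracks, alpha=alpha,
        flank=config.flank, junction_exclusion=config.junction_exclusion,
        statistic=statistic,
    )
    table = build_decision_table(labeled["label"], attributes)
    table = drop_no_modification(table)
    return table, internal, labeled, tracks


def run_synthetic_pipeline(
    config: SyntheticConfig,
    mcfs_params: MCFSParams | None = None,
    induction: InductionParams | None = None,
    top_k: int = 20,
    repeats: int = 10,
    cv_folds: int = 10,
    permutation_runs: int = 0,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PipelineResult:
    """Generate a dataset and run the full modelling pipeline on it.

    ``permutation_runs`` > 0 adds the label-permutation significance screen
    before the top-k attribute cut (costly: each run repeats the whole MCFS
    computation); at 0 the top-k cut uses the RI ranking alone.
    """
    mcfs_params = mcfs_params or MCFSParams()
    induction = induction or InductionParams()
    seed = config.seed if seed is None else seed

    dataset = SyntheticDataset.generate(config)
    table, internal, labeled, tracks = build_synthetic_table(dataset, alpha=alpha)
    counts = table.class_counts()
    stage_counts = {
        "internal_exons_labeled": len(table.attributes)
        + int((labeled["label"] == "unlabeled").sum()),
        "decision_table_objects": table.n_objects,
        "spliced_out": counts["spliced_out"],
        "included": counts["included"],
        "attributes": len(table.attribute_names),
    }

    mcfs_rng = np.random.default_rng([seed, 10])
    if permutation_runs > 0:
        params = mcfs_params.replace(cutpoint_runs=permutation_runs)
        ranking = permutation_significance(table, params, mcfs_rng)
    else:
        ranking = rank_attributes(table, mcfs_params, mcfs_rng)
    selected = select_top(ranking, k=top_k)

    model = repeat_and_merge(
        table.select_attributes(selected),
        repeats=repeats, cv_folds=cv_folds, params=induction,
        rng=np.random.default_rng([seed, 11]),
    )
    return PipelineResult(
        dataset=dataset,
        tracks=tracks,
        internal_exons=internal,
        labels=labeled,
        table=table,
        ranking=ranking,
        selected_attributes=selected,
        model=model,
        stage_counts=stage_counts,
    )
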