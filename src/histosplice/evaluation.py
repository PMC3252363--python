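"""Balanced resampling, cross-validation, model merging and rule footprints.

The evaluation protocol mirrors the original study: the minority class is
kept whole and the majority class subsampled to the same size; on each of
``repeats`` such balanced tables a rule model is induced and a stratified
10-fold cross-validation run; the per-repeat models are merged
(deduplicated) and the merged rules re-evaluated on the full, unbalanced
table. Classification accuracy is reported over covered (non-abstained)
objects only, with coverage reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exons import DecisionTable
from .rough import (
    DEFAULT_HITTING_FRACTION,
    DEFAULT_MIN_ACCURACY,
    DEFAULT_MIN_SUPPORT,
    Rule,
    classify,
    filter_rules,
    induce_rules,
    merge_rules,
)
from .rulestats import evaluate_rules
from .signal import PileupTrack


@dataclass(frozen=True)
class InductionParams:
    """Settings shared by model induction and cross-validation."""

    hitting_fraction: float = DEFAULT_HITTING_FRACTION
    min_support: int = DEFAULT_MIN_SUPPORT
    min_accuracy: float = DEFAULT_MIN_ACCURACY
    weighting: str = "product"


@dataclass
class CVResult:
    repeat: int
    fold: int
    accuracy: float
    coverage: float


def balanced_resample(table: DecisionTable, rng) -> DecisionTable:
    """All minority-class objects plus an equal-size majority subsample."""
    rng = np.random.default_rng(rng)
    counts = table.class_counts()
    if min(counts.values()) == 0:
        raise ValueError("balanced resampling requires both classes")
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    if minority == majority:  # equal counts; keep a fixed orientation
        minority, majority = sorted(counts)
    y = table.decision.to_numpy()
    keep_min = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    keep_maj = rng.choice(maj_idx, size=len(keep_min), replace=False)
    order = rng.permutation(np.concatenate([keep_min, keep_maj]))
    return table.iloc(order)


def stratified_folds(decision: pd.Series, k: int, rng) -> list[np.ndarray]:
    """Disjoint, exhaustive, class-stratified fold index arrays."""
    rng = np.random.default_rng(rng)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in sorted(decision.unique()):
        idx = np.flatnonzero((decision == cls).to_numpy())
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has fewer objects ({len(idx)}) than folds")
        perm = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(perm, k)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(
    table: DecisionTable,
    k: int = 10,
    params: InductionParams | None = None,
    rng=None,
    repeat: int = 0,
) -> list[CVResult]:
    """Stratified k-fold CV of the rule pipeline on one (balanced) table."""
    params = params or InductionParams()
    rng = np.random.default_rng(rng)
    folds = stratified_folds(table.decision, k, rng)
    n = table.n_objects
    results = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train = table.iloc(train_idx)
        test = table.iloc(test_idx)
        rules = induce_rules(
            train, params.hitting_fraction,
            min_support=params.min_support, min_accuracy=params.min_accuracy,
        )
        preds = classify(rules, test.attributes, params.weighting)
        covered = np.array([p is not None for p in preds])
        coverage = float(covered.mean()) if len(preds) else 0.0
        if covered.any():
            correct = preds[covered] == test.decision.to_numpy()[covered]
            accuracy = float(correct.mean())
        else:
            accuracy = float("nan")
        results.append(CVResult(repeat=repeat, fold=f, accuracy=accuracy,
                                coverage=coverage))
    return results


@dataclass
class MergedModel:
    """Merged rule set with its full-table statistics and CV summary."""

    rules: list[Rule]
    statistics: pd.DataFrame
    cv_results: list[CVResult] = field(default_factory=list)
    cv_accuracy_mean: float = float("nan")
    cv_accuracy_sd: float = float("nan")
    coverage: float = float("nan")


def model_coverage(rules, table: DecisionTable) -> float:
    """Fraction of table objects matched by at least one rule."""
    if not rules:
        return 0.0
    covered = np.zeros(table.n_objects, dtype=bool)
    for rule in rules:
        covered |= rule.matches(table.attributes)
    return float(covered.mean())


def repeat_and_merge(
    table: DecisionTable,
    repeats: int = 10,
    cv_folds: int = 10,
    params: InductionParams | None = None,
    rng=None,
) -> MergedModel:
    """The full evaluation protocol on one decision table.

    Per repeat: balanced resample, rule model on the whole balanced table,
    and a separate stratified CV on the same balanced table. The merged,
    deduplicated rule set is re-evaluated on the full table (support,
    accuracy, theoretical accuracy, combinatorial gain, hypergeometric
    p-value), and the summary reports the mean and sd over the per-repeat
    mean CV accuracies plus the merged model's coverage of the full table.
    """
    params = params or InductionParams()
    rng = np.random.default_rng(rng)
    all_rules = []
    cv_results: list[CVResult] = []
    repeat_means = []
    for rep in range(repeats):
        balanced = balanced_resample(table, rng)
        model = induce_rules(
            balanced, params.hitting_fraction,
            min_support=params.min_support, min_accuracy=params.min_accuracy,
        )
        all_rules.append(model)
        fold_results = cross_validate(balanced, cv_folds, params, rng, repeat=rep)
        cv_results.extend(fold_results)
        accs = [r.accuracy for r in fold_results if np.isfinite(r.accuracy)]
        if accs:
            repeat_means.append(float(np.mean(accs)))

    merged = merge_rules(*all_rules)
    # refresh support/accuracy on the original, unbalanced data
    refreshed = []
    for rule in merged:
        mask = rule.matches(table.attributes)
        n = int(mask.sum())
        k = int((table.decision.to_numpy()[mask] == rule.decision).sum())
        refreshed.append(rule.with_stats(n, k / n if n else float("nan")))
    stats = evaluate_rules(refreshed, table)
    return MergedModel(
        rules=refreshed,
        statistics=stats,
        cv_results=cv_results,
        cv_accuracy_mean=float(np.mean(repeat_means)) if repeat_means else float("nan"),
        cv_accuracy_sd=float(np.std(repeat_means, ddof=1)) if len(repeat_means) > 1
        else float("nan"),
        coverage=model_coverage(refreshed, table),
    )


@dataclass
class Footprint:
    """Mean per-bp signal around the two exon junctions, per mark.

    Arrays span ``[-window, window)`` around the 5' (intron->exon) and 3'
    (exon->intron) junctions, oriented in transcription direction.
    """

    five_prime: np.ndarray
    three_prime: np.ndarray
    n_exons: int
    window: int


def footprint(
    rule: Rule,
    table: DecisionTable,
    exon_coords: pd.DataFrame,
    tracks: dict[str, PileupTrack],
    window: int = 1000,
    depth_normalize: bool = True,
) -> dict[str, Footprint]:
    """Junction-centred signal footprints over the exons supporting a rule.

    ``exon_coords`` maps exon ids (the table index) to chrom/start/end/
    strand. The per-mark signal is the mean per-bp fragment coverage across
    supporting exons, divided by the mark's total fragments in millions when
    ``depth_normalize`` is set.
    """
    mask = rule.matches(table.attributes)
    ids = table.attributes.index[mask]
    coords = exon_coords.set_index("exon_id").loc[ids.intersection(
        exon_coords["exon_id"])]
    if len(coords) == 0:
        raise ValueError("rule has no supporting exons with coordinates")

    out = {}
    for mark, track in tracks.items():
        sums5 = np.zeros(2 * window)
        cnt5 = np.zeros(2 * window)
        sums3 = np.zeros(2 * window)
        cnt3 = np.zeros(2 * window)
        for row in coords.itertuples():
            cov = track.coverage(row.chrom)
            size = len(cov)
            if row.strand == "-":
                j5, j3 = row.end, row.start
            else:
                j5, j3 = row.start, row.end
            for junction, sums, cnt in ((j5, sums5, cnt5), (j3, sums3, cnt3)):
                lo, hi = junction - window, junction + window
                clo, chi = max(lo, 0), min(hi, size)
                seg = cov[clo:chi].astype(float)
                offsets = np.arange(clo - lo, clo - lo + len(seg))
                if row.strand == "-":
                    offsets = 2 * window - 1 - offsets
                sums[offsets] += seg
                cnt[offsets] += 1
        scale = (track.total_fragments / 1e6) if depth_normalize else 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            f5 = np.where(cnt5 > 0, sums5 / np.maximum(cnt5, 1), np.nan) / scale
            f3 = np.where(cnt3 > 0, sums3 / np.maximum(cnt3, 1), np.nan) / scale
        out[mark] = Footprint(five_prime=f5, three_prime=f3,
                              n_exons=len(coords), window=window)
    return out
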