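"""Rule induction via object-relative Johnson approximate reducts.

For every object the discernibility list collects, for each opposite-class
object, the set of attributes on which the two differ. A greedy
most-frequent-attribute cover (the Johnson heuristic) over that list, stopped
once a ``hitting_fraction`` of the entries is hit and trimmed by a
minimality-by-removal pass, yields an approximate reduct; instantiating the
reduct with the focal object's attribute values gives one IF-THEN rule.
Identical rules from different objects are merged, and rules are filtered on
support and accuracy before use in the voting classifier (which abstains on
objects no rule matches and on exact vote ties).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exons import DecisionTable

logger = logging.getLogger(__name__)

DEFAULT_HITTING_FRACTION = 0.80
DEFAULT_MIN_SUPPORT = 100
DEFAULT_MIN_ACCURACY = 0.70


@dataclass(frozen=True)
class Rule:
    """An IF-THEN rule: a conjunction of attribute = 0/1 conditions.

    ``support`` counts the objects matching every condition on the table the
    rule was last evaluated on; ``accuracy`` is the fraction of those with
    the rule's decision.
    """

    conditions: tuple[tuple[str, int], ...]
    decision: str
    support: int = 0
    accuracy: float = float("nan")

    def __post_init__(self):
        conds = tuple(sorted((str(a), int(v)) for a, v in self.conditions))
        if not conds:
            raise ValueError("a rule needs at least one condition")
        attrs = [a for a, _ in conds]
        if len(set(attrs)) != len(attrs):
            raise ValueError("attribute repeated within a rule")
        object.__setattr__(self, "conditions", conds)

    @property
    def key(self):
        return (self.conditions, self.decision)

    def matches(self, attributes: pd.DataFrame) -> np.ndarray:
        """Boolean mask of rows satisfying every condition."""
        mask = np.ones(len(attributes), dtype=bool)
        for attr, value in self.conditions:
            mask &= attributes[attr].to_numpy() == value
        return mask

    def with_stats(self, support: int, accuracy: float) -> "Rule":
        return Rule(self.conditions, self.decision, support, accuracy)

    def __str__(self) -> str:
        lhs = " AND ".join(f"{a} = {v}" for a, v in self.conditions)
        return f"IF {lhs} THEN {self.decision}"


@dataclass
class DiscernibilityList:
    """Discernibility of one focal object against the opposite class.

    ``matrix[i, a]`` is True when opposite-class object *i* differs from the
    focal object on attribute *a*. Opposite-class objects with identical
    attribute vectors (empty difference sets) are inconsistencies; they are
    excluded from the matrix and listed separately.
    """

    matrix: np.ndarray
    opposite_index: np.ndarray
    inconsistent_index: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_entries(self) -> int:
        return self.matrix.shape[0]


def object_discernibility(table: DecisionTable, obj) -> DiscernibilityList:
    """Discernibility list for the object with label ``obj`` (or position)."""
    X = table.attributes.to_numpy(np.uint8)
    if isinstance(obj, (int, np.integer)):
        pos = int(obj)
    else:
        pos = table.attributes.index.get_loc(obj)
    y = table.decision.to_numpy()
    opposite = np.flatnonzero(y != y[pos])
    diff = X[opposite] != X[pos]
    nonempty = diff.any(axis=1)
    return DiscernibilityList(
        matrix=diff[nonempty],
        opposite_index=opposite[nonempty],
        inconsistent_index=opposite[~nonempty],
    )


def _required_hits(n_entries: int, hitting_fraction: float) -> int:
    return math.ceil(hitting_fraction * n_entries - 1e-9)


def johnson_approximate_reduct(
    disc: DiscernibilityList | np.ndarray,
    hitting_fraction: float = DEFAULT_HITTING_FRACTION,
) -> list[int]:
    """Greedy approximate cover of a discernibility list.

    Repeatedly picks the attribute present in the most not-yet-hit entries
    (ties to the lowest attribute index) until at least ``hitting_fraction``
    of the entries are hit, then removes attributes whose removal keeps the
    coverage at or above the threshold. Returns attribute column indices in
    the order chosen.
    """
    if not 0 < hitting_fraction <= 1:
        raise ValueError("hitting_fraction must be in (0, 1]")
    matrix = disc.matrix if isinstance(disc, DiscernibilityList) else np.asarray(disc)
    matrix = matrix.astype(bool)
    n = matrix.shape[0]
    if n == 0:
        return []
    required = _required_hits(n, hitting_fraction)
    hit = np.zeros(n, dtype=bool)
    chosen: list[int] = []
    while int(hit.sum()) < required:
        counts = matrix[~hit].sum(axis=0)
        best = int(np.argmax(counts))
        if counts[best] == 0:
            break  # remaining entries are uncoverable (should not happen)
        chosen.append(best)
        hit |= matrix[:, best]
    # minimality-by-removal pass
    for a in list(chosen):
        rest = [b for b in chosen if b != a]
        if not rest:
            continue
        if int(matrix[:, rest].any(axis=1).sum()) >= required:
            chosen = rest
    return chosen


def rule_from_object(table: DecisionTable, obj,
                     hitting_fraction: float = DEFAULT_HITTING_FRACTION
                     ) -> Rule | None:
    """The rule induced by one object's approximate reduct (None if empty)."""
    disc = object_discernibility(table, obj)
    reduct = johnson_approximate_reduct(disc, hitting_fraction)
    if not reduct:
        return None
    if isinstance(obj, (int, np.integer)):
        row = table.attributes.iloc[int(obj)]
        decision = table.decision.iloc[int(obj)]
    else:
        row = table.attributes.loc[obj]
        decision = table.decision.loc[obj]
    names = table.attribute_names
    conditions = tuple((names[a], int(row.iloc[a])) for a in reduct)
    return Rule(conditions, decision)


def evaluate_rule_counts(rule: Rule, table: DecisionTable) -> tuple[int, int]:
    """(support n, correct k) of a rule on a table."""
    mask = rule.matches(table.attributes)
    n = int(mask.sum())
    if n == 0:
        return 0, 0
    k = int((table.decision.to_numpy()[mask] == rule.decision).sum())
    return n, k


def induce_rules(
    table: DecisionTable,
    hitting_fraction: float = DEFAULT_HITTING_FRACTION,
    min_support: int | None = None,
    min_accuracy: float | None = None,
) -> list[Rule]:
    """Object-relative Johnson rules for every object, merged and evaluated.

    Objects with identical attribute vectors and the same decision yield the
    same rule, so reducts are computed once per distinct (pattern, class).
    Opposite-class duplicates (inconsistent pairs) are dropped from the
    discernibility lists rather than failing the run. Support and accuracy
    are evaluated on the generating table; optional thresholds filter the
    result.
    """
    X = table.attributes.to_numpy(np.uint8)
    y = (table.decision == "spliced_out").to_numpy()
    names = table.attribute_names
    decisions = {True: "spliced_out", False: "included"}

    rules: dict[tuple, Rule] = {}
    n_inconsistent = 0
    for is_pos in (True, False):
        own = X[y == is_pos]
        opp = X[y != is_pos]
        if len(own) == 0 or len(opp) == 0:
            raise ValueError("rule induction requires both decision classes")
        patterns = np.unique(own, axis=0)
        for v in patterns:
            diff = opp != v
            nonempty = diff.any(axis=1)
            n_inconsistent += int((~nonempty).sum())
            matrix = diff[nonempty]
            if matrix.shape[0] == 0:
                continue
            reduct = johnson_approximate_reduct(matrix, hitting_fraction)
            if not reduct:
                continue
            conditions = tuple((names[a], int(v[a])) for a in reduct)
            rule = Rule(conditions, decisions[is_pos])
            rules.setdefault(rule.key, rule)
    if n_inconsistent:
        logger.debug("excluded %d inconsistent object pairs", n_inconsistent)

    evaluated = []
    for rule in rules.values():
        n, k = evaluate_rule_counts(rule, table)
        evaluated.append(rule.with_stats(n, k / n if n else float("nan")))
    evaluated.sort(key=lambda r: (r.decision, -r.support, r.conditions))
    if min_support is not None or min_accuracy is not None:
        evaluated = filter_rules(
            evaluated,
            min_support if min_support is not None else 0,
            min_accuracy if min_accuracy is not None else 0.0,
        )
    return evaluated


def filter_rules(rules, min_support: int = DEFAULT_MIN_SUPPORT,
                 min_accuracy: float = DEFAULT_MIN_ACCURACY) -> list[Rule]:
    """Keep rules with support >= min_support and accuracy >= min_accuracy."""
    return [
        r for r in rules
        if r.support >= min_support
        and (np.isfinite(r.accuracy) and r.accuracy >= min_accuracy)
    ]


def merge_rules(*rule_sets) -> list[Rule]:
    """Deduplicated union of rule sets (first occurrence wins)."""
    merged: dict[tuple, Rule] = {}
    for rules in rule_sets:
        for rule in rules:
            merged.setdefault(rule.key, rule)
    return list(merged.values())


def classify(
    rules,
    attributes: pd.DataFrame,
    weighting: str = "product",
) -> np.ndarray:
    """Vote-based classification with abstention.

    Every firing rule votes for its decision with weight support x accuracy
    (``weighting`` may also be "support" or "accuracy"). The majority class
    wins; objects with no firing rule or an exact tie get ``None``.
    """
    if weighting not in ("product", "support", "accuracy"):
        raise ValueError(f"unknown weighting {weighting!r}")
    votes: dict[str, np.ndarray] = {}
    for rule in rules:
        if weighting == "support":
            w = float(rule.support)
        elif weighting == "accuracy":
            w = rule.accuracy if np.isfinite(rule.accuracy) else 0.0
        else:
            w = rule.support * (rule.accuracy if np.isfinite(rule.accuracy) else 0.0)
        mask = rule.matches(attributes)
        acc = votes.setdefault(rule.decision, np.zeros(len(attributes)))
        acc[mask] += w

    out = np.full(len(attributes), None, dtype=object)
    if not votes:
        return out
    classes = sorted(votes)
    stacked = np.vstack([votes[c] for c in classes])
    total = stacked.sum(axis=0)
    best = stacked.max(axis=0)
    winners = stacked == best
    decided = (total > 0) & (winners.sum(axis=0) == 1)
    winner_idx = stacked.argmax(axis=0)
    for i in np.flatnonzero(decided):
        out[i] = classes[winner_idx[i]]
    return out
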