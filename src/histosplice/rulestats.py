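"""Per-rule statistics: significance, independence-model accuracy, co-occurrence.

A rule with support *n* and *k* correct objects, drawn from a table of *N*
objects of which *K* carry the rule's decision, gets an upper-tail
hypergeometric p-value P(X >= k), X ~ Hypergeom(N, K, n), computed in log
space so that values far below 1e-200 remain exact.

The theoretical accuracy of a rule assumes its conditions are independent
within each class:

    |T| p1^T ... pn^T / (|T| p1^T ... pn^T + |F| p1^F ... pn^F)

where T is the rule's decision class, F the rest, and p_i^C the fraction of
class-C objects satisfying condition i. The combinatorial gain is the
empirical accuracy minus this value, in percentage points: a positive gain
means the condition combination carries information beyond its parts.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .exons import DecisionTable
from .rough import Rule, evaluate_rule_counts


def evaluate_on_data(rule: Rule, table: DecisionTable) -> tuple[int, int | None]:
    """Support and correct count of a rule on the (full) table.

    Returns ``(0, None)`` when no object matches: the accuracy is undefined,
    not zero.
    """
    n, k = evaluate_rule_counts(rule, table)
    if n == 0:
        return 0, None
    return n, k


def hypergeometric_pvalue(n: int, k: int, K: int, N: int) -> float:
    """Inclusive upper-tail hypergeometric probability P(X >= k).

    ``N`` objects, ``K`` of the rule's class, ``n`` drawn (the support),
    ``k`` correct. Computed via the log survival function for numerical
    safety in the extreme tails.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric configuration n={n} k={k} K={K} N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n={n}, K={K})")
    if k == 0:
        return 1.0
    return float(np.exp(hypergeom.logsf(k - 1, N, K, n)))


def condition_probabilities(rule: Rule, table: DecisionTable
                            ) -> pd.DataFrame:
    """Per-condition satisfaction fractions within class T and class F."""
    in_T = (table.decision == rule.decision).to_numpy()
    rows = []
    for attr, value in rule.conditions:
        satisfied = table.attributes[attr].to_numpy() == value
        rows.append(
            {
                "condition": f"{attr} = {value}",
                "p_T": float(satisfied[in_T].mean()) if in_T.any() else np.nan,
                "p_F": float(satisfied[~in_T].mean()) if (~in_T).any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def theoretical_accuracy(rule: Rule, table: DecisionTable) -> float | None:
    """Rule accuracy predicted under within-class condition independence.

    ``None`` when both class products vanish (the formula is undefined); for
    single-condition rules the value equals the empirical accuracy exactly.
    """
    probs = condition_probabilities(rule, table)
    in_T = (table.decision == rule.decision).to_numpy()
    size_T = int(in_T.sum())
    size_F = int((~in_T).sum())
    num = size_T * float(np.prod(probs["p_T"].to_numpy()))
    alt = size_F * float(np.prod(probs["p_F"].to_numpy()))
    if num + alt == 0:
        return None
    return num / (num + alt)


def combinatorial_gain(accuracy: float, theoretical: float | None) -> float | None:
    """Empirical minus theoretical accuracy, in percentage points."""
    if theoretical is None or not np.isfinite(accuracy):
        return None
    return 100.0 * (accuracy - theoretical)


def recover_correct_count(support: int, printed_accuracy: float,
                          decimals: int = 3) -> int:
    """The unique k with round(k / support, decimals) == printed accuracy.

    Used to reconstruct exact correct counts from published (support,
    accuracy) pairs; raises when no k or more than one k reproduces the
    printed rounding.
    """
    matches = [
        k for k in range(support + 1)
        if round(k / support, decimals) == round(printed_accuracy, decimals)
    ]
    if len(matches) != 1:
        raise ValueError(
            f"correct count not uniquely recoverable from support={support}, "
            f"accuracy={printed_accuracy} ({len(matches)} candidates)"
        )
    return matches[0]


def evaluate_rules(rules, table: DecisionTable) -> pd.DataFrame:
    """Full statistics table for a rule set evaluated on ``table``.

    Columns: rule, decision, n_conditions, support, accuracy,
    theoretical_accuracy, comb_gain, p_value. Class sizes K come from the
    evaluation table itself; rules with zero support get missing statistics.
    """
    counts = table.class_counts()
    N = table.n_objects
    rows = []
    for rule in rules:
        n, k = evaluate_on_data(rule, table)
        if k is None:
            acc = theo = gain = p = np.nan
        else:
            acc = k / n
            theo = theoretical_accuracy(rule, table)
            gain = combinatorial_gain(acc, theo)
            p = hypergeometric_pvalue(n, k, counts[rule.decision], N)
            theo = np.nan if theo is None else theo
            gain = np.nan if gain is None else gain
        rows.append(
            {
                "rule": " AND ".join(f"{a} = {v}" for a, v in rule.conditions),
                "decision": rule.decision,
                "n_conditions": len(rule.conditions),
                "support": n,
                "accuracy": acc,
                "theoretical_accuracy": theo,
                "comb_gain": gain,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def cooccurrence_counts(rules, by_class: bool = True):
    """Symmetric condition-pair co-occurrence counts across rules.

    For each unordered pair of conditions (attribute = value), count the
    rules containing both. Returns a dict keyed by decision class when
    ``by_class`` (the default), otherwise a single matrix over all rules.
    """

    def _matrix(rule_list) -> pd.DataFrame:
        labels = sorted(
            {f"{a} = {v}" for r in rule_list for a, v in r.conditions}
        )
        mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
        for rule in rule_list:
            conds = sorted(f"{a} = {v}" for a, v in rule.conditions)
            for c1, c2 in combinations(conds, 2):
                mat.loc[c1, c2] += 1
                mat.loc[c2, c1] += 1
        return mat

    if not by_class:
        return _matrix(list(rules))
    out = {}
    for cls in sorted({r.decision for r in rules}):
        out[cls] = _matrix([r for r in rules if r.decision == cls])
    return out
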