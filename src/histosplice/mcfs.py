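"""Monte Carlo feature selection over binary decision attributes.

Attribute importance is aggregated over many small decision trees: ``s``
random subsets of ``m`` attributes are drawn, and on each subset ``t`` trees
are grown on class-balanced random train/test splits. The relative
importance of attribute *k* is

    RI_k = sum over trees  (wAcc)^u * sum over nodes splitting on k
           [ GR(node) * (n_node / n_root)^v ]

with gain-ratio splits, ``u = 0`` (tree-accuracy weighting off) and
``v = 1`` at the defaults. Significance comes from re-running the whole
procedure on label-permuted tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exons import DecisionTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCFSParams:
    """Tunables of the Monte Carlo feature selection run.

    The desk-scale default uses ``s = 500`` subsets; :meth:`full_scale`
    restores the full ``s = 5000`` setting. ``u``/``v`` are the exponents on
    the tree accuracy weight and the node-fraction weight.
    """

    s: int = 500
    m: int = 10
    t: int = 5
    u: float = 0.0
    v: float = 1.0
    split_ratio: float = 0.66
    balance_classes: bool = True
    balance_ratio: float = 1.0
    cutpoint_runs: int = 30
    alpha: float = 0.05
    min_leaf: int = 2

    def __post_init__(self):
        if min(self.s, self.m, self.t) < 1:
            raise ValueError("s, m and t must all be >= 1")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")

    @classmethod
    def full_scale(cls, **kwargs) -> "MCFSParams":
        return cls(**{"s": 5000, **kwargs})

    def replace(self, **kwargs) -> "MCFSParams":
        return replace(self, **kwargs)


def _entropy(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binary entropy of pos/n, elementwise, with 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, pos / np.maximum(n, 1), 0.0)
        h = -(np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0)
              + np.where(p < 1, (1 - p) * np.log2(np.maximum(1 - p, 1e-300)), 0.0))
    return np.where(n > 0, h, 0.0)


class _Tree:
    """A gain-ratio decision tree over binary attributes.

    Grown greedily: at each node the attribute with the highest gain ratio
    (among attributes with positive information gain and both children at
    least ``min_leaf`` objects) is chosen; ties go to the lowest attribute
    index. Nodes record (attribute, gain ratio, node size) for the RI sum.
    """

    __slots__ = ("nodes", "n_root", "_tree")

    def __init__(self, X: np.ndarray, y: np.ndarray, min_leaf: int = 2):
        self.nodes: list[tuple[int, float, int]] = []
        self.n_root = len(y)
        used = np.zeros(X.shape[1], dtype=bool)
        self._tree = self._grow(X, y, np.arange(len(y)), used, min_leaf)

    def _grow(self, X, y, idx, used, min_leaf):
        ysub = y[idx]
        n = len(idx)
        n_pos = int(ysub.sum())
        majority = bool(n_pos * 2 >= n)
        if n_pos == 0 or n_pos == n or n < 2 * min_leaf or used.all():
            return majority
        sub = X[idx]
        n1 = sub.sum(axis=0)
        n0 = n - n1
        pos1 = sub[ysub].sum(axis=0) if n_pos else np.zeros_like(n1)
        pos0 = n_pos - pos1
        h_parent = _entropy(np.array([n_pos]), np.array([n]))[0]
        h_children = (n0 * _entropy(pos0, n0) + n1 * _entropy(pos1, n1)) / n
        ig = h_parent - h_children
        split_info = _entropy(n1, np.full_like(n1, n))
        valid = (~used) & (n0 >= min_leaf) & (n1 >= min_leaf) & (ig > 1e-12)
        if not valid.any():
            return majority
        gr = np.where(valid & (split_info > 0), ig / np.maximum(split_info, 1e-300),
                      -np.inf)
        a = int(np.argmax(gr))
        self.nodes.append((a, float(gr[a]), n))
        mask = X[idx, a].astype(bool)
        used_child = used.copy()
        used_child[a] = True
        left = self._grow(X, y, idx[~mask], used_child, min_leaf)
        right = self._grow(X, y, idx[mask], used_child, min_leaf)
        return (a, left, right)

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X), dtype=bool)
        for i, row in enumerate(X):
            node = self._tree
            while not isinstance(node, bool):
                a, left, right = node
                node = right if row[a] else left
            out[i] = node
        return out


def _balanced_split(idx_pos, idx_neg, split_ratio, balance, balance_ratio, rng):
    """Stratified train/test split with optional majority subsampling."""
    parts = []
    test_parts = []
    for idx in (idx_pos, idx_neg):
        perm = rng.permutation(idx)
        n_train = max(1, int(round(split_ratio * len(idx))))
        n_train = min(n_train, len(idx) - 1) if len(idx) > 1 else n_train
        parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    if balance:
        sizes = [len(p) for p in parts]
        target = int(round(min(sizes) * balance_ratio))
        for i in range(2):
            if len(parts[i]) > target:
                parts[i] = rng.choice(parts[i], target, replace=False)
    train = np.concatenate(parts)
    test = np.concatenate(test_parts)
    return train, test


def _weighted_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class recalls (the MCFS wAcc convention)."""
    recalls = []
    for cls in (False, True):
        mask = y_true == cls
        if mask.any():
            recalls.append(float((y_pred[mask] == cls).mean()))
    return float(np.mean(recalls)) if recalls else np.nan


def rank_attributes(
    table: DecisionTable,
    params: MCFSParams | None = None,
    rng: np.random.Generator | int | None = None,
    return_details: bool = False,
):
    """Relative importance per attribute, sorted by decreasing RI.

    Returns a frame with columns ``name`` and ``ri`` (plus a details dict
    with the per-tree weighted accuracies when requested).
    """
    params = params or MCFSParams()
    rng = np.random.default_rng(rng)
    X = table.attributes.to_numpy(np.uint8)
    names = np.array(table.attribute_names)
    y = (table.decision == "spliced_out").to_numpy()
    if y.all() or not y.any():
        raise ValueError("MCFS requires objects from both decision classes")
    idx_pos = np.flatnonzero(y)
    idx_neg = np.flatnonzero(~y)

    n_attrs = X.shape[1]
    m = min(params.m, n_attrs)
    ri = np.zeros(n_attrs)
    waccs = []
    for _ in range(params.s):
        subset = rng.choice(n_attrs, size=m, replace=False)
        Xs = X[:, subset]
        for _ in range(params.t):
            train, test = _balanced_split(
                idx_pos, idx_neg, params.split_ratio, params.balance_classes,
                params.balance_ratio, rng,
            )
            tree = _Tree(Xs[train], y[train], params.min_leaf)
            wacc = (
                _weighted_accuracy(y[test], tree.predict(Xs[test]))
                if len(test) else np.nan
            )
            waccs.append(wacc)
            weight = 1.0 if params.u == 0 else (wacc if np.isfinite(wacc) else 0.0) ** params.u
            for a_local, gr, n_node in tree.nodes:
                ri[subset[a_local]] += weight * gr * (n_node / tree.n_root) ** params.v

    ranking = pd.DataFrame({"name": names, "ri": ri})
    ranking = ranking.sort_values(["ri", "name"], ascending=[False, True],
                                  kind="stable").reset_index(drop=True)
    if return_details:
        return ranking, {"wacc": np.array(waccs)}
    return ranking


def permutation_significance(
    table: DecisionTable,
    params: MCFSParams | None = None,
    rng: np.random.Generator | int | None = None,
    observed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Permutation p-values for the RI scores.

    The full ranking is recomputed ``cutpoint_runs`` times on tables with
    permuted decision labels; the p-value of attribute *k* is the smoothed
    fraction ``(1 + #{runs with RI_perm >= RI_obs}) / (runs + 1)``, and
    ``selected`` flags p < alpha.
    """
    params = params or MCFSParams()
    rng = np.random.default_rng(rng)
    if observed is None:
        observed = rank_attributes(table, params, rng)
    obs = observed.set_index("name")["ri"]
    exceed = pd.Series(0, index=obs.index, dtype=int)
    for _ in range(params.cutpoint_runs):
        permuted = DecisionTable(
            table.attributes,
            pd.Series(rng.permutation(table.decision.to_numpy()),
                      index=table.decision.index),
        )
        perm = rank_attributes(permuted, params, rng).set_index("name")["ri"]
        exceed += (perm.reindex(obs.index) >= obs).astype(int)
    p = (1 + exceed) / (params.cutpoint_runs + 1)
    out = observed.copy()
    out["p_value"] = p.reindex(out["name"]).to_numpy()
    out["selected"] = out["p_value"] < params.alpha
    return out


def select_top(ranking: pd.DataFrame, k: int = 20) -> list[str]:
    """The k attributes with the largest RI, ties broken by name.

    When the ranking carries permutation p-values, only significant
    attributes are eligible; if fewer than k are significant all of them are
    returned with a warning.
    """
    pool = ranking
    if "selected" in ranking.columns:
        pool = ranking[ranking["selected"]]
        if len(pool) < k:
            logger.warning(
                "only %d significant attributes available (requested %d)",
                len(pool), k,
            )
    pool = pool.sort_values(["ri", "name"], ascending=[False, True], kind="stable")
    return pool["name"].head(k).tolist()
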