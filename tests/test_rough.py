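"""Discernibility, Johnson approximate reducts, rule induction and voting."""

import itertools
import math

import numpy as np
import pytest

import histosplice as hs
from histosplice.rough import johnson_approximate_reduct
from tests.conftest import random_table, table_from_arrays


def brute_force_min_hitting_set(matrix) -> int:
    """Exhaustive minimum hitting-set size for a full-coverage instance."""
    matrix = np.asarray(matrix, dtype=bool)
    n_attrs = matrix.shape[1]
    for size in range(1, n_attrs + 1):
        for combo in itertools.combinations(range(n_attrs), size):
            if matrix[:, combo].any(axis=1).all():
                return size
    raise AssertionError("no hitting set exists")


class TestObjectDiscernibility:
    def test_matches_exhaustive_pairwise_comparison(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, 30, 5)
        X = table.attributes.to_numpy()
        y = table.decision.to_numpy()
        for pos in range(table.n_objects):
            disc = hs.object_discernibility(table, pos)
            expected = []
            for j in range(table.n_objects):
                if y[j] != y[pos]:
                    diff = set(np.flatnonzero(X[j] != X[pos]))
                    if diff:
                        expected.append((j, diff))
            got = [
                (int(j), set(np.flatnonzero(row)))
                for j, row in zip(disc.opposite_index, disc.matrix)
            ]
            assert got == expected

    def test_single_discerning_attribute(self):
        t = table_from_arrays(
            [[1, 0], [0, 0], [0, 0]],
            ["spliced_out", "included", "included"],
        )
        disc = hs.object_discernibility(t, 0)
        assert disc.n_entries == 2
        assert all(set(np.flatnonzero(r)) == {0} for r in disc.matrix)

    def test_duplicate_opposite_object_flagged_inconsistent(self):
        t = table_from_arrays(
            [[1, 0], [1, 0], [0, 1]],
            ["spliced_out", "included", "included"],
        )
        disc = hs.object_discernibility(t, 0)
        assert list(disc.inconsistent_index) == [1]
        assert disc.n_entries == 1


class TestJohnsonReduct:
    def test_single_column_instance(self):
        matrix = np.zeros((4, 3), dtype=bool)
        matrix[:, 1] = True
        assert johnson_approximate_reduct(matrix, 1.0) == [1]

    def test_stops_at_hitting_fraction(self):
        # a0 hits 8 of 10 entries, a1 hits the other 2
        matrix = np.zeros((10, 2), dtype=bool)
        matrix[:8, 0] = True
        matrix[8:, 1] = True
        assert johnson_approximate_reduct(matrix, 0.80) == [0]
        assert sorted(johnson_approximate_reduct(matrix, 1.0)) == [0, 1]

    @pytest.mark.parametrize("hf", [0.0, -0.1, 1.2])
    def test_invalid_hitting_fraction(self, hf):
        with pytest.raises(ValueError):
            johnson_approximate_reduct(np.ones((2, 2), dtype=bool), hf)

    def test_greedy_vs_exhaustive_oracle(self):
        """Full-coverage greedy reducts respect the classical set-cover bound."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            n_entries = int(rng.integers(5, 60))
            n_attrs = int(rng.integers(3, 10))
            matrix = rng.random((n_entries, n_attrs)) < 0.3
            matrix = matrix[matrix.any(axis=1)]
            if matrix.shape[0] == 0:
                continue
            reduct = johnson_approximate_reduct(matrix, 1.0)
            # 100% coverage
            assert matrix[:, reduct].any(axis=1).all()
            # minimal by removal
            for a in reduct:
                rest = [b for b in reduct if b != a]
                assert not (rest and matrix[:, rest].any(axis=1).all())
            # classical H(d) approximation bound for greedy set cover
            opt = brute_force_min_hitting_set(matrix)
            d = matrix.sum(axis=0).max()
            harmonic = sum(1.0 / k for k in range(1, d + 1))
            assert len(reduct) <= math.ceil(harmonic * opt)
            # partial coverage respects its threshold
            partial = johnson_approximate_reduct(matrix, 0.8)
            covered = matrix[:, partial].any(axis=1).mean()
            assert covered >= 0.8


class TestRuleInduction:
    def hand_table(self):
        # planted 2-condition pattern (a1=1, a2=1) separates the classes,
        # with single-attribute leakage in the included class
        return table_from_arrays(
            [
                [1, 1, 0, 0],  # spliced, planted pattern
                [1, 1, 0, 1],  # spliced, planted + background
                [0, 0, 0, 0],
                [1, 0, 0, 0],
                [0, 1, 0, 0],
            ],
            ["spliced_out", "spliced_out", "included", "included", "included"],
        )

    def test_exact_reducts_recover_planted_condition_set(self):
        rules = hs.induce_rules(self.hand_table(), hitting_fraction=1.0)
        keys = {(r.conditions, r.decision) for r in rules}
        planted = ((("a1", 1), ("a2", 1)), "spliced_out")
        assert planted in keys
        planted_rule = next(r for r in rules if r.conditions == planted[0])
        assert planted_rule.support == 2
        assert planted_rule.accuracy == 1.0

    def test_rule_from_single_object(self):
        t = table_from_arrays(
            [[1, 0], [0, 0], [0, 1]],
            ["spliced_out", "included", "included"],
        )
        rule = hs.rule_from_object(t, 0, hitting_fraction=1.0)
        assert rule.conditions == (("a1", 1),)
        assert rule.decision == "spliced_out"

    def test_identical_objects_yield_one_rule(self):
        t = table_from_arrays(
            [[1, 0], [1, 0], [0, 1]],
            ["spliced_out", "spliced_out", "included"],
        )
        rules = hs.induce_rules(t, hitting_fraction=1.0)
        assert len([r for r in rules if r.decision == "spliced_out"]) == 1

    def test_consistent_table_objects_covered_by_own_rules(self):
        """At hitting fraction 1, each object's rule matches and classifies it."""
        rng = np.random.default_rng(5)
        X = (rng.random((40, 6)) < 0.4).astype(np.uint8)
        # decision as a deterministic function of the pattern => consistent
        y = np.where(X[:, 0] ^ X[:, 1], "spliced_out", "included")
        if len(set(y)) < 2:
            raise AssertionError("degenerate test setup")
        t = table_from_arrays(X, y)
        for pos in range(t.n_objects):
            rule = hs.rule_from_object(t, pos, hitting_fraction=1.0)
            assert rule is not None
            assert rule.matches(t.attributes)[pos]
            pred = hs.classify([rule.with_stats(1, 1.0)],
                               t.attributes.iloc[[pos]])
            assert pred[0] == y[pos]


class TestFilterAndClassify:
    def make(self, conds, dec, support, acc):
        return hs.Rule(conds, dec, support, acc)

    def test_filter_thresholds(self):
        rules = [
            self.make((("a1", 1),), "included", 5, 0.9),
            self.make((("a2", 1),), "included", 150, 0.9),
        ]
        assert len(hs.filter_rules(rules, 100, 0.7)) == 1
        assert len(hs.filter_rules(rules, 0, 0.0)) == 2

    def test_published_rules_pass_default_filter(self):
        from histosplice.reference import REFERENCE_RULES

        rules = [
            self.make(tuple(r["conditions"]), r["decision"], r["support"],
                      r["accuracy"])
            for r in REFERENCE_RULES
        ]
        assert len(hs.filter_rules(rules)) == len(rules)

    def test_voting_and_abstention(self):
        import pandas as pd

        attrs = pd.DataFrame(
            {"a1": [1, 0, 1], "a2": [0, 0, 1]}, index=["x", "y", "z"])
        r1 = self.make((("a1", 1),), "spliced_out", 10, 1.0)
        r2 = self.make((("a2", 1),), "included", 10, 1.0)
        preds = hs.classify([r1, r2], attrs)
        assert preds[0] == "spliced_out"  # only r1 fires
        assert preds[1] is None           # nothing fires
        assert preds[2] is None           # equal-weight tie
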