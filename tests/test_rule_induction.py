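"""SOM updates, binarization, FP-growth and predominance filtering."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest

import fuzzybiopsy as fb
from fuzzybiopsy.cohort import NEGATIVE, POSITIVE
from fuzzybiopsy.rule_induction import (BinarizationScheme, InductionConfig,
                                        SOMConfig, SOMGrid, assign_clusters,
                                        binarize, default_binarization_scheme,
                                        fp_growth, induce_rule_base,
                                        match_counts, maximal_itemsets,
                                        score_predominance, som_update,
                                        train_som)
from conftest import make_separable_cohort


def grid_with(weights: np.ndarray, **cfg) -> SOMGrid:
    return SOMGrid(np.array(weights, dtype=float), SOMConfig(**cfg))


class TestSom:
    def test_winner_at_input_is_unchanged(self):
        w = np.tile(np.arange(16, dtype=float)[:, None], (1, 2))
        grid = grid_with(w.copy())
        som_update(grid, np.array([5.0, 5.0]))    # equals neuron 5's weight
        assert np.allclose(grid.weights[5], [5.0, 5.0])

    def test_winner_step_is_eta_times_error(self):
        # winner at (0,0), input (1,1): step = 1 * 0.4 * (x - w) = (0.4, 0.4)
        w = np.full((16, 2), 10.0)
        w[0] = [0.0, 0.0]
        grid = grid_with(w)
        som_update(grid, np.array([1.0, 1.0]))
        assert np.allclose(grid.weights[0], [0.4, 0.4])

    def test_distance1_neighbor_half_step(self):
        # neuron 1 is lattice-distance 1 from winner 0: step 0.5*0.4 = 0.2
        w = np.full((16, 2), 10.0)
        w[0] = [0.0, 0.0]
        w[1] = [0.0, 0.0]
        # make neuron 0 the unique winner for x near the origin
        w[0] = [0.1, 0.1]
        grid = grid_with(w)
        som_update(grid, np.array([1.0, 1.0]))
        assert np.allclose(grid.weights[1], [0.2, 0.2])

    def test_far_neurons_untouched(self):
        w = np.full((16, 2), 10.0)
        w[0] = [0.0, 0.0]
        grid = grid_with(w.copy())
        som_update(grid, np.array([1.0, 1.0]))
        # Chebyshev distance >= 2 from corner neuron 0: indices 2,3, 8..
        for far in (2, 3, 8, 10, 15):
            assert np.allclose(grid.weights[far], w[far])

    def test_manhattan_excludes_diagonal(self):
        w = np.full((16, 2), 10.0)
        w[0] = [0.0, 0.0]
        grid = grid_with(w, lattice="manhattan")
        som_update(grid, np.array([1.0, 1.0]))
        assert np.allclose(grid.weights[5], [10.0, 10.0])  # diagonal neighbor

    def test_repeated_record_converges_monotonically(self):
        rng = np.random.default_rng(0)
        grid = grid_with(rng.uniform(0, 1, (16, 3)))
        x = np.array([0.7, 0.2, 0.9])
        win = int(np.argmin(np.sum((grid.weights - x) ** 2, axis=1)))
        prev = np.linalg.norm(grid.weights[win] - x)
        for _ in range(20):
            som_update(grid, x)
            dist = np.linalg.norm(grid.weights[win] - x)
            assert dist <= prev + 1e-12
            prev = dist
        assert prev < 1e-3

    def test_training_deterministic(self):
        X = np.random.default_rng(1).uniform(0, 1, (40, 5))
        cfg = SOMConfig(seed=4, epochs=10)
        assert np.array_equal(train_som(X, cfg).weights,
                              train_som(X, cfg).weights)

    def test_assignment_matches_brute_force(self):
        rng = np.random.default_rng(2)
        grid = grid_with(rng.uniform(0, 1, (16, 4)))
        X = rng.uniform(0, 1, (50, 4))
        assigned = assign_clusters(grid, X)
        for i, x in enumerate(X):
            d = [float(np.sum((w - x) ** 2)) for w in grid.weights]
            assert assigned[i] == int(np.argmin(d))

    def test_tie_breaks_to_lowest_index(self):
        w = np.zeros((16, 2))
        w[3] = [1.0, 0.0]
        w[7] = [1.0, 0.0]
        grid = grid_with(w)
        assert assign_clusters(grid, np.array([[1.0, 0.0]]))[0] == 3

    def test_empty_input_rejected(self):
        with pytest.raises(Exception):
            train_som(np.empty((0, 3)), SOMConfig())


class TestBinarize:
    def test_interval_membership(self, separable_cohort):
        scheme = default_binarization_scheme()
        tx = binarize(separable_cohort, scheme)
        j = tx.items.index("psa_density=high")
        pos_rows = [i for i, r in enumerate(separable_cohort)
                    if r.label == POSITIVE]
        assert all(tx.matrix[i, j] == 1 for i in pos_rows)

    def test_one_item_per_variable(self, study_cohort):
        tx = binarize(study_cohort)
        assert np.all(tx.matrix.sum(axis=1) == 6)

    def test_categorical_items(self, separable_cohort):
        tx = binarize(separable_cohort)
        assert np.all(tx.matrix[:, tx.items.index("dre=negative")] == 1)
        assert np.all(tx.matrix[:, tx.items.index("dre=positive")] == 0)

    def test_uncovered_value_named(self):
        from fuzzybiopsy.rule_induction import Interval
        scheme = BinarizationScheme(
            numeric={"psa_density": (Interval("low", 0.0, 0.05),),
                     "n_lesions": (Interval("any", 1.0, 99.0),)},
            categorical={"dre": ("negative", "positive"),
                         "prior_biopsy": ("no", "yes"),
                         "lesion_location": ("peripheral",
                                             "transitional_anterior"),
                         "pirads": ("3", "4", "5")})
        cohort = make_separable_cohort(3)
        with pytest.raises(Exception, match="psa_density"):
            binarize(cohort, scheme)


def brute_force_itemsets(transactions, min_support):
    """Enumerate every sub-itemset of every transaction and count support."""
    counts = Counter()
    for t in transactions:
        items = sorted(t)
        for r in range(1, len(items) + 1):
            for combo in itertools.combinations(items, r):
                counts[frozenset(combo)] += 1
    n = len(transactions)
    return {s: c for s, c in counts.items() if c >= min_support * n - 1e-9}


class TestFpGrowth:
    def test_hand_example(self):
        tx = [frozenset("AB"), frozenset("AB"), frozenset("A")]
        out = dict(fp_growth(tx, 0.6))
        assert out == {frozenset("A"): 3, frozenset("B"): 2,
                       frozenset("AB"): 2}

    def test_full_support_only_universal_items(self):
        tx = [frozenset("ABC"), frozenset("AB"), frozenset("AD")]
        out = dict(fp_growth(tx, 1.0))
        assert out == {frozenset("A"): 3}

    def test_empty_input(self):
        assert fp_growth([], 0.5) == []

    def test_invalid_support(self):
        with pytest.raises(ValueError):
            fp_growth([frozenset("A")], 0.0)

    @pytest.mark.parametrize("min_support", [0.1, 0.3, 0.5])
    def test_oracle_equivalence_random(self, min_support):
        rng = np.random.default_rng(int(min_support * 100))
        alphabet = [f"i{j}" for j in range(10)]
        for _ in range(10):
            tx = [frozenset(a for a in alphabet if rng.random() < 0.35)
                  for _ in range(30)]
            tx = [t for t in tx if t]
            assert dict(fp_growth(tx, min_support)) == \
                brute_force_itemsets(tx, min_support)

    def test_output_order_deterministic(self):
        tx = [frozenset("ABC"), frozenset("BC"), frozenset("AC"),
              frozenset("C")]
        out = fp_growth(tx, 0.25)
        supports = [c for _, c in out]
        assert supports == sorted(supports, reverse=True)
        assert out == fp_growth(tx, 0.25)


class TestMaximalItemsets:
    def test_subsets_removed(self):
        freq = [(frozenset("A"), 5), (frozenset("B"), 4),
                (frozenset("AB"), 3), (frozenset("C"), 2)]
        kept = dict(maximal_itemsets(freq))
        assert kept == {frozenset("AB"): 3, frozenset("C"): 2}


class TestPredominance:
    def test_pure_rule_kept(self):
        rule = score_predominance(frozenset({"dre=negative"}), 0, 10,
                                  threshold=2.0, provenance=(NEGATIVE, 1))
        assert rule is not None
        assert rule.consequent == NEGATIVE
        assert rule.predominance == 10.0

    def test_balanced_rule_discarded(self):
        assert score_predominance(frozenset({"x"}), 5, 5, 1.01,
                                  (POSITIVE, 0)) is None

    def test_no_match_discarded(self):
        assert score_predominance(frozenset({"x"}), 0, 0, 1.0,
                                  (POSITIVE, 0)) is None


class TestInduceRuleBase:
    def test_deterministic(self, study_cohort):
        cfg = InductionConfig(som=SOMConfig(seed=3, epochs=15))
        a = induce_rule_base(study_cohort, cfg)
        b = induce_rule_base(study_cohort, cfg)
        assert a == b

    def test_separable_cohort_yields_pure_rules(self, separable_cohort):
        rules = induce_rule_base(separable_cohort)
        assert rules
        for r in rules:
            assert min(r.n_match_pos, r.n_match_neg) == 0

    def test_match_counts_recount_oracle(self, study_cohort):
        scheme = default_binarization_scheme()
        rules = induce_rule_base(
            study_cohort, InductionConfig(som=SOMConfig(seed=5, epochs=15)))
        for rule in rules[:25]:
            n_pos = n_neg = 0
            for rec in study_cohort:
                items = {scheme.item_for(rec, v) for v in scheme.variables}
                if rule.antecedent <= items:
                    if rec.label == POSITIVE:
                        n_pos += 1
                    else:
                        n_neg += 1
            assert (rule.n_match_pos, rule.n_match_neg) == (n_pos, n_neg)

    def test_single_class_rejected(self, separable_cohort):
        only_pos = separable_cohort.subset(
            [i for i, r in enumerate(separable_cohort)
             if r.label == POSITIVE])
        with pytest.raises(Exception, match="both"):
            induce_rule_base(only_pos)

    def test_small_class_warns(self, separable_cohort):
        few = separable_cohort.subset(list(range(8)) + list(range(100, 108)))
        with pytest.warns(UserWarning, match="fewer"):
            induce_rule_base(few)
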