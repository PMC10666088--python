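"""Entropy, split search and one-vs-rest tree training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatetree import (
    HyperParams,
    TreeTrainingError,
    best_split,
    entropy_change,
    shannon_entropy,
    train_cell_type_tree,
    train_model,
)
from gatetree.trees import AT_MOST, GREATER, MarkerCondition, merge_conditions

from conftest import make_sample


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.5, 1.0), (0.0, 0.0), (1.0, 0.0), (0.25, 0.811278), (0.75, 0.811278)],
    )
    def test_closed_forms(self, p, expected):
        assert shannon_entropy(p) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("p", [-0.1, 1.1, 2.0])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            shannon_entropy(p)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_symmetric_and_bounded(self, p):
        h = shannon_entropy(p)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(shannon_entropy(1.0 - p), abs=1e-12)


class TestEntropyChange:
    def test_perfect_split_of_balanced_parent(self):
        assert entropy_change(0.5, 0.0, 1.0, 0.5) == pytest.approx(1.0)

    def test_children_equal_to_parent_gain_zero(self):
        assert entropy_change(0.3, 0.3, 0.3, 0.4) == pytest.approx(0.0)

    def test_worked_example(self):
        # parent: 100 cells, 50 targets; left: 60 cells / 50 targets; right: 40 / 0
        gain = entropy_change(0.5, 50 / 60, 0.0, 0.6)
        assert gain == pytest.approx(0.609987, abs=1e-6)

    def test_inconsistent_split_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            entropy_change(0.5, 1.0, 1.0, 0.5)

    @settings(max_examples=300, derandomize=True)
    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.001, max_value=0.999),
    )
    def test_concavity_gain_never_negative(self, left_p, right_p, w):
        parent_p = w * left_p + (1 - w) * right_p
        assert entropy_change(parent_p, left_p, right_p, w) >= -1e-12


def brute_force_best_split(X, target):
    """Independent exhaustive oracle over every (marker, midpoint) candidate."""
    n = X.shape[0]
    best = None
    for m in range(X.shape[1]):
        xs = np.unique(X[:, m])
        for thr in (xs[:-1] + xs[1:]) / 2.0:
            left = X[:, m] <= thr
            nl = int(left.sum())
            pl = target[left].mean() if nl else 0.0
            pr = target[~left].mean() if n - nl else 0.0
            gain = entropy_change(
                target.mean(), float(pl), float(pr), nl / n
            )
            if gain > 0 and (best is None or gain > best[0]):
                direction = GREATER if pr > pl else AT_MOST
                best = (gain, m, float(thr), direction)
    return best


class TestBestSplit:
    def test_perfect_one_marker_split(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [5.0]])
        target = np.array([False, False, False, True, True, True])
        cand = best_split(X, target)
        assert cand.threshold == pytest.approx(2.5)
        assert cand.gain == pytest.approx(1.0)
        assert cand.direction == GREATER

    def test_constant_marker_gives_no_split_signal(self):
        X = np.ones((10, 1))
        target = np.arange(10) < 5
        assert best_split(X, target) is None

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(15):
            n, m = int(rng.integers(20, 120)), int(rng.integers(2, 6))
            X = rng.normal(size=(n, m)) + rng.normal(size=m)
            target = rng.random(n) < 0.4
            if target.all() or not target.any():
                continue
            cand = best_split(X, target)
            oracle = brute_force_best_split(X, target)
            if oracle is None:
                assert cand is None
                continue
            gain, marker, thr, direction = oracle
            assert cand.marker_index == marker
            assert cand.threshold == pytest.approx(thr, abs=1e-9)
            assert cand.gain == pytest.approx(gain, abs=1e-9)
            assert cand.direction == direction

    def test_respects_node_mask(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        target = np.array([False, True, False, True])
        node = np.array([True, True, False, False])
        cand = best_split(X, target, node)
        assert cand.threshold == pytest.approx(0.5)


class TestMergeConditions:
    def test_same_marker_same_direction_tightest_bound(self):
        conds = [
            MarkerCondition("A", GREATER, 1.0),
            MarkerCondition("B", AT_MOST, 5.0),
            MarkerCondition("A", GREATER, 2.0),
            MarkerCondition("B", AT_MOST, 4.0),
        ]
        merged = merge_conditions(conds)
        assert merged == (
            MarkerCondition("A", GREATER, 2.0),
            MarkerCondition("B", AT_MOST, 4.0),
        )

    def test_opposite_directions_both_kept(self):
        conds = [
            MarkerCondition("A", GREATER, 1.0),
            MarkerCondition("A", AT_MOST, 3.0),
        ]
        assert merge_conditions(conds) == tuple(conds)


def _two_blob_reference(seed=0, separation=6.0, n=400, sd=1.0):
    rng = np.random.default_rng(seed)
    target = rng.normal([separation, separation], sd, size=(n, 2))
    rest = rng.normal([0.0, 0.0], sd, size=(n, 2))
    X = np.vstack([target, rest])
    labels = np.array(["hit"] * n + ["rest"] * n, dtype=object)
    return make_sample(X, labels=labels)


class TestTrainCellTypeTree:
    def test_well_separated_blobs_yield_tight_two_marker_rule(self):
        ref = _two_blob_reference()
        rule = train_cell_type_tree(ref, "hit")
        assert len(rule.conditions) >= 2
        assert len(set(rule.markers)) >= 2
        hit = ref.labels == "hit"
        captured = rule.mask(ref)
        assert (captured & hit).sum() / hit.sum() >= 0.99
        assert (captured & ~hit).sum() / (~hit).sum() <= 0.01

    def test_inseparable_target_raises(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 3))
        labels = np.where(rng.random(400) < 0.5, "hit", "rest").astype(object)
        ref = make_sample(X, labels=labels)
        with pytest.raises(TreeTrainingError, match="hit"):
            train_cell_type_tree(ref, "hit")

    def test_constructed_threshold_recovery(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 5, size=(400, 3))
        labels = np.where((X[:, 0] > 2) & (X[:, 1] > 3), "hit", "rest").astype(object)
        ref = make_sample(X, labels=labels)
        rule = train_cell_type_tree(ref, "hit")
        learned = {c.marker: c.threshold for c in rule.conditions}
        for marker, column, truth in (("m1", 0, 2.0), ("m2", 1, 3.0)):
            below = X[:, column][X[:, column] <= truth].max()
            above = X[:, column][X[:, column] > truth].min()
            assert below <= learned[marker] <= above, marker

    def test_too_few_target_cells(self):
        ref = make_sample([[0, 0], [1, 1], [2, 2]], labels=["a", "b", "b"])
        with pytest.raises(TreeTrainingError, match="at least 2"):
            train_cell_type_tree(ref, "a")

    def test_leaf_constraints_reported_in_rule(self):
        ref = _two_blob_reference()
        rule = train_cell_type_tree(ref, "hit")
        assert rule.leaf_target_fraction > 0.9
        assert 0.0 <= rule.leaf_purity <= 1.0


class TestTrainModel:
    def test_suite_reference_gives_rule_and_centroid_per_type(self, suite, model):
        types = suite.reference.gated_types()
        assert model.cell_types == types
        assert model.centroids.types == types
        assert all(len(r.conditions) >= 2 for r in model.rules)

    def test_ungated_never_gets_rule_or_centroid(self, model):
        assert "ungated" not in model.cell_types
        assert "ungated" not in model.centroids

    def test_retraining_is_bit_identical(self, suite, model):
        again = train_model(suite.reference, HyperParams())
        assert again.to_dict() == model.to_dict()

    def test_rules_reapplied_to_reference_keep_over_90pct(self, suite, model):
        for rule in model.rules:
            in_type = suite.reference.labels == rule.cell_type
            captured = rule.mask(suite.reference)
            assert (captured & in_type).sum() / in_type.sum() > 0.9
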