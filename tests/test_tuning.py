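"""Boundary tuning, reclassification, drift detection and the full pipeline."""

import numpy as np
import pytest

from gatetree import (
    CentroidSet,
    GatingRule,
    HyperParams,
    MarkerCondition,
    SampleError,
    aggregate_f,
    centroid_drift,
    reclassify,
    tune_rule,
)
from gatetree.labeling import LabelVector
from gatetree.trees import AT_MOST, GREATER
from gatetree.tuning import TunedRule

from conftest import make_sample


def _rule(cell_type, *conds):
    return GatingRule(
        cell_type=cell_type,
        conditions=tuple(MarkerCondition(m, d, t) for m, d, t in conds),
        leaf_target_fraction=0.95,
        leaf_purity=0.99,
    )


def _labels(values, sentinel="ungated"):
    values = np.asarray(values, dtype=object)
    return LabelVector(values, np.full(values.shape, "tree-label", dtype=object),
                       ungated_sentinel=sentinel)


def _cross_fixture(seed=0, n=4000, shift_m1=0.0):
    """Type A at (3,3); B overlaps A on m1, C overlaps A on m2.

    A's rule (m1 > 2, m2 > 2) has each threshold at a density crossing, so
    the tuned boundary should reproduce it up to sweep resolution.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal([3.0, 3.0], 0.5, size=(n, 2))
    b = rng.normal([1.0, 3.0], 0.5, size=(n, 2))
    c = rng.normal([3.0, 1.0], 0.5, size=(n, 2))
    X = np.vstack([a, b, c])
    X[:, 0] += shift_m1
    labels = np.array(["A"] * n + ["B"] * n + ["C"] * n, dtype=object)
    sample = make_sample(X, labels=labels)
    rule = _rule("A", ("m1", GREATER, 2.0), ("m2", GREATER, 2.0))
    reference_centroid = np.array([3.0, 3.0])
    return sample, rule, reference_centroid, _labels(labels)


class TestTuneRule:
    def _step(self, sample, marker):
        col = sample.marker_column(marker)
        return (col.max() - col.min()) / HyperParams().sweep_bins

    def test_no_batch_effect_keeps_thresholds(self):
        sample, rule, ref_cent, tentative = _cross_fixture()
        tuned = tune_rule(rule, sample, tentative, reference_centroid=ref_cent)
        for cond, thr in zip(rule.conditions, tuned.thresholds):
            step = self._step(sample, cond.marker)
            assert abs(thr - cond.threshold) <= 2 * step, cond.marker

    def test_pure_shift_moves_only_the_shifted_threshold(self):
        shift = 0.5
        sample, rule, ref_cent, tentative = _cross_fixture(shift_m1=shift)
        tuned = tune_rule(rule, sample, tentative, reference_centroid=ref_cent)
        step1 = self._step(sample, "m1")
        step2 = self._step(sample, "m2")
        assert abs(tuned.thresholds[0] - (2.0 + shift)) <= 2 * step1
        assert abs(tuned.thresholds[1] - 2.0) <= 2 * step2

    def test_expansion_halts_before_dense_opposing_mass(self):
        rng = np.random.default_rng(3)
        own = rng.normal([3.0, 3.0], 0.3, size=(1000, 2))
        opposing = np.column_stack([
            rng.normal(1.8, 0.15, size=3000),
            rng.normal(3.0, 0.3, size=3000),
        ])
        X = np.vstack([own, opposing])
        labels = np.array(["A"] * 1000 + ["other"] * 3000, dtype=object)
        sample = make_sample(X, labels=labels)
        rule = _rule("A", ("m1", GREATER, 2.4), ("m2", GREATER, 2.0))
        tuned = tune_rule(rule, sample, _labels(labels),
                          reference_centroid=np.array([3.0, 3.0]))
        admitted_opposing = tuned.mask(sample)[1000:]
        assert admitted_opposing.mean() <= 0.01

    def test_zero_tentative_cells_returns_untuned(self, caplog):
        sample, rule, ref_cent, _ = _cross_fixture(n=50)
        none = _labels(["ungated"] * sample.n_cells)
        with caplog.at_level("WARNING"):
            tuned = tune_rule(rule, sample, none, reference_centroid=ref_cent)
        assert tuned.thresholds == tuple(c.threshold for c in rule.conditions)
        assert "untuned" in caplog.text

    def test_tuned_region_contains_tentative_centroid(self, suite, model):
        from gatetree.labeling import tentative_label

        sample = model.prepare(suite.shifted_batch[0])
        tentative = tentative_label(model, sample)
        for rule in model.rules:
            tuned = tune_rule(rule, sample, tentative, model.params,
                              model.centroids[rule.cell_type])
            mask = tentative.labels == rule.cell_type
            centroid = sample.matrix[mask].mean(axis=0)
            for cond in tuned.conditions:
                v = centroid[sample.marker_index(cond.marker)]
                assert cond.admits(np.asarray(v)), (rule.cell_type, cond)


class TestReclassify:
    def _setup(self):
        X = [[5.0, 0.0], [0.0, 5.0], [5.0, 5.0], [0.0, 0.0]]
        sample = make_sample(X)
        ra = TunedRule(_rule("a", ("m1", GREATER, 2.0)), (2.0,), 0.05)
        rb = TunedRule(_rule("b", ("m2", GREATER, 2.0)), (2.0,), 0.20)
        tentative = _labels(["a", "b", "a", "ungated"])
        return sample, (ra, rb), tentative

    def test_single_match_gets_that_type(self):
        sample, rules, tentative = self._setup()
        out = reclassify(rules, sample, tentative)
        assert out.labels[0] == "a" and out.labels[1] == "b"

    def test_multi_match_goes_to_lowest_impurity(self):
        sample, rules, tentative = self._setup()
        out = reclassify(rules, sample, tentative)
        assert out.labels[2] == "a"  # impurity 0.05 < 0.20

    def test_no_match_is_ungated(self):
        sample, rules, tentative = self._setup()
        out = reclassify(rules, sample, tentative)
        assert out.labels[3] == "ungated"

    def test_impurity_tie_breaks_by_type_order(self):
        sample, (ra, rb), tentative = self._setup()
        rb = TunedRule(rb.base, rb.thresholds, ra.impurity)
        out = reclassify((ra, rb), sample, tentative)
        assert out.labels[2] == "a"


class TestCentroidDrift:
    def _cents(self, offsets):
        base = {"a": [0.0, 0.0], "b": [5.0, 5.0], "c": [9.0, 1.0], "d": [2.0, 8.0]}
        moved = {
            t: np.asarray(v, dtype=float) + offsets.get(t, 0.0)
            for t, v in base.items()
        }
        mk = ("m1", "m2")
        return CentroidSet(mk, base), CentroidSet(mk, moved)

    def test_identical_sets_do_not_drift(self):
        ref, new = self._cents({})
        assert centroid_drift(new, ref) is False

    def test_all_displaced_far_drifts(self):
        ref, new = self._cents({t: 1.0 for t in "abcd"})
        assert centroid_drift(new, ref) is True

    def test_exactly_half_is_not_a_strict_majority(self):
        ref, new = self._cents({"a": 1.0, "b": 1.0})
        assert centroid_drift(new, ref) is False

    def test_type_set_mismatch_errors(self):
        ref, _ = self._cents({})
        other = CentroidSet(("m1", "m2"), {"a": [0.0, 0.0]})
        with pytest.raises(SampleError):
            centroid_drift(other, ref)


class TestGateSample:
    def test_reference_self_gating_scores_high(self, suite, model):
        out = model.gate(suite.reference)
        f = aggregate_f(suite.reference.labels, out.labels, include_ungated=False)
        assert f > 0.9

    def test_no_batch_effect_converges_in_one_iteration(self, suite, model):
        out = model.gate(suite.reference)
        assert out.iterations == 1 and out.converged

    def test_shifted_sample_beats_untuned_ablation(self, suite, model):
        s = suite.shifted_batch[0]
        tuned = aggregate_f(s.labels, model.gate(s).labels, include_ungated=False)
        untuned = aggregate_f(
            s.labels, model.gate(s, tune=False).labels, include_ungated=False
        )
        assert tuned > untuned

    def test_background_only_sample_stays_ungated(self, model):
        rng = np.random.default_rng(17)
        X = rng.normal(0.6, 0.4, size=(2000, 8))
        s = make_sample(X, markers=model.marker_names)
        out = model.gate(s)
        assert (out.labels.labels == "ungated").mean() >= 0.95

    def test_label_conservation_at_every_stage(self, suite, model):
        out = model.gate(suite.shifted_batch[1])
        assert sum(out.labels.counts().values()) == suite.shifted_batch[1].n_cells

    def test_bit_identical_reruns(self, suite, model):
        a = model.gate(suite.shifted_batch[2])
        b = model.gate(suite.shifted_batch[2])
        np.testing.assert_array_equal(a.labels.labels, b.labels.labels)
        assert a.iterations == b.iterations
        assert [t.thresholds for t in a.tuned_rules] == [
            t.thresholds for t in b.tuned_rules
        ]

    def test_monotone_benefit_under_location_shift(self, suite, model):
        """Tuning never hurts (within noise) for shifts in [0, 1] arcsinh units."""
        from gatetree.simulate import BatchEffectSpec, apply_batch_effect

        base = suite.same_batch[0]
        for magnitude in (0.0, 0.4, 0.8):
            shifts = tuple(
                -magnitude if k % 2 == 0 else magnitude for k in range(8)
            )
            s = apply_batch_effect(base, BatchEffectSpec(shifts=shifts))
            tuned = aggregate_f(s.labels, model.gate(s).labels, include_ungated=False)
            untuned = aggregate_f(
                s.labels, model.gate(s, tune=False).labels, include_ungated=False
            )
            assert tuned >= untuned - 0.01, magnitude
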