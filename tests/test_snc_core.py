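"""Small-neighborhood clustering: chain growth, weights, classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import loop_chain_clustering
from osnc.errors import InputError, ShapeError
from osnc.evaluation import mask_agreement
from osnc.features import FeatureConfig, extract_features, flatten_samples
from osnc.snc_core import (
    ClusterModel,
    NeighborhoodParams,
    assign,
    class_distance,
    discover_classes,
    estimate_attribute_weights,
    neighbor_attribute_center,
    segment,
)


def make_model(means, mins, maxs, weights=None, sizes=None):
    means = np.atleast_2d(np.asarray(means, dtype=float))
    n, m = means.shape
    w = np.full(m, 1.0 / m) if weights is None else np.asarray(weights, dtype=float)
    sizes = np.ones(n, dtype=int) if sizes is None else np.asarray(sizes)
    return ClusterModel(
        n=n,
        class_means=means,
        attribute_weights=w,
        class_sizes=sizes,
        class_min=np.atleast_2d(np.asarray(mins, dtype=float)),
        class_max=np.atleast_2d(np.asarray(maxs, dtype=float)),
        densest_count=int(sizes.max()),
    )


class TestNeighborAttributeCenter:
    def test_k_zero_returns_the_sample_itself(self):
        samples = np.array([[0.2], [0.4], [0.9]])
        assert neighbor_attribute_center(samples, 1, 0, 0) == pytest.approx(0.4)

    def test_mean_over_sample_and_successors(self):
        samples = np.array([[2.0], [4.0], [6.0]])
        assert neighbor_attribute_center(samples, 0, 2, 0) == pytest.approx(4.0)

    def test_constant_attribute_mean_is_the_constant(self):
        samples = np.full((5, 2), 0.3)
        for K in range(4):
            assert neighbor_attribute_center(samples, 0, K, 1) == pytest.approx(0.3)

    def test_out_of_range_raises(self):
        with pytest.raises(IndexError):
            neighbor_attribute_center(np.zeros((3, 1)), 2, 2, 0)


class TestAttributeWeights:
    def test_identical_samples_give_unit_weights(self):
        samples = np.tile([0.4, 0.7], (6, 1))
        zeta, zeta_p, p = estimate_attribute_weights(samples, NeighborhoodParams())
        np.testing.assert_allclose(zeta, 1.0)
        assert zeta_p == 1.0 and p == 0  # first index on ties

    def test_chain_from_central_value_absorbs_only_itself(self):
        # values 0, 0.5, 1 with K covering all: start center 0.5, eps 0.05
        samples = np.array([[0.0], [0.5], [1.0]])
        zeta, _, _ = estimate_attribute_weights(
            samples, NeighborhoodParams(epsilon=0.05, K=2)
        )
        assert zeta[0] == pytest.approx(1 / 3)

    def test_constant_attribute_dominates_spread_attribute(self, rng):
        const = np.full(30, 0.5)
        spread = np.linspace(0, 1, 30)
        samples = np.column_stack([const, spread])
        zeta, zeta_p, p = estimate_attribute_weights(
            samples, NeighborhoodParams(epsilon=0.02)
        )
        assert zeta[0] > zeta[1]
        assert p == 0 and zeta_p == pytest.approx(zeta[0])


class TestDiscoverClasses:
    def test_two_tight_clusters(self):
        samples = np.array([[0.1], [0.11], [0.9], [0.09], [0.91]])
        model = discover_classes(samples, NeighborhoodParams(epsilon=0.05))
        assert model.n == 2
        np.testing.assert_allclose(sorted(model.class_means.ravel()), [0.1, 0.905], atol=0.01)
        assert model.class_sizes.sum() == 5

    def test_identical_samples_form_one_class(self):
        samples = np.tile([0.2, 0.8], (7, 1))
        model = discover_classes(samples, NeighborhoodParams())
        assert model.n == 1
        assert model.class_sizes[0] == 7
        assert model.densest_count == 7

    def test_matches_naive_chain_resimulation(self, rng):
        for _ in range(5):
            samples = rng.uniform(0, 1, size=(20, 2))
            eps = 0.25
            model = discover_classes(samples, NeighborhoodParams(epsilon=eps))
            labels, n = loop_chain_clustering(samples, eps)
            assert model.n == n
            # class ids are discovery-ordered in both, so sizes and means match
            np.testing.assert_array_equal(
                np.bincount(labels, minlength=n), model.class_sizes
            )
            for c in range(n):
                np.testing.assert_allclose(
                    model.class_means[c], samples[labels == c].mean(axis=0)
                )

    def test_deterministic_given_order(self, rng):
        samples = rng.uniform(0, 1, (30, 3))
        a = discover_classes(samples, NeighborhoodParams())
        b = discover_classes(samples, NeighborhoodParams())
        np.testing.assert_array_equal(a.class_sizes, b.class_sizes)
        np.testing.assert_allclose(a.class_means, b.class_means)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            discover_classes(np.empty((0, 2)), NeighborhoodParams())

    def test_max_classes_cap_attaches_leftovers(self):
        samples = np.array([[0.0], [0.3], [0.6], [0.9]])
        model = discover_classes(
            samples, NeighborhoodParams(epsilon=0.01, max_classes=2)
        )
        assert model.n == 2
        assert model.class_sizes.sum() == 4


class TestClassDistance:
    def test_zero_at_class_mean(self):
        model = make_model([[0.5, 0.5]], [[0.2, 0.1]], [[0.9, 0.8]])
        assert class_distance(np.array([0.5, 0.5]), model, 0) == 0.0

    def test_single_attribute_range_normalized_value(self):
        model = make_model([[10.0]], [[10.0]], [[20.0]], weights=[1.0])
        assert class_distance(np.array([15.0]), model, 0) == pytest.approx(0.5)

    def test_invariant_under_attribute_rescaling(self):
        model = make_model([[10.0, 3.0]], [[8.0, 1.0]], [[20.0, 5.0]], weights=[0.6, 0.4])
        x = np.array([15.0, 2.0])
        d0 = class_distance(x, model, 0)
        scaled = make_model(
            [[20.0, 3.0]], [[16.0, 1.0]], [[40.0, 5.0]], weights=[0.6, 0.4]
        )
        d1 = class_distance(np.array([30.0, 2.0]), scaled, 0)
        assert d1 == pytest.approx(d0)

    def test_zero_range_attribute_contributes_nothing(self):
        model = make_model([[0.5, 0.3]], [[0.5, 0.0]], [[0.5, 1.0]], weights=[0.5, 0.5])
        # attribute 0 has zero range even with x included
        d = class_distance(np.array([0.5, 0.8]), model, 0)
        assert d == pytest.approx(0.5 * 0.5 / 1.0)

    def test_bad_class_index_raises(self):
        model = make_model([[0.5]], [[0.0]], [[1.0]])
        with pytest.raises(IndexError):
            class_distance(np.array([0.5]), model, 3)


class TestAssign:
    def test_tie_resolves_to_lowest_index(self):
        model = make_model([[0.25], [0.75]], [[0.0], [0.5]], [[0.5], [1.0]], weights=[1.0])
        a = assign(np.array([0.5]), model)
        assert a.class_index == 0
        np.testing.assert_allclose(a.weights, [0.5, 0.5])

    def test_decision_weights_match_hand_computation(self):
        from osnc.snc_core import _decision_weights

        # distances (1, 3): lambda = (0.75, 0.25)
        np.testing.assert_allclose(_decision_weights(np.array([1.0, 3.0])), [0.75, 0.25])
        w = _decision_weights(np.array([1.0, 3.0, 6.0]))
        assert w.sum() == pytest.approx(1.0)
        assert np.argmax(w) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=2, max_size=8)
    )
    def test_weights_sum_to_one_and_agree_with_argmin(self, dists):
        from osnc.snc_core import _decision_weights

        d = np.array(dists)
        w = _decision_weights(d)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        # the smallest distance carries the largest weight (value-level:
        # distances equal at float resolution may share the maximum)
        assert w[np.argmin(d)] == w.max()

    def test_weight_strictly_decreasing_in_distance(self):
        from osnc.snc_core import _decision_weights

        base = np.array([1.0, 2.0, 3.0])
        bumped = np.array([1.0, 2.5, 3.0])
        assert _decision_weights(bumped)[1] < _decision_weights(base)[1]

    def test_single_class_gets_unit_weight(self):
        model = make_model([[0.5]], [[0.0]], [[1.0]])
        a = assign(np.array([0.9]), model)
        np.testing.assert_allclose(a.weights, [1.0])
        assert a.class_index == 0


class TestSegment:
    def test_two_region_image_recovered(self, rng):
        img = np.full((64, 64), 50, dtype=float)
        img[:, 32:] = 200
        img += rng.normal(0, 2, img.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        stack = extract_features(img, FeatureConfig())
        feats, _ = flatten_samples(stack, stride=2)
        model = discover_classes(feats, NeighborhoodParams(epsilon=0.15))
        mask = segment(stack, model)
        truth = (np.arange(64)[None, :] >= 32).astype(int) * np.ones((64, 1), dtype=int)
        res = mask_agreement(mask, truth)
        assert res.pixel_accuracy >= 0.95

    def test_single_class_model_labels_everything_zero(self, rng):
        img = rng.integers(100, 110, (8, 8), dtype=np.uint8)
        stack = extract_features(img, FeatureConfig(("gray",)))
        model = make_model([[0.5]], [[0.0]], [[1.0]])
        mask = segment(stack, model)
        assert mask.shape == (8, 8)
        assert np.all(mask == 0)

    def test_attribute_mismatch_raises(self, rng):
        img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        stack = extract_features(img, FeatureConfig(("gray", "local_mean")))
        model = make_model([[0.5]], [[0.0]], [[1.0]])
        with pytest.raises(ShapeError):
            segment(stack, model)
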