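import numpy as np
import pytest

from micsel import (
    FeatureMap,
    FeatureMatrix,
    ReliefConfig,
    ValidationError,
    class_center_order,
    feature_diff,
    features_to_channels,
    iterrelcen,
    nearest_neighbors,
    relieff_weights,
)
from oracles import (
    brute_force_center_order,
    brute_force_neighbors,
    brute_force_relieff,
)


def fm_from(values, labels):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return FeatureMatrix(
        values=values,
        labels=np.asarray(labels, dtype=int),
        map=FeatureMap(values.shape[1], 1),
    )


class TestFeatureDiff:
    def test_direct_arithmetic(self):
        assert feature_diff(0, np.array([0.3]), np.array([0.7]), (0.0, 1.0)) == \
            pytest.approx(0.4)
        assert feature_diff(0, np.array([5.0]), np.array([9.0]), (1.0, 9.0)) == \
            pytest.approx(0.5)

    def test_identical_samples(self):
        r = np.array([0.3, 0.9])
        assert feature_diff(1, r, r.copy(), (0.0, 2.0)) == 0.0

    def test_degenerate_range_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert feature_diff(0, np.array([1.0]), np.array([2.0]), (3.0, 3.0)) == 0.0


class TestNearestNeighbors:
    def test_one_dimensional_ordering(self):
        target = np.array([0.0])
        pool = np.array([[0.1], [0.5], [0.9]])
        idx = nearest_neighbors(target, pool, k=2)
        np.testing.assert_array_equal(idx, [0, 1])

    def test_ties_break_by_ascending_index(self):
        target = np.array([0.5])
        pool = np.array([[0.7], [0.3], [0.9]])  # 0.7 and 0.3 equidistant
        idx = nearest_neighbors(target, pool, k=1)
        assert idx[0] == 0

    def test_matches_exhaustive_sort(self):
        rng = np.random.default_rng(21)
        target = rng.uniform(size=5)
        pool = rng.uniform(size=(20, 5))
        got = nearest_neighbors(target, pool, k=3)
        np.testing.assert_array_equal(got, brute_force_neighbors(target, pool, 3))

    def test_pool_smaller_than_k_rejected(self):
        with pytest.raises(ValidationError):
            nearest_neighbors(np.zeros(2), np.zeros((2, 2)), k=3)


class TestRelieffWeights:
    def test_hand_evaluated_two_class_update(self):
        """Equal classes, m=1, k=1: hit diff 0.2 and miss diff 0.8 give
        weight -0.2 + (0.5/0.5)*0.8 = 0.6."""
        # feature range (0, 1); target 0.0, hit at 0.2, miss at 0.8
        fm = fm_from([[0.0], [0.2], [0.8], [1.0]], [0, 0, 1, 1])
        w = relieff_weights(fm, ReliefConfig(k=1), targets=[0])
        assert w.weights[0] == pytest.approx(0.6)

    def test_constant_feature_has_zero_weight(self):
        values = np.column_stack([np.full(12, 3.0),
                                  np.random.default_rng(0).uniform(size=12)])
        fm = fm_from(values, np.arange(12) % 2)
        with pytest.warns(UserWarning):
            w = relieff_weights(fm, ReliefConfig(k=2),
                                targets=np.arange(12))
        assert w.weights[0] == 0.0

    def test_three_class_prior_factor(self):
        """With three equal classes each miss class is scaled by
        (1/3)/(2/3) = 0.5; verified against the plain-loop oracle."""
        rng = np.random.default_rng(30)
        X = rng.uniform(size=(15, 4))
        y = np.arange(15) % 3
        fm = fm_from(X, y)
        targets = np.arange(15)
        w = relieff_weights(fm, ReliefConfig(k=2), targets=targets)
        np.testing.assert_allclose(
            w.weights, brute_force_relieff(X, y, 2, targets), atol=1e-12
        )

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(31)
        X = rng.uniform(size=(40, 6))
        y = rng.integers(0, 2, size=40)
        y[:6] = [0, 0, 0, 1, 1, 1]  # guarantee both classes have >= k+1
        fm = fm_from(X, y)
        targets = np.arange(40)
        w = relieff_weights(fm, ReliefConfig(k=3), targets=targets)
        np.testing.assert_allclose(
            w.weights, brute_force_relieff(X, y, 3, targets), atol=1e-12
        )

    def test_symmetric_hit_miss_feature_weighs_zero(self):
        # hit and miss diffs mirror each other across the four targets
        fm = fm_from([[0.0], [0.4], [0.6], [1.0]], [0, 0, 1, 1])
        w = relieff_weights(fm, ReliefConfig(k=1), targets=[0, 1, 2, 3])
        assert abs(w.weights[0]) < 1e-12

    def test_weights_bounded_on_normalized_input(self):
        rng = np.random.default_rng(32)
        X = rng.uniform(-1, 1, size=(60, 10))
        fm = fm_from(X, np.arange(60) % 2)
        w = relieff_weights(fm, ReliefConfig(k=5, seed=7))
        assert np.all(w.weights >= -1.0 - 1e-12)
        assert np.all(w.weights <= 1.0 + 1e-12)

    def test_ranking_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(33)
        X = rng.uniform(size=(30, 8))
        y = np.arange(30) % 2
        targets = np.arange(30)
        w1 = relieff_weights(fm_from(X, y), ReliefConfig(k=3), targets=targets)
        scale = rng.uniform(0.5, 20.0, size=8)
        shift = rng.uniform(-5, 5, size=8)
        w2 = relieff_weights(fm_from(X * scale + shift, y), ReliefConfig(k=3),
                             targets=targets)
        # the range normalization makes the weights themselves invariant
        np.testing.assert_allclose(w2.weights, w1.weights, atol=1e-10)

    def test_seeded_target_draw_is_reproducible(self, random_features):
        cfg = ReliefConfig(k=3, m=20, seed=123)
        w1 = relieff_weights(random_features, cfg)
        w2 = relieff_weights(random_features, cfg)
        np.testing.assert_array_equal(w1.weights, w2.weights)

    def test_class_smaller_than_k_plus_one_rejected(self):
        fm = fm_from([[0.0], [0.5], [1.0]], [0, 0, 1])
        with pytest.raises(ValidationError):
            relieff_weights(fm, ReliefConfig(k=1), targets=[0])


class TestClassCenterOrder:
    def test_center_sample_ranks_first(self):
        X = np.array([[0, 0], [4, 0], [0, 4], [4, 4], [2, 2]], dtype=float)
        y = np.zeros(5, dtype=int)
        order = class_center_order(fm_from(X, y), 0)
        assert order[0] == 4  # (2, 2) is the class center

    def test_single_sample_class(self):
        fm = fm_from([[1.0, 2.0], [5.0, 0.0]], [0, 1])
        np.testing.assert_array_equal(class_center_order(fm, 1), [1])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(40)
        X = rng.uniform(size=(10, 3))
        y = np.zeros(10, dtype=int)
        np.testing.assert_array_equal(
            class_center_order(fm_from(X, y), 0),
            brute_force_center_order(X, y, 0),
        )

    def test_empty_class_rejected(self):
        fm = fm_from([[0.0], [1.0]], [0, 0])
        with pytest.raises(ValidationError):
            class_center_order(fm, 1)


class TestIterRelCen:
    def small_fm(self, n_features=26, seed=50):
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(30, n_features))
        return fm_from(X, np.arange(30) % 2)

    def test_elimination_schedule(self):
        fm = self.small_fm(26)
        trace = iterrelcen(fm, ReliefConfig(k=3), N=10)
        assert trace.surviving_sizes() == [26, 16, 6, 0]
        assert len(trace.iterations) == 3
        # surviving sets strictly nested
        for rec in trace.iterations:
            assert set(rec.survivors) < set(rec.features)
            assert rec.removed.size == min(10, rec.features.size)

    def test_single_pass_equals_relieff_bitwise(self):
        """With N = n_features and a fixed target list, the one weight pass
        must reproduce plain Relieff exactly."""
        fm = self.small_fm(12)
        targets = np.arange(30)
        trace = iterrelcen(fm, ReliefConfig(k=3), N=12, targets=targets)
        assert len(trace.iterations) == 1
        ref = relieff_weights(fm, ReliefConfig(k=3), targets=targets)
        np.testing.assert_array_equal(
            trace.iterations[0].weights.weights, ref.weights
        )

    def test_no_rng_identical_traces(self):
        fm = self.small_fm(20)
        t1 = iterrelcen(fm, ReliefConfig(k=3), N=7)
        t2 = iterrelcen(fm, ReliefConfig(k=3), N=7)
        for a, b in zip(t1.iterations, t2.iterations):
            np.testing.assert_array_equal(a.removed, b.removed)
            np.testing.assert_array_equal(a.weights.weights, b.weights.weights)

    def test_evaluator_called_on_initial_and_each_surviving_set(self):
        fm = self.small_fm(9)
        seen = []

        def evaluator(ids):
            seen.append(np.array(ids))
            return float(len(ids))

        trace = iterrelcen(fm, ReliefConfig(k=3), N=3, evaluator=evaluator)
        assert [len(s) for s in seen] == [9, 6, 3]
        assert trace.initial_accuracy == 9.0
        assert trace.iterations[-1].accuracy is None  # final set is empty

    def test_evaluator_failure_reports_iteration(self):
        fm = self.small_fm(6)

        def evaluator(ids):
            if len(ids) <= 3:
                raise RuntimeError("boom")
            return 1.0

        with pytest.raises(RuntimeError, match="iteration"):
            iterrelcen(fm, ReliefConfig(k=3), N=3, evaluator=evaluator)

    def test_planted_features_outlive_noise(self):
        """5 informative features among 45 pure-noise ones: with N=5 the
        informative ones must survive longer than at least 40 noise features
        in >= 90% of 20 generator seeds."""
        successes = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 60
            y = np.arange(n) % 2
            X = rng.uniform(size=(n, 50))
            X[:, :5] += 0.8 * y[:, None]  # class-shifted informative features
            fm = fm_from(X, y)
            trace = iterrelcen(fm, ReliefConfig(k=5), N=5)
            removal_iter = np.empty(50, dtype=int)
            for i, rec in enumerate(trace.iterations):
                removal_iter[rec.removed] = i
            informative_iters = removal_iter[:5]
            noise_later_or_equal = sum(
                int((removal_iter[5:] < it).sum()) >= 40
                for it in informative_iters
            )
            if noise_later_or_equal == 5:
                successes += 1
        assert successes >= 18

    def test_invalid_removal_size_rejected(self):
        fm = self.small_fm(5)
        with pytest.raises(ValidationError):
            iterrelcen(fm, ReliefConfig(k=3), N=0)
        with pytest.raises(ValidationError):
            iterrelcen(fm, ReliefConfig(k=3), N=6)


class TestFeaturesToChannels:
    def test_index_arithmetic(self):
        np.testing.assert_array_equal(
            features_to_channels([0, 13, 25], n_bands=13), [0, 1]
        )

    def test_empty_set(self):
        assert features_to_channels([], n_bands=13).size == 0

    def test_full_feature_set_covers_all_channels(self):
        np.testing.assert_array_equal(
            features_to_channels(np.arange(767), n_bands=13), np.arange(59)
        )
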