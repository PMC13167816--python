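import numpy as np
import pytest

import optxfe as ox
from optxfe.cwinca import NcaWeights, nca_weights, select, threshold_range


def _labelled_noise(n=100, d=6, informative=1, seed=0, noise=0.3):
    """Feature 0..informative-1 = label + small noise; the rest pure noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 2], n // 2)
    X = rng.normal(size=(n, d))
    for j in range(informative):
        X[:, j] = y + noise * rng.normal(size=n)
    return X, y


def _complementary_planted(seed, n=96, d=15, k=3, delta=2.5):
    """Each class-1 sample is displaced along exactly one of k informative
    axes, so no subset of fewer than k features separates all samples."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 2], n // 2)
    X = rng.normal(size=(n, d))
    for i, s in enumerate(np.where(y == 1)[0]):
        X[s, i % k] += delta
    return X, y


class TestNcaWeights:
    def test_informative_feature_dominates(self):
        X, y = _labelled_noise(n=100, d=2, seed=0)
        w = nca_weights(X, y)
        assert w.weights[0] > w.weights[1]

    def test_duplicated_feature_gets_symmetric_weight(self):
        X, y = _labelled_noise(n=80, d=3, seed=1)
        X[:, 2] = X[:, 0]
        w = nca_weights(X, y)
        assert w.weights[2] == pytest.approx(w.weights[0], rel=0.10)

    def test_constant_feature_not_above_informative(self):
        X, y = _labelled_noise(n=80, d=3, seed=2)
        X[:, 2] = 7.0
        w = nca_weights(X, y)
        assert w.weights[2] <= w.weights[0]

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            nca_weights(X, np.ones(10))

    def test_weights_non_negative_and_order_valid(self):
        X, y = _labelled_noise(n=60, d=5, seed=3)
        w = nca_weights(X, y)
        assert np.all(w.weights >= 0)
        assert sorted(w.order) == list(range(5))
        assert np.all(np.diff(w.weights[w.order]) <= 0)

    def test_deterministic(self):
        X, y = _labelled_noise(n=60, d=4, seed=4)
        np.testing.assert_array_equal(nca_weights(X, y).weights, nca_weights(X, y).weights)


class TestThresholdRange:
    def _w(self, values):
        v = np.asarray(values, dtype=float)
        return NcaWeights(weights=v, order=np.argsort(-v, kind="stable"))

    def test_hand_example(self):
        start, stop = threshold_range(self._w([0.5, 0.3, 0.1, 0.06, 0.04]))
        assert (start, stop) == (1, 5)

    def test_degenerate_mass(self):
        assert threshold_range(self._w([1.0, 0.0, 0.0])) == (1, 1)

    @pytest.mark.parametrize("m", [4, 5, 10, 100])
    def test_uniform_closed_form(self, m):
        start, stop = threshold_range(self._w(np.ones(m)))
        assert start == int(np.ceil(0.5 * m))
        assert stop == int(np.ceil(0.99 * m))

    def test_start_never_exceeds_stop(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            start, stop = threshold_range(self._w(rng.uniform(size=12)))
            assert start <= stop

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            threshold_range(self._w([0.0, 0.0]))


class TestSelect:
    def test_recovers_planted_informative_features(self):
        X, y = _complementary_planted(seed=0)
        res = select(X, y, seed=0)
        assert res.nsf >= 3
        assert {1, 2, 3}.issubset(set(res.ind.tolist()))
        assert max(res.per_k_accuracy.values()) == res.per_k_accuracy[res.nsf]

    def test_selected_accuracy_is_max_and_ties_go_small(self):
        X, y = _labelled_noise(n=60, d=8, informative=2, seed=7)
        res = select(X, y, seed=7)
        best = max(res.per_k_accuracy.values())
        winners = [k for k, v in res.per_k_accuracy.items() if v == best]
        assert res.nsf == min(winners)

    def test_collapsed_range_single_candidate(self):
        X, y = _labelled_noise(n=60, d=6, seed=8)
        res = select(X, y, t_low=0.7, t_high=0.7, seed=8)
        assert len(res.per_k_accuracy) == 1
        assert res.nsf == res.start_k == res.stop_k

    def test_sx_matches_indices(self):
        X, y = _labelled_noise(n=60, d=6, seed=9)
        res = select(X, y, seed=9)
        np.testing.assert_array_equal(res.SX, X[:, res.ind - 1])

    def test_deterministic(self):
        X, y = _labelled_noise(n=60, d=6, seed=10)
        a, b = select(X, y, seed=10), select(X, y, seed=10)
        np.testing.assert_array_equal(a.ind, b.ind)
        assert a.per_k_accuracy == b.per_k_accuracy

    def test_noise_feature_robustness(self):
        """Appending one pure-noise column leaves the selected informative
        subset unchanged in at least 9 of 10 seeded replicates."""
        informative = {1, 2, 3}
        hits = 0
        for seed in range(10):
            X, y = _complementary_planted(seed=seed)
            rng = np.random.default_rng(1000 + seed)
            X2 = np.column_stack([X, rng.normal(size=len(y))])
            base = set(select(X, y, seed=seed).ind.tolist()) & informative
            plus = set(select(X2, y, seed=seed).ind.tolist()) & informative
            hits += base == plus
        assert hits >= 9
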