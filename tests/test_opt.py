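import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import optxfe as ox
from optxfe.opt import OperatorBank, descending_identities, operator_outputs, opt_transform


class TestOperatorOutputs:
    def test_hand_example(self):
        outs = operator_outputs([3, 1], [2, 5], OperatorBank(epsilon=1e-12))
        np.testing.assert_allclose(outs[0], [3, 5])
        np.testing.assert_allclose(outs[1], [2, 1])
        np.testing.assert_allclose(outs[2], [5, 6])
        np.testing.assert_allclose(outs[3], [1, 4])
        np.testing.assert_allclose(outs[4], [1.5, 0.2], rtol=1e-9)

    def test_zero_vectors(self):
        outs = operator_outputs([0.0, 0.0], [0.0, 0.0])
        for o in outs[:4]:
            np.testing.assert_array_equal(o, [0.0, 0.0])
        np.testing.assert_array_equal(outs[4], [0.0, 0.0])

    def test_max_at_least_min(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=6), rng.normal(size=6)
            outs = operator_outputs(a, b)
            assert np.all(outs[0] >= outs[1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            operator_outputs([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            operator_outputs([1.0, np.nan], [1.0, 2.0])

    def test_ratio_near_negative_epsilon_stays_finite(self):
        eps = 1e-6
        outs = operator_outputs([1.0, 1.0], [-eps, -eps / 2], OperatorBank(epsilon=eps))
        assert np.all(np.isfinite(outs[4]))

    def test_bank_is_extensible(self):
        bank = OperatorBank(extra_operators=(("prod", lambda a, b: a * b),))
        assert len(bank) == 6
        outs = operator_outputs([2.0, 3.0], [4.0, 5.0], bank)
        np.testing.assert_allclose(outs[5], [8.0, 15.0])


class TestDescendingIdentities:
    @pytest.mark.parametrize(
        "v,expected",
        [([3, 5], [2, 1]), ([7, 7, 7], [1, 2, 3]), ([1, 3, 2], [2, 3, 1])],
    )
    def test_examples(self, v, expected):
        np.testing.assert_array_equal(descending_identities(v), expected)

    @given(arrays(np.float64, st.integers(2, 9),
                  elements=st.floats(-1e6, 1e6, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_sorted_values_non_increasing(self, v):
        order = descending_identities(v)
        sorted_v = v[order - 1]
        assert np.all(np.diff(sorted_v) <= 0)
        assert sorted(order) == list(range(1, len(v) + 1))


class TestOptTransform:
    def test_toy_hand_derivation(self, toy_matrix):
        expected = {
            1: [2, 1, 2, 1], 2: [1, 2, 2, 1], 3: [2, 1, 2, 1],
            4: [2, 1, 1, 2], 5: [1, 2, 2, 1],
        }
        for t in opt_transform(toy_matrix):
            np.testing.assert_array_equal(t.identities, expected[t.operator_index])

    def test_constant_signal_gives_identity_blocks(self):
        data = np.full((5, 4), 3.25)
        for t in opt_transform(data):
            np.testing.assert_array_equal(t.blocks(), np.tile([1, 2, 3, 4], (4, 1)))

    def test_length_and_count_contract(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(11, 5))
        ts = opt_transform(data)
        assert len(ts) == 5
        for t in ts:
            assert t.identities.size == 10 * 5

    @given(st.integers(0, 2**31 - 1), st.integers(3, 20), st.integers(2, 8))
    @settings(max_examples=30, deadline=None)
    def test_blocks_are_permutations(self, seed, n, cn):
        data = np.random.default_rng(seed).normal(size=(n, cn))
        for t in opt_transform(data):
            blocks = t.blocks()
            assert blocks.shape == (n - 1, cn)
            assert np.all(np.sort(blocks, axis=1) == np.arange(1, cn + 1))

    def test_positive_scaling_invariance(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(8, 4))
        base = opt_transform(data)
        scaled = opt_transform(1000.0 * data)
        for t0, t1 in zip(base, scaled):
            np.testing.assert_array_equal(t0.identities, t1.identities)

    def test_channel_permutation_equivariance(self):
        # relabelling channels by p relabels each identity i -> p^{-1}(i)
        rng = np.random.default_rng(7)
        data = rng.normal(size=(5, 4))  # continuous => tie-free a.s.
        p = np.array([2, 0, 3, 1])
        inv = np.argsort(p)
        permuted = data[:, p]
        for t_orig, t_perm in zip(opt_transform(data)[:4], opt_transform(permuted)[:4]):
            np.testing.assert_array_equal(t_perm.identities, inv[t_orig.identities - 1] + 1)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            opt_transform(np.ones((1, 4)))
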