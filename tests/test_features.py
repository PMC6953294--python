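import numpy as np
import pytest

from coevonet import features as F
from coevonet.msa import EncodedAlignment
from coevonet.nn.autodiff import Tensor

from conftest import brute_force_covariance, random_alignment


class TestWeightedFrequencies:
    def test_uniform_weights_reduce_to_plain_counts(self, toy_enc):
        single, pair = F.weighted_frequencies(toy_enc, np.ones(3))
        # {AC, AD, GC}: f(A at 0) = 2/3, f(C at 1) = 2/3, f(A0, C1) = 1/3
        assert single[0, 0] == pytest.approx(2 / 3)
        assert single[1, 1] == pytest.approx(2 / 3)
        assert pair[0, 1, 0, 1] == pytest.approx(1 / 3)

    def test_single_sequence_gives_one_hot(self):
        enc = EncodedAlignment(codes=np.array([[0, 5, 19]], dtype=np.int8))
        single, _ = F.weighted_frequencies(enc, np.ones(1))
        np.testing.assert_allclose(single.sum(axis=1), 1.0)
        assert single[0, 0] == 1.0 and single[1, 5] == 1.0 and single[2, 19] == 1.0

    def test_normalization(self):
        rng = np.random.default_rng(0)
        enc = random_alignment(rng, 7, 9)
        w = rng.random(7) + 0.1
        single, pair = F.weighted_frequencies(enc, w)
        np.testing.assert_allclose(single.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(pair.sum(axis=(2, 3)), 1.0, atol=1e-12)

    def test_nonpositive_weights_rejected(self, toy_enc):
        with pytest.raises(ValueError):
            F.weighted_frequencies(toy_enc, np.zeros(3))


class TestCovariance:
    def test_worked_example(self, toy_enc):
        single, pair = F.weighted_frequencies(toy_enc, np.ones(3))
        S = F.covariance(single, pair)
        # S(i=0, j=1, A, C) = 1/3 - (2/3)(2/3) = -1/9
        assert S[0, 1, 21 * 0 + 1] == pytest.approx(-1 / 9)

    def test_identical_sequences_give_zero(self):
        enc = EncodedAlignment(codes=np.tile([[3, 7, 11]], (5, 1)).astype(np.int8))
        single, pair = F.weighted_frequencies(enc, np.ones(5))
        np.testing.assert_allclose(F.covariance(single, pair), 0.0, atol=1e-15)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n, length = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            enc = random_alignment(rng, n, length)
            w = rng.random(n) + 0.05
            single, pair = F.weighted_frequencies(enc, w)
            S = F.covariance(single, pair)
            oracle = brute_force_covariance(enc.codes, w)
            assert np.max(np.abs(S - oracle)) <= 1e-12

    def test_pair_transpose_symmetry(self):
        rng = np.random.default_rng(2)
        enc = random_alignment(rng, 8, 12)
        single, pair = F.weighted_frequencies(enc, rng.random(8) + 0.1)
        S = F.covariance(single, pair)
        S4 = S.reshape(12, 12, 21, 21)
        np.testing.assert_allclose(S4, S4.transpose(1, 0, 3, 2), atol=1e-12)

    def test_entries_bounded(self):
        rng = np.random.default_rng(3)
        enc = random_alignment(rng, 10, 6)
        single, pair = F.weighted_frequencies(enc, rng.random(10) + 0.1)
        S = F.covariance(single, pair)
        assert np.all(np.abs(S) <= 0.25 + 1e-12)

    def test_differentiable_in_weights(self, toy_enc):
        w = Tensor(np.array([1.0, 1.0, 1.0]), requires_grad=True)
        single, pair = F.weighted_frequencies(toy_enc, w)
        S = F.covariance(single, pair)
        (S * S).sum().backward()
        assert w.grad is not None and np.all(np.isfinite(w.grad))

        def value(wv):
            s, p = F.weighted_frequencies(toy_enc, wv)
            return float((F.covariance(s, p) ** 2).sum())

        step = 1e-6
        for i in range(3):
            hi, lo = np.ones(3), np.ones(3)
            hi[i] += step
            lo[i] -= step
            fd = (value(hi) - value(lo)) / (2 * step)
            assert fd == pytest.approx(w.grad[i], rel=1e-4)


class TestDerivedFeatures:
    def test_pssm_is_weighted_frequencies(self):
        rng = np.random.default_rng(4)
        enc = random_alignment(rng, 6, 5)
        single, _ = F.weighted_frequencies(enc, np.ones(6))
        np.testing.assert_array_equal(F.pssm(single), single)
        np.testing.assert_allclose(F.pssm(single).sum(axis=1), 1.0)

    def test_entropy_closed_forms(self):
        conserved = np.zeros((1, 21))
        conserved[0, 3] = 1.0
        assert F.column_entropy(conserved)[0] == pytest.approx(0.0, abs=1e-12)
        two_state = np.zeros((1, 21))
        two_state[0, [0, 1]] = 0.5
        assert F.column_entropy(two_state)[0] == pytest.approx(np.log(2))
        uniform = np.full((1, 21), 1 / 21)
        assert F.column_entropy(uniform)[0] == pytest.approx(np.log(21))

    def test_mutual_information_independent_and_coupled(self):
        # X = AGAG, Y = CCDD: joint = product of marginals -> MI = 0
        indep = EncodedAlignment(
            codes=np.array([[0, 1], [5, 1], [0, 2], [5, 2]], dtype=np.int8)
        )
        single, pair = F.weighted_frequencies(indep, np.ones(4))
        mi = F.mutual_information(pair, single)
        assert mi[0, 1] == pytest.approx(0.0, abs=1e-12)
        # X = AAGG, Y = CCDD: perfectly coupled two-state -> ln 2
        coupled = EncodedAlignment(
            codes=np.array([[0, 1], [0, 1], [5, 2], [5, 2]], dtype=np.int8)
        )
        single, pair = F.weighted_frequencies(coupled, np.ones(4))
        mi = F.mutual_information(pair, single)
        assert mi[0, 1] == pytest.approx(np.log(2))

    def test_mi_diagonal_equals_entropy_and_symmetry(self):
        rng = np.random.default_rng(5)
        enc = random_alignment(rng, 9, 7)
        single, pair = F.weighted_frequencies(enc, rng.random(9) + 0.1)
        mi = F.mutual_information(pair, single)
        np.testing.assert_allclose(mi, mi.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mi), F.column_entropy(single), atol=1e-10)
        assert np.all(mi >= -1e-12)

    def test_sequence_separation(self):
        sep = F.sequence_separation(8)
        assert sep[0, 0] == 0.0
        assert sep[0, 5] == pytest.approx(5 / 100)
        np.testing.assert_array_equal(sep, sep.T)
        assert F.sequence_separation(300).max() == 1.0  # clipped


class TestFeatureAssembly:
    def test_channel_count_527(self, toy_enc):
        x = F.build_input_tensor(toy_enc, extra_features=True)
        assert x.shape == (527, 2, 2)
        manifest = F.channel_manifest()
        assert manifest[-1][2] == 527
        assert sum(b - a for _, a, b in manifest) == 527

    def test_baseline_bypasses_extras(self, toy_enc):
        x = F.build_input_tensor(toy_enc, extra_features=False)
        assert x.shape == (441, 2, 2)

    def test_query_tiling_orientation(self):
        rng = np.random.default_rng(6)
        enc = random_alignment(rng, 4, 6)
        x = F.build_input_tensor(enc, extra_features=True)  # (C, L, L)
        row_block = x[441:461]  # first copy: depends only on j
        for i in range(1, 6):
            np.testing.assert_array_equal(row_block[:, i, :], row_block[:, 0, :])
        col_block = x[461:481]  # transpose copy: depends only on i
        for j in range(1, 6):
            np.testing.assert_array_equal(col_block[:, :, j], col_block[:, :, 0])

    def test_shape_mismatch_rejected(self, toy_enc):
        single, pair = F.weighted_frequencies(toy_enc, np.ones(3))
        cov = F.covariance(single, pair)
        with pytest.raises(ValueError):
            F.tile_and_concat(
                cov,
                np.zeros((3, 20)),  # wrong L
                F.pssm(single),
                F.column_entropy(single),
                F.mutual_information(pair, single),
                F.sequence_separation(2),
            )
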