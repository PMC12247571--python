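"""Spatial filters: CSD inversion, orientations, single/pair filters, Grams."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beamcoh import beamform as bf
from conftest import random_psd_csd


class TestInvertCSD:
    def test_identity(self):
        csd = bf.invert_csd(np.eye(4))
        np.testing.assert_allclose(csd.inverse, np.eye(4), atol=1e-12)
        assert csd.rank == 4

    def test_diagonal(self):
        csd = bf.invert_csd(np.diag([2.0, 4.0]))
        np.testing.assert_allclose(csd.inverse, np.diag([0.5, 0.25]), atol=1e-14)

    def test_rank_one_pseudo_inverse_satisfies_penrose(self, rng):
        v = rng.standard_normal(5) + 1j * rng.standard_normal(5)
        C = np.outer(v, v.conj())
        csd = bf.invert_csd(C)
        assert csd.rank == 1
        P = csd.inverse
        np.testing.assert_allclose(C @ P @ C, C, atol=1e-10 * np.abs(C).max())
        np.testing.assert_allclose(P @ C @ P, P, atol=1e-10 * np.abs(P).max())
        np.testing.assert_allclose(C @ P, (C @ P).conj().T, atol=1e-12)
        np.testing.assert_allclose(P @ C, (P @ C).conj().T, atol=1e-12)

    def test_non_hermitian_rejected(self, rng):
        with pytest.raises(ValueError):
            bf.invert_csd(rng.standard_normal((4, 4)) + np.triu(np.ones((4, 4))))

    @given(seed=st.integers(0, 1000), n=st.integers(2, 8))
    def test_inverse_consistency_random_psd(self, seed, n):
        C = random_psd_csd(np.random.default_rng(seed), n)
        inv = bf.invert_csd(C).inverse
        np.testing.assert_allclose(
            C @ inv @ C, C, atol=1e-8 * np.abs(C).max()
        )


class TestFixedOrientation:
    def test_single_nonzero_column(self, rng):
        H = np.zeros((10, 3))
        H[:, 1] = rng.standard_normal(10)
        h, q = bf.fixed_orientation(H, np.eye(10))
        np.testing.assert_allclose(np.abs(q), [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(h, H @ q, atol=1e-14)

    def test_orthogonal_columns_pick_weakest(self, rng):
        # with C = I the output power is 1/||h(q)||^2: maximized along the
        # smallest-norm column of an orthogonal gain
        Q_mat, _ = np.linalg.qr(rng.standard_normal((12, 3)))
        H = Q_mat * np.array([1.0, 2.0, 3.0])
        _, q = bf.fixed_orientation(H, np.eye(12))
        np.testing.assert_allclose(np.abs(q), [1, 0, 0], atol=1e-10)

    def test_unit_norm_and_sign_convention(self, rng):
        H = rng.standard_normal((20, 3))
        _, q = bf.fixed_orientation(H, np.eye(20))
        assert np.linalg.norm(q) == pytest.approx(1.0, abs=1e-12)
        assert q[np.argmax(np.abs(q))] > 0

    def test_all_zero_gain_raises(self):
        with pytest.raises(ValueError):
            bf.fixed_orientation(np.zeros((5, 3)), np.eye(5))

    def test_batched_matches_scalar(self, rng):
        Hf = rng.standard_normal((16, 7, 3))
        C = random_psd_csd(rng, 16)
        inv = bf.invert_csd(C).inverse
        H_all, Q_all = bf.fixed_orientations(Hf, inv)
        for i in range(7):
            h, q = bf.fixed_orientation(Hf[:, i, :], inv)
            np.testing.assert_allclose(Q_all[i], q, atol=1e-8)
            np.testing.assert_allclose(H_all[:, i], h, atol=1e-8)


class TestSingleFilter:
    def test_identity_csd_closed_form(self, rng):
        h = rng.standard_normal(8)
        w = bf.single_filter(h, np.eye(8)).weights
        np.testing.assert_allclose(w, h / (h @ h), atol=1e-14)

    def test_unit_gain(self, rng):
        C = random_psd_csd(rng, 8)
        inv = bf.invert_csd(C).inverse
        h = rng.standard_normal(8)
        w = bf.single_filter(h, inv).weights
        assert w @ h == pytest.approx(1.0, abs=1e-10)

    def test_gain_scaling_homogeneity(self, rng):
        C = random_psd_csd(rng, 6)
        inv = bf.invert_csd(C).inverse
        h = rng.standard_normal(6)
        w1 = bf.single_filter(h, inv).weights
        w2 = bf.single_filter(3.0 * h, inv).weights
        np.testing.assert_allclose(w2, w1 / 3.0, rtol=1e-12)

    def test_insensitive_location_raises(self):
        with pytest.raises(ValueError):
            bf.single_filter(np.zeros(4), np.eye(4))


class TestPairFilter:
    @given(seed=st.integers(0, 500))
    def test_identity_gain_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        C = random_psd_csd(rng, 10)
        inv = bf.invert_csd(C).inverse
        h1, h2 = rng.standard_normal((2, 10))
        W = bf.pair_filter(h1, h2, inv)
        np.testing.assert_allclose(
            W @ np.column_stack([h1, h2]), np.eye(2), atol=1e-8
        )

    def test_orthogonal_pair_identity_csd_reduces_to_single(self, rng):
        H, _ = np.linalg.qr(rng.standard_normal((10, 2)))
        W = bf.pair_filter(H[:, 0], H[:, 1], np.eye(10))
        np.testing.assert_allclose(
            W[0], bf.single_filter(H[:, 0], np.eye(10)).weights, atol=1e-12
        )
        np.testing.assert_allclose(
            W[1], bf.single_filter(H[:, 1], np.eye(10)).weights, atol=1e-12
        )

    def test_swapping_dipoles_swaps_rows(self, rng):
        C = random_psd_csd(rng, 8)
        inv = bf.invert_csd(C).inverse
        h1, h2 = rng.standard_normal((2, 8))
        W = bf.pair_filter(h1, h2, inv)
        W_swapped = bf.pair_filter(h2, h1, inv)
        np.testing.assert_allclose(W_swapped, W[::-1], atol=1e-12)

    def test_collinear_pair_rejected(self, rng):
        h = rng.standard_normal(8)
        with pytest.raises(ValueError):
            bf.pair_filter(h, h * (1 + 1e-9), np.eye(8))


def _toy_gram(rng, n_ch=24, n_src=10, n_obs=200):
    H = rng.standard_normal((n_ch, n_src))
    X = (
        rng.standard_normal((n_ch, n_obs)) + 1j * rng.standard_normal((n_ch, n_obs))
    ) / np.sqrt(2)
    C = X @ X.conj().T / n_obs
    csd = bf.invert_csd(C)
    return H, C, csd


class TestAllPairsMaps:
    def test_vectorized_equals_naive_pair_loop(self, rng):
        H, C, csd = _toy_gram(rng)
        pg = bf.pair_gram(H, csd)
        dual = bf.dual_pair_maps(pg)
        single = bf.single_dipole_maps(pg)
        n = H.shape[1]
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert not dual.valid[i, j]
                    continue
                W = bf.pair_filter(H[:, i], H[:, j], csd.inverse)
                S = W @ C @ W.conj().T
                WW = W @ W.conj().T
                assert abs(S[0, 1]) == pytest.approx(dual.cross_abs[i, j], abs=1e-10)
                assert S[0, 0].real == pytest.approx(dual.power[i, j], abs=1e-10)
                assert S[1, 1].real == pytest.approx(dual.power[j, i], abs=1e-10)
                assert abs(WW[0, 1]) == pytest.approx(dual.winner_abs[i, j], abs=1e-10)
                coh = abs(S[0, 1]) / np.sqrt(S[0, 0].real * S[1, 1].real)
                assert coh == pytest.approx(dual.coherence[i, j], abs=1e-10)
                wi = bf.single_filter(H[:, i], csd.inverse).weights
                wj = bf.single_filter(H[:, j], csd.inverse).weights
                assert abs(wi @ C @ wj.conj()) == pytest.approx(
                    single.cross_abs[i, j], abs=1e-10
                )
                assert abs(wi @ wj.conj()) == pytest.approx(
                    single.winner_abs[i, j], abs=1e-10
                )

    def test_pair_powers_real_nonnegative(self, rng):
        H, _, csd = _toy_gram(rng)
        dual = bf.dual_pair_maps(bf.pair_gram(H, csd))
        assert np.all(dual.power[dual.valid] >= 0)

    def test_noiseless_two_source_recovery(self, rng):
        # the defining leakage-cancellation property of the identity-gain pair
        # filter: with X = h1 s1 + h2 s2 exactly, both sources are recovered
        n_obs = 64
        h1, h2 = rng.standard_normal((2, 12))
        S = rng.standard_normal((2, n_obs)) + 1j * rng.standard_normal((2, n_obs))
        X = np.outer(h1, S[0]) + np.outer(h2, S[1])
        csd = bf.invert_csd(X @ X.conj().T / n_obs)
        W = bf.pair_filter(h1, h2, csd.inverse)
        S_hat = W @ X
        np.testing.assert_allclose(S_hat, S, rtol=1e-8, atol=1e-8 * np.abs(S).max())
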