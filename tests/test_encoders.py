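import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcanet import (Dictionary, LCAEncoder, LCAParams, LearnConfig,
                    LinearEncoder, ReluEncoder, SigmoidEncoder,
                    energy, lca_encode, learn_dictionary, linear_encode,
                    relu_encode, sigmoid_encode, soft_threshold)
from lcanet.encoders import lca_fixed_point_residual

from oracles import ista_nonneg_lasso


class TestSoftThreshold:
    @pytest.mark.parametrize("u,lam,expected", [
        (0.5, 0.5, 0.0),          # at threshold: output exactly zero
        (-3.0, 0.5, 0.0),         # nonnegative variant kills negative drive
        (1.0, 0.4, 0.6),          # above threshold: shrink by lam
    ])
    def test_branches(self, u, lam, expected):
        assert soft_threshold(np.array([u]), lam)[0] == pytest.approx(expected)

    def test_negative_lam_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.zeros(3), -0.1)

    @given(st.floats(-10, 10), st.floats(0, 5))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_output_nonnegative_and_shrunk(self, u, lam):
        out = soft_threshold(np.array([u]), lam)[0]
        assert out >= 0
        assert out <= max(u, 0)


class TestLCAEncode:
    def test_large_threshold_silences_network(self, small_dictionary, rng):
        s = rng.standard_normal(16)
        b = small_dictionary.phi.T @ s
        lam = float(np.abs(b).max()) + 0.1
        res = lca_encode(s, small_dictionary, LCAParams(lam=lam))
        assert np.all(res.a == 0)

    def test_orthonormal_dictionary_closed_form(self):
        d = Dictionary(np.eye(8))
        c, lam = 1.5, 0.2
        s = c * d.phi[:, 3]
        res = lca_encode(s, d, LCAParams(lam=lam, n_steps=2000, step=0.1))
        expected = np.zeros(8)
        expected[3] = c - lam
        np.testing.assert_allclose(res.a, expected, atol=1e-6)

    def test_matches_nonneg_lasso_oracle(self, rng):
        lam = 0.2
        for _ in range(5):
            d = Dictionary.from_columns(rng.standard_normal((8, 16)))
            s = rng.standard_normal(8)
            res = lca_encode(s, d, LCAParams(lam=lam, n_steps=4000, step=0.1))
            a_star = ista_nonneg_lasso(s, d.phi, lam)
            assert np.max(np.abs(res.a - a_star)) < 1e-3

    def test_dimension_mismatch_rejected(self, small_dictionary):
        with pytest.raises(ValueError):
            lca_encode(np.zeros(7), small_dictionary)

    def test_energy_nonincreasing_along_dynamics(self, rng):
        for _ in range(20):
            d = Dictionary.from_columns(rng.standard_normal((16, 32)))
            s = rng.standard_normal(16)
            s /= np.linalg.norm(s)
            res = lca_encode(s, d, LCAParams(step=0.05), record_trace=True)
            diffs = np.diff(res.energy_trace)
            assert np.all(diffs[1:] <= 1e-8)

    def test_fixed_point_residual_shrinks_with_steps(self, small_dictionary, rng):
        s = rng.standard_normal(16)
        s /= np.linalg.norm(s)
        r_T = lca_fixed_point_residual(
            lca_encode(s, small_dictionary, LCAParams(n_steps=150)),
            s, small_dictionary)
        r_4T = lca_fixed_point_residual(
            lca_encode(s, small_dictionary, LCAParams(n_steps=600)),
            s, small_dictionary)
        assert r_4T < r_T

    def test_scale_covariance_orthonormal(self):
        d = Dictionary(np.eye(6))
        s = np.array([1.0, 0.3, 0.0, 0.0, -0.2, 0.6])
        p1 = LCAParams(lam=0.2, n_steps=1000, step=0.1)
        p2 = LCAParams(lam=0.4, n_steps=1000, step=0.1)
        a1 = lca_encode(s, d, p1).a
        a2 = lca_encode(2 * s, d, p2).a
        np.testing.assert_allclose(a2, 2 * a1, atol=1e-8)

    def test_activation_is_thresholded_membrane(self, small_dictionary, rng):
        s = rng.standard_normal(16)
        params = LCAParams(lam=0.3)
        res = lca_encode(s, small_dictionary, params)
        np.testing.assert_array_equal(res.a, soft_threshold(res.u, params.lam))
        assert np.all(res.a >= 0)


class TestEnergy:
    def test_zero_everything(self, small_dictionary):
        assert energy(np.zeros(16), np.zeros(32), small_dictionary, 0.2) == 0.0

    def test_exact_reconstruction_leaves_only_penalty(self, small_dictionary, rng):
        a = np.abs(rng.standard_normal(32))
        s = small_dictionary.phi @ a
        assert energy(s, a, small_dictionary, 0.3) == pytest.approx(
            0.3 * a.sum(), rel=1e-12)

    def test_term_by_term_recomputation(self, small_dictionary, rng):
        s = rng.standard_normal(16)
        a = rng.standard_normal(32)
        resid = s - sum(a[i] * small_dictionary.phi[:, i] for i in range(32))
        direct = 0.5 * np.dot(resid, resid) + 0.5 * np.sum(np.abs(a))
        assert energy(s, a, small_dictionary, 0.5) == pytest.approx(
            direct, abs=1e-12)


class TestLearning:
    def test_zero_learning_rate_is_identity(self, small_dictionary, rng):
        S = rng.standard_normal((30, 16))
        out = learn_dictionary(S, small_dictionary,
                               LearnConfig(eta=0.0, n_epochs=2, seed=0))
        np.testing.assert_array_equal(out.phi, small_dictionary.phi)

    def test_single_unit_update_direction(self, rng):
        # one stimulus, one active unit k: the unnormalized update touches
        # only column k and equals (s - s_hat) * a_k
        d = Dictionary(np.eye(4))
        lam = 0.1
        s = np.array([0.9, 0.05, 0.0, 0.0])
        params = LCAParams(lam=lam, n_steps=3000, step=0.1)
        res = lca_encode(s, d, params)
        active = np.flatnonzero(res.a > 0)
        assert list(active) == [0]
        eta = 1e-6           # small enough that renormalization is negligible
        out = learn_dictionary(s[None], d,
                               LearnConfig(eta=eta, batch_size=1, n_epochs=1,
                                           seed=0), params)
        s_hat = d.phi @ res.a
        expected_delta = eta * np.outer(s - s_hat, res.a)
        raw = out.phi * np.linalg.norm(d.phi + expected_delta, axis=0)
        np.testing.assert_allclose(raw - d.phi, expected_delta, atol=1e-10)

    def test_training_reduces_energy_and_is_deterministic(self, rng):
        from lcanet import make_gabor_ground_truth, sample_sparse_patches, standardize
        gt = make_gabor_ground_truth(6, 6, 48, seed=3, noise_sd=0.02)
        patches = standardize(sample_sparse_patches(gt, 400, 0.06, seed=4))
        init = Dictionary.from_columns(rng.standard_normal((36, 48)))
        cfg = LearnConfig(eta=0.5, batch_size=100, n_epochs=5, seed=8)
        out1, log = learn_dictionary(patches, init, cfg, return_log=True)
        out2 = learn_dictionary(patches, init, cfg)
        assert log[-1]["mean_energy"] < log[0]["mean_energy"]
        np.testing.assert_array_equal(out1.phi, out2.phi)
        np.testing.assert_allclose(np.linalg.norm(out1.phi, axis=0), 1.0,
                                   atol=1e-12)


class TestPointwiseEncoders:
    def test_linear_invariant_to_orthogonal_perturbation(self, small_dictionary, rng):
        k = 5
        s = rng.standard_normal(16)
        e = rng.standard_normal(16)
        phi_k = small_dictionary.phi[:, k]
        e -= (e @ phi_k) / (phi_k @ phi_k) * phi_k
        r1 = linear_encode(s, small_dictionary)[k]
        r2 = linear_encode(s + e, small_dictionary)[k]
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_relu_zero_on_antipreferred(self, small_dictionary):
        s = -small_dictionary.phi[:, 2]
        assert relu_encode(s, small_dictionary)[2] == 0.0

    def test_sigmoid_monotone_in_projection(self, small_dictionary):
        k = 0
        cs = np.linspace(-2, 2, 9)
        vals = [sigmoid_encode(c * small_dictionary.phi[:, k],
                               small_dictionary, gain=2.0)[k] for c in cs]
        assert np.all(np.diff(vals) > 0)

    def test_encoder_objects_match_functions(self, small_dictionary, rng):
        S = rng.standard_normal((4, 16))
        np.testing.assert_array_equal(LinearEncoder(small_dictionary)(S),
                                      linear_encode(S, small_dictionary))
        np.testing.assert_array_equal(ReluEncoder(small_dictionary)(S),
                                      relu_encode(S, small_dictionary))
        np.testing.assert_array_equal(
            SigmoidEncoder(small_dictionary, gain=3.0)(S),
            sigmoid_encode(S, small_dictionary, gain=3.0))

    def test_lca_encoder_batch_matches_single(self, small_dictionary, rng):
        S = rng.standard_normal((3, 16))
        enc = LCAEncoder(small_dictionary, LCAParams(n_steps=50))
        batch = enc.encode(S)
        for i in range(3):
            single = lca_encode(S[i], small_dictionary, LCAParams(n_steps=50))
            np.testing.assert_allclose(batch[i], single.a, atol=1e-12)


class TestDictionaryType:
    def test_rejects_unnormalized(self, rng):
        with pytest.raises(ValueError):
            Dictionary(2.0 * np.eye(4))

    def test_overcompleteness(self, small_dictionary):
        assert small_dictionary.overcompleteness == 2.0

    def test_roundtrip(self, small_dictionary, tmp_path):
        small_dictionary.save(tmp_path / "d")
        loaded = Dictionary.load(tmp_path / "d")
        np.testing.assert_array_equal(loaded.phi, small_dictionary.phi)
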