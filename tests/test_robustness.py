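import numpy as np
import pytest
from scipy.special import logit

from lcanet import (AttackConfig, Dictionary, LCAEncoder, LCAParams,
                    LinearEncoder, ReluEncoder, encoder_input_gradient,
                    single_neuron_attack, targeted_confidence_attack,
                    train_pixel_mlp, train_softmax)
from lcanet.robustness import (AccuracyMismatch, ClassifierModel,
                               LCAClassifierModel,
                               matched_hidden_size, mse_summary,
                               perturbation_alignment,
                               random_incorrect_targets,
                               robustness_experiment, targeted_attack_batch)


class TestInputGradients:
    def test_linear_gradient_is_weight_vector(self, small_dictionary, rng):
        enc = LinearEncoder(small_dictionary)
        for k in (0, 7):
            g = encoder_input_gradient(enc, k, rng.standard_normal(16))
            np.testing.assert_allclose(g, small_dictionary.phi[:, k],
                                       atol=1e-12)

    def test_relu_gradient_zero_when_inactive(self, small_dictionary):
        enc = ReluEncoder(small_dictionary)
        s = -2.0 * small_dictionary.phi[:, 3]
        g = encoder_input_gradient(enc, 3, s)
        np.testing.assert_array_equal(g, np.zeros(16))

    def test_lca_gradient_matches_finite_differences(self, rng):
        d = Dictionary.from_columns(rng.standard_normal((10, 20)))
        enc = LCAEncoder(d, LCAParams(n_steps=100))
        s = rng.standard_normal(10)
        s *= 2.0 / np.linalg.norm(s)
        k = int(np.argmax(enc.encode(s[None])[0]))
        g = encoder_input_gradient(enc, k, s)
        h = 1e-5
        fd = np.empty(10)
        for i in range(10):
            sp, sm = s.copy(), s.copy()
            sp[i] += h
            sm[i] -= h
            fd[i] = (enc.response(sp[None], k)[0]
                     - enc.response(sm[None], k)[0]) / (2 * h)
        assert np.max(np.abs(g - fd)) / max(np.max(np.abs(fd)), 1e-12) < 1e-4


class TestSingleNeuronAttack:
    def test_zero_budget_keeps_perturbation_zero(self, small_dictionary, rng):
        cfg = AttackConfig(step=0.01, eps_inf=0.0, max_iters=10)
        trace = single_neuron_attack(LinearEncoder(small_dictionary), 0,
                                     rng.standard_normal(16), cfg)
        np.testing.assert_array_equal(trace.perturbation, np.zeros(16))
        assert trace.mse == 0.0

    def test_linear_trajectory_parallel_to_weight(self, small_dictionary):
        cfg = AttackConfig(step=1e-3, eps_inf=1.0, max_iters=20)
        s = np.zeros(16)
        trace = single_neuron_attack(LinearEncoder(small_dictionary), 2, s, cfg)
        phi_k = small_dictionary.phi[:, 2]
        for it in trace.iterates[1:]:
            e = it - s
            cos = e @ phi_k / (np.linalg.norm(e) * np.linalg.norm(phi_k))
            assert 1 - cos < 1e-10

    def test_feasibility_exact(self, small_dictionary, rng):
        cfg = AttackConfig(step=0.5, eps_inf=0.05, max_iters=30)
        trace = single_neuron_attack(LinearEncoder(small_dictionary), 5,
                                     rng.standard_normal(16), cfg)
        # the projected perturbation obeys the bound exactly; recovering it
        # from s + e - s only holds to machine precision
        assert np.max(np.abs(trace.perturbation)) <= cfg.eps_inf
        for it in trace.iterates:
            assert np.max(np.abs(it - trace.iterates[0])) <= cfg.eps_inf + 1e-12

    def test_descent_sign_lowers_activation(self, small_dictionary):
        s = 2.0 * small_dictionary.phi[:, 1]
        cfg = AttackConfig(step=0.01, eps_inf=0.3, max_iters=50)
        tr = single_neuron_attack(LinearEncoder(small_dictionary), 1, s, cfg,
                                  sign=-1)
        assert tr.confidences[-1] < tr.confidences[0]

    def test_infinite_bound_rejected(self, small_dictionary):
        with pytest.raises(ValueError):
            single_neuron_attack(LinearEncoder(small_dictionary), 0,
                                 np.zeros(16), AttackConfig(step=0.1))


class TestTrainSoftmax:
    def test_separable_two_class_is_perfect(self, rng):
        codes = np.vstack([rng.normal(3, 0.3, (40, 4)),
                           rng.normal(-3, 0.3, (40, 4))])
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        clf = train_softmax(codes, labels)
        assert np.mean(clf.predict(codes) == labels) == 1.0

    def test_label_permutation_permutes_columns(self, rng):
        codes = rng.standard_normal((60, 5))
        labels = rng.integers(0, 3, 60)
        perm = np.array([2, 0, 1])
        clf1 = train_softmax(codes, labels)
        clf2 = train_softmax(codes, perm[labels])
        # class c of the first fit becomes class perm[c] of the second
        np.testing.assert_allclose(clf1.weights, clf2.weights[:, perm],
                                   atol=1e-4)

    def test_gradient_vanishes_at_optimum(self, rng):
        codes = rng.standard_normal((50, 3))
        labels = rng.integers(0, 2, 50)
        l2 = 1e-3
        clf = train_softmax(codes, labels, l2=l2)
        n = len(labels)
        p = clf.predict_proba(codes)
        onehot = np.eye(2)[labels]
        grad_w = codes.T @ (p - onehot) / n + l2 * clf.weights
        grad_b = (p - onehot).sum(axis=0) / n
        assert np.max(np.abs(grad_w)) < 1e-6
        assert np.max(np.abs(grad_b)) < 1e-6


class _LogisticPixelModel(ClassifierModel):
    """1-pixel, 2-class logistic model with analytic behavior for oracles."""

    def __init__(self, w, b):
        self.w, self.b = w, b

    def predict_proba(self, S):
        z = self.w * np.atleast_2d(S)[:, 0] + self.b
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p1, p1])

    def target_logprob_grad(self, S, y):
        p = self.predict_proba(S)
        y = np.asarray(y, dtype=int)
        sign = np.where(y == 1, 1.0, -1.0)
        return (sign * (1 - p[np.arange(len(p)), y]) * self.w)[:, None]


class TestTargetedAttack:
    def test_already_confident_halts_immediately(self):
        model = _LogisticPixelModel(w=4.0, b=10.0)
        cfg = AttackConfig(step=0.1, conf_target=0.9, max_iters=100,
                           clip_lo=-100, clip_hi=100)
        tr = targeted_confidence_attack(model, np.array([0.0]), 1, cfg)
        assert tr.halted_at == 0
        assert tr.mse == 0.0
        np.testing.assert_array_equal(tr.perturbation, np.zeros(1))

    def test_logistic_halting_iteration_closed_form(self):
        w, b, alpha = 2.5, -1.0, 0.01
        model = _LogisticPixelModel(w=w, b=b)
        cfg = AttackConfig(step=alpha, conf_target=0.9, conf_snapshot=0.95,
                           max_iters=10_000, clip_lo=-100, clip_hi=100)
        s0 = 0.0
        tr = targeted_confidence_attack(model, np.array([s0]), 1, cfg)
        logit0 = w * s0 + b
        expected = int(np.ceil((logit(0.9) - logit0) / (alpha * abs(w))))
        assert tr.halted_at == expected

    def test_perturbation_bounded_by_step_count(self):
        model = _LogisticPixelModel(w=1.5, b=0.0)
        cfg = AttackConfig(step=0.02, conf_target=0.9, max_iters=1000,
                           clip_lo=-100, clip_hi=100)
        tr = targeted_confidence_attack(model, np.array([0.0]), 1, cfg)
        assert np.max(np.abs(tr.perturbation)) <= cfg.step * tr.halted_at + 1e-12

    def test_clipping_keeps_iterates_in_range(self):
        model = _LogisticPixelModel(w=1.0, b=0.0)
        cfg = AttackConfig(step=0.5, conf_target=0.999, conf_snapshot=0.9995,
                           max_iters=50, clip_lo=0.0, clip_hi=1.0)
        tr = targeted_confidence_attack(model, np.array([0.5]), 1, cfg,
                                        record_iterates=True)
        assert np.all(tr.iterates >= 0.0) and np.all(tr.iterates <= 1.0)

    def test_batch_attack_matches_single(self):
        model = _LogisticPixelModel(w=2.0, b=-0.5)
        cfg = AttackConfig(step=0.01, conf_target=0.9, conf_snapshot=0.95,
                           max_iters=2000, clip_lo=-100, clip_hi=100)
        S = np.array([[0.0], [0.3], [-0.4]])
        table = targeted_attack_batch(model, S, np.array([1, 1, 1]), cfg)
        for i in range(3):
            tr = targeted_confidence_attack(model, S[i], 1, cfg)
            assert table.loc[i, "halted_at"] == tr.halted_at
            assert table.loc[i, "mse"] == pytest.approx(tr.mse, abs=1e-12)


class TestExperiment:
    def test_random_targets_never_correct(self, rng):
        labels = rng.integers(0, 10, 500)
        targets = random_incorrect_targets(labels, 10, rng)
        assert np.all(targets != labels)
        assert targets.min() >= 0 and targets.max() < 10

    def test_matched_hidden_size_parameter_parity(self):
        P, N, K = 64, 128, 10
        H = matched_hidden_size(P, N, K)
        lca_params = P * N + N * K + K
        mlp_params = P * H + H + H * K + K
        assert abs(mlp_params - lca_params) / lca_params < 0.01

    def test_identical_models_identical_mse(self, rng):
        model = _LogisticPixelModel(w=2.0, b=0.0)
        cfg = AttackConfig(step=0.01, conf_target=0.9, max_iters=2000,
                           clip_lo=-100, clip_hi=100)
        S = rng.normal(0, 0.5, (20, 1))
        labels = (S[:, 0] > 0).astype(int)
        ok = model.predict(S) == labels
        S, labels = S[ok], labels[ok]
        table = robustness_experiment({"a": model, "b": model}, S, labels, 2,
                                      cfg, seed=3)
        ma = table[table.model == "a"]["mse"].to_numpy()
        mb = table[table.model == "b"]["mse"].to_numpy()
        np.testing.assert_array_equal(ma, mb)

    def test_accuracy_mismatch_aborts(self, rng):
        good = _LogisticPixelModel(w=5.0, b=0.0)
        bad = _LogisticPixelModel(w=-5.0, b=0.0)
        S = rng.normal(0, 1, (30, 1))
        labels = (S[:, 0] > 0).astype(int)
        with pytest.raises(AccuracyMismatch):
            robustness_experiment({"a": good, "b": bad}, S, labels, 2,
                                  AttackConfig(step=0.01), seed=0)

    def test_mse_summary_quantile_ordering(self, rng):
        import pandas as pd
        table = pd.DataFrame(dict(model=["m"] * 50,
                                  mse=rng.random(50), halted=True))
        summ = mse_summary(table).iloc[0]
        assert summ["p05"] <= summ["q1"] <= summ["median"] <= summ["q3"] \
            <= summ["p95"]

    def test_perturbation_alignment_extremes(self):
        means = np.array([[1.0, 0.0], [0.0, 1.0]])
        perts = np.array([[2.0, 0.0], [0.0, -3.0]])
        cos = perturbation_alignment(perts, [0, 1], means)
        np.testing.assert_allclose(cos, [1.0, -1.0], atol=1e-12)


class TestLCAClassifierGradient:
    def test_target_logprob_grad_matches_finite_differences(self, rng):
        d = Dictionary.from_columns(rng.standard_normal((8, 16)))
        enc = LCAEncoder(d, LCAParams(n_steps=60))
        S = rng.random((12, 8))
        labels = rng.integers(0, 3, 12)
        clf = train_softmax(enc.encode(S), labels)
        model = LCAClassifierModel(enc, clf)
        s = S[0]
        y = 2
        g = model.target_logprob_grad(s[None], [y])[0]
        h = 1e-5
        fd = np.empty(8)
        for i in range(8):
            sp, sm = s.copy(), s.copy()
            sp[i] += h
            sm[i] -= h
            fd[i] = (np.log(model.predict_proba(sp[None])[0, y])
                     - np.log(model.predict_proba(sm[None])[0, y])) / (2 * h)
        np.testing.assert_allclose(g, fd, atol=1e-5)

    def test_pixel_mlp_trains_and_differentiates(self, rng):
        S = np.vstack([rng.normal(0.3, 0.05, (30, 6)),
                       rng.normal(0.7, 0.05, (30, 6))])
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        model = train_pixel_mlp(S, labels, hidden=8, seed=1)
        assert model.accuracy(S, labels) == 1.0
        s, y = S[0], 1
        g = model.target_logprob_grad(s[None], [y])[0]
        h = 1e-6
        fd = np.empty(6)
        for i in range(6):
            sp, sm = s.copy(), s.copy()
            sp[i] += h
            sm[i] -= h
            fd[i] = (np.log(model.predict_proba(sp[None])[0, y])
                     - np.log(model.predict_proba(sm[None])[0, y])) / (2 * h)
        np.testing.assert_allclose(g, fd, atol=1e-4)
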