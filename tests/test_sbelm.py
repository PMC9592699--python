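"""Sparse Bayesian ELM: posterior algebra, ARD updates, and the ensemble."""

import numpy as np
import pytest

from dualmatch import sbelm, synthetic
from dualmatch.evaluation import roc_auc
from dualmatch.sbelm import SBELMConfig


def separable_toy(n=40, seed=0):
    rng = np.random.default_rng(seed)
    t = np.repeat([0.0, 1.0], n // 2)
    x = np.column_stack([t + rng.normal(0, 0.05, n),
                         rng.normal(0, 1, n)])
    return x, t


class TestHiddenOutput:
    def test_zero_input_zero_bias_sigmoid_is_half(self):
        cfg = SBELMConfig(hidden_width=5, seed=1)
        model = sbelm.init_hidden(3, cfg)
        model.b_in = np.zeros(5)
        out = sbelm.hidden_output(np.zeros((2, 3)), model)
        np.testing.assert_allclose(out, 0.5)

    def test_identity_hidden_returns_raw_input(self, rng):
        cfg = SBELMConfig(activation="identity")
        model = sbelm.init_hidden(4, cfg)
        raw = rng.normal(0, 1, (3, 4))
        np.testing.assert_array_equal(sbelm.hidden_output(raw, model), raw)

    def test_matches_elementwise_loop_oracle(self, rng):
        cfg = SBELMConfig(hidden_width=4, activation="sigmoid", seed=2)
        model = sbelm.init_hidden(3, cfg)
        raw = rng.normal(0, 1, (5, 3))
        out = sbelm.hidden_output(raw, model)
        for i in range(5):
            for j in range(4):
                z = sum(raw[i, k] * model.w_in[k, j] for k in range(3)) + model.b_in[j]
                assert out[i, j] == pytest.approx(1 / (1 + np.exp(-z)), abs=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        model = sbelm.init_hidden(3, SBELMConfig(hidden_width=4))
        with pytest.raises(ValueError):
            sbelm.hidden_output(rng.normal(0, 1, (2, 5)), model)


class TestPosterior:
    def test_scalar_worked_example(self):
        x = np.array([[1.0], [1.0]])
        t = np.array([1.0, 1.0])
        m, sigma = sbelm.posterior(x, t, np.array([1.0]), 1.0)
        assert sigma[0, 0] == pytest.approx(1 / 3)
        assert m[0] == pytest.approx(2 / 3)

    def test_prior_dominates_as_beta_vanishes(self, rng):
        x = rng.normal(0, 1, (10, 3))
        t = rng.normal(0, 1, 10)
        m, _ = sbelm.posterior(x, t, np.ones(3), 1e-12)
        np.testing.assert_allclose(m, 0, atol=1e-9)

    def test_mean_equals_ridge_solution(self, rng):
        for _ in range(20):
            n, d = 15, 4
            x = rng.normal(0, 1, (n, d))
            t = rng.normal(0, 1, n)
            alpha = rng.uniform(0.1, 5.0, d)
            beta = rng.uniform(0.5, 4.0)
            m, _ = sbelm.posterior(x, t, alpha, beta)
            ridge = np.linalg.solve(x.T @ x + np.diag(alpha) / beta, x.T @ t)
            np.testing.assert_allclose(m, ridge, atol=1e-8)

    def test_sigma_symmetric_positive_definite(self, rng):
        x = rng.normal(0, 1, (12, 5))
        t = rng.normal(0, 1, 12)
        _, sigma = sbelm.posterior(x, t, rng.uniform(0.1, 10, 5), 2.0)
        np.testing.assert_allclose(sigma, sigma.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(sigma) > 0)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            sbelm.posterior(np.array([[np.nan]]), np.array([1.0]),
                            np.array([1.0]), 1.0)


class TestLogEvidence:
    def test_scalar_case_matches_direct_formula(self):
        x = np.array([[1.0], [1.0]])
        t = np.array([1.0, 1.0])
        alpha, beta = np.array([1.0]), 1.0
        m, sigma = sbelm.posterior(x, t, alpha, beta)
        val = sbelm.log_evidence(x, t, alpha, beta, m, sigma)
        direct = 0.5 * (np.log(1.0) + 2 * np.log(1.0) + np.log(1 / 3)
                        - 1.0 * (2 * (1 / 3) ** 2) - (2 / 3) ** 2
                        - 2 * np.log(2 * np.pi))
        assert val == pytest.approx(direct, abs=1e-12)

    def test_matches_gaussian_marginal_closed_form(self, rng):
        n, d = 8, 3
        x = rng.normal(0, 1, (n, d))
        t = rng.normal(0, 1, n)
        alpha = rng.uniform(0.5, 3.0, d)
        beta = 1.7
        m, sigma = sbelm.posterior(x, t, alpha, beta)
        val = sbelm.log_evidence(x, t, alpha, beta, m, sigma)
        c = np.eye(n) / beta + x @ np.diag(1 / alpha) @ x.T
        direct = -0.5 * (n * np.log(2 * np.pi) + np.linalg.slogdet(c)[1]
                         + t @ np.linalg.solve(c, t))
        assert val == pytest.approx(direct, abs=1e-6)


class TestUpdateHyperparams:
    def test_scalar_worked_example(self):
        x = np.array([[1.0], [1.0]])
        t = np.array([1.0, 1.0])
        m, sigma = sbelm.posterior(x, t, np.array([1.0]), 1.0)
        alpha_new, beta_new, gamma = sbelm.update_hyperparams(m, sigma, x, t,
                                                              np.array([1.0]))
        assert gamma[0] == pytest.approx(2 / 3)
        assert alpha_new[0] == pytest.approx(1.5)
        assert beta_new == pytest.approx(6.0)

    def test_zero_mean_weight_is_pruned(self):
        x = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        m = np.array([0.5, 0.0])
        sigma = np.diag([0.1, 0.5])
        alpha_new, _, _ = sbelm.update_hyperparams(m, sigma, x,
                                                   np.array([0.5, 0.5, 0.5]),
                                                   np.array([1.0, 1.0]),
                                                   alpha_max=1e8)
        assert alpha_new[1] == 1e8


class TestFit:
    def test_separable_toy_training_auc_is_one(self):
        x, t = separable_toy()
        model, trace = sbelm.fit_sbelm(x, t, SBELMConfig(hidden_width=20, seed=1))
        scores = sbelm.predict(model, x)
        assert roc_auc(scores, t) == 1.0
        assert ((scores >= 0.5).astype(float) == t).all()

    def test_evidence_non_decreasing(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, (30, 6))
            t = x @ rng.normal(0, 1, 6) + rng.normal(0, 0.3, 30)
            _, trace = sbelm.fit_sbelm(
                x, t, SBELMConfig(activation="identity", seed=seed))
            ev = np.array(trace.log_evidence)
            assert np.all(np.diff(ev) >= -1e-8)

    def test_support_recovery_on_sparse_signal(self):
        precisions = []
        for seed in range(10):
            x, t, w = synthetic.gen_sparse_regression(200, 50, 5, 0.1, seed=seed)
            model, _ = sbelm.fit_sbelm(
                x, t, SBELMConfig(activation="identity", seed=seed))
            pruned = np.flatnonzero(model.pruned)
            irrelevant = np.flatnonzero(w == 0)
            if len(pruned):
                precisions.append(np.isin(pruned, irrelevant).mean())
        assert np.median(precisions) >= 0.8

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            sbelm.fit_sbelm(np.zeros((1, 2)), np.zeros(1))


class TestPredict:
    def test_zero_weights_give_zero_scores(self, rng):
        model = sbelm.init_hidden(3, SBELMConfig(hidden_width=4))
        model.m = np.zeros(4)
        model.fitted = True
        np.testing.assert_array_equal(
            sbelm.predict(model, rng.normal(0, 1, (5, 3))), 0)

    def test_unfitted_model_rejected(self, rng):
        model = sbelm.init_hidden(3, SBELMConfig())
        with pytest.raises(ValueError):
            sbelm.predict(model, rng.normal(0, 1, (2, 3)))

    def test_joint_permutation_of_features_and_init_is_invariant(self, rng):
        x, t = separable_toy(seed=3)
        model, _ = sbelm.fit_sbelm(x, t, SBELMConfig(hidden_width=10, seed=4))
        base = sbelm.predict(model, x)
        perm = rng.permutation(x.shape[1])
        model.w_in = model.w_in[perm]
        np.testing.assert_allclose(sbelm.predict(model, x[:, perm]), base,
                                   atol=1e-9)


class TestEnsemble:
    def test_single_base_preserves_ranking(self):
        x, t = separable_toy(seed=5)
        ens = sbelm.fit_ensemble(x, t, m_bases=1,
                                 config=SBELMConfig(hidden_width=15, seed=6))
        ens_scores = sbelm.predict_ensemble(ens, x)
        base_scores = sbelm.predict(ens.bases[0], x)
        assert roc_auc(ens_scores, t) == roc_auc(base_scores, t)

    def test_separable_toy_ensemble_auc_is_one(self):
        x, t = separable_toy(seed=7)
        ens = sbelm.fit_ensemble(x, t, m_bases=5,
                                 config=SBELMConfig(hidden_width=15, seed=8))
        assert roc_auc(sbelm.predict_ensemble(ens, x), t) == 1.0

    def test_same_seed_reproduces_ensemble(self):
        x, t = separable_toy(seed=9)
        cfg = SBELMConfig(hidden_width=10, seed=10)
        a = sbelm.fit_ensemble(x, t, m_bases=3, config=cfg)
        b = sbelm.fit_ensemble(x, t, m_bases=3, config=cfg)
        np.testing.assert_array_equal(sbelm.predict_ensemble(a, x),
                                      sbelm.predict_ensemble(b, x))

    def test_prediction_composes_base_and_combiner(self, rng):
        x, t = separable_toy(seed=11)
        ens = sbelm.fit_ensemble(x, t, m_bases=3,
                                 config=SBELMConfig(hidden_width=10, seed=12))
        xq = rng.normal(0, 1, (7, 2))
        by_hand = sbelm.predict(
            ens.combiner,
            np.column_stack([sbelm.predict(b, xq) for b in ens.bases]))
        np.testing.assert_allclose(sbelm.predict_ensemble(ens, xq), by_hand,
                                   atol=1e-12)

    def test_identical_bases_degenerate_design_handled(self):
        x, t = separable_toy(seed=13)
        cfg = SBELMConfig(hidden_width=10, seed=14)
        ens = sbelm.fit_ensemble(x, t, m_bases=4, bag_fraction=1.0, config=cfg)
        # force all base scores identical: rank-1 combiner design
        scores = np.tile(sbelm.predict(ens.bases[0], x)[:, None], (1, 4))
        combiner, _ = sbelm.fit_sbelm(scores, t, SBELMConfig(activation="identity"))
        out = sbelm.predict(combiner, scores)
        assert np.all(np.isfinite(out))

    def test_single_class_subsets_rejected(self):
        x = np.random.default_rng(0).normal(0, 1, (6, 2))
        with pytest.raises(ValueError):
            sbelm.fit_ensemble(x, np.zeros(6), m_bases=2)
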