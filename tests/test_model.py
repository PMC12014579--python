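import numpy as np
import pytest

from cnmclda.model import (
    Hyperparameters,
    compute_losses,
    conv_forward,
    forward_disease,
    forward_lncrna,
    init_parameters,
    loss_and_gradients,
    predict_scores,
    sigmoid,
)
from conftest import max_relative_gradient_error, numerical_gradient


class TestConvForward:
    def test_zero_input_zero_bias_gives_zero(self):
        out = conv_forward(np.zeros(3), np.ones((2, 3)), np.zeros(2))
        np.testing.assert_array_equal(out, np.zeros(2))

    def test_kernel_equal_to_input_gives_inner_product(self):
        x = np.array([1.0, 0.0, 1.0])
        out = conv_forward(x, x[None, :], np.zeros(1))
        assert out.tolist() == [2.0]

    def test_negative_preactivation_clamped(self):
        out = conv_forward(np.ones(2), np.array([[-1.0, -2.0]]), np.zeros(1))
        assert out.tolist() == [0.0]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conv_forward(np.zeros(3), np.ones((2, 4)), np.zeros(2))


class TestForwardPasses:
    @pytest.mark.parametrize("nm,nd,nl", [(4, 3, 5), (7, 2, 3), (5, 6, 4)])
    def test_layer_output_dimensions(self, nm, nd, nl):
        rng = np.random.default_rng(0)
        params = init_parameters(nm, nd, nl, seed=1, init_std=0.1)
        MD = rng.integers(0, 2, size=(nm, nd)).astype(float)
        ML = rng.integers(0, 2, size=(nm, nl)).astype(float)
        hd = forward_disease(0, MD, params)
        assert [h.shape for h in hd] == [(nd,), (nd,), (nm,), (1,)]
        hl = forward_lncrna(0, ML, params)
        assert [h.shape for h in hl] == [(nl,), (nl,), (nm,), (1,)]

    def test_zero_parameters_give_zero_outputs(self):
        params = init_parameters(4, 3, 5, seed=0, init_std=0.1).zeros_like()
        MD = np.ones((4, 3))
        for h in forward_disease(1, MD, params):
            np.testing.assert_array_equal(h, np.zeros_like(h))

    def test_matches_independent_affine_relu_evaluation(self):
        rng = np.random.default_rng(3)
        params = init_parameters(4, 3, 5, seed=2, init_std=0.7)
        for name, arr in params.items():
            arr += rng.normal(0, 0.2, arr.shape)
        MD = rng.integers(0, 2, size=(4, 3)).astype(float)
        x = MD[:, 2]
        r = lambda z: np.maximum(z, 0)
        e1 = r(params.Wd1 @ x + params.Bd1)
        e2 = r(params.Wd2.T @ e1 + params.Bd2)
        e3 = r(params.Wd3.T @ e2 + params.Bd3)
        e4 = r(params.Wd4.T @ e3 + params.Bd4)
        h1, h2, h3, h4 = forward_disease(2, MD, params)
        for got, want in zip((h1, h2, h3, h4), (e1, e2, e3, e4)):
            np.testing.assert_allclose(got, want, rtol=1e-14)

    def test_index_out_of_range(self):
        params = init_parameters(4, 3, 5, seed=0)
        with pytest.raises(IndexError):
            forward_disease(3, np.zeros((4, 3)), params)


class TestPredictScores:
    def test_zero_weights_give_half_everywhere(self):
        params = init_parameters(4, 3, 5, seed=0).zeros_like()
        np.testing.assert_array_equal(predict_scores(params), 0.5 * np.ones((5, 3)))

    def test_entries_strictly_inside_unit_interval(self):
        # moderate weights: strict bounds hold exactly until the sigmoid
        # saturates past |logit| ~ 37 in double precision
        params = init_parameters(6, 4, 7, seed=5, init_std=0.5)
        scores = predict_scores(params)
        assert scores.shape == (7, 4)
        assert (scores > 0).all() and (scores < 1).all()

    def test_matches_naive_chain_product(self):
        params = init_parameters(4, 2, 3, seed=7, init_std=0.8)
        expect = 1.0 / (
            1.0
            + np.exp(-(params.Wl2 @ params.Wl3 @ params.Wd3.T @ params.Wd2.T))
        )
        np.testing.assert_allclose(predict_scores(params), expect, rtol=1e-14)

    def test_lncrna_permutation_equivariance(self):
        params = init_parameters(4, 3, 5, seed=9, init_std=0.5)
        perm = np.array([3, 0, 4, 1, 2])
        permuted = params.copy()
        permuted.Wl1 = params.Wl1[perm]
        permuted.Bl1 = params.Bl1[perm]
        permuted.Wl2 = params.Wl2[np.ix_(perm, perm)]
        permuted.Bl2 = params.Bl2[perm]
        permuted.Wl3 = params.Wl3[perm]
        np.testing.assert_allclose(
            predict_scores(permuted), predict_scores(params)[perm], rtol=1e-14
        )


class TestLosses:
    def test_zero_parameters_closed_form(self, toy_problem):
        dataset, similarities, mask = toy_problem
        params = init_parameters(dataset.nm, dataset.nd, dataset.nl, 0).zeros_like()
        lb = compute_losses(dataset, similarities, mask, params, Hyperparameters())
        p, q = len(mask.positives), len(mask.negatives)
        assert lb.loss1 == 0.25 * (p + q)

    def test_zero_lambdas_reduce_total_to_loss1(self, toy_problem):
        dataset, similarities, mask = toy_problem
        params = init_parameters(dataset.nm, dataset.nd, dataset.nl, 1, 0.3)
        hyper = Hyperparameters(lambda1=0, lambda2=0, lambda3=0, lambda4=0)
        lb = compute_losses(dataset, similarities, mask, params, hyper)
        assert lb.loss_total == lb.loss1

    def test_similarity_anchored_weights_zero_loss3(self, toy_problem):
        dataset, similarities, mask = toy_problem
        params = init_parameters(dataset.nm, dataset.nd, dataset.nl, 1, 0.3)
        params.Wl2 = similarities.S_L.copy()
        params.Wd2 = similarities.S_D.copy()
        lb = compute_losses(dataset, similarities, mask, params, Hyperparameters())
        assert lb.loss3 == 0.0

    def test_all_terms_nonnegative_and_total_linear_in_each_lambda(self, toy_problem):
        dataset, similarities, mask = toy_problem
        params = init_parameters(dataset.nm, dataset.nd, dataset.nl, 2, 0.4)
        base = Hyperparameters(lambda1=0, lambda2=0, lambda3=0, lambda4=0)
        lb0 = compute_losses(dataset, similarities, mask, params, base)
        for term in ("loss1", "loss2", "loss3", "loss4", "loss5"):
            assert getattr(lb0, term) >= 0
        for k, term in enumerate(("loss2", "loss3", "loss4", "loss5"), start=1):
            kwargs = {f"lambda{k}": 2.5, **{
                f"lambda{j}": 0 for j in range(1, 5) if j != k
            }}
            lb = compute_losses(
                dataset, similarities, mask, params, Hyperparameters(**kwargs)
            )
            assert lb.loss_total == pytest.approx(
                lb0.loss1 + 2.5 * getattr(lb0, term), rel=1e-12
            )

    def test_analytic_gradients_match_finite_differences(self, toy_problem):
        dataset, similarities, mask = toy_problem
        rng = np.random.default_rng(0)
        params = init_parameters(dataset.nm, dataset.nd, dataset.nl, 1, 0.5)
        for _, arr in params.items():  # generic point away from ReLU kinks
            arr += rng.normal(0, 0.3, arr.shape)
        hyper = Hyperparameters()
        _, analytic = loss_and_gradients(dataset, similarities, mask, params, hyper)
        numeric = numerical_gradient(dataset, similarities, mask, params, hyper)
        assert max_relative_gradient_error(analytic, numeric) <= 1e-4
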