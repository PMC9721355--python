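import numpy as np
import pytest

from tensorcog.similarity_tensor import correction_mask
from tensorcog.temporal_smoothness import build_P, smoothness_penalty
from tensorcog.tensor_ops import cp_reconstruct
from tensorcog.tmtl_model import (
    TMTLHyperparameters,
    TMTLModel,
    fit,
    objective_joint,
    objective_single,
    predict,
    predict_sample,
    soft_threshold,
)


class TestSoftThreshold:
    def test_zero_threshold_is_identity(self, rng):
        Z = rng.normal(size=(4, 5))
        np.testing.assert_array_equal(soft_threshold(Z, 0.0), Z)

    def test_closed_form_values(self):
        out = soft_threshold(np.array([3.0, -0.5]), 1.0)
        np.testing.assert_allclose(out, [2.0, 0.0])

    def test_minimizes_prox_objective(self, rng):
        # per entry: argmin_v 0.5 (v - z)^2 + tau |v|, checked on a fine grid
        tau = 0.7
        for z in rng.uniform(-3, 3, size=20):
            v_star = soft_threshold(np.array([z]), tau)[0]
            grid = np.linspace(-4, 4, 8001)
            obj = 0.5 * (grid - z) ** 2 + tau * np.abs(grid)
            assert 0.5 * (v_star - z) ** 2 + tau * abs(v_star) <= obj.min() + 1e-6

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.zeros(2), -0.1)


class TestPredictSample:
    def test_zero_weights_annihilate(self, rng):
        d, r = 4, 2
        K = correction_mask(d, d)
        out = predict_sample(rng.normal(size=(d, r)), rng.normal(size=(d, r)),
                             np.zeros((d, d)), K, rng.random((d, d)))
        assert out == 0.0

    def test_all_ones_counts_upper_triangle(self):
        d = 3
        K = correction_mask(d, d)
        out = predict_sample(np.ones((d, 1)), np.ones((d, 1)), np.ones((d, d)), K,
                             np.ones((d, d)))
        assert out == pytest.approx(3.0)

    def test_matches_double_loop(self, rng):
        d, r = 5, 2
        K = correction_mask(d, d)
        for _ in range(20):
            A, B = rng.normal(size=(2, d, r))
            W, Xn = rng.normal(size=(2, d, d))
            brute = 0.0
            for i in range(d):
                for j in range(d):
                    u = sum(A[i, q] * B[j, q] for q in range(r))
                    brute += u * K[i, j] * W[i, j] * Xn[i, j]
            assert predict_sample(A, B, W, K, Xn) == pytest.approx(brute, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        K = correction_mask(3, 3)
        with pytest.raises(ValueError):
            predict_sample(np.ones((3, 2)), np.ones((3, 2)), np.ones((4, 4)), K,
                           np.ones((3, 3)))


class TestObjectives:
    def test_all_zero_instance(self):
        hp = TMTLHyperparameters(lam=1.0, beta=0.5, theta=0.2, rank=2)
        X = np.zeros((4, 4, 3))
        val = objective_single(X, np.zeros(3), np.zeros((4, 2)), np.zeros((4, 2)),
                               np.zeros((3, 2)), np.zeros((4, 4)), hp)
        assert val == 0.0

    def test_perfect_prediction_with_no_regularization(self, rng, random_tensor):
        d, n = random_tensor.shape[0], random_tensor.shape[2]
        hp = TMTLHyperparameters(lam=0.0, beta=0.0, theta=0.0, rank=2)
        A, B = rng.normal(size=(2, d, 2))
        W = rng.normal(size=(d, d))
        K = correction_mask(d, d)
        y = np.array([predict_sample(A, B, W, K, random_tensor[:, :, k])
                      for k in range(n)])
        val = objective_single(random_tensor, y, A, B, rng.normal(size=(n, 2)), W, hp)
        assert val == pytest.approx(0.0, abs=1e-18)

    def test_single_matches_term_by_term_oracle(self, rng, random_tensor):
        d, n = random_tensor.shape[0], random_tensor.shape[2]
        r = 2
        hp = TMTLHyperparameters(lam=0.7, beta=0.3, theta=0.0, rank=r)
        A, B = rng.normal(size=(2, d, r))
        C = rng.normal(size=(n, r))
        W = rng.normal(size=(d, d))
        y = rng.normal(size=n)
        y[1] = np.nan
        K = correction_mask(d, d)
        emp = 0.5 * sum(
            (predict_sample(A, B, W, K, random_tensor[:, :, k]) - y[k]) ** 2
            for k in range(n) if not np.isnan(y[k]))
        cp = 0.5 * 0.7 * np.sum((random_tensor - cp_reconstruct(A, B, C)) ** 2)
        l1 = 0.3 * (np.abs(W).sum() + np.abs(A).sum() + np.abs(B).sum() + np.abs(C).sum())
        val = objective_single(random_tensor, y, A, B, C, W, hp)
        assert val == pytest.approx(emp + cp + l1, rel=1e-10)

    def test_joint_reduces_to_sum_when_theta_zero(self, rng, random_tensor):
        d, n = random_tensor.shape[0], random_tensor.shape[2]
        t, r = 3, 2
        hp = TMTLHyperparameters(lam=0.5, beta=0.1, theta=0.0, rank=r)
        K = correction_mask(d, d)
        model = TMTLModel(
            A=[rng.normal(size=(d, r)) for _ in range(t)],
            B=[rng.normal(size=(d, r)) for _ in range(t)],
            C=[rng.normal(size=(n, r)) for _ in range(t)],
            W=[rng.normal(size=(d, d)) for _ in range(t)],
            K=K, hp=hp, smoothness=build_P(t, [0.3]))
        Y = rng.normal(size=(n, t))
        total = sum(objective_single(random_tensor, Y[:, ti], model.A[ti], model.B[ti],
                                     model.C[ti], model.W[ti], hp, K) for ti in range(t))
        assert objective_joint(random_tensor, Y, model) == pytest.approx(total, rel=1e-12)

    def test_joint_smoothness_term_matches_oracle(self, rng, random_tensor):
        d, n = random_tensor.shape[0], random_tensor.shape[2]
        t, r = 3, 2
        hp = TMTLHyperparameters(lam=0.5, beta=0.1, theta=0.8, rank=r)
        op = build_P(t, [0.4])
        K = correction_mask(d, d)
        W_same = rng.normal(size=(d, d))
        model = TMTLModel(
            A=[rng.normal(size=(d, r)) for _ in range(t)],
            B=[rng.normal(size=(d, r)) for _ in range(t)],
            C=[rng.normal(size=(n, r)) for _ in range(t)],
            W=[W_same.copy() for _ in range(t)],
            K=K, hp=hp, smoothness=op)
        Y = rng.normal(size=(n, t))
        # identical W_t across time points: the smoothness term vanishes
        total = sum(objective_single(random_tensor, Y[:, ti], model.A[ti], model.B[ti],
                                     model.C[ti], model.W[ti], hp, K) for ti in range(t))
        assert objective_joint(random_tensor, Y, model) == pytest.approx(total, rel=1e-12)
        # and for distinct W it equals the independently computed penalty
        model.W = [rng.normal(size=(d, d)) for _ in range(t)]
        pen = smoothness_penalty(model.W_unfolded(), op)
        total = sum(objective_single(random_tensor, Y[:, ti], model.A[ti], model.B[ti],
                                     model.C[ti], model.W[ti], hp, K) for ti in range(t))
        assert objective_joint(random_tensor, Y, model) == pytest.approx(
            total + 0.8 * pen, rel=1e-10)


class TestFit:
    @pytest.fixture(scope="class")
    def fitted(self, small_problem):
        cohort, tensors, Y, truth = small_problem
        hp = TMTLHyperparameters(lam=1.0, beta=5e-3, theta=1e-3, rank=2,
                                 max_iter=150, init_sweeps=60, seed=0, tol=1e-8)
        return tensors[0], Y, fit(tensors[0], Y, hp)

    def test_objective_trace_monotone(self, fitted):
        _, _, model = fitted
        tr = np.asarray(model.objective_trace)
        assert len(tr) >= 2
        assert np.all(np.diff(tr) <= 1e-10 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_same_seed_bitwise_identical(self, small_problem):
        cohort, tensors, Y, truth = small_problem
        hp = TMTLHyperparameters(lam=1.0, beta=5e-3, theta=1e-3, rank=2,
                                 max_iter=25, seed=42)
        m1 = fit(tensors[0], Y, hp)
        m2 = fit(tensors[0], Y, hp)
        for w1, w2 in zip(m1.W, m2.W):
            np.testing.assert_array_equal(w1, w2)

    def test_max_iter_zero_returns_initialization(self, small_problem):
        cohort, tensors, Y, truth = small_problem
        hp = TMTLHyperparameters(rank=2, max_iter=0, seed=0)
        model = fit(tensors[0], Y, hp)
        assert len(model.objective_trace) == 1
        for w in model.W:
            np.testing.assert_array_equal(w, 0.0)

    def test_noiseless_forward_model_is_fit_closely(self):
        from tensorcog import SyntheticSpec, make_regression_problem
        from tensorcog.evaluation import rmse
        spec = SyntheticSpec(n=50, d=10, rank=2, score_noise_frac=0.0, seed=5)
        cohort, tensors, Y, truth = make_regression_problem(spec)
        hp = TMTLHyperparameters(lam=0.05, beta=1e-5, theta=1e-5, rank=2,
                                 max_iter=2000, init_sweeps=100, seed=0, tol=1e-12)
        model = fit(tensors[0], Y, hp)
        pred = predict(model, tensors[0])
        train = np.mean([rmse(Y[:, ti], pred[:, ti]) for ti in range(Y.shape[1])])
        assert train < 1e-2

    def test_sparsity_monotone_in_beta(self, small_problem):
        cohort, tensors, Y, truth = small_problem
        nnz = []
        for beta in (1e-4, 1e-2, 1.0):
            hp = TMTLHyperparameters(lam=1.0, beta=beta, theta=1e-3, rank=2,
                                     max_iter=150, seed=0, tol=1e-9)
            model = fit(tensors[0], Y, hp)
            nnz.append(int(sum((w != 0).sum() for w in model.W)))
        assert nnz[0] >= nnz[1] >= nnz[2]

    def test_lower_triangle_perturbation_is_ignored(self, fitted, rng):
        X, Y, model = fitted
        base = predict(model, X)
        arr = X.values.copy()
        d = arr.shape[0]
        pert = np.tril(rng.normal(size=(d, d)), k=-1)
        arr += pert[:, :, None]
        np.testing.assert_allclose(predict(model, arr), base, atol=1e-12)

    def test_predict_matches_predict_sample(self, fitted):
        X, Y, model = fitted
        pred = predict(model, X)
        k = 3
        for ti in range(model.t):
            one = predict_sample(model.A[ti], model.B[ti], model.W[ti], model.K,
                                 X.values[:, :, k])
            assert pred[k, ti] == pytest.approx(one, abs=1e-12)

    def test_zero_tensor_predicts_zero(self, fitted):
        X, Y, model = fitted
        out = predict(model, np.zeros_like(X.values))
        np.testing.assert_array_equal(out, 0.0)

    def test_unfitted_model_cannot_predict(self, small_problem):
        cohort, tensors, Y, truth = small_problem
        hp = TMTLHyperparameters(rank=2)
        model = TMTLModel(A=[], B=[], C=[], W=[np.zeros((10, 10))],
                          K=correction_mask(10, 10), hp=hp, smoothness=None)
        with pytest.raises(ValueError, match="not fitted"):
            predict(model, tensors[0])

    def test_invalid_inputs_rejected(self, small_problem):
        cohort, tensors, Y, truth = small_problem
        with pytest.raises(ValueError, match="rank"):
            fit(tensors[0], Y, TMTLHyperparameters(rank=99, max_iter=1))
        bad = tensors[0].values.copy()
        bad[0, 1, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit(bad, Y, TMTLHyperparameters(rank=2, max_iter=1))

    def test_missing_targets_are_masked(self, small_problem):
        cohort, tensors, Y, truth = small_problem
        Y2 = Y.copy()
        Y2[::3, 1] = np.nan
        hp = TMTLHyperparameters(lam=1.0, beta=5e-3, theta=1e-3, rank=2,
                                 max_iter=40, seed=0)
        model = fit(tensors[0], Y2, hp)
        assert np.isfinite(model.objective_trace).all()

    def test_roundtrip_serialization(self, fitted, tmp_path):
        X, Y, model = fitted
        model.save(tmp_path / "model.npz")
        back = TMTLModel.load(tmp_path / "model.npz")
        for w1, w2 in zip(model.W, back.W):
            np.testing.assert_array_equal(w1, w2)
        np.testing.assert_allclose(predict(back, X), predict(model, X))
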