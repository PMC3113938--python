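"""Solver correctness: L2 dual, L1 linear program, LQA engine, Elastic Net,
recursive feature elimination."""

import numpy as np
import pytest

from pensvm.core import Dataset, PenaltySpec, predict
from pensvm.solvers import (
    LQAControl,
    LQAState,
    build_lqa_system,
    fit_elastic_net_svm,
    fit_l1_svm,
    fit_l2_svm,
    fit_lqa,
    halving_schedule,
    hinge_loss,
    penalized_objective,
    rfe_svm,
    _compute_weights,
)

from conftest import oracle_l2_objective, oracle_penalized_objective, random_dataset


class TestL2SVM:
    def test_symmetric_pair(self, toy_separable):
        res = fit_l2_svm(toy_separable, C=100.0)
        w, b = res.model.w, res.model.b
        assert w[0] > 0.1 and abs(w[1]) < 1e-8
        assert b == pytest.approx(0.0, abs=1e-8)
        assert set(res.model.meta["support"]) == {0, 1}

    def test_separable_constraints_feasible(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-3, 0.5, (10, 3)), rng.normal(3, 0.5, (10, 3))])
        y = np.concatenate([-np.ones(10), np.ones(10)])
        res = fit_l2_svm(Dataset(X, y), C=100.0)
        margins = y * (X @ res.model.w + res.model.b)
        assert np.all(margins >= 1.0 - 1e-6)

    def test_objective_matches_convex_oracle(self):
        for seed in range(3):
            data = random_dataset(20, 5, seed)
            mine = fit_l2_svm(data, C=1.0).objective
            oracle = oracle_l2_objective(data, 1.0)
            assert mine == pytest.approx(oracle, rel=1e-4)

    def test_dual_reconstruction_of_w(self):
        data = random_dataset(30, 6, 4)
        res = fit_l2_svm(data, C=2.0)
        alpha = res.model.meta["alpha"]
        w_dual = (alpha * data.y) @ data.X
        assert np.allclose(w_dual, res.model.w, atol=1e-6)
        assert np.all(alpha >= 0) and np.all(alpha <= 2.0 + 1e-9)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_l2_svm(Dataset(np.zeros((3, 2)), np.ones(3)), C=1.0)

    def test_no_feature_selection(self):
        data = random_dataset(20, 7, 5)
        assert fit_l2_svm(data, C=1.0).n_features_selected == 7


class TestL1SVM:
    def test_huge_lambda_shrinks_everything(self):
        data = random_dataset(30, 8, 0)
        res = fit_l1_svm(data, lambda1=1e3)
        assert res.n_features_selected == 0
        # intercept-only model predicting one constant class; its mean hinge is
        # twice the fraction of the class it sacrifices
        preds = predict(res.model, data.X)
        assert len(set(preds)) == 1
        n_pos = int(np.sum(data.y == 1))
        expected_hinge = 2.0 * min(n_pos, 30 - n_pos) / 30.0
        hinge = np.maximum(1.0 - data.y * res.model.b, 0.0).mean()
        assert hinge == pytest.approx(expected_hinge, abs=1e-8)
        if n_pos != 15:
            majority = 1.0 if n_pos > 15 else -1.0
            assert preds[0] == majority

    def test_single_informative_feature(self):
        X = np.array([[-2.0], [-1.5], [1.5], [2.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        res = fit_l1_svm(Dataset(X, y), lambda1=0.01)
        assert res.n_features_selected == 1
        assert res.model.w[0] > 0

    def test_objective_matches_convex_oracle(self):
        for seed in range(3):
            data = random_dataset(30, 8, 10 + seed)
            mine = fit_l1_svm(data, lambda1=0.1).objective
            oracle = oracle_penalized_objective(data, 0.1, 0.0)
            assert mine == pytest.approx(oracle, rel=1e-6, abs=1e-6)

    def test_selection_bounded_by_sample_size(self):
        """The L1 penalty cannot select more features than samples (+intercept)."""
        for seed in range(3):
            data = random_dataset(20, 300, 20 + seed)
            res = fit_l1_svm(data, lambda1=0.01)
            assert res.n_features_selected <= 21


class TestLQAEngine:
    def test_system_spd_with_ridge_term(self):
        data = random_dataset(25, 6, 1)
        spec = PenaltySpec("elastic_scad", lambda1=0.5, lambda2=0.4)
        state = LQAState(b0=0.1, w0=np.full(6, 0.3), active=np.arange(6))
        A, rhs = build_lqa_system(data, state, spec)
        eigvals = np.linalg.eigvalsh(A[1:, 1:])
        assert np.all(eigvals > 0)
        c = np.linalg.solve(A, rhs)
        assert np.max(np.abs(A @ c - rhs)) < 1e-8

    def test_local_model_gradient_matches_objective(self):
        """At an expansion point with no sample on the margin and no
        coefficient at a spline knot, the quadratic model's gradient equals
        the finite-difference gradient of the true objective."""
        data = random_dataset(25, 5, 6)
        spec = PenaltySpec("elastic_scad", lambda1=0.3, lambda2=0.2)
        rng = np.random.default_rng(8)
        w0 = rng.uniform(0.2, 0.9, 5) * np.where(rng.random(5) < 0.5, 1, -1)
        b0 = 0.17
        state = LQAState(b0=b0, w0=w0.copy(), active=np.arange(5))
        _compute_weights(data, state, spec, zero_floor=1e-12, hinge_floor=1e-12)
        A, rhs = build_lqa_system(data, state, spec)
        n = data.n_samples
        c0 = np.concatenate([[b0], w0])
        # local quadratic: (1/n)[c'Ac - 2 rhs'c] + const -> gradient (2/n)(Ac - rhs)
        grad_quad = 2.0 * (A @ c0 - rhs) / n

        def true_obj(c):
            return penalized_objective(data, c[1:], c[0], spec)

        h = 1e-6
        for j in range(6):
            e = np.zeros(6)
            e[j] = h
            fd = (true_obj(c0 + e) - true_obj(c0 - e)) / (2 * h)
            assert grad_quad[j] == pytest.approx(fd, abs=1e-5)

    def test_majorant_value_matches_at_expansion(self):
        data = random_dataset(20, 4, 9)
        spec = PenaltySpec("scad", lambda1=0.4)
        w0 = np.array([0.6, -0.8, 0.3, 1.2])
        state = LQAState(b0=-0.2, w0=w0.copy(), active=np.arange(4))
        _compute_weights(data, state, spec, zero_floor=1e-12, hinge_floor=1e-12)
        # reconstruct the full local model incl. dropped constants and compare
        m0 = 1.0 - data.y * (data.X @ w0 - 0.2)
        s = state.hinge_weights
        local_hinge = (s * m0**2 + m0 / 2.0 + np.abs(m0) / 4.0).mean()
        assert local_hinge == pytest.approx(hinge_loss(data.y, data.X @ w0 - 0.2).mean(), abs=1e-10)

    def test_elastic_scad_zero_ridge_identical_to_scad(self):
        data = random_dataset(40, 10, 12)
        r_scad = fit_lqa(data, PenaltySpec("scad", lambda1=0.2))
        r_es = fit_lqa(data, PenaltySpec("elastic_scad", lambda1=0.2, lambda2=0.0))
        assert np.array_equal(r_scad.model.w, r_es.model.w)
        assert r_scad.model.b == r_es.model.b
        assert r_scad.objective_trace == pytest.approx(r_es.objective_trace)

    def test_full_shrinkage_gives_majority_model(self):
        data = random_dataset(30, 6, 13)
        res = fit_lqa(data, PenaltySpec("scad", lambda1=50.0))
        assert res.n_features_selected == 0
        majority = 1.0 if np.sum(data.y == 1) >= 15 else -1.0
        assert np.all(predict(res.model, data.X) == majority)

    def test_final_objective_near_direct_search_polish(self):
        from conftest import polish_active_set

        data = random_dataset(40, 10, 14)
        spec = PenaltySpec("elastic_scad", lambda1=0.15, lambda2=0.05)
        res = fit_lqa(data, spec)
        best = polish_active_set(data, res, spec)
        assert res.objective <= best * 1.01 + 1e-9

    def test_descent_on_non_removal_steps(self):
        for seed in (15, 16, 17):
            data = random_dataset(50, 20, seed)
            res = fit_lqa(data, PenaltySpec("scad", lambda1=0.1))
            trace = res.objective_trace
            removal = set(res.model.meta["removal_steps"])
            increases = [
                trace[i] - trace[i - 1] for i in range(1, len(trace)) if i not in removal
            ]
            assert max(increases, default=0.0) <= 1e-6

    def test_refit_is_bit_identical(self):
        data = random_dataset(35, 12, 18)
        spec = PenaltySpec("elastic_scad", lambda1=0.1, lambda2=0.05)
        r1, r2 = fit_lqa(data, spec), fit_lqa(data, spec)
        assert np.array_equal(r1.model.w, r2.model.w)
        assert r1.model.b == r2.model.b

    def test_nonconvergence_flagged_not_raised(self):
        data = random_dataset(40, 10, 19)
        res = fit_lqa(data, PenaltySpec("scad", lambda1=0.05), control=LQAControl(max_iter=2))
        assert res.model.meta["converged"] in (False, True)  # returned, no exception


class TestElasticNet:
    def test_zero_ridge_delegates_to_l1(self):
        data = random_dataset(30, 8, 21)
        r_en = fit_elastic_net_svm(data, 0.1, 0.0)
        r_l1 = fit_l1_svm(data, 0.1)
        assert r_en.objective == pytest.approx(r_l1.objective, abs=1e-12)
        assert np.array_equal(r_en.model.w, r_l1.model.w)

    def test_objective_matches_convex_oracle(self):
        for seed in range(3):
            data = random_dataset(30, 8, 30 + seed)
            mine = fit_elastic_net_svm(data, 0.1, 0.05).objective
            oracle = oracle_penalized_objective(data, 0.1, 0.05)
            assert mine == pytest.approx(oracle, rel=1e-4)

    def test_grouping_effect_on_duplicated_feature(self):
        """With a ridge component, two identical features share the coefficient."""
        rng = np.random.default_rng(31)
        base = rng.standard_normal((60, 1))
        noise = rng.standard_normal((60, 3)) * 0.5
        X = np.hstack([base, base, noise])
        y = np.where(base.ravel() + 0.3 * noise[:, 0] > 0, 1.0, -1.0)
        res = fit_elastic_net_svm(Dataset(X, y), lambda1=0.05, lambda2=0.5)
        w = res.model.w
        assert w[0] == pytest.approx(w[1], abs=1e-3)
        assert w[0] > 0

    def test_requires_some_penalty(self):
        data = random_dataset(10, 3, 33)
        with pytest.raises(ValueError):
            fit_elastic_net_svm(data, 0.0, 0.0)


class TestRFE:
    def test_schedule_halves_powers_of_two(self):
        assert halving_schedule(8) == [8, 4, 2, 1]

    def test_schedule_contains_256_for_microarray_width(self):
        assert 256 in halving_schedule(4919)

    def test_schedule_always_ends_at_one(self):
        for p in (2, 3, 10, 100, 1000):
            s = halving_schedule(p)
            assert s[0] == p and s[-1] == 1
            assert all(a > b for a, b in zip(s, s[1:]))

    def test_permuting_features_permutes_retained_sets(self):
        from pensvm.model_selection import stratified_kfold

        data = random_dataset(40, 8, 40)
        plan = stratified_kfold(data.y, 4, seed=0)
        res = rfe_svm(data, C=1.0, plan=plan)

        perm = np.random.default_rng(1).permutation(8)
        data_p = Dataset(data.X[:, perm], data.y)
        res_p = rfe_svm(data_p, C=1.0, plan=plan)
        inv = np.argsort(perm)
        for s, s_p in zip(res.feature_sets, res_p.feature_sets):
            assert set(s) == set(perm[s_p])

    def test_cv_error_recorded_per_size(self):
        from pensvm.model_selection import stratified_kfold

        data = random_dataset(30, 8, 41)
        plan = stratified_kfold(data.y, 3, seed=0)
        res = rfe_svm(data, C=1.0, plan=plan)
        assert len(res.cv_errors) == len(res.sizes) == 4
        assert res.best_size in res.sizes
        assert len(res.best_features) == res.best_size
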