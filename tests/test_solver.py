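"""Alternating solver: objective, multiplicative F updates, closed-form
propagation, and the outer loop."""

import numpy as np
import pytest
from scipy.optimize import minimize, nnls
from sklearn.metrics import adjusted_rand_score

import lpfs
from lpfs.solver import auxiliary_diagonal, binarize, f_objective, update_F

from conftest import make_xm


def random_instance(rng, n=6, m=4, c=2):
    X = rng.uniform(0.1, 2.0, size=(n, m))
    xm = make_xm(X)
    graph = lpfs.build_sample_graph(xm, "auto")
    Y = np.zeros((n, c))
    Y[np.arange(n), rng.integers(0, c, n)] = 1.0
    F = rng.uniform(0, 1, size=(m, c))
    H = rng.uniform(0, 1, size=(n, c))
    return xm, graph, Y, F, H


class TestObjective:
    def test_zero_everywhere_gives_zero(self, rng):
        xm, graph, *_ = random_instance(rng)
        zero_hy = np.zeros((6, 2))
        F = np.zeros((4, 2))
        assert lpfs.objective(xm, graph, zero_hy, zero_hy, F, 0.2, 0.2) == 0.0

    def test_smoothness_vanishes_for_constant_normalized_rows(self, rng):
        xm, graph, _, F, _ = random_instance(rng)
        # H_i proportional to sqrt(d_ii): normalized rows identical
        H = np.sqrt(graph.degrees)[:, None] * np.ones((1, 2))
        obj = lpfs.objective(xm, graph, H, H, F, 0.5, 0.0)
        fit = np.sum((xm.values @ F - H) ** 2)
        assert obj == pytest.approx(fit, rel=1e-10)

    def test_matches_brute_force_double_loop(self, rng):
        xm, graph, Y, F, H = random_instance(rng)
        mu, beta = 0.3, 0.4
        Hn = H / np.sqrt(graph.degrees)[:, None]
        smooth = sum(
            graph.W[i, j] * np.sum((Hn[i] - Hn[j]) ** 2)
            for i in range(6)
            for j in range(6)
        )
        anchor = sum(np.sum((H[i] - Y[i]) ** 2) for i in range(6))
        fit = np.sum((xm.values @ F - H) ** 2)
        l21 = sum(np.sqrt(np.sum(F[:, j] ** 2)) for j in range(2))
        expect = smooth + mu * anchor + fit + beta * l21
        assert lpfs.objective(xm, graph, H, Y, F, mu, beta) == pytest.approx(expect, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        xm, graph, Y, F, H = random_instance(rng)
        with pytest.raises(lpfs.ValidationError):
            lpfs.objective(xm, graph, H, Y[:-1], F, 0.2, 0.2)


class TestUpdateF:
    def test_kkt_fixed_point_is_stationary(self, rng):
        # build an exactly-consistent instance: H = X F  with beta = 0
        X = rng.uniform(0.5, 1.5, size=(6, 4))
        F = rng.uniform(0.2, 1.0, size=(4, 2))
        H = X @ F
        fsm = lpfs.FeatureSelectionMatrix.from_F(F)
        out = update_F(fsm, X, H, beta=0.0)
        np.testing.assert_allclose(out.F, F, rtol=1e-9)

    def test_zero_entries_are_absorbing(self, rng):
        X = rng.uniform(0.1, 1.0, size=(5, 3))
        H = rng.uniform(0, 1, size=(5, 2))
        F = rng.uniform(0.1, 1.0, size=(3, 2))
        F[1, 0] = 0.0
        out = update_F(lpfs.FeatureSelectionMatrix.from_F(F), X, H, beta=0.3)
        assert out.F[1, 0] == 0.0
        assert np.all(out.F >= 0)

    def test_single_update_never_increases_subproblem(self, rng):
        X = rng.uniform(0, 1, size=(6, 4))
        H = rng.uniform(0, 1, size=(6, 2))
        F = rng.uniform(0, 1, size=(4, 2))
        before = f_objective(X, F, H, 0.2)
        out = update_F(lpfs.FeatureSelectionMatrix.from_F(F), X, H, 0.2)
        assert f_objective(X, out.F, H, 0.2) <= before * (1 + 1e-12)

    def test_negative_input_rejected(self):
        fsm = lpfs.FeatureSelectionMatrix(F=np.array([[-1.0]]), u=np.array([1.0]))
        with pytest.raises(lpfs.ValidationError):
            update_F(fsm, np.ones((2, 1)), np.ones((2, 1)), 0.2)


class TestSolveF:
    def test_zero_target_drives_F_to_zero(self, rng):
        X = rng.uniform(0.5, 1.5, size=(6, 3))
        H = np.zeros((6, 2))
        fsm, trace = lpfs.solve_F(X, H, beta=0.2, tol=1e-10, max_iter=2000, seed=0)
        assert np.all(fsm.F >= 0)
        assert np.max(fsm.F) < 1e-3
        assert trace[-1] <= trace[0]

    def test_beta_zero_matches_nnls_oracle(self, rng):
        X = rng.uniform(0.5, 2.0, size=(8, 3))
        H = rng.uniform(0, 1, size=(8, 3))
        fsm, _ = lpfs.solve_F(X, H, beta=0.0, tol=1e-12, max_iter=20000, seed=1)
        obj = np.sum((X @ fsm.F - H) ** 2)
        F_oracle = np.column_stack([nnls(X, H[:, j])[0] for j in range(3)])
        obj_oracle = np.sum((X @ F_oracle - H) ** 2)
        assert obj == pytest.approx(obj_oracle, rel=1e-4, abs=1e-12)

    def test_same_seed_bitwise_identical_and_seeds_agree_on_objective(self, rng):
        X = rng.uniform(0.5, 2.0, size=(8, 4))
        H = (rng.uniform(0, 1, size=(8, 2)) > 0.5).astype(float)
        a, _ = lpfs.solve_F(X, H, 0.2, tol=1e-8, max_iter=5000, seed=42)
        b, _ = lpfs.solve_F(X, H, 0.2, tol=1e-8, max_iter=5000, seed=42)
        np.testing.assert_array_equal(a.F, b.F)
        c, _ = lpfs.solve_F(X, H, 0.2, tol=1e-8, max_iter=5000, seed=43)
        oa = f_objective(X, a.F, H, 0.2)
        oc = f_objective(X, c.F, H, 0.2)
        assert oa == pytest.approx(oc, rel=1e-3)

    def test_auxiliary_diagonal_definition(self, rng):
        F = rng.uniform(0, 1, size=(5, 3))
        u = auxiliary_diagonal(F)
        np.testing.assert_allclose(u, 1.0 / (2 * np.linalg.norm(F, axis=0)))


class TestSolveH:
    def test_defining_linear_system_residual(self, rng):
        for _ in range(5):
            xm, graph, Y, F, _ = random_instance(rng, n=8, m=5, c=3)
            prop = lpfs.solve_H(graph, Y, xm, F, mu=0.2)
            A = 1.2 * np.eye(8) - graph.Z
            rhs = 0.2 * Y + xm.values @ F
            res = np.linalg.norm(A @ prop.H_star - rhs) / np.linalg.norm(rhs)
            assert res <= 1e-8

    def test_large_mu_anchors_to_initial_labels(self, rng):
        xm, graph, Y, _, _ = random_instance(rng, n=8, m=5, c=3)
        F = np.zeros((5, 3))
        prop = lpfs.solve_H(graph, Y, xm, F, mu=1e6)
        np.testing.assert_array_equal(prop.labels, np.argmax(Y, axis=1) + 1)

    def test_disconnected_blocks_propagate_their_seed_label(self):
        # two 3-sample blocks, far apart: one labeled sample per block
        vals = np.vstack([np.full((3, 2), 0.0) + [[0, 0], [0.1, 0], [0, 0.1]],
                          np.full((3, 2), 50.0) + [[0, 0], [0.1, 0], [0, 0.1]]])
        xm = make_xm(vals)
        graph = lpfs.build_sample_graph(xm, delta=0.5)
        Y = np.zeros((6, 2))
        Y[0, 0] = 1.0
        Y[3, 1] = 1.0
        prop = lpfs.solve_H(graph, Y, xm, np.zeros((2, 2)), mu=0.2)
        np.testing.assert_array_equal(prop.labels, [1, 1, 1, 2, 2, 2])

    def test_matches_generic_minimizer_of_propagation_objective(self, rng):
        # The closed form is the exact minimizer of
        #   1/2 sum_ij w_ij ||H_i/sqrt(d_ii) - H_j/sqrt(d_jj)||^2
        #   + mu ||H - (Y + XF/mu)||_F^2
        xm, graph, Y, F, _ = random_instance(rng, n=5, m=4, c=2)
        mu = 0.3
        prop = lpfs.solve_H(graph, Y, xm, F, mu)
        target = Y + xm.values @ F / mu

        def q(hflat):
            H = hflat.reshape(5, 2)
            Hn = H / np.sqrt(graph.degrees)[:, None]
            smooth = sum(
                graph.W[i, j] * np.sum((Hn[i] - Hn[j]) ** 2)
                for i in range(5)
                for j in range(5)
            )
            return 0.5 * smooth + mu * np.sum((H - target) ** 2)

        res = minimize(q, np.zeros(10), method="L-BFGS-B",
                       options={"ftol": 1e-15, "gtol": 1e-12})
        assert q(prop.H_star.ravel()) == pytest.approx(res.fun, rel=1e-4)
        np.testing.assert_allclose(prop.H_star.ravel(), res.x, atol=1e-5)

    def test_sample_permutation_equivariance(self, rng):
        xm, graph, Y, F, _ = random_instance(rng, n=7, m=4, c=2)
        prop = lpfs.solve_H(graph, Y, xm, F, mu=0.2)
        perm = rng.permutation(7)
        xp = xm.subset_samples(perm)
        gp = lpfs.build_sample_graph(xp, lpfs.suggest_delta(xm))
        pp = lpfs.solve_H(gp, Y[perm], xp, F, mu=0.2)
        np.testing.assert_allclose(pp.H_star, prop.H_star[perm], atol=1e-10)

    def test_argmax_ties_break_to_smallest_index(self):
        labels, H_bin = binarize(np.array([[0.5, 0.5, 0.2], [0.1, 0.3, 0.3]]))
        np.testing.assert_array_equal(labels, [1, 2])
        assert H_bin.sum() == 2


class TestLpfsFit:
    def _fit(self, seed, effect=2.0, mu=0.2):
        xm, truth = lpfs.simulate_dataset(
            n_per_category=8, c=3, m=120, markers_per_category=8,
            effect=effect, seed=seed,
        )
        spec = lpfs.full_labels(truth)
        cfg = lpfs.LPFSConfig(mu=mu, delta="auto", seed=seed)
        return lpfs.lpfs_fit(xm, spec, cfg), truth

    def test_recovers_strongly_separated_categories(self):
        fit, truth = self._fit(seed=0)
        ari = adjusted_rand_score(truth.labels, fit.propagation.labels)
        assert ari >= 0.9

    def test_large_mu_returns_input_labels(self):
        fit, truth = self._fit(seed=1, mu=1e6)
        np.testing.assert_array_equal(fit.propagation.labels, truth.labels)

    def test_outer_objective_nonincreasing(self):
        for seed in range(3):
            fit, _ = self._fit(seed=seed)
            t = np.array(fit.trace.outer_objective)
            rel_inc = np.max((t[1:] - t[:-1]) / np.maximum(np.abs(t[:-1]), 1e-12))
            assert rel_inc <= 1e-6

    def test_f_nonnegative_and_trace_structure(self):
        fit, _ = self._fit(seed=2)
        assert np.all(fit.feature_selection.F >= 0)
        assert fit.trace.rounds_used == len(fit.trace.outer_objective)
        for f_trace in fit.trace.f_objective:
            t = np.array(f_trace)
            assert np.all(t[1:] <= t[:-1] * (1 + 1e-10))

    def test_partial_labels_recover_given_informative_graph(self):
        # Unlabeled samples have no anchor, so semi-supervised recovery
        # needs clear within/between category contrast in the sample graph.
        xm, truth = lpfs.simulate_dataset(
            n_per_category=8, c=3, m=60, markers_per_category=10,
            effect=4.0, seed=5,
        )
        spec = lpfs.make_partial_labels(truth, 0.5, seed=5)
        assert spec.n_labeled == 12  # stratified: 4 of 8 per category
        cfg = lpfs.LPFSConfig(delta="auto", seed=5)
        fit = lpfs.lpfs_fit(xm, spec, cfg)
        ari = adjusted_rand_score(truth.labels, fit.propagation.labels)
        assert ari >= 0.9
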