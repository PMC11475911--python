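import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import gammaln

from spotdec import glrm, io_prep


@pytest.fixture(scope="module")
def sig_small():
    """Two well-separated cell-type signatures over 12 genes."""
    rng = np.random.default_rng(11)
    mu = np.vstack([
        np.concatenate([rng.uniform(0.1, 0.15, 6), rng.uniform(0.002, 0.004, 6)]),
        np.concatenate([rng.uniform(0.002, 0.004, 6), rng.uniform(0.1, 0.15, 6)]),
    ])
    mu = mu / mu.sum(axis=1, keepdims=True)
    return pd.DataFrame(mu, index=["A", "B"], columns=[f"g{j}" for j in range(12)])


def _simulate_spots(mu, thetas, N=2000, seed=0):
    rng = np.random.default_rng(seed)
    muv = mu.to_numpy()
    Y = np.column_stack([rng.poisson(N * (t @ muv)) for t in thetas])
    return pd.DataFrame(Y, index=mu.columns,
                        columns=[f"spot{i}" for i in range(len(thetas))])


class TestSignatures:
    def test_single_cell_per_type_equals_profile(self):
        ref = pd.DataFrame({"c1": [2, 2], "c2": [9, 1]}, index=["g1", "g2"])
        annot = pd.Series({"c1": "A", "c2": "B"})
        mu = glrm.compute_signatures(ref, annot, ["g1", "g2"])
        assert np.allclose(mu.loc["A"], [0.5, 0.5])
        assert np.allclose(mu.loc["B"], [0.9, 0.1])

    def test_duplicating_cells_leaves_mean_unchanged(self):
        ref = pd.DataFrame({"c1": [2, 4], "c2": [3, 3], "c3": [8, 2]},
                           index=["g1", "g2"])
        annot = pd.Series({"c1": "A", "c2": "A", "c3": "B"})
        mu1 = glrm.compute_signatures(ref, annot, ["g1", "g2"])
        dup = pd.concat([ref, ref.add_suffix("_d")], axis=1)
        annot2 = pd.concat([annot, annot.set_axis([f"{c}_d" for c in annot.index])])
        mu2 = glrm.compute_signatures(dup, annot2, ["g1", "g2"])
        pd.testing.assert_frame_equal(mu1, mu2)

    def test_three_cell_arithmetic_oracle(self):
        ref = pd.DataFrame({"c1": [1, 3], "c2": [2, 2], "c3": [5, 0]},
                           index=["g1", "g2"])
        annot = pd.Series({"c1": "A", "c2": "A", "c3": "B"})
        mu = glrm.compute_signatures(ref, annot, ["g1", "g2"])
        # c1 normalized (0.25, 0.75); c2 (0.5, 0.5) -> A mean (0.375, 0.625)
        assert np.allclose(mu.loc["A"], [0.375, 0.625])
        assert np.allclose(mu.loc["B"], [1.0, 0.0])


class TestHeavyTailDensity:
    @pytest.mark.parametrize("sigma", [0.1, 0.5, 1.0, 2.0])
    def test_integrates_to_one(self, sigma):
        val, _ = quad(lambda e: glrm.heavy_tail_density(e, sigma),
                      -8 * sigma, 8 * sigma,
                      points=[-3 * sigma, 3 * sigma], limit=200)
        assert abs(val - 1.0) < 1e-6

    def test_symmetry(self):
        eps = np.array([0.1, 0.4, 1.1, 2.5])
        assert np.allclose(glrm.heavy_tail_density(eps, 0.5),
                           glrm.heavy_tail_density(-eps, 0.5))

    def test_gaussian_core_ratio(self):
        sigma = 0.7
        e = 1.2
        ratio = glrm.heavy_tail_density(e, sigma) / glrm.heavy_tail_density(0.0, sigma)
        assert np.isclose(ratio, math.exp(-(e**2) / (2 * sigma**2)))

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            glrm.heavy_tail_density(0.1, 0.0)


class TestBaseNegloglik:
    def test_sigma_zero_reduces_to_poisson(self):
        Y = np.array([3.0, 0.0, 7.0])
        mu = pd.DataFrame([[0.2, 0.3, 0.5]], index=["A"]).to_numpy()
        N = 20.0
        ours = glrm.base_negloglik(np.array([1.0]), 0.0, Y, N, mu, sigma2=0.0,
                                   grid=glrm.epsilon_grid(0.0))
        rate = N * mu[0]
        direct = -np.sum(Y * np.log(rate) - rate - gammaln(Y + 1))
        assert np.isclose(ours, direct)

    def test_zero_count_unit_rate_contributes_one(self):
        # Y=0, N=1, mu=1, alpha=0, sigma->0: -log(e^-1) = 1 per gene
        val = glrm.base_negloglik(np.array([1.0]), 0.0, np.array([0.0]), 1.0,
                                  np.array([[1.0]]), 0.0, grid=glrm.epsilon_grid(0.0))
        assert np.isclose(val, 1.0)

    def test_matches_dense_quadrature_oracle(self):
        rng = np.random.default_rng(0)
        K, J = 3, 8
        mu = rng.uniform(0.1, 1.0, size=(K, J))
        theta = np.array([0.5, 0.3, 0.2])
        alpha, N, sigma2 = 0.1, 500.0, 0.09
        s = theta @ mu
        Y = rng.poisson(N * np.exp(alpha) * s).astype(float)
        sg = math.sqrt(sigma2)
        dense = glrm.epsilon_grid(sg, n_core=20001)
        ours = glrm.base_negloglik(theta, alpha, Y, N, mu, sigma2, grid=dense)
        oracle = 0.0
        for j in range(J):
            f = lambda e: glrm.heavy_tail_density(e, sg) * np.exp(
                Y[j] * np.log(N * np.exp(alpha + e) * s[j])
                - N * np.exp(alpha + e) * s[j] - gammaln(Y[j] + 1))
            I, _ = quad(f, -8 * sg, 8 * sg, points=[-3 * sg, 3 * sg], limit=400)
            oracle -= np.log(I)
        assert abs(ours - oracle) < 1e-6

    def test_simplex_violation_rejected(self):
        with pytest.raises(ValueError):
            glrm.base_negloglik(np.array([0.7, 0.7]), 0.0, np.array([1.0]), 1.0,
                                np.ones((2, 1)), 0.01)


class TestFitBaseMle:
    def test_pure_type_recovery(self, sig_small):
        Y = _simulate_spots(sig_small, [np.array([1.0, 0.0])] * 4, seed=1)
        theta, alpha, sigma2 = glrm.fit_base_mle(Y, np.full(4, 2000.0), sig_small)
        assert (theta["A"] > 0.95).all()

    def test_even_mixture_recovery(self, sig_small):
        Y = _simulate_spots(sig_small, [np.array([0.5, 0.5])] * 4, N=5000, seed=2)
        theta, _, _ = glrm.fit_base_mle(Y, np.full(4, 5000.0), sig_small)
        assert np.abs(theta.to_numpy() - 0.5).max() < 0.05

    def test_likelihood_no_worse_than_uniform_start(self, sig_small):
        Y = _simulate_spots(sig_small, [np.array([0.8, 0.2])], seed=3)
        N = np.array([2000.0])
        theta, alpha, sigma2 = glrm.fit_base_mle(Y, N, sig_small)
        grid = glrm.epsilon_grid(math.sqrt(sigma2))
        muv = sig_small.to_numpy()
        y = Y.to_numpy(float)[:, 0]
        at_opt = glrm.base_negloglik(theta.to_numpy()[0], alpha[0], y, N[0], muv,
                                     sigma2, grid)
        at_unif = glrm.base_negloglik(np.array([0.5, 0.5]), alpha[0], y, N[0], muv,
                                      sigma2, grid)
        assert at_opt <= at_unif + 1e-6


class TestPenalties:
    def test_adaptive_lasso_hand_value(self):
        assert glrm.adaptive_lasso_penalty(np.array([0.5, 0.25]), np.array([2.0, 4.0])) == 2.0
        assert glrm.adaptive_lasso_penalty(np.zeros(3), np.ones(3)) == 0.0

    def test_positive_homogeneity(self, rng):
        theta = rng.random(5)
        q = rng.random(5) + 0.1
        for c in (0.0, 0.3, 2.7):
            assert np.isclose(glrm.adaptive_lasso_penalty(c * theta, q),
                              c * glrm.adaptive_lasso_penalty(theta, q))

    def test_weights_are_floored_reciprocals(self):
        theta = pd.DataFrame([[0.5, 0.0]], columns=["A", "B"])
        q = glrm.weights_from_mle(theta)
        assert np.isclose(q.iloc[0, 0], 2.0)
        assert np.isclose(q.iloc[0, 1], 1e4)

    def test_laplacian_zero_for_identical_rows(self):
        L = np.array([[1.0, -1.0], [-1.0, 1.0]])
        theta = np.array([[0.3, 0.7], [0.3, 0.7]])
        assert glrm.laplacian_penalty(theta, L) == 0.0

    def test_laplacian_two_spot_hand_value(self):
        L = np.array([[1.0, -1.0], [-1.0, 1.0]])
        theta = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.isclose(glrm.laplacian_penalty(theta, L), 2.0)

    def test_laplacian_equals_pairwise_sum(self, rng):
        n, K = 7, 4
        A = (rng.random((n, n)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        L = np.diag(A.sum(axis=1)) - A
        theta = rng.dirichlet(np.ones(K), size=n)
        pairwise = 0.5 * sum(
            A[s, t] * np.sum((theta[s] - theta[t]) ** 2)
            for s in range(n) for t in range(n)
        )
        assert np.isclose(glrm.laplacian_penalty(theta, L), pairwise)

    def test_asymmetric_adjacency_rejected(self):
        with pytest.raises(ValueError):
            glrm.laplacian_penalty(np.ones((2, 2)), np.array([[1.0, 0.0], [-1.0, 1.0]]))


class TestSpatialGraph:
    def test_two_spots(self):
        coords = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 0.0]}, index=["a", "b"])
        g = glrm.build_spatial_graph(coords)
        assert np.array_equal(g.adjacency, [[0, 1], [1, 0]])
        assert np.allclose(g.laplacian.sum(axis=1), 0.0)

    def test_isolated_spot_degree_zero(self):
        coords = pd.DataFrame({"x": [0.0, 1.0, 50.0], "y": [0.0, 0.0, 0.0]})
        g = glrm.build_spatial_graph(coords)
        assert g.adjacency[2].sum() == 0

    def test_3x3_grid_interior_degree_four(self):
        pts = [(i % 3, i // 3) for i in range(9)]
        coords = pd.DataFrame(pts, columns=["x", "y"])
        g = glrm.build_spatial_graph(coords)
        assert g.adjacency[4].sum() == 4  # center of the grid

    def test_laplacian_psd(self, grid5x5):
        g = glrm.build_spatial_graph(grid5x5)
        eig = np.linalg.eigvalsh(g.laplacian)
        assert eig.min() > -1e-10


class TestProjectSimplex:
    def test_projection_properties(self, rng):
        for _ in range(20):
            v = rng.normal(size=6) * 3
            p = glrm.project_simplex(v)
            assert np.isclose(p.sum(), 1.0) and (p >= 0).all()

    def test_already_feasible_unchanged(self):
        v = np.array([0.2, 0.3, 0.5])
        assert np.allclose(glrm.project_simplex(v), v)


@pytest.fixture(scope="module")
def stage_data(sig_small):
    thetas = [np.array([1.0, 0.0]), np.array([0.0, 1.0]),
              np.array([0.7, 0.3]), np.array([0.3, 0.7])]
    Y = _simulate_spots(sig_small, thetas, N=3000, seed=4)
    N = np.full(4, 3000.0)
    theta_mle, alpha, sigma2 = glrm.fit_base_mle(Y, N, sig_small)
    q = glrm.weights_from_mle(theta_mle)
    return Y, N, sig_small, theta_mle, alpha, sigma2, q


class TestStage1:
    def test_zero_penalty_matches_mle_support(self, stage_data):
        Y, N, mu, theta_mle, alpha, sigma2, q = stage_data
        theta, selected, _ = glrm.stage1_select(Y, N, mu, sigma2, alpha, q,
                                                lam_r=0.0, max_iter=60,
                                                theta_init=theta_mle)
        for i in range(4):
            mle_sup = set(np.flatnonzero(theta_mle.to_numpy()[i] >= 1e-3))
            assert set(selected[i]) == mle_sup

    def test_pure_spot_selects_single_type(self, stage_data):
        Y, N, mu, theta_mle, alpha, sigma2, q = stage_data
        _, selected, _ = glrm.stage1_select(Y, N, mu, sigma2, alpha, q,
                                            lam_r=50.0, max_iter=60,
                                            theta_init=theta_mle)
        assert len(selected[0]) == 1 and len(selected[1]) == 1

    def test_selection_nesting_along_lambda_ladder(self, stage_data):
        Y, N, mu, theta_mle, alpha, sigma2, q = stage_data
        supports = []
        for lam in (0.0, 1.0, 10.0, 100.0):
            _, sel, _ = glrm.stage1_select(Y, N, mu, sigma2, alpha, q, lam,
                                           max_iter=60, theta_init=theta_mle)
            supports.append([set(s) for s in sel])
        for weak, strong in zip(supports[:-1], supports[1:]):
            # allow one solver-noise violation across all spots
            violations = sum(not s <= w for w, s in zip(weak, strong))
            assert violations <= 1

    def test_rows_on_simplex(self, stage_data):
        Y, N, mu, theta_mle, alpha, sigma2, q = stage_data
        theta, _, _ = glrm.stage1_select(Y, N, mu, sigma2, alpha, q, 1.0,
                                         max_iter=40, theta_init=theta_mle)
        v = theta.to_numpy()
        assert np.allclose(v.sum(axis=1), 1.0) and (v >= 0).all()

    def test_objective_non_increasing(self, stage_data):
        Y, N, mu, theta_mle, alpha, sigma2, q = stage_data
        _, _, trace = glrm.stage1_select(Y, N, mu, sigma2, alpha, q, 1.0,
                                         max_iter=40, theta_init=theta_mle,
                                         track_objective=True)
        for objs in trace.objective_per_spot:
            if len(objs) > 1:
                assert np.diff(objs).max() <= 1e-3 * max(1.0, abs(objs[0]))


class TestStage2:
    def test_zero_laplacian_decouples_into_per_spot_fits(self, stage_data):
        Y, N, mu, theta_mle, alpha, sigma2, q = stage_data
        sel = [np.array([0, 1])] * 4
        L = np.zeros((4, 4))
        joint, _ = glrm.stage2_smooth(Y, N, mu, sigma2, alpha, sel, L, 0.0,
                                      max_iter=40, theta_init=theta_mle)
        single_rows = []
        for i in range(4):
            yi = Y.iloc[:, [i]]
            sub, _ = glrm.stage2_smooth(yi, N[[i]], mu, sigma2, alpha[[i]],
                                        [sel[i]], np.zeros((1, 1)), 0.0,
                                        max_iter=40, theta_init=theta_mle.iloc[[i]])
            single_rows.append(sub.to_numpy()[0])
        assert np.allclose(joint.to_numpy(), np.vstack(single_rows), atol=5e-3)

    def test_large_lambda_shrinks_across_spot_variance(self, stage_data):
        Y, N, mu, theta_mle, alpha, sigma2, q = stage_data
        sel = [np.array([0, 1])] * 4
        A = np.ones((4, 4)) - np.eye(4)  # fully connected
        L = np.diag(A.sum(axis=1)) - A
        variances = []
        for lam in (0.0, 10.0, 1000.0):
            th, _ = glrm.stage2_smooth(Y, N, mu, sigma2, alpha, sel, L, lam,
                                       max_iter=40, theta_init=theta_mle)
            variances.append(th.to_numpy().var(axis=0).sum())
        assert variances[2] < variances[1] < variances[0]
        assert variances[2] < 0.2 * variances[0]

    def test_zeros_preserved_outside_selection_and_simplex(self, stage_data):
        Y, N, mu, theta_mle, alpha, sigma2, q = stage_data
        sel = [np.array([0]), np.array([1]), np.array([0, 1]), np.array([0, 1])]
        L = np.zeros((4, 4))
        th, _ = glrm.stage2_smooth(Y, N, mu, sigma2, alpha, sel, L, 0.0,
                                   max_iter=30, theta_init=theta_mle)
        v = th.to_numpy()
        assert v[0, 1] == 0.0 and v[1, 0] == 0.0
        assert np.allclose(v.sum(axis=1), 1.0)

    def test_empty_selection_falls_back_to_all_types(self, stage_data):
        Y, N, mu, theta_mle, alpha, sigma2, q = stage_data
        sel = [np.array([], dtype=int)] + [np.array([0, 1])] * 3
        th, _ = glrm.stage2_smooth(Y, N, mu, sigma2, alpha, sel,
                                   np.zeros((4, 4)), 0.0, max_iter=20,
                                   theta_init=theta_mle)
        assert np.isclose(th.to_numpy()[0].sum(), 1.0)


class TestCrossValidate:
    def test_single_candidate_returned(self, stage_data):
        Y, N, mu, theta_mle, alpha, sigma2, q = stage_data
        L = np.zeros((4, 4))
        lr, ll, table = glrm.cross_validate(Y, N, mu, L, sigma2, alpha, q,
                                            theta_mle, [2.5], [7.0],
                                            n_folds=3, seed=0, admm_iter=10)
        assert (lr, ll) == (2.5, 7.0)
        assert len(table) == 1

    def test_seeded_fold_determinism(self, stage_data):
        Y, N, mu, theta_mle, alpha, sigma2, q = stage_data
        L = np.zeros((4, 4))
        args = (Y, N, mu, L, sigma2, alpha, q, theta_mle, [0.5, 5.0], [1.0])
        a = glrm.cross_validate(*args, n_folds=3, seed=9, admm_iter=10)
        b = glrm.cross_validate(*args, n_folds=3, seed=9, admm_iter=10)
        assert a[:2] == b[:2]
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_empty_grid_rejected(self, stage_data):
        Y, N, mu, theta_mle, alpha, sigma2, q = stage_data
        with pytest.raises(ValueError):
            glrm.cross_validate(Y, N, mu, np.zeros((4, 4)), sigma2, alpha, q,
                                theta_mle, [], [1.0])
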