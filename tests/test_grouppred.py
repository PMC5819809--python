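import numpy as np
import pytest

import netpred as nps
from netpred.grouppred import (_group_lasso_path, _group_index,
                               _standardize, _sgl_path,
                               group_lasso_lambda_max, sgl_lambda_max)
from netpred.modules import ModulePartition
from netpred.network import WeightedNetwork

from conftest import fista, group_prox


def _part(labels):
    return ModulePartition.from_labels(labels)


class TestSelectHubs:
    def test_star_center_is_hub(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 0.5
        net = WeightedNetwork(W, "wgcna")
        hubs = nps.select_hubs(net, _part(np.ones(5, dtype=int)))
        assert hubs.hubs == {1: [0]}

    def test_ties_all_kept(self):
        # nodes 0 and 1 each have three within-module edges
        W = np.zeros((5, 5))
        for i, j in [(0, 2), (0, 3), (0, 1), (1, 4), (1, 2)]:
            W[i, j] = W[j, i] = 0.4
        net = WeightedNetwork(W, "wgcna")
        hubs = nps.select_hubs(net, _part(np.ones(5, dtype=int)))
        assert hubs.hubs == {1: [0, 1]}

    def test_generative_hub_recovered_at_large_n(self):
        scn = nps.SimScenario(n_samples=1000, n_features=80, n_modules=4,
                              seed=21)
        X, _, truth = nps.simulate_dataset(scn)
        # sparsified correlation network keeps only strong edges, so
        # within-module degree discriminates the generative hub
        C = np.abs(np.corrcoef(X, rowvar=False))
        np.fill_diagonal(C, 0.0)
        # keep only hub-spoke strength edges (rho=0.9) and drop the
        # spoke-spoke ones (rho^2=0.81): the generative hub dominates
        W = np.where(C > 0.85, C, 0.0)
        net = WeightedNetwork(W, "wgcna")
        hubs = nps.select_hubs(net, _part(truth.module_labels))
        assert hubs.hubs[1] == [0]   # first feature of module 1 is its hub

    def test_empty_partition_rejected(self):
        net = WeightedNetwork(np.zeros((3, 3)), "wgcna")
        with pytest.raises(ValueError):
            nps.select_hubs(net, _part(np.array([], dtype=int)))


class TestGroupLasso:
    def test_singleton_groups_equal_lasso(self, small_regression):
        X, y, _ = small_regression
        singletons = _part(np.arange(1, 9))
        lam = 5.0
        m_grp = nps.fit_group_lasso(X, y, singletons, lambda_grid=[lam])
        m_lasso = nps.fit_baseline(X, y, "lasso", lambda_grid=[lam])
        assert np.abs(m_grp.coef - m_lasso.coef).max() <= 1e-6

    def test_lambda_max_zeroes_everything(self, small_regression):
        X, y, labels = small_regression
        Xs, yc, *_ = _standardize(X, y)
        groups = _group_index(labels, 8)
        lmax = group_lasso_lambda_max(Xs, yc, groups)
        m = nps.fit_group_lasso(X, y, _part(labels),
                                lambda_grid=[lmax * 1.001])
        assert np.all(m.coef == 0)
        m2 = nps.fit_group_lasso(X, y, _part(labels),
                                 lambda_grid=[lmax * 0.99])
        assert np.any(m2.coef != 0)

    def test_objective_matches_fista_oracle(self, small_regression):
        X, y, labels = small_regression
        Xs, yc, *_ = _standardize(X, y)
        lam = 4.0
        groups = _group_index(labels, 8)
        betas, _ = _group_lasso_path(Xs, yc, groups, [lam])
        b_ref = fista(Xs, yc, group_prox(labels, lam, alpha=0.0),
                      np.linalg.norm(Xs, 2) ** 2)

        def obj(b):
            pen = sum(np.sqrt((labels == l).sum())
                      * np.linalg.norm(b[labels == l])
                      for l in np.unique(labels))
            return ((yc - Xs @ b) ** 2).sum() + lam * pen

        assert obj(betas[:, 0]) <= obj(b_ref) + 1e-6

    def test_kkt_residual_small(self, small_regression):
        X, y, labels = small_regression
        m = nps.fit_group_lasso(X, y, _part(labels))
        Xs, yc, *_ = _standardize(X, y)
        assert nps.kkt_residual(Xs, yc, m.coef, labels, m.lam,
                                kind="grplasso") <= 1e-5


class TestSparseGroupLasso:
    @pytest.mark.parametrize("alpha,equiv", [(0.0, "grplasso"),
                                             (1.0, "lasso")])
    def test_boundary_alphas_reduce_to_known_models(self, small_regression,
                                                    alpha, equiv):
        X, y, labels = small_regression
        lam = 3.0
        m = nps.fit_sparse_group_lasso(X, y, _part(labels),
                                       lambda_grid=[lam], alpha=alpha)
        if equiv == "grplasso":
            ref = nps.fit_group_lasso(X, y, _part(labels), lambda_grid=[lam])
        else:
            ref = nps.fit_baseline(X, y, "lasso", lambda_grid=[lam])
        assert np.abs(m.coef - ref.coef).max() <= 1e-6

    def test_objective_matches_fista_oracle(self, small_regression):
        X, y, labels = small_regression
        Xs, yc, *_ = _standardize(X, y)
        lam, alpha = 4.0, 0.5
        groups = _group_index(labels, 8)
        betas, _ = _sgl_path(Xs, yc, groups, [lam], alpha)
        b_ref = fista(Xs, yc, group_prox(labels, lam, alpha=alpha),
                      np.linalg.norm(Xs, 2) ** 2)

        def obj(b):
            pen_g = sum(np.sqrt((labels == l).sum())
                        * np.linalg.norm(b[labels == l])
                        for l in np.unique(labels))
            return (((yc - Xs @ b) ** 2).sum()
                    + (1 - alpha) * lam * pen_g
                    + alpha * lam * np.abs(b).sum())

        assert obj(betas[:, 0]) <= obj(b_ref) + 1e-6

    def test_lambda_max_and_kkt(self, small_regression):
        X, y, labels = small_regression
        Xs, yc, *_ = _standardize(X, y)
        groups = _group_index(labels, 8)
        lmax = sgl_lambda_max(Xs, yc, groups, 0.5)
        m0 = nps.fit_sparse_group_lasso(X, y, _part(labels),
                                        lambda_grid=[lmax * 1.001],
                                        alpha=0.5)
        assert np.all(m0.coef == 0)
        m = nps.fit_sparse_group_lasso(X, y, _part(labels), alpha=0.5)
        assert nps.kkt_residual(Xs, yc, m.coef, labels, m.lam, alpha=0.5,
                                kind="sgl") <= 1e-5


class TestAdaptiveGroupRidge:
    def test_unit_multipliers_reproduce_ridge_exactly(self,
                                                      small_regression):
        X, y, labels = small_regression
        grid = [0.5, 5.0, 50.0]
        m = nps.fit_adaptive_group_ridge(X, y, _part(labels),
                                         lambda_grid=grid, max_iter=0)
        r = nps.fit_baseline(X, y, "ridge", lambda_grid=grid)
        assert m.lam == r.lam
        assert np.allclose(m.coef, r.coef, atol=1e-12)

    def test_orthonormal_single_group_closed_form(self):
        rng = np.random.default_rng(8)
        Q, _ = np.linalg.qr(rng.standard_normal((50, 4)))
        Xs = Q  # orthonormal columns
        beta = np.array([1.0, -2.0, 0.5, 0.0])
        yc = Xs @ beta
        from netpred.grouppred import _agr_solve
        lam = 3.0
        b = _agr_solve(Xs, yc, np.full(4, lam))
        assert np.allclose(b, (Xs.T @ yc) / (1 + lam), atol=1e-10)

    def test_noise_group_gets_larger_multiplier(self):
        # simulation oracle: two groups, one carries all the signal
        rng = np.random.default_rng(9)
        X = rng.standard_normal((500, 20))
        beta = np.zeros(20)
        beta[:10] = 1.0
        y = X @ beta + rng.normal(0, 1.0, 500)
        labels = np.repeat([1, 2], 10)
        m = nps.fit_adaptive_group_ridge(X, y, _part(labels), seed=2)
        assert m.params["multipliers"][2] > m.params["multipliers"][1]
        assert m.group_lambdas[2] > m.group_lambdas[1]

    def test_dual_solve_matches_primal(self):
        rng = np.random.default_rng(10)
        Xs = rng.standard_normal((15, 40))  # p > n triggers the dual path
        yc = rng.standard_normal(15)
        from netpred.grouppred import _agr_solve
        lam_vec = rng.uniform(0.5, 3.0, 40)
        b_dual = _agr_solve(Xs, yc, lam_vec)
        b_primal = np.linalg.solve(Xs.T @ Xs + np.diag(lam_vec), Xs.T @ yc)
        assert np.allclose(b_dual, b_primal, atol=1e-8)


class TestBaselinesAndPredict:
    def test_lasso_lambda_max_zeroes(self, small_regression):
        X, y, _ = small_regression
        Xs, yc, *_ = _standardize(X, y)
        lmax = 2 * np.abs(Xs.T @ yc).max()
        m = nps.fit_baseline(X, y, "lasso", lambda_grid=[lmax * 1.01])
        assert np.all(m.coef == 0)
        assert m.intercept == pytest.approx(y.mean())

    def test_enet_objective_matches_fista_oracle(self, small_regression):
        X, y, _ = small_regression
        Xs, yc, *_ = _standardize(X, y)
        n = Xs.shape[0]
        lam, alpha = 8.0, 0.5
        m = nps.fit_baseline(X, y, "enet", lambda_grid=[lam], alpha=alpha)
        # sklearn convention: (1/2n)||y-Xb||^2 + a*(alpha||b||1
        #                     + (1-alpha)/2 ||b||^2), a = lam/(2n)
        a = lam / (2 * n)

        def prox(v, step):
            u = np.sign(v) * np.maximum(np.abs(v) - step * lam * alpha, 0.0)
            return u / (1.0 + step * lam * (1 - alpha))

        b_ref = fista(Xs, yc, prox, np.linalg.norm(Xs, 2) ** 2)

        def obj(b):
            return (((yc - Xs @ b) ** 2).sum() / (2 * n)
                    + a * (alpha * np.abs(b).sum()
                           + (1 - alpha) / 2 * (b ** 2).sum()))

        assert obj(m.coef) <= obj(b_ref) + 1e-6

    def test_lasso_kkt_residual(self, small_regression):
        X, y, _ = small_regression
        m = nps.fit_baseline(X, y, "lasso")
        Xs, yc, *_ = _standardize(X, y)
        assert nps.kkt_residual(Xs, yc, m.coef, None, m.lam,
                                kind="lasso") <= 1e-5

    def test_predict_reproduces_ols_at_tiny_penalty(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((200, 5))
        y = X @ np.array([1.0, 2.0, -1.0, 0.0, 0.5]) + rng.normal(0, 0.1,
                                                                  200)
        m = nps.fit_baseline(X, y, "ridge", lambda_grid=[1e-10])
        Xs, yc, *_ = _standardize(X, y)
        ols = np.linalg.lstsq(Xs, yc, rcond=None)[0]
        assert np.allclose(m.coef, ols, atol=1e-6)
        assert np.allclose(nps.predict(m, X), y.mean() + Xs @ m.coef)

    def test_predict_validates_columns(self, small_regression):
        X, y, labels = small_regression
        m = nps.fit_baseline(X, y, "ridge")
        with pytest.raises(ValueError):
            nps.predict(m, X[:, :5])

    def test_hub_ridge_single_hub_matches_ols_slope(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((100, 6))
        y = 2.0 * X[:, 3] + rng.normal(0, 0.1, 100)
        hubs = nps.HubSet(hubs={1: [3]})
        m = nps.fit_hub_ridge(X, y, hubs, lambda_grid=[1e-10])
        Xs, yc, *_ = _standardize(X, y)
        slope = (Xs[:, 3] @ yc) / (Xs[:, 3] @ Xs[:, 3])
        assert m.coef[3] == pytest.approx(slope, abs=1e-6)
        assert np.all(m.coef[[0, 1, 2, 4, 5]] == 0)

    def test_hub_ridge_infinite_penalty_flattens(self, small_regression):
        X, y, _ = small_regression
        m = nps.fit_hub_ridge(X, y, nps.HubSet(hubs={1: [0, 1]}),
                              lambda_grid=[1e12])
        assert np.abs(m.coef).max() < 1e-6
        assert m.intercept == pytest.approx(y.mean())


class TestPermutationInvariance:
    def test_group_lasso_fit_permutes_with_features(self, small_regression):
        X, y, labels = small_regression
        rng = np.random.default_rng(13)
        perm = rng.permutation(8)
        m1 = nps.fit_group_lasso(X, y, _part(labels), lambda_grid=[3.0])
        m2 = nps.fit_group_lasso(X[:, perm], y, _part(labels[perm]),
                                 lambda_grid=[3.0])
        assert np.allclose(m1.coef[perm], m2.coef, atol=1e-8)
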