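import numpy as np
import pytest

from spikenets.glm import (
    build_functional_network,
    convolve_inputs,
    design_matrix,
    fit_sparse_glm,
    kernels_from_coefficients,
    laguerre_basis,
    reconstruct_network,
)
from spikenets.io import AnalysisConfig, SpikeTrainSet
from spikenets.synthetic import make_ground_truth, simulate_spike_trains


class TestLaguerreBasis:
    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.8])
    def test_rows_orthonormal(self, alpha):
        b = laguerre_basis(alpha, 4, 300).values
        gram = b @ b.T
        assert np.abs(gram - np.eye(4)).max() < 1e-6

    def test_smaller_alpha_decays_faster(self):
        def last_big_lag(values):
            return max(np.flatnonzero(np.abs(v) >= 1e-3).max() for v in values)

        slow = laguerre_basis(0.8, 3, 200).values
        fast = laguerre_basis(0.2, 3, 200).values
        assert last_big_lag(fast) < last_big_lag(slow)

    def test_single_order_is_normalized_geometric(self):
        b = laguerre_basis(0.5, 1, 200)
        v = b.values[0]
        ratios = v[1:] / v[:-1]
        np.testing.assert_allclose(ratios, np.sqrt(0.5), atol=1e-12)
        assert abs(np.sum(v**2) - 1.0) < 1e-12

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.3, 1.5])
    def test_alpha_out_of_range_rejected(self, alpha):
        with pytest.raises(ValueError):
            laguerre_basis(alpha, 3, 50)


class TestConvolution:
    def test_delta_input_reproduces_basis(self):
        basis = laguerre_basis(0.5, 3, 20)
        x = np.zeros((1, 100), dtype=np.uint8)
        t0 = 30
        x[0, t0] = 1
        v = convolve_inputs(x, basis)
        for j in range(3):
            col = v[:, j]
            assert np.all(col[:t0] == 0)
            np.testing.assert_allclose(col[t0 : t0 + 20], basis.values[j])

    def test_zero_input_gives_zero_columns(self):
        basis = laguerre_basis(0.5, 2, 10)
        v = convolve_inputs(np.zeros((3, 50), dtype=np.uint8), basis)
        assert np.all(v == 0)

    def test_matches_brute_force_double_loop(self, rng):
        basis = laguerre_basis(0.4, 3, 15)
        x = (rng.random((2, 80)) < 0.2).astype(np.uint8)
        v = convolve_inputs(x, basis)
        for n in range(2):
            for j in range(3):
                expected = np.zeros(80)
                for t in range(80):
                    for tau in range(15):
                        if t - tau >= 0:
                            expected[t] += basis.values[j, tau] * x[n, t - tau]
                np.testing.assert_allclose(v[:, n * 3 + j], expected, atol=1e-12)

    def test_design_lag_shifts_columns(self, rng):
        basis = laguerre_basis(0.5, 2, 10)
        x = (rng.random((1, 60)) < 0.3).astype(np.uint8)
        v = convolve_inputs(x, basis)
        d = design_matrix(x, basis, lag=1)
        assert np.all(d[0] == 0)
        np.testing.assert_allclose(d[1:], v[:-1])


class TestKernels:
    def test_unit_coefficient_recovers_basis_row(self):
        basis = laguerre_basis(0.5, 3, 40)
        coef = np.zeros((1, 3))
        coef[0, 1] = 1.0
        np.testing.assert_allclose(
            kernels_from_coefficients(coef, basis)[0], basis.values[1]
        )

    def test_random_coefficients_match_matrix_product(self, rng):
        basis = laguerre_basis(0.6, 4, 30)
        coef = rng.normal(size=(5, 4))
        np.testing.assert_allclose(
            kernels_from_coefficients(coef, basis), coef @ basis.values
        )


class TestSparseGlm:
    def test_independent_target_is_mostly_zero(self, rng):
        basis = laguerre_basis(0.5, 3, 30)
        x = (rng.random((5, 5000)) < 0.05).astype(np.uint8)
        design = design_matrix(x, basis, lag=1)
        target = (rng.random(5000) < 0.05).astype(float)
        m = fit_sparse_glm(design, target, basis=basis)
        assert np.mean(m.coef == 0) >= 0.9

    def test_planted_single_input_recovered(self, rng):
        basis = laguerre_basis(0.5, 3, 30)
        hits = 0
        for trial in range(20):
            trng = np.random.default_rng(500 + trial)
            x = (trng.random((5, 4000)) < 0.1).astype(np.uint8)
            v = convolve_inputs(x, basis)
            target = 0.8 * v[:, 3 * 3 + 0] + trng.normal(0, 0.1, 4000)
            m = fit_sparse_glm(v, target, basis=basis)
            groups = m.input_groups_nonzero()
            if groups[3] and not np.any(groups[[0, 1, 2, 4]]):
                hits += 1
        assert hits >= 19  # >= 95% of runs

    def test_huge_penalty_saturates_to_intercept(self, rng):
        basis = laguerre_basis(0.5, 2, 20)
        x = (rng.random((3, 2000)) < 0.1).astype(np.uint8)
        design = design_matrix(x, basis, lag=1)
        target = rng.normal(0.5, 0.2, 2000)
        m = fit_sparse_glm(design, target, zeta_grid=[1e6], basis=basis,
                           prune_alpha=None)
        assert np.all(m.coef == 0)
        assert abs(m.intercept - target.mean()) < 1e-9

    def test_degenerate_design_warns_and_zeroes(self):
        basis = laguerre_basis(0.5, 2, 10)
        with pytest.warns(UserWarning, match="degenerate"):
            m = fit_sparse_glm(np.zeros((100, 4)), np.ones(100), basis=basis)
        assert np.all(m.coef == 0)
        assert m.intercept == 1.0

    def test_selected_deviance_is_grid_minimum(self, rng):
        basis = laguerre_basis(0.5, 3, 30)
        x = (rng.random((4, 3000)) < 0.08).astype(np.uint8)
        design = design_matrix(x, basis, lag=1)
        target = x[0].astype(float)
        m = fit_sparse_glm(design, target, basis=basis, selection="min")
        chosen = m.cv_deviance[np.flatnonzero(m.zeta_grid == m.zeta)[0]]
        assert chosen <= m.cv_deviance.min() + 1e-12

    def test_sparsity_nonincreasing_in_penalty(self, rng):
        from sklearn.linear_model import lasso_path

        basis = laguerre_basis(0.5, 3, 30)
        x = (rng.random((5, 3000)) < 0.1).astype(np.uint8)
        design = design_matrix(x, basis, lag=1)
        target = design[:, 0] * 0.5 + rng.normal(0, 0.2, 3000)
        zetas = np.logspace(-5, -1, 20)[::-1]
        _, coefs, _ = lasso_path(design - design.mean(0), target - target.mean(),
                                 alphas=zetas)
        counts = (coefs != 0).sum(axis=0)  # along decreasing penalty
        assert np.all(np.diff(counts) >= 0)

    def test_prediction_routes_agree(self, rng):
        # intensity from expanded kernels == intercept + design @ coefficients
        basis = laguerre_basis(0.5, 3, 30)
        x = (rng.random((4, 2000)) < 0.1).astype(np.uint8)
        design = design_matrix(x, basis, lag=1)
        m = fit_sparse_glm(design, x[1].astype(float), basis=basis)
        pred_design = m.predict(design)
        kern = m.kernels()  # (4, 30)
        t = x.shape[1]
        pred_kernel = np.full(t, m.intercept)
        xf = x.astype(float)
        for n in range(4):
            conv = np.convolve(xf[n], kern[n])[:t]
            pred_kernel[1:] += conv[:-1]
        np.testing.assert_allclose(pred_design, pred_kernel, atol=1e-10)


class TestFunctionalNetwork:
    def test_all_zero_models_give_empty_network(self, rng):
        basis = laguerre_basis(0.5, 2, 10)
        x = np.zeros((3, 500), dtype=np.uint8)
        models = []
        with pytest.warns(UserWarning):
            for i in range(3):
                models.append(
                    fit_sparse_glm(design_matrix(x, basis), x[i].astype(float),
                                   basis=basis, output_index=i)
                )
        net = build_functional_network(models)
        assert net.number_of_nodes() == 0

    def test_no_self_loops_ever(self, rng):
        gt = make_ground_truth(6, 0.4, kernel_scale=0.12, seed=3, duration=50.0)
        sts = simulate_spike_trains(gt, seed=30)
        cfg = AnalysisConfig(alpha_grid=(0.5,))
        _, net = reconstruct_network(sts, cfg)
        assert all(u != v for u, v in net.edges)

    def test_planted_chain_recovered(self):
        basis = laguerre_basis(0.5, 3, 50)
        good = 0
        for trial in range(20):
            coef = np.zeros((3, 3, 3))
            coef[1, 0, 0] = 0.15  # a -> b
            coef[2, 1, 0] = 0.15  # b -> c
            gt = make_ground_truth(3, 0.0, seed=trial, duration=100.0)
            gt.coefficients = coef
            gt.graph.add_edges_from([("n0", "n1"), ("n1", "n2")])
            sts = simulate_spike_trains(gt, seed=900 + trial)
            cfg = AnalysisConfig(alpha_grid=(0.5,))
            _, net = reconstruct_network(sts, cfg)
            edges = set(net.edges)
            if {("n0", "n1"), ("n1", "n2")} <= edges and len(edges) <= 3:
                good += 1
        assert good >= 18  # >= 90% of trials
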