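import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

from spikenets.simulate import (
    DEFAULT_SPACE,
    ElectrodeArray,
    calibrate_sampling_radius,
    calibrate_threshold,
    connect_model1,
    connect_model2,
    connect_threshold,
    connection_prob_model1,
    connection_prob_model2,
    fit_pattern_ga,
    place_electrodes,
    place_neurons,
    sample_network,
)


class TestPlacement:
    def test_deterministic_under_seed(self):
        a = place_neurons(500, (1.0, 1.0, 1.0), seed=7)
        b = place_neurons(500, (1.0, 1.0, 1.0), seed=7)
        np.testing.assert_array_equal(a, b)

    def test_positions_inside_cuboid(self):
        pos = place_neurons(200, DEFAULT_SPACE, seed=1)
        assert np.all(pos >= 0)
        assert np.all(pos <= np.asarray(DEFAULT_SPACE))

    def test_axis_means_near_midpoint(self):
        n = 4000
        pos = place_neurons(n, (100.0, 200.0, 50.0), seed=3)
        mid = np.array([50.0, 100.0, 25.0])
        se = np.array([100.0, 200.0, 50.0]) / np.sqrt(12 * n)
        assert np.all(np.abs(pos.mean(axis=0) - mid) < 3 * se)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            place_neurons(1, DEFAULT_SPACE)
        with pytest.raises(ValueError):
            place_neurons(10, (0.0, 1.0, 1.0))


class TestThresholdModel:
    def test_probability_one_gives_complete_graph(self):
        pos = place_neurons(30, seed=0)
        net = connect_threshold(pos, 10.0, 1.0, 1.0, seed=1)
        assert net.n_edges == 30 * 29 // 2

    def test_probability_zero_gives_empty_graph(self):
        pos = place_neurons(30, seed=0)
        net = connect_threshold(pos, 10.0, 0.0, 0.0, seed=1)
        assert net.n_edges == 0

    def test_adjacency_symmetric_no_self(self):
        pos = place_neurons(50, seed=2)
        net = connect_threshold(pos, 100.0, 0.5, 0.05, seed=3)
        assert np.array_equal(net.adjacency, net.adjacency.T)
        assert not np.any(np.diag(net.adjacency))

    def test_calibrated_density_hits_target(self):
        dens = []
        for seed in range(20):
            pos = place_neurons(500, seed=seed)
            l = calibrate_threshold(pos, 0.25, 0.05, 0.0832)
            dens.append(connect_threshold(pos, l, 0.25, 0.05, seed=seed + 100).edge_density)
        assert abs(np.mean(dens) - 0.0832) < 0.005

    def test_conditional_probabilities_recovered(self):
        pos = place_neurons(400, seed=5)
        l = float(np.quantile(pdist(pos), 0.2))
        net = connect_threshold(pos, l, 0.6, 0.1, seed=6)
        d = pdist(pos)
        from scipy.spatial.distance import squareform

        a = squareform(net.adjacency.astype(float))
        near = d <= l
        p_near, p_far = a[near].mean(), a[~near].mean()
        se_near = np.sqrt(0.6 * 0.4 / near.sum())
        se_far = np.sqrt(0.1 * 0.9 / (~near).sum())
        assert abs(p_near - 0.6) < 4 * se_near
        assert abs(p_far - 0.1) < 4 * se_far

    def test_infeasible_calibration_rejected(self):
        pos = place_neurons(50, seed=1)
        with pytest.raises(ValueError):
            calibrate_threshold(pos, 0.25, 0.05, 0.5)


class TestParametricModels:
    d = np.linspace(0.0, 500.0, 60)

    def test_model1_initial_state_is_alpha(self):
        assert connection_prob_model1(0.0, 0.8, 0.5) == pytest.approx(0.8)

    def test_model1_monotone_in_lambda(self):
        lo = connection_prob_model1(self.d[1:], 0.8, 0.1)
        hi = connection_prob_model1(self.d[1:], 0.8, 0.9)
        assert np.all(hi > lo)

    def test_model1_vanishes_at_long_range(self):
        assert connection_prob_model1(1e6, 0.8, 0.5) < 1e-12

    def test_model2_initial_state_is_gamma(self):
        assert connection_prob_model2(0.0, 1.0, 0.7) == pytest.approx(0.7)

    def test_model2_stays_above_asymptote(self):
        p = connection_prob_model2(self.d, 2.0, 0.5, p1=0.02)
        assert np.all(p > 0.02)

    def test_model2_monotone_in_beta(self):
        lo = connection_prob_model2(self.d[1:], 5.0, 0.9)
        hi = connection_prob_model2(self.d[1:], 0.5, 0.9)
        assert np.all(hi > lo)

    @pytest.mark.parametrize("model", [connection_prob_model1, connection_prob_model2])
    def test_monotone_nonincreasing_and_bounded(self, model):
        p = (model(self.d, 0.9, 0.5) if model is connection_prob_model1
             else model(self.d, 1.5, 0.9))
        assert np.all(np.diff(p) <= 1e-15)
        assert np.all((p >= 0) & (p <= 1))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            connection_prob_model1(10.0, 0.5, 1.5)
        with pytest.raises(ValueError):
            connection_prob_model2(10.0, -1.0, 0.5)

    def test_model2_tail_heavier_than_model1(self):
        # same initial state; the hyperbolic tail dominates at long range
        far = 400.0
        p1 = connection_prob_model1(far, 0.9, 0.5)
        p2 = connection_prob_model2(far, 1.0, 0.9)
        assert p2 > p1

    def test_graph_constructors_run(self):
        pos = place_neurons(60, seed=8)
        m1 = connect_model1(pos, 0.9, 0.5, seed=9)
        m2 = connect_model2(pos, 1.0, 0.9, seed=9)
        for net in (m1, m2):
            assert np.array_equal(net.adjacency, net.adjacency.T)


class TestElectrodeSampling:
    def test_huge_radius_samples_everything(self):
        pos = place_neurons(100, seed=0)
        net = connect_threshold(pos, 100.0, 0.3, 0.05, seed=1)
        arr = place_electrodes(6, seed=2, radius=1e6)
        sub, idx = sample_network(net, arr)
        assert idx.size == 100
        np.testing.assert_array_equal(sub, net.adjacency)

    def test_tiny_radius_flags_empty_sample(self):
        pos = place_neurons(100, seed=0)
        net = connect_threshold(pos, 100.0, 0.3, 0.05, seed=1)
        arr = ElectrodeArray(positions=np.array([[-1e5, -1e5, -1e5]]), radius=1.0)
        with pytest.raises(ValueError, match="no neuron"):
            sample_network(net, arr)

    def test_induced_subgraph_matches_pair_scan(self):
        pos = place_neurons(200, seed=3)
        net = connect_threshold(pos, 150.0, 0.4, 0.05, seed=4)
        arr = place_electrodes(6, seed=5, radius=60.0)
        sub, idx = sample_network(net, arr)
        sampled = set(idx)
        for a, i in enumerate(idx):
            for b, j in enumerate(idx):
                assert sub[a, b] == net.adjacency[i, j]
        # nothing outside the radius got in
        d = cdist(pos, arr.positions).min(axis=1)
        assert np.all(d[idx] <= arr.radius)
        assert np.all(d[np.setdiff1d(np.arange(200), idx)] > arr.radius)

    def test_radius_calibration_hits_target_count(self):
        pos = place_neurons(300, seed=6)
        arr = place_electrodes(6, seed=7)
        r = calibrate_sampling_radius(pos, arr.positions, 60)
        d = cdist(pos, arr.positions).min(axis=1)
        assert (d <= r).sum() == 60


class TestPatternGa:
    def test_self_recovery_of_simulated_pattern(self):
        # fit to the pattern of an actual threshold graph: the GA should
        # drive the objective to ~0
        from spikenets.metrics import (
            average_clustering_dense,
            average_path_length_dense,
        )

        rng = np.random.default_rng(0)
        pos = place_neurons(40, seed=1)
        l = float(np.quantile(pdist(pos), 0.3))
        net = connect_threshold(pos, l, 0.8, 0.2, seed=2)
        target_l = average_path_length_dense(net.adjacency)
        target_c = average_clustering_dense(net.adjacency)
        fit = fit_pattern_ga(target_l, target_c, 40, generations=25, pop=24, seed=3)
        assert fit.objective < 1e-3

    def test_complete_limit(self):
        fit = fit_pattern_ga(1.0, 1.0, 25, generations=20, pop=20, seed=4)
        assert fit.achieved_C > 0.9

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            fit_pattern_ga(1.5, 1.5, 40)
        with pytest.raises(ValueError):
            fit_pattern_ga(0.5, 0.5, 40)

    def test_constraint_pin_ge_pout(self):
        fit = fit_pattern_ga(1.4, 0.6, 30, generations=10, pop=16, seed=5)
        assert fit.p_in >= fit.p_out
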