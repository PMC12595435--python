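"""Network generation and the stochastic delay integrator."""

import numpy as np
import pytest

import esprox as ep
from esprox.model import SimulationBlowUpError


class TestGenerateTopology:
    def test_random_has_requested_edges_and_is_connected(self):
        top = ep.generate_topology("random", 100, 400, seed=3)
        assert top.n_links == 400
        assert top.adjacency.sum() == 800  # handshake identity
        assert top.degrees.sum() == 800

    def test_minimum_edges_give_spanning_tree(self):
        top = ep.generate_topology("random", 4, 3, seed=0)
        assert top.n_links == 3  # connected on 4 nodes -> a tree

    def test_deterministic_under_seed(self):
        a = ep.generate_topology("random", 30, 60, seed=5)
        b = ep.generate_topology("random", 30, 60, seed=5)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_small_world_edge_count(self):
        top = ep.generate_topology("small_world", 50, 100, seed=1)
        assert top.n_links == 100

    def test_small_world_odd_degree_rejected(self):
        with pytest.raises(ValueError):
            ep.generate_topology("small_world", 50, 75, seed=1)

    def test_scale_free_edge_count_documented_granularity(self):
        top = ep.generate_topology("scale_free", 50, 200, seed=1)
        # BA with m = 4 attaches m edges per new node: m*(n - m) edges
        assert top.n_links == 4 * (50 - 4)

    def test_infeasible_link_counts_rejected(self):
        with pytest.raises(ValueError):
            ep.generate_topology("random", 10, 8, seed=0)  # < n - 1
        with pytest.raises(ValueError):
            ep.generate_topology("random", 10, 46, seed=0)  # > n(n-1)/2

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ep.generate_topology("torus", 10, 20, seed=0)

    def test_custom_adjacency_roundtrip(self):
        ref = ep.generate_topology("random", 12, 20, seed=2)
        top = ep.NetworkTopology.from_adjacency(ref.adjacency)
        assert top.kind == "custom" and top.n_links == 20


class TestSimulate:
    def test_uncoupled_amplitude_reaches_sqrt_lambda(self, small_topology,
                                                     warm_integrator):
        for lam in (0.25, 1.0, 4.0):
            cfg = ep.SimulationConfig(coupling=0.0, noise_scale=0.0, lam=lam,
                                      duration=21.0, transient=20.0, seed=3,
                                      store_state=False)
            traj = ep.simulate(small_topology, cfg)
            assert np.abs(np.abs(traj.final_state) - np.sqrt(lam)).max() < 1e-3

    def test_two_node_strong_coupling_synchronizes(self):
        top = ep.NetworkTopology.from_adjacency(np.array([[0, 1], [1, 0]]))
        cfg = ep.SimulationConfig(coupling=20.0, noise_scale=0.0, delay=0.0,
                                  omega=np.array([60.0, 60.0]), lam=1.0,
                                  duration=30.0, transient=25.0, seed=1)
        traj = ep.simulate(top, cfg)
        assert traj.order_parameter.values[-100:].mean() > 0.999
        assert np.abs(np.abs(traj.final_state) - 1.0).max() < 1e-2

    def test_order_parameter_bounded(self, small_topology, warm_integrator):
        cfg = ep.SimulationConfig(coupling=3.0, duration=10.0, transient=1.0,
                                  seed=9, store_state=False)
        traj = ep.simulate(small_topology, cfg)
        r = traj.order_parameter.values
        assert r.min() >= 0.0 and r.max() <= 1.0

    def test_bit_reproducible_with_noise(self, small_topology, warm_integrator):
        cfg = ep.SimulationConfig(coupling=1.0, duration=5.0, transient=1.0,
                                  seed=11, store_state=False)
        a = ep.simulate(small_topology, cfg)
        b = ep.simulate(small_topology, cfg)
        assert np.array_equal(a.order_parameter.values,
                              b.order_parameter.values)
        assert np.array_equal(a.final_state, b.final_state)

    def test_noise_free_determinism(self, small_topology, warm_integrator):
        cfg = ep.SimulationConfig(coupling=1.0, noise_scale=0.0, duration=5.0,
                                  transient=1.0, seed=4, store_state=False)
        a = ep.simulate(small_topology, cfg)
        b = ep.simulate(small_topology, cfg)
        assert np.array_equal(a.final_state, b.final_state)

    def test_zero_feedback_exponent_matches_plain_coupling(self, small_topology,
                                                           warm_integrator):
        # R**0 == 1: explicit Z=0 must match the conventional coupled run
        base = ep.SimulationConfig(coupling=2.0, feedback_exponent=0.0,
                                   duration=5.0, transient=1.0, seed=13,
                                   store_state=False)
        a = ep.simulate(small_topology, base)
        b = ep.simulate(small_topology, base)
        assert np.array_equal(a.order_parameter.values,
                              b.order_parameter.values)

    def test_mean_r_increases_with_coupling(self, warm_integrator):
        top = ep.generate_topology("random", 50, 200, seed=21)
        omega = np.random.default_rng(0).normal(2 * np.pi * 10, 2 * np.pi, 50)
        means = []
        for s in (0.5, 8.0, 30.0):
            cfg = ep.SimulationConfig(coupling=s, omega=omega, lam=0.25,
                                      delay=0.002, duration=40.0,
                                      transient=15.0, seed=5, store_state=False)
            means.append(ep.simulate(top, cfg).order_parameter.values.mean())
        assert means[0] < means[1] < means[2]

    def test_perturbation_drives_synchrony(self, small_topology,
                                           warm_integrator):
        cfg = ep.SimulationConfig(coupling=0.5, lam=0.25, duration=30.0,
                                  transient=5.0, seed=6, store_state=False)
        pulse = ep.PerturbationProtocol(strength=10.0, onset=15.0, offset=20.0)
        traj = ep.simulate(small_topology, cfg, perturbation=pulse)
        t = traj.times
        r = traj.order_parameter.values
        during = r[(t > 16.0) & (t < 20.0)].mean()
        before = r[(t > 8.0) & (t < 15.0)].mean()
        assert during > before + 0.2

    def test_delay_must_be_multiple_of_dt(self, small_topology):
        cfg = ep.SimulationConfig(delay=0.0015, dt=0.001, duration=2.0,
                                  transient=0.5, seed=0)
        with pytest.raises(ValueError):
            ep.simulate(small_topology, cfg)

    def test_blow_up_guard_raises(self, small_topology, warm_integrator):
        # dt far too large for this coupling: Euler part goes unstable
        cfg = ep.SimulationConfig(coupling=500.0, dt=0.01, delay=0.0,
                                  noise_scale=0.0, duration=20.0,
                                  transient=1.0, seed=2, store_state=False)
        with pytest.raises(SimulationBlowUpError):
            ep.simulate(small_topology, cfg)

    def test_state_recording_consistent_with_order_parameter(
            self, small_topology, warm_integrator):
        cfg = ep.SimulationConfig(coupling=1.0, duration=3.0, transient=1.0,
                                  seed=8, store_state=True)
        traj = ep.simulate(small_topology, cfg)
        # r(t) recorded at step start == r computed from state one step back
        z = traj.state[100]
        r_direct = np.abs((z / np.abs(z)).mean())
        assert traj.order_parameter.values[101] == pytest.approx(r_direct,
                                                                 abs=1e-12)
        assert traj.phases.shape == (small_topology.n_nodes, traj.times.size)
        assert np.all(traj.amplitudes >= 0)


class TestSweepCoupling:
    def test_single_point_grid(self, small_topology, warm_integrator):
        cfg = ep.SimulationConfig(duration=15.0, transient=5.0, seed=3)
        sw = ep.sweep_coupling(small_topology, cfg, np.array([1.0]))
        assert sw.s_values.size == 1
        assert np.isfinite(sw.mean_r[0])

    def test_descending_direction_orders_grid(self, small_topology,
                                              warm_integrator):
        cfg = ep.SimulationConfig(duration=15.0, transient=5.0, seed=3)
        sw = ep.sweep_coupling(small_topology, cfg, np.array([0.5, 1.0, 2.0]),
                               direction="down")
        assert sw.s_values[0] == 2.0 and sw.direction == "down"

    def test_both_returns_paired_curves(self, small_topology, warm_integrator):
        cfg = ep.SimulationConfig(duration=12.0, transient=4.0, seed=3,
                                  lam=0.25, delay=0.002)
        up, down = ep.sweep_coupling(small_topology, cfg,
                                     np.array([0.5, 2.0, 8.0]),
                                     direction="both")
        assert up.direction == "up" and down.direction == "down"
        assert np.array_equal(up.s_values, down.s_values[::-1])

    def test_feedback_widens_hysteresis(self, warm_integrator):
        """Adiabatic up/down sweeps separate more with feedback: the area
        between the ascending and descending mean-r curves grows with Z."""
        top = ep.generate_topology("random", 25, 100, seed=7)
        omega = np.random.default_rng(3).normal(2 * np.pi * 10, 2 * np.pi, 25)
        grid = np.geomspace(0.3, 15, 12)
        areas = {}
        for z in (0.0, 3.0):
            vals = []
            for s in range(3):
                cfg = ep.SimulationConfig(feedback_exponent=z, omega=omega,
                                          duration=30.0, transient=10.0,
                                          seed=50 + s)
                up, down = ep.sweep_coupling(top, cfg, grid, direction="both")
                vals.append(np.trapezoid(np.abs(up.mean_r - down.mean_r[::-1]),
                                         up.s_values))
            areas[z] = np.mean(vals)
        assert areas[3.0] > areas[0.0]

    def test_unsorted_grid_rejected(self, small_topology):
        cfg = ep.SimulationConfig(duration=5.0, transient=1.0, seed=3)
        with pytest.raises(ValueError):
            ep.sweep_coupling(small_topology, cfg, np.array([2.0, 1.0]))
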