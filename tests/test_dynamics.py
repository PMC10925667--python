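import numpy as np
import pytest

from netspread import (
    BinaryGraph,
    ReactionSpec,
    SimulationConfig,
    diffuse_closed_form,
    integrate,
    laplacian,
    point_seed,
    rd_rhs,
)
from netspread.errors import ConfigurationError, ValidationError

P2 = BinaryGraph(adjacency=np.array([[0, 1], [1, 0]]))
NO_REACTION = ReactionSpec(kind="none")


class TestPointSeed:
    def test_places_mass_at_single_node(self):
        np.testing.assert_array_equal(point_seed(3, 1, 0.1), [0.0, 0.1, 0.0])
        np.testing.assert_array_equal(point_seed(1, 0, 1.0), [1.0])

    def test_total_mass_equals_theta0(self):
        assert point_seed(379, 52, 0.1).sum() == pytest.approx(0.1)

    @pytest.mark.parametrize("i", [-1, 3])
    def test_out_of_range_index(self, i):
        with pytest.raises(ValidationError):
            point_seed(3, i, 0.1)


class TestClosedFormDiffusion:
    def test_identity_at_time_zero(self):
        theta0 = np.array([0.3, 0.7])
        np.testing.assert_array_equal(
            diffuse_closed_form(laplacian(P2), theta0, 1.0, 0.0), theta0
        )

    @pytest.mark.parametrize("t", [0.1, 0.5, 2.0])
    def test_two_node_analytic_solution(self, t):
        """On a single edge the Laplacian has eigenvalues {0, -2}, giving
        theta_1(t) = (1 + e^{-2t})/2 and theta_2(t) = (1 - e^{-2t})/2."""
        got = diffuse_closed_form(laplacian(P2), np.array([1.0, 0.0]), 1.0, t)
        np.testing.assert_allclose(
            got, [(1 + np.exp(-2 * t)) / 2, (1 - np.exp(-2 * t)) / 2], atol=1e-12
        )

    def test_relaxes_to_uniform_on_connected_graph(self, small_fixtures):
        G = small_fixtures["random_20"]
        theta0 = point_seed(20, 3, 0.8)
        final = diffuse_closed_form(laplacian(G), theta0, 1.0, 200.0)
        np.testing.assert_allclose(final, 0.8 / 20, atol=1e-6)

    def test_conserves_total_mass(self, small_fixtures):
        G = small_fixtures["random_20"]
        theta0 = point_seed(20, 0, 1.0)
        final = diffuse_closed_form(laplacian(G), theta0, 1.0, 3.0)
        assert final.sum() == pytest.approx(1.0, rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError, match="mismatch"):
            diffuse_closed_form(laplacian(P2), np.ones(3), 1.0, 1.0)


class TestRhs:
    @pytest.mark.parametrize("kind", ["logistic", "strong_allee", "neutral_allee"])
    def test_uniform_capacity_is_fixed_point(self, small_fixtures, kind):
        G = small_fixtures["random_20"]
        spec = ReactionSpec(kind=kind, theta_c=0.001)
        assert np.max(np.abs(rd_rhs(G, spec, 1.0, np.ones(20)))) == 0.0

    def test_isolated_node_logistic(self):
        G = BinaryGraph(adjacency=np.zeros((1, 1), dtype=int))
        spec = ReactionSpec(kind="logistic", r=1.0)
        assert rd_rhs(G, spec, 1.0, np.array([0.5]))[0] == pytest.approx(0.25)

    def test_pure_flux_along_single_edge(self):
        got = rd_rhs(P2, NO_REACTION, 1.0, np.array([1.0, 0.0]))
        np.testing.assert_allclose(got, [-1.0, 1.0])


class TestIntegrate:
    @pytest.mark.parametrize("method", ["euler", "rk45", "expm"])
    def test_pure_diffusion_conserves_mass(self, small_fixtures, method):
        G = small_fixtures["random_20"]
        cfg = SimulationConfig(
            w=1.0, reaction=NO_REACTION, t_max=5.0, dt=0.5, method=method,
            euler_dt=1e-3,
        )
        traj = integrate(G, NO_REACTION, cfg, point_seed(20, 0, 1.0))
        sums = traj.states.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, rtol=1e-9)

    def test_methods_agree_on_pure_diffusion(self, small_fixtures):
        """Euler (small step), RK45 and the matrix exponential coincide."""
        G = small_fixtures["random_20"]
        theta0 = point_seed(20, 5, 1.0)
        finals = {}
        for method, edt in [("euler", 1e-4), ("rk45", 1e-3), ("expm", 1e-3)]:
            cfg = SimulationConfig(
                w=1.0, reaction=NO_REACTION, t_max=5.0, dt=1.0, method=method,
                euler_dt=edt,
            )
            finals[method] = integrate(G, NO_REACTION, cfg, theta0).final_state
        assert np.max(np.abs(finals["rk45"] - finals["expm"])) <= 1e-5
        assert np.max(np.abs(finals["euler"] - finals["expm"])) <= 1e-5

    def test_rk45_endpoint_matches_closed_form(self, small_fixtures):
        G = small_fixtures["hub_pendant_20"]
        theta0 = point_seed(20, 0, 0.5)
        cfg = SimulationConfig(w=1.0, reaction=NO_REACTION, t_max=4.0, dt=0.5)
        traj = integrate(G, NO_REACTION, cfg, theta0)
        ref = diffuse_closed_form(laplacian(G), theta0, 1.0, float(traj.times[-1]))
        assert np.max(np.abs(traj.final_state - ref)) <= 1e-6

    def test_trajectory_starts_at_initial_condition(self, small_fixtures):
        G = small_fixtures["K3"]
        theta0 = point_seed(3, 2, 0.25)
        cfg = SimulationConfig(reaction=NO_REACTION, t_max=1.0, dt=0.1)
        traj = integrate(G, NO_REACTION, cfg, theta0)
        assert traj.times[0] == 0.0
        np.testing.assert_array_equal(traj.states[0], theta0)

    def test_logistic_invades_everything(self, small_fixtures):
        G = small_fixtures["random_20"]
        spec = ReactionSpec(kind="logistic", r=1.0)
        cfg = SimulationConfig(w=1.0, reaction=spec, t_max=40.0, dt=1.0)
        traj = integrate(G, spec, cfg, point_seed(20, 0, 0.1))
        np.testing.assert_allclose(traj.final_state, 1.0, atol=1e-3)

    def test_strong_allee_subthreshold_decays_monotonically(self):
        """With no diffusion, a uniform state below the Allee threshold has
        negative growth everywhere and decays toward zero."""
        G = BinaryGraph(adjacency=np.zeros((4, 4), dtype=int))
        spec = ReactionSpec(kind="strong_allee", r=1.0, theta_c=0.001)
        cfg = SimulationConfig(w=0.0, reaction=spec, t_max=2000.0, dt=100.0)
        traj = integrate(G, spec, cfg, np.full(4, 0.0005))
        M = traj.states.mean(axis=1)
        assert np.all(np.diff(M) < 0)
        assert M[-1] < M[0] / 2

    @pytest.mark.parametrize("kind", ["logistic", "strong_allee", "neutral_allee"])
    @pytest.mark.parametrize("uniform", [0.0, 1.0])
    def test_homogeneous_fixed_points_are_stationary(
        self, small_fixtures, kind, uniform
    ):
        G = small_fixtures["K3"]
        spec = ReactionSpec(kind=kind, theta_c=0.001)
        cfg = SimulationConfig(w=1.0, reaction=spec, t_max=5.0, dt=1.0)
        traj = integrate(G, spec, cfg, np.full(3, uniform))
        assert traj.t_converged == 0.0
        np.testing.assert_array_equal(traj.final_state, np.full(3, uniform))

    @pytest.mark.parametrize("kind", ["logistic", "strong_allee", "neutral_allee"])
    def test_trajectories_stay_in_unit_box(self, small_fixtures, kind):
        G = small_fixtures["hub_pendant_20"]
        spec = ReactionSpec(kind=kind, theta_c=0.001)
        cfg = SimulationConfig(w=1.0, reaction=spec, t_max=30.0, dt=0.5)
        traj = integrate(G, spec, cfg, point_seed(20, 19, 0.7))
        assert traj.states.min() >= 0.0  # clip_negative on
        assert traj.states.max() <= 1.0 + 1e-6

    def test_diffusion_vs_logistic_endpoints(self, small_fixtures):
        """Same graph, same seed: pure diffusion plateaus at theta0/N while
        the logistic reaction drives every node to capacity."""
        G = small_fixtures["random_20"]
        theta0 = point_seed(20, 0, 0.1)
        cfg_d = SimulationConfig(w=1.0, reaction=NO_REACTION, t_max=200.0, dt=20.0)
        diff_final = integrate(G, NO_REACTION, cfg_d, theta0).final_state
        spec = ReactionSpec(kind="logistic")
        cfg_l = SimulationConfig(w=1.0, reaction=spec, t_max=40.0, dt=5.0)
        logi_final = integrate(G, spec, cfg_l, theta0).final_state
        np.testing.assert_allclose(diff_final, 0.1 / 20, atol=1e-6)
        np.testing.assert_allclose(logi_final, 1.0, atol=1e-3)

    def test_euler_stability_guard_warns_and_reduces(self, small_fixtures):
        G = small_fixtures["S4"]  # hub degree 4 -> bound 0.5/(4 + ~1)
        spec = ReactionSpec(kind="logistic")
        cfg = SimulationConfig(
            w=1.0, reaction=spec, t_max=2.0, dt=0.5, method="euler", euler_dt=0.5
        )
        with pytest.warns(UserWarning, match="stability bound"):
            traj = integrate(G, spec, cfg, point_seed(5, 0, 0.5))
        assert np.all(np.isfinite(traj.states))
        assert traj.states.max() <= 1.0 + 1e-6

    def test_expm_requires_pure_diffusion(self):
        spec = ReactionSpec(kind="logistic")
        with pytest.raises(ConfigurationError, match="expm"):
            SimulationConfig(reaction=spec, method="expm")

    def test_rk45_matches_euler_oracle_with_reaction(self, small_fixtures):
        """Adaptive RK45 agrees with a brute-force fixed-step Euler path."""
        G = small_fixtures["hub_pendant_20"]
        spec = ReactionSpec(kind="neutral_allee", r=1.0, theta_c=0.001)
        theta0 = point_seed(20, 19, 0.3)
        cfg_rk = SimulationConfig(w=1.0, reaction=spec, t_max=3.0, dt=0.5)
        cfg_eu = SimulationConfig(
            w=1.0, reaction=spec, t_max=3.0, dt=0.5, method="euler", euler_dt=1e-4
        )
        rk = integrate(G, spec, cfg_rk, theta0)
        eu = integrate(G, spec, cfg_eu, theta0)
        assert np.max(np.abs(rk.final_state - eu.final_state)) <= 1e-4
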