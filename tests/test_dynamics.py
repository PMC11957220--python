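import numpy as np
import pytest

from chaostopo import (
    CoupledSystem,
    OscillatorSpec,
    coupled_field,
    integrate,
    nodal_field,
    perturbative_trajectory,
    sync_diagnostics,
)
from chaostopo.dynamics import (
    IntegrationDivergence,
    random_initial_states,
    rk4_step,
)
from conftest import random_zero_row_sum


class TestNodalField:
    def test_lorenz_origin_fixed_point(self, lorenz_spec):
        np.testing.assert_array_equal(
            nodal_field(np.zeros(3), lorenz_spec), np.zeros(3)
        )

    def test_lorenz_at_ones(self, lorenz_spec):
        # alpha=10, gamma=60, beta=8/3 at (1,1,1)
        np.testing.assert_allclose(
            nodal_field(np.array([1.0, 1.0, 1.0]), lorenz_spec),
            [0.0, 58.0, 1.0 - 8.0 / 3.0],
        )

    def test_rossler_at_origin(self):
        spec = OscillatorSpec(model="rossler")
        np.testing.assert_allclose(
            nodal_field(np.zeros(3), spec), [0.0, 0.0, 0.1]
        )

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            OscillatorSpec(model="chen")


class TestCoupledField:
    def test_zero_coupling_reduces_to_nodal(self, rng, lorenz_spec):
        G = random_zero_row_sum(rng, 5)
        system = CoupledSystem(spec=lorenz_spec, G=G, epsilon=0.0)
        states = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(
            coupled_field(states, system), nodal_field(states, lorenz_spec)
        )

    def test_identical_states_cancel_coupling_exactly(self, rng, lorenz_spec):
        G = random_zero_row_sum(rng, 6)
        system = CoupledSystem(spec=lorenz_spec, G=G, epsilon=2.7)
        s = rng.normal(size=3)
        states = np.tile(s, (6, 1))
        np.testing.assert_array_equal(
            coupled_field(states, system), nodal_field(states, lorenz_spec)
        )

    def test_two_node_diffusive_form(self, lorenz_spec):
        G = np.array([[-1.0, 1.0], [1.0, -1.0]])
        system = CoupledSystem(spec=lorenz_spec, G=G, epsilon=0.5)
        states = np.array([[1.0, 2.0, 3.0], [4.0, 0.0, -1.0]])
        out = coupled_field(states, system)
        expected = nodal_field(states, lorenz_spec)
        expected[0] += 0.5 * (states[1] - states[0])
        expected[1] += 0.5 * (states[0] - states[1])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_nonzero_row_sum_rejected(self, lorenz_spec):
        with pytest.raises(ValueError, match="row sums"):
            CoupledSystem(spec=lorenz_spec, G=np.eye(3))


class TestIntegrate:
    def test_rk4_scalar_decay_single_step(self):
        # dy/dt = -y, h=0.1: 1 - h + h^2/2 - h^3/6 + h^4/24
        val = rk4_step(lambda y: -y, np.array([1.0]), 0.1)[0]
        assert val == pytest.approx(0.9048375, abs=1e-12)

    def test_euler_single_step_lorenz(self, lorenz_spec):
        system = CoupledSystem(spec=lorenz_spec, G=np.zeros((1, 1)), epsilon=0.0)
        traj = integrate(
            system, np.array([[1.0, 1.0, 1.0]]), h=1e-3, n_steps=2,
            scheme="euler", transient=0,
        )
        expected = np.array([1.0, 1.0, 1.0]) + 1e-3 * np.array([0.0, 58.0, -5.0 / 3.0])
        np.testing.assert_allclose(traj.states[0, :, 1], expected, atol=1e-15)

    @pytest.mark.parametrize(
        "scheme,order,tol", [("euler", 1.0, 0.2), ("rk2", 2.0, 0.2), ("rk4", 4.0, 0.3)]
    )
    def test_empirical_convergence_order(self, lorenz_spec, scheme, order, tol):
        system = CoupledSystem(spec=lorenz_spec, G=np.zeros((1, 1)), epsilon=0.0)
        init = np.array([[1.0, 1.0, 1.0]])
        horizon = 0.1
        ref = integrate(system, init, h=1e-6, n_steps=int(horizon / 1e-6) + 1,
                        scheme="rk4", transient=0).states[:, :, -1]
        hs = [4e-3, 2e-3, 1e-3]
        errs = [
            np.linalg.norm(
                integrate(system, init, h=h, n_steps=int(round(horizon / h)) + 1,
                          scheme=scheme, transient=0).states[:, :, -1] - ref
            )
            for h in hs
        ]
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert slope == pytest.approx(order, abs=tol)

    def test_divergence_reports_step(self, lorenz_spec):
        # a huge unstable coupling blows up quickly
        G = np.array([[-1.0, 1.0], [1.0, -1.0]])
        system = CoupledSystem(spec=lorenz_spec, G=G, epsilon=1e7)
        with pytest.raises(IntegrationDivergence, match="step"):
            integrate(system, np.array([[1.0, 1, 1], [0, 0, 0.0]]),
                      h=1e-3, n_steps=2000, scheme="euler")

    def test_bad_scheme_rejected(self, lorenz_spec):
        system = CoupledSystem(spec=lorenz_spec, G=np.zeros((1, 1)))
        with pytest.raises(ValueError, match="scheme"):
            integrate(system, np.zeros((1, 3)), scheme="heun")


class TestPerturbative:
    def test_nontarget_nodes_rest_when_uncoupled(self, lorenz_spec):
        G = np.zeros((4, 4))
        system = CoupledSystem(spec=lorenz_spec, G=G, epsilon=0.0)
        traj = perturbative_trajectory(system, target=1, n_steps=500)
        assert traj.target == 1
        for i in (0, 2, 3):
            np.testing.assert_array_equal(traj.states[i], 0.0)
        assert np.abs(traj.states[1]).max() > 0

    def test_coupling_spreads_perturbation(self, lorenz_spec):
        G = np.array([[-1.0, 1.0], [1.0, -1.0]])
        system = CoupledSystem(spec=lorenz_spec, G=G, epsilon=1.0)
        traj = perturbative_trajectory(system, target=0, n_steps=500)
        assert np.abs(traj.states[1]).max() > 1e-6

    def test_relabeling_equivariance(self, rng, lorenz_spec):
        G = random_zero_row_sum(rng, 5)
        perm = rng.permutation(5)
        Gp = G[np.ix_(perm, perm)]
        for target in range(3):
            t1 = perturbative_trajectory(
                CoupledSystem(spec=lorenz_spec, G=G, epsilon=0.8),
                target=perm[target], n_steps=300,
            )
            t2 = perturbative_trajectory(
                CoupledSystem(spec=lorenz_spec, G=Gp, epsilon=0.8),
                target=target, n_steps=300,
            )
            np.testing.assert_allclose(
                t1.states[perm[target]], t2.states[target], atol=1e-10
            )


class TestSyncDiagnostics:
    def test_identical_trajectories_full_regime(self, rng, lorenz_spec):
        G = random_zero_row_sum(rng, 5)
        system = CoupledSystem(spec=lorenz_spec, G=G, epsilon=1.0)
        init = np.tile(rng.uniform(-1, 1, 3), (5, 1))
        traj = integrate(system, init, n_steps=2000)
        diag = sync_diagnostics(traj)
        assert diag.regime == "full"
        assert diag.global_error.max() < 1e-10

    def test_uncoupled_chaos_regime_none(self, lorenz_spec):
        system = CoupledSystem(spec=lorenz_spec, G=np.zeros((6, 6)), epsilon=0.0)
        init = random_initial_states(6, seed=3)
        traj = integrate(system, init, n_steps=8000, scheme="euler")
        assert sync_diagnostics(traj).regime == "none"

    def test_planted_two_cluster_partition(self):
        # two internally identical groups far apart -> partial with the
        # planted split
        T = 400
        t = np.linspace(0, 1, T)
        a = np.stack([np.sin(7 * t), np.cos(7 * t), t])
        b = a + 50.0
        states = np.stack([a, a, a, b, b])
        traj_states = states
        from chaostopo import TrajectoryEnsemble

        traj = TrajectoryEnsemble(states=traj_states, h=1e-3, transient=100,
                                  scheme="euler")
        diag = sync_diagnostics(traj)
        assert diag.regime == "partial"
        assert sorted(sorted(c) for c in diag.clusters) == [[0, 1, 2], [3, 4]]

    def test_manifold_invariance_many_couplings(self, rng, lorenz_spec):
        for _ in range(5):
            n = rng.integers(3, 9)
            G = random_zero_row_sum(rng, n)
            system = CoupledSystem(spec=lorenz_spec, G=G,
                                   epsilon=float(rng.uniform(0, 3)))
            init = np.tile(rng.uniform(-1, 1, 3), (n, 1))
            traj = integrate(system, init, n_steps=1500)
            assert sync_diagnostics(traj).global_error.max() < 1e-10
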