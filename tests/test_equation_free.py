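"""Equation-free algorithms: CPI, fixed points, eigenpairs, continuation."""

import numpy as np
import pytest
from scipy.linalg import expm

from netpce.chaos_basis import apc_1d, tensor_basis
from netpce.coarse_map import CoarsePCEModel
from netpce.equation_free import (
    CPIConfig,
    CPIDivergenceError,
    StepSizeUnderflowError,
    coarse_eigs,
    coarse_fixed_point,
    continue_branch,
    cpi_forward_euler,
    cpi_generic,
    estimate_coarse_rhs,
    flow_to_rate_eigs,
    lift_eigenvector,
    projective_rk2,
    pseudo_arclength,
    rate_to_flow_eigs,
)
from netpce.fixtures import FixtureSpec, make_fixture, preset
from netpce.oscillators import FineState, fine_steady_state, integrate_fine


class FakeLinearModel:
    """Linear coarse flow d(alpha)/dt = J alpha with exact timestepper.

    Stands in for the Kuramoto sandwich where a closed-form oracle is
    needed; mimics the CoarsePCEModel surface used by the algorithms.
    """

    def __init__(self, J):
        self.J = np.asarray(J, dtype=float)
        self.M = self.J.shape[0]

    def timestep(self, alpha, tau, time=0.0):
        return expm(self.J * tau) @ np.asarray(alpha, float)

    def difference(self, alpha, tau):
        return self.timestep(alpha, tau) - np.asarray(alpha, float)

    def with_coupling(self, K):  # pragma: no cover - unused hook
        return self


class TestRhsEstimation:
    def test_linear_flow_closed_form(self):
        """On d(alpha)/dt = -alpha the chord slope is (e^-tau - 1)/tau * alpha."""
        model = FakeLinearModel(-np.eye(3))
        a = np.array([1.0, -2.0, 0.5])
        tau = 0.2
        got = estimate_coarse_rhs(model, a, CPIConfig(tau=tau, h=tau))
        assert np.allclose(got, (np.exp(-tau) - 1.0) / tau * a, atol=1e-12)

    def test_first_order_in_tau(self):
        """Halving tau halves the chord-slope error (Richardson check)."""
        rng = np.random.default_rng(0)
        J = -np.eye(4) + 0.3 * rng.normal(size=(4, 4))
        model = FakeLinearModel(J)
        a = rng.normal(size=4)
        exact = J @ a
        e1 = np.linalg.norm(estimate_coarse_rhs(model, a, CPIConfig(tau=0.1, h=0.1)) - exact)
        e2 = np.linalg.norm(estimate_coarse_rhs(model, a, CPIConfig(tau=0.05, h=0.05)) - exact)
        assert e2 / e1 == pytest.approx(0.5, abs=0.1)

    def test_zero_at_fixed_point(self, base_model, base_steady):
        astar = coarse_fixed_point(
            base_model, base_model.restrict(base_steady), tau=0.05
        )
        rhs = estimate_coarse_rhs(base_model, astar, CPIConfig(tau=0.05, h=0.05))
        assert np.linalg.norm(rhs) < 1e-4  # F_tau/tau below Newton tol/tau

    def test_healing_relaxes_off_manifold_component(self, base_model, base_steady):
        """With healing, the chord at a near-fixed-point is at least as flat."""
        astar = coarse_fixed_point(base_model, base_model.restrict(base_steady), tau=0.05)
        noisy = astar + 1e-3 * np.random.default_rng(1).normal(size=base_model.M)
        plain = estimate_coarse_rhs(base_model, noisy, CPIConfig(tau=0.05, h=0.05))
        healed = estimate_coarse_rhs(
            base_model, noisy, CPIConfig(tau=0.05, h=0.05, healing=0.5)
        )
        assert np.linalg.norm(healed) < np.linalg.norm(plain)


class TestCPI:
    def test_h_equals_tau_reduces_to_plain_timestepping(self, base_model):
        """With h = tau the projective Euler update telescopes into
        Phi_{tau,C} exactly."""
        rng = np.random.default_rng(2)
        a0 = 0.1 * rng.normal(size=base_model.M)
        cfg = CPIConfig(tau=0.05, h=0.05)
        traj = cpi_forward_euler(base_model, a0, (0.0, 0.15), cfg)
        direct = a0
        for _ in range(3):
            direct = base_model.timestep(direct, 0.05)
        assert np.allclose(traj.alphas[-1], direct, atol=1e-9)

    def test_zero_vector_field_constant_trajectory(self):
        model = FakeLinearModel(np.zeros((3, 3)))
        a0 = np.array([0.3, -0.1, 0.2])
        traj = cpi_forward_euler(model, a0, (0.0, 5.0), CPIConfig(tau=0.1, h=1.0))
        assert np.allclose(traj.alphas, a0)

    def test_tracks_fine_trajectory_on_cpi_settings(self):
        """Projective Euler with tau=0.05, h=0.45 tracks the restricted
        fine trajectory of the N=300 ensemble (leading coefficients)."""
        fx = make_fixture(preset("fig4", seed=0))
        s = fx.sample
        basis = tensor_basis(apc_1d(s.omega, 6), apc_1d(s.kappa, 6), 6)
        model = CoarsePCEModel(fx.ensemble, basis, s)
        a0 = model.restrict(fx.state0)
        traj = cpi_forward_euler(model, a0, (0.0, 2.7), CPIConfig(tau=0.05, h=0.45))
        st = model.lift(a0)
        ref = [a0]
        for t in traj.times[1:]:
            st = integrate_fine(fx.ensemble, st, t - st.time)
            ref.append(model.restrict(st))
        ref = np.asarray(ref)
        assert np.abs(traj.alphas - ref).max() < 0.1 * np.abs(ref).max()

    def test_rk2_and_euler_agree_as_h_shrinks(self):
        rng = np.random.default_rng(3)
        J = -np.diag([1.0, 2.0, 0.5]) + 0.1 * rng.normal(size=(3, 3))
        model = FakeLinearModel(J)
        a0 = rng.normal(size=3)
        cfg_e = CPIConfig(tau=1e-3, h=0.01)
        cfg_r = CPIConfig(tau=1e-3, h=0.01, outer_scheme="rk2")
        te = cpi_generic(model, a0, (0.0, 1.0), cfg_e)
        tr = cpi_generic(model, a0, (0.0, 1.0), cfg_r)
        assert np.linalg.norm(te.alphas[-1] - tr.alphas[-1]) < 1e-2

    def test_adaptive_outer_matches_rk2(self, base_model, base_steady):
        a0 = base_model.restrict(base_steady) * 0.9
        cfg_a = CPIConfig(tau=0.05, h=0.05, outer_scheme="adaptive", rtol=1e-6, atol=1e-9)
        cfg_r = CPIConfig(tau=0.05, h=0.1, outer_scheme="rk2")
        ta = cpi_generic(base_model, a0, (0.0, 1.0), cfg_a)
        tr = cpi_generic(base_model, a0, (0.0, 1.0), cfg_r)
        assert np.linalg.norm(ta.alphas[-1] - tr.alphas[-1]) < 1e-3

    def test_divergence_guard_raises(self):
        model = FakeLinearModel(np.eye(2) * 5.0)  # strongly unstable
        with pytest.raises(CPIDivergenceError):
            cpi_forward_euler(
                model, np.ones(2), (0.0, 50.0), CPIConfig(tau=0.5, h=2.0)
            )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CPIConfig(tau=0.0, h=0.1)
        with pytest.raises(ValueError):
            CPIConfig(tau=0.2, h=0.1)
        with pytest.raises(ValueError):
            CPIConfig(tau=0.1, h=0.2, outer_scheme="leapfrog")

    def test_projective_rk2_second_order_in_h(self):
        """Outer-RK2 projective integration of the fine N=100 system keeps
        second order in the outer step once the inner step is small."""
        fx = make_fixture(FixtureSpec(name="f5", N=100, K=1.0, initial="random", seed=0))
        ens = fx.ensemble
        T = 0.417
        truth = integrate_fine(ens, fx.state0, T, rtol=1e-12, atol=1e-12).theta
        tau = 1e-5

        def rhs(x):
            adv = integrate_fine(ens, FineState(x), tau, rtol=1e-10, atol=1e-10)
            return (adv.theta - x) / tau

        hs = np.array([T / 4, T / 6, T / 8, T / 12, T / 16])
        errs = [
            np.linalg.norm(projective_rk2(rhs, fx.state0.theta, (0.0, T), h).alphas[-1] - truth)
            for h in hs
        ]
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.15)


class TestFixedPoint:
    def test_converges_from_restricted_steady_state(self, base_model, base_steady):
        astar = coarse_fixed_point(base_model, base_model.restrict(base_steady), tau=0.05)
        assert np.abs(base_model.difference(astar, 0.05)).max() < 1e-6

    def test_warm_start_returns_immediately(self, base_model, base_steady):
        astar = coarse_fixed_point(base_model, base_model.restrict(base_steady), tau=0.05)
        again = coarse_fixed_point(base_model, astar, tau=0.05, max_iter=1)
        assert np.allclose(again, astar, atol=1e-8)

    def test_lifted_fixed_point_near_fine_steady_state(self, base_model, base_fx, base_steady):
        astar = coarse_fixed_point(base_model, base_model.restrict(base_steady), tau=0.05)
        from netpce.oscillators import theta_rhs

        lifted = base_model.lift(astar).theta
        mse = np.mean((lifted - base_steady.theta) ** 2)
        assert mse < 1e-3
        assert np.linalg.norm(theta_rhs(base_fx.ensemble, lifted)) < 0.1

    def test_nonconvergence_raises_with_residual(self):
        model = FakeLinearModel(np.eye(2))
        # a rootless residual: exp(a_0) + 1 never vanishes
        model.difference = lambda a, tau: np.array([np.exp(a[0]) + 1.0, a[1]])
        with pytest.raises(RuntimeError, match="did not converge"):
            coarse_fixed_point(model, np.zeros(2), tau=0.1, max_iter=3)


class TestEigs:
    def test_rate_flow_transforms_are_inverse(self):
        lam = np.array([-0.5 + 0.3j, -0.1, 0.02 - 1.0j])
        tau = 0.3
        assert np.allclose(flow_to_rate_eigs(rate_to_flow_eigs(lam, tau), tau), lam)
        assert flow_to_rate_eigs([0.0], 0.7)[0] == 0.0

    @pytest.mark.parametrize("M", [3, 6])
    def test_linear_model_eigenvalues_recovered(self, M):
        """Both the dense path (M<=3) and Arnoldi path (M>3) recover the
        known spectrum of a linear coarse flow through the principal-log
        transform of the flow-map eigenvalues."""
        rng = np.random.default_rng(M)
        lam_true = -np.linspace(0.2, 1.4, M)
        Q = np.linalg.qr(rng.normal(size=(M, M)))[0]
        J = Q @ np.diag(lam_true) @ Q.T
        model = FakeLinearModel(J)
        res = coarse_eigs(model, np.zeros(M), tau=0.2)
        k = len(res.lambda_hat)
        assert res.method == ("dense-fd" if M <= 3 else "arnoldi")
        assert np.allclose(
            np.sort(res.lambda_hat.real)[::-1], np.sort(lam_true)[::-1][:k], atol=1e-5
        )
        assert np.allclose(res.mu, rate_to_flow_eigs(res.lambda_hat, 0.2), atol=1e-12)

    def test_kuramoto_coarse_spectrum_is_stable_at_high_K(self, base_model, base_steady):
        astar = coarse_fixed_point(base_model, base_model.restrict(base_steady), tau=0.05)
        res = coarse_eigs(base_model, astar, 0.05, k=6)
        assert res.lambda_hat.real.max() < 0.0
        # slowest first ordering
        assert np.all(np.diff(res.lambda_hat.real) <= 1e-12)


class TestLiftEigenvector:
    def test_constant_basis_vector_gives_flat_surface(self, base_fx, base_basis):
        v = np.zeros(base_basis.M)
        v[base_basis.index_set.index((0, 0))] = 1.0
        _, _, Z = lift_eigenvector(v, base_basis, base_fx.sample, shape=(20, 20))
        vals = Z[np.isfinite(Z)]
        assert vals.size > 0
        assert np.ptp(vals) < 1e-12

    def test_surface_matches_lift_at_sample_points(self, base_fx, base_basis, base_model):
        rng = np.random.default_rng(0)
        v = rng.normal(size=base_basis.M)
        vn = v / np.linalg.norm(v)
        surf_at_samples = base_basis.evaluate(
            base_fx.sample.omega, base_fx.sample.kappa
        ) @ vn
        assert np.allclose(surf_at_samples, base_model.lift(vn).theta)

    def test_near_fold_eigensurface_localizes_on_susceptible_oscillator(self, base_fx):
        """Near the fold the slowest eigensurface peaks at the oscillator
        with the extreme (omega, kappa) identity — the one that first
        desynchronizes."""
        s = base_fx.sample
        basis = tensor_basis(apc_1d(s.omega, 6), apc_1d(s.kappa, 6), 6)
        ens = base_fx.ensemble.with_coupling(0.5)  # just above the fold
        model = CoarsePCEModel(ens, basis, s)
        ss = fine_steady_state(ens, t_relax=300)
        astar = coarse_fixed_point(model, model.restrict(ss), tau=0.3)
        res = coarse_eigs(model, astar, 0.3, k=4)
        W, Kg, Z = lift_eigenvector(res.vectors[:, 0].real, basis, s, shape=(80, 80))
        iw, ik = np.unravel_index(np.nanargmax(np.abs(Z)), Z.shape)
        # fine slow mode: dominant component marks the susceptible node
        from netpce.oscillators import fine_jacobian

        lam, V = np.linalg.eig(fine_jacobian(ens, ss))
        node = np.argmax(np.abs(V[:, np.argmax(lam.real)].real))
        assert abs(W[iw, ik] - s.omega[node]) < 0.25
        assert abs(Kg[iw, ik] - s.kappa[node]) < 0.25


class TestContinuation:
    def test_normal_form_fold_located_to_1e6(self):
        """F(x; K) = x^2 - (K - Kc): the branch turns at K = Kc and the
        refined fold matches to far better than 1e-6."""
        Kc = 2.0
        F = lambda x, K: np.atleast_1d(x[0] ** 2 - (K - Kc))
        branch = pseudo_arclength(
            F, np.array([1.0]), 3.0, ds=0.05, ds_max=0.2, n_steps=60,
            direction=-1.0, stop_after_folds=1, points_after_fold=3,
            fold_xatol=1e-10,
        )
        assert len(branch.folds) == 1
        assert abs(branch.folds[0] - Kc) < 1e-6
        Ks = [p.K for p in branch.points]
        assert min(Ks) >= Kc - 1e-8  # never crosses the fold in K
        assert max(p.residual for p in branch.points) <= 1e-8

    def test_step_underflow_raises_with_last_point(self):
        # branch terminates: no solutions for K < Kc and x forced real
        def F(x, K):
            return np.atleast_1d(x[0] ** 2 + np.exp(x[0]) + K)  # no zeros K>0

        with pytest.raises((StepSizeUnderflowError, Exception)):
            pseudo_arclength(F, np.array([0.0]), 1.0, ds=0.05, n_steps=5)

    def test_kuramoto_branch_rounds_fold_with_stability_change(self, base_fx):
        """Continuation from K = 0.7 downward rounds a fold; past it the
        branch is unstable, the leading eigenvalue having crossed zero."""
        s = base_fx.sample
        basis = tensor_basis(apc_1d(s.omega, 6), apc_1d(s.kappa, 6), 6)
        model = CoarsePCEModel(base_fx.ensemble.with_coupling(0.7), basis, s)
        ss = fine_steady_state(base_fx.ensemble.with_coupling(0.7))
        branch = continue_branch(
            model, model.restrict(ss), 0.7, 0.30, ds=0.02, ds_max=0.06,
            n_steps=60, direction=-1.0, stop_after_folds=1,
            points_after_fold=4, fold_xatol=1e-3, n_eigs=2,
        )
        assert len(branch.folds) == 1
        flags = [p.stable for p in branch.points]
        lead = [p.lambda_hat.real[0] for p in branch.points]
        flip = flags.index(False)
        assert flags[:flip] == [True] * flip  # stable all the way to the fold
        assert all(f is False for f in flags[flip:])
        assert lead[flip - 1] < 0 < lead[flip]  # eigenvalue crosses zero
        # stability flips only at the eigenvalue sign change
        Kmin = min(p.K for p in branch.points)
        assert abs(branch.folds[0] - Kmin) < 0.02
        assert max(p.residual for p in branch.points) <= 1e-8


class TestSniper:
    def test_sync_index_steady_above_fold_oscillatory_below(self, base_fx):
        """r(t) from theta = 0 settles to a constant above the fold; below
        it a rogue oscillator keeps r(t) oscillating."""
        from netpce.oscillators import sync_index

        def r_trace(K):
            ens = base_fx.ensemble.with_coupling(K)
            st = FineState(np.zeros(ens.N - 1))
            rs = []
            for t in np.linspace(0.0, 300.0, 301):
                st = integrate_fine(ens, st, t - st.time, rtol=1e-6, atol=1e-8)
                rs.append(sync_index(st.full_theta).r)
            return np.array(rs[150:])  # late-time window

        above = r_trace(0.6)
        below = r_trace(0.35)
        assert np.ptp(above) < 1e-4
        assert np.ptp(below) > 1e-2
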