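"""Headline experiments, re-runnable at reduced scale from the CLI.

Each runner regenerates its inputs from the given seed, performs the
computation through the library, and writes plain CSV outputs (plus an
optional PNG).  Problem sizes are scaled to finish in seconds to a few
minutes on one CPU; the docs note the sizes used.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .chaos_basis import apc_1d, tensor_basis
from .coarse_map import CoarsePCEModel, restrict, save_coarse_states
from .equation_free import (
    CPIConfig,
    coarse_eigs,
    coarse_fixed_point,
    continue_branch,
    cpi_forward_euler,
    projective_rk2,
)
from .fixtures import FixtureSpec, make_fixture, preset
from .oscillators import (
    FineState,
    fine_jacobian,
    fine_steady_state,
    integrate_fine,
    sync_index,
    theta_rhs,
    wrapped_deviations,
)


def _basis_model(fx, pmax=6, K=None, rtol=1e-8, atol=1e-8):
    basis = tensor_basis(
        apc_1d(fx.sample.omega, pmax), apc_1d(fx.sample.kappa, pmax), pmax
    )
    ens = fx.ensemble if K is None else fx.ensemble.with_coupling(K)
    return basis, CoarsePCEModel(ens, basis, fx.sample, rtol=rtol, atol=atol)


def _maybe_plot(plot, fname, draw):
    if not plot:
        return []
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5), constrained_layout=True)
    draw(ax)
    fig.savefig(fname, dpi=150)
    plt.close(fig)
    return [fname]


def figure2(outdir: Path, seed: int = 0, plot: bool = False, N: int = 2000):
    """Collapse of a random phase cloud onto the identity surface (K=0.5).

    Writes the relative surface-fit residual of the wrapped phases along the
    transient.
    """
    fx = make_fixture(FixtureSpec(name="fig2", N=N, K=0.5, initial="random", seed=seed))
    basis, model = _basis_model(fx, rtol=1e-6, atol=1e-6)
    st = fx.state0
    rows = []
    for t in [0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0]:
        if t > st.time:
            st = integrate_fine(fx.ensemble, st, t - st.time, rtol=1e-6, atol=1e-6)
        w = wrapped_deviations(st.full_theta)[: fx.sample.n]
        _, rep = restrict(w, basis, fx.sample)
        rows.append((t, rep.residual / np.mean(w**2), sync_index(st.full_theta).r))
    path = outdir / "fig2_slaving.csv"
    np.savetxt(path, rows, delimiter=",", header="time,rel_residual,r", comments="")
    rows = np.asarray(rows)
    extra = _maybe_plot(
        plot, outdir / "fig2_slaving.png",
        lambda ax: (ax.semilogy(rows[:, 0], rows[:, 1], "o-"),
                    ax.set_xlabel("t"), ax.set_ylabel("relative fit residual")),
    )
    return [path, *extra]


def figure4(outdir: Path, seed: int = 0, plot: bool = False):
    """CPI vs direct fine integration for the leading coefficients."""
    fx = make_fixture(preset("fig4", seed=seed))
    basis, model = _basis_model(fx, pmax=6)
    alpha0 = model.restrict(fx.state0)
    cfg = CPIConfig(tau=0.05, h=0.45)
    traj = cpi_forward_euler(model, alpha0, (0.0, 2.7), cfg)
    st = model.lift(alpha0)
    ref = [alpha0]
    for t in traj.times[1:]:
        st = integrate_fine(fx.ensemble, st, t - st.time)
        ref.append(model.restrict(st))
    ref = np.asarray(ref)
    p1 = outdir / "fig4_cpi.csv"
    p2 = outdir / "fig4_fine_reference.csv"
    save_coarse_states(p1, traj.times, traj.alphas, basis_name="fig4-cpi")
    save_coarse_states(p2, traj.times, ref, basis_name="fig4-fine")
    extra = _maybe_plot(
        plot, outdir / "fig4_cpi.png",
        lambda ax: (ax.plot(traj.times, ref[:, :4], "k-"),
                    ax.plot(traj.times, traj.alphas[:, :4], "o"),
                    ax.set_xlabel("t"), ax.set_ylabel("leading alpha_k")),
    )
    return [p1, p2, *extra]


def figure5(outdir: Path, seed: int = 0, plot: bool = False, N: int = 100):
    """Error of projective RK2 on the fine system vs outer step h.

    For fixed small inner step tau the scheme keeps second order in h until
    the tau-induced floor takes over.
    """
    fx = make_fixture(FixtureSpec(name="fig5", N=N, K=1.0, initial="random", seed=seed))
    ens = fx.ensemble
    T = 0.417
    truth = integrate_fine(ens, fx.state0, T, rtol=1e-12, atol=1e-12).theta
    rows = []
    for tau in [1e-3, 1e-4, 1e-5]:
        def rhs(x, tau=tau):
            adv = integrate_fine(ens, FineState(x), tau, rtol=1e-10, atol=1e-10)
            return (adv.theta - x) / tau

        for n in [4, 6, 8, 12, 16, 24]:
            out = projective_rk2(rhs, fx.state0.theta, (0.0, T), T / n)
            rows.append((tau, T / n, np.linalg.norm(out.alphas[-1] - truth)))
    path = outdir / "fig5_order.csv"
    np.savetxt(path, rows, delimiter=",", header="tau,h,error", comments="")
    rows = np.asarray(rows)
    extra = _maybe_plot(
        plot, outdir / "fig5_order.png",
        lambda ax: ([ax.loglog(rows[rows[:, 0] == tau, 1],
                               rows[rows[:, 0] == tau, 2], "o-", label=f"tau={tau:g}")
                     for tau in np.unique(rows[:, 0])],
                    ax.legend(), ax.set_xlabel("h"), ax.set_ylabel("error at T")),
    )
    return [path, *extra]


def figure6(outdir: Path, seed: int = 0, plot: bool = False,
            n_replicates: int = 8, N_basis: int = 2000):
    """Fine-space error of coarse fixed points vs basis size M.

    Polynomials come from one large (N_basis) realization; fixed points are
    computed on n_replicates independent N=196 realizations and compared
    with each realization's directly computed fine steady state (MSE).
    """
    big = make_fixture(FixtureSpec(name="fig6-basis", N=N_basis, K=1.0, seed=seed + 900))
    ops = {p: apc_1d(big.sample.omega, p) for p in range(1, 7)}
    kps = {p: apc_1d(big.sample.kappa, p) for p in range(1, 7)}
    rows = []
    for rep in range(n_replicates):
        fx = make_fixture(preset("base", seed=seed + 100 + rep))
        ss = fine_steady_state(fx.ensemble)
        for p in range(1, 7):
            basis = tensor_basis(ops[p], kps[p], p)
            model = CoarsePCEModel(fx.ensemble, basis, fx.sample)
            astar = coarse_fixed_point(model, model.restrict(ss), tau=0.05)
            mse = float(np.mean((model.lift(astar).theta - ss.theta) ** 2))
            rows.append((rep, basis.M, mse))
    path = outdir / "fig6_fixed_point_mse.csv"
    np.savetxt(path, rows, delimiter=",", header="replicate,M,mse", comments="")
    rows = np.asarray(rows)
    med = [(M, np.median(rows[rows[:, 1] == M, 2])) for M in np.unique(rows[:, 1])]
    med = np.asarray(med)
    extra = _maybe_plot(
        plot, outdir / "fig6_fixed_point_mse.png",
        lambda ax: (ax.semilogy(med[:, 0], med[:, 1], "o-"),
                    ax.set_xlabel("M"), ax.set_ylabel("median fine MSE")),
    )
    return [path, *extra]


def figure7(outdir: Path, seed: int = 0, plot: bool = False):
    """Coarse vs fine eigenvalues at the synchronized state (K=1, M=28)."""
    fx = make_fixture(preset("base", seed=seed))
    basis, model = _basis_model(fx, pmax=6)
    ss = fine_steady_state(fx.ensemble)
    astar = coarse_fixed_point(model, model.restrict(ss), tau=0.05)
    res = coarse_eigs(model, astar, 0.05, k=6)
    lam_fine = np.sort(np.linalg.eigvals(fine_jacobian(fx.ensemble, ss)).real)[::-1]
    k = len(res.lambda_hat)
    path = outdir / "fig7_eigenvalues.csv"
    np.savetxt(
        path,
        np.column_stack([np.arange(1, k + 1), res.lambda_hat.real[:k], lam_fine[:k]]),
        delimiter=",", header="index,coarse_lambda_hat,fine_lambda", comments="",
    )
    extra = _maybe_plot(
        plot, outdir / "fig7_eigenvalues.png",
        lambda ax: (ax.plot(np.arange(1, k + 1), lam_fine[:k], "b.", label="fine"),
                    ax.plot(np.arange(1, k + 1), res.lambda_hat.real[:k], "rd",
                            label="coarse"),
                    ax.legend(), ax.set_xlabel("index"), ax.set_ylabel("lambda")),
    )
    return [path, *extra]


def figure8(outdir: Path, seed: int = 0, plot: bool = False):
    """Coarse bifurcation diagram in K with a SNIPER fold, plus r(t) insets."""
    fx = make_fixture(preset("fig8", seed=seed))
    basis, model = _basis_model(fx, pmax=6, K=0.7)
    ss = fine_steady_state(fx.ensemble.with_coupling(0.7))
    branch = continue_branch(
        model, model.restrict(ss), 0.7, 0.30, ds=0.02, ds_max=0.06, n_steps=60,
        direction=-1.0, stop_after_folds=1, points_after_fold=5,
        fold_xatol=1e-3, n_eigs=2,
    )
    p1 = outdir / "fig8_branch.csv"
    rows = [
        np.concatenate([[p.K], [np.linalg.norm(p.x)],
                        [p.lambda_hat.real[0], float(p.stable)]])
        for p in branch.points
    ]
    np.savetxt(p1, rows, delimiter=",",
               header="K,alpha_norm,re_lambda_1,stable", comments="")

    # r(t) from theta = 0 above and below the fold
    p2 = outdir / "fig8_sync_traces.csv"
    traces = []
    ts = np.linspace(0.0, 300.0, 601)
    for K in (0.6, 0.35):
        ens = fx.ensemble.with_coupling(K)
        st = FineState(np.zeros(ens.N - 1))
        rs = []
        for t in ts:
            st = integrate_fine(ens, st, t - st.time, rtol=1e-6, atol=1e-8)
            rs.append(sync_index(st.full_theta).r)
        traces.append(rs)
    np.savetxt(p2, np.column_stack([ts, *traces]), delimiter=",",
               header="time,r_above_fold,r_below_fold", comments="")
    rows = np.asarray(rows)
    extra = _maybe_plot(
        plot, outdir / "fig8_branch.png",
        lambda ax: (ax.plot(rows[rows[:, 3] == 1, 0], rows[rows[:, 3] == 1, 1], "r.-",
                            label="stable"),
                    ax.plot(rows[rows[:, 3] == 0, 0], rows[rows[:, 3] == 0, 1], "k.-",
                            label="unstable"),
                    ax.legend(), ax.set_xlabel("K"), ax.set_ylabel("||alpha||")),
    )
    return [p1, p2, *extra]
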