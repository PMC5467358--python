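"""Equation-free computation on the coarse (PCE-coefficient) variables.

The coarse vector field is never available in closed form; every algorithm
here only ever calls the coarse timestepper Phi_{tau,C} (short bursts of
fine integration wrapped in lift/restrict):

* coarse projective integration — estimate d(alpha)/dt from the chord
  (Phi_{tau,C}(alpha) - alpha)/tau and hand it to an outer integrator
  (projective forward Euler, explicit RK2/Heun, or an adaptive embedded
  pair) with outer step h >> tau;
* coarse fixed points — zeros of F_tau(alpha) = Phi_{tau,C}(alpha) - alpha
  via matrix-free Newton-Krylov (GMRES inner solves, forward-difference
  directional derivatives);
* coarse stability — leading eigenpairs of the Jacobian of F_tau by
  implicitly restarted Arnoldi (dense finite-difference Jacobian for
  M <= 3), mapped to rate eigenvalues by lambda_hat = ln(mu + 1)/tau;
* coarse bifurcation diagrams — pseudo-arclength continuation in the
  coupling K with secant predictor and Newton-GMRES corrector, fold
  detection/refinement and stability flagging along the branch.

The lambda_hat transform uses the principal complex logarithm; eigenvalues
with |Im lambda| * tau >= pi alias and cannot be recovered, which bounds the
usable tau for oscillatory modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import eig as dense_eig
from scipy.optimize import minimize_scalar, newton_krylov
from scipy.optimize import NoConvergence
from scipy.sparse.linalg import LinearOperator, eigs as arnoldi_eigs

from .coarse_map import CoarsePCEModel

__all__ = [
    "CPIConfig",
    "CPIDivergenceError",
    "CoarseTrajectory",
    "EigenResult",
    "BranchPoint",
    "ContinuationBranch",
    "StepSizeUnderflowError",
    "estimate_coarse_rhs",
    "projective_euler",
    "projective_rk2",
    "projective_adaptive",
    "cpi_forward_euler",
    "cpi_generic",
    "coarse_fixed_point",
    "coarse_eigs",
    "flow_to_rate_eigs",
    "rate_to_flow_eigs",
    "lift_eigenvector",
    "pseudo_arclength",
    "continue_branch",
]

_SQRT_EPS = float(np.sqrt(np.finfo(float).eps))


class CPIDivergenceError(RuntimeError):
    """Projective trajectory norm grew beyond the divergence guard."""


class StepSizeUnderflowError(RuntimeError):
    """Continuation step control shrank below its floor."""

    def __init__(self, message, last_point=None):
        super().__init__(message)
        self.last_point = last_point


@dataclass(frozen=True)
class CPIConfig:
    """Coarse-projective-integration settings.

    tau : inner fine-burst duration (> 0)
    h : outer projective step; h >= tau for a genuine projective step
    healing : fine relaxation run after lifting, before the chord is drawn
    outer_scheme : forward_euler | rk2 | adaptive
    rtol, atol : tolerances of the adaptive outer integrator
    guard_factor : divergence guard on the trajectory norm
    """

    tau: float
    h: float
    healing: float = 0.0
    outer_scheme: str = "forward_euler"
    rtol: float = 1e-6
    atol: float = 1e-9
    guard_factor: float = 1e3

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.h < self.tau:
            raise ValueError("outer step h must be >= inner step tau")
        if self.healing < 0:
            raise ValueError("healing must be >= 0")
        if self.outer_scheme not in ("forward_euler", "rk2", "adaptive"):
            raise ValueError(f"unknown outer scheme {self.outer_scheme!r}")


@dataclass
class CoarseTrajectory:
    """Times (n,) and coefficient rows (n, M) of a coarse trajectory."""

    times: np.ndarray
    alphas: np.ndarray


def estimate_coarse_rhs(
    model: CoarsePCEModel, alpha: np.ndarray, config: CPIConfig
) -> np.ndarray:
    """Chord estimate of d(alpha)/dt from one short fine burst.

    With healing > 0 the lifted state is first relaxed for the healing
    duration and re-restricted; the chord is then drawn between the healed
    coarse state and its tau-advanced image, damping off-manifold
    components the coarse representation cannot carry.
    """
    alpha = np.asarray(alpha, dtype=float)
    if config.healing > 0:
        fine = model.lift(alpha)
        healed = model.integrate(fine, config.healing)
        alpha0 = model.restrict(healed)
        advanced = model.integrate(healed, config.tau)
        return (model.restrict(advanced) - alpha0) / config.tau
    return (model.timestep(alpha, config.tau) - alpha) / config.tau


def _guard(x, x0_norm, factor):
    if not np.all(np.isfinite(x)) or np.linalg.norm(x) > factor * (1.0 + x0_norm):
        raise CPIDivergenceError(
            "projective trajectory diverged past the guard; reduce h or "
            "increase the inner burst"
        )


def projective_euler(rhs, x0, t_span, h, guard_factor=1e3) -> CoarseTrajectory:
    """Projective forward Euler: x(t+h) = x(t) + h * rhs(x(t))."""
    t0, t1 = t_span
    x = np.asarray(x0, dtype=float).copy()
    x0_norm = np.linalg.norm(x)
    times, rows = [t0], [x.copy()]
    t = t0
    while t < t1 - 1e-12:
        step = min(h, t1 - t)
        x = x + step * rhs(x)
        _guard(x, x0_norm, guard_factor)
        t += step
        times.append(t)
        rows.append(x.copy())
    return CoarseTrajectory(np.array(times), np.array(rows))


def projective_rk2(rhs, x0, t_span, h, guard_factor=1e3) -> CoarseTrajectory:
    """Projective explicit RK2 (Heun) with the chord estimator as RHS."""
    t0, t1 = t_span
    x = np.asarray(x0, dtype=float).copy()
    x0_norm = np.linalg.norm(x)
    times, rows = [t0], [x.copy()]
    t = t0
    while t < t1 - 1e-12:
        step = min(h, t1 - t)
        k1 = rhs(x)
        k2 = rhs(x + step * k1)
        x = x + 0.5 * step * (k1 + k2)
        _guard(x, x0_norm, guard_factor)
        t += step
        times.append(t)
        rows.append(x.copy())
    return CoarseTrajectory(np.array(times), np.array(rows))


def projective_adaptive(rhs, x0, t_span, rtol=1e-6, atol=1e-9) -> CoarseTrajectory:
    """Adaptive embedded outer pair (RK45) driven by the chord estimator."""
    sol = solve_ivp(
        lambda t, y: rhs(y), t_span, np.asarray(x0, float), method="RK45",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise CPIDivergenceError(f"adaptive outer integrator failed: {sol.message}")
    return CoarseTrajectory(sol.t, sol.y.T)


def cpi_forward_euler(
    model: CoarsePCEModel, alpha0: np.ndarray, t_span, config: CPIConfig
) -> CoarseTrajectory:
    """Coarse projective forward Euler over t_span."""
    rhs = lambda a: estimate_coarse_rhs(model, a, config)
    return projective_euler(rhs, alpha0, t_span, config.h, config.guard_factor)


def cpi_generic(
    model: CoarsePCEModel, alpha0: np.ndarray, t_span, config: CPIConfig
) -> CoarseTrajectory:
    """CPI with the outer scheme named in the config."""
    rhs = lambda a: estimate_coarse_rhs(model, a, config)
    if config.outer_scheme == "forward_euler":
        return projective_euler(rhs, alpha0, t_span, config.h, config.guard_factor)
    if config.outer_scheme == "rk2":
        return projective_rk2(rhs, alpha0, t_span, config.h, config.guard_factor)
    return projective_adaptive(rhs, alpha0, t_span, config.rtol, config.atol)


# ---------------------------------------------------------------------------
# coarse fixed points


def coarse_fixed_point(
    model: CoarsePCEModel,
    alpha_guess: np.ndarray,
    tau: float,
    f_tol: float = 1e-6,
    max_iter: int = 60,
) -> np.ndarray:
    """Zero of F_tau by matrix-free Newton-Krylov (GMRES inner solves).

    Jacobian-vector products are forward differences of F_tau with relative
    step sqrt(machine epsilon); the GMRES subspace is allowed to reach the
    full coarse dimension M.  ``f_tol`` bounds the max-norm of F_tau at the
    returned point.
    """
    F = lambda a: model.difference(a, tau)
    alpha0 = np.asarray(alpha_guess, dtype=float)
    if np.abs(F(alpha0)).max() <= f_tol:
        return alpha0.copy()  # warm start: already converged
    try:
        alpha = newton_krylov(
            F,
            alpha0,
            method="gmres",
            f_tol=f_tol,
            rdiff=_SQRT_EPS,
            maxiter=max_iter,
            inner_maxiter=max(20, model.M),
        )
    except NoConvergence as exc:
        final = np.asarray(exc.args[0], dtype=float)
        raise RuntimeError(
            "coarse fixed point did not converge within "
            f"{max_iter} Newton iterations; final ||F_tau|| = "
            f"{np.linalg.norm(F(final)):.3e}"
        ) from exc
    return np.asarray(alpha, dtype=float)


# ---------------------------------------------------------------------------
# coarse eigenpairs


def flow_to_rate_eigs(mu, tau: float) -> np.ndarray:
    """Map flow-map eigenvalues mu to rate eigenvalues ln(mu + 1)/tau."""
    return np.log(np.asarray(mu, dtype=complex) + 1.0) / tau


def rate_to_flow_eigs(lam, tau: float) -> np.ndarray:
    """Inverse transform mu = exp(lambda tau) - 1."""
    return np.exp(np.asarray(lam, dtype=complex) * tau) - 1.0


@dataclass
class EigenResult:
    """Leading eigenpairs of the Jacobian of F_tau at a coarse fixed point.

    ``mu`` are flow-map-difference eigenvalues, ``lambda_hat`` the
    corresponding rate eigenvalues ln(mu + 1)/tau, sorted slowest first
    (descending real part of lambda_hat).
    """

    mu: np.ndarray
    lambda_hat: np.ndarray
    tau: float
    vectors: np.ndarray
    method: str


def _fd_jacobian_operator(F, x0, F0):
    x0 = np.asarray(x0, dtype=float)
    base = _SQRT_EPS * (1.0 + np.linalg.norm(x0))

    def matvec(v):
        v = np.asarray(v)
        if np.iscomplexobj(v):
            return matvec(v.real) + 1j * matvec(v.imag)
        nv = np.linalg.norm(v)
        if nv == 0:
            return np.zeros_like(v)
        eps = base / nv
        return (F(x0 + eps * v) - F0) / eps

    return matvec


def coarse_eigs(
    model: CoarsePCEModel,
    alpha_star: np.ndarray,
    tau: float,
    k: int | None = None,
) -> EigenResult:
    """Leading eigenpairs of the coarse difference map's Jacobian.

    For M > 3 the Jacobian is never formed: implicitly restarted Arnoldi
    runs on the shifted operator v -> v + J v, whose largest-magnitude
    eigenvalues mu + 1 = exp(lambda tau) single out the slowest rate
    eigenvalues; mu is recovered by subtracting 1.  For M <= 3 a dense
    forward-difference Jacobian (fixed step 0.001) is diagonalized directly.
    """
    alpha_star = np.asarray(alpha_star, dtype=float)
    M = alpha_star.size
    F = lambda a: model.difference(a, tau)
    F0 = F(alpha_star)
    if M <= 3:
        J = np.empty((M, M))
        step = 1e-3
        for j in range(M):
            e = np.zeros(M)
            e[j] = step
            J[:, j] = (F(alpha_star + e) - F0) / step
        mu, vecs = dense_eig(J)
        method = "dense-fd"
    else:
        if k is None:
            k = min(M - 2, 6)
        k = min(k, M - 2)
        matvec = _fd_jacobian_operator(F, alpha_star, F0)
        op = LinearOperator((M, M), matvec=lambda v: v + matvec(v))
        vals, vecs = arnoldi_eigs(op, k=k, which="LM")
        mu = vals - 1.0
        method = "arnoldi"
    lam = flow_to_rate_eigs(mu, tau)
    order = np.argsort(-lam.real, kind="stable")
    return EigenResult(
        mu=mu[order], lambda_hat=lam[order], tau=tau,
        vectors=vecs[:, order], method=method,
    )


def lift_eigenvector(v, basis, sample, shape=(60, 60)):
    """Evaluate a coarse eigenvector as a surface over identity space.

    The surface sum_k v_k psi^(k)(omega, kappa) is evaluated on a
    rectangular grid clipped (NaN outside) to the convex hull of the
    sampled normalized (omega, kappa) points.  Returns (omega_grid,
    kappa_grid, surface); the eigenvector is normalized to unit length
    first.
    """
    from scipy.spatial import Delaunay

    v = np.asarray(v)
    v = v / np.linalg.norm(v)
    og = np.linspace(sample.omega.min(), sample.omega.max(), shape[0])
    kg = np.linspace(sample.kappa.min(), sample.kappa.max(), shape[1])
    W, Kg = np.meshgrid(og, kg, indexing="ij")
    pts = np.column_stack([sample.omega, sample.kappa])
    tri = Delaunay(pts)
    inside = tri.find_simplex(np.column_stack([W.ravel(), Kg.ravel()])) >= 0
    Z = basis.evaluate(W.ravel(), Kg.ravel()) @ v
    Z = np.where(inside, Z, np.nan).reshape(shape)
    return W, Kg, Z


# ---------------------------------------------------------------------------
# pseudo-arclength continuation


@dataclass
class BranchPoint:
    """One accepted continuation point."""

    K: float
    x: np.ndarray
    arclength: float
    residual: float
    lambda_hat: np.ndarray | None = None
    stable: bool | None = None


@dataclass
class ContinuationBranch:
    """Accepted branch points and refined fold locations (K values)."""

    points: list[BranchPoint] = field(default_factory=list)
    folds: list[float] = field(default_factory=list)

    def as_arrays(self):
        K = np.array([p.K for p in self.points])
        X = np.array([p.x for p in self.points])
        return K, X


def _corrector(F, z_pred, tangent, tol, maxiter=40):
    """Newton-GMRES on [F(x, K); tangent . (z - z_pred)] = 0.

    The inner tolerance is scaled so the *2-norm* of F at the accepted
    point is below ``tol``.
    """
    n = z_pred.size - 1

    def G(z):
        return np.append(F(z[:n], z[n]), tangent @ (z - z_pred))

    with np.errstate(invalid="ignore"):
        z = newton_krylov(
            G, z_pred, method="gmres", f_tol=tol / np.sqrt(n + 1),
            rdiff=_SQRT_EPS, maxiter=maxiter, inner_maxiter=max(20, n + 1),
        )
    return z, float(np.linalg.norm(F(z[:n], z[n])))


def _natural_solve(F, x0, K, tol):
    with np.errstate(invalid="ignore"):
        x = newton_krylov(
            lambda x: F(x, K), np.asarray(x0, float), method="gmres",
            f_tol=tol / np.sqrt(np.size(x0)), rdiff=_SQRT_EPS,
            inner_maxiter=max(20, np.size(x0)),
        )
    return np.asarray(x, dtype=float)


def _fold_K(F, z_a, z_b, tol, xatol=1e-8, minimum: bool = True):
    """Refine a bracketed fold: extremize K along the branch chord.

    K restricted to the branch has a quadratic extremum at the fold
    (a minimum when K was decreasing before the turn, else a maximum); a
    bounded scalar minimization over the predictor fraction f in [0, 1]
    (each evaluation is one corrector solve) locates it.
    """
    chord = z_b - z_a
    tangent = chord / np.linalg.norm(chord)
    sign = 1.0 if minimum else -1.0

    def K_at(f):
        z, _ = _corrector(F, z_a + f * chord, tangent, tol)
        return z[-1]

    res = minimize_scalar(
        lambda f: sign * K_at(f), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": xatol},
    )
    return float(K_at(res.x))


def pseudo_arclength(
    F,
    x0,
    K0: float,
    *,
    ds: float = 0.01,
    ds_max: float = 0.1,
    ds_min: float = 1e-10,
    n_steps: int = 100,
    direction: float = -1.0,
    corrector_tol: float = 1e-8,
    delta_K: float = 0.01,
    K_min: float | None = None,
    K_max: float | None = None,
    stop_after_folds: int | None = None,
    points_after_fold: int = 5,
    refine_folds: bool = True,
    fold_xatol: float = 1e-8,
) -> ContinuationBranch:
    """Generic pseudo-arclength continuation of 0 = F(x; K).

    The branch is seeded by two natural-parameter solves at K0 and
    K0 + direction * delta_K; thereafter a secant predictor and a
    Newton-GMRES corrector on the arclength-augmented system march along
    the branch.  Step control halves ds on corrector failure and grows it
    by 1.3 on success.  A fold is recorded whenever the secant tangent's
    K-component changes sign; with ``refine_folds`` the fold K is polished
    by a bounded scalar extremization between the bracketing points.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    branch = ContinuationBranch()

    xa = _natural_solve(F, x0, K0, corrector_tol)
    K1 = K0 + direction * delta_K
    xb = _natural_solve(F, xa, K1, corrector_tol)
    za = np.append(xa, K0)
    zb = np.append(xb, K1)
    s = 0.0
    branch.points.append(BranchPoint(K0, xa, 0.0, float(np.linalg.norm(F(xa, K0)))))
    s += np.linalg.norm(zb - za)
    branch.points.append(BranchPoint(K1, xb, s, float(np.linalg.norm(F(xb, K1)))))

    tangent = (zb - za) / np.linalg.norm(zb - za)
    fold_pending: list[tuple[np.ndarray, np.ndarray, bool]] = []
    steps_since_last_fold = 0

    for _ in range(n_steps):
        step = ds
        while True:
            z_pred = zb + step * tangent
            try:
                z_new, resid = _corrector(F, z_pred, tangent, corrector_tol)
                break
            except NoConvergence:
                step *= 0.5
                if step < ds_min:
                    raise StepSizeUnderflowError(
                        "continuation step size underflow",
                        last_point=branch.points[-1],
                    )
        ds = min(step * 1.3, ds_max)
        new_tangent = (z_new - zb) / np.linalg.norm(z_new - zb)
        if np.sign(new_tangent[-1]) != np.sign(tangent[-1]) and tangent[-1] != 0:
            # K was monotone za -> zb and reversed zb -> z_new: the fold
            # (extremum of K along the branch) lies between za and z_new,
            # a minimum of K iff K was decreasing before the turn.
            fold_pending.append((za.copy(), z_new.copy(), tangent[-1] < 0))
            steps_since_last_fold = 0
        elif fold_pending:
            steps_since_last_fold += 1
        s += np.linalg.norm(z_new - zb)
        branch.points.append(BranchPoint(float(z_new[n]), z_new[:n].copy(), s, resid))
        za, zb, tangent = zb, z_new, new_tangent
        K_now = z_new[n]
        if K_min is not None and K_now < K_min:
            break
        if K_max is not None and K_now > K_max:
            break
        if (
            stop_after_folds is not None
            and len(fold_pending) >= stop_after_folds
            and steps_since_last_fold >= points_after_fold
        ):
            break

    for z_lo, z_hi, is_min in fold_pending:
        if refine_folds:
            branch.folds.append(
                _fold_K(F, z_lo, z_hi, corrector_tol, fold_xatol, minimum=is_min)
            )
        else:
            branch.folds.append(float(0.5 * (z_lo[-1] + z_hi[-1])))
    return branch


def continue_branch(
    model: CoarsePCEModel,
    alpha0: np.ndarray,
    K0: float,
    tau: float,
    *,
    compute_eigs: bool = True,
    n_eigs: int = 2,
    **kwargs,
) -> ContinuationBranch:
    """Pseudo-arclength continuation of coarse fixed points over K.

    At each accepted point the leading rate eigenvalues are computed
    (matrix-free) and the point is flagged stable iff all their real parts
    are negative; the flag can only flip where a leading eigenvalue's real
    part changes sign.
    """

    def F(alpha, K):
        return model.with_coupling(K).difference(alpha, tau)

    branch = pseudo_arclength(F, alpha0, K0, **kwargs)
    if compute_eigs:
        for pt in branch.points:
            res = coarse_eigs(model.with_coupling(pt.K), pt.x, tau, k=n_eigs)
            pt.lambda_hat = res.lambda_hat
            pt.stable = bool(np.all(res.lambda_hat.real < 0))
    return branch
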