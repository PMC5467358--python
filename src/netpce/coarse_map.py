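"""Restriction/lifting between fine states and PCE coefficients.

Restriction R: R^(N-1) -> R^M fits the surface theta(omega, kappa) ~
sum_k alpha_k psi^(k)(omega, kappa) by weighted least squares (uniform
Monte-Carlo weights 1/n by default), solved through a QR factorization of
the design matrix.  Lifting L: R^M -> R^(N-1) evaluates the surface at the
fitted nodes.  The fitted node set is nodes 1..N-1, the independent
co-moving coordinates; node N's phase is reconstructed from the zero-sum
constraint after lifting.

The coarse timestepper is the sandwich R o Phi_{tau,F} o L: lift a
coefficient vector to a consistent fine state, integrate the fine system for
tau, and restrict back.  This package always lifts to the one network and
frequency vector held by the model ("single instance" lifting).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .chaos_basis import Basis2D, HeterogeneitySample, design_matrix
from .oscillators import FineState, OscillatorEnsemble, integrate_fine

__all__ = [
    "CoarseState",
    "FitReport",
    "RankDeficiencyError",
    "restrict",
    "lift",
    "coarse_timestep",
    "coarse_difference",
    "CoarsePCEModel",
    "save_coarse_states",
    "load_coarse_states",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    """The design matrix lost column rank (e.g., too few distinct degrees)."""


@dataclass
class CoarseState:
    """PCE coefficient vector alpha in R^M at a given time."""

    alpha: np.ndarray
    basis: Basis2D
    time: float = 0.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (self.basis.M,):
            raise ValueError("alpha length must equal basis size M")
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("alpha must be finite")


@dataclass(frozen=True)
class FitReport:
    """Weighted squared residual of the fit and a design-matrix condition estimate."""

    residual: float
    condition: float


def _weighted_qr(Psi: np.ndarray, weights: np.ndarray):
    sw = np.sqrt(weights)
    Q, R = np.linalg.qr(sw[:, None] * Psi)
    dr = np.abs(np.diag(R))
    if dr.min() <= dr.max() * np.finfo(float).eps * max(Psi.shape):
        raise RankDeficiencyError(
            "design matrix is numerically rank-deficient; the sample does not "
            "resolve this basis (too few distinct identity values?)"
        )
    return Q, R, sw


def _fit(Q, R, sw, Psi, weights, f):
    alpha = solve_triangular(R, Q.T @ (sw * f))
    resid = f - Psi @ alpha
    sigma_hat = float(np.sum(weights * resid**2))
    sv = np.linalg.svd(R, compute_uv=False)
    return alpha, FitReport(residual=sigma_hat, condition=float(sv[0] / sv[-1]))


def restrict(
    state: FineState | np.ndarray,
    basis: Basis2D,
    sample: HeterogeneitySample,
    weights: np.ndarray | None = None,
) -> tuple[CoarseState, FitReport]:
    """Weighted least-squares fit of a fine state onto the basis (QR solve)."""
    theta = state.theta if isinstance(state, FineState) else np.asarray(state, float)
    time = state.time if isinstance(state, FineState) else 0.0
    n = sample.n
    if theta.shape != (n,):
        raise ValueError("fitting node set must match the sample")
    if basis.M > n:
        raise ValueError("need at least M sample points")
    weights = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
    Psi = design_matrix(basis, sample)
    Q, R, sw = _weighted_qr(Psi, weights)
    alpha, report = _fit(Q, R, sw, Psi, weights, theta)
    return CoarseState(alpha, basis, time), report


def lift(
    coarse: CoarseState | np.ndarray,
    basis: Basis2D | None = None,
    sample: HeterogeneitySample | None = None,
) -> FineState:
    """Evaluate the surface at the fitted nodes: theta_i = sum_k alpha_k psi^(k)."""
    if isinstance(coarse, CoarseState):
        alpha, basis, time = coarse.alpha, coarse.basis, coarse.time
    else:
        alpha, time = np.asarray(coarse, float), 0.0
        if basis is None:
            raise ValueError("basis required when lifting a bare vector")
    if sample is None:
        raise ValueError("sample required")
    return FineState(design_matrix(basis, sample) @ alpha, time)


class CoarsePCEModel:
    """Bundle of ensemble + basis + sample with cached fit factorization.

    All the equation-free algorithms talk to the coarse dynamics through
    this object: ``timestep`` is Phi_{tau,C} = R o Phi_{tau,F} o L and
    ``difference`` is F_tau(alpha) = Phi_{tau,C}(alpha) - alpha.
    """

    def __init__(
        self,
        ensemble: OscillatorEnsemble,
        basis: Basis2D,
        sample: HeterogeneitySample,
        weights: np.ndarray | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-8,
        method: str = "RK45",
    ):
        if sample.n != ensemble.N - 1:
            raise ValueError(
                "sample must cover the N-1 fitted nodes of the ensemble"
            )
        self.ensemble = ensemble
        self.basis = basis
        self.sample = sample
        self.rtol, self.atol, self.method = rtol, atol, method
        n = sample.n
        self.weights = (
            np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
        )
        self._Psi = design_matrix(basis, sample)
        self._Q, self._R, self._sw = _weighted_qr(self._Psi, self.weights)

    @property
    def M(self) -> int:
        return self.basis.M

    def with_coupling(self, K: float) -> "CoarsePCEModel":
        """Same basis/sample/factorization, different coupling strength."""
        clone = object.__new__(CoarsePCEModel)
        clone.__dict__.update(self.__dict__)
        clone.ensemble = self.ensemble.with_coupling(K)
        return clone

    def lift(self, alpha: np.ndarray, time: float = 0.0) -> FineState:
        return FineState(self._Psi @ np.asarray(alpha, float), time)

    def restrict(self, state: FineState | np.ndarray) -> np.ndarray:
        theta = state.theta if isinstance(state, FineState) else np.asarray(state, float)
        return solve_triangular(self._R, self._Q.T @ (self._sw * theta))

    def restrict_report(self, state: FineState | np.ndarray) -> tuple[np.ndarray, FitReport]:
        theta = state.theta if isinstance(state, FineState) else np.asarray(state, float)
        return _fit(self._Q, self._R, self._sw, self._Psi, self.weights, theta)

    def integrate(self, state: FineState, tau: float) -> FineState:
        return integrate_fine(
            self.ensemble, state, tau, rtol=self.rtol, atol=self.atol, method=self.method
        )

    def timestep(self, alpha: np.ndarray, tau: float, time: float = 0.0) -> np.ndarray:
        """One coarse timestep Phi_{tau,C}(alpha)."""
        if tau == 0:
            # R o L is the least-squares projection restricted to the basis
            # range, i.e. the identity on coefficient space.
            return self.restrict(self.lift(alpha, time))
        return self.restrict(self.integrate(self.lift(alpha, time), tau))

    def difference(self, alpha: np.ndarray, tau: float) -> np.ndarray:
        """Coarse difference map F_tau(alpha) = Phi_{tau,C}(alpha) - alpha."""
        if tau <= 0:
            raise ValueError("tau must be > 0 for the difference map")
        return self.timestep(alpha, tau) - np.asarray(alpha, float)


def coarse_timestep(
    alpha: CoarseState,
    tau: float,
    ensemble: OscillatorEnsemble,
    sample: HeterogeneitySample,
    **solver_kw,
) -> CoarseState:
    """Functional form of Phi_{tau,C} (builds a throwaway model)."""
    model = CoarsePCEModel(ensemble, alpha.basis, sample, **solver_kw)
    return CoarseState(model.timestep(alpha.alpha, tau, alpha.time), alpha.basis, alpha.time + tau)


def coarse_difference(
    alpha: CoarseState,
    tau: float,
    ensemble: OscillatorEnsemble,
    sample: HeterogeneitySample,
    **solver_kw,
) -> np.ndarray:
    model = CoarsePCEModel(ensemble, alpha.basis, sample, **solver_kw)
    return model.difference(alpha.alpha, tau)


# ---------------------------------------------------------------------------
# serialization


def save_coarse_states(path, times, alphas, basis_name: str = "basis") -> None:
    """CSV rows (time, alpha_1..alpha_M) with a header naming the basis."""
    alphas = np.atleast_2d(np.asarray(alphas, float))
    cols = ["time"] + [f"alpha_{k + 1}" for k in range(alphas.shape[1])]
    df = pd.DataFrame(np.column_stack([np.asarray(times, float), alphas]), columns=cols)
    with open(path, "w") as fh:
        fh.write(f"# basis: {basis_name}\n")
        df.to_csv(fh, index=False)


def load_coarse_states(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, comment="#")
    return df["time"].to_numpy(), df.drop(columns="time").to_numpy()
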