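"""Deterministic scenario construction for tests, examples and the CLI.

A :class:`FixtureSpec` fully determines a reproducible experiment: the
Chung-Lu network (or an explicit adjacency), the truncated-normal frequency
draw, the coupling strength, and the initial condition.  Named presets ship
the standard study conditions:

* ``base`` — N = 196, K = 1 (the base-case network size)
* ``fig2`` — N = 4000, K = 0.5, random initial cloud (surface-slaving demo)
* ``fig4`` — N = 300, K = 1, pmax = 6 (M = 28), tau = 0.05, h = 0.45 (CPI)
* ``fig8`` — N = 196, tau = 0.30 (continuation/bifurcation runs)

Sub-seeds are derived from the spec seed: network = seed, frequencies =
seed + 1000, initial condition = seed + 2000.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chaos_basis import HeterogeneitySample
from .network import ChungLuParams, NetworkRealization, generate_network
from .oscillators import FineState, FrequencySpec, OscillatorEnsemble, sample_frequencies

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "preset", "PRESETS"]


@dataclass(frozen=True)
class FixtureSpec:
    """Complete, reproducible description of a test scenario."""

    name: str
    N: int
    K: float = 1.0
    chung_lu: ChungLuParams | None = None
    adjacency: object | None = None  # explicit NetworkRealization
    frequency: FrequencySpec = field(default_factory=FrequencySpec)
    initial: str = "zeros"  # zeros | random | lift
    initial_alpha: np.ndarray | None = None
    seed: int = 0
    pmax: int = 6
    tau: float = 0.05
    h: float = 0.45


@dataclass
class Fixture:
    """Fully constructed scenario."""

    spec: FixtureSpec
    ensemble: OscillatorEnsemble
    state0: FineState
    sample: HeterogeneitySample


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the (ensemble, initial state, heterogeneity sample) triple."""
    if spec.adjacency is not None:
        net: NetworkRealization = spec.adjacency
    else:
        params = spec.chung_lu or ChungLuParams(N=spec.N, seed=spec.seed)
        if params.N != spec.N:
            raise ValueError("chung_lu.N must match spec.N")
        net = generate_network(replace(params, seed=spec.seed))
    omega = sample_frequencies(spec.frequency, spec.N, seed=spec.seed + 1000)
    ensemble = OscillatorEnsemble(network=net, omega_hat=omega, K=spec.K)

    if spec.initial == "zeros":
        theta = np.zeros(spec.N - 1)
    elif spec.initial == "random":
        # A uniform cloud of phases on [-pi, pi), moved to the co-moving frame.
        rng = np.random.default_rng(spec.seed + 2000)
        phi = rng.uniform(-np.pi, np.pi, size=spec.N)
        theta = (phi - phi.mean())[: spec.N - 1]
    elif spec.initial == "lift":
        if spec.initial_alpha is None:
            raise ValueError("initial='lift' needs initial_alpha")
        from .chaos_basis import apc_1d, tensor_basis
        from .coarse_map import lift as _lift

        sample = HeterogeneitySample.from_ensemble(ensemble)
        basis = tensor_basis(
            apc_1d(sample.omega, spec.pmax),
            apc_1d(sample.kappa, spec.pmax),
            spec.pmax,
        )
        theta = _lift(np.asarray(spec.initial_alpha, float), basis, sample).theta
    else:
        raise ValueError(f"unknown initial-condition recipe {spec.initial!r}")

    sample = HeterogeneitySample.from_ensemble(ensemble)
    return Fixture(spec, ensemble, FineState(theta), sample)


PRESETS: dict[str, FixtureSpec] = {
    "base": FixtureSpec(name="base", N=196, K=1.0),
    "fig2": FixtureSpec(name="fig2", N=4000, K=0.5, initial="random"),
    "fig4": FixtureSpec(name="fig4", N=300, K=1.0, initial="random",
                        pmax=6, tau=0.05, h=0.45),
    "fig8": FixtureSpec(name="fig8", N=196, K=1.0, tau=0.30),
}


def preset(name: str, seed: int = 0) -> FixtureSpec:
    """Look up a named preset, re-seeded."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return replace(spec, seed=seed)
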