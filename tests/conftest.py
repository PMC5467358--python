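"""Shared fixtures: small deterministic scenarios, built once per session."""

import numpy as np
import pytest

from netpce import (
    CoarsePCEModel,
    apc_1d,
    fine_steady_state,
    make_fixture,
    preset,
    tensor_basis,
)
from netpce.fixtures import FixtureSpec


@pytest.fixture(scope="session")
def base_fx():
    """The base study ensemble: N = 196 Chung-Lu network, K = 1, seed 0."""
    return make_fixture(preset("base", seed=0))


@pytest.fixture(scope="session")
def base_basis(base_fx):
    s = base_fx.sample
    return tensor_basis(apc_1d(s.omega, 6), apc_1d(s.kappa, 6), 6)


@pytest.fixture(scope="session")
def base_model(base_fx, base_basis):
    return CoarsePCEModel(base_fx.ensemble, base_basis, base_fx.sample)


@pytest.fixture(scope="session")
def base_steady(base_fx):
    return fine_steady_state(base_fx.ensemble)


@pytest.fixture(scope="session")
def small_fx():
    """A small (N = 40) ensemble for dense-Jacobian and transform tests."""
    return make_fixture(FixtureSpec(name="small", N=40, K=1.0, initial="random", seed=5))
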