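"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

from evoneuro.dynamics import EnsembleState
from evoneuro.landscapes import DirectionalLandscape
from evoneuro.networks import make_complete


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def directional_equilibrium_state(phi: np.ndarray, S: float = 2.0) -> EnsembleState:
    """Self-consistent marginal equilibrium of the firing probabilities for a
    fixed (frozen) weight matrix under a symmetric directional landscape.

    Computed by damped fixed-point iteration on the per-locus balance
    ``S*rho*(1-rho) = M(Y)*(2*rho-1)`` — a route independent of the ODE
    integrator, used to prepare equilibrium-adjacent states for the
    information tests.
    """
    n = phi.shape[0]
    topo = make_complete(n)
    rho = np.full(n, 0.7)
    for _ in range(400):
        x = 2.0 * rho - 1.0
        y = phi @ x
        m = 0.5 * np.exp(-(y**2))
        new = np.empty(n)
        for i in range(n):
            f = lambda r, mi=m[i]: S * r * (1.0 - r) + mi * (1.0 - 2.0 * r)
            new[i] = brentq(f, 0.5, 1.0 - 1e-15)
        rho = 0.5 * rho + 0.5 * new
    return EnsembleState(topo, rho, phi)


@pytest.fixture
def triangle_equilibrium():
    """n=3 complete circuit at equilibrium with moderate frozen weights."""
    phi = np.array(
        [
            [0.0, 0.30, 0.10],
            [0.30, 0.0, 0.25],
            [0.10, 0.25, 0.0],
        ]
    )
    return directional_equilibrium_state(phi, S=2.0), DirectionalLandscape(S=2.0)
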