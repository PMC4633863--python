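"""Tiny deterministic systems and brute-force oracles.

Everything here re-derives quantities by routes independent of the main code
paths — exhaustive enumeration of circuit configurations, fixed-step Euler
re-integration written directly against the model equations, and bisection on
the one-locus balance — so the main implementation can be validated without
external data. Oracles are deliberately slow and simple.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import product
import numpy as np

from .landscapes import (
    DirectionalLandscape,
    Landscape,
    StabilizingLandscape,
)
from .networks import Topology, make_explicit

__all__ = [
    "ToySystem",
    "enumerate_joint",
    "enumeration_fitness_terms",
    "euler_oracle",
    "exact_balance_root",
    "toy_triangle",
]

BALANCE_NO_ROOT = -1.0


@dataclass
class ToySystem:
    """A tiny (n <= 4) explicit system with oracle-computed expectations."""

    n: int
    edges: tuple
    rho0: tuple
    phi0: tuple  # row-major n*n
    landscape_kind: str
    landscape_params: dict
    expected: dict

    def topology(self) -> Topology:
        return make_explicit(self.n, self.edges)

    def landscape(self) -> Landscape:
        if self.landscape_kind == "directional":
            return DirectionalLandscape(**self.landscape_params)
        return StabilizingLandscape(**self.landscape_params)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ToySystem":
        return cls(**json.loads(text))


def enumerate_joint(rho: np.ndarray):
    """All 2^n signed configurations with their product-measure probabilities.

    Returns ``(states, probs)`` with ``states`` of shape (2^n, n) in {-1,+1}.
    Refuses n > 12 (oracle territory only).
    """
    rho = np.asarray(rho, dtype=float)
    n = len(rho)
    if n > 12:
        raise ValueError(f"enumeration limited to n <= 12, got {n}")
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("firing probabilities must lie in [0, 1]")
    states = np.array(list(product((-1, 1), repeat=n)), dtype=float)
    g = (states + 1) / 2
    probs = np.prod(np.where(g == 1, rho, 1 - rho), axis=1)
    return states, probs


def _w_of_state(landscape: Landscape, x: np.ndarray) -> float:
    n = len(x)
    g = (x + 1) / 2
    if isinstance(landscape, DirectionalLandscape):
        s = landscape.s_vector(n)
        return float(np.exp(np.sum(s * (g - 1))))
    omega = float(g.sum())
    return float(np.exp(-landscape.beta * (landscape.T - omega) ** 2))


def enumeration_fitness_terms(landscape: Landscape, rho: np.ndarray):
    """Brute-force ``(W_i, Wbar_i)`` by summing over all 2^n configurations."""
    rho = np.asarray(rho, dtype=float)
    n = len(rho)
    states, probs = enumerate_joint(rho)
    w = np.array([_w_of_state(landscape, x) for x in states])
    wbar = float(np.sum(probs * w))
    w_on = np.empty(n)
    for i in range(n):
        on = states[:, i] == 1
        mass = probs[on].sum()
        w_on[i] = float(np.sum(probs[on] * w[on]) / mass) if mass > 0 else 0.0
    return w_on, np.full(n, wbar)


def euler_oracle(
    rho0: np.ndarray,
    phi0: np.ndarray,
    adjacency: np.ndarray,
    landscape: Landscape,
    lam: float,
    t_max: float,
    dt: float = 0.01,
    selection: str = "approx",
    max_retries: int = 6,
):
    """Fixed-step explicit Euler integration written directly from the model
    equations (selection + symmetric switching + Oja learning), independent
    of the adaptive-solver code path.

    Halves ``dt`` and restarts if the firing probabilities leave [0, 1] by
    more than 1e-9. Returns ``(rho, phi)`` at ``t_max``.
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    for _attempt in range(max_retries):
        rho = np.asarray(rho0, dtype=float).copy()
        phi = np.asarray(phi0, dtype=float).copy()
        steps = int(np.ceil(t_max / dt))
        ok = True
        for _ in range(steps):
            x = 2.0 * rho - 1.0
            y = phi @ x
            m = 0.5 * np.exp(-(y**2))
            if selection == "approx":
                if isinstance(landscape, DirectionalLandscape):
                    s = landscape.s_vector(len(rho))
                else:
                    omega_bar = rho.sum()
                    s = 2.0 * landscape.beta * (landscape.T - omega_bar)
                    if landscape.include_variance:
                        s = s + landscape.beta * (2.0 * rho - 1.0)
                sel = rho * (1.0 - rho) * s
            else:  # exact, via enumeration (tiny n only)
                w_on, wbar = enumeration_fitness_terms(landscape, rho)
                sel = rho * (w_on - wbar) / wbar
            drho = sel + m * (1.0 - 2.0 * rho)
            dphi = lam * (np.outer(y, x) - (y**2)[:, None] * phi)
            dphi[~adjacency] = 0.0
            rho = rho + dt * drho
            phi = phi + dt * dphi
            if np.any(rho < -1e-9) or np.any(rho > 1 + 1e-9):
                ok = False
                break
            rho = np.clip(rho, 0.0, 1.0)
        if ok:
            return rho, phi
        dt /= 2.0
    raise RuntimeError("Euler oracle unstable even after halving dt")


def exact_balance_root(S: float, M: float) -> float:
    """Mutation–selection balance of a single locus under constant gradient
    ``S`` and constant switching ``M``: the root of
    ``S*rho*(1-rho) + M*(1-2*rho)`` in [1/2, 1], found by bisection.

    Boundary cases: ``M = 0`` gives 1 (pure selection fixes the locus),
    ``S = 0`` gives 1/2 (pure symmetric switching). Returns the sentinel
    ``BALANCE_NO_ROOT`` if no sign change exists (transcription
    inconsistency guard).
    """
    if S < 0 or M < 0:
        raise ValueError("S and M must be non-negative")
    if S == 0:
        return 0.5
    if M == 0:
        return 1.0

    def f(r):
        return S * r * (1.0 - r) + M * (1.0 - 2.0 * r)

    lo, hi = 0.5, 1.0
    if f(lo) <= 0 or f(hi) >= 0:
        return BALANCE_NO_ROOT
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def toy_triangle(seed: int = 0, landscape_kind: str = "directional") -> ToySystem:
    """Three fully connected loci with small random initial conditions."""
    rng = np.random.default_rng(seed)
    n = 3
    edges = ((0, 1), (0, 2), (1, 2))
    rho0 = rng.uniform(0.0, 0.01, n)
    adj = np.zeros((n, n), dtype=bool)
    for (i, j) in edges:
        adj[i, j] = adj[j, i] = True
    phi0 = np.zeros((n, n))
    phi0[adj] = rng.uniform(0.0, 0.01, int(adj.sum()))
    if landscape_kind == "directional":
        params = {"S": 2.0}
    else:
        params = {"beta": 0.5, "T": 2}
    return ToySystem(
        n=n,
        edges=edges,
        rho0=tuple(rho0),
        phi0=tuple(phi0.ravel()),
        landscape_kind=landscape_kind,
        landscape_params=params,
        expected={},
    )
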