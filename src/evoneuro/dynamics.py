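"""Coupled selection–mutation and Oja-learning dynamics on a fixed topology.

The state of the infinite ensemble of circuits is a firing-probability vector
``rho`` (one entry per neuronal locus; the fraction of circuits in which that
locus fires) and a directed weight matrix ``phi`` supported on the topology
(two independent weights per undirected synapse). Writing the mean signed
state ``Xbar_j = 2*rho_j - 1``, the mean input activity of locus ``i`` is

    Y_i = sum_j phi_ij * Xbar_j                      (variance terms neglected)

and the switching probability — the state-dependent analogue of a mutation
rate — follows the activity rule

    M_i = (1/2) * exp(-Y_i**2),

so a naive neuron (zero net input) switches with probability ~1/2 while a
neuron driven hard either way is frozen in its state. The dynamics are

    drho_i/dt = rho_i*(1 - rho_i)*s_i + M_i*(1 - 2*rho_i)
    dphi_ij/dt = lambda * Y_i * (Xbar_j - Y_i * phi_ij)      (Oja's rule)

with ``s_i`` the per-locus selection differential: the first term is the
replicator (hill-climbing) term, the second drives ``rho`` toward 1/2 at rate
``M_i`` (symmetric switching), and Oja's rule is Hebbian covariance learning
with Euclidean weight normalization (the incoming weight norm of a driven
neuron tends to 1). Two selection backends exist: the default first-order
coefficients (``landscapes.selection_coefficients``) and the exact replicator
term ``rho*(1-rho)*(W_on - W_off)/Wbar`` from the product-measure conditional
fitness (``backend="exact"``, the oracle for the first).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .landscapes import (
    DirectionalLandscape,
    Landscape,
    conditional_fitness,
    mean_fitness,
    selection_coefficients,
)
from .networks import Topology

__all__ = [
    "EnsembleState",
    "DynamicsParams",
    "Trajectory",
    "random_initial_state",
    "mean_activity",
    "switching_probability",
    "rho_rate",
    "phi_rate",
    "integrate",
    "convergence_time",
]

CONVERGENCE_SENTINEL = -1.0


@dataclass
class EnsembleState:
    """Firing probabilities and directed synaptic weights on a topology."""

    topology: Topology
    rho: np.ndarray
    phi: np.ndarray

    def __post_init__(self):
        n = self.topology.n
        self.rho = np.asarray(self.rho, dtype=float).copy()
        self.phi = np.asarray(self.phi, dtype=float).copy()
        if self.rho.shape != (n,):
            raise ValueError(f"rho must have shape ({n},), got {self.rho.shape}")
        if self.phi.shape != (n, n):
            raise ValueError(f"phi must have shape ({n},{n}), got {self.phi.shape}")
        if np.any((self.rho < 0) | (self.rho > 1)):
            raise ValueError("firing probabilities must lie in [0, 1]")
        off = ~self.topology.adjacency()
        if np.any(self.phi[off] != 0.0):
            raise ValueError("phi must be zero off the topology")

    def copy(self) -> "EnsembleState":
        return EnsembleState(self.topology, self.rho.copy(), self.phi.copy())


@dataclass
class DynamicsParams:
    """Parameters of the coupled ODE system.

    lambda (``lam``) is the Hebbian learning rate; the intended regime is
    learning slower than selection (``lam < S``) — violating it only warns.
    Initial conditions for both ``rho`` and ``phi`` are U[init_low, init_high]
    per locus / per directed weight.
    """

    lam: float = 0.001
    t_max: float = 10_000.0
    rtol: float = 1e-8
    atol: float = 1e-10
    seed: Optional[int] = None
    init_low: float = 0.0
    init_high: float = 0.01
    allow_negative_weights: bool = True
    backend: str = "approx"  # "approx" (first order) or "exact"
    method: str = "LSODA"
    n_out: int = 200
    conv_tol: float = 1e-6

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"learning rate must be >= 0, got {self.lam}")
        if self.backend not in ("approx", "exact"):
            raise ValueError(f"unknown backend {self.backend!r}")


def random_initial_state(
    topology: Topology,
    rng: np.random.Generator,
    low: float = 0.0,
    high: float = 0.01,
) -> EnsembleState:
    """Uniform-random naive initial conditions on a topology: every firing
    probability and every directed weight drawn from U[low, high]."""
    n = topology.n
    rho = rng.uniform(low, high, size=n)
    adj = topology.adjacency()
    phi = np.zeros((n, n))
    phi[adj] = rng.uniform(low, high, size=int(adj.sum()))
    return EnsembleState(topology, rho, phi)


# -- elementary rates ----------------------------------------------------------

def mean_activity(state: EnsembleState, i: Optional[int] = None):
    """Mean input activity ``Y_i = sum_j phi_ij * (2*rho_j - 1)``."""
    y = state.phi @ (2.0 * state.rho - 1.0)
    return y if i is None else float(y[i])


def switching_probability(y):
    """Activity rule ``M = (1/2) * exp(-Y^2)``: M in (0, 1/2], ~1/2 for a
    naive neuron, asymptotically 0 as the input drive grows."""
    y = np.asarray(y, dtype=float)
    m = 0.5 * np.exp(-(y**2))
    return float(m) if m.ndim == 0 else m


def _selection_term(rho: np.ndarray, landscape: Landscape, backend: str) -> np.ndarray:
    if backend == "approx":
        return rho * (1.0 - rho) * selection_coefficients(landscape, rho)
    w_on, w_off = conditional_fitness(landscape, rho)
    wbar = rho * w_on + (1.0 - rho) * w_off
    return rho * (1.0 - rho) * (w_on - w_off) / wbar


def rho_rate(
    state: EnsembleState, landscape: Landscape, backend: str = "approx"
) -> np.ndarray:
    """Time derivative of the firing probabilities (selection + switching)."""
    rho = state.rho
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("state has firing probabilities outside [0, 1]")
    m = switching_probability(mean_activity(state))
    return _selection_term(rho, landscape, backend) + m * (1.0 - 2.0 * rho)


def phi_rate(
    state: EnsembleState, lam: float, allow_negative_weights: bool = True
) -> np.ndarray:
    """Oja-rule weight derivative on the mean activities; zero off-topology."""
    adj = state.topology.adjacency()
    xbar = 2.0 * state.rho - 1.0
    y = state.phi @ xbar
    dphi = lam * (np.outer(y, xbar) - (y**2)[:, None] * state.phi)
    dphi[~adj] = 0.0
    if not allow_negative_weights:
        dphi = np.where((state.phi > 0) | (dphi > 0), dphi, 0.0)
    return dphi


# -- trajectories --------------------------------------------------------------

@dataclass
class Trajectory:
    """Time series of the ensemble dynamics at the requested output times."""

    t: np.ndarray                 # (T,)
    rho: np.ndarray               # (T, n)
    phi: np.ndarray               # (T, n, n)
    M: np.ndarray                 # (T, n)
    fitness: np.ndarray           # (T,) exact ensemble mean fitness
    topology: Topology
    landscape: Landscape = field(repr=False, default=None)
    final_rate_norm: float = np.nan
    converged: bool = True

    @property
    def final_state(self) -> EnsembleState:
        return EnsembleState(self.topology, np.clip(self.rho[-1], 0, 1), self.phi[-1])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (t, variable, index, value) for rho and M."""
        rows = []
        for name, arr in (("rho", self.rho), ("M", self.M)):
            for j in range(arr.shape[1]):
                rows.append(
                    pd.DataFrame(
                        {"t": self.t, "variable": name, "index": j, "value": arr[:, j]}
                    )
                )
        rows.append(
            pd.DataFrame(
                {
                    "t": self.t,
                    "variable": "fitness",
                    "index": -1,
                    "value": self.fitness,
                }
            )
        )
        return pd.concat(rows, ignore_index=True)

    def write(self, outdir) -> None:
        """CSV trajectory + final weight matrix + JSON summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_long_frame().to_csv(outdir / "trajectory.csv", index=False)
        np.savetxt(outdir / "weights_final.csv", self.phi[-1], delimiter=",")
        summary = {
            "final_rho": self.rho[-1].tolist(),
            "final_phi_norm": float(np.linalg.norm(self.phi[-1])),
            "final_fitness": float(self.fitness[-1]),
            "final_rate_norm": float(self.final_rate_norm),
            "converged": bool(self.converged),
            "convergence_time_90": convergence_time(self, 0.9),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def _output_times(t_max: float, n_out: int) -> np.ndarray:
    t0 = max(t_max * 1e-4, 1e-3)
    return np.concatenate([[0.0], np.geomspace(t0, t_max, n_out)])


def _selection_scale(landscape: Landscape) -> float:
    if isinstance(landscape, DirectionalLandscape):
        return float(np.max(np.abs(np.atleast_1d(landscape.S))))
    return 2.0 * landscape.beta * landscape.T


def integrate(
    state0: EnsembleState,
    params: DynamicsParams,
    landscape: Landscape,
    topology: Optional[Topology] = None,
) -> Trajectory:
    """Integrate the ``n + k`` coupled ODEs to ``t_max``.

    Output times are log-spaced (the dynamics unfold on log time). The final
    rate norm is reported as a convergence diagnostic; failing to converge is
    flagged on the trajectory, not fatal.
    """
    topology = topology if topology is not None else state0.topology
    if topology.edges != state0.topology.edges or topology.n != state0.topology.n:
        raise ValueError("state and topology disagree")
    n = topology.n
    adj = topology.adjacency()
    mask = adj.ravel()
    lam = params.lam

    s_scale = _selection_scale(landscape)
    if lam > 0 and lam >= s_scale:
        warnings.warn(
            f"learning rate lambda={lam} is not slower than selection "
            f"(scale {s_scale:.3g}); outside the intended regime",
            stacklevel=2,
        )

    def rhs(_t, y):
        rho = np.clip(y[:n], 0.0, 1.0)
        phi = np.zeros(n * n)
        phi[mask] = y[n:]
        phi = phi.reshape(n, n)
        xbar = 2.0 * rho - 1.0
        yact = phi @ xbar
        m = 0.5 * np.exp(-(yact**2))
        drho = _selection_term(rho, landscape, params.backend) + m * (1.0 - 2.0 * rho)
        # keep the flow inward at the boundary (floating-point guard)
        drho = np.where((y[:n] <= 0.0) & (drho < 0), 0.0, drho)
        drho = np.where((y[:n] >= 1.0) & (drho > 0), 0.0, drho)
        dphi = lam * (np.outer(yact, xbar) - (yact**2)[:, None] * phi)
        if not params.allow_negative_weights:
            dphi = np.where((phi > 0) | (dphi > 0), dphi, 0.0)
        return np.concatenate([drho, dphi.ravel()[mask]])

    y0 = np.concatenate([state0.rho, state0.phi.ravel()[mask]])
    t_eval = _output_times(params.t_max, params.n_out)
    sol = solve_ivp(
        rhs,
        (0.0, params.t_max),
        y0,
        method=params.method,
        t_eval=t_eval,
        rtol=params.rtol,
        atol=params.atol,
    )
    if not sol.success:
        warnings.warn(f"ODE solver stopped early: {sol.message}", stacklevel=2)

    nt = sol.y.shape[1]
    rho_t = np.clip(sol.y[:n].T, 0.0, 1.0)
    phi_t = np.zeros((nt, n * n))
    phi_t[:, mask] = sol.y[n:].T
    phi_t = phi_t.reshape(nt, n, n)
    xbar_t = 2.0 * rho_t - 1.0
    y_t = np.einsum("tij,tj->ti", phi_t, xbar_t)
    m_t = 0.5 * np.exp(-(y_t**2))
    fit_t = np.array([mean_fitness(landscape, r) for r in rho_t])

    rate = rhs(sol.t[-1], sol.y[:, -1])
    rate_norm = float(np.linalg.norm(rate, ord=np.inf))
    return Trajectory(
        t=sol.t,
        rho=rho_t,
        phi=phi_t,
        M=m_t,
        fitness=fit_t,
        topology=topology,
        landscape=landscape,
        final_rate_norm=rate_norm,
        converged=bool(rate_norm < params.conv_tol),
    )


def convergence_time(trajectory: Trajectory, fitness_fraction: float = 0.9) -> float:
    """First time at which the (running-max smoothed) mean fitness exceeds
    ``fitness_fraction`` of its final value; sentinel -1.0 if never."""
    fit = np.maximum.accumulate(trajectory.fitness)
    target = fitness_fraction * fit[-1]
    hit = np.nonzero(fit >= target)[0]
    if len(hit) == 0:
        return CONVERGENCE_SENTINEL
    return float(trajectory.t[hit[0]])
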