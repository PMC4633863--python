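"""Mutual information carried by a single synapse.

The information content of synapse (i, j) is the mutual information between
the binary states of the two neurons across the ensemble. It is computed by a
conditioning protocol: fix neuron ``j`` on (``rho_j = 1``) or off
(``rho_j = 0``), recompute the activity and hence the switching probability
``M_i|j`` of neuron ``i`` with all weights frozen and every other locus held
at its current firing probability, and relax locus ``i`` alone to its
equilibrium. The two conditional firing probabilities, together with the
marginal ``rho_j``, give the joint table from which the mutual information is
assembled. A synapse with ``phi_ij = 0`` transmits nothing: conditioning does
not move the activity, so ``H_ij = 0`` identically.

Two evaluation paths exist: the exact conditional-dynamics computation and a
closed-form quadratic (small-weight) approximation in which the conditional
shift is linearized through the equilibrium gain ``d rho*/d M``; the latter
exposes the characteristic ``H proportional to phi**2`` scaling and is the
cheap path the structural-plasticity loop uses.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .dynamics import EnsembleState, mean_activity, switching_probability
from .landscapes import (
    DirectionalLandscape,
    Landscape,
    selection_coefficients,
)

__all__ = [
    "conditional_firing",
    "mutual_information_exact",
    "mutual_information_approx",
    "information_matrix",
]

LOG_BASES = {"bits": 2.0, "nats": np.e}


def _locus_rate_factory(state: EnsembleState, landscape: Landscape, i: int, m_i: float):
    """Scalar rate function f(rho_i) for locus i with frozen weights, frozen
    switching probability and all other loci held at their ensemble values."""
    rho_others = state.rho.copy()

    def f(r: float) -> float:
        rho = rho_others.copy()
        rho[i] = r
        s_i = selection_coefficients(landscape, rho)[i]
        return r * (1.0 - r) * s_i + m_i * (1.0 - 2.0 * r)

    return f


def _equilibrium_near(f, rho_start: float) -> float:
    """Root of the scalar locus rate nearest to ``rho_start``.

    The stabilizing landscape's disruptive variance term admits several
    equilibria; the assessment relaxes the locus from its current state, so
    the nearest stable root is the relevant one.
    """
    grid = np.linspace(0.0, 1.0, 2001)
    vals = np.array([f(g) for g in grid])
    roots = []
    for k in range(len(grid) - 1):
        a, b = vals[k], vals[k + 1]
        if a == 0.0:
            roots.append(grid[k])
        elif a * b < 0:
            roots.append(brentq(f, grid[k], grid[k + 1]))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    if not roots:  # rate one-signed: flow hits the nearer absorbing boundary
        return 1.0 if vals[len(grid) // 2] > 0 else 0.0
    # keep only attracting roots (rate decreasing through zero) when any exist
    stable = [r for r in roots if f(min(r + 1e-6, 1.0)) <= 0.0 <= f(max(r - 1e-6, 0.0))]
    cand = stable if stable else roots
    return min(cand, key=lambda r: abs(r - rho_start))


def conditional_firing(
    state: EnsembleState,
    landscape: Landscape,
    i: int,
    j: int,
    x_j: Literal["on", "off"],
) -> float:
    """Equilibrium firing probability of locus ``i`` given neuron ``j``
    clamped on or off, with all weights frozen.

    For a non-edge (or ``phi_ij = 0``) the conditioning has no effect and the
    marginal equilibrium is returned.
    """
    if x_j not in ("on", "off"):
        raise ValueError(f"x_j must be 'on' or 'off', got {x_j!r}")
    xbar_j = 1.0 if x_j == "on" else -1.0
    y_i = mean_activity(state, i)
    # replace j's mean contribution by the clamped state
    y_cond = y_i + state.phi[i, j] * (xbar_j - (2.0 * state.rho[j] - 1.0))
    m_cond = switching_probability(y_cond)
    f = _locus_rate_factory(state, landscape, i, m_cond)
    return _equilibrium_near(f, float(state.rho[i]))


def _mi_from_table(p_on_j: float, p_i_on: float, p_i_off: float, units: str) -> float:
    """Mutual information of the binary pair from P(x_j=on) and the two
    conditionals P(x_i=on | x_j)."""
    base = LOG_BASES[units]
    pj = np.array([p_on_j, 1.0 - p_on_j])
    pi_cond = np.array([p_i_on, p_i_off])
    joint = np.empty((2, 2))  # [x_i, x_j]
    joint[0] = pi_cond * pj
    joint[1] = (1.0 - pi_cond) * pj
    pi = joint.sum(axis=1)
    h = 0.0
    for a in range(2):
        for b in range(2):
            if joint[a, b] > 0 and pi[a] > 0 and pj[b] > 0:
                h += joint[a, b] * np.log(joint[a, b] / (pi[a] * pj[b]))
    return max(h / np.log(base), 0.0)


def mutual_information_exact(
    state: EnsembleState,
    landscape: Landscape,
    i: int,
    j: int,
    units: str = "bits",
) -> float:
    """Synaptic mutual information via the conditional-dynamics protocol."""
    p_on = conditional_firing(state, landscape, i, j, "on")
    p_off = conditional_firing(state, landscape, i, j, "off")
    return _mi_from_table(float(state.rho[j]), p_on, p_off, units)


def _stabilizing_ds_drho(landscape: Landscape) -> float:
    """d s_i / d rho_i of the first-order selection coefficient."""
    if isinstance(landscape, DirectionalLandscape):
        return 0.0
    # -2*beta from the mean-distance term, +2*beta from the variance term
    return 0.0 if landscape.include_variance else -2.0 * landscape.beta


def mutual_information_approx(
    state: EnsembleState,
    landscape: Landscape,
    i: int,
    j: int,
    units: str = "bits",
) -> float:
    """Closed-form quadratic approximation of the synaptic information.

    Linearizes the conditional equilibrium shift around the current state:
    clamping ``j`` moves the activity of ``i`` by ``+/- phi_ij`` around its
    mean, which moves ``M_i`` by ``delta_M`` and the equilibrium by
    ``delta_rho = (d rho*/d M) * delta_M`` with the gain obtained from the
    implicit derivative of the locus rate. For weakly coupled binary
    variables ``H ~ rho_j(1-rho_j) * delta_rho^2 / (2 ln2 rho_i(1-rho_i))``,
    which is proportional to ``phi_ij**2`` for small weights, vanishes at
    ``phi_ij = 0`` and is suppressed for a randomly spiking focal neuron.
    """
    base = LOG_BASES[units]
    rho_i = float(state.rho[i])
    rho_j = float(state.rho[j])
    phi_ij = float(state.phi[i, j])
    if phi_ij == 0.0:
        return 0.0
    vi = rho_i * (1.0 - rho_i)
    vj = rho_j * (1.0 - rho_j)
    if vi <= 0.0 or vj <= 0.0:
        return 0.0
    y_i = mean_activity(state, i)
    xbar_j = 2.0 * rho_j - 1.0
    m_on = switching_probability(y_i + phi_ij * (1.0 - xbar_j))
    m_off = switching_probability(y_i + phi_ij * (-1.0 - xbar_j))
    delta_m = m_on - m_off
    m_i = switching_probability(y_i)
    s_i = float(selection_coefficients(landscape, state.rho)[i])
    # f(rho) = rho(1-rho) s(rho) + M (1-2 rho); implicit gain drho*/dM
    f_rho = (1.0 - 2.0 * rho_i) * s_i + vi * _stabilizing_ds_drho(landscape) - 2.0 * m_i
    f_m = 1.0 - 2.0 * rho_i
    if f_rho == 0.0:
        return 0.0
    delta_rho = -f_m / f_rho * delta_m
    h_nats = vj * delta_rho**2 / (2.0 * vi)
    return h_nats / np.log(base)


def information_matrix(
    state: EnsembleState,
    landscape: Landscape,
    method: str = "approx",
    units: str = "bits",
) -> np.ndarray:
    """Per-directed-synapse information ``H_ij`` (zero off-topology)."""
    fn = mutual_information_approx if method == "approx" else mutual_information_exact
    n = state.topology.n
    h = np.zeros((n, n))
    for (a, b) in state.topology.edges:
        h[a, b] = fn(state, landscape, a, b, units=units)
        h[b, a] = fn(state, landscape, b, a, units=units)
    return h


def write_information_csv(
    state: EnsembleState,
    landscape: Landscape,
    path,
    method: str = "approx",
    units: str = "bits",
) -> None:
    """Edge-list CSV of synaptic information: columns i, j, phi_ij, H_ij
    (one row per directed weight on the topology)."""
    import csv

    fn = mutual_information_approx if method == "approx" else mutual_information_exact
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["i", "j", "phi_ij", "H_ij"])
        for (a, b) in state.topology.edges:
            for (i, j) in ((a, b), (b, a)):
                writer.writerow(
                    [i, j, state.phi[i, j], fn(state, landscape, i, j, units=units)]
                )


def edge_information(
    state: EnsembleState,
    landscape: Landscape,
    i: int,
    j: int,
    method: str = "approx",
    units: str = "bits",
) -> float:
    """Information of the undirected synapse {i, j}: mean of the two directed
    assessments (the conditioning protocol is directional; the synapse is not)."""
    fn = mutual_information_approx if method == "approx" else mutual_information_exact
    return 0.5 * (
        fn(state, landscape, i, j, units=units) + fn(state, landscape, j, i, units=units)
    )
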