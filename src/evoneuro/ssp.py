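"""Structural synaptic plasticity: Metropolis–Hastings search over topologies.

Each step builds one proposal topology from three neuroscience-inspired
moves, re-equilibrates the learning dynamics on it, and accepts or rejects
the rewired circuit by a Metropolis rule on the cost-penalized equilibrium
fitness:

* **synaptogenesis** — one unconnected pair is drawn with probability
  proportional to the co-firing product ``rho_i * rho_j``, so pairs that are
  both likely to spike tend to gain a synapse;
* **disbanding** — an existing synapse is removed with probability
  ``R(H) = r_max * exp(-gamma * H)``, a decreasing function of its
  information content ``H`` (informative synapses persist);
* **random rewiring** — with a small probability ``u`` an existing edge and a
  missing edge are exchanged uniformly at random (edge count preserved).

By default one circuit modification is attempted per step (``scheduling=
"single"``); the ``"joint"`` variant applies a synaptogenesis draw plus the
full independent disbanding sweep in one proposal.

Acceptance: a fitter topology always spreads; otherwise it spreads with a
probability that decays in the fitness deficit — by default the Metropolis
ratio ``W_new / W_old`` (equivalently ``exp(ln W_new - ln W_old)``), which
keeps its discrimination when synapse costs drive ``W`` toward zero; the
additive variant ``exp(W_new - W_old)`` is available as an option. Either
way, occasionally accepting worse topologies lets the ensemble escape
impasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dynamics import (
    DynamicsParams,
    EnsembleState,
    integrate,
    random_initial_state,
)
from .information import mutual_information_approx
from .landscapes import Landscape, apply_synapse_cost, mean_fitness
from .networks import Topology

__all__ = [
    "SSPParams",
    "SSPRecord",
    "propose_synaptogenesis",
    "propose_disbanding",
    "propose_random_rewire",
    "disbanding_probability",
    "metropolis_accept",
    "run_ssp",
    "sample_topologies",
]


@dataclass
class SSPParams:
    """Parameters of the structural-plasticity loop.

    ``r_max`` and ``gamma`` parameterize the information-gated disbanding
    probability ``R(H) = r_max * exp(-gamma * H)``: ``r_max`` is the removal
    probability of a synapse carrying no information, and ``1/gamma`` is the
    information scale (in the units of ``H``, bits by default) at which a
    synapse becomes safe from removal.
    """

    n_steps: int = 2000
    k_cost: float = 0.0
    u: float = 0.01
    r_max: float = 1.0
    gamma: float = 50.0
    scheduling: str = "single"  # one modification per step, or "joint" sweep
    weight_policy: str = "reset-all"  # or "keep-and-randomize-new"
    reset_rho: bool = False
    seed: Optional[int] = None
    inner_t_max: float = 2000.0
    inner_rtol: float = 1e-6
    inner_atol: float = 1e-8
    acceptance: str = "ratio"  # or "literal-exp"

    def __post_init__(self):
        if not 0.0 <= self.u <= 1.0:
            raise ValueError(f"rewire probability u must be in [0,1], got {self.u}")
        if self.k_cost < 0:
            raise ValueError(f"synapse cost must be >= 0, got {self.k_cost}")
        if self.n_steps < 1:
            raise ValueError(f"need at least one step, got {self.n_steps}")
        if self.weight_policy not in ("reset-all", "keep-and-randomize-new"):
            raise ValueError(f"unknown weight policy {self.weight_policy!r}")
        if self.acceptance not in ("ratio", "literal-exp"):
            raise ValueError(f"unknown acceptance rule {self.acceptance!r}")
        if self.scheduling not in ("single", "joint"):
            raise ValueError(f"unknown scheduling {self.scheduling!r}")


@dataclass
class SSPRecord:
    """One Metropolis–Hastings step of the topology chain."""

    step: int
    moves: Tuple[str, ...]
    d: int
    fitness: float          # cost-penalized equilibrium fitness of the proposal
    accepted: bool
    current_fitness: float  # after accept/reject
    running_best: float
    topology: Topology = field(repr=False, default=None)
    state: EnsembleState = field(repr=False, default=None)


# -- proposal moves ------------------------------------------------------------

def propose_synaptogenesis(
    state: EnsembleState, topology: Topology, rng: np.random.Generator
) -> Optional[Tuple[int, int]]:
    """Candidate new synapse among unconnected pairs, drawn with probability
    proportional to the co-firing product ``rho_i * rho_j``; ``None`` on a
    complete graph. Falls back to uniform when all weights vanish."""
    non_edges = topology.non_edges()
    if not non_edges:
        return None
    w = np.array([state.rho[i] * state.rho[j] for (i, j) in non_edges])
    total = w.sum()
    if total <= 0.0:
        p = np.full(len(non_edges), 1.0 / len(non_edges))
    else:
        p = w / total
    k = rng.choice(len(non_edges), p=p)
    return non_edges[k]


def disbanding_probability(h: float, r_max: float = 1.0, gamma: float = 50.0) -> float:
    """Removal probability of a synapse with information ``h``:
    ``R(H) = r_max * exp(-gamma * H)``, maximal at H = 0 and monotone
    decreasing in H."""
    if h < 0:
        raise ValueError(f"synaptic information must be >= 0, got {h}")
    return float(r_max * np.exp(-gamma * h))


def propose_disbanding(
    state: EnsembleState,
    topology: Topology,
    rng: np.random.Generator,
    landscape: Landscape = None,
    r_max: float = 1.0,
    gamma: float = 50.0,
) -> List[Tuple[int, int]]:
    """Edges flagged for removal: each existing synapse independently with
    probability ``R(H_ij)``; empty list for an empty graph."""
    removals = []
    for (i, j) in topology.edges:
        if landscape is None:
            h = 0.0
        else:
            h = 0.5 * (
                mutual_information_approx(state, landscape, i, j)
                + mutual_information_approx(state, landscape, j, i)
            )
        if rng.random() < disbanding_probability(h, r_max, gamma):
            removals.append((i, j))
    return removals


def _uniform_rewire(
    topology: Topology, rng: np.random.Generator
) -> Optional[Tuple[Tuple[int, int], Tuple[int, int]]]:
    edges = topology.edges
    non_edges = topology.non_edges()
    if not edges or not non_edges:
        return None
    drop = edges[rng.integers(len(edges))]
    add = non_edges[rng.integers(len(non_edges))]
    return drop, add


def propose_random_rewire(
    topology: Topology, u: float, rng: np.random.Generator
) -> Optional[Tuple[Tuple[int, int], Tuple[int, int]]]:
    """With probability ``u``: (edge to remove, edge to add), both uniform;
    ``None`` otherwise or when the graph is empty or complete."""
    if rng.random() >= u:
        return None
    return _uniform_rewire(topology, rng)


def metropolis_accept(
    w_new: float, w_old: float, rng: np.random.Generator
) -> bool:
    """Accept with probability ``min(1, exp(W_new - W_old))``."""
    if w_new >= w_old:
        return True
    return rng.random() < np.exp(w_new - w_old)


# -- the SSP loop --------------------------------------------------------------

def _edge_information(state, landscape, i, j) -> float:
    return 0.5 * (
        mutual_information_approx(state, landscape, i, j)
        + mutual_information_approx(state, landscape, j, i)
    )


def _assemble_proposal(
    state: EnsembleState,
    topology: Topology,
    landscape: Landscape,
    params: SSPParams,
    rng: np.random.Generator,
) -> Tuple[Tuple[str, ...], Topology]:
    """One proposal topology.

    ``single`` scheduling (default) makes one circuit modification per step:
    with probability ``u`` a random rewire, otherwise a fair choice between a
    synaptogenesis draw and a disbanding attempt (one edge uniformly at
    random, removed with probability ``R(H)``). ``joint`` scheduling applies
    one synaptogenesis draw, the full disbanding sweep and an occasional
    rewire to a single proposal.
    """
    moves: List[str] = []
    proposal = topology
    if params.scheduling == "single":
        if rng.random() < params.u:
            rewire = _uniform_rewire(proposal, rng)
            if rewire is not None:
                proposal = proposal.with_edges(remove=[rewire[0]], add=[rewire[1]])
                moves.append("rewire")
        elif rng.random() < 0.5:
            grow = propose_synaptogenesis(state, proposal, rng)
            if grow is not None:
                proposal = proposal.with_edges(add=[grow])
                moves.append("synaptogenesis")
        else:
            if proposal.edges:
                k = rng.integers(len(proposal.edges))
                (i, j) = proposal.edges[k]
                h = _edge_information(state, landscape, i, j)
                if rng.random() < disbanding_probability(h, params.r_max, params.gamma):
                    proposal = proposal.with_edges(remove=[(i, j)])
                    moves.append("disbanding")
        return tuple(moves), proposal

    grow = propose_synaptogenesis(state, proposal, rng)
    if grow is not None:
        proposal = proposal.with_edges(add=[grow])
        moves.append("synaptogenesis")
    drop = propose_disbanding(
        state, topology, rng, landscape, params.r_max, params.gamma
    )
    if drop:
        proposal = proposal.with_edges(remove=drop)
        moves.append("disbanding")
    rewire = propose_random_rewire(proposal, params.u, rng)
    if rewire is not None:
        proposal = proposal.with_edges(remove=[rewire[0]], add=[rewire[1]])
        moves.append("rewire")
    return tuple(moves), proposal

def _proposal_weights(
    topology: Topology,
    prev_topology: Topology,
    prev_phi: np.ndarray,
    params: SSPParams,
    rng: np.random.Generator,
    init_low: float,
    init_high: float,
) -> np.ndarray:
    n = topology.n
    adj = topology.adjacency()
    phi = np.zeros((n, n))
    if params.weight_policy == "reset-all":
        phi[adj] = rng.uniform(init_low, init_high, size=int(adj.sum()))
        return phi
    kept = adj & prev_topology.adjacency()
    phi[kept] = prev_phi[kept]
    new = adj & ~kept
    phi[new] = rng.uniform(init_low, init_high, size=int(new.sum()))
    return phi


def run_ssp(
    topology0: Topology,
    landscape: Landscape,
    dyn_params: DynamicsParams,
    ssp_params: SSPParams,
    state0: Optional[EnsembleState] = None,
    keep_states: bool = False,
) -> List[SSPRecord]:
    """Run the Metropolis–Hastings structural-plasticity chain.

    Every step assembles one proposal (synaptogenesis draw + information-gated
    disbanding sweep + occasional random rewire), re-equilibrates the
    selection–learning dynamics on it, applies the synapse cost
    ``exp(-k_cost * d)`` and the Metropolis rule. Records one
    :class:`SSPRecord` per step; ``keep_states`` retains topology and
    equilibrium state on each record (memory-heavier).
    """
    rng = np.random.default_rng(ssp_params.seed)
    inner = DynamicsParams(
        lam=dyn_params.lam,
        t_max=ssp_params.inner_t_max,
        rtol=ssp_params.inner_rtol,
        atol=ssp_params.inner_atol,
        allow_negative_weights=dyn_params.allow_negative_weights,
        backend=dyn_params.backend,
        n_out=25,
    )
    lo, hi = dyn_params.init_low, dyn_params.init_high

    current_topo = topology0
    current_state = (
        state0.copy() if state0 is not None else random_initial_state(current_topo, rng, lo, hi)
    )
    traj = integrate(current_state, inner, landscape)
    current_state = traj.final_state
    w_current = apply_synapse_cost(
        mean_fitness(landscape, current_state.rho), ssp_params.k_cost, current_topo.d
    )

    records: List[SSPRecord] = []
    best = w_current
    for step in range(ssp_params.n_steps):
        moves, proposal = _assemble_proposal(
            current_state, current_topo, landscape, ssp_params, rng
        )
        if proposal.edges == current_topo.edges:
            # nothing was modified: no new circuit to evaluate
            records.append(
                SSPRecord(
                    step=step,
                    moves=(),
                    d=current_topo.d,
                    fitness=w_current,
                    accepted=False,
                    current_fitness=w_current,
                    running_best=best,
                    topology=current_topo if keep_states else None,
                    state=current_state.copy() if keep_states else None,
                )
            )
            continue

        phi0 = _proposal_weights(
            proposal, current_topo, current_state.phi, ssp_params, rng, lo, hi
        )
        rho0 = (
            rng.uniform(lo, hi, size=proposal.n)
            if ssp_params.reset_rho
            else current_state.rho.copy()
        )
        prop_state = EnsembleState(proposal, rho0, phi0)
        traj = integrate(prop_state, inner, landscape)
        eq_state = traj.final_state
        w_new = apply_synapse_cost(
            mean_fitness(landscape, eq_state.rho), ssp_params.k_cost, proposal.d
        )

        if ssp_params.acceptance == "ratio":
            # Metropolis on the fitness ratio: target distribution prop. to W.
            # The additive exp(W_new - W_old) form loses all discrimination
            # once synapse costs push W toward 0, so the ratio form is the
            # default (see the methods note).
            accepted = metropolis_accept(
                np.log(max(w_new, 1e-300)), np.log(max(w_current, 1e-300)), rng
            )
        else:
            accepted = metropolis_accept(w_new, w_current, rng)
        if accepted:
            current_topo = proposal
            current_state = eq_state
            w_current = w_new
        best = max(best, w_current)
        records.append(
            SSPRecord(
                step=step,
                moves=tuple(moves),
                d=proposal.d,
                fitness=w_new,
                accepted=accepted,
                current_fitness=w_current,
                running_best=best,
                topology=current_topo if keep_states else None,
                state=current_state.copy() if keep_states else None,
            )
        )
    return records


def records_to_frame(records: Sequence[SSPRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "step": [r.step for r in records],
            "moves": ["+".join(r.moves) for r in records],
            "d": [r.d for r in records],
            "fitness": [r.fitness for r in records],
            "accepted": [r.accepted for r in records],
            "current_fitness": [r.current_fitness for r in records],
            "running_best": [r.running_best for r in records],
        }
    )


def save_topology_snapshots(
    records: Sequence[SSPRecord], outdir, every: int = 1
) -> None:
    """Edge-list snapshots of the accepted topology along a chain (records
    must have been produced with ``keep_states=True``)."""
    from .networks import write_edge_list

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in records[::every]:
        if r.topology is not None and r.accepted:
            write_edge_list(r.topology, outdir / f"topology_step{r.step:05d}.txt")


# -- validation sampler --------------------------------------------------------

def sample_topologies(
    fitness_fn: Callable[[Topology], float],
    n: int,
    n_steps: int,
    rng: np.random.Generator,
    topology0: Optional[Topology] = None,
) -> List[Topology]:
    """Metropolis chain over topologies with a symmetric single-edge-toggle
    proposal and a user-supplied fitness table.

    With the symmetric kernel the chain's stationary distribution is exactly
    ``pi(G) proportional to exp(fitness_fn(G))``, which makes this the
    reference instrument for validating the Metropolis acceptance rule
    (the full structural-plasticity kernel is deliberately asymmetric).
    """
    topo = topology0 if topology0 is not None else Topology(n, ())
    w = fitness_fn(topo)
    out = []
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for _ in range(n_steps):
        i, j = pairs[rng.integers(len(pairs))]
        if topo.has_edge(i, j):
            cand = topo.with_edges(remove=[(i, j)])
        else:
            cand = topo.with_edges(add=[(i, j)])
        w_cand = fitness_fn(cand)
        if metropolis_accept(w_cand, w, rng):
            topo, w = cand, w_cand
        out.append(topo)
    return out
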