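"""Config-driven experiment families.

Five reproducible experiment families cover the simulator's headline
behaviours:

* ``directional_comparison`` — selection-learning dynamics on a complete
  circuit against the no-learning (naive switching, M ~ 1/2) baseline and a
  re-run with the already-learnt weights;
* ``stabilizing_census`` — stabilizing landscape with target T: count of
  loci that end active, per seed;
* ``random_topologies`` — ER/BA/WS circuits against the matched complete
  baseline;
* ``ssp_evolution`` — structural plasticity without synapse costs;
* ``cost_sweep`` — structural plasticity across a grid of synapse costs.

Each run emits a manifest (config, seeds, package version) sufficient to
re-create every summary table bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import cost_sweep_summary, spearman_dependence
from .dynamics import (
    DynamicsParams,
    Trajectory,
    integrate,
    mean_activity,
    random_initial_state,
    switching_probability,
)
from .landscapes import (
    DirectionalLandscape,
    Landscape,
    StabilizingLandscape,
)
from .networks import (
    Topology,
    make_ba,
    make_complete,
    make_er,
    make_explicit,
    make_ws,
)
from .ssp import SSPParams, SSPRecord, records_to_frame, run_ssp

__all__ = [
    "RunConfig",
    "landscape_from_config",
    "topology_from_config",
    "run_directional_comparison",
    "run_stabilizing_census",
    "run_random_topologies",
    "run_ssp_evolution",
    "run_cost_sweep",
    "run_selection_strength_sweep",
    "EXPERIMENTS",
    "run_experiment",
]


@dataclass
class RunConfig:
    """Serializable description of one experiment run."""

    experiment: str = "directional_comparison"
    n: int = 20
    landscape: dict = field(default_factory=lambda: {"type": "directional", "S": 5.0})
    topology: dict = field(default_factory=lambda: {"type": "complete"})
    lam: float = 0.001
    t_max: float = 10_000.0
    seed: int = 0
    replicates: int = 20
    init_low: float = 0.0
    init_high: float = 0.01
    allow_negative_weights: bool = True
    backend: str = "approx"
    ssp: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def dynamics_params(self, seed: Optional[int] = None) -> DynamicsParams:
        return DynamicsParams(
            lam=self.lam,
            t_max=self.t_max,
            seed=self.seed if seed is None else seed,
            init_low=self.init_low,
            init_high=self.init_high,
            allow_negative_weights=self.allow_negative_weights,
            backend=self.backend,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def seeds(self) -> List[int]:
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(self.replicates)]


def landscape_from_config(cfg: dict, n: Optional[int] = None) -> Landscape:
    kind = cfg.get("type", "directional")
    if kind == "directional":
        return DirectionalLandscape(S=cfg["S"])
    if kind == "stabilizing":
        T = cfg["T"]
        if "beta" in cfg:
            beta = cfg["beta"]
        elif "S" in cfg:
            beta = cfg["S"] / (2.0 * T)  # beta from S = 2*beta*T
        else:
            raise ValueError("stabilizing landscape needs beta or S")
        return StabilizingLandscape(
            beta=beta, T=T, include_variance=cfg.get("include_variance", True)
        )
    raise ValueError(f"unknown landscape type {kind!r}")


def topology_from_config(cfg: dict, n: int, seed=None) -> Topology:
    kind = cfg.get("type", "complete")
    if kind == "complete":
        return make_complete(n)
    if kind == "er":
        return make_er(n, cfg["r"], seed=seed)
    if kind == "ba":
        return make_ba(n, cfg["k_attach"], seed=seed)
    if kind == "ws":
        return make_ws(n, cfg["r"], cfg.get("base_degree", 4), seed=seed)
    if kind == "explicit":
        return make_explicit(n, cfg["edges"])
    raise ValueError(f"unknown topology type {kind!r}")


def _write_manifest(outdir: Optional[Path], config: RunConfig, seeds: Sequence[int]):
    if outdir is None:
        return
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "seeds": list(map(int, seeds)),
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))



def _split_rng(seed: int):
    """Independent streams for topology generation and initial conditions, so
    that runs over different topology types share identical initial draws."""
    c1, c2 = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(c1), np.random.default_rng(c2)


# -- experiment families -------------------------------------------------------

def run_directional_comparison(
    config: RunConfig, outdir=None
) -> Dict[str, Trajectory]:
    """Learning vs no-learning vs learnt-weights re-run on a complete circuit.

    The no-learning arm runs with zero weights (naive switching, M = 1/2
    exactly) and lambda = 0; the re-run arm keeps the learnt weight matrix
    and by default restarts from fresh random firing probabilities
    (``extra={"rerun_rho": "same"}`` reuses the original initial state).
    """
    n = config.n
    topo = topology_from_config(config.topology, n, seed=config.seed)
    landscape = landscape_from_config(config.landscape, n)
    _, rng = _split_rng(config.seed)
    state0 = random_initial_state(topo, rng, config.init_low, config.init_high)

    learning = integrate(state0.copy(), config.dynamics_params(), landscape)

    naive = state0.copy()
    naive.phi = np.zeros_like(naive.phi)
    params_nolearn = dataclasses.replace(config.dynamics_params(), lam=0.0)
    no_learning = integrate(naive, params_nolearn, landscape)

    if config.extra.get("rerun_rho", "fresh") == "same":
        rerun_state = state0.copy()
    else:
        rerun_state = random_initial_state(topo, rng, config.init_low, config.init_high)
    rerun_state.phi = learning.phi[-1].copy()
    relearnt = integrate(rerun_state, config.dynamics_params(), landscape)

    out = {"learning": learning, "no_learning": no_learning, "learnt_weights": relearnt}
    if outdir is not None:
        outdir = Path(outdir)
        for name, traj in out.items():
            traj.write(outdir / name)
        _write_manifest(outdir, config, [config.seed])
    return out


def run_stabilizing_census(config: RunConfig, outdir=None) -> pd.DataFrame:
    """Per-seed census of active loci under a stabilizing landscape.

    One row per seed: number of loci with final rho > 0.5, mean final rho of
    those active loci, identity of the active set, final mean fitness.
    """
    n = config.n
    landscape = landscape_from_config(config.landscape, n)
    rows = []
    seeds = config.seeds()
    for seed in seeds:
        topo_rng, init_rng = _split_rng(seed)
        topo = topology_from_config(config.topology, n, seed=topo_rng)
        state0 = random_initial_state(topo, init_rng, config.init_low, config.init_high)
        traj = integrate(state0, config.dynamics_params(seed), landscape)
        rho = traj.rho[-1]
        active = rho > 0.5
        rows.append(
            {
                "seed": seed,
                "census": int(active.sum()),
                "mean_rho_active": float(rho[active].mean()) if active.any() else np.nan,
                "mean_rho_inactive": float(rho[~active].mean()) if (~active).any() else np.nan,
                "active_set": tuple(np.nonzero(active)[0].tolist()),
                "fitness": float(traj.fitness[-1]),
                "converged": traj.converged,
            }
        )
    df = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "census.csv", index=False)
        _write_manifest(outdir, config, seeds)
    return df


def run_random_topologies(config: RunConfig, outdir=None) -> pd.DataFrame:
    """ER/BA/WS circuits against the matched complete-topology baseline.

    Per (topology, replicate): final mean fitness plus per-node degree and
    final switching probability (for the degree–M relationship).
    """
    n = config.n
    landscape = landscape_from_config(config.landscape, n)
    specs = config.extra.get(
        "topologies",
        [
            {"type": "complete"},
            {"type": "er", "r": 0.2},
            {"type": "ba", "k_attach": 2},
            {"type": "ws", "r": 0.2, "base_degree": 4},
        ],
    )
    seeds = config.seeds()
    rows = []
    for spec in specs:
        name = spec["type"]
        for seed in seeds:
            topo_rng, init_rng = _split_rng(seed)
            topo = topology_from_config(spec, n, seed=topo_rng)
            state0 = random_initial_state(topo, init_rng, config.init_low, config.init_high)
            traj = integrate(state0, config.dynamics_params(seed), landscape)
            st = traj.final_state
            m = switching_probability(mean_activity(st))
            deg = topo.degree()
            rows.append(
                {
                    "topology": name,
                    "seed": seed,
                    "d": topo.d,
                    "fitness": float(traj.fitness[-1]),
                    "degrees": tuple(int(x) for x in deg),
                    "final_M": tuple(float(x) for x in m),
                    "final_rho": tuple(float(x) for x in st.rho),
                }
            )
    df = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "random_topologies.csv", index=False)
        _write_manifest(outdir, config, seeds)
    return df


def _ssp_params(config: RunConfig, seed: int, **overrides) -> SSPParams:
    kwargs = dict(config.ssp)
    kwargs.update(overrides)
    kwargs["seed"] = seed
    return SSPParams(**kwargs)


def run_ssp_evolution(
    config: RunConfig, outdir=None, keep_states: bool = True
) -> List[List[SSPRecord]]:
    """Structural-plasticity chains (no or fixed cost), one per replicate.

    The starting topology is drawn from the configured ensemble (default:
    sparse ER with r = 0.2)."""
    n = config.n
    landscape = landscape_from_config(config.landscape, n)
    seeds = config.seeds()
    start = config.extra.get("start_topology", {"type": "er", "r": 0.2})
    chains = []
    for seed in seeds:
        topo_rng, _ = _split_rng(seed)
        topo0 = topology_from_config(start, n, seed=topo_rng)
        params = _ssp_params(config, seed)
        chains.append(
            run_ssp(topo0, landscape, config.dynamics_params(seed), params,
                    keep_states=keep_states)
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for k, chain in enumerate(chains):
            records_to_frame(chain).to_csv(outdir / f"ssp_chain_{k}.csv", index=False)
        _write_manifest(outdir, config, seeds)
    return chains


def run_cost_sweep(
    config: RunConfig, outdir=None
) -> Tuple[Dict[float, List[List[SSPRecord]]], pd.DataFrame]:
    """Structural plasticity across a grid of synapse costs.

    Returns the raw chains keyed by cost and the stationary summary table."""
    n = config.n
    landscape = landscape_from_config(config.landscape, n)
    costs = config.extra.get("costs", [0.01, 0.1, 0.5, 1.0])
    seeds = config.seeds()
    start = config.extra.get("start_topology", {"type": "er", "r": 0.2})
    by_cost: Dict[float, List[List[SSPRecord]]] = {}
    for k_cost in costs:
        chains = []
        for seed in seeds:
            topo_rng, _ = _split_rng(seed)
            topo0 = topology_from_config(start, n, seed=topo_rng)
            params = _ssp_params(config, seed, k_cost=k_cost)
            chains.append(
                run_ssp(topo0, landscape, config.dynamics_params(seed), params,
                        keep_states=True)
            )
        by_cost[float(k_cost)] = chains
    stationary = config.extra.get("stationary_points", 50)
    summary = cost_sweep_summary(by_cost, stationary_points=stationary)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "cost_sweep.csv", index=False)
        _write_manifest(outdir, config, seeds)
    return by_cost, summary


def run_selection_strength_sweep(
    config: RunConfig, strengths: Sequence[float] = (1.0, 2.0, 5.0, 10.0), outdir=None
) -> Tuple[pd.DataFrame, Tuple[float, float]]:
    """Equilibrium weight magnitude as a function of selection strength,
    with the Spearman rank test of the dependence."""
    n = config.n
    rows = []
    seeds = config.seeds()
    for S in strengths:
        landscape = DirectionalLandscape(S=float(S))
        for seed in seeds:
            topo_rng, init_rng = _split_rng(seed)
            topo = topology_from_config(config.topology, n, seed=topo_rng)
            state0 = random_initial_state(topo, init_rng, config.init_low, config.init_high)
            traj = integrate(state0, config.dynamics_params(seed), landscape)
            adj = topo.adjacency()
            rows.append(
                {
                    "S": float(S),
                    "seed": seed,
                    "mean_abs_phi": float(np.abs(traj.phi[-1][adj]).mean()),
                }
            )
    df = pd.DataFrame(rows)
    rho_s, p = spearman_dependence(df["S"], df["mean_abs_phi"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "selection_strength_sweep.csv", index=False)
        (outdir / "spearman.json").write_text(
            json.dumps({"rho_s": rho_s, "p_value": p}, indent=2)
        )
        _write_manifest(outdir, config, seeds)
    return df, (rho_s, p)


EXPERIMENTS = {
    "directional_comparison": run_directional_comparison,
    "stabilizing_census": run_stabilizing_census,
    "random_topologies": run_random_topologies,
    "ssp_evolution": run_ssp_evolution,
    "cost_sweep": run_cost_sweep,
    "selection_strength_sweep": run_selection_strength_sweep,
}


def run_experiment(config: RunConfig, outdir=None):
    """Dispatch a config to its experiment family."""
    try:
        fn = EXPERIMENTS[config.experiment]
    except KeyError:
        raise ValueError(
            f"unknown experiment {config.experiment!r}; "
            f"choose from {sorted(EXPERIMENTS)}"
        ) from None
    return fn(config, outdir=outdir)
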