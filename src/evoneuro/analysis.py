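"""Statistical post-processing of simulation sweeps.

Covers the three analyses used downstream of the simulator: the rank
(Spearman) dependence of equilibrium weights on selection strength, the
binomial null test of evolved degree distributions, and stationary summaries
of synapse-cost sweeps.
"""

from __future__ import annotations

import warnings
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .networks import Topology, edge_connectivity

__all__ = [
    "spearman_dependence",
    "degree_null_test",
    "cost_sweep_summary",
    "plot_cost_sweep",
]


def spearman_dependence(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation and two-sided p-value.

    Suited to the monotone-but-nonlinear dependence of equilibrium weights on
    selection strength. Raises on constant input (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 5:
        raise ValueError(f"need at least 5 paired observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def degree_null_test(
    topologies: Sequence[Topology], alpha: float = 0.01
) -> Tuple[float, float, float]:
    """Chi-square test of pooled node degrees against Binomial(n-1, p_hat).

    The null model is the Erdős–Rényi ensemble whose connection probability
    ``p_hat`` is estimated from the empirical mean degree; every node of every
    sampled network contributes one degree observation. Bins with expected
    count < 5 are pooled from both tails; degrees of freedom are
    ``bins - 1 - 1`` (one estimated parameter).

    Returns ``(p_hat, chi2, p_value)``.
    """
    topologies = list(topologies)
    if len(topologies) < 30:
        warnings.warn(
            f"only {len(topologies)} network samples; the test is underpowered",
            stacklevel=2,
        )
    n = topologies[0].n
    if any(t.n != n for t in topologies):
        raise ValueError("all topologies must have the same number of loci")
    degrees = np.concatenate([t.degree() for t in topologies])
    p_hat = float(degrees.mean() / (n - 1))
    obs = np.bincount(degrees, minlength=n)
    exp = stats.binom.pmf(np.arange(n), n - 1, p_hat) * len(degrees)

    # pool sparse expected bins from both tails inward
    obs_b, exp_b = _pool_bins(obs.astype(float), exp, min_expected=5.0)
    dof = len(obs_b) - 1 - 1
    if dof < 1:
        # extreme pooling (tiny samples): fall back to unpooled with a warning
        warnings.warn("too few informative bins after pooling", stacklevel=2)
        obs_b, exp_b = obs.astype(float), exp
        dof = max(len(obs_b) - 2, 1)
    chi2 = float(np.sum((obs_b - exp_b) ** 2 / exp_b))
    p_value = float(stats.chi2.sf(chi2, dof))
    return p_hat, chi2, p_value


def _pool_bins(obs: np.ndarray, exp: np.ndarray, min_expected: float):
    """Pool adjacent bins (left-to-right) until every expected count reaches
    the threshold; a trailing sparse bin is merged into its predecessor."""
    obs_out, exp_out = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_out.append(acc_o)
            exp_out.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0.0:
        if exp_out:
            obs_out[-1] += acc_o
            exp_out[-1] += acc_e
        else:
            obs_out.append(acc_o)
            exp_out.append(acc_e)
    return np.array(obs_out), np.array(exp_out)


def cost_sweep_summary(
    ssp_records_by_cost: dict,
    stationary_points: int = 50,
) -> pd.DataFrame:
    """Stationary averages of cost-sweep chains.

    ``ssp_records_by_cost`` maps each synapse cost to a list of replicate
    record sequences (each a list of :class:`SSPRecord` carrying states).
    Averages are taken over the last ``stationary_points`` recorded steps of
    each replicate. Returns one row per (cost, replicate) with equilibrium
    mean firing probability, mean |weight|, mean switching probability of
    connected nodes, edge count, edge connectivity and relative fitness.
    """
    rows = []
    for k_cost, replicates in sorted(ssp_records_by_cost.items()):
        for rep, records in enumerate(replicates):
            if not records:
                continue
            tail = records[-stationary_points:]
            if len(records) < stationary_points:
                warnings.warn(
                    f"chain for cost {k_cost} has only {len(records)} points; "
                    "consider a longer run",
                    stacklevel=2,
                )
            d_mean = float(np.mean([r.d for r in tail]))
            fit_mean = float(np.mean([r.current_fitness for r in tail]))
            last = tail[-1]
            row = {
                "k_cost": k_cost,
                "replicate": rep,
                "fitness": fit_mean,
                "d": d_mean,
            }
            if last.state is not None:
                st = last.state
                deg = st.topology.degree()
                connected = deg > 0
                from .dynamics import mean_activity, switching_probability

                m = switching_probability(mean_activity(st))
                row.update(
                    {
                        "mean_rho": float(st.rho.mean()),
                        "mean_abs_phi": float(
                            np.abs(st.phi[st.topology.adjacency()]).mean()
                        )
                        if st.topology.d
                        else 0.0,
                        "mean_M_connected": float(m[connected].mean())
                        if connected.any()
                        else np.nan,
                        "mean_degree": float(deg.mean()),
                        "edge_connectivity": edge_connectivity(st.topology),
                    }
                )
            rows.append(row)
    return pd.DataFrame(rows)


def plot_cost_sweep(summary: pd.DataFrame, outpath=None):
    """Three-panel overview of a cost sweep: relative fitness, mean degree and
    mean switching probability of connected nodes against synapse cost."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = summary.groupby("k_cost").mean(numeric_only=True).reset_index()
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    panels = [
        ("fitness", "equilibrium fitness"),
        ("mean_degree", "mean degree"),
        ("mean_M_connected", "mean M (connected nodes)"),
    ]
    for ax, (col, label) in zip(axes, panels):
        if col in agg:
            ax.plot(agg["k_cost"], agg[col], "o-")
        ax.set_xlabel("cost per synapse k")
        ax.set_ylabel(label)
        ax.set_xscale("log")
    fig.tight_layout()
    if outpath is not None:
        fig.savefig(outpath, dpi=120)
        plt.close(fig)
    return fig
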