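"""Fitness landscapes over circuit firing configurations.

A circuit configuration is a vector of signed neuron states ``x in {-1,+1}^n``.
Its output is the number of firing neurons, ``Omega = #{i : x_i = +1}``.
Two landscape families are provided:

* **Stabilizing** (Gaussian): ``W = exp(-beta * (T - Omega)^2)``. Many
  equivalent optima (any configuration with exactly ``T`` neurons on); the
  nonlinearity couples loci, the analogue of epistasis.
* **Directional**: constant per-locus selection gradient ``S_i``; normalized
  as ``W = exp(sum_i S_i * (g_i - 1))`` with ``g_i = (x_i + 1)/2 in {0,1}``,
  so that ``W in (0, 1]`` with the optimum at all neurons on. For symmetric
  ``S_i = S`` this is the large-distance limit of the stabilizing landscape
  with ``S = 2 * beta * T``.

Across the infinite ensemble of circuits, loci are independent with
``P(x_j = +1) = rho_j`` (the product-measure assumption), so every
expectation here is taken under that measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

__all__ = [
    "StabilizingLandscape",
    "DirectionalLandscape",
    "Landscape",
    "output_of_state",
    "fitness",
    "locus_fitness_terms",
    "conditional_fitness",
    "selection_coefficients",
    "mean_fitness",
    "apply_synapse_cost",
    "gradient_from_target",
    "on_count_distribution",
]


def output_of_state(x: np.ndarray) -> int:
    """Network output Omega: the count of firing (+1) neurons."""
    x = np.asarray(x)
    if not np.all(np.isin(x, (-1, 1))):
        raise ValueError("states must be +/-1")
    return int(np.sum(x == 1))


@dataclass(frozen=True)
class StabilizingLandscape:
    """Gaussian landscape around a target number ``T`` of spiking neurons.

    Parameters
    ----------
    beta : selection sharpness (> 0, dimensionless).
    T : target number of spiking neurons.
    include_variance : whether the first-order selection coefficients include
        the gradient of the output variance ``Var(Omega) = sum rho(1-rho)``
        in addition to the squared mean distance. The variance gradient is
        the disruptive term that polarizes loci to 0/1; without it the
        symmetric dynamics cannot single out exactly ``T`` active loci.
    """

    beta: float
    T: float
    include_variance: bool = True

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.T < 0:
            raise ValueError(f"target T must be >= 0, got {self.T}")

    def w_of_count(self, n: int) -> np.ndarray:
        """Fitness of each output value Omega = 0..n."""
        omega = np.arange(n + 1, dtype=float)
        return np.exp(-self.beta * (self.T - omega) ** 2)


@dataclass(frozen=True)
class DirectionalLandscape:
    """Constant-gradient landscape; ``S`` may be a scalar (symmetric case)
    or a per-locus vector (asymmetric landscape)."""

    S: Union[float, np.ndarray]

    def __post_init__(self):
        s = np.asarray(self.S, dtype=float)
        if not np.all(np.isfinite(s)):
            raise ValueError("selection gradients must be finite")

    def s_vector(self, n: int) -> np.ndarray:
        s = np.asarray(self.S, dtype=float)
        if s.ndim == 0:
            return np.full(n, float(s))
        if s.shape != (n,):
            raise ValueError(f"S has shape {s.shape}, expected ({n},)")
        return s


Landscape = Union[StabilizingLandscape, DirectionalLandscape]


def fitness(landscape: Landscape, omega: float, n: int = None) -> float:
    """Fitness of a configuration with output ``omega``.

    For the directional landscape the symmetric gradient is applied to the
    output count (``n`` is required to normalize the optimum to W = 1).
    """
    if isinstance(landscape, StabilizingLandscape):
        delta = landscape.T - omega
        return float(np.exp(-landscape.beta * delta**2))
    s = np.asarray(landscape.S, dtype=float)
    if s.ndim != 0:
        raise ValueError("per-configuration fitness of an asymmetric "
                         "landscape needs the full state, not just Omega")
    if n is None:
        raise ValueError("directional fitness needs the circuit size n")
    return float(np.exp(float(s) * (omega - n)))


def gradient_from_target(beta: float, T: float) -> float:
    """Directional gradient implied by a stabilizing landscape far from its
    target: ``S = 2 * beta * T``."""
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    if T < 0:
        raise ValueError(f"target T must be >= 0, got {T}")
    return 2.0 * beta * T


def apply_synapse_cost(W: float, k_cost: float, d: int) -> float:
    """Multiplicative synapse cost: ``W' = W * exp(-k_cost * d)`` for a
    circuit with ``d`` synapses."""
    if k_cost < 0:
        raise ValueError(f"synapse cost must be >= 0, got {k_cost}")
    if d < 0:
        raise ValueError(f"edge count must be >= 0, got {d}")
    return W * float(np.exp(-k_cost * d))


# -- product-measure expectations ---------------------------------------------

def on_count_distribution(rho: np.ndarray) -> np.ndarray:
    """Distribution of the number of firing neurons under independent loci
    (Poisson-binomial), by the O(n^2) convolution recursion."""
    rho = _check_rho(rho)
    q = np.array([1.0])
    for p in rho:
        nxt = np.zeros(len(q) + 1)
        nxt[: len(q)] += q * (1.0 - p)
        nxt[1:] += q * p
        q = nxt
    return q


def _check_rho(rho) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("firing probabilities must lie in [0, 1]")
    return rho


def conditional_fitness(
    landscape: Landscape, rho: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact per-locus conditional fitness pair ``(E[W|x_i=+1], E[W|x_i=-1])``
    under the product measure, via the on-count distribution of the other
    ``n - 1`` loci (no sampling)."""
    rho = _check_rho(rho)
    n = len(rho)
    w_on = np.empty(n)
    w_off = np.empty(n)
    if isinstance(landscape, DirectionalLandscape):
        # separable: per-locus factors cancel in every other coordinate
        s = landscape.s_vector(n)
        factors = rho + (1 - rho) * np.exp(-s)  # E[e^{s(g-1)}] per locus
        total = np.prod(factors)
        for i in range(n):
            others = total / factors[i] if factors[i] > 0 else 0.0
            w_on[i] = others  # e^{s_i * 0} = 1
            w_off[i] = others * np.exp(-s[i])
    else:
        w = landscape.w_of_count(n)
        for i in range(n):
            q = on_count_distribution(np.delete(rho, i))  # counts of others
            w_on[i] = float(q @ w[1:])
            w_off[i] = float(q @ w[:-1])
    return w_on, w_off


def locus_fitness_terms(
    landscape: Landscape, rho: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact conditional and mean fitness per locus.

    Returns ``(W_i, Wbar_i)`` where ``W_i = E[W | x_i = +1]`` and
    ``Wbar_i = E[W]`` under the product measure with ``P(x_j=+1) = rho_j``.
    """
    rho = _check_rho(rho)
    w_on, w_off = conditional_fitness(landscape, rho)
    wbar = rho * w_on + (1 - rho) * w_off
    return w_on, wbar


def mean_fitness(landscape: Landscape, rho: np.ndarray) -> float:
    """Exact ensemble mean fitness E[W] under the product measure."""
    rho = _check_rho(rho)
    n = len(rho)
    if isinstance(landscape, DirectionalLandscape):
        s = landscape.s_vector(n)
        return float(np.prod(rho + (1 - rho) * np.exp(-s)))
    q = on_count_distribution(rho)
    return float(q @ landscape.w_of_count(n))


def selection_coefficients(landscape: Landscape, rho: np.ndarray) -> np.ndarray:
    """First-order (log-mean-fitness gradient) selection coefficients.

    This is the closed form the selection term of the firing-probability
    dynamics uses by default:

    * directional: ``s_i = S_i`` (constant gradient);
    * stabilizing: ``s_i = beta * (2*(T - Omega_bar) + (2*rho_i - 1))``,
      the gradient of ``-beta*[(T - Omega_bar)^2 + Var(Omega)]`` with respect
      to ``rho_i`` (the variance term is dropped when
      ``include_variance=False``).
    """
    rho = _check_rho(rho)
    n = len(rho)
    if isinstance(landscape, DirectionalLandscape):
        return landscape.s_vector(n)
    omega_bar = float(np.sum(rho))
    s = np.full(n, 2.0 * landscape.beta * (landscape.T - omega_bar))
    if landscape.include_variance:
        s = s + landscape.beta * (2.0 * rho - 1.0)
    return s
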