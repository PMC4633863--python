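"""Circuit topologies: construction, interrogation and I/O.

A topology is an undirected simple graph on ``n`` neuronal loci; an edge is a
synapse. Generators cover the complete graph and the three classical random
ensembles (Erdős–Rényi, Barabási–Albert, Watts–Strogatz). Neither self-loops
nor multi-edges are allowed, and node identity carries no meaning: analyses
downstream must be permutation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
import numpy as np

__all__ = [
    "Topology",
    "make_complete",
    "make_er",
    "make_ba",
    "make_ws",
    "make_explicit",
    "edge_connectivity",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
]

SeedLike = Union[None, int, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Topology:
    """Undirected simple graph on ``n`` neuronal loci.

    Edges are stored as a sorted tuple of ordered pairs ``(i, j)`` with
    ``i < j``; construction validates the simple-graph constraint.
    """

    n: int
    edges: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"need at least one locus, got n={self.n}")
        seen = set()
        canon = []
        for (i, j) in self.edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-loop at node {i} is not allowed")
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise ValueError(f"edge ({i},{j}) outside node range 0..{self.n - 1}")
            e = (min(i, j), max(i, j))
            if e in seen:
                raise ValueError(f"multi-edge {e} is not allowed")
            seen.add(e)
            canon.append(e)
        object.__setattr__(self, "edges", tuple(sorted(canon)))

    # -- basic interrogation -------------------------------------------------
    @property
    def d(self) -> int:
        """Number of synapses (edges)."""
        return len(self.edges)

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for (i, j) in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix (symmetric, zero diagonal)."""
        a = np.zeros((self.n, self.n), dtype=bool)
        for (i, j) in self.edges:
            a[i, j] = a[j, i] = True
        return a

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in set(self.edges)

    def non_edges(self) -> list:
        present = set(self.edges)
        return [
            (i, j)
            for i in range(self.n)
            for j in range(i + 1, self.n)
            if (i, j) not in present
        ]

    def with_edges(self, add: Iterable = (), remove: Iterable = ()) -> "Topology":
        """Copy with edges added/removed (pairs in any order)."""
        cur = set(self.edges)
        for (i, j) in remove:
            cur.discard((min(i, j), max(i, j)))
        for (i, j) in add:
            cur.add((min(i, j), max(i, j)))
        return Topology(self.n, tuple(sorted(cur)))

    # -- conversion ----------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, n: Optional[int] = None) -> "Topology":
        nodes = sorted(g.nodes())
        relabel = {v: k for k, v in enumerate(nodes)}
        n = n if n is not None else len(nodes)
        return cls(n, tuple((relabel[u], relabel[v]) for u, v in g.edges()))


# -- generators ---------------------------------------------------------------

def make_complete(n: int) -> Topology:
    """Fully connected circuit; ``d = n(n-1)/2``."""
    if n < 2:
        raise ValueError(f"complete topology needs n >= 2, got {n}")
    return Topology(n, tuple((i, j) for i in range(n) for j in range(i + 1, n)))


def make_er(n: int, r: float, seed: SeedLike = None) -> Topology:
    """Erdős–Rényi G(n, r): each pair connected independently with probability r."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"connection probability r must be in [0, 1], got {r}")
    rng = _rng(seed)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < r:
                edges.append((i, j))
    return Topology(n, tuple(edges))


def make_ba(n: int, k_attach: int, seed: SeedLike = None) -> Topology:
    """Barabási–Albert preferential attachment.

    The seed graph is the complete graph on ``max(k_attach, 2)`` nodes (a
    single isolated node cannot receive preferential attachment); every later
    node attaches to ``k_attach`` existing nodes with probability proportional
    to their degree, giving ``d = C(m, 2) + k_attach * (n - m)`` with
    ``m = max(k_attach, 2)`` — a tree of ``n - 1`` edges for ``k_attach = 1``.
    """
    if not 1 <= k_attach < n:
        raise ValueError(f"need 1 <= k_attach < n, got k_attach={k_attach}, n={n}")
    rng = _rng(seed)
    nx_seed = int(rng.integers(2**31 - 1))
    m = max(k_attach, 2)
    g = nx.barabasi_albert_graph(
        n, k_attach, seed=nx_seed, initial_graph=nx.complete_graph(m)
    )
    return Topology.from_networkx(g, n=n)


def make_ws(n: int, r: float, base_degree: int = 4, seed: SeedLike = None) -> Topology:
    """Watts–Strogatz small world: ring lattice of even ``base_degree``,
    each edge rewired with probability ``r`` avoiding loops and multi-edges."""
    if base_degree % 2 != 0:
        raise ValueError(f"base_degree must be even, got {base_degree}")
    if base_degree >= n:
        raise ValueError(f"base_degree must be < n, got {base_degree} >= {n}")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"rewiring probability r must be in [0, 1], got {r}")
    rng = _rng(seed)
    nx_seed = int(rng.integers(2**31 - 1))
    g = nx.watts_strogatz_graph(n, base_degree, r, seed=nx_seed)
    return Topology.from_networkx(g, n=n)


def make_explicit(n: int, edges: Iterable) -> Topology:
    """Topology from an explicit edge list."""
    return Topology(n, tuple(tuple(e) for e in edges))


# -- interrogation ------------------------------------------------------------

def edge_connectivity(t: Topology) -> int:
    """Global minimum edge cut: the number of synapses whose removal splits
    the circuit into two unconnected subsets. Zero iff already disconnected."""
    if t.n < 2:
        return 0
    g = t.to_networkx()
    if not nx.is_connected(g):
        return 0
    return nx.edge_connectivity(g)


# -- I/O -----------------------------------------------------------------------

def write_edge_list(t: Topology, path) -> None:
    """Whitespace-delimited 0-based edge list; first line is ``n d``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{t.n} {t.d}\n")
        for (i, j) in t.edges:
            fh.write(f"{i} {j}\n")


def read_edge_list(path) -> Topology:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        n = int(header[0])
        edges = []
        for line in fh:
            parts = line.split()
            if parts:
                edges.append((int(parts[0]), int(parts[1])))
    return Topology(n, tuple(edges))


def write_graphml(t: Topology, path) -> None:
    nx.write_graphml(t.to_networkx(), str(path))


def read_graphml(path) -> Topology:
    g = nx.read_graphml(str(path), node_type=int)
    return Topology.from_networkx(g)
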