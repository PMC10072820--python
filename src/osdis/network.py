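"""Weighted-network data model, synthetic generators and path metrics.

A network is an undirected simple graph whose edges carry a strictly
positive propagation delay ``theta`` (time units).  Node identifiers are
contiguous non-negative integers; files using 1-based ids are converted at
the I/O boundary.

Two synthetic families are provided:

* scale-free growth with nonlinear preferential attachment (attachment
  weight ``degree**power + 1``, so isolated seed nodes remain attachable),
* small-world ring lattices with radius-2 neighborhoods and random edge
  rewiring.

Delays are drawn i.i.d. from a Gaussian ``N(mu, sigma^2)``; non-positive
draws are redrawn so that path delays are strictly increasing in path
length.  The default ``mu/sigma = 4`` keeps the redraw probability below
``1e-4`` per edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

from .exceptions import EdgeListFormatError, ParameterError, UnreachableError

__all__ = [
    "Network",
    "DelayModel",
    "GeneratorRecipe",
    "generate_ba",
    "generate_ws",
    "generate_network",
    "assign_delays",
    "read_edgelist",
    "write_edgelist",
    "shortest_hop",
    "shortest_delay",
]

DELAY_KEY = "delay"


class Network:
    """Undirected simple graph with optional per-edge propagation delays.

    Parameters
    ----------
    graph
        A :class:`networkx.Graph` with integer node labels ``0..n-1``.
        Edge delays, when present, live in the ``"delay"`` attribute and
        must be strictly positive.

    The wrapper validates the invariants once at construction and exposes
    cached sorted adjacency for the deterministic tree traversals.
    """

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise ParameterError("network must have at least one node")
        nodes = sorted(graph.nodes())
        if nodes != list(range(len(nodes))):
            raise ParameterError(
                "node identifiers must be contiguous integers starting at 0; "
                f"got {nodes[:5]}..."
            )
        if any(u == v for u, v in graph.edges()):
            raise ParameterError("self-loops are not allowed")
        for u, v, data in graph.edges(data=True):
            if DELAY_KEY in data and not data[DELAY_KEY] > 0:
                raise ParameterError(
                    f"edge ({u},{v}) has non-positive delay {data[DELAY_KEY]}"
                )
        self._g = graph
        self._adj: dict[int, list[int]] | None = None

    # -- basic accessors -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def nodes(self) -> list[int]:
        return list(range(self.n_nodes))

    def edges(self) -> Iterator[tuple[int, int]]:
        return iter(self._g.edges())

    @property
    def has_delays(self) -> bool:
        return all(DELAY_KEY in d for _, _, d in self._g.edges(data=True))

    def delay(self, u: int, v: int) -> float:
        """Symmetric delay theta_uv of edge (u, v)."""
        return float(self._g[u][v][DELAY_KEY])

    def degree(self, u: int) -> int:
        return self._g.degree(u)

    def neighbors(self, u: int) -> list[int]:
        """Neighbors of ``u`` in ascending id order (cached)."""
        if self._adj is None:
            self._adj = {n: sorted(self._g.neighbors(n)) for n in self._g}
        return self._adj[u]

    def has_edge(self, u: int, v: int) -> bool:
        return self._g.has_edge(u, v)

    def is_connected(self) -> bool:
        return nx.is_connected(self._g)

    def copy(self) -> "Network":
        return Network(self._g.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        w = "weighted" if self.has_delays else "unweighted"
        return f"<Network |V|={self.n_nodes} |E|={self.n_edges} {w}>"


@dataclass(frozen=True)
class DelayModel:
    """Gaussian edge-delay model N(mu, sigma^2), redrawing non-positive draws.

    The defaults (mu=4, sigma=1) realize the mean-to-spread ratio
    mu/sigma = 4 used throughout the evaluation protocol.
    """

    mu: float = 4.0
    sigma: float = 1.0
    redraw_nonpositive: bool = True

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ParameterError(f"mu must be > 0, got {self.mu}")
        if not self.sigma > 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        draws = rng.normal(self.mu, self.sigma, size=size)
        if self.redraw_nonpositive:
            bad = draws <= 0
            while bad.any():
                draws[bad] = rng.normal(self.mu, self.sigma, size=int(bad.sum()))
                bad = draws <= 0
        return draws


@dataclass(frozen=True)
class GeneratorRecipe:
    """Parameters of a synthetic-network family.

    family 'ba': growth with ``m`` edges per new node and attachment
    probability proportional to ``degree**power + 1``.
    family 'ws': one-dimensional ring of ``n`` nodes, each wired to its
    ``radius`` nearest neighbors per side, then rewired with probability
    ``p``.
    """

    family: str
    n: int
    power: float = 1.0
    m: int = 2
    radius: int = 2
    p: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in ("ba", "ws"):
            raise ParameterError(f"unknown family {self.family!r}")
        if self.n < 2:
            raise ParameterError(f"n must be >= 2, got {self.n}")
        if self.family == "ba" and self.m < 1:
            raise ParameterError(f"m must be >= 1, got {self.m}")
        if self.family == "ws":
            if not 0 <= self.p <= 1:
                raise ParameterError(f"p must be in [0,1], got {self.p}")
            if self.radius < 1:
                raise ParameterError(f"radius must be >= 1, got {self.radius}")


def generate_ba(recipe: GeneratorRecipe, seed: int | None = None) -> Network:
    """Scale-free network by growth and nonlinear preferential attachment.

    Starting from a single node, each new node attaches up to ``m`` edges
    to *distinct* existing nodes chosen without replacement with
    probability proportional to ``degree**power + 1``.  The additive
    zero-appeal term keeps degree-0 nodes attachable, so the graph is
    connected and simple by construction, with
    ``|E| = 1 + m*(n-2)`` edges for ``n > m`` when ``m = 2``.
    """
    if recipe.family != "ba":
        raise ParameterError("generate_ba requires a 'ba' recipe")
    rng = np.random.default_rng(seed if seed is not None else recipe.seed)
    n, m, power = recipe.n, recipe.m, recipe.power

    g = nx.Graph()
    g.add_nodes_from(range(n))
    degree = np.zeros(n, dtype=float)
    for new in range(1, n):
        k = min(m, new)
        weights = degree[:new] ** power + 1.0
        targets = rng.choice(new, size=k, replace=False, p=weights / weights.sum())
        for t in targets:
            g.add_edge(new, int(t))
            degree[new] += 1
            degree[t] += 1
    return Network(g)


def generate_ws(recipe: GeneratorRecipe, seed: int | None = None) -> Network:
    """Small-world ring lattice with random rewiring.

    Each node links to its ``radius`` nearest neighbors on each side
    (degree ``2*radius``); every edge is then rewired with probability
    ``p``, skipping rewirings that would create self-loops or duplicate
    edges, so the edge count ``n * radius`` is conserved for all p.
    """
    if recipe.family != "ws":
        raise ParameterError("generate_ws requires a 'ws' recipe")
    s = seed if seed is not None else recipe.seed
    g = nx.watts_strogatz_graph(recipe.n, 2 * recipe.radius, recipe.p, seed=s)
    return Network(g)


def generate_network(recipe: GeneratorRecipe, seed: int | None = None) -> Network:
    """Dispatch on the recipe family."""
    if recipe.family == "ba":
        return generate_ba(recipe, seed=seed)
    return generate_ws(recipe, seed=seed)


def assign_delays(
    net: Network, model: DelayModel | None = None, seed: int | None = None
) -> Network:
    """Return a copy of ``net`` with fresh i.i.d. Gaussian edge delays.

    Existing delays are overwritten.  The resulting weighted graph is the
    one visible to both the simulator and the locator.
    """
    model = model or DelayModel()
    rng = np.random.default_rng(seed)
    g = net.graph.copy()
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    draws = model.sample(len(edges), rng)
    for (u, v), th in zip(edges, draws):
        g[u][v][DELAY_KEY] = float(th)
    return Network(g)


# -- edge-list I/O -------------------------------------------------------

def read_edgelist(
    path, has_delay_column: bool = False, index_base: int = 0
) -> Network:
    """Read a whitespace-separated ``u v [theta]`` edge list.

    Lines starting with ``#`` are comments.  ``index_base`` declares the
    file's node numbering (0 or 1); nodes are re-indexed to 0-based
    contiguous ids internally (file ids are assumed contiguous from the
    base).  Duplicate edges and self-loops are format errors.
    """
    if index_base not in (0, 1):
        raise ParameterError(f"index_base must be 0 or 1, got {index_base}")
    g = nx.Graph()
    seen: set[tuple[int, int]] = set()
    max_node = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if has_delay_column and len(parts) < 3:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: delay column declared but missing"
                )
            try:
                u, v = int(parts[0]) - index_base, int(parts[1]) - index_base
            except ValueError as exc:
                raise EdgeListFormatError(f"{path}:{lineno}: bad node id") from exc
            if u < 0 or v < 0:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: negative node id after re-indexing"
                )
            if u == v:
                raise EdgeListFormatError(f"{path}:{lineno}: self-loop {u}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise EdgeListFormatError(f"{path}:{lineno}: duplicate edge {key}")
            seen.add(key)
            if has_delay_column:
                theta = float(parts[2])
                g.add_edge(u, v, **{DELAY_KEY: theta})
            else:
                g.add_edge(u, v)
            max_node = max(max_node, u, v)
    g.add_nodes_from(range(max_node + 1))
    return Network(g)


def write_edgelist(net: Network, path, index_base: int = 0) -> None:
    """Write ``u v [theta]`` lines (delays included when present)."""
    with open(path, "w") as fh:
        fh.write(f"# |V|={net.n_nodes} |E|={net.n_edges}\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            if net.has_delays:
                fh.write(
                    f"{u + index_base} {v + index_base} "
                    f"{net.delay(u, v):.10g}\n"
                )
            else:
                fh.write(f"{u + index_base} {v + index_base}\n")


# -- path metrics --------------------------------------------------------

def shortest_hop(net: Network, u: int, v: int) -> int:
    """Minimum number of edges between ``u`` and ``v`` (unweighted)."""
    try:
        return nx.shortest_path_length(net.graph, u, v)
    except nx.NetworkXNoPath as exc:
        raise UnreachableError(f"nodes {u} and {v} are disconnected") from exc


def shortest_delay(net: Network, u: int, v: int) -> float:
    """Minimum total propagation delay along any u-v path."""
    try:
        return float(
            nx.shortest_path_length(net.graph, u, v, weight=DELAY_KEY)
        )
    except nx.NetworkXNoPath as exc:
        raise UnreachableError(f"nodes {u} and {v} are disconnected") from exc
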