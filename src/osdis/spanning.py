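"""Rooted spanning-tree heuristics: relaxed direction-induced search and BFS.

The relaxed direction-induced search (DIS) grows a tree from a candidate
root by breadth-first expansion under one constraint: an observer may
only be attached through the edge from its recorded direction neighbor
(the node it was actually infected from), while a non-observer attaches
to whichever tree node reaches it first.  If the constraints are
consistent the traversal covers all nodes and yields a spanning tree
approximating the actual diffusion tree; if not, the root is infeasible
and ``None`` is returned — the locator treats that as "candidate
excluded", not as an error.

Both traversals use a FIFO frontier with neighbors explored in ascending
node id, so each root maps to exactly one tree.
"""

from __future__ import annotations

import csv
from collections import deque
from dataclasses import dataclass

from .exceptions import InconsistentRecordError, ParameterError
from .network import Network
from .simulate import ObserverRecords

__all__ = ["SpanningTree", "relaxed_dis_tree", "bfs_tree"]


@dataclass
class SpanningTree:
    """Rooted tree as a parent map plus cumulative root-to-node delays."""

    root: int
    parent: dict[int, int | None]
    cum_delay: dict[int, float]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_edges(self) -> int:
        return len(self.parent) - 1

    def edges(self) -> list[tuple[int, int]]:
        return [(p, v) for v, p in self.parent.items() if p is not None]

    def path_to_root(self, v: int) -> list[int]:
        """Nodes from ``v`` up to the root, inclusive."""
        path = [v]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path

    def depth(self, v: int) -> int:
        return len(self.path_to_root(v)) - 1

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["node", "parent", "cum_delay"])
            for v in sorted(self.parent):
                p = self.parent[v]
                writer.writerow(
                    [v, "" if p is None else p, f"{self.cum_delay[v]:.10g}"]
                )


def _validate_records(net: Network, records: ObserverRecords) -> dict[int, int]:
    """Map observer -> forced direction neighbor, checking adjacency.

    Records with no direction (an observer that happens to be the true
    source) impose no constraint and are dropped.
    """
    forced: dict[int, int] = {}
    for r in records:
        if r.direction is None:
            continue
        if not net.has_edge(r.observer, r.direction):
            raise InconsistentRecordError(
                f"observer {r.observer}: direction {r.direction} is not a neighbor"
            )
        forced[r.observer] = r.direction
    return forced


def relaxed_dis_tree(
    net: Network, root: int, records: ObserverRecords
) -> SpanningTree | None:
    """Relaxed direction-induced search from ``root``.

    Returns a spanning tree iff every node can be attached under the
    observer-direction constraints (``|E(T)| = |V| - 1``); otherwise
    returns ``None``.  When the root is itself an observer its direction
    record is ignored for rooting.
    """
    if root not in range(net.n_nodes):
        raise ParameterError(f"root {root} not in network")
    forced = _validate_records(net, records)
    forced.pop(root, None)  # the root needs no parent

    use_delay = net.has_delays
    parent: dict[int, int | None] = {root: None}
    cum: dict[int, float] = {root: 0.0}
    frontier: deque[int] = deque([root])
    while frontier:
        v = frontier.popleft()
        for u in net.neighbors(v):
            if u in parent:
                continue
            # observers attach only via their recorded direction neighbor
            if u in forced and forced[u] != v:
                continue
            parent[u] = v
            cum[u] = cum[v] + (net.delay(v, u) if use_delay else 1.0)
            frontier.append(u)
    if len(parent) != net.n_nodes:
        return None
    return SpanningTree(root=root, parent=parent, cum_delay=cum)


def bfs_tree(net: Network, root: int) -> SpanningTree:
    """Plain breadth-first spanning tree with ascending-id neighbor order."""
    if root not in range(net.n_nodes):
        raise ParameterError(f"root {root} not in network")
    use_delay = net.has_delays
    parent: dict[int, int | None] = {root: None}
    cum: dict[int, float] = {root: 0.0}
    frontier: deque[int] = deque([root])
    while frontier:
        v = frontier.popleft()
        for u in net.neighbors(v):
            if u in parent:
                continue
            parent[u] = v
            cum[u] = cum[v] + (net.delay(v, u) if use_delay else 1.0)
            frontier.append(u)
    return SpanningTree(root=root, parent=parent, cum_delay=cum)
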