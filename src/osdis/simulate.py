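"""Discrete SI diffusion with per-edge delays, and observer extraction.

Model.  A single source s* becomes infectious at start time t*.  When a
node v is infected at time t_v it attempts to infect each susceptible
neighbor u across the weighted edge vu with per-attempt success
probability beta.  Attempts are unit-time retries: transmission succeeds
on the W-th attempt with W ~ Geometric(beta) on {1, 2, ...}, and the
infection lands at ``t_v + (W - 1) + theta_vu``.  A node's infection time
is the earliest candidate arrival over its infected neighbors; the
arg-min neighbor is its infector, and the infector edges form the actual
diffusion tree rooted at s*.  At beta = 1 the process reduces to the pure
delay model: infection times equal t* plus delay-weighted shortest-path
distance from the source.

The geometric waits are driven by one uniform variate per directed edge,
pre-drawn from the run seed (common random numbers), so for a fixed seed
lowering beta never makes any node's infection earlier.

Observers.  A subset of nodes records, once infected, (1) the diffusion
direction — the neighbor the infection arrived from — and (2) the
infection time.  These records are all the locator ever sees.
"""

from __future__ import annotations

import csv
import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .exceptions import IncompleteObservationError, ParameterError
from .network import Network

__all__ = [
    "DiffusionConfig",
    "DiffusionOutcome",
    "ObserverRecord",
    "ObserverRecords",
    "run_si",
    "sample_observers",
    "observe",
]


@dataclass(frozen=True)
class DiffusionConfig:
    """Source, start time, propagation ratio and seed of one diffusion."""

    source: int
    start_time: float = 0.0
    beta: float = 1.0
    seed: int | None = None
    #: "geometric" — failed attempts cost one time unit each (default);
    #: "thinning" — failures cost no time, so beta only shapes tie-breaks
    #: and the process degenerates to the pure delay model.
    semantics: str = "geometric"

    def __post_init__(self) -> None:
        if not 0 < self.beta <= 1:
            raise ParameterError(f"beta must be in (0, 1], got {self.beta}")
        if self.start_time < 0:
            raise ParameterError(f"start time must be >= 0, got {self.start_time}")
        if self.semantics not in ("geometric", "thinning"):
            raise ParameterError(f"unknown semantics {self.semantics!r}")


@dataclass
class DiffusionOutcome:
    """Realized diffusion: infection times, infectors, the diffusion tree."""

    source: int
    start_time: float
    times: dict[int, float]
    infectors: dict[int, int | None]

    def infected_nodes(self) -> list[int]:
        return sorted(self.times)

    def tree_edges(self) -> list[tuple[int, int]]:
        """Edges (infector, node) of the actual diffusion tree."""
        return [
            (w, v) for v, w in self.infectors.items() if w is not None
        ]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["node", "time", "infector"])
            for v in self.infected_nodes():
                w = self.infectors[v]
                writer.writerow([v, f"{self.times[v]:.10g}", "" if w is None else w])


@dataclass(frozen=True)
class ObserverRecord:
    """One observer: its id, the neighbor it was infected from, the time."""

    observer: int
    direction: int | None
    time: float


class ObserverRecords:
    """Ordered collection of observer records, CSV round-trippable."""

    def __init__(self, records: Iterable[ObserverRecord]):
        self._records = list(records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ObserverRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> ObserverRecord:
        return self._records[i]

    @property
    def observers(self) -> list[int]:
        return [r.observer for r in self._records]

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self._records], dtype=float)

    def direction_of(self, observer: int) -> int | None:
        for r in self._records:
            if r.observer == observer:
                return r.direction
        raise KeyError(observer)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["observer", "direction", "time"])
            for r in self._records:
                writer.writerow(
                    [r.observer, "" if r.direction is None else r.direction,
                     f"{r.time:.10g}"]
                )

    @classmethod
    def from_csv(cls, path) -> "ObserverRecords":
        records = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                d = row["direction"].strip()
                records.append(
                    ObserverRecord(
                        observer=int(row["observer"]),
                        direction=int(d) if d else None,
                        time=float(row["time"]),
                    )
                )
        return cls(records)

    def __eq__(self, other) -> bool:
        return isinstance(other, ObserverRecords) and self._records == other._records


def _geometric_waits(u: np.ndarray, beta: float) -> np.ndarray:
    """W = inverse-CDF Geometric(beta) on {1,2,...} from uniforms ``u``.

    Monotone non-increasing in beta pointwise, which couples runs across
    beta under common random numbers.
    """
    if beta >= 1.0:
        return np.ones_like(u)
    return np.ceil(np.log1p(-u) / math.log1p(-beta))


def run_si(net: Network, cfg: DiffusionConfig) -> DiffusionOutcome:
    """Simulate one SI diffusion; event-driven first-arrival semantics.

    Tentative infections are processed in nondecreasing time; once a node
    is infected, later candidate arrivals are discarded.  Exact time ties
    are broken uniformly at random.  The process runs until no susceptible
    node remains in the source's component.
    """
    if cfg.source not in range(net.n_nodes):
        raise ParameterError(f"source {cfg.source} not in network")
    if not net.has_delays:
        raise ParameterError("network has no edge delays; call assign_delays first")

    rng = np.random.default_rng(cfg.seed)
    # One uniform per directed edge, indexed by (tail, head), drawn in a
    # fixed order so the coupling is a function of (seed, graph) only.
    directed = [
        (u, v) for u in range(net.n_nodes) for v in net.neighbors(u)
    ]
    uniforms = dict(zip(directed, rng.random(len(directed))))

    times: dict[int, float] = {cfg.source: cfg.start_time}
    infectors: dict[int, int | None] = {cfg.source: None}
    heap: list[tuple[float, float, int, int]] = []

    geometric = cfg.semantics == "geometric"

    def push_attempts(v: int, t_v: float) -> None:
        for u in net.neighbors(v):
            if u in times:
                continue
            if geometric:
                w = _geometric_waits(np.array([uniforms[(v, u)]]), cfg.beta)[0]
            else:
                w = 1.0
            arrival = t_v + (w - 1.0) + net.delay(v, u)
            heapq.heappush(heap, (arrival, rng.random(), v, u))

    push_attempts(cfg.source, cfg.start_time)
    while heap:
        arrival, _, v, u = heapq.heappop(heap)
        if u in times:
            continue
        times[u] = arrival
        infectors[u] = v
        push_attempts(u, arrival)

    return DiffusionOutcome(
        source=cfg.source,
        start_time=cfg.start_time,
        times=times,
        infectors=infectors,
    )


def sample_observers(
    net: Network,
    fraction: float,
    exclude: Iterable[int] = (),
    seed: int | None = None,
) -> list[int]:
    """Uniformly draw ``ceil(fraction * |V|)`` observers without replacement.

    Nodes in ``exclude`` are never selected.  At least one observer is
    always drawn.
    """
    if not 0 < fraction < 1:
        raise ParameterError(f"fraction must be in (0, 1), got {fraction}")
    pool = sorted(set(net.nodes) - set(exclude))
    k = max(1, math.ceil(fraction * net.n_nodes))
    if k > len(pool):
        raise ParameterError(
            f"cannot draw {k} observers from {len(pool)} eligible nodes"
        )
    rng = np.random.default_rng(seed)
    return sorted(int(x) for x in rng.choice(pool, size=k, replace=False))


def observe(outcome: DiffusionOutcome, observers: Sequence[int]) -> ObserverRecords:
    """Extract direction + timing records for the given observers."""
    records = []
    for o in observers:
        if o not in outcome.times:
            raise IncompleteObservationError(f"observer {o} was never infected")
        records.append(
            ObserverRecord(
                observer=o,
                direction=outcome.infectors[o],
                time=outcome.times[o],
            )
        )
    return ObserverRecords(records)
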