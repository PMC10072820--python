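"""Monte-Carlo evaluation harness for the source locators.

Protocol (one experiment): fix a network topology (synthetic recipe or a
file); per run, redraw the Gaussian edge delays, draw a fresh observer
set (5% of nodes by default), draw the true source uniformly outside the
observer set, simulate an SI diffusion, extract the observer records and
run each configured locator.  Performance is summarized per algorithm by

* precision — the fraction of runs with error hop exactly 0,
* mean error hop — unweighted shortest-path distance estimate↔truth,
* mean error delay — delay-weighted shortest-path distance, and
* the error-hop quartiles (for box plots made externally).

Runs where a locator returns no estimate (all candidates infeasible) are
counted separately and excluded from the error means.  All randomness
descends from one master seed via per-run child seeds, so a repeated
invocation reproduces the table bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SummaryError, UnreachableError
from .locate import LocatorConfig, SourceLocator
from .network import (
    DelayModel,
    GeneratorRecipe,
    Network,
    assign_delays,
    generate_network,
    shortest_delay,
    shortest_hop,
)
from .simulate import DiffusionConfig, observe, run_si, sample_observers

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "summarize",
    "error_hop",
    "error_delay",
]


def error_hop(net: Network, s_true: int, s_hat: int) -> int:
    """Unweighted shortest-path distance between truth and estimate."""
    return 0 if s_hat == s_true else shortest_hop(net, s_true, s_hat)


def error_delay(net: Network, s_true: int, s_hat: int) -> float:
    """Delay-weighted shortest-path distance between truth and estimate."""
    return 0.0 if s_hat == s_true else shortest_delay(net, s_true, s_hat)


@dataclass(frozen=True)
class ExperimentConfig:
    """One Monte-Carlo experiment.

    Exactly one of ``recipe`` / ``network`` is given.  ``source_policy``
    is "uniform" (uniform over non-observers, ``runs`` independent runs)
    or "every-node" (each node in turn as source; ``runs`` is then
    ignored and equals |V| minus skipped observers per round).
    ``refresh_delays`` controls whether delays are redrawn every run or
    realized once for the whole experiment.
    """

    recipe: GeneratorRecipe | None = None
    network: Network | None = None
    beta: float = 0.5
    observer_fraction: float = 0.05
    runs: int = 100
    delay_model: DelayModel = field(default_factory=DelayModel)
    source_policy: str = "uniform"
    refresh_delays: bool = True
    algorithms: tuple[str, ...] = ("osdis", "osbfs")
    exclude_observer_candidates: bool = True
    fallback_bfs: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.recipe is None) == (self.network is None):
            raise ParameterError("give exactly one of recipe or network")
        if self.runs < 1:
            raise ParameterError(f"runs must be >= 1, got {self.runs}")
        if not 0 < self.beta <= 1:
            raise ParameterError(f"beta must be in (0, 1], got {self.beta}")
        if self.source_policy not in ("uniform", "every-node"):
            raise ParameterError(f"unknown source_policy {self.source_policy!r}")
        bad = set(self.algorithms) - {"osdis", "osbfs"}
        if bad:
            raise ParameterError(f"unknown algorithms {sorted(bad)}")


_HEURISTIC = {"osdis": "dis", "osbfs": "bfs"}


@dataclass
class ExperimentResult:
    """Per-run records and the aggregated metrics table."""

    runs: pd.DataFrame
    metrics: pd.DataFrame
    config: ExperimentConfig


def _run_sources(cfg: ExperimentConfig, n_nodes: int) -> list[int | None]:
    """Source per run: None means 'draw uniformly outside the observers'."""
    if cfg.source_policy == "uniform":
        return [None] * cfg.runs
    return list(range(n_nodes))


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Execute the Monte-Carlo protocol and aggregate the metrics."""
    master = np.random.SeedSequence(cfg.seed)
    topo_seed, *_ = master.spawn(1)
    if cfg.network is not None:
        base_net = cfg.network
    else:
        base_net = generate_network(
            cfg.recipe, seed=int(topo_seed.generate_state(1)[0] % 2**31)
        )

    net = base_net
    if not cfg.refresh_delays or not base_net.has_delays:
        # one shared realization (only used when refresh_delays=False;
        # otherwise overwritten per run below)
        net = assign_delays(
            base_net, cfg.delay_model,
            seed=int(master.spawn(1)[0].generate_state(1)[0] % 2**31),
        )

    sources = _run_sources(cfg, base_net.n_nodes)
    rows = []
    for run_idx, forced_source in enumerate(sources):
        run_ss = np.random.SeedSequence(entropy=master.entropy, spawn_key=(1000 + run_idx,))
        s_delay, s_obs, s_src, s_sim = (
            int(c.generate_state(1)[0] % 2**31) for c in run_ss.spawn(4)
        )
        if cfg.refresh_delays:
            net = assign_delays(base_net, cfg.delay_model, seed=s_delay)

        observers = sample_observers(
            net, cfg.observer_fraction,
            exclude=() if forced_source is None else (forced_source,),
            seed=s_obs,
        )
        if forced_source is None:
            pool = sorted(set(net.nodes) - set(observers))
            rng = np.random.default_rng(s_src)
            source = int(rng.choice(pool))
        else:
            source = forced_source

        outcome = run_si(
            net, DiffusionConfig(source=source, beta=cfg.beta, seed=s_sim)
        )
        records = observe(outcome, observers)

        candidates = (
            tuple(sorted(set(net.nodes) - set(observers)))
            if cfg.exclude_observer_candidates
            else None
        )
        for alg in cfg.algorithms:
            loc_cfg = LocatorConfig(
                heuristic=_HEURISTIC[alg],
                candidates=candidates,
                fallback_bfs=cfg.fallback_bfs,
            )
            res = SourceLocator(net, records, config=loc_cfg).fit()
            if res.estimate is None:
                rows.append(
                    dict(run=run_idx, algorithm=alg, source=source,
                         estimate=None, feasible=False,
                         error_hop=np.nan, error_delay=np.nan)
                )
                continue
            try:
                eh = error_hop(net, source, res.estimate)
                ed = error_delay(net, source, res.estimate)
            except UnreachableError:
                eh, ed = np.nan, np.nan
            rows.append(
                dict(run=run_idx, algorithm=alg, source=source,
                     estimate=res.estimate, feasible=True,
                     error_hop=eh, error_delay=ed)
            )

    runs_df = pd.DataFrame(rows)
    return ExperimentResult(runs=runs_df, metrics=summarize(runs_df), config=cfg)


def summarize(runs: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-run records into the per-algorithm metrics table.

    Precision counts exact hits over *all* runs; error means and
    quartiles are taken over the located (feasible) runs only, with the
    infeasible count reported alongside.
    """
    if len(runs) == 0:
        raise SummaryError("no run records to summarize")
    out = []
    for alg, grp in runs.groupby("algorithm", sort=True):
        total = len(grp)
        located = grp[grp["feasible"]]
        hops = located["error_hop"].to_numpy(dtype=float)
        delays = located["error_delay"].to_numpy(dtype=float)
        n_loc = len(located)
        out.append(
            {
                "algorithm": alg,
                "runs": total,
                "located": n_loc,
                "infeasible": total - n_loc,
                "precision": float((hops == 0).sum()) / total,
                "mean_error_hop": float(np.mean(hops)) if n_loc else np.nan,
                "median_error_hop": float(np.median(hops)) if n_loc else np.nan,
                "q1_error_hop": float(np.percentile(hops, 25)) if n_loc else np.nan,
                "q3_error_hop": float(np.percentile(hops, 75)) if n_loc else np.nan,
                "mean_error_delay": float(np.mean(delays)) if n_loc else np.nan,
            }
        )
    return pd.DataFrame(out)
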