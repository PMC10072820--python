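"""The maximum-similarity source estimator and its BFS ablation."""

import networkx as nx
import numpy as np
import pytest

from osdis import (
    DiffusionConfig,
    LocatorConfig,
    Network,
    ObserverRecord,
    ObserverRecords,
    SourceLocator,
    bfs_tree,
    estimate_t_star,
    observe,
    order_similarity,
    osbfs_locate,
    osdis_locate,
    path_delays,
    relaxed_dis_tree,
    run_si,
    time_similarity,
)
from osdis.cli import build_fixture
from osdis.exceptions import LocatorError

from conftest import make_weighted, random_tree_net


def independent_candidate_scores(net, records, heuristic="dis"):
    """Oracle: rescore every candidate straight from the scoring
    primitives, bypassing the locator's bookkeeping."""
    obs = records.observers
    obs_times = records.times
    contradicted = {
        r.observer for r in records if r.direction is not None
    } if heuristic == "dis" else set()
    scores = {}
    for s in net.nodes:
        if s in contradicted:
            continue
        tree = (
            relaxed_dis_tree(net, s, records)
            if heuristic == "dis"
            else bfs_tree(net, s)
        )
        if tree is None:
            continue
        d = path_delays(tree, obs)
        z = sum(
            tree.cum_delay[v] - tree.cum_delay[p] for p, v in tree.edges()
        )
        t = estimate_t_star(obs_times, d, z)
        scores[s] = time_similarity(obs_times, t + d) * order_similarity(
            obs_times, t + d
        )
    return scores


class TestOsdisLocate:
    def test_tree_network_full_records_recovers_source(self):
        """On a tree with beta=1 and full observation, the source scores
        exactly 1 and wins; verified against an exhaustive rescoring of
        every candidate root."""
        net = random_tree_net(15, seed=8)
        s_star = 6
        out = run_si(net, DiffusionConfig(source=s_star, beta=1))
        rec = observe(out, [v for v in net.nodes if v != s_star])
        res = osdis_locate(net, rec)
        assert res.estimate == s_star
        assert res.best_score == pytest.approx(1.0)
        oracle = independent_candidate_scores(net, rec)
        assert max(oracle, key=lambda s: (oracle[s], -s)) == s_star

    def test_worked_example_fixture(self):
        """The bundled toy scenario: root 1 reproduces the observation
        times (4, 7, 6) exactly, product score 1."""
        net, rec = build_fixture()
        res = osdis_locate(net, rec)
        assert res.estimate == 1
        best = res.score_of(1)
        assert best.score == pytest.approx(1.0)
        assert best.t_star_hat == pytest.approx(1.0)
        tree = relaxed_dis_tree(net, 1, rec)
        meas = best.t_star_hat + path_delays(tree, rec.observers)
        assert meas == pytest.approx([4.0, 7.0, 6.0])

    def test_perturbed_fixture_scores_below_one(self):
        net, rec = build_fixture()
        bumped = ObserverRecords(
            [ObserverRecord(r.observer, r.direction, r.time + (1.0 if i == 0 else 0.0))
             for i, r in enumerate(rec)]
        )
        res = osdis_locate(net, bumped)
        assert res.best_score < 1.0

    def test_single_node_network(self):
        g = nx.Graph()
        g.add_node(0)
        rec = ObserverRecords([ObserverRecord(0, None, 3.0)])
        res = osdis_locate(Network(g), rec)
        assert res.estimate == 0

    def test_argmax_matches_independent_scan(self):
        net = random_tree_net(20, seed=4)
        out = run_si(net, DiffusionConfig(source=2, beta=0.5, seed=5))
        rec = observe(out, [5, 9, 13, 17])
        res = osdis_locate(net, rec)
        oracle = independent_candidate_scores(net, rec)
        df = res.scores
        feas = df[df["feasible"]]
        assert set(feas["candidate"]) == set(oracle)
        for _, row in feas.iterrows():
            assert row["score"] == pytest.approx(oracle[row["candidate"]])
        best = feas["score"].max()
        assert res.estimate == min(
            feas[feas["score"] == best]["candidate"]
        )

    def test_empty_records_raise(self, path_net):
        with pytest.raises(LocatorError):
            SourceLocator(path_net, ObserverRecords([]))

    def test_deterministic(self):
        net = random_tree_net(15, seed=1)
        out = run_si(net, DiffusionConfig(source=0, beta=0.5, seed=2))
        rec = observe(out, [3, 7])
        a, b = osdis_locate(net, rec), osdis_locate(net, rec)
        assert a.estimate == b.estimate
        assert a.scores.equals(b.scores)


class TestOsbfsLocate:
    def test_path_graph_end_source(self):
        net = make_weighted([(i, i + 1, 2.0 + i) for i in range(5)])
        out = run_si(net, DiffusionConfig(source=0, beta=1))
        rec = observe(out, [2, 4, 5])
        res = osbfs_locate(net, rec)
        assert res.estimate == 0
        oracle = independent_candidate_scores(net, rec, heuristic="bfs")
        assert max(oracle, key=lambda s: (oracle[s], -s)) == 0

    def test_identical_to_dis_on_trees(self):
        """A tree has a unique spanning tree, so both heuristics produce
        identical score tables whenever the DIS root is feasible."""
        net = random_tree_net(12, seed=9)
        out = run_si(net, DiffusionConfig(source=3, beta=1))
        rec = observe(out, [v for v in net.nodes if v != 3])
        dis = osdis_locate(net, rec).score_of(3)
        bfs = osbfs_locate(net, rec).score_of(3)
        assert dis.score == pytest.approx(bfs.score)

    def test_every_candidate_feasible(self):
        net = random_tree_net(12, seed=9)
        out = run_si(net, DiffusionConfig(source=3, beta=0.5, seed=0))
        rec = observe(out, [5, 7])
        res = osbfs_locate(net, rec)
        assert res.feasible_count == net.n_nodes


class TestConfigPolicies:
    def _conflicted(self):
        # path 0-1-2-3 with fabricated mutually-pointing observer
        # directions: any root other than the observers is infeasible
        net = make_weighted([(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])
        rec = ObserverRecords(
            [ObserverRecord(1, 2, 4.0), ObserverRecord(2, 1, 3.0)]
        )
        return net, rec

    def test_all_infeasible_returns_no_estimate(self):
        net, rec = self._conflicted()
        res = SourceLocator(
            net, rec, config=LocatorConfig(candidates=(0, 3))
        ).fit()
        assert res.estimate is None and res.feasible_count == 0

    def test_fallback_to_bfs(self):
        net, rec = self._conflicted()
        res = SourceLocator(
            net, rec,
            config=LocatorConfig(candidates=(0, 3), fallback_bfs=True),
        ).fit()
        assert res.estimate is not None
        assert res.heuristic_used == "bfs"

    def test_exclude_observer_candidates(self):
        net = random_tree_net(10, seed=5)
        out = run_si(net, DiffusionConfig(source=0, beta=1))
        rec = observe(out, [4, 6])
        res = SourceLocator(
            net, rec,
            config=LocatorConfig(candidates=(0, 1, 2, 3, 5, 7, 8, 9)),
        ).fit()
        assert res.estimate not in (4, 6)

    def test_random_tie_break_is_seeded(self):
        net, rec = build_fixture()
        cfg = LocatorConfig(tie_break="random", seed=11)
        a = SourceLocator(net, rec, config=cfg).fit().estimate
        b = SourceLocator(net, rec, config=cfg).fit().estimate
        assert a == b

    def test_mean_delay_mode(self):
        """With delay knowledge restricted to mu, measuring times use
        hop-depth * mu instead of realized delays."""
        net = random_tree_net(10, seed=6)
        out = run_si(net, DiffusionConfig(source=0, beta=1))
        rec = observe(out, [4, 6, 9])
        res = SourceLocator(
            net, rec,
            config=LocatorConfig(delay_mode="mean", delay_mean=4.0),
        ).fit()
        assert res.estimate is not None
        tree = relaxed_dis_tree(net, res.estimate, rec)
        sc = res.score_of(res.estimate)
        d = np.array([tree.depth(o) * 4.0 for o in rec.observers])
        meas = sc.t_star_hat + d
        assert sc.time_sim == pytest.approx(time_similarity(rec.times, meas))
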