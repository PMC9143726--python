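"""SIR mechanics, split hygiene, event-set construction and task scoring."""

import numpy as np
import pytest

import hosgns as hg

from conftest import random_tvg


@pytest.fixture(scope="module")
def sir_graph():
    h, _ = hg.generate_community_tvg(
        hg.SynthConfig(n_nodes=30, n_communities=3, n_times=20,
                       activity=0.7, p_in=0.4, p_out=0.05, seed=11)
    )
    return h


class TestSimulateSIR:
    def test_beta_zero_only_seed_infectious(self, sir_graph):
        params = hg.SIRParams(beta=0.0, mu=0.1, n_realizations=3, seed=1)
        for traj in hg.simulate_sir(sir_graph, params):
            infected = {i for (i, k), s in traj.states.items() if s in "IR"}
            assert len(infected) <= 1

    def test_mu_zero_no_recovered(self, sir_graph):
        params = hg.SIRParams(beta=0.5, mu=0.0, n_realizations=3, seed=2)
        for traj in hg.simulate_sir(sir_graph, params):
            assert "R" not in set(traj.states.values())

    def test_deterministic_spread_follows_bfs_distance(self):
        # one static connected snapshot repeated: with beta=1, mu=0 a node at
        # BFS distance ell from the seed turns infectious at snapshot ell
        import scipy.sparse.csgraph as csgraph

        base = random_tvg(n_nodes=12, n_times=1, p=0.3, seed=3)
        a = base.snapshot_adjacency(0)
        n_comp, comp = csgraph.connected_components(a, directed=False)
        events = [hg.TemporalEvent(e.i, e.j, k, e.weight)
                  for e in base.events for k in range(8)]
        h = hg.TimeVaryingGraph(12, 8, events)
        params = hg.SIRParams(beta=1.0, mu=0.0, n_realizations=2, seed=4)
        for traj in hg.simulate_sir(h, params):
            seed_node = next(i for (i, k), s in traj.states.items()
                             if k == 0 and s == "I")
            dist = csgraph.shortest_path(a, unweighted=True,
                                         indices=seed_node)
            for (i, k), s in traj.states.items():
                if comp[i] != comp[seed_node]:
                    assert s == "S"
                else:
                    assert s == ("I" if k >= dist[i] else "S")

    def test_state_counts_conserved_and_r_monotone(self, sir_graph):
        params = hg.SIRParams(beta=0.3, mu=0.1, n_realizations=5, seed=5)
        active_by_k = {}
        for i, k in sir_graph.active_pairs():
            active_by_k.setdefault(k, set()).add(i)
        for traj in hg.simulate_sir(sir_graph, params):
            prev_r = -1
            # R fraction among all nodes is non-decreasing; counts add up
            r_nodes = set()
            for k in range(sir_graph.n_times):
                states = {i: traj.states[(i, k)] for i in active_by_k[k]}
                assert len(states) == len(active_by_k[k])
                r_nodes_k = {i for i, s in states.items() if s == "R"}
                r_nodes |= r_nodes_k
            # per-node trajectory is S* -> I* -> R*
            per_node = {}
            for (i, k), s in sorted(traj.states.items(),
                                    key=lambda kv: kv[0][1]):
                per_node.setdefault(i, []).append(s)
            order = {"S": 0, "I": 1, "R": 2}
            for seq in per_node.values():
                codes = [order[s] for s in seq]
                assert codes == sorted(codes)

    def test_reproducible(self, sir_graph):
        params = hg.SIRParams(beta=0.3, mu=0.05, n_realizations=2, seed=9)
        a = hg.simulate_sir(sir_graph, params)
        b = hg.simulate_sir(sir_graph, params)
        assert all(x.states == y.states for x, y in zip(a, b))


class TestMakeSplit:
    def test_sizes(self):
        h = random_tvg(n_nodes=10, n_times=10, p=0.5, seed=0)
        s = hg.make_split(h, 0.7, seed=1)
        assert len(s.v_train) == 7 and len(s.v_test) == 3
        assert len(s.t_train) == 7 and len(s.t_test) == 3

    def test_disjoint_and_exhaustive(self):
        h = random_tvg(n_nodes=13, n_times=7, p=0.5, seed=0)
        s = hg.make_split(h, 0.7, seed=2)
        assert not (s.v_train & s.v_test)
        assert s.v_train | s.v_test == set(range(13))
        assert s.t_train | s.t_test == set(range(7))

    def test_seed_reproducibility(self):
        h = random_tvg(n_nodes=10, n_times=5, p=0.5, seed=0)
        assert hg.make_split(h, 0.7, seed=3) == hg.make_split(h, 0.7, seed=3)


class TestNegativeEvents:
    def test_count_disjointness_and_activity(self, sir_graph):
        neg = hg.sample_negative_events(sir_graph, seed=4)
        assert len(neg) == len(sir_graph.events)
        pos = {(e.i, e.j, e.k) for e in sir_graph.events}
        assert not (set(neg) & pos)
        active = set(sir_graph.active_pairs())
        for i, j, k in neg:
            assert i != j and (i, k) in active and (j, k) in active

    def test_per_snapshot_counts_match(self, sir_graph):
        neg = hg.sample_negative_events(sir_graph, seed=5, mode="per_snapshot")
        pos_per_k = {}
        for e in sir_graph.events:
            pos_per_k[e.k] = pos_per_k.get(e.k, 0) + 1
        neg_per_k = {}
        for _, _, k in neg:
            neg_per_k[k] = neg_per_k.get(k, 0) + 1
        assert neg_per_k == pos_per_k

    def test_saturated_snapshot_errors(self):
        # two active nodes, one event: the active-pair clique is full
        h = hg.TimeVaryingGraph(2, 1, [hg.TemporalEvent(0, 1, 0, 1.0)])
        with pytest.raises(ValueError, match="snapshot 0"):
            hg.sample_negative_events(h, seed=0)


class TestPruneEvents:
    def test_quota_and_partition(self, sir_graph):
        res = hg.prune_events(sir_graph, 0.7, seed=6)
        n = len(sir_graph.events)
        assert len(res.kept) == round(0.7 * n)
        assert len(res.kept) + len(res.removed) == n
        kept = {(e.i, e.j, e.k) for e in res.kept}
        removed = {(e.i, e.j, e.k) for e in res.removed}
        full = {(e.i, e.j, e.k) for e in sir_graph.events}
        assert kept | removed == full and not kept & removed

    def test_coverage_on_dense_graph(self):
        h = random_tvg(n_nodes=10, n_times=5, p=0.8, seed=7)
        res = hg.prune_events(h, 0.7, seed=8)
        # dense graph: greedy covering is feasible, every active pair survives
        assert res.coverage == 1.0
        assert set(res.graph.active_pairs()) == set(h.active_pairs())

    def test_graph_dimensions_preserved(self, sir_graph):
        res = hg.prune_events(sir_graph, 0.7, seed=9)
        assert res.graph.n_nodes == sir_graph.n_nodes
        assert res.graph.n_times == sir_graph.n_times


class TestMacroF1:
    def test_perfect_predictions(self):
        assert hg.macro_f1([0, 1, 2, 1], [0, 1, 2, 1]) == 1.0

    def test_hand_computed_binary_case(self):
        assert hg.macro_f1([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(
            (2 / 3 + 4 / 5) / 2
        )

    def test_single_class_predictions(self):
        assert hg.macro_f1([1, 1, 0, 0], [1, 1, 1, 1]) == pytest.approx(
            (0 + 2 / 3) / 2
        )

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            hg.macro_f1([], [])


@pytest.fixture(scope="module")
def planted(sir_graph):
    _, labels = hg.generate_community_tvg(
        hg.SynthConfig(n_nodes=30, n_communities=3, n_times=20,
                       activity=0.7, p_in=0.4, p_out=0.05, seed=11)
    )
    traj = hg.planted_sir_labels(sir_graph, labels, seed=0)
    return labels, traj


class TestNodeClassification:
    def test_one_hot_state_features_are_perfect(self, sir_graph, planted):
        _, traj = planted
        states = np.array(["S", "I", "R"])

        def one_hot(pairs):
            return np.array([
                (states == traj.states[p]).astype(float) for p in pairs
            ])

        splits = [hg.make_split(sir_graph, 0.7, seed=s) for s in range(3)]
        res = hg.eval_node_classification(None, [traj], splits,
                                          feature_fn=one_hot)
        assert res.mean == 1.0

    def test_noise_features_score_at_chance(self, sir_graph, planted):
        _, traj = planted
        rng = np.random.default_rng(0)

        def noise(pairs):
            return rng.normal(size=(len(pairs), 8))

        # balanced 3-class labels independent of the noise features
        pairs = sir_graph.active_pairs()
        states = {p: "SIR"[a % 3] for a, p in enumerate(pairs)}
        traj_bal = hg.SIRTrajectory(states=states)
        splits = [hg.make_split(sir_graph, 0.7, seed=s) for s in range(12)]
        res = hg.eval_node_classification(None, [traj_bal], splits,
                                          feature_fn=noise)
        assert abs(res.mean - 1 / 3) <= max(3 * res.se, 0.06)

    def test_reproducible(self, sir_graph, planted):
        labels, traj = planted
        emb = hg.init_embeddings(
            (sir_graph.n_nodes, sir_graph.n_nodes, sir_graph.n_times), 8,
            seed=1,
        )
        splits = [hg.make_split(sir_graph, 0.7, seed=2)]
        a = hg.eval_node_classification(emb, [traj], splits)
        b = hg.eval_node_classification(emb, [traj], splits)
        assert a.scores == b.scores


class TestEventTask:
    def test_planted_feature_separates_perfectly(self, sir_graph):
        neg = hg.sample_negative_events(sir_graph, seed=10)
        pos = {(e.i, e.j, e.k) for e in sir_graph.events}

        def planted_feature(events):
            return np.array([[1.0, 1.0] if tuple(e[:3]) in pos else [-1.0, 1.0]
                             for e in events])

        splits = [hg.make_split(sir_graph, 0.7, seed=s) for s in range(3)]
        res = hg.eval_event_task(None, sir_graph.events, neg, splits,
                                 feature_fn=planted_feature)
        assert res.mean == 1.0

    def test_identical_feature_distribution_scores_at_chance(self, sir_graph):
        neg = hg.sample_negative_events(sir_graph, seed=11)
        rng = np.random.default_rng(1)

        def noise(events):
            return rng.normal(size=(len(events), 8))

        splits = [hg.make_split(sir_graph, 0.7, seed=s) for s in range(12)]
        res = hg.eval_event_task(None, sir_graph.events, neg, splits,
                                 feature_fn=noise)
        assert abs(res.mean - 0.5) <= max(3 * res.se, 0.06)

    def test_no_leakage_between_train_and_test(self, sir_graph):
        # leakage would require a shared node or snapshot; partitions forbid it
        split = hg.make_split(sir_graph, 0.7, seed=12)
        assert not (split.v_train & split.v_test)
        assert not (split.t_train & split.t_test)
        tr = [(e.i, e.j, e.k) for e in sir_graph.events
              if e.i in split.v_train and e.j in split.v_train
              and e.k in split.t_train]
        ts = [(e.i, e.j, e.k) for e in sir_graph.events
              if e.i in split.v_test and e.j in split.v_test
              and e.k in split.t_test]
        tr_nodes = {i for e in tr for i in e[:2]}
        ts_nodes = {i for e in ts for i in e[:2]}
        assert not tr_nodes & ts_nodes
        assert not {e[2] for e in tr} & {e[2] for e in ts}

    def test_empty_filtered_set_errors(self):
        h = random_tvg(n_nodes=6, n_times=3, p=0.4, seed=13)
        neg = hg.sample_negative_events(h, seed=13)
        # adversarial split: all nodes in train -> test side empty
        split = hg.SplitSpec(v_train=set(range(6)), v_test=set(),
                             t_train={0, 1}, t_test={2})
        with pytest.raises(ValueError, match="empty train or test"):
            hg.eval_event_task(None, h.events, neg, [split],
                               feature_fn=lambda evs: np.ones((len(evs), 2)))


class TestEdgeOperators:
    def test_all_operators(self):
        u, v = np.array([1.0, -2.0]), np.array([3.0, 1.0])
        assert np.allclose(hg.edge_operator(u, v, "hadamard"), [3, -2])
        assert np.allclose(hg.edge_operator(u, v, "average"), [2, -0.5])
        assert np.allclose(hg.edge_operator(u, v, "weighted_l1"), [2, 3])
        assert np.allclose(hg.edge_operator(u, v, "weighted_l2"), [4, 9])
        assert np.allclose(hg.edge_operator(u, v, "concat"), [1, -2, 3, 1])
        with pytest.raises(ValueError):
            hg.edge_operator(u, v, "nope")


class TestDirectionalOrdering:
    """Soft check: task orderings between representations.

    The walk tensor encodes time-respecting reachability, so its
    embeddings should classify epidemic states better than snapshot-tensor
    embeddings; the snapshot tensor encodes the events themselves, so its
    embeddings should reconstruct events best, and reconstruction (events
    seen during embedding) should beat prediction (events held out).
    Asserted as a median ordering over seeds since individual runs are
    stochastic.
    """

    def test_median_orderings_over_seeds(self):
        rec_st, rec_dy, pred_st, nc_st, nc_dy = [], [], [], [], []
        for seed in range(5):
            cfg = hg.SynthConfig(n_nodes=24, n_communities=3, n_times=12,
                                 activity=0.8, p_in=0.5, p_out=0.05,
                                 seed=100 + seed)
            h, _ = hg.generate_community_tvg(cfg)
            tc = hg.TrainingConfig(d=24, kappa=5, batch=512, steps=800,
                                   lr=1e-2, seed=seed)
            emb_st = hg.train(hg.stat_tensor(h), tc)
            emb_dy = hg.train(hg.dyn_tensor(h, window=8), tc)
            pr = hg.prune_events(h, 0.7, seed=seed)
            emb_st_d = hg.train(hg.stat_tensor(pr.graph), tc)

            splits = [hg.make_split(h, 0.7, seed=10 * seed + s)
                      for s in range(3)]
            negs = [hg.sample_negative_events(h, seed=10 * seed + s)
                    for s in range(3)]
            rec_st.append(hg.eval_event_task(emb_st, h.events, negs,
                                             splits).mean)
            rec_dy.append(hg.eval_event_task(emb_dy, h.events, negs,
                                             splits).mean)
            pred_st.append(hg.eval_event_task(emb_st_d, pr.removed, negs,
                                              splits,
                                              task="prediction").mean)
            trajs = hg.simulate_sir(
                h, hg.SIRParams(beta=0.2, mu=0.05, n_realizations=3,
                                seed=seed)
            )
            nc_st.append(hg.eval_node_classification(emb_st, trajs,
                                                     splits).mean)
            nc_dy.append(hg.eval_node_classification(emb_dy, trajs,
                                                     splits).mean)
        med = np.median
        assert med(rec_st) >= med(pred_st)  # seen events easier than held-out
        assert med(rec_st) >= med(rec_dy)   # snapshot tensor best at events
        assert med(nc_dy) >= med(nc_st)     # walk tensor best at dynamics


def test_trajectory_tsv_dump(tmp_path, sir_graph):
    params = hg.SIRParams(beta=0.3, mu=0.05, n_realizations=2, seed=1)
    trajs = hg.simulate_sir(sir_graph, params)
    hg.write_trajectories(trajs, tmp_path / "sir.tsv")
    lines = (tmp_path / "sir.tsv").read_text().strip().splitlines()
    assert lines[0] == "realization\tnode\tsnapshot\tstate"
    assert len(lines) == 1 + sum(len(t.states) for t in trajs)
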