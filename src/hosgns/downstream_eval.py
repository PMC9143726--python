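"""Downstream evaluation: SIR epidemics, splits, event sets, Macro-F1 tasks.

Three tasks probe what the embeddings encode:

* **node classification** — classify each active node-time pair into its
  S/I/R epidemic state (from simulated spreading on the same graph) using
  the Hadamard feature ``w_i o t_k``;
* **temporal event reconstruction** — separate the true events of H from an
  equal number of sampled non-events among active nodes, using event
  features ``w o c o t [o s]`` from embeddings trained on the full graph;
* **missing event prediction** — the same classifier, but embeddings are
  trained on a 70%-event pruned graph and the positives are the removed
  events.

Train/test splits partition nodes and times independently (70/30); train
items use only train nodes at train times and test items only test nodes
at test times, so no node or snapshot is shared across the boundary.
Scores are Macro-F1 from an L2-regularized logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.multiclass import OneVsRestClassifier

from ._rng import stream
from .hosgns_train import EmbeddingSet
from .tempgraph import TemporalEvent, TimeVaryingGraph

__all__ = [
    "SIRParams",
    "SIRTrajectory",
    "SplitSpec",
    "PruneResult",
    "TaskResult",
    "simulate_sir",
    "make_split",
    "sample_negative_events",
    "prune_events",
    "eval_node_classification",
    "eval_event_task",
    "macro_f1",
    "edge_operator",
    "write_trajectories",
]

_S, _I, _R = 0, 1, 2
_STATE_NAMES = np.array(["S", "I", "R"])


@dataclass
class SIRParams:
    """Discrete-time SIR parameters on snapshot sequences.

    ``beta`` is the per-unit-weight infection parameter: a susceptible node
    in contact with an infectious one through an event of weight ``w``
    is infected with probability ``1 - (1 - beta)^w`` for that snapshot.
    ``mu`` is the per-snapshot recovery probability.  One initial
    infectious node is drawn uniformly among the nodes active at the first
    snapshot.
    """

    beta: float
    mu: float
    n_realizations: int = 30
    initial_infected: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.beta <= 1.0 and 0.0 <= self.mu <= 1.0):
            raise ValueError("beta and mu must lie in [0, 1]")


@dataclass
class SIRTrajectory:
    """Epidemic state per active node-time pair of one realization."""

    states: dict[tuple[int, int], str]

    def labels_for(self, pairs) -> np.ndarray:
        return np.array([self.states[p] for p in pairs])


def simulate_sir(h: TimeVaryingGraph, params: SIRParams) -> list[SIRTrajectory]:
    """Run ``n_realizations`` discrete-time SIR chains over the snapshots.

    Updates are synchronous: infections and recoveries drawn at snapshot k
    take effect at k+1.  States are recorded only at active pairs.
    """
    rng = stream(params.seed, "sir")
    i_arr, j_arr, k_arr, w_arr = h.event_arrays()
    events_by_k: dict[int, list[int]] = {}
    for row, k in enumerate(k_arr):
        events_by_k.setdefault(int(k), []).append(row)
    active_by_k: dict[int, list[int]] = {}
    for i, k in h.active_pairs():
        active_by_k.setdefault(k, []).append(i)
    first_active = active_by_k.get(0, list(range(h.n_nodes)))

    out = []
    for _ in range(params.n_realizations):
        state = np.full(h.n_nodes, _S, dtype=np.int8)
        seeds = rng.choice(first_active, size=min(params.initial_infected,
                                                  len(first_active)),
                           replace=False)
        state[seeds] = _I
        rec: dict[tuple[int, int], str] = {}
        for k in range(h.n_times):
            for i in active_by_k.get(k, ()):
                rec[(i, k)] = _STATE_NAMES[state[i]]
            new_inf = []
            for row in events_by_k.get(k, ()):
                a, b, w = int(i_arr[row]), int(j_arr[row]), w_arr[row]
                for u, v in ((a, b), (b, a)):
                    if state[u] == _S and state[v] == _I:
                        if rng.random() < 1.0 - (1.0 - params.beta) ** w:
                            new_inf.append(u)
            recovering = (state == _I) & (rng.random(h.n_nodes) < params.mu)
            state[recovering] = _R
            state[new_inf] = _I
        out.append(SIRTrajectory(states=rec))
    return out


def write_trajectories(trajectories, path) -> None:
    """TSV dump: realization, node, snapshot, state."""
    with open(path, "w") as fh:
        fh.write("realization\tnode\tsnapshot\tstate\n")
        for r, traj in enumerate(trajectories):
            for (i, k), s in sorted(traj.states.items()):
                fh.write(f"{r}\t{i}\t{k}\t{s}\n")


# -- splits and event sets ------------------------------------------------


@dataclass
class SplitSpec:
    """Disjoint node and time partitions for leakage-free evaluation."""

    v_train: set[int]
    v_test: set[int]
    t_train: set[int]
    t_test: set[int]

    def __post_init__(self):
        if self.v_train & self.v_test or self.t_train & self.t_test:
            raise ValueError("train/test partitions overlap")


def make_split(h: TimeVaryingGraph, proportion: float = 0.7,
               seed: int = 0) -> SplitSpec:
    if not (0.0 < proportion < 1.0):
        raise ValueError("proportion must be in (0, 1)")
    rng = stream(seed, "split")
    v = rng.permutation(h.n_nodes)
    t = rng.permutation(h.n_times)
    nv = int(round(proportion * h.n_nodes))
    nt = int(round(proportion * h.n_times))
    return SplitSpec(
        v_train=set(map(int, v[:nv])), v_test=set(map(int, v[nv:])),
        t_train=set(map(int, t[:nt])), t_test=set(map(int, t[nt:])),
    )


def sample_negative_events(
    h: TimeVaryingGraph, seed: int = 0, mode: str = "per_snapshot"
) -> list[tuple[int, int, int]]:
    """Sample |E| non-events among the nodes active at each snapshot.

    ``per_snapshot`` (default) matches the per-snapshot count of positives
    exactly, removing any time-marginal signal from the negatives;
    ``global`` only matches the total, drawing snapshots proportionally to
    available non-edges.
    """
    if mode not in ("per_snapshot", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = stream(seed, "negative_events")
    pos_by_k: dict[int, set[tuple[int, int]]] = {}
    for e in h.events:
        pos_by_k.setdefault(e.k, set()).add((e.i, e.j))
    active_by_k: dict[int, list[int]] = {}
    for i, k in h.active_pairs():
        active_by_k.setdefault(k, []).append(i)

    free_by_k: dict[int, list[tuple[int, int]]] = {}
    for k, act in active_by_k.items():
        act = sorted(act)
        existing = pos_by_k.get(k, set())
        free_by_k[k] = [
            (act[a], act[b])
            for a in range(len(act))
            for b in range(a + 1, len(act))
            if (act[a], act[b]) not in existing
        ]

    out: list[tuple[int, int, int]] = []
    if mode == "per_snapshot":
        for k in sorted(pos_by_k):
            need = len(pos_by_k[k])
            free = free_by_k[k]
            if len(free) < need:
                raise ValueError(
                    f"snapshot {k}: only {len(free)} non-events available "
                    f"for {need} positives (active-pair clique saturated)"
                )
            for r in rng.choice(len(free), size=need, replace=False):
                i, j = free[r]
                out.append((i, j, k))
    else:
        pool = [(i, j, k) for k, free in free_by_k.items() for (i, j) in free]
        need = len(h.events)
        if len(pool) < need:
            raise ValueError(f"only {len(pool)} non-events available for {need}")
        for r in rng.choice(len(pool), size=need, replace=False):
            out.append(pool[r])
    return out


@dataclass
class PruneResult:
    """A pruned graph, the removed events, and active-pair coverage."""

    graph: TimeVaryingGraph
    kept: list[TemporalEvent]
    removed: list[TemporalEvent]
    coverage: float


def prune_events(h: TimeVaryingGraph, fraction: float = 0.7,
                 seed: int = 0) -> PruneResult:
    """Keep round(fraction |E|) events, preserving active pairs when feasible.

    A greedy pass first retains one incident event per active pair (in
    random order); the quota is then filled uniformly.  If the covering
    set alone exceeds the quota it is trimmed at random and the resulting
    coverage fraction is reported.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    rng = stream(seed, "prune")
    n_keep = int(round(fraction * len(h.events)))
    order = rng.permutation(len(h.events))
    covered: set[tuple[int, int]] = set()
    cover_rows: list[int] = []
    rest: list[int] = []
    for row in order:
        e = h.events[row]
        pairs = {(e.i, e.k), (e.j, e.k)}
        if pairs - covered:
            cover_rows.append(row)
            covered |= pairs
        else:
            rest.append(row)
    if len(cover_rows) > n_keep:
        keep_rows = [cover_rows[r] for r in
                     rng.choice(len(cover_rows), size=n_keep, replace=False)]
    else:
        extra = rng.choice(len(rest), size=n_keep - len(cover_rows),
                           replace=False) if rest else []
        keep_rows = cover_rows + [rest[r] for r in extra]
    keep_set = set(keep_rows)
    kept = [h.events[r] for r in sorted(keep_set)]
    removed = [h.events[r] for r in range(len(h.events)) if r not in keep_set]
    pruned = TimeVaryingGraph(
        n_nodes=h.n_nodes, n_times=h.n_times, events=kept,
        node_ids=list(h.node_ids), time_values=list(h.time_values),
    )
    all_pairs = set(h.active_pairs())
    kept_pairs = set(pruned.active_pairs())
    coverage = len(kept_pairs) / len(all_pairs) if all_pairs else 1.0
    return PruneResult(graph=pruned, kept=kept, removed=removed,
                       coverage=coverage)


# -- classifiers and scores -----------------------------------------------


def macro_f1(labels, predictions) -> float:
    """Unweighted mean of per-class F1 scores."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if len(labels) == 0:
        raise ValueError("empty input")
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions differ in length")
    return float(f1_score(labels, predictions, average="macro", zero_division=0))


def _fit_predict(x_tr, y_tr, x_ts):
    base = LogisticRegression(C=1.0, max_iter=1000)
    clf = base if len(np.unique(y_tr)) <= 2 else OneVsRestClassifier(base)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x_tr, y_tr)
    return clf.predict(x_ts)


@dataclass
class TaskResult:
    """Mean Macro-F1 with standard error over evaluation repetitions."""

    scores: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))

    @property
    def se(self) -> float:
        if len(self.scores) < 2:
            return 0.0
        return float(np.std(self.scores, ddof=1) / np.sqrt(len(self.scores)))

    @property
    def n(self) -> int:
        return len(self.scores)


def eval_node_classification(
    emb: EmbeddingSet | None,
    trajectories,
    splits,
    feature_fn=None,
) -> TaskResult:
    """Macro-F1 of S/I/R state classification from ``w_i o t_k`` features.

    ``splits`` may be one :class:`SplitSpec` or a list; every trajectory is
    scored against every split.  A realization whose training set misses a
    state class is skipped with a warning.  ``feature_fn(pairs)`` overrides
    the embedding features (used for calibration baselines).
    """
    if isinstance(splits, SplitSpec):
        splits = [splits]
    if feature_fn is None:
        if emb is None:
            raise ValueError("either embeddings or feature_fn is required")

        def feature_fn(pairs):
            arr = np.asarray(pairs)
            return emb.W[arr[:, 0]] * emb.T[arr[:, 1]]

    scores = []
    for split in splits:
        for traj in trajectories:
            tr = [p for p in traj.states
                  if p[0] in split.v_train and p[1] in split.t_train]
            ts = [p for p in traj.states
                  if p[0] in split.v_test and p[1] in split.t_test]
            if not tr or not ts:
                warnings.warn("empty train or test pair set; skipping realization")
                continue
            y_tr = traj.labels_for(tr)
            y_ts = traj.labels_for(ts)
            if len(np.unique(y_tr)) < len(np.unique(np.concatenate([y_tr, y_ts]))):
                warnings.warn("state class absent from train set; skipping")
                continue
            pred = _fit_predict(feature_fn(tr), y_tr, feature_fn(ts))
            scores.append(macro_f1(y_ts, pred))
    if not scores:
        raise ValueError("no realization produced a valid train/test set")
    return TaskResult(scores=scores)


def _event_features(emb: EmbeddingSet, events) -> np.ndarray:
    arr = np.asarray([(e[0], e[1], e[2]) for e in events], dtype=np.int64)
    out = emb.W[arr[:, 0]] * emb.C[arr[:, 1]] * emb.T[arr[:, 2]]
    if emb.order == 4:
        out = out * emb.S[arr[:, 2]]
    return out


def eval_event_task(
    emb: EmbeddingSet | None,
    positives,
    negatives,
    splits,
    task: str = "reconstruction",
    feature_fn=None,
) -> TaskResult:
    """Macro-F1 of event-vs-non-event classification with Hadamard features.

    For ``reconstruction`` the positives are the events the embeddings were
    trained on; for ``prediction`` they are events removed before training.
    ``negatives`` is a list of non-event sets, one per split (a single set
    is broadcast).  Train events need both endpoints in the train nodes and
    their snapshot in the train times; test events symmetrically.
    """
    if task not in ("reconstruction", "prediction"):
        raise ValueError(f"unknown task {task!r}")
    if isinstance(splits, SplitSpec):
        splits = [splits]
    def _is_single_set(neg):
        first = neg[0]
        return (len(first) == 3 and np.isscalar(first[0])) or isinstance(
            first, TemporalEvent
        )

    if _is_single_set(negatives):
        negatives = [negatives] * len(splits)
    if len(negatives) != len(splits):
        raise ValueError("need one negative-event set per split")
    if feature_fn is None:
        if emb is None:
            raise ValueError("either embeddings or feature_fn is required")
        feature_fn = lambda evs: _event_features(emb, evs)

    pos = [(e.i, e.j, e.k) if isinstance(e, TemporalEvent) else tuple(e[:3])
           for e in positives]
    scores = []
    for split, neg in zip(splits, negatives):
        neg = [(e.i, e.j, e.k) if isinstance(e, TemporalEvent) else tuple(e[:3])
               for e in neg]

        def _filter(evs, v_set, t_set):
            return [e for e in evs
                    if e[0] in v_set and e[1] in v_set and e[2] in t_set]

        pos_tr = _filter(pos, split.v_train, split.t_train)
        pos_ts = _filter(pos, split.v_test, split.t_test)
        neg_tr = _filter(neg, split.v_train, split.t_train)
        neg_ts = _filter(neg, split.v_test, split.t_test)
        if not (pos_tr and neg_tr) or not (pos_ts and neg_ts):
            raise ValueError(
                "empty train or test event set after split filtering; "
                "use a denser graph or a different split proportion"
            )
        x_tr = np.vstack([feature_fn(pos_tr), feature_fn(neg_tr)])
        y_tr = np.concatenate([np.ones(len(pos_tr)), np.zeros(len(neg_tr))])
        x_ts = np.vstack([feature_fn(pos_ts), feature_fn(neg_ts)])
        y_ts = np.concatenate([np.ones(len(pos_ts)), np.zeros(len(neg_ts))])
        pred = _fit_predict(x_tr, y_tr, x_ts)
        scores.append(macro_f1(y_ts, pred))
    return TaskResult(scores=scores)


def edge_operator(u: np.ndarray, v: np.ndarray, op: str = "hadamard") -> np.ndarray:
    """Generic binary operators for pairing vector embeddings."""
    if op == "hadamard":
        return u * v
    if op == "average":
        return (u + v) / 2.0
    if op == "weighted_l1":
        return np.abs(u - v)
    if op == "weighted_l2":
        return (u - v) ** 2
    if op == "concat":
        return np.concatenate([u, v], axis=-1)
    raise ValueError(f"unknown operator {op!r}")
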