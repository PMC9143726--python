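"""Synthetic time-varying contact networks with known structure.

The generator emulates face-to-face proximity data: a fixed population
split into communities (classes), sparse bursty activation per snapshot,
denser within-community than between-community contacts, and positive
integer event weights standing for raw-interaction counts inside an
aggregation window.  Because activation is stochastic, the active
node-time pairs are a strict subset of V x T, as in empirical data.

Defaults are sized so that exact tensor construction, training and all
three downstream tasks run quickly while the community/temporal structure
remains easily recoverable: 60 nodes in 3 communities over 40 snapshots,
activity 0.6, within-community edge probability 0.3 versus 0.02 between,
and weights 1 + Poisson(1.5) (mean 2.5, in the range of count-aggregated
contact data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import stream
from .tempgraph import TemporalEvent, TimeVaryingGraph

__all__ = [
    "SynthConfig",
    "generate_community_tvg",
    "toy_fig1_graph",
    "TOY_SUPRA_EDGES",
    "planted_sir_labels",
    "random_lowrank_tensor",
    "write_metadata",
]


@dataclass
class SynthConfig:
    n_nodes: int = 60
    n_communities: int = 3
    n_times: int = 40
    p_in: float = 0.3
    p_out: float = 0.02
    activity: float = 0.6
    weight_rate: float = 1.5  # weights are 1 + Poisson(weight_rate)
    seed: int = 0

    def __post_init__(self):
        for name in ("p_in", "p_out", "activity"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_nodes % self.n_communities:
            raise ValueError("n_communities must divide n_nodes")

    def community_labels(self) -> np.ndarray:
        size = self.n_nodes // self.n_communities
        return np.repeat(np.arange(self.n_communities), size)

    def expected_within_events_per_snapshot(self) -> float:
        """Closed-form mean within-community event count of one snapshot."""
        m = self.n_nodes // self.n_communities
        pairs = self.n_communities * m * (m - 1) / 2
        return pairs * self.activity**2 * self.p_in

    def expected_between_events_per_snapshot(self) -> float:
        m = self.n_nodes // self.n_communities
        pairs = (self.n_nodes * (self.n_nodes - 1) / 2
                 - self.n_communities * m * (m - 1) / 2)
        return pairs * self.activity**2 * self.p_out

    def expected_mean_weight(self) -> float:
        return 1.0 + self.weight_rate


def generate_community_tvg(
    config: SynthConfig,
) -> tuple[TimeVaryingGraph, np.ndarray]:
    """Sample a community-structured temporal contact graph.

    Per snapshot each node activates independently; simultaneously active
    pairs are joined with probability ``p_in`` (same community) or
    ``p_out``; weights are 1 + Poisson(weight_rate).  Snapshots that end
    up with no events are dropped and the rest re-indexed, mirroring the
    empirical aggregation convention.  Returns the graph and the
    ground-truth community label per node.
    """
    rng = stream(config.seed, "synth")
    labels = config.community_labels()
    events: list[TemporalEvent] = []
    k_out = 0
    kept_windows = []
    for k in range(config.n_times):
        active = np.flatnonzero(rng.random(config.n_nodes) < config.activity)
        snap = []
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                i, j = int(active[a]), int(active[b])
                p = config.p_in if labels[i] == labels[j] else config.p_out
                if rng.random() < p:
                    w = 1.0 + rng.poisson(config.weight_rate)
                    snap.append((i, j, w))
        if snap:
            events.extend(TemporalEvent(i, j, k_out, w) for i, j, w in snap)
            kept_windows.append(k)
            k_out += 1
    if not events:
        raise ValueError("degenerate configuration produced an empty graph")
    h = TimeVaryingGraph(
        n_nodes=config.n_nodes, n_times=k_out, events=events,
        time_values=kept_windows,
    )
    return h, labels


def write_metadata(labels, path) -> None:
    """Node metadata TSV: node_id, class label."""
    with open(path, "w") as fh:
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{lab}\n")


# -- hand-checkable fixtures ----------------------------------------------


def toy_fig1_graph() -> TimeVaryingGraph:
    """A fixed 4-node, 3-snapshot graph exercising every supra rule.

    Node 1 and node 3 are inactive in the middle snapshot, so their
    cross-/self-coupling edges skip a snapshot; the last-snapshot events
    generate no outgoing edges.
    """
    events = [
        TemporalEvent(0, 1, 0, 2.0),
        TemporalEvent(2, 3, 0, 1.0),
        TemporalEvent(0, 2, 1, 1.0),
        TemporalEvent(1, 2, 2, 3.0),
        TemporalEvent(0, 3, 2, 1.0),
    ]
    return TimeVaryingGraph(n_nodes=4, n_times=3, events=events)


#: expected directed supra edges of :func:`toy_fig1_graph`, derived by hand
#: from the coupling rules: ((node, time), (node, time), weight)
TOY_SUPRA_EDGES = [
    ((1, 0), (0, 1), 2.0),  # cross: event (0,1,0), node 0 next active at 1
    ((0, 0), (0, 1), 1.0),  # self-coupling of node 0 across 0 -> 1
    ((0, 0), (1, 2), 2.0),  # cross: event (0,1,0), node 1 next active at 2
    ((1, 0), (1, 2), 1.0),  # self-coupling of node 1 across 0 -> 2
    ((3, 0), (2, 1), 1.0),  # cross: event (2,3,0), node 2 next active at 1
    ((2, 0), (2, 1), 1.0),  # self-coupling of node 2 across 0 -> 1
    ((2, 0), (3, 2), 1.0),  # cross: event (2,3,0), node 3 next active at 2
    ((3, 0), (3, 2), 1.0),  # self-coupling of node 3 across 0 -> 2
    ((2, 1), (0, 2), 1.0),  # cross: event (0,2,1), node 0 next active at 2
    ((0, 1), (0, 2), 1.0),  # self-coupling of node 0 across 1 -> 2
    ((0, 1), (2, 2), 1.0),  # cross: event (0,2,1), node 2 next active at 2
    ((2, 1), (2, 2), 1.0),  # self-coupling of node 2 across 1 -> 2
]


def random_lowrank_tensor(shape=(20, 20, 10), rank=50, scale=3.0,
                          seed: int = 0):
    """A random probability tensor whose shifted PMI has bounded rank.

    Entries are a softmax of a random multilinear score tensor of the given
    rank, so ``log P`` (hence the shifted PMI, which differs from it by
    rank-one marginal corrections) has multilinear rank at most
    ``rank + 4``.  This places an embedding dimension ``d >= rank + 4`` in
    the full-rank regime, where the skip-gram stationary point reproduces
    the shifted PMI exactly — the setting in which reconstruction tests
    are meaningful.  ``scale`` sets the spread of the scores (log-odds).
    """
    from .cooc_tensors import CoocTensor

    rng = stream(seed, "lowrank")
    factors = [rng.normal(0.0, (1.0 / rank) ** 0.5, size=(n, rank)) * scale
               for n in shape]
    subs = ",".join(f"{ax}r" for ax in "ijkl"[: len(shape)])
    scores = np.einsum(f"{subs}->{'ijkl'[:len(shape)]}", *factors)
    p = np.exp(scores)
    p /= p.sum()
    idx = np.indices(shape).reshape(len(shape), -1).T
    return CoocTensor(shape=tuple(shape), indices=idx, values=p.ravel())


def planted_sir_labels(h: TimeVaryingGraph, labels, seed: int = 0):
    """Deterministic S/I/R-like states separable by community and time block.

    Snapshots are cut into three equal blocks; the state of an active pair
    is a fixed function of (community, block), so one-hot features of the
    community-block cell separate the classes perfectly.  The seed only
    rotates which (community, block) cells map to which state.
    """
    from .downstream_eval import SIRTrajectory

    rng = stream(seed, "planted")
    offset = int(rng.integers(3))
    labels = np.asarray(labels)
    n_blocks = 3
    block_len = max(1, -(-h.n_times // n_blocks))
    states = {}
    names = np.array(["S", "I", "R"])
    for i, k in h.active_pairs():
        block = min(k // block_len, n_blocks - 1)
        states[(i, k)] = str(names[(int(labels[i]) + block + offset) % 3])
    return SIRTrajectory(states=states)
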