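"""Time-varying graph data model, I/O, aggregation and supra-adjacency.

A time-varying graph is a sequence of weighted undirected snapshots over a
shared node set; events are quadruples ``(i, j, k, w)`` with ``i < j``,
snapshot index ``k`` and positive weight ``w`` (for count-aggregated contact
data, the number of raw interactions of the pair inside window ``k``).

The supra-adjacency representation lifts the temporal graph to a static
graph over the *active* node-time pairs: for each event ``(i, j, t0)``, if
``i`` is next active at ``t1 > t0`` a cross-coupling edge ``(j^(t0),
i^(t1))`` with the event weight is added (and symmetrically for ``j``), plus
self-coupling edges ``(i^(t0), i^(t1))`` of unit weight.  Random walks on
this graph follow time-respecting paths of the original dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

__all__ = [
    "TemporalEvent",
    "TimeVaryingGraph",
    "SupraGraph",
    "GraphStats",
    "read_contact_list",
    "aggregate_windows",
    "graph_stats",
    "build_supra",
    "active_nodes",
    "nodes_density",
    "links_density",
    "write_edge_list",
    "write_supra",
]


class ContactListError(ValueError):
    """Malformed contact-list input."""


@dataclass(frozen=True)
class TemporalEvent:
    """An undirected interaction ``(i, j)`` at snapshot ``k`` with weight ``w``."""

    i: int
    j: int
    k: int
    weight: float

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError(f"self-loop event ({self.i}, {self.j}, {self.k})")
        if self.weight <= 0:
            raise ValueError(f"non-positive event weight {self.weight}")


@dataclass
class TimeVaryingGraph:
    """A temporal graph: node count, snapshot count and event list.

    Events store each undirected pair once with ``i < j``.  ``node_ids``
    maps internal contiguous indices back to the original labels;
    ``time_values`` maps snapshot indices to the original timestamps or
    window indices (empty windows are dropped on aggregation, so snapshot
    indices are always contiguous).  ``resolution`` is the native sampling
    interval in seconds for raw contact data, if known.
    """

    n_nodes: int
    n_times: int
    events: list[TemporalEvent]
    node_ids: list = field(default_factory=list)
    time_values: list = field(default_factory=list)
    resolution: float | None = None

    def __post_init__(self):
        if not self.node_ids:
            self.node_ids = list(range(self.n_nodes))
        if not self.time_values:
            self.time_values = list(range(self.n_times))
        for e in self.events:
            if not (0 <= e.k < self.n_times):
                raise ValueError(f"snapshot index {e.k} out of range [0, {self.n_times})")
            if not (0 <= e.i < self.n_nodes and 0 <= e.j < self.n_nodes):
                raise ValueError(f"node index out of range in event {e}")

    # -- array views ------------------------------------------------------

    def event_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Events as parallel arrays ``(i, j, k, w)``."""
        if not self.events:
            z = np.empty(0, dtype=np.int64)
            return z, z.copy(), z.copy(), np.empty(0)
        arr = np.array([(e.i, e.j, e.k, e.weight) for e in self.events])
        return (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2].astype(np.int64),
            arr[:, 3],
        )

    def snapshot_adjacency(self, k: int) -> sp.csr_matrix:
        """Symmetric weighted adjacency of snapshot ``k``."""
        i, j, kk, w = self.event_arrays()
        m = kk == k
        a = sp.coo_matrix(
            (np.concatenate([w[m], w[m]]),
             (np.concatenate([i[m], j[m]]), np.concatenate([j[m], i[m]]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return a.tocsr()

    def volume(self) -> float:
        """vol(H): total interaction weight, both orientations counted."""
        return 2.0 * float(sum(e.weight for e in self.events))

    def active_pairs(self) -> list[tuple[int, int]]:
        """Active node-time pairs (i, k), lexicographic in (k, i)."""
        pairs = {(e.i, e.k) for e in self.events} | {(e.j, e.k) for e in self.events}
        return sorted(pairs, key=lambda p: (p[1], p[0]))


@dataclass
class GraphStats:
    """The seven summary statistics of a time-varying graph."""

    n_nodes: int
    n_times: int
    n_events: int
    n_active: int
    avg_weight: float
    nodes_density: float
    links_density: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_times": self.n_times,
            "n_events": self.n_events,
            "n_active": self.n_active,
            "avg_weight": self.avg_weight,
            "nodes_density": self.nodes_density,
            "links_density": self.links_density,
        }


def nodes_density(n_active: int, n_nodes: int, n_times: int) -> float:
    """|V^(T)| / (|V| |T|): fraction of node-time pairs that are active."""
    return n_active / (n_nodes * n_times)


def links_density(n_events: int, n_nodes: int, n_times: int) -> float:
    """2|E| / (|V|(|V|-1)|T|): fraction of realizable temporal edges present."""
    return 2.0 * n_events / (n_nodes * (n_nodes - 1) * n_times)


def graph_stats(h: TimeVaryingGraph) -> GraphStats:
    n_events = len(h.events)
    n_active = len(h.active_pairs())
    avg_w = float(np.mean([e.weight for e in h.events])) if h.events else 0.0
    return GraphStats(
        n_nodes=h.n_nodes,
        n_times=h.n_times,
        n_events=n_events,
        n_active=n_active,
        avg_weight=avg_w,
        nodes_density=nodes_density(n_active, h.n_nodes, h.n_times),
        links_density=links_density(n_events, h.n_nodes, h.n_times),
    )


def active_nodes(h: TimeVaryingGraph) -> list[tuple[int, int]]:
    """Ordered active node-time pairs (i, k), sorted by (k, i)."""
    return h.active_pairs()


# -- contact-list I/O -----------------------------------------------------


def read_contact_list(
    path, format: str = "tij", resolution: float = 20.0
) -> TimeVaryingGraph:
    """Read a contact list into a time-varying graph.

    ``tij`` lines are ``t i j`` (one raw interaction per line; duplicates
    accumulate into the weight); ``weighted_edge_list`` lines are
    ``i j k w``.  Node labels are remapped to contiguous 0-based indices
    (mapping kept in ``node_ids``); snapshots are re-indexed contiguously
    preserving temporal order, with the originals kept in ``time_values``.
    For ``tij`` input the snapshot axis is the raw timestamp sequence —
    pass the result to :func:`aggregate_windows` before analysis.
    """
    if format not in ("tij", "weighted_edge_list", "weighted"):
        raise ValueError(f"unknown format {format!r}")
    text = Path(path).read_text()
    ncol = 3 if format == "tij" else 4
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != ncol:
            raise ContactListError(
                f"line {lineno}: expected {ncol} columns, got {len(parts)}"
            )
        try:
            if format == "tij":
                t = float(parts[0])
                u, v = parts[1], parts[2]
                w = 1.0
            else:
                u, v = parts[0], parts[1]
                t = float(parts[2])
                w = float(parts[3])
        except ValueError as exc:
            raise ContactListError(f"line {lineno}: {exc}") from None
        if u == v:
            raise ContactListError(f"line {lineno}: self-loop ({u}, {v})")
        if w <= 0:
            raise ContactListError(f"line {lineno}: non-positive weight {w}")
        rows.append((t, u, v, w))
    if not rows:
        raise ContactListError(f"empty contact list: {path}")

    def _key(x):
        try:
            return (0, float(x))
        except ValueError:
            return (1, x)

    node_labels = sorted({r[1] for r in rows} | {r[2] for r in rows}, key=_key)
    node_index = {lab: idx for idx, lab in enumerate(node_labels)}
    times = sorted({r[0] for r in rows})
    time_index = {t: idx for idx, t in enumerate(times)}

    acc: dict[tuple[int, int, int], float] = {}
    for t, u, v, w in rows:
        a, b = sorted((node_index[u], node_index[v]))
        key = (a, b, time_index[t])
        acc[key] = acc.get(key, 0.0) + w
    events = [TemporalEvent(i, j, k, w) for (i, j, k), w in sorted(acc.items())]
    labels = [_maybe_int(x) for x in node_labels]
    return TimeVaryingGraph(
        n_nodes=len(node_labels),
        n_times=len(times),
        events=events,
        node_ids=labels,
        time_values=list(times),
        resolution=resolution if format == "tij" else None,
    )


def _maybe_int(x):
    try:
        f = float(x)
        return int(f) if f == int(f) else f
    except (TypeError, ValueError):
        return x


def aggregate_windows(raw: TimeVaryingGraph, window: float) -> TimeVaryingGraph:
    """Aggregate a raw-resolution graph onto windows of ``window`` seconds.

    The weight of ``(i, j, k)`` becomes the total raw weight of the pair in
    window ``k``; windows without interactions are dropped and the
    remaining snapshots re-indexed contiguously (the original window index
    of each snapshot is kept in ``time_values``).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    res = raw.resolution if raw.resolution is not None else 1.0
    if window < res:
        raise ValueError(f"window {window} smaller than resolution {res}")
    acc: dict[tuple[int, int, int], float] = {}
    for e in raw.events:
        t = raw.time_values[e.k]
        win = int(float(t) // window)
        key = (e.i, e.j, win)
        acc[key] = acc.get(key, 0.0) + e.weight
    windows = sorted({k for (_, _, k) in acc})
    win_index = {w: idx for idx, w in enumerate(windows)}
    events = [
        TemporalEvent(i, j, win_index[k], w) for (i, j, k), w in sorted(acc.items())
    ]
    return TimeVaryingGraph(
        n_nodes=raw.n_nodes,
        n_times=len(windows),
        events=events,
        node_ids=list(raw.node_ids),
        time_values=windows,
        resolution=None,
    )


def write_edge_list(h: TimeVaryingGraph, path) -> None:
    """Write the canonical weighted temporal edge list ``i j k w`` (TSV)."""
    with open(path, "w") as fh:
        for e in h.events:
            fh.write(f"{e.i}\t{e.j}\t{e.k}\t{e.weight:.10g}\n")


# -- supra-adjacency ------------------------------------------------------


@dataclass
class SupraGraph:
    """Time-respecting static graph over the active node-time pairs.

    ``nodes[a] = (i, k)`` lists the supra nodes in (k, i) order.  The
    directed form has every edge pointing from an earlier to a later
    snapshot; ``adjacency`` is its symmetrization, used for random walks.
    """

    nodes: list[tuple[int, int]]
    adj_directed: sp.csr_matrix

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def adjacency(self) -> sp.csr_matrix:
        return (self.adj_directed + self.adj_directed.T).tocsr()

    def strengths(self) -> np.ndarray:
        """Weighted degrees d_{i^(k)} of the symmetric form."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def volume(self) -> float:
        """vol(G_H): sum of all symmetric adjacency entries."""
        return float(self.adjacency.sum())

    def transition(self) -> sp.csr_matrix:
        """Row-normalized operator P = D^{-1} A (zero rows for isolated nodes)."""
        d = self.strengths()
        inv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
        return sp.diags(inv).dot(self.adjacency).tocsr()

    def index(self) -> dict[tuple[int, int], int]:
        return {p: a for a, p in enumerate(self.nodes)}


def build_supra(h: TimeVaryingGraph) -> SupraGraph:
    """Apply the cross-/self-coupling rules to build the supra graph.

    For each event ``(i, j, t0)``: if ``i`` is next active at ``t1 > t0``,
    add cross-coupling edge ``(j^(t0), i^(t1))`` with the event weight and
    self-coupling edge ``(i^(t0), i^(t1))`` with weight 1; symmetrically
    for ``j``.  Self-coupling edges arising repeatedly keep weight 1.
    Events at a node's last activation contribute no outgoing edges.
    """
    pairs = h.active_pairs()
    idx = {p: a for a, p in enumerate(pairs)}
    # next activation snapshot per node
    active_times: dict[int, list[int]] = {}
    for i, k in pairs:
        active_times.setdefault(i, []).append(k)
    nxt: dict[tuple[int, int], int | None] = {}
    for i, ks in active_times.items():
        ks.sort()
        for a, k in enumerate(ks):
            nxt[(i, k)] = ks[a + 1] if a + 1 < len(ks) else None

    cross: dict[tuple[int, int], float] = {}
    self_c: dict[tuple[int, int], float] = {}
    for e in h.events:
        for u, v in ((e.i, e.j), (e.j, e.i)):
            t1 = nxt[(u, e.k)]
            if t1 is not None:
                key = (idx[(v, e.k)], idx[(u, t1)])
                cross[key] = cross.get(key, 0.0) + e.weight
                self_c[(idx[(u, e.k)], idx[(u, t1)])] = 1.0

    edges = dict(cross)
    for key, w in self_c.items():
        edges[key] = edges.get(key, 0.0) + w
    n = len(pairs)
    if edges:
        r, c = zip(*edges.keys())
        adj = sp.coo_matrix((list(edges.values()), (r, c)), shape=(n, n)).tocsr()
    else:
        adj = sp.csr_matrix((n, n))
    return SupraGraph(nodes=pairs, adj_directed=adj)


def write_supra(g: SupraGraph, edge_path, node_path) -> None:
    """Write the symmetric supra edge list and the supra-node index table."""
    with open(node_path, "w") as fh:
        for a, (i, k) in enumerate(g.nodes):
            fh.write(f"{a}\t{i}\t{k}\n")
    coo = sp.triu(g.adjacency).tocoo()
    with open(edge_path, "w") as fh:
        for a, b, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")
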