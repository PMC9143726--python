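"""Closed-form higher-order co-occurrence tensors and shifted-PMI tensors.

Three probability tensors summarize a time-varying graph H:

* ``stat`` (order 3): entry ``(i, j, k) = w(i,j,k) / vol(H)`` — the relative
  frequency of node pairs in temporal edges (both orientations stored, so
  the tensor is symmetric in ``i <-> j`` and sums to 1).
* ``dyn`` (order 4): entry ``(i, j, k, l)`` is the probability that a
  degree-weighted random walk on the symmetrized supra-adjacency graph
  co-locates ``i^(k)`` and ``j^(l)`` within a window of ``T`` steps,

      (1/2T) sum_{r=1..T} [ d_a/vol (P^r)_{ab} + d_b/vol (P^r)_{ba} ]

  with ``a = i^(k)``, ``b = j^(l)``, strengths ``d``, walk operator
  ``P = D^{-1} A`` and ``vol`` the total strength.
* ``stat_dyn`` (order 4): the average ``(stat * delta_{kl} + dyn) / 2``.

The shifted PMI of any of these, ``log(P_D / prod of marginals) - log k``,
is the tensor the multilinear skip-gram objective implicitly factorizes.
The same window-``T`` walk statistics on an ordinary static graph give the
expected PMI matrix that DeepWalk-style skip-gram factorizes; it is exposed
here (:func:`deepwalk_pmi`) as the degenerate order-2 case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .tempgraph import SupraGraph, TimeVaryingGraph, build_supra

__all__ = [
    "TensorConfig",
    "CoocTensor",
    "SPMITensor",
    "stat_tensor",
    "dyn_tensor",
    "statdyn_tensor",
    "marginals",
    "spmi_tensor",
    "deepwalk_cooc",
    "deepwalk_pmi",
    "save_tensor",
    "load_tensor",
]

#: refuse exact construction beyond this many stored entries
DEFAULT_NNZ_BUDGET = 20_000_000


@dataclass
class TensorConfig:
    """Choice of representation and random-walk window.

    ``stat`` is 3rd order; ``dyn`` and ``stat_dyn`` are 4th order.  The
    window ``T`` is the context size of the underlying random walks; it
    only affects the walk-based (``dyn``) part.
    """

    representation: str = "stat"
    window: int = 10

    def __post_init__(self):
        if self.representation not in ("stat", "dyn", "stat_dyn"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    @property
    def order(self) -> int:
        return 3 if self.representation == "stat" else 4


@dataclass
class CoocTensor:
    """Sparse nonnegative probability tensor with per-mode marginals.

    ``indices`` is an ``(nnz, order)`` integer array, ``values`` the
    matching probabilities.  Zero entries are never stored; entries and
    every marginal sum to 1.
    """

    shape: tuple[int, ...]
    indices: np.ndarray
    values: np.ndarray
    _marginals: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.indices.ndim != 2 or self.indices.shape[1] != len(self.shape):
            raise ValueError("indices must be (nnz, order)")
        if len(self.values) != len(self.indices):
            raise ValueError("values/indices length mismatch")
        if np.any(self.values <= 0):
            raise ValueError("stored entries must be positive")
        total = self.values.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tensor entries sum to {total!r}, expected 1")

    @property
    def order(self) -> int:
        return len(self.shape)

    @property
    def nnz(self) -> int:
        return len(self.values)

    def marginal(self, mode: int) -> np.ndarray:
        """Mode-``mode`` marginal distribution (sums over all other modes)."""
        if self._marginals is None:
            self._marginals = [
                np.bincount(self.indices[:, m], weights=self.values,
                            minlength=self.shape[m])
                for m in range(self.order)
            ]
        return self._marginals[mode]

    def all_marginals(self) -> list[np.ndarray]:
        return [self.marginal(m) for m in range(self.order)]

    def noise_values(self) -> np.ndarray:
        """Product-of-marginals probability P_N at each stored index."""
        out = np.ones(self.nnz)
        for m in range(self.order):
            out *= self.marginal(m)[self.indices[:, m]]
        return out

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.shape)
        dense[tuple(self.indices.T)] = self.values
        return dense


def marginals(p: CoocTensor) -> list[np.ndarray]:
    """Per-mode marginal distributions of a co-occurrence tensor."""
    return p.all_marginals()


@dataclass
class SPMITensor:
    """Shifted PMI values on the support of a source probability tensor."""

    shape: tuple[int, ...]
    indices: np.ndarray
    values: np.ndarray
    kappa: float

    @property
    def nnz(self) -> int:
        return len(self.values)


def spmi_tensor(p: CoocTensor, kappa: float = 1.0) -> SPMITensor:
    """SPMI_kappa = log(P_D / P_N) - log(kappa), on the support only."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    vals = np.log(p.values) - np.log(p.noise_values()) - np.log(kappa)
    return SPMITensor(shape=p.shape, indices=p.indices.copy(), values=vals,
                      kappa=kappa)


# -- constructions --------------------------------------------------------


def stat_tensor(h: TimeVaryingGraph) -> CoocTensor:
    """Order-3 snapshot tensor: entry (i,j,k) = w(i,j,k)/vol(H), both orientations."""
    if not h.events:
        raise ValueError("empty graph")
    i, j, k, w = h.event_arrays()
    vol = 2.0 * w.sum()
    idx = np.concatenate(
        [np.stack([i, j, k], axis=1), np.stack([j, i, k], axis=1)]
    )
    vals = np.concatenate([w, w]) / vol
    return CoocTensor(shape=(h.n_nodes, h.n_nodes, h.n_times), indices=idx,
                      values=vals)


def _walk_cooc_matrix(adj: sp.csr_matrix, window: int) -> sp.csr_matrix:
    """Symmetric co-occurrence matrix (1/2T) sum_r [Dvol P^r + (Dvol P^r)^T]."""
    d = np.asarray(adj.sum(axis=1)).ravel()
    vol = d.sum()
    inv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    p = sp.diags(inv).dot(adj).tocsr()
    x = sp.diags(d / vol).dot(p).tocsr()  # Dvol P^1
    acc = x.copy()
    for _ in range(window - 1):
        x = x.dot(p)
        acc = acc + x
    m = (acc + acc.T) * (1.0 / (2.0 * window))
    m.eliminate_zeros()
    return m.tocsr()


def dyn_tensor(
    h: TimeVaryingGraph,
    window: int = 10,
    supra: SupraGraph | None = None,
    nnz_budget: int = DEFAULT_NNZ_BUDGET,
) -> CoocTensor:
    """Order-4 walk tensor from the symmetrized supra-adjacency graph.

    Disconnected supra graphs are handled transparently: walk operators
    never mix components and the normalization is by the global volume.
    """
    if supra is None:
        supra = build_supra(h)
    if supra.n_nodes == 0 or supra.adjacency.nnz == 0:
        raise ValueError("empty supra-adjacency graph")
    m = _walk_cooc_matrix(supra.adjacency, window).tocoo()
    if m.nnz > nnz_budget:
        raise ValueError(
            f"dyn tensor would hold {m.nnz} entries (> budget {nnz_budget}); "
            "consider Monte-Carlo walk sampling or a smaller window"
        )
    nodes = np.asarray(supra.nodes, dtype=np.int64)  # (n_supra, 2) of (i, k)
    ia, ka = nodes[m.row, 0], nodes[m.row, 1]
    jb, lb = nodes[m.col, 0], nodes[m.col, 1]
    idx = np.stack([ia, jb, ka, lb], axis=1)
    return CoocTensor(shape=(h.n_nodes, h.n_nodes, h.n_times, h.n_times),
                      indices=idx, values=m.data)


def statdyn_tensor(
    h: TimeVaryingGraph,
    window: int = 10,
    supra: SupraGraph | None = None,
) -> CoocTensor:
    """Order-4 average: (stat(i,j,k) delta_{kl} + dyn(i,j,k,l)) / 2."""
    st = stat_tensor(h)
    dy = dyn_tensor(h, window=window, supra=supra)
    st_idx4 = np.column_stack([st.indices, st.indices[:, 2]])  # l = k
    idx = np.concatenate([st_idx4, dy.indices])
    vals = np.concatenate([st.values, dy.values]) * 0.5
    uniq, inv = np.unique(idx, axis=0, return_inverse=True)
    merged = np.bincount(inv, weights=vals, minlength=len(uniq))
    return CoocTensor(shape=dy.shape, indices=uniq, values=merged)


def build_tensor(
    h: TimeVaryingGraph, config: TensorConfig
) -> CoocTensor:
    """Dispatch on the configured representation."""
    if config.representation == "stat":
        return stat_tensor(h)
    if config.representation == "dyn":
        return dyn_tensor(h, window=config.window)
    return statdyn_tensor(h, window=config.window)


# -- order-2 (classical skip-gram) oracle path ----------------------------


def deepwalk_cooc(adj, window: int) -> CoocTensor:
    """Order-2 window co-occurrence distribution of walks on a static graph."""
    adj = sp.csr_matrix(adj, dtype=float)
    _require_connected(adj)
    m = _walk_cooc_matrix(adj, window).tocoo()
    idx = np.stack([m.row, m.col], axis=1)
    return CoocTensor(shape=adj.shape, indices=idx, values=m.data)


def deepwalk_pmi(adj, window: int) -> np.ndarray:
    """Expected PMI matrix implicitly factorized by window-``T`` skip-gram.

    Entries for pairs never co-occurring within the window are ``-inf``.
    The input graph must be connected (the stationary walk distribution is
    otherwise not unique).
    """
    adj = sp.csr_matrix(adj, dtype=float)
    _require_connected(adj)
    m = _walk_cooc_matrix(adj, window).toarray()
    d = np.asarray(adj.sum(axis=1)).ravel()
    vol = d.sum()
    noise = np.outer(d / vol, d / vol)
    with np.errstate(divide="ignore"):
        return np.log(m) - np.log(noise)


def _require_connected(adj: sp.csr_matrix) -> None:
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp != 1:
        raise ValueError(f"graph is disconnected ({ncomp} components)")


# -- serialization --------------------------------------------------------


def save_tensor(p: CoocTensor, path) -> None:
    """Coordinate text format: header ``order mode_sizes... nnz``, then rows."""
    with open(path, "w") as fh:
        fh.write(" ".join(map(str, (p.order, *p.shape, p.nnz))) + "\n")
        for idx, v in zip(p.indices, p.values):
            fh.write(" ".join(map(str, idx)) + f" {v:.17g}\n")


def load_tensor(path) -> CoocTensor:
    with open(path) as fh:
        header = fh.readline().split()
        order = int(header[0])
        shape = tuple(int(x) for x in header[1 : 1 + order])
        nnz = int(header[1 + order])
        idx = np.empty((nnz, order), dtype=np.int64)
        vals = np.empty(nnz)
        for r in range(nnz):
            parts = fh.readline().split()
            idx[r] = [int(x) for x in parts[:order]]
            vals[r] = float(parts[order])
    return CoocTensor(shape=shape, indices=idx, values=vals)
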