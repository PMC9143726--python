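"""Higher-order skip-gram with negative sampling (HOSGNS).

Factor matrices W (nodes), C (context nodes), T (times) and, at 4th order,
S (context times) of rank ``d`` are trained so that the sigmoid of the
multilinear score

    score(i, j, k[, l]) = sum_r W_ir C_jr T_kr [S_lr]

classifies index tuples drawn from the data distribution ``P_D`` (a
:class:`~hosgns.cooc_tensors.CoocTensor`) against tuples drawn from the
product of its marginals ``P_N``.  At full rank the stationary point of
this objective reconstructs the shifted PMI tensor
``log(P_D/P_N) - log(kappa)``, so training is an implicit sparse tensor
factorization; at order 2 the model degenerates to classical SGNS.

Training runs mini-batch Adam on the sampled binary cross-entropy

    L = -(1/B) [ sum_{B pos} log s(score) + sum_{kB neg} log s(-score) ]

whose expectation equals the exact objective implemented in
:func:`loss_exact`.  All randomness derives from a single seed through
named streams (init / positives / negatives).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from ._rng import stream
from .cooc_tensors import CoocTensor, SPMITensor

__all__ = [
    "EmbeddingSet",
    "TrainingConfig",
    "TrainingDiverged",
    "multilinear_score",
    "init_embeddings",
    "count_parameters",
    "sample_positives",
    "sample_negatives",
    "loss_exact",
    "loss_exact_grad",
    "sampled_loss",
    "train",
    "combine",
    "reconstruction",
    "spmi_rmse",
    "save_embeddings",
    "load_embedding_matrix",
]

#: full enumeration cap for the exact loss (product of mode sizes)
DEFAULT_EXACT_CAP = 4_000_000


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class EmbeddingSet:
    """Rank-``d`` factor matrices, one per tensor mode.

    Order 3 holds ``[W, C, T]`` with shapes (|V|, d), (|V|, d), (|T|, d);
    order 4 adds ``S`` of shape (|T|, d).
    """

    factors: list[np.ndarray]

    def __post_init__(self):
        self.factors = [np.asarray(f, dtype=float) for f in self.factors]
        d = self.factors[0].shape[1]
        if any(f.ndim != 2 or f.shape[1] != d for f in self.factors):
            raise ValueError("all factors must be 2-D with equal rank")

    @property
    def order(self) -> int:
        return len(self.factors)

    @property
    def d(self) -> int:
        return self.factors[0].shape[1]

    @property
    def W(self) -> np.ndarray:
        return self.factors[0]

    @property
    def C(self) -> np.ndarray:
        return self.factors[1]

    @property
    def T(self) -> np.ndarray:
        return self.factors[2]

    @property
    def S(self) -> np.ndarray:
        if self.order < 4:
            raise AttributeError("S exists only at 4th order")
        return self.factors[3]

    def copy(self) -> "EmbeddingSet":
        return EmbeddingSet([f.copy() for f in self.factors])

    def scores(self, indices: np.ndarray) -> np.ndarray:
        """Multilinear scores of a batch of index tuples (n, order)."""
        indices = np.asarray(indices)
        prod = self.factors[0][indices[:, 0]].copy()
        for m in range(1, self.order):
            prod *= self.factors[m][indices[:, m]]
        return prod.sum(axis=1)


def multilinear_score(vectors) -> float:
    """Higher-order inner product: sum over r of the product of components."""
    vecs = [np.asarray(v, dtype=float) for v in vectors]
    d = vecs[0].shape
    if any(v.shape != d for v in vecs):
        raise ValueError("vectors must share the same dimension")
    prod = np.ones_like(vecs[0])
    for v in vecs:
        prod = prod * v
    return float(prod.sum())


def init_embeddings(
    sizes, d: int, seed: int = 0, scale: float = 1.0
) -> EmbeddingSet:
    """Uniform initialization in ``scale * [-0.5/d, 0.5/d]`` per factor."""
    rng = stream(seed, "init")
    bound = scale * 0.5 / d
    return EmbeddingSet(
        [rng.uniform(-bound, bound, size=(n, d)) for n in sizes]
    )


def count_parameters(emb: EmbeddingSet) -> int:
    """Total trainable parameters: sum of factor-matrix sizes.

    With shared node/time axes this is (2|V| + |T|) d at order 3 and
    (2|V| + 2|T|) d at order 4 — linear in |V| + |T|.
    """
    return int(sum(f.size for f in emb.factors))


# -- sampling -------------------------------------------------------------


def sample_positives(p: CoocTensor, batch: int, rng) -> np.ndarray:
    """I.i.d. draws of index tuples from the sparse data distribution."""
    if isinstance(rng, (int, np.integer)):
        rng = stream(int(rng), "positives")
    rows = rng.choice(p.nnz, size=batch, p=p.values)
    return p.indices[rows]


def sample_negatives(
    positives: np.ndarray,
    marginals: list[np.ndarray],
    kappa: int,
    rng,
    mode: str = "fix_first",
) -> np.ndarray:
    """Noise tuples for a batch of positives.

    ``fix_first`` keeps the first index of each positive and redraws the
    remaining modes independently from their marginals (kappa noise tuples
    per positive); ``product`` redraws every mode.  Either way the noise
    tuples follow the product of marginal distributions in the resampled
    modes.
    """
    if isinstance(rng, (int, np.integer)):
        rng = stream(int(rng), "negatives")
    if mode not in ("fix_first", "product"):
        raise ValueError(f"unknown negative-sampling mode {mode!r}")
    positives = np.asarray(positives)
    n = len(positives) * int(kappa)
    order = positives.shape[1]
    out = np.empty((n, order), dtype=np.int64)
    if mode == "fix_first":
        out[:, 0] = np.repeat(positives[:, 0], kappa)
        start = 1
    else:
        start = 0
    for m in range(start, order):
        pm = marginals[m]
        out[:, m] = rng.choice(len(pm), size=n, p=pm)
    return out


# -- exact objective ------------------------------------------------------


def _dense_scores(emb: EmbeddingSet, shape) -> np.ndarray:
    subs = "ir,jr,kr,lr"[: 3 * emb.order - 1]
    out = "ijkl"[: emb.order]
    return np.einsum(f"{subs}->{out}", *emb.factors)


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # stable: log s(x) = -log(1 + e^{-x}) = min(x,0) - log1p(e^{-|x|})
    return np.minimum(x, 0.0) - np.log1p(np.exp(-np.abs(x)))


def loss_exact(
    p: CoocTensor,
    emb: EmbeddingSet,
    kappa: float,
    cap: int = DEFAULT_EXACT_CAP,
) -> float:
    """Exact objective, enumerated over the full index range.

    - sum_{all tuples} [ P_D log s(score) + kappa P_N log s(-score) ].
    At all-zero embeddings every score is 0, so the loss is
    ``(1 + kappa) log 2``.
    """
    if int(np.prod(p.shape)) > cap:
        raise ValueError(
            f"full enumeration of {np.prod(p.shape)} tuples exceeds cap {cap}"
        )
    scores = _dense_scores(emb, p.shape)
    pd = p.to_dense()
    pn = p.marginal(0)
    for m in range(1, p.order):
        pn = np.multiply.outer(pn, p.marginal(m))
    loss = -(pd * _log_sigmoid(scores) + kappa * pn * _log_sigmoid(-scores))
    return float(loss.sum())


def loss_exact_grad(
    p: CoocTensor,
    emb: EmbeddingSet,
    kappa: float,
    cap: int = DEFAULT_EXACT_CAP,
) -> tuple[float, list[np.ndarray]]:
    """Exact loss and its analytic gradients w.r.t. every factor matrix."""
    if int(np.prod(p.shape)) > cap:
        raise ValueError("full enumeration exceeds cap")
    scores = _dense_scores(emb, p.shape)
    sig = 1.0 / (1.0 + np.exp(-scores))
    pd = p.to_dense()
    pn = p.marginal(0)
    for m in range(1, p.order):
        pn = np.multiply.outer(pn, p.marginal(m))
    loss = -(pd * _log_sigmoid(scores) + kappa * pn * _log_sigmoid(-scores))
    # d loss / d score
    g = -(pd * (1.0 - sig) - kappa * pn * sig)
    axes = "ijkl"[: p.order]
    grads = []
    for m in range(p.order):
        others = [emb.factors[mm] for mm in range(p.order) if mm != m]
        subs = ",".join(f"{axes[mm]}r" for mm in range(p.order) if mm != m)
        grads.append(np.einsum(f"{axes},{subs}->{axes[m]}r", g, *others))
    return float(loss.sum()), grads


def sampled_loss(
    p: CoocTensor,
    emb: EmbeddingSet,
    kappa: int,
    batch: int,
    rng_pos,
    rng_neg,
    negative_mode: str = "fix_first",
) -> float:
    """One-batch Monte-Carlo estimate of the exact objective."""
    pos = sample_positives(p, batch, rng_pos)
    neg = sample_negatives(pos, p.all_marginals(), kappa, rng_neg,
                           mode=negative_mode)
    return float(
        -(
            _log_sigmoid(emb.scores(pos)).sum()
            + _log_sigmoid(-emb.scores(neg)).sum()
        )
        / batch
    )


# -- training -------------------------------------------------------------


@dataclass
class TrainingConfig:
    """Hyper-parameters of the stochastic trainer.

    ``kappa`` is the negative-sampling constant, ``batch`` the number of
    positive tuples per step (each step also scores ``kappa * batch``
    noise tuples).  ``warmup_steps`` run first at ``lr * warmup_factor``.
    With ``lr_decay='linear'`` the main-stage rate anneals linearly to 0,
    which removes sampling noise from the final iterates.
    """

    d: int = 128
    kappa: int = 5
    batch: int = 1024
    steps: int = 2000
    lr: float = 1e-3
    optimizer: str = "adam"
    warmup_steps: int = 0
    warmup_factor: float = 0.1
    lr_decay: str = "linear"
    negative_mode: str = "fix_first"
    init_scale: float = 1.0
    seed: int = 0
    log_every: int = 100

    def __post_init__(self):
        if self.d < 1 or self.kappa < 1 or self.batch < 1:
            raise ValueError("d, kappa and batch must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_decay not in ("linear", "none"):
            raise ValueError(f"unknown lr_decay {self.lr_decay!r}")


class _Adam:
    def __init__(self, shapes, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * corr * m / (np.sqrt(v) + self.eps)


def train(
    p: CoocTensor,
    config: TrainingConfig,
    init: EmbeddingSet | None = None,
    log: list | None = None,
) -> EmbeddingSet:
    """Fit embeddings to a co-occurrence tensor by sampled mini-batch SGD.

    Returns the trained :class:`EmbeddingSet`; with ``steps=0`` the
    initialization is returned unchanged.  If ``log`` is a list, rows
    ``(step, sampled_loss, wall_time)`` are appended every
    ``config.log_every`` steps.
    """
    emb = init.copy() if init is not None else init_embeddings(
        p.shape, config.d, seed=config.seed, scale=config.init_scale
    )
    if tuple(f.shape[0] for f in emb.factors) != tuple(p.shape):
        raise ValueError("embedding sizes do not match tensor modes")
    rng_pos = stream(config.seed, "positives")
    rng_neg = stream(config.seed, "negatives")
    marg = p.all_marginals()
    opt = _Adam([f.shape for f in emb.factors]) if config.optimizer == "adam" else None
    total = config.warmup_steps + config.steps
    t0 = time.perf_counter()
    for step in range(total):
        if step < config.warmup_steps:
            lr = config.lr * config.warmup_factor
        else:
            frac = (step - config.warmup_steps) / max(config.steps, 1)
            lr = config.lr * (1.0 - frac) if config.lr_decay == "linear" else config.lr
        pos = sample_positives(p, config.batch, rng_pos)
        neg = sample_negatives(pos, marg, config.kappa, rng_neg,
                               mode=config.negative_mode)
        loss, grads = _batch_grads(emb, pos, neg, config.batch)
        if not np.isfinite(loss):
            raise TrainingDiverged(f"non-finite loss at step {step}")
        if opt is not None:
            opt.step(emb.factors, grads, lr)
        else:
            for f, g in zip(emb.factors, grads):
                f -= lr * g
        if log is not None and (step % config.log_every == 0 or step == total - 1):
            log.append((step, loss, time.perf_counter() - t0))
    return emb


def _batch_grads(emb, pos, neg, batch):
    """Sampled loss and factor gradients for one positive/negative batch."""
    order = emb.order
    rows_p = [pos[:, m] for m in range(order)]
    rows_n = [neg[:, m] for m in range(order)]
    fp = [emb.factors[m][rows_p[m]] for m in range(order)]
    fn = [emb.factors[m][rows_n[m]] for m in range(order)]
    prod_p = fp[0].copy()
    for m in range(1, order):
        prod_p *= fp[m]
    prod_n = fn[0].copy()
    for m in range(1, order):
        prod_n *= fn[m]
    s_p = prod_p.sum(axis=1)
    s_n = prod_n.sum(axis=1)
    loss = -(_log_sigmoid(s_p).sum() + _log_sigmoid(-s_n).sum()) / batch
    # d/ds of -log s(s) is -(1 - sigma); of -log s(-s) is +sigma
    g_p = -(1.0 / (1.0 + np.exp(s_p))) / batch
    g_n = (1.0 / (1.0 + np.exp(-s_n))) / batch
    grads = []
    for m in range(order):
        # product of the other factors' rows, elementwise; non-finite inputs
        # only propagate into the divergence check, so silence the FPU here
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            other_p = _prod_excluding(fp, m)
            other_n = _prod_excluding(fn, m)
            g = np.zeros_like(emb.factors[m])
            np.add.at(g, rows_p[m], g_p[:, None] * other_p)
            np.add.at(g, rows_n[m], g_n[:, None] * other_n)
        grads.append(g)
    return loss, grads


def _prod_excluding(rows, m):
    out = None
    for mm, r in enumerate(rows):
        if mm == m:
            continue
        out = r.copy() if out is None else out * r
    return out


# -- combination and diagnostics -----------------------------------------


def combine(emb: EmbeddingSet, indices, mode: str = "node_time") -> np.ndarray:
    """Hadamard combination of factor rows into feature vectors.

    ``node_time`` maps ``(i, k)`` to ``w_i o t_k``; ``event`` maps
    ``(i, j, k)`` to ``w_i o c_j o t_k`` (order 3) or
    ``w_i o c_j o t_k o s_k`` (order 4 — both time factors at the event's
    own snapshot).
    """
    if mode == "node_time":
        i, k = indices
        return emb.W[i] * emb.T[k]
    if mode == "event":
        if len(indices) == 4 and indices[2] != indices[3]:
            raise ValueError("event combination requires a single snapshot index")
        i, j, k = indices[0], indices[1], indices[2]
        out = emb.W[i] * emb.C[j] * emb.T[k]
        if emb.order == 4:
            out = out * emb.S[k]
        return out
    raise ValueError(f"unknown combination mode {mode!r}")


def reconstruction(emb: EmbeddingSet, indices: np.ndarray) -> np.ndarray:
    """Multilinear scores at given index tuples (the learned SPMI estimate)."""
    return emb.scores(indices)


def spmi_rmse(emb: EmbeddingSet, target: SPMITensor) -> float:
    """Support-restricted RMSE between the reconstruction and an SPMI tensor."""
    diff = emb.scores(target.indices) - target.values
    return float(np.sqrt(np.mean(diff**2)))


# -- persistence ----------------------------------------------------------


def save_embeddings(emb: EmbeddingSet, prefix, labels=None) -> None:
    """Write each factor in word2vec text format: ``count d`` then rows."""
    names = ["W", "C", "T", "S"][: emb.order]
    for name, mat in zip(names, emb.factors):
        ids = labels.get(name) if labels else range(mat.shape[0])
        with open(f"{prefix}.{name}.txt", "w") as fh:
            fh.write(f"{mat.shape[0]} {mat.shape[1]}\n")
            for lab, row in zip(ids, mat):
                fh.write(str(lab) + " " + " ".join(f"{x:.8g}" for x in row) + "\n")


def load_embedding_matrix(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        n, d = map(int, fh.readline().split())
        ids, rows = [], np.empty((n, d))
        for r in range(n):
            parts = fh.readline().split()
            ids.append(parts[0])
            rows[r] = [float(x) for x in parts[1:]]
    return ids, rows
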