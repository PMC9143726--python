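# Methods

This note records the model, the closed-form constructions, the numerical
and design choices, what the synthetic data does and does not emulate,
and the known limitations.

## Model

A time-varying graph H = (V, E, T) is a sequence of weighted undirected
snapshots A^(1), …, A^(|T|) over a shared node set; events (i, j, k, ω)
carry the interaction count ω of pair (i, j) inside aggregation window k.
Windows without interactions are dropped and snapshots re-indexed
contiguously (the original window index is retained for traceability).

The embedding model assigns rank-d factor matrices W, C ∈ R^{|V|×d} and
T ∈ R^{|T|×d} (plus S ∈ R^{|T|×d} at 4th order) and scores an index tuple
with the multilinear form ⟦w_i, c_j, t_k(, s_l)⟧ = Σ_r W_ir C_jr T_kr (S_lr).
Training minimizes the negative-sampling cross-entropy: tuples from a
data distribution P_D are positives, tuples with all-but-the-first index
redrawn from the product of P_D's marginals are negatives (κ per
positive). The exact objective, enumerated over the full index range, is

    L = − Σ [ P_D log σ(score) + κ P_N log σ(−score) ] .

Setting the derivative with respect to each score to zero gives
σ(score) = P_D/(P_D + κP_N), i.e. score = log(P_D/P_N) − log κ — the
shifted PMI (SPMI) of P_D. Training is therefore an implicit SPMI tensor
factorization; with two modes it is exactly classical SGNS, and the
trainer accepts order-2 tensors unchanged.

## Co-occurrence tensors

* **stat** (order 3): P(i,j,k) = ω(i,j,k)/vol(H), both orientations
  stored, vol(H) counting both orientations so the tensor is symmetric in
  i↔j and sums to one.
* **dyn** (order 4): built from the supra-adjacency graph over active
  node-time pairs. For each event (i,j,t0), if i is next active at
  t1 > t0 a cross-coupling edge (j^(t0), i^(t1)) with the event weight is
  added, and symmetrically for j; each rule firing also adds a unit
  self-coupling edge (i^(t0), i^(t1)). The directed form points strictly
  forward in time; the symmetrized form feeds the walk statistics.  With
  strengths d_a, volume vol(G_H) and walk operator P = D^{-1}A, the entry
  for supra nodes a = i^(k), b = j^(l) is

      (1/2T) Σ_{r=1..T} [ (d_a/vol) (P^r)_{ab} + (d_b/vol) (P^r)_{ba} ] ,

  the window-T co-occurrence probability of degree-weighted random walks.
  The same formula on an ordinary static graph, divided by the
  product of the stationary marginals d_i d_j / vol², is the expected PMI
  matrix that window-T skip-gram factorizes (`deepwalk_pmi`); the
  order-2 and tensor code paths are cross-checked against each other in
  the tests.
* **stat_dyn** (order 4): the average ½(stat·δ_{kl} + dyn).

Transition powers are accumulated by repeated sparse products, never by
densifying P; a configurable nonzero budget (default 2·10^7) aborts
constructions that would not fit, with a pointer toward walk sampling.
Disconnected supra graphs need no special casing: walk operators never
mix components and normalization is by the global volume (the static
`deepwalk_pmi` does require connectivity and enforces it). Zero-strength
supra nodes get zero walk rows and vanish from the tensor support.

## Choices that were genuinely open

* **Self-coupling scope.** The coupling rules tie self-coupling edges to
  event-rule firings rather than adding one for every consecutive
  activation of a node; repeated firings of the same self-coupling edge
  store weight 1, not a count. Both choices are implemented as stated
  here and exercised by the brute-force oracle tests.
* **Walk window.** The window T for the dyn tensor defaults to 10; it is
  a free parameter of the representation, exposed in `TensorConfig`.
* **Logarithms** are natural throughout: the sigmoid parametrization
  makes base e canonical.
* **SPMI support.** SPMI values are defined on the support of P_D only;
  zero-probability tuples are never materialized, and reconstruction
  errors are support-restricted.
* **Negative sampling** fixes the first mode of each positive and
  redraws the others (equivalent in expectation to full product
  sampling, which is available behind a switch for A/B tests).
* **Event features at 4th order** use both time factors at the event's
  own snapshot, w_i ∘ c_j ∘ t_k ∘ s_k.

## Training

Mini-batch Adam (β₁ = 0.9, β₂ = 0.999) on the sampled objective with B
positives and κB negatives per step. Defaults: κ = 5, B = 1024,
lr = 10⁻³ with linear decay to zero (removing sampling noise from the
final iterates), uniform initialization in [−0.5/d, 0.5/d] as in word2vec.
An optional warm-up stage runs the same objective at a reduced learning
rate (factor 0.1) before the main stage. All randomness flows from one
config seed through named, independent streams (init, positives,
negatives), so runs are bit-reproducible. Non-finite losses raise an
error naming the step.

The SPMI-reconstruction tests use a *full-rank-regime* fixture: a random
probability tensor defined as the softmax of a random multilinear score
tensor of bounded rank, so that its SPMI tensor is exactly representable
at the embedding dimension used. For a generic dense random tensor the
attainable reconstruction error is limited by CP rank, not by the
optimizer, and nothing about the factorization equivalence can be
concluded at d below the tensor's rank; the low-rank behaviour is an
open question and the tests deliberately stay out of it.

## Epidemic simulation and evaluation protocol

The SIR chain is discrete over snapshots: a susceptible node in contact
with an infectious one through an event of weight w is infected with
probability 1 − (1−β)^w; each infectious node recovers with per-snapshot
probability μ; updates are synchronous (drawn at k, effective at k+1).
One initial infectious node is drawn uniformly among the nodes active at
the first snapshot. States are recorded only at active node-time pairs.
The upstream protocol this mirrors leaves seeding, weight handling and
update order unspecified; these three choices are this package's own and
are the main reproduction gap for published epidemic-classification
scores.

Splits partition V and T independently at 70/30; train items use only
train nodes at train times and test items only test nodes at test times,
so no node or snapshot crosses the boundary. Negative events are sampled
per snapshot among active non-adjacent pairs, matching the per-snapshot
positive count (a global mode that only matches totals is also
provided); matching per snapshot removes a trivially learnable
time-marginal artifact. Pruning to 70% of events keeps at least one
incident event per active node-time pair when feasible (greedy covering
in random order) and reports the achieved coverage. Classification uses
L2-regularized logistic regression (C = 1, one-vs-rest for three
classes) on raw Hadamard features — no standardization, since the
features are scale-meaningful. Scores are Macro-F1, averaged over
realizations and splits with a standard error.

## Synthetic data

The generator emulates the structure of sensor-recorded proximity data:
a fixed population in equal communities, per-snapshot independent
activation (default activity 0.6), denser within-community than
between-community contact (p_in = 0.3 vs p_out = 0.02), and integer
weights 1 + Poisson(1.5) standing for within-window interaction counts
(mean 2.5, in the range of count-aggregated empirical data). Default
scale is 60 nodes, 3 communities, 40 snapshots — large enough for every
pipeline stage, small enough for exact tensors. Tests that train
embeddings repeatedly use 24–30 nodes and 12–20 snapshots so the full
suite stays fast.

What the generator does **not** emulate: circadian/schedule structure,
heavy-tailed contact durations, node-level activity heterogeneity,
community mixing events, or sensor artifacts. Tests passing on this
generator show the pipeline is correct and that the representations
behave directionally as expected (walk-tensor embeddings best at
epidemic-state classification, snapshot-tensor embeddings best at event
reconstruction, reconstruction easier than prediction); they do not
certify absolute score levels on empirical data.

## Numerical details

* Probability tensors assert Σ = 1 within 10⁻⁹ at construction; zero
  entries are never stored.
* log σ is computed as min(x,0) − log1p(e^{−|x|}).
* The exact loss enumerates the full index range and refuses above a
  configurable cap (default 4·10⁶ tuples).
* Node and time indices are contiguous 0-based integers internally;
  original labels are retained in mapping tables and used in all file
  formats (word2vec-style embedding text, coordinate tensor text, TSV
  edge lists and trajectories).

## Limitations

* Transductive: no representations for unseen time slices or nodes.
* Exact tensor construction only; walk-corpus approximation exists
  solely as a Monte-Carlo test oracle.
* Single-machine, CPU-only; no hierarchical softmax.
* Directed or continuous-time temporal graphs are out of scope.
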