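# hosgns

Disentangled node and time embeddings for time-varying graphs via
higher-order skip-gram with negative sampling (HOSGNS).

## The problem

Face-to-face proximity data — school, hospital, conference and workplace
contact networks recorded by wearable sensors, and agent-based epidemic
simulations — come as time-stamped interaction lists: a sequence of
weighted graph snapshots over a shared population. Analyses of spreading
processes, contact reconstruction and missing-link inference all need
vector representations of *node-time* pairs, but learning one vector per
pair costs O(|V|·|T|) parameters and entangles who a node is with when it
was seen.

This package learns **separate** node and time-slice embeddings with
O(|V| + |T|) parameters. Classical skip-gram with negative sampling
(SGNS) implicitly factorizes the shifted pointwise mutual information
(PMI) matrix of pair co-occurrences,

    W C^T ≈ log [ P(i,j) / (P(i)P(j)) ] − log κ .

HOSGNS generalizes this to tensors: factor matrices **W**, **C** (nodes),
**T** and, at 4th order, **S** (time slices), of rank *d*, are trained so
that the multilinear score ⟦w_i, c_j, t_k(, s_l)⟧ = Σ_r W_ir C_jr T_kr (S_lr)
classifies index tuples drawn from a co-occurrence distribution P_D
against tuples from the product of its marginals P_N. At full rank the
optimum satisfies

    ⟦w_i, c_j, t_k, …⟧ ≈ log [ P_D(i,j,k,…) / P_N(i,j,k,…) ] − log κ ,

i.e. an implicit factorization of the shifted PMI **tensor**.

Two closed-form co-occurrence tensors are built from a temporal contact
graph H:

* `stat` (order 3): `P(i,j,k) = ω(i,j,k) / vol(H)` — relative frequencies
  of node pairs in temporal edges (the snapshot representation);
* `dyn` (order 4): window-`T` co-occurrence probabilities of random walks
  on the time-respecting *supra-adjacency* graph over active node-time
  pairs (cross-coupling edges carry event weights to a node's next
  activation; self-coupling edges have unit weight);
* `stat_dyn` (order 4): their average.

Embeddings are evaluated the way practitioners use them: classifying
S/I/R epidemic states of active node-time pairs (features `w_i ∘ t_k`),
reconstructing temporal events against sampled non-events, and predicting
events removed before training (features `w ∘ c ∘ t (∘ s)`), with
node/time-disjoint 70/30 splits and Macro-F1 scores.

## Worked example

```python
import hosgns as hg

# a community-structured synthetic contact network (60 nodes, 3
# communities, 40 snapshots, bursty activation, integer weights)
h, labels = hg.generate_community_tvg(hg.SynthConfig(seed=42))
print(hg.graph_stats(h).as_dict())

# snapshot tensor -> order-3 embeddings
p = hg.stat_tensor(h)
emb = hg.train(p, hg.TrainingConfig(d=32, kappa=5, steps=2000, seed=1))

# SIR epidemic + the three downstream tasks
trajs = hg.simulate_sir(h, hg.SIRParams(beta=0.2, mu=0.05,
                                        n_realizations=5, seed=1))
splits = [hg.make_split(h, 0.7, seed=s) for s in range(5)]
negs = [hg.sample_negative_events(h, seed=s) for s in range(5)]
rec = hg.eval_event_task(emb, h.events, negs, splits)
print(f"event reconstruction Macro-F1 {rec.mean:.3f} +- {rec.se:.3f}")
```

Output of this exact script:

```
{'n_nodes': 60, 'n_times': 40, 'n_events': 2824, 'n_active': 1420,
 'avg_weight': 2.516643059490085, 'nodes_density': 0.5916666666666667,
 'links_density': 0.03988700564971751}
event reconstruction Macro-F1 0.797 +- 0.012
```

The first line says the generator produced 2,824 weighted events over 40
snapshots, with 59% of node-time pairs active and a mean event weight of
2.5 raw interactions per aggregation window; the last line says order-3
embeddings separate true events from active-pair non-events at Macro-F1
≈ 0.80 on node- and time-disjoint test folds (chance is 0.5).

The same pipeline is available from the shell:

```bash
hosgns synth --out edges.tsv
hosgns stats --input edges.tsv
hosgns pipeline --representation stat --dim 32 --steps 2000 --seed 1 --out run/
```

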