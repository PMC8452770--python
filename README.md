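# trajwalk

Trajectory inference for single-cell data — pseudotime, terminal cell
fates and lineage probabilities — built on **lazy-teleporting random walks
over a cluster graph**.  It is aimed at computational biologists analysing
single-cell matrices of any modality (transcriptomic counts, chromatin
accessibility scores, protein panels, image-derived morphology) whose
underlying dynamics may be multifurcating, cyclic or even disconnected —
shapes that tree-constrained trajectory methods distort.

## The model

Cells are joined into an exact KNN graph, clustered (Leiden by default,
K-means as a substitute), and the clusters become the nodes of a weighted
graph `G(V, E, W)` with degree matrix `D`.  A random walk on `G` with
transition matrix `P = D⁻¹W` is made *lazy* (stay put with probability
`1 − x`) and *teleporting* (jump uniformly with probability `1 − α`):

```
Z  = x·P + (1 − x)·I            Z′ = α·Z + (1 − α)·(1/n)·J
```

The pseudotime of a cluster is the expected number of steps for this walk,
started at a user-designated root, to first reach it.  It is evaluated in
closed form from the eigenpairs `(η_m, Φ_m)` of the symmetric normalized
Laplacian — with `β = 2(1 − α)/(2 − α)`:

```
R = Σ_m Φ_m Φ_mᵀ / (β + 2x(1 − β)·η_m)
h(q, r) = β · (e_r − e_q)ᵀ D^(−1/2) R D^(−1/2) e_r
```

followed by an exact spectral normalization into step units (see
`docs/methods.md` for the derivation and its verification against dense
linear-system solves).  Edges are then softly oriented by a logistic
function of the pseudotime difference (`f(Δt) = 1/(1 + e^(−bΔt))`, b = 1),
and the pseudotime is refined as the first quartile of first-visit times
over thousands of simulated walks on the biased graph — robust to spurious
edges without ever pruning any.  Terminal fates are a consensus vote over
out-degree, closeness and betweenness of the forward graph plus a
pseudotime gate; lineage likelihoods are visitation frequencies of walks
that successfully reach each terminal, projected to single cells through
the KNN graph.  A synthetic-topology simulator and a five-metric scoring
suite (Ipsen–Mikhailov, graph edit distance, F1-branch, temporal Pearson,
F1-fate, plus their composite) close the loop.

## Worked example

Simulate a 1000-cell, 1000-gene dataset along two cascading bifurcations
(four terminal fates), infer the trajectory from the earliest cell, and
score it against the known truth:

```bash
trajwalk simulate --kind multifurcation --seed 1 --outdir sim
trajwalk infer --input sim/matrix.csv --root-mode cell_index \
               --root-value 210 --seed 42 --outdir out
trajwalk score --inferred out --truth sim/truth.csv \
               --milestones sim/milestones.tsv
```

which prints (cell 210 is the cell with the smallest true time in `sim/truth.csv`):

```
15 clusters, terminals [1, 2, 5, 6, 10, 11, 12], outputs in out
{
  "im": 0.09947137671671837,
  "ged": 1,
  "ged_max": 31,
  "f1_branch": 0.9411764705882353,
  "pearson_time": 0.9202989252627377,
  "f1_fate": 1.0,
  "composite": 94.59491909236252,
  ...
}
```

Reading the numbers: the seven terminal clusters cover exactly the four
leaf branches of the reference (several clusters share a leaf), so the
cell-fate F1 is 1.0; the type-level inferred graph differs from the
reference branch graph by one edit out of a maximum of 31 (GED 1) and one
extra branch edge (F1-branch 0.94); the inferred pseudotime correlates with
true sampling time at Pearson 0.92; the spectral (Ipsen–Mikhailov)
distance is 0.10 on its 0–1 scale.  The composite averages the five
percentage-converted metrics to 94.6/100.  `out/` additionally contains
the cluster assignment, the undirected and forward-biased edge lists,
cluster- and cell-level pseudotime, the terminal-vote ledger, lineage
probability matrices and a run manifest; identical config + seed
reproduces every file byte for byte.

The same workflow is available as a library (`simulate_trajectory`,
`infer_trajectory`, `score_trajectory`, …) — see the test suite for
compact usage examples.

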