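# Methods

`trajwalk` infers cellular trajectories — pseudotime, branching structure,
terminal fates and lineage probabilities — from a single-cell feature matrix
by running lazy-teleporting random walks on a coarse cluster graph.  This
note records the model, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## The cluster graph

Cells are embedded (optionally log1p-transformed and reduced to a few
principal components), connected into an exact K-nearest-neighbour graph,
and clustered.  Distances become affinities through a locally adaptive
Gaussian kernel, `w = exp(-d² / σ_i²)` with `σ_i` the mean distance from
cell *i* to its K neighbours; the directed graph is symmetrised by taking
the maximum of the two directed weights so that rare-population links
survive.  Default clustering is Leiden community detection (resolution 1.0)
on this weighted graph; K-means is available as a drop-in substitute.
Cluster-to-cluster edge weights are the **sum** of the inter-cluster
single-cell affinities (a `mean` variant is exposed); summation reflects
population-level connectivity strength.  The result is an undirected
weighted graph `G(V, E, W)` with degree matrix `D`, typically 10–40 nodes
for a thousand cells.

## Pseudotime as hitting times of a lazy-teleporting walk

A standard random walk on `G` has transition matrix `P = D⁻¹W`.  Two
modifications keep global graph information in play: laziness (stay put
with probability `1 − x`) and teleportation (relocate uniformly with
probability `1 − α`):

    Z  = x·P + (1 − x)·I
    Z′ = α·Z + (1 − α)·(1/n)·J .

Pseudotime of a cluster is the expected number of steps for a walk started
at the root to first reach it.  Instead of solving one absorbing linear
system per target, we evaluate a closed form built from the personalized
PageRank of the lazy chain.  With the symmetric normalized Laplacian
eigenpairs `(η_m, Φ_m)`, `β = 2(1 − α)/(2 − α)` and

    R = Σ_m Φ_m Φ_mᵀ / (β + 2x(1 − β) η_m) ,

the quantity `h(q, r) = β (e_r − e_q)ᵀ D^{-1/2} R D^{-1/2} e_r` is a
spectral surrogate of the hitting time from `q` to `r`.  All eigenpairs are
used — the dimension is the number of clusters, so no truncation is needed,
and `β` and `x` damp the stationary-distribution eigenpair rather than
letting it dominate.

**Exact step-unit conversion.**  The surrogate is not itself a step count:
algebra on the resolvent `G = [(1 − α)I + αxL]⁻¹` shows

    h(q, r) = (1 − α)² · (G̃_rr) · a_q / d_r ,   a = (I − α Z_{-r})⁻¹ 1 ,

i.e. for every fixed target `r` the closed form is exactly proportional to
the expected absorption time `a_q` of the chain that jumps to `r` with
probability `1 − α` per step, and the uniform-teleport chain `Z′` is in
turn an exact per-target scalar multiple of `a`.  Both constants are
computable from the same eigendecomposition, so
`closed_form_hitting_times(..., scale="steps")` (the default) returns the
*exact* expected first-hitting step counts of `Z′` (teleport arrival at the
target counts as a hit); `scale="raw"` returns the literal spectral
expression.  The equivalence is verified against dense `(I − Q)h = 1`
solves to ~1e-13 on random graphs.  The conversion requires `α < 1`;
`α = 1` makes the `η = 0` denominator vanish and raises a
`DegenerateParameterError`.

Defaults `x = 0.95`, `α = 0.99` keep both corrections small: global
eigen-information enters without overwhelming the local structure.

## Forward bias and MCMC refinement

Each undirected edge is split into two directed orientations weighted by a
logistic function of the pseudotime difference, `f(Δt) = 1/(1 + e^{−bΔt})`
with growth factor `b = 1`; the orientation toward the later endpoint gets
`f > 0.5` and the two orientations sum to one, so no edge is ever pruned.
Because raw hitting times can span hundreds of steps and saturate the
logistic, the pipeline affinely rescales pseudotime to `[0, 10]` before
biasing (`time_scale`, configurable); the bias is then soft — roughly
0.6–0.9 toward the future for adjacent clusters — which preserves the
walk's ability to move "backward" and explore.

Pseudotime is then refined by simulating `n_mcmc = 1000` lazy-teleporting
walks on the row-normalized biased graph, all starting at the root and
capped at `max_steps = 1000·n` steps.  A teleport counts as a step and its
arrival as a visit; dead-end nodes become self-loops.  The refined
pseudotime of a node is the **first quartile** (linearly interpolated,
NumPy default) of its first-visit step counts over the walks that reached
it; the root is 0 by construction.  Nodes never visited fall back to an
affine rescaling of their closed-form value onto the refined scale, with a
warning.  The quartile makes the estimate robust to spurious low-weight
shortcuts: a 1 %-of-median long-range edge changes the refined rank order
by Spearman < 0.02 on the multifurcation benchmark.

## Terminal states

Terminal fates are detected on the *forward view* of the biased graph
(orientations with multiplier ≥ 0.5), using hop counts: out-degree,
closeness `C(q) = 1/Σ l(q, r)` over the nodes reachable from `q` (0 when
none), and betweenness `B(q) = Σ σ_rt(q)/σ_rt` over ordered pairs.  A node
is terminal iff its refined pseudotime is **strictly** above its
component's median (the gate) and it wins at least 2 of 3 connectivity
votes: out-degree at or below the median, closeness at or above,
betweenness at or below.  The connectivity comparisons are non-strict
because on small cluster graphs the leafward extreme (zero out-degree, zero
betweenness) frequently *is* the median; the strict pseudotime gate keeps
degenerate uniform-time topologies (a pure cycle, a complete graph) from
producing terminals — they return an empty set plus a warning.  The full
vote ledger is returned and written to disk for audit.

## Lineage likelihoods

For each terminal `j`, `n_mcmc` walks start at the root and stop on
reaching `j` (success) or at `max_steps`.  The lineage likelihood of
cluster `i` toward `j` is the number of visits to `i` during successful
walks divided by its visits over all walks of that batch; repeat visits
within one walk all count.  This deliberately avoids absorbing-Markov-chain
constraints — the walk may revisit and backtrack — and converges to the
analytic absorption probability where one exists (symmetric fork: 0.5 to
three Monte-Carlo standard errors at 10 000 walks).  With strong
teleportation and a generous step cap most walks eventually succeed, which
compresses likelihoods toward 1; smaller `max_steps` sharpens the contrast
and is exposed in the configuration.  Unreachable terminals yield a zero
column and a warning.

Cluster-level values (pseudotime, lineage probabilities) are projected to
cells by averaging, over each cell's KNN neighbours, the neighbours'
cluster values (`n_smooth` passes, default 1) — a convex combination, so
projected values never leave the range of the cluster values.

## Imputation and trend curves

Feature imputation diffuses the matrix with powers of the row-normalized
KNN affinity matrix (`t_steps = 3` by default); constants are fixed points,
per-component degree-weighted means are conserved, and isolated cells are
left untouched.  Lineage trends are penalized weighted B-spline fits of a
(possibly imputed) feature against cell pseudotime: cubic basis, 10 uniform
interior knots spanning the pseudotime range of positively weighted cells,
a second-difference coefficient penalty selected by GCV over a log-spaced
grid, evaluated on a 100-point grid with no extrapolation.  Weights are the
per-cell lineage probabilities, so cells committed to the lineage dominate
its curve.  Linear trends lie in the penalty null space and are recovered
exactly.

## Synthetic topologies

The simulator emulates the statistical structure of toy single-cell
trajectory benchmarks: ~1000 cells × 1000 features sampled along a small
milestone network (linear, bifurcation, two cascading bifurcations with
four leaves, a six-milestone cycle, a cycle with a bifurcating arm, or a
disconnected cycle + bifurcation pair).  Cells sit uniformly on edges; each
feature's mean is piecewise-linear between per-milestone archetype
log-levels drawn i.i.d. `N(0, 1)`; 20 % of features are branch markers
whose level rises by 2 along their designated edge (guaranteeing
monotone-in-time markers per branch); counts are negative-binomial with
dispersion 5 around `exp(log-level)` (a Gaussian-on-log-scale alternative
exists).  True time is the directed distance from the component's start
milestone, normalized to `[0, 1]` per component; terminal milestones are
those with out-degree 0 (cycles have none).

What this does *not* emulate: library-size variation, dropout beyond NB
sparsity, batch effects, doublets, or correlated gene modules.  Milestone
archetypes are mutually far apart relative to noise, so these benchmarks
certify the graph/walk machinery — topology recovery, ordering, fate
detection — not robustness to the full noise anatomy of real scRNA-seq.

## Scoring

Inferred clusters are mapped to reference branch types by majority vote
(ties to the lexicographically smaller type) and compared at type level:

* **Ipsen–Mikhailov** distance between Lorentzian-smoothed Laplacian
  spectral densities (frequencies `√λ`, one zero mode dropped), with the
  width `γ` solved numerically per node count so the empty and complete
  graphs are at distance exactly 1; smaller graphs are padded with isolated
  nodes.
* **Graph edit distance** with unit node/edge insertion and deletion costs
  (label substitution = delete + insert), exact search up to 12 nodes via
  networkx, an announced first-improvement approximation beyond.
* **F1-branch** over type-level edges; **F1-fate** =
  `tp / (tp + 0.5(fp + fn))` over terminal types; **Pearson correlation**
  between per-cell inferred and true times.
* **Composite**: each metric mapped to a percentage — `100(1 − IM)`,
  `100(1 − GED/GED_max)` with `GED_max` the cost of editing both graphs to
  empty, `100·F1`, `100·max(ρ, 0)` — and averaged (4 metrics when lineage
  prediction is excluded).  Scoring a trajectory against itself gives
  exactly `IM = 0, GED = 0, F1 = 1, ρ = 1`, composite 100.

## Problem sizes and determinism

The bundled benchmarks use 1000 cells × 1000 features, ten principal
components and K = 20 (K ∈ {5, 10, 20, 30} for the cyclic stress test);
unit tests use smaller fixtures (120–300 cells) chosen so each oracle is
exact or cheap.  A single integer seed drives simulation, clustering,
PCA and every Monte-Carlo stage; identical configurations produce
byte-identical output files.

## Known limitations

* The closed form requires `α < 1` and a connected component; components
  not containing the user's root get a structural fallback root (maximal
  eccentricity) rather than a biologically informed one.
* Lineage likelihoods saturate toward 1 when `max_steps` is large relative
  to the teleport rate (see above).
* The terminal vote is rank-based and therefore invariant to monotone
  pseudotime rescaling, but on very small graphs (≤ 3 nodes) medians are
  uninformative and detection may be empty.
* Exact GED is exponential; beyond 12 type-level nodes only the
  approximation is offered.
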