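# Methods

This note records the models, conventions and numerical choices behind
`netdesign`, in the order the pipeline runs them.

## Data model

Graphs are undirected and simple, nodes are re-indexed to `0..n−1` (original
labels are kept for file output), and each node may carry a length-`d` real
attribute vector.  An optional per-edge spillover probability `e.p ∈ [0, 1]`
models how likely influence is to cross that edge.  A *design* assigns every
node exactly one of three arms: treated, control, or excluded (bystander —
in the experiment's population but in neither arm).  Degree preprocessing
(`filter_min_degree`) is a **single pass**: with `dmin = 2` it removes exactly
the singletons and degree-1 nodes of the input, not the 2-core; iterating
would be a stronger operation than the usual preprocessing step it implements.

## Synthetic graphs

Two growth models generate test populations:

* **Preferential attachment** — seed graph is the complete graph on `m`
  nodes (a convention chosen so the edge count is deterministic:
  `C(m,2) + m(n−m)`); each arriving node attaches to `m` distinct nodes with
  probability proportional to degree.  Default `m = 3`.
* **Forest fire (undirected)** — each new node picks a uniform ambassador,
  links to it, and recursively burns unvisited neighbors: at every burned
  node the fire reaches a geometric number of neighbors with mean
  `p_f/(1−p_f) + p_b/(1−p_b)` (the forward and backward draws merge because
  edges are undirected; burn counts are "successes before first failure").
  Defaults `p_f = p_b = 0.3`.  The growth process guarantees connectivity.
  The burn-count parameterization is our reading of the standard model; the
  test suite cross-checks the density against an independently coded
  recursive-burn reference.

Attributes are `d = 10` i.i.d. Uniform(−1, 1) values per node, independent of
structure (no homophily).  Generation is a pure function of the configuration,
including the seed.

## Edge spillover probabilities

Tie strength proxies spillover.  The default metric is
`sim(x_i, x_j) = 1 − ‖x_i − x_j‖₂ / M`.  "Normalized" is ambiguous, so the
normalizer is explicit: `M = (range)·√d`, the diameter of the attribute box,
when bounds are known (synthetic data); otherwise the observed maximum
pairwise distance (sampled at ≤10⁶ pairs for large n, with the result clamped
to [0, 1]).  Cosine similarity is clamped at zero rather than affinely
rescaled, so 0 keeps meaning "no affinity" in threshold quantiles; vectors
with no direction (zero norm) get similarity 0.  Jaccard on real-valued
attributes is the generalized (Ruzicka) form `Σ min / Σ max` after shifting
by the attribute lower bound; on binary attributes it reduces to classic
Jaccard.

## Clustering (stage 1 of the cluster design)

**Markov clustering** runs on the `e.p`-weighted adjacency with self-loops of
weight equal to each node's maximum incident weight.  Defaults: inflation 2.0,
expansion 2, pruning threshold 1e−5, convergence tolerance 1e−8, 100
iterations max (non-convergence returns the current state with a warning).
Clusters are read off attractor rows; a node claimed by several attractors
goes to the lowest-indexed one, and a node pruned out of every attractor row
follows its strongest outgoing transition.  The discovered cluster count is
sensitive to inflation, which is why it is exposed.

**reLDG** streams nodes in a fresh seeded random order each pass and greedily
assigns each node to the cluster maximizing
`|N(v) ∩ cluster| · (1 − size/capacity)` subject to `size < capacity`,
`capacity = ⌈n/k⌉`, ties to the lowest index.  Each pass fills clusters from
empty while scoring against the latest known neighbor labels (this pass's
where already streamed, the previous pass's otherwise); re-assigning in place
under full capacities would freeze the first partition.  Ten passes by
default.  reLDG ignores edge weights by design.

## Independent-set design

`greedy_mis` scans a seeded random permutation once, adding a node iff no
neighbor is already in — O(|E|), maximal by construction.  `restarts > 1`
keeps the largest set over restarts, trading time for an approximation of the
maximum independent set.  The design splits the MIS uniformly (sizes differ by
at most one; a coin decides the odd node), and with `use_matching=True` pairs
MIS nodes by maximum-weight matching on L2-based attribute similarity first.
The bystander balance diagnostic is `100/|E| · (#T–E edges − #C–E edges)`,
normalized by **all** edges; its expectation over designs is zero.

## Cluster matching (stage 2)

Node-match rules: TNM*q* matches every cross-cluster pair with similarity
strictly above the *q*-th quartile (q ∈ {0,1,2,3}) of the pairwise node
similarity distribution (all pairs when `n(n−1)/2 ≤ 10⁶`, otherwise a seeded
uniform sample of 10⁶ pairs); quartile 0 is read as "no threshold" — every
cross-cluster pair matches — since a strict cut at the distribution minimum
would spuriously drop tied pairs.  BNM matches each node to its single most
similar node in a different cluster; a pair counts once if either direction
selects it (the rule is allowed to be asymmetric).

Cluster weights: `C` counts matched pairs; `S` averages their similarity (0
when nothing matches); `E` is the negated Euclidean distance between cluster
attribute means (negated so all weights are "larger = more similar");
`MC`/`MS`/`MSS` first restrict matches to a maximum-weight bipartite matching
over the TNM-admissible pairs, so each node counts at most once, then apply
count / mean / sum.  `BNM + {MC, MS, MSS}` is undefined (BNM already matches
each node at most once) and raises.

Candidate cluster pairs: TCM*q* keeps pairs with weight strictly above the
*q*-th quartile of the cluster-weight distribution (quartile 0 keeps all);
GCM keeps each cluster's single best partner (union over clusters).  The
final pairing maximizes total weight subject to each cluster matching at most
once (blossom algorithm).  For `E` weights, which are all ≤ 0, the pure
objective is maximized by the empty matching, so the design runs the matching
with cardinality priority — keeping as many nodes in the experiment as
possible, then breaking ties by similarity.  Matched pairs are split across
arms by a seeded coin; unmatched clusters are excluded.  All 115 defined
option bundles (5 node rules × {C,S,MC,MS,MSS} × 5 cluster rules, minus the
15 undefined BNM combinations, plus E × 5 cluster rules) are enumerable and
tested.  The default bundle is TNM2 + C + TCM2.

## Baselines

Node randomization splits uniformly (sizes within one).  The matching design
pairs all nodes by maximum-weight similarity matching — exact up to 500 nodes
(the blossom algorithm is cubic), sparsified to each node's 50 nearest
attribute neighbors above that — and splits each pair by a coin.  CR/CBR
cluster with reLDG, pair clusters into strata of two by greedy
nearest-neighbor on cluster attribute means (the stratification rule is
deliberately simple and exposed as a hook; an odd cluster leaves a lone
stratum), then CBR sends whole clusters to opposite arms while CR randomizes
node-level within each stratum.

## Outcome simulation

Stage 1 draws independent base activations: 0.4 for treated, 0.2 for control,
so the true total effect is 0.2.  Bystanders are **outside the outcome model
by default**: the model defines base activation only for the two arms, and
with the default the simulated estimates of the independent-set design track
its design property (no cross-arm edges ⇒ error at the binomial-noise floor).
`bystander_spillover=True` enables the variant in which bystanders take the
control-arm base probability and participate in contagion as their own
treatment class — the scenario the bystander-balance diagnostic is about.

Interference:

* **direct** — one pass; each treated neighbor of an inactive control node
  activates it independently with the edge's `e.p` (k treated neighbors give
  `1 − Π(1−e.p)`).  Read as per-neighbor trials deliberately.
* **contagion** — discrete rounds.  When an inactive node first has at least
  one activated neighbor in a different arm, it draws **one** activation
  trial with probability `1 − Π(1−e.p)` over those edges; newly activated
  nodes extend the frontier; the cascade stops when nothing changes.  One
  trial per node is the independent-cascade convention: unbounded per-round
  retrials would drive every exposed node's activation probability to 1 and
  destroy the signal.  Activation is monotone.

Estimation is difference-in-means over the two arms; excluded nodes never
enter the estimate.  `run_experiment` replicates
(generate → design → simulate → estimate) S times (default S = 10) and
reports the estimates, RMSE against the true effect 0.2, covariate distance,
cut statistics and bystander balance, with every stage's seed derived by
hashing (base seed, run index, stage name) so stages are independently
reproducible.

## Diagnostics

Cut statistics report the fraction of edges (and of `e.p` mass,
`θ̂ = Σ cross-arm e.p`) between arms.  Covariate distance is the Euclidean
distance between arm attribute means, excluded nodes omitted.  Degree balance
is quantified by the two-sample Kolmogorov–Smirnov statistic on the arms'
degree samples (a scalar summary of the usual visual histogram comparison).
Under the linear outcome model `E[y_i] = a_i + Σ_j B_ij T_j`, the bias
diagnostics are `μ = (1/n)Σ_ij B_ij` (true total effect),
`μ_cbr = (1/n)Σ B_ij 1[C(i)=C(j)]` (captured by cluster randomization),
`μ_rand = (1/n)Σ B_ii` (captured by node randomization), and the relative
bias `μ/μ_cbr − 1`, which is zero exactly when the clustering captures all
interference mass and is signaled as undefined when `μ_cbr = 0`.

## What the synthetic generator does and does not show

The generators reproduce the structural study conditions (scale-free or
forest-fire topology, attribute dimension and range, spillover scales) but
attributes are independent of structure, outcomes are binary with
homogeneous base rates, and spillover is memoryless.  Passing tests therefore
demonstrate the designs' interference/selection-bias behavior under these
controlled conditions; they do not certify performance on networks with
attribute homophily, heterogeneous treatment effects, or multi-hop diffusion
dynamics beyond the contagion model above.

## Problem sizes

The test suite and the acceptance script run forest-fire graphs up to
n = 50,000 for the selection-bias curve and n = 10,000 (S = 10) for the
interference RMSE comparison, property checks over hundreds of small random
graphs, and exhaustive brute-force cross-checks for matchings on up to 8
clusters — sizes chosen so the full suite completes in minutes on one CPU
while staying in the regime where the compared quantities are stable.

## Known limitations

Exact maximum-weight node matching is cubic and is sparsified above 500
nodes; Markov clustering densifies during expansion and is practical to a few
thousand nodes (use reLDG beyond); contagion assumes a single trial per node
(threshold/complex-contagion models are out of scope); outcomes are binary;
directed graphs and multigraphs are unsupported.
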