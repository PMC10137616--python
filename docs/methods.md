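# Methods

## The ranking model

The package treats node prioritization as a nearest-neighbour problem in
a hand-crafted feature space. Each node of an undirected simple graph is
described by a vector of centrality measures, and relevance to a query
(seed) set is the arithmetic mean of the cosine similarities between the
node's vector and each seed's vector. The underlying assumption is
guilt-by-association at the level of *structural role*: genes or proteins
participating in the same process tend to occupy similar positions in
interaction and co-expression networks — similar connectivity, similar
embeddedness in dense neighbourhoods, similar reachability — even when
they are not direct neighbours. Cosine (rather than Euclidean) similarity
deliberately ignores overall magnitude and compares only the *profile* of
centralities.

### The feature space

Nine columns, in fixed order: degree, betweenness, closeness,
eigenvector, PageRank, personalized PageRank, information (current-flow
closeness), a duplicate of eigenvector, and clustering coefficient. The
duplicated eigenvector column keeps the default space literally
9-dimensional, matching the method as published; it doubles the weight of
the eigenvector direction in the cosine, which is a quirk rather than a
design goal, and `dedupe_eigenvector=True` provides the clean
8-dimensional space. All measures are dimensionless and computed on the
unweighted topology by default (`weighted=True` switches to weighted
shortest paths / transition probabilities where the measure defines
them).

Conventions chosen so that every entry is finite on every graph:

* closeness uses the component-scaled (Wasserman–Faust) variant, so
  values remain comparable across disconnected components;
* eigenvector centrality is computed on the largest connected component
  (power iteration, tolerance 1e-10, ≤ 1000 iterations) and is 0
  elsewhere, with a warning; the tight tolerance keeps scores accurate to
  well below 1e-6, which the test suite's brute-force comparisons rely
  on;
* information centrality is computed per connected component as
  1/Σ_t r(v,t) with r the effective resistance (the same convention as
  networkx), and 0 on singleton components;
* both PageRank variants use damping 0.85 and iterate to tolerance 1e-12;
  the personalized variant teleports uniformly onto the seed set;
* clustering coefficient is 0 for nodes of degree < 2.

### Scoring and ranking

Cosine is applied to **raw** centrality vectors by default, which is the
method as published. Raw centralities span orders of magnitude (PageRank
entries sum to 1 over the whole graph while closeness is O(1) per node),
so the cosine is dominated by the large-magnitude columns; the optional
`zscore=True` mode standardises each column first and makes the ranking
provably invariant to per-column affine rescaling (a property test pins
this). Both behaviours are deliberate and documented rather than
reconciled: raw is faithful, z-scored is scale-robust.

Identical (bitwise-equal) and antipodal vector pairs short-circuit to
exactly ±1 before the floating-point quotient, so the defining cosine
identities hold exactly. All similarity outputs are clipped into
[−1, 1]. Nodes whose feature vector is exactly zero (fully isolated
nodes in the de-duplicated space) receive the sink score −1 with a
warning instead of aborting the run. Ranking ties are broken
lexicographically by node identifier, making every output
bit-reproducible.

Seeds are ranked along with all other nodes (the published pseudocode
ranks "all nodes", and seeds' own ranks are themselves an evaluation
output); a leave-one-out mode re-scores each seed with itself removed
from the seed set for an evaluation free of the self-similarity
advantage.

The optional seed-pruning step removes every seed whose mean similarity
to the other seeds falls below a threshold τ. The threshold is not fixed
by the published method; the default, used when τ is not given, is the
mean off-diagonal seed–seed similarity minus two standard deviations,
i.e. "prune clear outliers only". At least one seed always survives.

## Baseline rankers

**Random walk with restart.** p ← (1−r)·Wᵀp + r·e, with W the
column-normalised adjacency, e uniform over the seeds, p₀ = e, iterated
until the L1 change is below tolerance (default 1e-10, ≤ 10,000
iterations). Restart probability defaults to 0.5 — a common
prioritization default; the value used in the original comparison is
unreported, so it is exposed as a parameter. Dangling (degree-zero)
columns hand their probability mass to the restart vector, preserving
Σp = 1 exactly; a dense linear solve of the same fixed point is the test
oracle.

**DIAMOnD-style module expansion.** At each step, every candidate with at
least one link into the current module is scored by the hypergeometric
tail P(X ≥ k_s) (population = network size, successes = current module
size, draws = candidate degree, observed = links into module); the
lowest-p candidate is added (ties: more module links, then lexicographic)
and the module grows. Seed weighting is fixed at 1. The tail is computed
in exact rational arithmetic (`fractions.Fraction` over binomial
coefficients) because float tails can order two mathematically equal
p-values unequally and silently change the addition order; the float
value is reported in the output. If the module saturates its component(s)
before `n_added` nodes are placed, remaining disconnected candidates are
appended in lexicographic order with p = 1.

## Centrality-importance analysis

Nodes are clustered in centrality space — features are z-scored first,
since density clustering on raw centralities is scale-degenerate — with
either K-means (default k = 4, fixed seed 0) or DBSCAN (default
min_samples = 5, eps at the knee of the sorted 5-NN distance curve by the
max-distance-to-chord heuristic). Labelings unusable as a classification
target (all noise, or a single class) raise by default; `strict=False`
returns them for inspection. A random forest (500 trees, fixed seed,
stratified 70/30 split) predicts the labels, and each feature's
importance is the mean accuracy drop over 10 independent shuffles of that
column on the held-out split. The seed-dependent personalized-PageRank
column and the duplicate eigenvector column are excluded from this
analysis: the former has no meaning without a query context and the
latter is redundant by construction. Shuffling a constant column is a
no-op, so its importance is exactly 0 — a useful negative control that
the tests assert.

Ternary coordinates renormalise three chosen importances (clipped at 0)
to sum to 1, placing each network/clustering combination inside a
2-simplex; the default trio is closeness, eigenvector and information
centrality.

All clustering and forest hyperparameters used in the original analysis
are unreported; the defaults above are declared choices, not inferences.

## The synthetic benchmark

`generate_planted_network` samples a stochastic block model: one
Bernoulli draw per node pair from `numpy.random.default_rng(rng_seed)`
(PCG64), with probability p_in within a block and p_out between blocks.
The default conditions — blocks of 30 and 120 nodes, p_in = 0.25,
p_out = 0.02, a third of the dense block revealed as seeds — give a
planted seed module whose members have expected within-module degree
7.25 versus 0.6 for background nodes, a regime comparable to a
co-expression module embedded in a larger network. The SBM was preferred
to LFR-style generators because its expected edge count is exactly
computable (the generator test checks the observed count against a
4-standard-deviation binomial band).

Node identifiers are assigned to blocks by a random permutation drawn
from the same rng, so lexicographic order carries no information about
block membership; without this, any identifier-ordered null ranker would
spuriously "recover" the module. Everything is reproducible from
`rng_seed`.

What the benchmark does *not* emulate: weighted edges, degree
heterogeneity within blocks (no degree correction), overlapping modules,
and the measurement noise of real co-expression estimation. Passing the
planted-module recovery test therefore shows that the ranking recovers an
assortative community anchored by seeds under clean conditions — a
necessary sanity property — not that it ranks well on real PPI or
co-expression data.

## Problem sizes and numerical choices in the test suite

Brute-force equivalence of every centrality is checked on the complete
atlas of connected graphs on 2–7 nodes (995 graphs; the 1-node graph is
excluded because several measures are pure convention there) plus 100
random graphs of up to 20 nodes, all against independent implementations
(explicit shortest-path enumeration, dense eigensolves, Laplacian
pseudoinverse, dense power iteration) at 1e-6. RWR is checked against a
dense linear solve at 1e-8 and DIAMOnD against exhaustive exact
hypergeometric expansion. The planted-module recovery property uses 50
replicates of the default benchmark, requiring the median held-out rank
to fall within the top 20% of non-seed nodes in ≥ 90% of replicates and
to beat a lexicographic null; permutation-importance recovery uses 20
replicates of 240 nodes × 6 features. These sizes keep the full suite
under a minute while leaving each statistical check comfortably powered.

## Known limitations

* Raw-cosine mode inherits the scale imbalance of the centrality columns;
  rankings can be driven by a few large-magnitude measures (use `zscore`
  when this matters).
* The duplicated eigenvector column doubles that measure's weight in the
  default cosine.
* Module expansion re-ranks nothing once added: its output is an
  addition order, not a graded score, and on sparse graphs it saturates
  quickly.
* The importance analysis explains *cluster structure in centrality
  space*, not ranking quality; a centrality can be unimportant for the
  cluster labels yet decisive for a particular seed set.
* Directed and multi-edge networks are out of scope; edge weights are
  ignored unless explicitly enabled.
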