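# Methods

## Model and objective

The package learns the structure of a multinomial Bayesian network: each
variable X_i takes r_i ≥ 2 categories and, given its parents' joint
configuration, follows a categorical distribution. The learning objective
is the Bayesian information criterion in its decomposable, higher-is-better
form

    score(G) = Σ_i [ ln L̂_i − (k_i / 2) · ln n ],
    ln L̂_i  = Σ_{j,k} N_jk · ln(N_jk / N_j·),      0·ln 0 := 0,
    k_i      = (r_i − 1) · Π_{q ∈ pa(i)} r_q,

where N_jk counts rows with parent configuration j and child state k. The
classical reporting scale ln(n)·k − 2·ln L̂ equals −2× this score and is
exposed as `classic_bic`. Two conventions are fixed for determinism: parent
configurations never observed contribute nothing to the likelihood but keep
their parameters in k_i (degrees of freedom follow declared arities, not
observed support), and all logarithms are natural.

The score is score-equivalent (Markov-equivalent DAGs tie exactly — the
test suite asserts the three 3-chain orientations agree to 1e-9) and
consistent (with strong-edge fixtures at n = 50,000 the generating
5-node DAG's class attains the exhaustive maximum over all 29,281 5-node
DAGs). Consistency is asymptotic *and* parameter-dependent: an edge whose
conditional rows nearly coincide is statistically indistinguishable from no
edge at any finite n, which is why the consistency test uses explicitly
strong conditionals rather than random Dirichlet draws.

## Stage 1 — double-filtering screen

Marginal screen: for every pair, G = 2n·MÎ(X_i; X_j) in nats against
χ²_{(r_i−1)(r_j−1)}; admit at p < α. Conditional prune: for each surviving
edge {i, j}, test X_i ⟂ X_j | X_k for every common first-pass neighbor k,
one conditioner at a time (G = 2n·CMÎ, df = (r_i−1)(r_j−1)·r_cond); a
single non-significant test removes the edge symmetrically. Each
(pair, conditioner) combination is tested once and cached; removals do not
re-trigger scans. No multiple-testing adjustment is applied — α is a
per-test level, default **α = 0.01**.

The stage estimates a *cover* (superset) of the skeleton, not the skeleton
itself: single-variable conditioning cannot separate all non-adjacent pairs,
but it keeps each test's cell counts large, which is the design trade-off
favoring recall at modest n. The literal textual variant of the prune —
testing X_i against the common neighbor X_k given X_j and removing the
*conditioning* edge {i, j} on a non-significant result — is available as
`variant="literal"`; the default `"dseparation"` reading (remove the edge
under scrutiny) is the one consistent with pruning indirect chain edges and
is the package's recommendation.

Degenerate inputs: arity-1 (constant-domain) columns are never tested and
never become neighbors; missing data are rejected at load (the model has no
missingness mechanism).

## Stage 2 — adaptive SMC orientation

Each SMC sample orients the whole cover, block by block:

- Block choice: among fully connected triplets in the *remaining* cover,
  take one with the fewest outside connections (remaining undirected edges
  incident but not internal), ties uniform at random; when no triangle
  remains, partially connected triplets; then pairs. Counts are recomputed
  after every commit — a former triangle can degrade to a partial triplet.
  This dynamic recomputation is the "adaptive" part; a fixed-upfront
  schedule (same priorities computed once on the original cover) is kept as
  a comparator (`adaptive=False`).
- Configuration sampling: all 2^e joint orientations of the block's e
  internal edges are enumerated, those closing a directed cycle (through
  the block or the previously committed structure) are discarded, the rest
  are scored by the block nodes' summed local BIC, and one is drawn with
  probability ∝ exp(score/T). Softmax uses max-subtraction; at least one
  configuration always survives (orient along any linear extension).
- The temperature T (default **0.001**) sets greediness: T→0 is per-block
  greedy argmax, T→∞ uniform. Per-block greediness is myopic — committing a
  block's local optimum can force poor orientations later — so the expected
  quality is not monotone in 1/T; very low temperatures can underperform
  moderate ones on dense covers. This matches the U-shaped
  temperature-performance profile the method is known for, with useful
  values around 10⁻³–10⁻².
- Samples are mutually independent; sample s uses
  `SeedSequence(entropy=seed, spawn_key=(s,))`, so any worker count or
  execution order reproduces bit-identical results. The local-score cache
  shared across samples is an optimization only.

Default sample count is **2,000** in the library and CLI — sized for
12–40-node problems on a single CPU; production-scale runs of the original
protocol use 20,000 (`--samples 20000`).

## Stage 3 — random-order hill climbing

For each refined network: per round, draw one permutation of the nodes; for
every child i (ascending), scan candidate parents j in permutation order;
commit X_j→X_i immediately when it is absent, keeps the graph acyclic, and
has a strictly positive local-score delta (first-improvement, not
best-improvement). Rounds stop at **5** (default), on a round with no
additions, or when the evaluation budget `search_limit` (default 2·p²,
a declared choice reflecting the stage's O(p²)-per-round cost) is spent.
Only additions are performed — no deletions or reversals — so the score
ascends monotonically and the refined score is never below the input's.
Candidates are not restricted to the stage-1 cover; reclaiming screen
misses is the stage's purpose, and the additions are recorded in the
result's provenance.

Because stage 2 *orients* every cover edge (a pair's configurations are the
two directions; absence is not an option), the final network always
contains the whole cover: false-positive cover edges cannot be removed by
any stage. This is an intrinsic property of the method, visible in the
exhaustive-oracle experiment below.

## Synthetic data and study conditions

- `forward_sample`: ancestral sampling in topological order (ties by node
  index).
- `random_bn`: uniform random node order; each earlier→later edge kept with
  `edge_prob` (default 0.3) subject to `max_in_degree` (default 2); CPT
  rows i.i.d. symmetric Dirichlet (`dirichlet_conc`, default 0.5).
  Independently drawn rows can coincide, producing edges with little or no
  marginal signal — realistic, but unsuitable when a fixture must have
  every edge detectable.
- `noisy_threshold_bn`: binary network on a given DAG; roots are fair
  coins, a child with k parents is active with probability
  leak + lift·(active parents)/k (defaults 0.15 + 0.7·frac). Every edge
  shifts the child's conditional by lift/k, so all edges are visible to
  marginal tests; benchmark fixtures use this on `random_bn` DAG shapes.
- `preprocess_continuous`: single-pass 3-SD outlier removal (column
  moments from the unfiltered matrix), then per-column equal-frequency
  binning at empirical quantiles, boundary ties assigned to the lower bin
  (so tied boundaries distort bin sizes by exactly the tie multiplicity).
- Benchmark protocol (`run_benchmark`): for each observation size and
  replicate, seeds derive from (base_seed, size index, replicate);
  replicate defaults follow the standard design of 10 datasets per size at
  sizes 1,000/2,000/5,000.

What the generators do **not** emulate: latent confounders, selection bias,
missing data, measurement error correlated across variables, and the
near-deterministic logic gates of real diagnostic networks. Passing tests
therefore certify algorithmic correctness and calibration under
faithfulness and strong-signal conditions, not performance on any
particular real-world network.

## Evaluation

Skeleton quality is precision = TP/(TP+FP), recall = TP/(TP+FN) and their
harmonic mean over undirected edges, with 0 conventions at empty
denominators. Structure quality is the ratio score(truth)/score(learned)
on the internal scale; both scores are negative, so values above 1 mean the
learned network out-scores the generating one — expected at small n, where
the penalty legitimately prunes weak true edges.

## Numerical and design choices

- Sign convention: search internally maximizes ln L̂ − (k/2)·ln n so that
  exp(score/T) weights better configurations upward; the smaller-is-better
  classical scale is reporting-only. (A literal smaller-is-better BIC
  inside the Boltzmann weight would invert the search's preference.)
- Ties: topological order and candidate lists break ties by ascending node
  index; equal-score sample selection keeps the earliest sample; block ties
  are the one deliberately random choice (sample diversity).
- `creates_cycle` is the incremental reachability check used before every
  edge commit; enumeration restores the DAG exactly after each trial.
- Acceptance experiment sizes (4-node oracle at n=2,000 with 2,000 samples;
  12-node fixtures at n=2,000 with tens of samples per run) are desk-scale
  defaults chosen so the whole suite runs in seconds on one CPU while
  leaving each effect (reclamation gain, temperature gap, schedule
  comparison) well away from numerical noise.

## Known limitations

- False positives surviving the screen are permanent (orientation cannot
  drop edges); the learner's precision ceiling is the screen's.
- The exhaustive-oracle experiment hands stages 2–3 the optimum's own
  skeleton to isolate them; with the learner's own screen the attainment
  rate drops (typically 7–10/10 seed families) exactly when the cover
  retains a weak true edge the finite-n optimum excludes.
- Single-conditioner tests cannot remove edges between nodes whose
  separating sets all have size ≥ 2; dense neighborhoods inflate the cover.
- BIC assumes i.i.d. complete categorical observations; continuous data
  must be discretized first, losing information.
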