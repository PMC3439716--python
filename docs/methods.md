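# Methods

This package re-implements, end to end, an empirical evaluation of scoring
functions for discrete Bayesian network structure learning: gold-standard
networks are fixed, datasets are drawn from them by forward sampling,
structures are relearned under four scoring functions with an exact and a
greedy learner, and the learned structures are compared with the gold
standard by confusion-based metrics and by equivalence-class-aware
structural Hamming distance (SHD).

## Model and scores

A discrete Bayesian network is a pair B = {G, Θ}: a DAG G over variables
X_1..X_n and, for each variable, a conditional probability table
P(X_i | PA_i) with one row per joint parent configuration (mixed-radix
order, first-declared parent most significant) and one column per state.
The joint factorizes as P(V) = ∏_i P(x_i | pa_i).

All four scores are decomposable penalized log-likelihoods
Score(B|D) = Σ_i [ LL_i − Penalty_i ], maximized over structures, with
LL_i = Σ_j Σ_k N_ijk ln(N_ijk / N_ij), where N_ijk counts rows with
X_i = k and PA_i in configuration j, and 0·ln 0 = 0.  With
p_i = (r_i − 1)·q_i free parameters (r_i the arity, q_i the number of
parent configurations):

* **MDL/BIC** — penalty (ln N / 2)·p_i.  The description-length and
  large-sample Bayesian derivations coincide up to sign; we use the
  maximize-the-score sign convention throughout.
* **AIC** — penalty p_i.
* **BDeu(α)** — the local score is the log marginal likelihood under a
  symmetric Dirichlet prior with equivalent sample size α:
  Σ_j [lnΓ(α_j) − lnΓ(α_j + N_ij)] + Σ_jk [lnΓ(α_jk + N_ijk) − lnΓ(α_jk)]
  with α_j = α/q_i and α_jk = α/(r_i q_i).  The α grid used throughout is
  {0.1, 0.5, 1, 5, 10, 20, 50, 80, 100}.
* **fNML** — per-parent-configuration normalized maximum likelihood; the
  penalty is Σ_j log C(N_ij, r_i), where C(N, k) is the multinomial
  regret (parametric complexity): the sum over all k-ary datasets of size N
  of their maximized likelihoods.  C(N, 2) is computed by the closed-form
  binomial sum in log space (log-sum-exp); higher k comes from the linear
  recurrence C(N, k+2) = C(N, k+1) + (N/k)·C(N, k), also in log space,
  cached per N.  This is exact and stable to at least N = 10^5.

All logarithms in scores are natural; the discretization module converts to
bits where the coding argument is stated in bits.  Count tables store only
occupied parent configurations: empty configurations contribute nothing to
any score, and the occupied count is bounded by N while q_i grows
exponentially in the parent-set size.

MDL, AIC and BDeu are score equivalent (one value per Markov equivalence
class); fNML is not, and the test suite exhibits a violating pair.

## Learners

**Exact.**  Local scores are enumerated for every (variable, parent set)
pair — sufficient statistics are shared across score families — and the
global optimum is found by two subset dynamic programs: best parent set per
variable per candidate set, then the best network over every variable
subset W = max over sinks s of best(W∖{s}) + best_parents(s, W∖{s}).
Memory and time are O(n·2^n); the default variable limit is 16, with an
optional max-parents bound.  All optimal learners return score-equivalent
structures, so tie-breaking (smaller parent set, then lexicographic;
smallest-index sink) exists only to make outputs deterministic.

**Greedy.**  Steepest-ascent hill climbing over add/delete/reverse moves
that preserve acyclicity, accepting only strictly improving moves (every
accepted move raises the score, so climbs terminate at local optima).  A
fixed-length tabu list (default 100) holds the inverses of recent moves;
a tabu move is allowed only if it would beat the incumbent best
(aspiration).  Restart 0 starts from the empty graph; the remaining
restarts (default 10 total) start from random DAGs with edge probability
2/n.  A restart is abandoned after 50 accepted moves that fail to beat the
incumbent best.  These three defaults are this package's own choices; the
procedure they parameterize (restarts + tabu) is standard.  Runs are fully
reproducible from the seed.

**Brute force.**  For up to 5 variables, every labeled DAG is enumerated
(25 at n=3, 543 at n=4, 29 281 at n=5) and scored through the same local
score table; this is the independence oracle the exact learner is tested
against.

## Gold networks and sampling

The synthetic generator emulates gold networks learned from small real
categorical tables: 5–25 variables, average in-degree 1.3–2.7, arities 2–4.
A random generation order is drawn and each (predecessor, node) pair
becomes an edge with probability 2·d/(n−1) for target in-degree d (exact
edge counts use uniform pair sampling instead); the 13-profile benchmark
suite reproduces the (nodes, edges) shapes of the study's gold networks
exactly, from a 5-node/8-edge profile to a 17-node/46-edge one.

CPT parameterization has two modes:

* `dirichlet` (default): rows drawn from a symmetric Dirichlet with
  concentration 1.0 (uniform on the simplex) — realistic spread, but
  recoverability of the structure is *not* guaranteed: rows can be nearly
  identical (undetectable edges) or nearly deterministic, and
  near-deterministic rows can make the sampling distribution unfaithful to
  the generating DAG, in which case the large-sample optimum is a
  *different* equivalence class.
* `sharpened` (the determinism boost used by the recovery experiments):
  every row puts probability 0.9 on one dominant state and spreads the rest
  uniformly; the dominant-state assignment is rejection-sampled so that
  every parent changes the child's distribution somewhere.  Rows are
  strictly positive and every edge is identifiable, so the gold equivalence
  class is recoverable at moderate sample sizes.  This mode exists exactly
  because the directional recovery claims (below) presuppose identifiable
  gold structures.

Datasets are drawn by logic (forward ancestral) sampling: variables are
visited in topological order and each is sampled from its CPT row given the
already-sampled parent states; the implementation vectorizes over rows.
The study's sample-size grid is 200–1000 in steps of 200 plus 2000–10000 in
steps of 1000 — 14 distinct sizes.

What the generator does *not* emulate: real data's missingness and mixed
types enter only through the separate preprocessing module; gold CPTs are
not MLE fits of real tables; variables are never deterministically related
under `sharpened` mode.  Passing recovery tests therefore demonstrate the
learners' and scores' behaviour under identifiable synthetic conditions,
not performance on any particular real dataset.

## Preprocessing

Raw mixed tables are made complete and categorical in two stages, in this
order (imputation first keeps distances meaningful):

1. **kNN imputation (k = 5).**  A missing cell is filled from the k closest
   fully observed records, with distance Euclidean over min–max scaled
   continuous columns plus a 0/1 mismatch per categorical column, excluding
   the imputed column and any column missing in the query record.
   Continuous targets take the neighbour mean, categorical the majority
   vote (ties to the smallest label).
2. **MDLP discretization.**  Each continuous column is recursively split
   against the designated class column at the boundary T minimizing the
   size-weighted class entropy E = (|S1|/|S|)Ent(S1) + (|S2|/|S|)Ent(S2);
   a split is kept iff Gain > [log2(|S|−1) + Δ]/|S| with
   Δ = log2(3^k − 2) − [k·Ent(S) − k1·Ent(S1) − k2·Ent(S2)], k the number
   of distinct classes.  Candidate cuts are midpoints between consecutive
   distinct values, ties to the smaller T.  Columns with no accepted cut
   are single-state and dropped with a warning.

## Evaluation metrics

Over the n(n−1)/2 unordered pairs: a correctly oriented edge is a TP, a
pair absent from both graphs a TN, an extra edge an FP, a missing edge an
FN, and an edge oriented the wrong way both an FP *and* an FN.  Then
Accuracy = (TP+TN)/(TP+TN+FP+FN), Sensitivity = TP/(TP+FN),
AHD = (FP+FN)/n.  When a denominator is empty (both graphs empty; gold
empty) the metric is defined as 1 — no error was possible.

SHD compares completed PDAGs: each DAG is converted to its CPDAG by the
edge-ordering/labeling algorithm (compelled edges stay directed, reversible
edges become undirected; v-structure edges are always compelled), and SHD
counts unordered pairs whose adjacency, edge type or orientation differ.
Hence SHD(X→Y, X←Y) = 0 — both orientations of a covered edge encode the
same independencies — while accuracy, sensitivity and AHD all penalize the
reversal.  The reported decomposition is: **add** = pair adjacent only in
the learned CPDAG; **delete** = adjacency present only in gold as a
reversible edge; **missing** = adjacency present only in gold as a
compelled edge; **reverse** = adjacent in both with differing
orientation/type.  The delete/missing split by gold edge type is this
package's documented convention.  CPDAG correctness is cross-checked
exhaustively (n ≤ 4) against an independent skeleton + v-structure
equivalence oracle.

## Experiment pipeline and numerical choices

`run_experiment` iterates gold × size × replicate, draws a dataset, learns
under every (score, learner), and emits one tidy record per cell with all
metrics and the SHD decomposition; per-cell seeds are derived from the base
seed via `numpy.random.SeedSequence` (kept below 2^31), so reruns are
bit-identical.  Per-size datasets are independent by default; a nested
(prefix) mode is available.  Summaries report Min/Mean/Max/population-STD
of SHD across the grid, replicates averaged within a size first.  A series
has *converged* at the smallest grid size from which its value never
changes; a single point, or a change between the last two sizes, is not
convergence.

Degenerate inputs and ties: 0·log 0 = 0 everywhere; MLE rows for unobserved
parent configurations are uniform (keeps sampling well defined); CPT rows
must sum to 1 within 1e-9; the hill climber requires an improvement
> 1e-9 to accept a move; DP ties prefer smaller, lexicographically earlier
parent sets.  Score-table and record serialization orders follow variable
declaration order.

## Scales used in the shipped analyses

The bundled analysis scripts run the pipeline at a scale chosen for a
single-workstation session: the recovery experiment uses the six benchmark
shapes with ≤ 10 nodes over a thinned six-point grid (200–10 000) with all
12 score specifications; the greedy comparison uses three of those networks
over four sizes; the test suite's recovery check uses six profile networks
(n = 5–10, sharpened CPTs) at sizes 200 and 10 000 with 10 replicates.
Directional findings at this scale — recovery improves with sample size
for exact-MDL on every network; BDeu at α = 100 is far worse than α ≈ 1;
greedy search is never closer to the gold standard in score and rarely in
SHD — are stable.  Which family has the lowest mean SHD, however, depends
on the synthetic conditions (on this suite fNML converges fastest and
attains the lowest grid-mean SHD), so no cross-family headline should be
read off these synthetic runs.

## Known limitations

* The exact learner's O(n·2^n) tables stop at 16 variables by default;
  the three largest benchmark shapes (17, 19, 20 nodes) need the greedy
  learner or a max-parents bound.
* The brute-force oracle stops at 5 variables by design.
* SHD's delete/missing split is a convention; only their sum (with add and
  reverse) is convention-free.
* The kNN imputer's mixed-type metric is one documented choice among many;
  the generic distance literature offers alternatives (e.g. Gower weights).
* `dirichlet`-mode gold networks may be unrecoverable in principle; use
  `sharpened` mode when recovery itself is the quantity under study.
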