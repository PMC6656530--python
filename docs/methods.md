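# Methods

`fluencynet` estimates an individual's semantic network from their semantic
fluency lists by modelling retrieval as a noisy censored random walk, and
compares the resulting networks across diagnostic groups. This note records
the model, the estimation procedure, the synthetic-data design, the
numerical choices, and the limits of what the shipped tests demonstrate.

## Retrieval model

A participant's semantic store is an undirected, unweighted graph G over the
M unique responses they produced. A fluency list is generated by a random
walk on G that moves to a uniformly random neighbour at each step
(A_ij = G_ij / deg(i)). Nodes are spoken on first visit; a revisit is spoken
with probability `p_emit` (producing a perseveration) and silently censored
with probability 1 − p_emit. `p_emit = 0` recovers the deterministic
censored walk, under which repeats are impossible; `p_emit = 1` removes
censoring entirely. The first item of each list is drawn from the walk's
stationary distribution, deg(i) / 2|E|.

Each inter-emission transition is an absorbing Markov chain over the s
unique items already observed in the list: the transient kernel is
Q′ = (1 − p_emit)·Q (censored wandering among observed nodes), and
absorption happens either by re-emitting an observed node (columns
p_emit·Q) or by first-visiting a new node (the corresponding columns of A).
With the fundamental matrix E = (I − Q′)⁻¹, the probability that the next
emission is item i, starting from the last emitted item j, is Σₖ E_jk R′_ki,
and 0 when I − Q′ is singular. Probability mass absorbed at nodes outside
the list's item set corresponds to emitting some other list, so per-list
transition distributions are sub-stochastic unless the list covers all of G.
Consequences worth knowing:

- a list can never open with an immediate repeat ("lion, lion"), and the
  model assigns such data probability 0 for every graph and every p_emit;
  real transcripts containing them will (correctly) fail estimation;
- an emitted repeat later in a list is possible when the walker loops
  through censored revisits, and its probability is exactly what the
  fundamental matrix computes. Worked example: on the path b–a–c with
  history [b, a] and p_emit = ½ the next emission is b with 2/7, a with
  1/7, c with 4/7 (a geometric renewal series over censored return loops;
  the test suite confirms the values by Monte Carlo). Note the walker
  *continues* from a censored node — it does not restart at the last
  emitted item.

## Posterior and search

The posterior combines the walk likelihood of all lists, an independent
edge-wise prior, and a uniform prior over the 101-point grid
{0.00, 0.01, …, 1.00} for p_emit. The edge prior is anchored to a reference
association network (e.g. built from free-association norms): probability
2/3 for a pair adjacent in the reference, 0.4 for a reference pair that is
not adjacent, 0.5 when either label is unknown to the reference. All three
are configurable; with no reference the prior is flat and estimation is
driven by the likelihood alone. The prior is evaluated over the pairs of
the participant's M observed nodes only, which keeps the posterior
finite-dimensional.

MAP estimation is greedy stochastic search over graphs with p_emit profiled
out. The search starts from the "naive" network joining every pair of items
adjacent in some list (finite likelihood for every observed transition at
p_emit > 0). Each step proposes toggling one node pair — with probability ½
a pair that co-occurs in some list, otherwise a uniform pair, so informative
pairs are favoured while every graph stays reachable. A proposal is accepted
only if its best posterior over the p_emit grid strictly exceeds the
incumbent's; after each acceptance p_emit is re-fitted by full grid search
(ties towards the smaller value). The search stops after 300 consecutive
non-improving proposals (configurable `patience`; proposals, not distinct
pairs) or `max_iters`.

Design choices that were genuinely open:

- **Profile acceptance.** Accepting on the candidate's posterior *at the
  incumbent p_emit* — arguably the most literal greedy reading — wedges
  permanently on trivial inputs: a 3-node corpus whose naive triangle fits
  p_emit = 1.0 rejects every single toggle at that p_emit even though a
  two-edge graph at p_emit ≈ 0.2 has higher posterior. Since the target is
  the joint argmax over (G, p_emit), acceptance compares each candidate at
  its own grid-optimal p_emit. On corpora small enough to enumerate
  (all graphs × the full grid), the search then attains the global optimum
  in 20/20 seeded runs in the shipped tests.
- **Screening subgrid.** For speed, the profile used in the acceptance
  decision is evaluated on a 21-point subgrid (every 0.05) plus the
  incumbent grid point, after a cheap incumbent-p shortcut for obviously
  improving toggles. Accepts are sound (any grid point lower-bounds the
  profile maximum); an improving toggle whose advantage exists only between
  screening points can be missed on one pass but becomes eligible again
  after the next acceptance. Fitted p_emit values always come from the full
  101-point grid. Rejected pairs are memoized until the next acceptance
  (the graph and incumbent are unchanged, so the verdict cannot change).
- **Caching.** Per-list grid vectors of transition log-likelihoods are
  cached; a toggle of (i, j) invalidates only lists containing i or j,
  while the global stationary normaliser log 2|E| is re-added per list.
  For p_emit > 0, I − (1−p)Q is provably non-singular (the spectral radius
  of the sub-stochastic Q is ≤ 1), so all transitions of a list solve in
  one batched LAPACK call; only p_emit = 0 takes the guarded scalar path
  where singular systems map to probability 0.

Everything is driven by one `numpy` Generator seeded from the caller:
identical seed and input give bit-identical results.

## Mock networks and deltas

Networks estimated from more or longer lists have more nodes and edges,
which confounds nearly every graph measure. Each participant network is
therefore compared against k (default 50) *mock networks*: the item order
within each list is permuted uniformly, a network is re-estimated with
identical settings, and its measures are recorded. Each mock has exactly
the participant's M nodes. The *delta* of a measure is the participant's
value minus the mock mean; it is computed for diameter, density, mean and
median degree, average shortest-path length and clustering — not for the
small-world coefficient (already a ratio against size-matched random
graphs) or p_emit (not size-dependent). Mock replicates whose estimation
fails (e.g. a permutation opens a list with an immediate repeat, which has
probability 0 under the model) are excluded from the means and counted,
rather than retried — retrying would bias the permutation distribution.

Measures: density, diameter, average shortest-path length (both on the
largest connected component; NaN for single-node graphs), mean and median
degree, and global transitivity (3·triangles / connected triplets). The
small-world coefficient is (C/C_rand)/(L/L_rand) against the means of
`n_random` (default 100) Erdős–Rényi G(n, m) graphs matched in node and
edge count, with the same largest-component convention.

## Group statistics

Two-sample comparisons use a pooled-variance t test unless a two-sided F
test rejects equal variances at α = 0.05 (configurable), in which case the
Welch statistic is reported; the result records which branch ran. Diagnosis
models are binomial GLMs with intercept and main effects only; perfect
separation is flagged (and the fit completed by BFGS) rather than raised.
Stepwise selection is bidirectional: from the maximal model, the single
addition or removal that lowers AIC most is applied until no move lowers
it. Cross-validation uses stratified split halves (training halves take the
ceiling of each class count), fits on one half, predicts the other at
probability threshold 0.5, and averages the confusion counts over
repetitions (default 5,000); coefficients are refit per split but the
factor *selection* is fixed beforehand. No multiple-testing correction is
applied by default, matching the uncorrected reporting convention of the
analyses this package supports.

## Synthetic cohorts

The generator is the package's forward model and test oracle, and its
defaults define the synthetic study conditions used throughout the tests:

- shared base network: connected Watts–Strogatz ring, n = 60, k = 4,
  rewiring 0.1 — small-world, like human semantic networks, and large
  enough that no participant exhausts it;
- control group ("NC"): 10 participants, intact base network,
  p_emit = 0.07, 8 lists × 12 emissions, education ~ N(16, 2.5) years;
- impaired group ("PAD"): 10 participants, base network plus 30 spurious
  edges drawn uniformly from the non-edges (per participant), p_emit = 0.35,
  5 lists × 8 emissions, education ~ N(13.5, 2.5) years.

These mirror the clinical contrast the package targets — impaired
participants repeat more (higher p_emit), produce fewer and shorter lists,
and their stores carry spurious associations — at roughly half to one
quarter of the real cohort's data volume so the full pipeline (including
mock ensembles) runs on a laptop in minutes. Lists terminate on emission
count (the observable in time-limited fluency tasks), start from the
stationary distribution, and per-participant generator streams are derived
from (master seed, group index, participant index) so groups can be resized
without perturbing each other.

Under these conditions the estimated cohort reproduces the directional
pattern expected of the clinical contrast: control vocabularies are about
1.8× larger, impaired networks are denser and less small-world, their
fitted p_emit is higher, and all their delta measures sit closer to the
mock baseline. The acceptance suite asserts exactly these directions (no
effect sizes) at a fixed seed, with k = 6 mocks and 50 random graphs per
small-world coefficient to keep runtime near two minutes.

What the synthetic cohort does *not* emulate: real transcripts' lexical
structure (category violations, compound normalisation), retrieval
strategies beyond the walk (cluster switching, strategic jumps), visit-level
longitudinal drift, and the frequency-weighted item distribution of real
fluency norms. Passing tests therefore demonstrate correctness of the
machinery and the qualitative group logic, not clinical validity.

## Numerical choices and degenerate inputs

- Log-space accumulation everywhere; impossible data score exactly −inf,
  never a large negative sentinel.
- Linear solves, not explicit inversion; at p_emit = 0 a singular
  (I − Q) — or a residual above 1e-8 — maps the transition to probability 0.
- Transition probabilities are clipped to [0, 1] before logging to absorb
  rounding at the 1e-15 level.
- Grid ties in the p_emit fit break towards the smaller value, so
  repeat-free corpora fit exactly 0.0.
- Isolated nodes: rows of A are zeroed and the nodes reported; a list
  starting (or stepping) there scores −inf, which is how proposals that
  would strand a used node get rejected.
- Single-node largest components report diameter/aspl as NaN ("missing"),
  never 0.

## Known limitations

- With short lists on a large store, revisits are rare and p_emit is weakly
  identified: at the desk-scale cohort defaults the impaired group's fitted
  p_emit is correctly ordered but attenuated relative to its generating
  value, and group perseveration rates are closer together than in real
  cohorts (longer control lists create more repeat opportunities that
  partially offset their lower p_emit).
- The stochastic search is greedy; on multimodal posteriors different seeds
  can return different local optima (the exhaustive-enumeration tests bound
  this on tiny problems only).
- Mock ensembles inherit the estimator's cost: the default of k = 50
  replicates per participant is the dominant runtime term of the pipeline.
- Participants contributing rows under two diagnoses are treated as
  independent rows in the cohort table; the dependence is ignored.
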