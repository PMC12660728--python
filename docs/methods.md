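# Methods

## The DEC model as implemented

Geographic ranges are subsets of `n` discrete bioregions, encoded as
bitsets.  The state space enumerates the empty (null) range first, then all
non-empty subsets up to `max_range_size` (default: all `n` areas, so 2^7 =
128 states for a seven-region analysis), ordered by (cardinality, bitset
value).  This ordering is the package-wide convention for rate matrices,
conditional-likelihood vectors and serialized output.

**Anagenesis.**  Along a branch the range follows a continuous-time Markov
chain.  Range expansion `R -> R ∪ {j}` has rate `delta * Σ_{i∈R} m_ij`,
where `m` is the dispersal-multiplier matrix of the time slice the branch
is crossing; range contraction `R -> R \ {i}` has rate `e` per occupied
area.  A singleton contracting reaches the null range, which is absorbing
(its row of Q is zero).  Diagonal entries close each row to zero.  Rates
are per Myr; branch lengths are Myr, ages Ma.

**Cladogenesis.**  At a node, a singleton ancestor is copied to both
daughters.  A larger ancestor splits into one of the distinct ordered
daughter pairs produced by vicariance (`{i}` vs `R \ {i}`) or subset
sympatry (`{i}` vs `R`), each pair equally likely: 6 events for a 2-area
ancestor, `4s` for an `s`-area ancestor with `s >= 3`.  There is no
founder-event ("jump") parameter, so the model has exactly K = 2 free
parameters (delta, e), and AIC = 2K − 2 lnL.

**Time stratification.**  A landscape evolution model (LEM) carries one
multiplier matrix per time slice; slices tile root-to-present.  A slice
with bounds `(start, end)` contains ages `end <= a < start` (ages increase
into the past), so an event exactly at a boundary belongs to the older
slice and age 0 to the youngest.  The oldest slice's declared start (often
`inf`) is clamped to the tree's root age, making the likelihood independent
of any undated older bound.  Branches are cut at slice boundaries using
node ages from the ultrametric tree, and the per-slice transition matrices
are composed oldest to youngest.

**Likelihood.**  Felsenstein pruning over the full state space.  Tip
vectors are indicators of the observed (never null) range; node vectors
combine the daughters' branch-top vectors through the cladogenesis table;
each internal node is rescaled by its maximum with log factors accumulated,
so large trees do not underflow.  The root prior is uniform over non-null
states by default; a FitzJohn-style weighting (states weighted by their own
conditional likelihood) is available because reference implementations
differ in their root treatment and the choice is rarely reported.

**Transition matrices.**  `exp(Qt)` per slice via eigendecomposition of the
dense Q (states above `max_range_size` are excluded before exponentiation),
with two safety nets: the decomposition is only used when it reconstructs Q
to 1e-11 and its eigenvector matrix is well-conditioned, and any propagated
row whose sum drifts from 1 by more than 1e-9 triggers a fall back to
`scipy.linalg.expm` on that call.  Tiny negative entries from round-off are
clamped to zero.  The eigendecomposition route exists because ML fitting
evaluates thousands of branch exponentials; it is cross-checked against
`expm` directly in the test suite.

**Estimation.**  Bounded L-BFGS-B on (log delta, log e), bounds
`[1e-9, 10]` events/Myr, from 5 Latin-hypercube starting points drawn
log-uniformly in `[1e-3, 1]` events/Myr with a fixed seed — biologically
plausible starting rates, while the bounds stay wide.  Multi-start guards
against ridge-shaped likelihood surfaces; two runs with different start
seeds agreeing in lnL is a standard stability check and is asserted in the
tests.

**Conditioning on observability.**  The null range is unobservable: a
dataset only exists for lineages that survived in at least one area.  The
default likelihood, like the reference DEC implementations, ignores this.
`DECLikelihood(..., condition_on_survival=True)` divides the likelihood by
the probability that no tip is null — computed by a second pruning pass
whose tip vectors allow every non-null state — which matches a
data-generating process conditioned on complete tip observations.  The
parameter-recovery experiment uses this conditioned estimator; without it,
ML systematically drives the extinction rate to zero on simulated data
(the survival factor `P(no null tips)` decreases in `e`, and on data that
by construction contain no extinct lineage the unconditioned optimum sits
at the boundary).  On empirical data the unconditioned default keeps
results comparable to the reference implementations.

**Marginal ancestral ranges.**  Inside (subtree) conditionals from the
pruning pass are combined with outside (rest-of-tree) partials computed on
a root-to-tip sweep through the same cladogenesis tables and transposed
branch matrices; their product, normalized over non-null states, is the
marginal posterior at each internal node.  At the root this reduces to the
prior-weighted normalized root conditionals, which is asserted as an
algebraic identity in the tests, and the whole construction is checked
against explicit joint-state enumeration on small instances.

## Diversity partitioning

Alpha diversity per stream order has two senses in field use: the pooled
richness of an order, and the mean richness across communities within the
order.  The profile reports both (`pooled_richness`, `mean_alpha`); with
order-level occurrence data (the default) they coincide.  Whittaker's beta
is γ divided by mean alpha; per-order betas use that order's alpha.
Absolute turnover is computed pairwise only, mirroring how turnover
matrices are reported (lower triangle β_A, upper triangle the shared
proportion of the pooled pair richness).

Occurrence QC applies, in order: malformed-coordinate rejection (|lat| >
90, |lon| > 180, stream order outside 1–10), duplicate collapse on
(species, lat, lon) rounded to 4 decimals (~11 m — "duplicate coordinates"
needs a precision to be reproducible), and species-bounds filtering.  The
pipeline does not snap coordinates to river segments; records must arrive
with a stream order, because replicating raster hydrology is out of scope.

The alpha-density regression (richness per km vs stream order) is a simple
least-squares fit with a two-sided t-test on the slope (n − 2 df), no
multiple-testing correction — it is a single planned test.

## The synthetic-data generator

The generator emulates the study system at desk scale with known truth:

* **Trees** — birth–death via dendropy, conditioned on the tip count by
  simulate-and-retain; the stem edge is discarded so `root_age` is the
  crown age.  The default birth rate 0.14/Myr gives ~30 Ma root ages at
  100–200 tips, the depth typical of a Neogene fish radiation.
* **Range histories** — exact event-driven (Gillespie) jumps with
  slice-appropriate rates, cladogenetic draws from the same event tables
  the likelihood uses.  Lineages absorbed into the null range are
  unobservable, so by default the offending branch is redrawn
  (`resimulate-branch`), conditioning each branch on survival; at
  realistic rates (e = 0.01 over ~1400 Myr of tree length) a whole-history
  rejection scheme accepts ~e^-10 of replicates and is therefore only
  practical at toy scale, though it remains available
  (`reject-replicate`), as does keeping nulls for observability studies
  (`keep`).  Branch-level conditioning is slightly stronger than
  conditioning on observable tips jointly, which biases realized loss
  counts mildly downward; the recovery experiment absorbs this within its
  tolerance.
* **Riverscapes** — Horton's laws as geometric series: segment counts fall
  by the bifurcation ratio (default 4), mean lengths rise by the length
  ratio (default 2), widths and depths by their own ratios (1.9, 1.8), so
  length concentrates in low orders (orders 1–5 hold ~97% of length at the
  defaults) while volume concentrates downstream.  Lognormal,
  mean-preserving noise (sigma 0.3) roughens the series; sigma 0 gives the
  exact closed form.
* **Occurrences** — species carry a modal stream order and niche breadth;
  records draw orders from a discretized Gaussian niche, coordinates
  uniform in a basin box.  Planted duplicates and out-of-bounds records
  exercise the QC stage with known counts.

What the generator does *not* emulate: spatial autocorrelation of records
along real river geometry, detection/sampling biases, gene-tree error,
non-ultrametric trees, or fossil lineages.  Passing recovery tests
therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to their violation.

## Standardized experiments

The experiments module freezes the study conditions so tests and the
acceptance script run the same computation:

* **Likelihood oracle** — random instances (2–4 tips, 2–3 areas, random
  multiplier matrices with closed corridors, 1 or 2 slices, log-uniform
  rates); pruning lnL vs explicit summation over all joint assignments of
  internal-node states, with branch matrices straight from `expm`.
* **Parameter recovery** — truth (delta = 0.05, e = 0.01) on the 4-region
  chain; 20 replicates at 200 tips for the median check, 12 each at 100
  and 400 tips for the RMSE trend.
* **Model selection** — truth (delta = 0.08, e = 0.01) under a two-slice
  LEM whose connectivity switches from a linear chain to a complete graph
  at 10 Ma — a strong river-capture-like rearrangement; 50 replicates at
  150 tips, the true stratified model vs the single-slice chain, compared
  by AIC.

Replicate counts and tree sizes are the package's chosen desk-scale study
conditions; they keep the full experiment battery to roughly ten minutes
on a single CPU.

## Numerical choices and degenerate inputs

* Ultrametricity tolerance: 1e-3 × tree height, judged against the median
  root-to-tip distance so the reported worst tip is the aberrant one.
* Branch segmentation tolerance: slice durations must tile each branch to
  1e-6 relative; zero-duration segments (< 1e-12 Myr) are dropped.
* Cladogenesis probabilities sum to 1 exactly by construction (equal
  weights over an enumerated set); rate-matrix rows sum to zero to 1e-10.
* Min–max normalization of a constant vector, Whittaker beta with zero
  mean alpha, turnover with c > min(S1, S2), and regressions on constant x
  are errors, not silent NaNs.
* Model-comparison ties are broken by model name and all tied models are
  flagged co-best.
* `fit_ml` with all starts non-finite raises an optimization error naming
  the LEM; likelihood underflow raises an explicit error suggesting
  rescaling rather than returning −inf.

## Known limitations

* No DEC+J, no Bayesian inference, no stochastic mapping; K is fixed at 2.
* The extinction rate is weakly identified from extant ranges alone; even
  with the conditioned estimator its sampling spread at 200 tips is of the
  order of the true value, and a quarter of replicates estimate it at the
  boundary.  Median behavior is well calibrated; individual ê values
  should be read with care — a caveat that applies to DEC fits generally.
* The shipped seven-region LEM configs are plausibility reconstructions
  for demonstration, not the study's supplementary matrices.
* Stream-order assignment from raw coordinates is out of scope; upstream
  GIS processing must supply it.
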