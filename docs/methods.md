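# Methods

## Model and state spaces

A lineage's state is a pair `(count, trait)`: a haploid chromosome number
and, in the two-trait models, a binary phenotype. Evolution is a
continuous-time Markov chain with generator Q; off-diagonal entries are
instantaneous event rates, the diagonal closes each row to zero, and
`P(t) = exp(Qt)` gives transition probabilities along a branch of length
`t`. Rates and branch lengths share one time unit, so only their product
is identified — trees are typically time-calibrated and rates are events
per unit time.

Bounded spaces enumerate counts `1..c_max` (default 25, user-settable)
plus one LARGE state per trait that absorbs all counts above `c_max`.
Event moves in BiChroM, for a lineage with trait j and count i:

* gain `i -> i+1` at λⱼ (into LARGE_j when i = c_max),
* loss `i -> i-1` at μⱼ for i ≥ 2 (no loss from count 1),
* doubling `i -> 2i` at ρⱼ (into LARGE_j when 2i > c_max),
* trait flip `(i, j) -> (i, 1-j)` at q₀₁ / q₁₀,
* LARGE_j -> LARGE_{1-j} at εⱼ; LARGE states have no count-changing exits.

Two conventions are deliberate. First, overflowing events enter LARGE at
the full event rate rather than being truncated, and LARGE is absorbing
for counts: the ε parameters are exactly "trait change while the count is
large", and no information is invented about re-entry into the explicit
range. Second, multiple events sharing a source/target cell add (from
count 1, gain and doubling both reach count 2 at λ + ρ) — standard
competing-exponential semantics.

The Solanum model lives on the enumerated space {12, 18, 24, 36, 48} ×
{H, W} with doubling (12→24, 18→36, 24→48), demiploidy (12→18, 24→36) and
growth-form flips. Transitions whose arithmetic target (27, 54, 72, 96)
is not an observed count are simply absent: the model is a hypothesis
about movement among the counts that occur in the clade, and adding
hidden out-of-set states would change the tested hypothesis. The
single-trait constant-rate model uses the bounded space; demiploidy from
an odd count i, where 1.5i is fractional, splits the rate equally between
⌊1.5i⌋ and ⌈1.5i⌉ (a demiploidy "half" whose target equals the source,
possible only at count 1, is dropped as a non-event).

State ordering is fixed (first-trait block, counts ascending, then LARGE;
then the second block) but carries no semantics: every lookup goes through
the index map, and a shuffled ordering yields identical inference — this
is tested.

## Likelihood

Felsenstein pruning with per-node rescaling: tips carry 0/1 conditioning
vectors (one-hot when fully observed, with counts above `c_max` mapped to
the trait's LARGE state; masks over the missing dimension otherwise), each
internal node takes the elementwise product over children of
`P(t_child) @ child_partial`, and each partial is divided by its maximum
with the log factors accumulated, so trees with thousands of tips cannot
underflow. The root combines the final partial with a prior — uniform by
default, with stationary and custom-vector options. Uniform is the most
transparent choice where nothing else is stated; the choice matters in the
third decimal of absolute log-likelihoods but cancels almost entirely in
likelihood-ratio statistics between models sharing a state space.
Optimization works on natural-log rates (positivity by construction);
`negloglik` exponentiates before calling the Q-builder, and validates any
builder's output (row sums within 1e-9, nonnegative off-diagonals) so
user-supplied models fail loudly, naming the offending row.

Branch propagation has a reference route and a fast route:

* **`expm`** (default): one scaling-and-squaring exponential per *unique*
  branch length (lengths keyed to 12 significant digits; duplicate
  lengths are cache hits, zero-length branches use the identity). This is
  the accuracy reference; small transition probabilities keep full
  relative precision.
* **`fast`** (used inside optimization): partial vectors are propagated
  without ever forming P. When Q's eigendecomposition is well conditioned
  (verified per evaluation by reconstructing P at the longest and shortest
  branch and checking row-stochasticity to 1e-6), each branch costs two
  small matrix-vector products in the eigenbasis. When Q is nearly
  defective — which happens systematically at parameter-space boundaries,
  e.g. a vanishing loss rate turns a trait block into a pure birth chain
  with one large Jordan block — propagation switches to uniformization
  (Jensen's method): `exp(Qt)v` as a Poisson-weighted series in the
  stochastic matrix `I + Q/Λ`, with Λ the maximum exit rate. The series
  involves only nonnegative terms and is effectively exact; its cost
  grows with Λt, so stiff proposals (Λ·t_max ≥ 600 or an excessive total
  term budget) fall back to the expm stack. The fast route's absolute
  error (~1e-12 for spectral in practice, ~1e-13 for uniformization) is
  far below optimizer stopping tolerances, but reported likelihood values
  and all reference comparisons use `expm`.

Pruning is organized level by level (all nodes whose subtrees are complete
are processed together) so propagation is batched into matrix-matrix
products; the schedule is cached per tree, as are tip conditioning
vectors.

Probability-zero data (e.g. two identical-length-zero tips in conflicting
states) yield +infinity with a structured warning naming the node rather
than an exception: an optimizer can retreat from such points.

## Estimation and testing

`fit_mle` minimizes the negative log-likelihood over free log-rates with
L-BFGS-B (finite-difference gradients) inside box bounds, default
`[1e-10, 100]` on the natural scale — generous cover for empirical rates
of 1e-6 to ~1. A Nelder-Mead polish runs when quasi-Newton terminates
abnormally, and by default three additional starts jittered by sd 0.5 on
the log scale (seeded) guard against multimodality. Default inits are
0.01 for every rate, the scale of typical eudicot estimates. Fits are
deterministic given seed and options.

The LRT uses `D = 2(nll_reduced - nll_full)` with df the difference in
free-parameter counts and an upper-tail χ² p-value. D in `[-1e-6, 0)` is
clipped to zero as float noise; anything more negative raises a nesting
error, because a reduced fit strictly beating a full fit can only mean the
full optimization failed. Profile likelihoods re-optimize nuisances at
each grid value of the focal parameter, warm-started from the global MLE;
95% likelihood intervals are read off where the profile crosses the
minimum plus `χ²₁(0.95)/2 = 1.92`, linearly interpolated, with endpoints
the grid fails to bracket flagged open rather than raised.

## Simulation design

Trees are pure-birth (Yule) with birth rate fixed at 1, grown from two
root lineages by exponential waiting times until the target tip count,
plus one further interval so pendant edges are positive; heights are then
set by uniform rescaling, which decouples topology from timescale. Tip
data are simulated by exact Gillespie jumps along each branch.

The three built-in scenarios fix the eight nuisance rates at λ₀ = 0.01,
λ₁ = 0.005, μ₀ = 0.01, μ₁ = 0.005, q₀₁ = 0.01, q₁₀ = 0.005,
ε₀ = ε₁ = 1e-6 and differ in (ρ₀, ρ₁): S1 (0.01, 0.01), S2 (0.01, 0.002),
S3 (0.01, 0.008). All ten (nine) parameters are re-estimated in every
fit. The default tree height is 50: the trait-0 event rate λ₀+μ₀+ρ₀+q₀₁ =
0.04 then gives about two expected chromosome-number events per
root-to-tip lineage, the midpoint of the zero-to-four design range that
keeps the data informative without saturating. The root state is drawn
uniformly per replicate (recorded via the replicate seed); the few
percent of replicates rooted in a LARGE state carry little rate
information and dilute all scenarios equally.

Per replicate, the reduced fit is warm-started from the full MLE (shared
ρ at the geometric mean of ρ̂₀, ρ̂₁); if it nonetheless undercuts the full
fit, the full model is refit from the reduced solution, which restores
nesting without touching the test itself. Power-study fits run a single
quasi-Newton start with a stopping tolerance (relative 1e-7) far below
the resolution of the χ² test — simulated data are generated at rates on
the scale of the default init, so multistart adds cost, not accuracy.
Replicate seeds are `base_seed + index`; the entire report is
bit-reproducible.

### What the generator does and does not emulate

The simulations match the stated study conditions: Yule topologies,
trait-linked CTMC characters, exact observations at every tip. Real data
differ in ways the generator deliberately omits — extinction and
incomplete taxon sampling, trait-dependent diversification, measurement
and database error in counts, phylogenetic uncertainty, and missing
observations. Passing tests therefore establish the correctness and
calibration of the inference machinery under the model, not robustness to
model violations.

### Study sizes

The full published design for this kind of power study (300 trees per
scenario at up to 1000 taxa) is a cluster-scale computation. The test
suite runs the same experiment at 100 tips with 50 replicates per
scenario plus a 250-tip recovery run (20 replicates);
`scripts/acceptance.py` uses 30 replicates per scenario and 10 at 250
tips. These sizes were chosen as the smallest at which the qualitative
claims — type-I error near α, the S2 ≫ S3 power ordering, unbiased ρ
recovery — are statistically resolvable with exact binomial intervals.

## Numerical choices

* Generator validation: row sums within 1e-12 at build time (1e-9 inside
  the engine, where Q is rebuilt from exponentiated log-rates each
  evaluation), off-diagonals ≥ 0.
* `exp(Qt)` rows must be stochastic within 1e-10 on the public route;
  entries are clipped to [0, 1] after the check.
* Branch-length cache key: 12 significant digits. Zero-length branches
  use the identity without an exponential.
* Fast-route admission: spectral row-sum check 1e-6; uniformization
  truncation at Poisson tail mass < ~1e-13 with early exit, admitted when
  Λ·t_max < 600.
* D clipping threshold -1e-6 separates float noise from optimizer
  failure; exact binomial (Clopper-Pearson) intervals summarize rejection
  proportions.
* Tie-breaks: odd-count demiploidy splits equally floor/ceil; a taxon
  recorded as both woody and herbaceous codes as woody; multiple counts
  code as the largest.

## Known limitations

Rates are count-independent (no linear or exponential rate functions);
at most two trait categories; no extinction in the tree simulator;
no analytic gradients (finite differences only); ε rates are weakly
identified unless many taxa exceed `c_max`; MLEs of nearly-unobserved
event types routinely sit on the lower bound, where likelihood surfaces
are flat and profile intervals are one-sided; absolute log-likelihood
values (not ratios) depend on the root-prior convention.
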