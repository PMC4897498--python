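# Methods

## Model and sampling scheme

The package estimates the two-parameter normal ogive (2PNO) model,
`P(y_ij = 1) = Φ(α_j θ_i − β_j)`, by Gibbs sampling with truncated-normal
data augmentation.  Each iteration draws the augmented matrix `Z`, then
the traits `θ`, then the item pairs `ξ_j = (α_j, β_j)'`, each conditional
on the freshest values; the priors are `θ_i ~ N(0,1)`, `p(β_j) ∝ 1`, and
`p(α_j) ∝ I(α_j > 0)`.  Early draws are discarded as burn-in (no further
convergence diagnostics are applied beyond MCSEs; traces can be exported
for external diagnostics).

### The two trait-update modes

The classical unit-information trait update uses
`mean_i = Σ_j (Z_ij + β_j) α_j / Σ_j α_j²` and variance `1/Σ_j α_j²`.
That update is *not* the posterior implied by the `θ_i ~ N(0,1)` prior:
full conjugacy adds the prior precision, giving denominators
`1 + Σ_j α_j²`.  Both are implemented — `prior_mode="as-printed"` (the
default, matching the classical update exactly) and
`prior_mode="conjugate"` (the recommendation; it is the variant whose
joint target actually contains the stated trait prior, it shrinks traits
toward 0, and it anchors the latent scale better).  The discrepancy is a
real tension in the literature on this sampler and is surfaced as an
option rather than silently corrected.

### Truncated-normal draws

All truncated-normal variates use a one-uniform-per-draw inverse-CDF
transform based on the survival identity `sf(t) = (1 − u)·sf(a)`.
Moderate truncations (standardized bound ≤ 5) are evaluated in linear
probability space through `ndtr`/`ndtri`, picking whichever side of the
median keeps the quantile function accurate; far tails switch to a
log-space route (`log_ndtr` + `ndtri_exp`) that retains full relative
accuracy where linear-space masses underflow.  One uniform per variate
makes the stream consumption of an update predictable, which the blocked
runner's serial-equivalence guarantee depends on; a rejection scheme with
variable consumption could not offer that.  A draw that rounds exactly
onto a finite truncation bound is nudged one ulp into the open interval —
the measure-zero analogue of rejecting boundary values.

### Positive-slope constraint

The bivariate item draw is redrawn jointly until the slope coordinate is
positive, matching the indicator form of the truncated conditional (not a
conditional decomposition of β given a truncated α).  The rejection
budget defaults to 10,000 proposals per item per iteration; exhausting it
raises an error naming the item and the estimated acceptance probability
rather than silently biasing the draw.  Zero-variance trait vectors (all
`θ_i` equal) make the item design singular and raise a degenerate-design
error; jittering would silently change the model.

## Block-decomposed execution

A `BlockGrid` partitions the response matrix into `r × c` contiguous
blocks (uneven dimensions give the trailing block the remainder — padding
would bias sums).  The Z update runs independently per block; the trait
update per row block; the item update per column block.  Two stream modes
define the randomness contract:

- **serial-equivalent**: a single stream is consumed in the canonical
  draw order (Z cells row-major, traits by ascending person index, items
  by ascending item index), and reductions use the canonical single-pass
  routine on full arrays.  Because within-block work is elementwise or
  per-row/per-item, the result is bitwise identical to the serial runner
  for *every* grid shape.  This mode exists to prove the decomposition
  geometry correct.
- **per-block**: each (update-kernel, block) pair owns an independent
  generator seeded from the chain seed and the block coordinates (via
  `SeedSequence` spawn keys), and cross-block sums — `Σ_j α_j²`, the trait
  numerators, and the `x'x` / `x'Z_j` moments — are accumulated as
  per-block partials reduced in ascending block index.  The fixed
  reduction order makes runs deterministic despite floating-point
  non-associativity; partial-sum totals agree with single-pass sums to
  1e-10 relative tolerance but not bitwise, so this mode produces a
  different, equally valid chain.

The backend is an execution contract, not a technology: the sequential
loop over blocks shipped here conforms, and so would any concurrent
executor that honors the per-block streams and the reduction order.

## Initialization

Starting traits are standardized person sum scores (sample SD; all-equal
scores fall back to zeros) — the classical-test-theory estimate, which
starts the chain with the right person ordering.  Slopes start at 1,
intercepts at 0, and the initial `Z` is implied by the first augmentation
draw.  A `zeros` policy is available for sensitivity checks.  Thinning
(default 1) is provided purely for memory control on long chains; kept
draws number exactly `floor((L − burn_in)/thin)`.

## Posterior summaries

Posterior means are arithmetic means over kept draws.  MCSEs use
non-overlapping batch means with `floor(sqrt(M))` equal batches (trailing
remainder dropped), a standard choice that is robust to the
autocorrelation of Gibbs output.  Difficulty ratios `β̂/α̂` are carried at
full precision and rounded to 4 decimals (half-even) only in report
tables.  The trait-density table uses a Gaussian kernel with Silverman
bandwidth over a grid spanning the mean ± 4 SD.

## Synthetic data

The generator draws from the model itself: `θ ~ N(0,1)`, slopes from a
law with strictly positive support (default U(0.3, 1.3), bracketing the
published CBASE calibration range of roughly 0.29–0.72 while allowing
steeper items), intercepts standard normal by default, responses
Bernoulli with probit probabilities.  Truth is always returned and
serialized next to the data.  Generated data are exchangeable across
persons and locally independent across items; real responses with
guessing, testlet dependence or missingness will violate those
assumptions, so passing recovery tests here demonstrates correctness of
the sampler, not robustness to model misspecification.  A closed-form
oracle checks the generator: the marginal proportion correct of item j is
`Φ(−β_j / √(1 + α_j²))`.

## Propriety of the posterior, and what the tiny-instance check shows

With `p(β) ∝ 1` and `p(α) ∝ I(α > 0)` the joint posterior is formally
improper for any finite data set: at every trait configuration that
threshold-orders an item's responses, the item likelihood tends to a
positive constant over an infinite cone of `(α, β)`, so the item
parameters' integral diverges.  For realistic `n` the likelihood decays
long before the flat directions matter and finite chains behave well —
the n=1000 recovery checks pass comfortably — but on a 3-person, 2-item
instance the pathology is visible: a 20,000-iteration chain drifts to
ever larger slopes and has no stationary law, and box-truncated
quadrature moments depend on the box.  The package therefore validates
conditional correctness with checks that are mathematically well-posed:
sub-chains holding items (or traits) fixed target proper posteriors and
are compared against independent dense-grid quadrature
(`ogive.quadrature` for the joint evaluator; 1-D and 2-D grids in the
tests), and the full joint comparison on the tiny instance is retained,
and expected to fail, as a faithful record of the diffuse-prior model's
behavior.  Users who need a proper posterior at small `n` should use
informative item priors, which are outside this package's scope.

## Problem sizes and numerical choices

- Quadrature grids: slopes on (0, 10] and intercepts on [−10, 10] at 100
  midpoints each, traits on [−5, 5] at 41 points (joint evaluator);
  finer 1-D/2-D grids in the sub-chain tests.
- Recovery studies: n=1000, k=20, 4,000 iterations with 2,000 burn-in,
  conjugate mode, three to five seeds.
- Blocked-equivalence: n=500, k=20; bit-identity over 1×1, 2×2, 5×5 (and
  uneven) grids; per-block statistical agreement over 2,000 kept draws.
- Monte Carlo tolerances are 3 standard errors around closed forms or
  quadrature (4 SE for decile-style multiple comparisons); the Φ
  evaluation is checked to 1e-12 against a direct erf formula.
- All chains, generators and streams are seeded; identical seeds give
  bitwise-identical output, including across the serial/blocked boundary
  in serial-equivalent mode.

## Known limitations

- Diffuse item priors: improper joint posterior at small `n` (above);
  no informative-prior option.
- No logistic-link (2PL), guessing (3PNO) or multidimensional variants.
- No within-process parallel backend is shipped; the block contract is
  the extension point.
- MCSE is the only built-in convergence diagnostic; export traces for
  anything richer.
- Wall-clock benchmark output is hardware-dependent and carries no
  correctness guarantee; only the S = T_S/T_P and E = S/P arithmetic is
  tested.
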