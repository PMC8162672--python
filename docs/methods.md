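# Methods

## Model and assumptions

All procedures assume N independent pairs (X_i, Y_i) from a bivariate
normal distribution with correlation rho, and work with two large-sample
approximations:

- r ~ N(rho, sigma_r^2), sigma_r = (1 - rho^2)/sqrt(N - 3);
- zeta_hat = atanh(r) ~ N(atanh(rho), sigma_zeta^2), sigma_zeta = 1/sqrt(N - 3).

The Fisher transformation is variance-stabilizing and normalizing, so the
zeta-scale approximation is the more accurate of the two at small N and
extreme correlations. Neither approximation is exact; the Monte-Carlo
engine exists to quantify how well the nominal error rates are attained
under the true sampling distribution of r. Sample sizes below 4 are
rejected outright (the approximations need N - 3 > 0), as are correlations
on or outside [-1, 1]; nothing is clamped, because the solvers assume
finite positive variances.

## Equivalence hypotheses and the solved regions

The equivalence null is H0: rho <= rho_L or rho >= rho_U against
H1: rho_L < rho < rho_U; rejection declares equivalence. The extended
tests choose the rejection interval so its probability equals alpha at
*both* bounds under the relevant normal approximation.

On the zeta scale the variance does not depend on the bound, so the
solution is symmetric about the midpoint of (zeta_L, zeta_U) and reduces to
one scalar equation in the half-width d,

    Phi((delta/2 + d)/sigma) - Phi((delta/2 - d)/sigma) = alpha,

whose left side rises monotonically from 0 to 1: the root exists, is
unique, and is found by bracketed Brent iteration (probability tolerance
1e-12 or better; brackets expanded geometrically if needed).

On the r scale the two constraints carry different standard deviations and
the 2x2 system has no symmetry. It is solved by a Gauss–Seidel alternation
that inverts one constraint for one endpoint with the other held fixed,
seeded from the zeta-scale solution mapped through tanh, then polished by a
damped Newton step with the closed-form normal-density Jacobian. The
alternation was chosen over a nested scalar root-find because each step
inverts the normal CDF at a moderate quantile: when the region is wide
relative to sigma the two constraints nearly decouple (each endpoint
contributes only a far-tail probability, ~1e-14, to the other bound's
constraint) and any scheme that recovers one endpoint from the *tail mass*
of the other loses ten significant figures there. Every solved region is
re-verified post hoc: both rejection probabilities must equal alpha to
1e-10 absolute or the solver raises with diagnostics rather than return
silently.

For symmetric bounds (-rho_B, rho_B) the reflection r -> -r forces
U = -L and a single equation remains (`solve_equt_symmetric`); it agrees
with the general solvers to ~1e-14 and is exposed both for speed and
because the one-dimensional form is the natural presentation of the
lack-of-association test. Region endpoints are open intervals: a tie at a
critical value does not reject. This is immaterial for continuous r but
fixed for determinism.

## TOST comparators and their degeneracy

TOST rejects when both one-sided z tests at the two bounds reject,
giving half-widths rho_B - z_alpha*sigma_B (r scale) and
zeta_B - z_alpha*sigma_zeta (zeta scale). When the half-width is <= 0 the
region is empty, reported as (0, 0) with an `empty` flag; the test then
never rejects, so its true size and power are exactly zero. The true Type I
error at the bound, Phi(-z_alpha) - Phi(z_alpha - 2b/s), stays strictly
below alpha at every finite N and approaches it only asymptotically.

`tost_min_sample_size` reports the conventional closed-form thresholds

    r scale:    N > z_alpha^2 (1 + rho_B^2)^2 / rho_B^2 + 3
    zeta scale: N > z_alpha^2 / zeta_B^2 + 3,

with min_n the smallest integer strictly above the threshold (a half-width
of exactly zero counts as empty). The zeta threshold is the exact flip
point of the region. The r-scale form is the published convention and is
conservative: the half-width actually turns positive at the smaller bound
z_alpha^2 (1 - rho_B^2)^2 / rho_B^2 + 3, so every N >= min_n is guaranteed
nonempty while some smaller N already are. Both the conventional threshold
and the exact flip behaviour are unit-tested. An asymmetric-bounds TOST
(`tost_region_general`) is included as a marked extension; the standard
construction is defined only for the symmetric case.

## Power and sample size

Power is the normal probability of the solved region evaluated at the true
parameter — on the r scale with sigma_r(rho), on the zeta scale wholly in
zeta coordinates with zeta = atanh(rho). At either bound it reduces to
alpha by construction, which the tests exploit as a size check. TOST
variants use their closed-form regions and have power 0 while empty.

`sample_size` searches for the minimal integer N with power >= target
(default 0.80 at alpha = 0.05, the conventional planning values):
exponential doubling from N = 8 brackets the target, integer bisection
narrows it, and a final +/-2 scan guards against local wobble, since the
critical values are re-solved at every N and are not perfectly monotone in
it. The search caps at N = 10^7 and raises if the target is unreachable
(true rho too close to a bound pins power near alpha). The target is
supplied as a power (1 - beta), not as beta.

## Monte-Carlo engine

Datasets are generated by the Cholesky map: x and e standard normal,
y = rho*x + sqrt(1-rho^2)*e, with means and standard deviations applied
affinely afterwards (r is invariant to them; defaults 0 and 1). Randomness
flows through a single `numpy.random.default_rng(seed)` Generator, and the
seed is recorded in every result, so identical (seed, config) pairs are
bit-identical. Pearson correlations are computed row-wise and vectorized;
a degenerate zero-variance draw (probability zero under the model) would
be redrawn and logged.

When several procedures are compared, all regions are evaluated on the
same draws. This paired design makes the containment ordering (TOST region
inside the matching extended-test region, hence fewer rejections) hold
replicate-by-replicate, not just in expectation, and removes between-method
Monte-Carlo noise from power contrasts. The benchmark tables were
originally produced with 10,000 replicates per cell, and the acceptance
checks use the same count (binomial SE <= 0.005); unit tests run at 2,000
replicates with tolerance bands widened by the corresponding factor.
`reproduce_table` derives an independent child seed per cell from the
master seed via `SeedSequence`, so whole tables are reproducible and cells
are independent.

What the generator does *not* emulate: non-normal tails, dependence between
pairs, missingness, or measurement error. Passing calibration checks here
therefore show that the procedures attain their nominal properties under
the bivariate-normal model they assume — not robustness beyond it.

## Numerical choices

- Quantiles z_alpha come from `scipy.stats.norm.isf`, never hard-coded.
- All computation is double precision; published-table comparisons are at
  4 decimals, with full precision kept internally and rounding applied only
  at presentation (`--round`).
- Root-finder tolerances: Brent xtol 1e-14 on endpoints; Newton polish to
  residuals < 1e-14; the hard post-hoc contract is 1e-10 on both size
  constraints.
- Uniqueness of the asymmetric (L, U) solution is not assumed: the solver
  verifies residuals and raises on failure. A brute-force coarse-to-fine
  grid search over (L, U) serves as an independent oracle in the tests.
- The solved regions are non-monotone in N at some configurations (the
  interval is narrowest near N = 100 for bounds (0, 0.2)); this is a real
  feature of the dual-constraint solution under the r-scale approximation
  and is reproduced, not smoothed.

## Benchmark grids

The standing study designs behind `reproduce_table` use alpha = 0.05,
reference ranges between 0 and 0.3 (where most observed correlations in
the applied literature fall), sample sizes 25–500, and 10,000 Monte-Carlo
replicates. The T5 sample-size grid pairs each range with interior rho
values at distances 0.05–0.3 from the nearer bound; its row with bounds
(-0.2, 0.2) uses rho = 0.15 (distance 0.05), in line with the other
distance-0.05 rows. The simulated Type I error column of the critical-value
tables is taken at rho = rho_U (equivalently rho_B); by the reflection
symmetry of the symmetric case and the near-symmetry of the general case,
the lower-bound rate is statistically indistinguishable, and the
acceptance suite checks both bounds explicitly.

## Limitations

- Everything rests on the two asymptotic approximations; exact
  small-sample inference based on the true density of r is out of scope.
- Only Pearson correlation under bivariate normality is covered — no rank
  or robust correlation measures.
- The TOST generalization to asymmetric bounds is a convenience extension,
  not a recommended procedure.
- Confidence-interval (interval-inclusion) formulations of equivalence are
  not implemented.
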