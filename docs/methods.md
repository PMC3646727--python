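# Methods

This note documents the model, the numerical choices, and what the
synthetic-data validation does and does not establish.

## Model

### Blocks, paths and the fragmentation kernel

Two present-day chromosomes that coalesce at a genomic site along a
pedigree path of `n` meioses share, around that site, an IBD block whose
length is set by the recombinations accumulated along the path.  With
homogeneous Poisson recombination (no interference, sex-averaged map,
autosomes only), a chromosome of genetic length `G` Morgans cut by `n`
meioses yields an expected

    K(n, x) = exp(-n x) (1 + n (G - x)),   0 <= x <= G,

pieces of length at least `x`; `K(n, x) = 0` beyond the chromosome.  The
`1 + ...` term carries a discrete atom at `x = G` (the uncut chromosome,
mass `e^{-nG}`); the continuous length density is
`n e^{-nx}(2 + n(G - x))` per Morgan.  Genome-wide expectations sum over
chromosomes and multiply by 4 (the four chromosome-copy pairs).

Let `mu(n)` be the coalescent-time distribution: the probability that a
random site's most recent common ancestor for the pair sits at path depth
`n` meioses (the ancestor lived `n/2` generations, `15 n` years at the
default 30-year generation time).  The expected number of shared blocks of
length `>= x` is then linear in `mu`:

    E[N(x)] = sum_n mu(n) * 4 * sum_k K(n, x / 1),

and the expected number of *genetic common ancestors* from depth `n` — the
expected blocks of any length — is `mu(n) * 4 * sum_k (1 + n G_k)`.
`r(n) = 2^{-n} sum_k (1 + n G_k)` is the expected number of blocks
transmitted along one *specific* pedigree path; `m / r(n)` converts `m`
genetic ancestors into an order-of-magnitude count of genealogical ones.
On the default map `1/r(36) ~ 5.9e7` and `r(16) ~ 0.008`, the package's
standing sanity anchors.

### Observation channel

IBD callers miss short blocks, mis-measure lengths and emit spurious
blocks.  The channel model, fit from labeled spike-in calls:

* detection power `c(x)` — logistic in `x` (cM);
* error sign `gamma(x)` — logistic; with probability `gamma` the length
  error is positive, `Exp(lambda_plus(x))`; otherwise negative,
  `Exp(lambda_minus(x))` conditioned below `x` (renormalized truncation);
* rates `lambda_±(x) = exp(a + b log x)` — power laws, per cM;
* false positives: a Poisson process with density
  `f(x) = exp(a + b x + c log x)` per pair per cM.

The families are pluggable.  The shipped `"fastibd"` configuration is
calibrated to the operating characteristics reported for multi-run fastIBD
calling on a POPRES-scale array after postprocessing — power ~70% at 1 cM,
~85% at 2 cM, >=95% by 4 cM, `c(0) < 0.5`; false positives around a tenth
of the observed rate overall, rising below 1 cM and negligible beyond
5 cM; error scales of a few tenths of a cM growing with length.  The
original study's printed coefficients are not shipped verbatim; any fitted
channel can be saved and loaded as a flat key-value config.  Fits of `f`
below 2 cM are flagged low-confidence.

### Channel fitting

With no reporting threshold the likelihood factorizes exactly into three
pieces — `(c, gamma)`, `lambda_minus`, `lambda_plus` — maximized in that
order.  Reported blocks shorter than `min_obs_length` (default 1 cM) are
removed before fitting and treated as unreported; the threshold couples
the pieces (the probability of surviving it depends on the error rates),
so the staged sequence is swept three times with threshold-aware terms, an
ECM-style scheme that restores consistency: on 5e4-call fixtures all four
curves are recovered within a few percent over 1-10 cM.  Degenerate inputs
(no reported calls, or no calls in one error branch) raise an error naming
the offending piece.  Optimizers are derivative-free simplex searches with
a BFGS polish, on unconstrained scales (logistic weights; log rates), so
the probability and positivity constraints hold by construction.

## Inversion

### Discretization

Observed lengths `>= 2 cM` (shorter blocks are dominated by false
positives and block-overlap effects the model excludes) are binned by
100-quantile edges; quantile bins wider than 1 cM are discarded and the
remaining range is covered by 1 cM chunks, giving roughly equal-variance
counts per bin.  Time is discretized into 360 intervals whose widths grow
linearly with index (triangular scheme), reaching 6,660 meioses = 99,900
years; resolution is finest at recent times.  The published analysis used
the same interval count and depth; the exact published spacing rule is not
recoverable from the available text, and both count and spacing are
configurable (the study itself found the discretization immaterial).

The kernel matrix `L[i, j]` (expected observed true blocks per pair, bin
`i`, per unit coalescent density on interval `j`) is computed with the
depth and observed-length integrals in closed form and panelled
Gauss-Legendre quadrature over true length, with panels split at bin edges
and chromosome ends and the whole-chromosome atoms added explicitly.  Two
quadrature orders are compared and refined once; residual relative
discrepancy above 1e-6 is an error naming the worst cell.  With an
identity channel the fully closed form is used, which the tests check
against the kernel differences to 1e-4.

### Penalized Poisson likelihood

Counts are Poisson, `N_i ~ Poisson(n_p (F_i + (L mu)_i))`.  The fit
minimizes the per-pair negative log-likelihood (rescaling by `n_p` makes
penalty strengths comparable across population pairs) plus
`gamma_0 z(mu)`, over `mu >= 0` with total mass `<= 1`.  The problem is
convex but ridge-shaped enough that quasi-Newton box solvers (L-BFGS-B,
projected Newton, trust-region interior point) reproducibly stall at
false stationary points several log-likelihood units above the optimum —
fatal for machinery built on 2-unit likelihood differences.  The solver
is therefore a multiplicative (Richardson-Lucy/EM-type) update with
SQUAREM acceleration: for this objective the update is a monotone
majorize-minimize step, linear penalties fold into the update denominator
exactly, the quadratic roughness penalty enters one-step-late under an
objective guard, and iteration stops when 200 steps improve the
log-likelihood by less than 0.01 units.  The mass bound is a soft
quadratic barrier with a final projection: nearly dead deep-time kernel
columns act as slack variables that can legitimately drive the mass to
its bound, where hard-constrained solvers break down.  Starting points
come from the nonnegative least-squares approximation
(`scipy.optimize.lsq_linear`, with an SLSQP fallback when the mass bound
binds).  After the unpenalized fit, three perturbed restarts probe
uniqueness; if objectives disagree by more than 1e-3 a tiny roughness
penalty (1e-8) is added, which suffices to pin a unique minimizer.

Penalty functionals `z(mu)`:

* `roughness` — squared second divided differences of `mu` at interval
  midpoints, weighted by midpoint gaps (a quadratic form; the published
  functional is a typeset display not recoverable from the text, so the
  form is configurable and recorded in fit metadata);
* `interval_total` / `exterior_total` — expected genetic ancestors inside
  / outside a meioses interval, linear in `mu`.

### Profiles and bounds

The ill-conditioning is quantified, not hidden: the *smoothest consistent*
history takes the largest `gamma_0` (bisection on `log10 gamma_0` over
[-14, 8], to 0.01 decades, at most 40 iterations, each fit warm-started
from the admissible less-penalized side — multiplicative updates shrink
coordinates easily but regrow floored ones only slowly) whose
minimizer stays within 2 natural-log-likelihood units of the optimum —
read the truth as lying between the MLE and this curve.  Interval bounds
on total ancestors in a year window (snapped to grid endpoints; the snap
is reported) penalize ancestry inside the window (lower bound) or outside
it (upper bound) at the largest admissible strength.  Lower bounds
frequently collapse toward zero when the window is narrower than the
kernel's temporal resolution — mass escapes to flanking peaks at little
likelihood cost — while upper bounds are comparatively reliable.  The
monotonicity of the likelihood drop along the `gamma_0` trace is verified
and warned about, not assumed silently.

## Synthetic data

The simulator is the sampling counterpart of the forward model: per pair,
chromosome-copy pair, chromosome and grid interval, an effective depth is
drawn uniformly in the interval (matching the continuous-depth
convention), Poisson breakpoints cut the chromosome, and each piece is
retained with the interval's coalescent mass as probability.  Only the
retained-piece count is simulated exactly per draw (Binomial over the
Poisson piece count); positions are materialized only for retained pieces,
which keeps deep, low-mass intervals cheap.  The channel layer then thins
by `c`, perturbs lengths by the signed-exponential mixture, drops blocks
below the 1 cM reporting threshold, and adds false positives uniformly
over pairs and map positions (no placement model is claimed in the source
analysis).  Blocks from different depths may overlap on a pair; they are
deliberately not deduplicated, matching the additive expectation.

Study conditions for the validation (chosen once): a three-epoch history
with per-pair ancestor totals ~0.4 (0-500 ya), ~18 (500-1,500 ya) and
~130 (1,500-2,500 ya) — magnitudes in the range reported for European
population pairs — at `n_p = 5e5` pairs-equivalent, 20 seeded replicates.
At that scale spectra are sampled at the bin level
(`N_i ~ Poisson(n_p(F + L mu)_i)`); the block-level simulator is checked
against the same forward model separately, at 1e4 pairs, so the two
validations jointly tie the sampler, the kernel and the inversion
together without resting the recovery claim on the kernel alone.
Channel fixtures use 5e4 true lengths uniform on 0.5-20 cM.

What passing does **not** show about real data: the generator assumes the
channel model is exactly right (real callers have haplotype-frequency-
dependent, population-dependent error), recombination is interference-free
and map error absent, pairs are exchangeable within a population sample,
and block overlaps/mergers across distinct ancestors are absent.  Real
spectra below ~2 cM are known not to fit this model family.

## Numerical details worth knowing

* Closed-form depth integrals switch to a 3-term Taylor series when
  `x * n < 1e-3` (relative error O((xn)^3)) to avoid catastrophic
  cancellation; integrands are clipped at zero where roundoff would leave
  ~-1e-17 residues.
* `genealogical_from_genetic` works in log space and offers a log10
  output, since `1/r(n)` overflows beyond a few thousand meioses.
* Quantile binning collapses duplicate edges; fully tied data produce a
  single legal bin.
* Postprocessing merges left-to-right and iterates to a fixpoint, making
  the result order-independent; it is idempotent on its own output.
* All stochastic entry points take explicit seeds (or Generators) and are
  bitwise reproducible; identical inputs give identical fits.

## Known limitations

* The shipped channel coefficients are calibrated to printed operating
  anchors, not transcribed fits; analyses of real call sets should refit
  the channel from their own spike-ins.
* Interval lower bounds are qualitative near the resolution limit (see
  above); bounds for different windows are profiled independently, so
  their joint coverage is not controlled.
* Only pairwise summaries are modelled; no joint inference across more
  than two populations, no sex-specific maps, no X chromosome, no
  crossover interference, and no genotype-level simulation.
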