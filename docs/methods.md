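# Methods

## The estimand

The package estimates a food-limited carrying capacity: the number of
*Speyeria adiaste* larvae that the *Viola purpurea quercetorum* leaf area
on a site could feed to pupation if every leaf were found and eaten.
This is deliberately an upper-bound construct — it ignores larval
movement, predation, induced plant defenses and competition — and is
meant to be compared against an independent adult population estimate
(here a mark-release-recapture figure, consumed as a constant with its
95% CI, never recomputed).

## Distribution fitting (`distfit`)

Five families compete per dataset: normal, log-normal, left-truncated
normal, gamma, Weibull. Conventions:

- Pure MLE throughout; the normal (and log-scale normal) variance uses
  the *n* denominator so log-likelihoods, and therefore AIC = 2k − 2ℓ̂
  (k = 2 for every family here, 1 for the exponential), are comparable.
- Closed forms are used where they exist (normal, log-normal,
  exponential). Gamma and Weibull use scipy's numerical MLE with the
  location pinned to 0.
- The truncated normal is this package's own likelihood: a normal
  (μ, σ) restricted to x ≥ 0 with normalizer Φ(μ/σ), evaluated via
  `log_ndtr` for stability and maximized with L-BFGS-B from
  method-of-moments starts (ftol 1e−8). The truncation point is fixed at
  0, not estimated, so k = 2: all four datasets are non-negative
  measurements and 0 is the only physically meaningful bound. (Truncation
  elsewhere would be a different scientific claim; it is not supported.)
- AIC ties within 1e−9 break by the caller's family order, making
  selection deterministic.
- Constant data are rejected (`FitFailureError`): no family has a finite
  MLE there, and letting a zero-variance "fit" through poisons every
  downstream draw with NaNs.
- Sampling from a fitted family uses inverse-transform draws
  (`ppf(U)`). This costs a little speed versus scipy's `rvs` but makes
  samples a monotone function of the underlying uniforms, so seeded
  comparisons across parameter settings (e.g. "larvae that eat twice as
  much") are element-wise meaningful.

## Zero-inflated density model (`zimix`)

Per-segment violet density (count/area) mixes exact zeros with a
continuous positive part. The model places weight *w* on {0} and 1 − *w*
on Exponential(λ); the MLE is closed-form: *w* = zero fraction, λ =
1/mean of the positive values. Zeros are detected by exact equality with
0.0, which is safe because densities are constructed as integer counts
over positive areas.

The likelihood-ratio test against the pure exponential (rate = 1/overall
mean, zeros contributing the *density* value λe⁰ = λ) uses
2·(ℓ_mix − ℓ_exp) clipped at 0 with 1 df. Two caveats are worth stating
plainly:

1. **The comparison is scale-dependent.** The mixture prices a zero as
   log *w* ≤ 0 (a probability), while the exponential prices it as
   log λ (a density, which exceeds 0 whenever λ > 1). On per-m²
   densities, where λ is 10–60, the exponential can out-score the
   mixture at the zeros and the clipped statistic collapses to 0; the
   same data expressed as counts per segment (positive values ≫ 1) give
   the mixture a decisive win, with statistics in the hundreds for
   realistic zero fractions. The test is therefore informative only on
   scales where typical positive values exceed ~1 unit, and the fitting
   functions themselves (which is what the simulation consumes) do not
   depend on it.
2. The null hypothesis *w* = 0 lies on the boundary of the parameter
   space, so the χ²₁ reference is conservative by the usual factor of
   about two. This is documented, not corrected.

Mixture sampling uses a single uniform per draw through the mixture's
quantile function (u < *w* → 0, else a rescaled exponential quantile),
again to keep seeded runs monotone in their uniforms.

## Capacity Monte Carlo (`capacity_sim`)

Per iteration: the density term is the mean of `n_density_draws`
(default 1,000) mixture draws — averaging is what makes iterations with
literally zero violets impossible while keeping density stochastic — and
leaves per plant, leaf area per leaf and consumption are one draw each.
Then

    leaf area present [m²] = reference_area × density × leaves × leaf_area(mm²) × 1e−6
    pupae                  = leaf area present / consumption (m²)

Unit contract: leaf areas enter in mm² and larval consumption in m²
(the reported Weibull scale 0.027 m² ≈ 270 cm², matching a mean
consumption of ~254 cm²); the conversion to m² happens once, inside the
simulation. Field consumption tables are stored in cm² and divided by
10⁴ before fitting.

One draw per iteration for the three plant/larva terms (rather than
per-plant resampling) reproduces the reported dispersion of the pupae
distribution; resampling per plant would shrink it by central-limit
averaging. Pupae values stay continuous; rounding is cosmetic and
happens only in printed output. A consumption draw ≤ 0 — possible only
for a normal consumption fit — is rejected and redrawn, with the count
recorded on the returned sample.

The expected value factorizes because the four draws are independent:
E[pupae] = A·E[D]·E[L]·E[S]·1e−6·E[1/C]. `semianalytic_mean_pupae`
computes each marginal expectation by quadrature and serves as the
independent oracle for the simulation mean in the tests (agreement
within 3 Monte-Carlo standard errors).

Determinism: a run is a pure function of (config, fits, seed); doubling
the reference area exactly doubles every iteration under a shared seed.

## Density sweep (`density_sweep`)

The simulation is re-run with density pinned at each point of a
0.010–0.100 m⁻² grid (step 0.001, 91 points), bypassing the mixture
stage. Ordinary least squares is fitted to the per-density *medians*
(the grid's central-tendency curve); that is the regression whose slope
times a density has the natural reading "median pupae at that density".
Because every other term is multiplicative, the median is nearly
proportional to density (r² > 0.99) and the interquartile range widens
linearly. Iterations per grid density default to the main run's 10,000;
the acceptance script uses 2,000 per density, at which the slope is
stable to well under the comparison tolerance (two independent
10,000-iteration sweeps agree to < 2%, tested).

## Segment capacity (`segment_capacity`)

The plants-per-pupa threshold is ceil(consumption / (mean leaves × mean
leaf area)). With male mean consumption (196.7 cm²) and average leaf
metrics (10.3 leaves × 1.99 cm²) this gives 10 plants; the pooled-sex
mean (253.9 cm²) gives 13. The threshold is therefore an explicit
argument, defaulting to the male-based 10. Counting considers full 30-m
segments only by default (their count × 60 m² is the sampled-area
denominator); extrapolation to the site uses floor(n × total/sampled).
The derived food density is density × leaves × leaf area (cm²/m²), and
area-per-larva is consumption divided by that; both are returned
unrounded (the published ground-area figures differ from the unrounded
quotients by ~1 m² because they were computed from rounded
intermediates).

## Synthetic data (`synthetic_data`)

No raw field tables exist, so the generator fabricates a season with the
survey's design and the fitted structure: 135 transects with
gamma-distributed lengths (shape 3, mean 92.16 m — the survey reports
only the mean; shape 3 gives a plausible right-skewed spread), cut into
30-m segments plus a remainder (slivers < 0.5 m dropped); a latent
per-segment density from the zero/exponential mixture; and an observed
violet count Poisson(latent density × segment area), so observed
count/area densities carry both structural and sampling zeros, as a real
survey's would. Leaves per plant are ceil of log-normal draws (integer,
≥ 1); leaf areas are gamma (mm²); consumption is Weibull with a shared
shape and sex-specific scales matched to the female/male means (290.6 /
196.7 cm²), sexes assigned 1:1 — the analysis pipeline still fits a
single pooled consumption distribution, as the field analysis did.

The default zero weight is 0.55 with the exponential rate solved from a
mixture mean of 0.037 m⁻² (the observed per-transect average); the zero
weight itself is a calibration choice recorded in the generator manifest,
not an observed quantity — the simulation is nearly insensitive to it
because the 1,000-draw mean concentrates at the mixture mean. What the
generator does **not** emulate: spatial clumping beyond zero inflation,
between-transect habitat gradients, observer error in counts, and
year-to-year variation. Tests passing on synthetic data therefore
validate the statistical machinery, not those field realities.

Because counts are Poisson given a latent density and then refit as
continuous densities, the refitted mixture parameters are only
approximately the generator's (the zero weight absorbs Poisson zeros);
recovery tests compare against discretization-aware pseudo-truths
(e.g. a 10⁶-draw ceil'd log-normal oracle for the leaf-count fit) where
that bias is material.

## Problem sizes and tolerances

The test suite runs the headline simulation at its full 10,000
iterations (shared across tests via a session fixture), sweeps at 2,000
iterations per density with one 10,000-iteration stability check,
parameter-recovery at n = 10,000 against observed-information standard
errors (3 SE), and brute-force generator checks at ~10⁵ segments. The
acceptance script uses 10,000 iterations for the headline and
doubled-density runs and 2,000 per sweep density. Quadrature oracles use
`scipy.integrate.quad` to 1e−6 or better. Optimizer tolerance is 1e−8 on
the objective; AIC ties break at 1e−9.

## Known limitations

- The capacity construct assumes complete host findability; it bounds,
  rather than predicts, the supportable population. The segment-level
  count is the package's only concession to plant spatial structure.
- The zero-inflation LRT is uninformative on small-magnitude density
  scales (see above).
- Consumption is measured on a surrogate host (*V. papilionacea*) in the
  lab; the package treats it as exchangeable with field consumption.
- The truncated-normal family fixes its bound at 0; censored or
  interval data are out of scope, as are goodness-of-fit tests beyond
  AIC and Bayesian alternatives.
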