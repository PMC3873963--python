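# Methods

## Model

The population is the realization of an inhomogeneous Poisson point
process of activity centers over a bounded rectangular state space B with
first-order intensity λ(s) = exp(x(s)′β). The number of centers in B is
Poisson with mean μ = ∫_B λ(s) ds, and given the total, centers are
i.i.d. with density λ(s)/μ (uniform when the intensity is homogeneous).
Covariates enter through x(s) = (1, v, v², …) where v is a habitat value
standardized to mean 0 and unit variance over the grid pixels; the
standardization constants are stored so predictions can be made on the
raw covariate scale.

Two observation models share this ecological layer:

- **Trapping arrays.** Each of K proximity detectors can record an
  individual at most once per occasion, over J occasions; detections are
  independent Bernoulli with half-normal probability
  p(d) = p0·exp(−d²/2σ²) of the center-to-trap distance d. The count at
  trap k is therefore Binomial(J, p(d_k)), independent across traps.
  Inputs with more than one detection per trap and occasion must be
  collapsed upstream (the reader for long-format captures does this, with
  a warning).
- **Area searches.** On each of J occasions an individual's location is
  bivariate normal N₂(s, σ²I) around its center; if the location falls
  in the searched plot S the individual is detected with probability p
  and the location recorded. For rectangular S the probability that a
  location lands in the plot factorizes into univariate normal CDF
  differences. The model assumes locations stay inside B; the fitter
  warns when the buffer between S and the edge of B is thinner than five
  estimated movement scales.

Marginalizing the latent centers makes the detected individuals a thinned
Poisson process. The log-likelihood used everywhere is the thinned form

  ℓ(θ) = −μ(1−π₀) + Σ_i log ∫_B [history_i | s] λ(s) ds − log n!,

where π₀ is the intensity-weighted probability of an all-zero history.
This is algebraically identical to summing the complete-data likelihood
over the unknown number of undetected individuals n₀; the test suite
verifies the identity against an explicit truncated summation on small
instances to 1e-8.

## Numerical integration

All integrals over B are midpoint Riemann sums on a square pixel lattice
(floor-based: ⌊side/width⌋ pixels per side, centers at
xmin + (i+½)·width). Covariates are sampled at pixel centers from the
nearest raster cell. The statistical resolution requirement is that
halving the pixel width leaves the maximized log-likelihood essentially
unchanged; `refine` rebuilds a grid at half width and
`check_grid_stability` warns above a 0.01 change. At the default
configurations (0.16 km pixels for the 2 km trap-array region, 10 m for
the 600 m lizard region, 0.03 km for the area-search study region) the
observed change is ~1e-5.

## Estimation

**Maximum likelihood.** Optimization runs on an unconstrained scale
(β free, logit p0 or p, log σ) with L-BFGS-B and numeric gradients.
Default starts: detection probability from the crude per-occasion
recapture fraction, σ from half the mean nearest-neighbor trap spacing
(traps) or the within-individual capture-location spread (area), and the
intercept from a naive count/area ratio; all overridable. The
variance-covariance matrix is the inverse observed information, computed
by central finite differences with relative step 1e-4 on the estimation
scale; a singular or indefinite Hessian yields a flagged fit without a
vcov rather than a silent failure. Wald intervals are computed on the
estimation scale and back-transformed, giving symmetric intervals for β
and multiplicatively symmetric ones for p0, p, σ and density.

**Empirical Bayes abundance.** By Bayes' rule the conditional
distribution of the undetected count n₀ given the data and θ is
Poisson(μ(θ)π₀(θ)) for any Poisson point-process observation model, so
N̂ = n + μ̂π̂₀ and v̂ = μ̂π̂₀ + G′Σ̂G, with G the central-difference
gradient of μπ₀ at θ̂ (step 1e-4, estimation scale). The 95% interval is
lognormal, moment-matched on N̂ (mean N̂, variance v̂) — this reproduces
the multiplicatively symmetric intervals expected of abundance estimates.
An alternative that moment-matches the lognormal on the undetected part
n̂₀ and adds n back is available via `interval_on="n0"`; it guarantees a
lower limit above the observed count and is slightly narrower below. The
default was chosen because the full-N parameterization matches how such
intervals are conventionally reported for SECR abundance.

Subregion abundance combines, per pixel, each detected individual's
posterior center mass (∝ exp(conditional history loglik)·λ_g·a at θ̂)
with the thinned intensity λ_g π₀_g a of undetected individuals; its
variance adds the Bernoulli membership variance of the detected part to
the Poisson floor and delta-method term. With the subregion equal to B
this reduces exactly to the global estimator. The realized-density map is
the same decomposition divided by pixel area and integrates back to N̂.

**Bayesian estimation.** The sampler targets the complete-data posterior
with n₀ retained as a parameter. Because n₀ | θ is exactly
Poisson(μπ₀), the Gibbs step for n₀ is an exact draw; θ components are
updated one at a time by Gaussian random-walk Metropolis on the natural
scale, with proposals rejected outside the prior support. Proposal scales
adapt toward ~0.3 acceptance during burn-in (default M/10) and are frozen
afterwards, preserving the stationary distribution. Priors default to
N(0, 10²) on β (an improper flat option exists), uniform(0,1) on the
detection probability, and uniform(0, σ_max) on σ with σ_max defaulting
to the state-space diagonal. Chains are bit-reproducible given a seed.
Setting the proposal scale to zero freezes θ and yields i.i.d. Poisson
draws of n₀ — used as an exactness test, alongside a prior-recovery run
with no data that must reproduce the prior quantiles.

Posterior summaries of N = n + n₀ include a Rao-Blackwellized pmf
(the Poisson conditional pmf averaged over θ draws). Monte Carlo standard
errors of chain means use overlapping batch means with default batch size
⌊√M⌋: σ̂² = Mb/((M−b)(M−b+1))·Σ_k(ȳ_k−ȳ)², MCSE = σ̂/√M. Subregion
posteriors sample each detected individual's center pixel from its
conditional per (thinned) draw and add a Poisson draw for the undetected
part.

## Synthetic data and the study drivers

`sim_habitat` generates a smooth habitat field as Gaussian white noise
smoothed with a Gaussian filter (correlation length 0.4 in region units
by default, periodic boundary) and standardized; it stands in for real
habitat maps, which have structure (anisotropy, hard edges, spatial
trends) this generator does not emulate. `sim_centers` draws
N ~ Poisson(μ), assigns pixels multinomially by λ_g a/μ and jitters
uniformly within pixels — consistent with the discretized likelihood by
construction, so parameter-recovery results quantify estimation error,
not discretization mismatch. The protocol simulators thin these centers
exactly as the observation models describe.

Study conditions (the generator defaults):

- **Trap arrays**: 2 km × 2 km region, 100 traps at 0.1 km spacing in the
  central square kilometre, J = 5, p0 = 0.25, σ = 0.4 km, log-quadratic
  intensity in standardized habitat with coefficients
  (4.412, 0.557, −1.123). Under this design detection is nearly
  exhaustive (π₀ ≈ 1e-3), so trap-array abundance intervals are tight;
  the quadratic coefficients bound the mean density near exp(β₀), and a
  `target_mu` option rescales the intercept when a specific expected
  population size is required.
- **Area searches**: homogeneous density 23.4, 46.9 or 78.1
  individuals km⁻², movement scale 0.1 or 0.2 km, a 1 km × 1 km plot
  searched J = 5 times with per-survey detection probability 0.5, buffer
  0.25 km, 50 × 50 integration pixels. The density and σ values are the
  replicated experimental grid; the plot size, J, p and buffer are this
  package's choices of a realistic design at those densities (expected
  20–90 individuals observed), recorded here because the corresponding
  design constants are not published.

The drivers fit every replicate, record relative bias and 95% interval
coverage of realized abundance N and expected density λ with Monte Carlo
standard errors (binomial SE for coverage), log failed fits rather than
dropping them silently, and are deterministic given a seed. Default
replicate counts are 300 (full) and 50 (fast mode, with 2000-draw
chains); the tests and the acceptance script use the fast sizes with
maximum-likelihood/empirical-Bayes arms so a complete run stays within a
few minutes on one CPU, and full-size runs are a single argument away.

## Limitations

- Only rectangular state spaces, plots and subregions (plus boolean pixel
  masks); no polygon geometry or projections — coordinates are planar in
  one declared unit per analysis.
- One detection per trap per occasion; no trap competition, behavioral or
  temporal detection effects, no Poisson-count observation model.
- Movement draws are independent across occasions given the center; no
  serial correlation or non-normal movement kernels.
- The empirical Bayes variance uses the delta method; a parametric
  bootstrap would be more accurate in small samples but costs as much as
  the fully Bayesian analysis, which is provided instead.
- Lognormal intervals rely on an approximately multiplicative sampling
  distribution; at very small expected undetected counts the interval
  degenerates toward a point at n, which is the honest limit.
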