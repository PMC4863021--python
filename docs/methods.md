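# Methods

`droughtscale` fits a Bayesian hierarchical beta regression in which the
temporal aggregation scale of a drought index is itself an estimated,
discrete parameter. This note records the model, the numerical choices,
and the design decisions, in enough detail to reimplement the package.

## The scientific problem

Closed-basin prairie wetlands ("potholes") fill and dry with multi-year
climate fluctuations. A standard way to couple an ecological response to
climate is a standardized drought index: SPEI (z-score of the k-month sum
of the climatic water balance, precipitation minus potential
evapotranspiration) or SPI (z-score of k-month precipitation alone). The
aggregation timescale k is usually picked by intuition or stepwise model
selection. Here k is treated as an unknown parameter with a posterior
distribution, estimated jointly with the regression, separately for a
historical (pre-1970) and a contemporary (post-2003) observation era.

## Index engine

**Potential evapotranspiration.** Hargreaves' temperature-based form,
`PET_day = 0.0023 · Ra · (Tmean + 17.8) · sqrt(Tmax − Tmin)` in mm/day,
with Ra the extraterrestrial radiation (FAO-56 daily formulas, converted
with 0.408 mm per MJ m⁻²) averaged over the actual days of the month
(leap-aware) and the result scaled by days in month. A nonpositive
`Tmean + 17.8` (deep continental winter) clamps PET to 0 with a logged
warning rather than producing negative evapotranspiration.

**Aggregation.** A "uniform correlation function" over k months is an
unweighted backward-looking k-month sum; the first k−1 months of a record
are undefined, and observations falling there are rejected, not imputed.

**SPEI standardization.** Per calendar month, a three-parameter
log-logistic distribution is fitted to the reference-period aggregated
values by unbiased probability-weighted moments (w_s = E[X(1−F)^s],
estimated with the C(n−i, s)/C(n−1, s) order-statistic weights), and each
value maps through the fitted CDF to a standard-normal quantile. The
log-logistic supports only positively L-skewed samples (its shape is
1/τ₃, which must exceed 1); long-timescale aggregates are near-Gaussian
and their sample L-skewness is negative roughly half the time, a case the
published recipe leaves undefined. Such months are standardized through
the mirrored sample (fit −x, return −z), which preserves monotonicity and
the N(0, 1) calibration. z-scores are clipped at ±6, far outside anything
a century of monthly data can produce.

**SPI standardization.** Per calendar month, a two-parameter gamma fitted
by maximum likelihood to the positive reference values, with a point mass
q = (#zeros/n) at zero: H(x) = q + (1−q)·G(x), then the normal quantile.
H(0) = q (no plotting-position correction).

**Reference period.** The full available record, per site, by default (a
configurable (start, end) year range is accepted). With a full-record
reference, every index column has per-calendar-month mean ≈ 0 and SD ≈ 1
over the series; the test suite asserts ±0.15.

**The bank.** SPEI is precomputed at every k in 1..120 and SPI at 1..3
(both grids configurable) for every site-month, so the sampler's
timescale moves are pure column lookups. Minimum record length for a
grid with largest scale K is ceil(K/12) + 20 years (20 reference values
per calendar month).

## Probability model

For wetland i, year j, the clamped proportion of basin covered with water
y_ij ∈ (0, 1):

    y_ij ~ Beta(μ_ij φ_ij, (1 − μ_ij) φ_ij)
    logit(μ_ij) = x_ij' β + γ_i + δ_ij
    log(φ_ij)   = β_φ     + ε_i + ζ_ij

with x_ij = (1, era, SPEI, SPI, SPEI·era, SPEI·SPI, SPEI·SPI·era). The
SPEI covariate is read at an era-specific timescale — t_hist for
historical rows, t_cont for contemporary rows — and SPI at a shared
t_spi; every interaction column inherits the era-specific SPEI value,
since anything else would mix timescales within one column. γ, ε are
wetland random effects and δ, ζ residual errors, all mean-zero normal
with precisions τ_γ, τ_δ, τ_ε, τ_ζ (τ = 1/σ²; the gamma-prior-on-precision
convention is the one that yields closed-form Gibbs updates).

Raw ratios ≥ 1 (digitization error) are recoded to 0.99999 and ratios
≤ 0 to 0.00001 before fitting; the clamp count is reported.

Priors: N(0, precision 10⁻⁶) on each regression coefficient,
Gamma(shape 0.001, rate 0.001) on each precision, and an independent
uniform categorical over its grid for each timescale (the flat Dirichlet
marginalized). All hyperparameters are configurable.

## Sampler

Each sweep cycles:

1. **Latent Metropolis.** Random-walk proposals on l_ij = logit(μ_ij)
   (step 0.3, logit scale) and m_ij = log(φ_ij) (step 0.3, log scale),
   vectorized over observations; the acceptance ratio combines the beta
   likelihood and the normal density about the linear predictor. The
   residuals δ, ζ are stored implicitly as latent-minus-predictor.
   Optional burn-in-only adaptation rescales the steps toward 0.44
   acceptance and freezes them afterward.
2. **Gibbs.** Exact multivariate-normal draws of β (precision
   τ_δ XᵀX + P₀), per-wetland normals for γ and ε, a normal for β_φ, and
   gamma draws for the four precisions.
3. **Timescale Metropolis.** For t_hist, t_cont, t_spi in turn, a
   symmetric integer window proposal (half-width 12 for SPEI, 1 for SPI)
   reflected at the half-integer grid edges — reflection at the edge
   itself would break proposal symmetry. Only the latent-mean normal term
   moves, so the acceptance ratio is exp(−τ_δ/2 · ΔSS).

Two kinds of auxiliary moves are interleaved because the centered
parameterization mixes slowly along two well-known ridges:

* **Global ridge moves** (each a plain Metropolis step on the same
  posterior): a coherent shift of all m_ij together with β_φ; a rescaling
  of all mean residuals l − pred by a log-normal factor (Jacobian c^N in
  the ratio); and the analogous rescaling of dispersion residuals. These
  traverse the trade-off between observation-level beta noise and
  logit-scale residual noise, which single-site walks cross extremely
  slowly.
* **Partially collapsed precision updates.** The plain (γ, τ_γ) Gibbs
  pair self-traps: once γ ≈ 0, τ_γ explodes and pins γ at 0. After the
  standard gamma draws, τ_γ is re-sampled by Metropolis from its
  conditional with γ integrated analytically (each wetland's residual
  mean is normal with variance 1/(n_i τ_δ) + 1/τ_γ), followed by an exact
  conditional redraw of γ; likewise (ε, τ_ε). The composition targets the
  same posterior.

**Initialization.** Timescales start at grid midpoints; β from OLS of
logit(y) on the midpoint design plus N(0, 0.5²) seed-specific jitter
(the overdispersed starts); random effects at zero; precisions at 1; the
latent means at the observed logit(y) (winsorized at ±12) so the first
precision update sees realistic residuals, and the latent dispersions at
a moment estimate of log φ. Starting the latents at their linear
predictors instead (residuals = 0) was tried and discarded: it leaves the
dispersion/residual ridge unconverged within any short run.

**Protocol.** Defaults mirror the full analysis: 3 chains, 10,000-sweep
burn-in, 100,000 further sweeps thinned to every 100th, pooled after
convergence checks. Convergence is the classic (non-split) Gelman–Rubin
potential scale reduction factor, computed per scalar parameter
(timescales included via their numeric values); the summary command warns
above 1.1.

## Posterior quantities

* **Summary table**: posterior mean, SD, and empirical 2.5%/97.5%
  quantiles per parameter, chains pooled.
* **Predictive R²**: for each stored draw a replicate dataset is
  simulated from the beta likelihood and the squared Pearson correlation
  with the observations is averaged over draws. *Marginal* redraws
  wetland effects from their precisions (fixed effects only);
  *conditional* keeps the stored wetland effects; residual terms are
  redrawn in both modes.
* **Weighted index**: each SPEI column weighted by the posterior relative
  frequency of its timescale in the thinned draws (the only distribution
  over t the analysis produces) and summed; defined only where every
  positively weighted column is defined.
* **Era × region comparison**: mean weighted index per cell with
  normal-approximation 95% intervals.
* **Predictions**: population-level μ = logit⁻¹(x'β) per draw with random
  effects at zero and SPI held at its mean value, summarized by pointwise
  mean and 95% quantiles; a flag instead integrates wetland and residual
  terms by sampling them from their precisions.

## Synthetic data

The generator emulates the study system from the same model the sampler
fits, with every parameter recorded for recovery scoring. Defaults are
realistic study-scale magnitudes (β = (−0.62, 0.65, 0.68, −0.02, −0.32, 0,
0), β_φ = 3.65, τ_γ = 19.7, τ_δ = 0.51, τ_ε = 0.2, τ_ζ = 0.51, t_hist =
84, t_cont = 64, t_spi = 2). Climate is per-site: monthly precipitation
from calendar-month gamma distributions with occasional winter zeros;
temperatures from a seasonal sinusoid (annual mean 4.5 °C, half-range
16 °C, diurnal range 12 °C) plus AR(1) noise, tmax > tmin enforced.
Twenty independent site series by default — the study's twenty sampling
clusters; identifiability of the timescale requires multiple independent
climate series. Observation windows default to the study design (32
historical years ending 1969; 7 contemporary years from 2003), with
basin areas log-uniform on 0.5–750 ha. Responses are exact beta draws —
no measurement floor is imposed, so the per-cell probability-integral
calibration test is exact; float-underflow 0/1 draws are recoded by the
standard clamp.

What the generator does *not* emulate: spatial correlation between
sites, land-use (consolidation-drainage) covariates, observation gaps,
digitization/censoring error beyond the 0/1 recode. Passing recovery
tests therefore demonstrate correctness of the machinery under the
model's own assumptions, not robustness to real-data misspecification.

## Study scales

The verification suite runs a reduced-scale recovery study chosen to keep
a 20-replicate experiment within minutes on one CPU: 100 wetlands × 10
years per era (2,000 observations), one shared 118-year climate record
over 20 sites, 3 chains × 5,000 sweeps (1,000 burn-in), thinned to every
10th. The convergence fixture used for the R̂ check is smaller and longer
(40 wetlands × 8 years per era with a 24-scale grid and a longer chain),
because the dispersion intercept β_φ is the slowest-mixing scalar.

## Known limitations

* The dispersion-side hierarchy (β_φ, ε, ζ and their precisions) is
  weakly identified with one observation per wetland-year: the beta
  likelihood is nearly flat in φ for a single y. Posterior draws are
  valid but slow-mixing; β_φ is the binding constraint on R̂.
* τ_γ is weakly identified at the reduced recovery scale: the
  between-wetland excess variance implied by the default generating parameters (0.051
  on the logit scale) carries a sampling SE of ~0.02 over 100 wetlands,
  and under the heavy-right-tailed Gamma(0.001, 0.001) precision prior
  the 95% interval can land above the generating value when the excess
  fluctuates low. The reproduction script reports the measured coverage
  honestly; an informative precision prior would mask, not fix, this.
* The era-specific timescale applies to SPEI only; SPI shares one
  timescale across eras (one t_spi is reported by the analysis this
  mirrors).
* The zero-inflated beta likelihood, spatial mapping, and
  Penman–Monteith/Thornthwaite PET variants are out of scope.
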