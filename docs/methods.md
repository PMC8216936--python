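# Methods

## Model

`openscr` fits an open-population spatial capture–recapture model to
line-transect survey data.  The state space S is a regular grid of G
square pixels (row-major indexing, optional validity mask; every
coordinate is planar and pre-scaled — the loaders accept a scale factor,
and 1 unit = 10 km is the conventional choice for aerial marine surveys).
The hierarchy, in generative order:

1. **Group membership.** `group_i ~ Categorical(pi_group)` with
   `pi_group_v = a_v / sum(a)`, `a_v ~ Gamma(1,1)` — equivalently a flat
   Dirichlet prior.  Group is data when observed, latent otherwise
   (including for all augmented individuals).  Arrival, persistence,
   movement scale, and baseline detection may be group-indexed; habitat
   coefficients and the detection shape parameters are shared, so the
   effect of distance on detection is common to groups.
2. **Presence.** Data augmentation adds M - n all-zero histories.
   `z[i,1] ~ Bern(gamma_1)`; for t > 1,
   `z[i,t] ~ Bern(phi_{t-1} z[i,t-1] + gamma_t (1 - z[i,t-1]))`.
   `logit gamma_t = bg1 + bg2 time_t + bg3 time_t^2` and
   `logit phi_t = bp1 + bp2 time_t`, with `time` the period indices
   1..T standardized to mean 0, sd 1.  We use the population standard
   deviation (ddof = 0); `standardize_time` exposes the choice.
   Multiple entries and exits are allowed with a shared gamma;
   single-entry variants are deliberately not implemented.
3. **Activity centers.** `log E(D[g,t]) = sum_j beta_j X[j,g,t]` with no
   intercept (the population process fixes total abundance, so density is
   relative), and `s[i,t] ~ Categorical(pi_Density[.,t])`, independent
   across primary periods.  Quadratic covariate effects are data
   construction: the loader/simulator appends squared companions of
   standardized base columns on request, and the model stays linear in
   the supplied columns.  Standardization pools over pixels *and*
   periods; squares are taken after standardizing and are not
   re-standardized.  Missing covariate pixels are filled with the mean of
   non-missing neighbors within a configurable radius (default 1.5 units,
   i.e., 15 km at the usual scaling); a missing pixel with no neighbor in
   radius is an error.
4. **Locations.** On occasion k the individual occupies pixel g with
   probability proportional to
   `exp(-d(s,g)^2 / (2 sigma_move^2) + sum_j beta_j X[j,g,t])`, then an
   exact location uniform on that pixel's square.  Distances are between
   pixel centers.  The movement state space, covariates, and coefficients
   equal the density ones by default; `decouple_movement_beta` gives
   movement its own coefficient vector.
5. **Detection.** `y[i,k,t] ~ Bern(z[i,t] p[i,k,t])`, with p a function
   of `mindist`, the distance to the closest point on the closest
   surveyed segment, evaluated with the nearest segment platform's
   family: half-normal `p0 exp(-d^2/(2 s^2))` or hazard-rate
   `p0 (1 - exp(-(d/s)^-b))`.  The hazard-rate expression is undefined at
   d = 0 and is assigned its limit p0 there.  Point-to-segment distance
   uses the clamped projection `u = clip((p-a).(b-a)/|b-a|^2, 0, 1)`,
   which equals the perpendicular-or-endpoint two-case formula and is
   well defined for vertical segments and invariant to endpoint order.
   Occasions with no surveyed segments contribute no detection
   opportunity (p = 0).  With several groups the default baseline layout
   is additive on the logit scale, `logit p0 = alpha_platform +
   alpha_group` (2 x 2 baselines from 3 free parameters); a fully crossed
   layout is available by configuration.

Derived quantities per posterior draw: `N_t`, recruitment `R_t` (with
`R_1 = N_1` reported as *initial* entries, since pre-study recruitment is
undefined), superpopulation size (individuals ever present, overall and
per group), and realized density `RD[g,t]` = present activity centers per
pixel / pixel area, whose area-weighted sum equals `N_t` exactly.

## Sampler

A Metropolis-within-Gibbs scheme, bespoke to this model family:

* `z[i,t]`: Gibbs, combining the two adjacent transition factors with the
  period-t observation likelihood; individuals detected in t are fixed at
  z = 1.
* `s[i,t]`: Gibbs over all G pixels (Gumbel-max on log weights).
* Latent locations: by default (`mode="latent"`, the BUGS-style
  formulation) a location U is instantiated for every individual-occasion
  with y = 0 and refreshed by an independence proposal from the movement
  kernel, accepted with ratio `(1 - z p(U')) / (1 - z p(U))`.  The
  alternative `mode="marginal"` integrates U out of the y = 0 likelihood,
  `P(y=0|s,z=1) = sum_g pi_move[g] (1 - pbar[g])`, where `pbar`
  approximates the within-pixel average detection probability by an
  m x m midpoint quadrature (`quad_m`, default 1 = pixel center).  The
  marginal mode is 2–3x faster; it is exact only as m grows.  With small
  detection scales relative to the pixel side, m = 1 noticeably biases
  p0 downward (we observed this directly), so m >= 3 is recommended
  whenever `sigma_det < side`; the two modes then agree within
  Monte-Carlo error (tested).
* Parameters: random-walk Metropolis in blocks (arrival/persistence per
  group; habitat coefficients jointly; movement scale per group; all
  detection parameters jointly), with uniform priors enforced by
  rejection.  Proposal scales adapt toward ~0.3 acceptance during
  burn-in only and are frozen afterwards, preserving the stationary
  distribution.  `pi_group` has a conjugate Dirichlet(1 + counts) Gibbs
  update; unknown group indices are Gibbs-sampled from their categorical
  full conditional.
* Numerical care: movement kernels are computed in log space with
  max-subtraction before exponentiation, so extreme `sigma_move` values
  (1e-2 to 1e6 are tested) cannot overflow or produce an all-zero kernel.

Default priors: coefficients U(-10, 10); `sigma_move`, `sigma_det`
U(~0, diameter of S); hazard-rate shape U(1, 50); crossed p0 U(0, 1);
additive detection offsets U(-10, 10).  All bounds are configurable —
and should be tightened when the data are sparse.  Chains default to the
common practice for this model family (3 chains of 12,000 iterations,
first 6,000 discarded); convergence is assessed with split-R̂ (each
post-burn-in chain halved; < 1.1 conventional).  Because squared
covariate columns are collinear with their bases, individual habitat
coefficients may show elevated R̂ while the composed response curves are
stable; summaries should then be read on the curves, not the raw
coefficients.

Guidance on M: start at ~1.5x the observed n and increase if the
posterior of any `N_t` or the superpopulation size approaches M.

## Correctness checks

* **Exhaustive enumeration.** On a micro study (M = 4, T = 2, G = 4,
  K = 1) the marginal-mode posterior is a finite sum over z-paths and
  s-configurations; `brute_force_posterior` computes it exactly and the
  MCMC marginals agree within Monte-Carlo error.
* **Simulation-based calibration** (successive-conditional / Geweke):
  alternating exact data simulation with a fixed number of MCMC sweeps
  must leave parameter marginals at their prior.  Run with tight uniform
  priors on a small design, the monitored arrival coefficient,
  `sigma_move`, and `p0` marginals pass Kolmogorov–Smirnov tests against
  their priors, and posterior means match prior means to three decimals.
* **Independent reference sampler.** With presence histories fully
  observed and all other blocks frozen, the arrival/persistence posterior
  matches an affine-invariant ensemble sampler (emcee) run on the same
  likelihood.
* **Parameter recovery.** Replicated simulate-and-refit studies: 95%
  credible-interval coverage of arrival, persistence, habitat, movement,
  and baseline-detection parameters is consistent with nominal (binomial
  test at alpha = 0.01), and posterior-mean abundance has mean absolute
  relative bias well under 10%.

## Synthetic data

The simulator draws every layer of the hierarchy in generative order and
retains all latent truth for testing.  Covariate surfaces are low-order
spatial polynomials plus a linear temporal trend plus i.i.d. noise,
standardized; they emulate the smoothness of fields like sea-surface
temperature or depth but none of their physics, so passing recovery tests
demonstrate correct inference *under the model*, not robustness to real
oceanographic structure, location measurement error (locations are exact
in the model and the simulator), or misread identities.

Scenario defaults (chosen once as a realistic desk-scale study):
15 x 15 grid of unit pixels, T = 5 primary periods of K = 3 occasions,
M = 150, one group, one half-normal platform, J = 2 covariates plus
squares, six parallel north-south transects whose offsets shift across
occasions.  True values: `beta_gamma = (-1.2, 0.4, -0.5)` and
`beta_phi = (1.2, 0.3)` give arrival peaking mid-study with rising
persistence; `beta = (0.5, -0.3, -0.4, -0.2)` gives a peaked density
response; `sigma_move = 1.2` (about one pixel); `p0 = 0.85`.

The detection scale is set by a survey-design identifiability rule from
distance sampling: the largest observable `mindist` under the transect
spacing should reach ~2 `sigma_det`, so the falloff of the detection
function is actually observed.  (With spacing/2 ≈ sigma the likelihood
has a ridge — large scale with low p0 mimics flat detection — which we
confirmed empirically as stuck chains with R̂ > 1.7 on `sigma_det`.)
Hence `sigma_det = 0.6` for the desk default (spacing 2.5) and 0.5 for
the recovery scenario (spacing 2.0).

The recovery suite (`parameter_recovery_study`) runs a reduced scenario
sized for a single CPU: 10 x 10 grid, T = 5, M = 80, five transects,
J = 2 plain covariates, 5 replicate datasets, 2 chains of 3,500
iterations (1,500 burn-in) each, fitted with the exact latent-location
likelihood.  These sizes are the package's own defaults for a
several-minute verification run; larger replications only tighten the
same checks.  A `paper_like_scenario` helper mirrors the shape of a
two-group, two-platform (half-normal + hazard-rate), T = 8 application
for slower exploratory runs.

## Known limitations

* No distance truncation by default; far-outlier sightings should be
  filtered in data preparation (`max_mindist` is provided as a loader
  option).
* Movement is anchored to per-period activity centers; correlated random
  walks across occasions, telemetry integration, group-size effects on
  detection, and survey-condition covariates are out of scope.
* No geodesic handling: inputs must already be in a planar CRS.
* Maximum-likelihood fitting is not provided; inference is MCMC only.
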