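# Methods

This note documents the model, the synthetic-cohort generator, the sampler,
and the standardization conventions implemented in `rdsem`, together with
the design choices that were genuinely open and the package's resolution of
them.

## Model

Three outcomes per person per occasion on the rescaled metric — DUDIT-C/5
(drug consumption), SWLS/10 (life satisfaction), SCL-90-R GSI (distress) —
are decomposed into a latent person intercept, a person-specific linear time
trend (years since baseline, uncentred), and a residual:

    y_vit = alpha_vi + beta_vi * tau_t + eps_vit.

The residual vector follows a lag-1 VAR on a 3-month lattice,
`eps_t = Phi eps_{t-1} + u_t`, `u_t ~ N(0, Sigma_u)`, with the first
occasion drawn from the stationary distribution
`Sigma_eps = solve(Sigma = Phi Sigma Phi' + Sigma_u)`.  Modelling the
autoregression on detrended residuals (rather than the outcomes) keeps
lagged effects from absorbing growth; latent centring keeps them from
absorbing person means.  `Phi` is sparse by design — the substance-use
equation receives all three lagged residuals, the other two only their own
lag — and fixed across persons: eleven observed occasions are too few to
identify person-varying autoregression.  Between persons, intercepts and
trend slopes are regressed on gender (male = 1) and standardized age;
intercept residuals have an unstructured 3×3 covariance, slope residuals are
independent of each other and of the intercepts (the calibration targets
carry intercept covariances but no slope covariances, and slope-residual
variance shares near 1 make any such covariance unidentifiable in practice).

**Time lattice.**  The nominal schedule mixes quarterly (months 0–24) and
annual (24–48) follow-up.  `expand_time_lattice` inserts phantom rows at
every 3-month multiple so that one lag means one quarter everywhere; phantom
cells and item non-response are treated identically as latent values.  The
`stayer11` preset (11 occasions, months {0, 3, …, 24, 36, 48}) is the
default; `stayer12` appends a 60-month wave.  The published occasion count
is ambiguous between these two readings, so the schedule is a configuration
parameter rather than a constant.

## Priors

Two regimes, both fully conjugate for the Gibbs sampler:

| block | reference | admissible_range |
|---|---|---|
| lagged coefficients (each free Phi entry) | N(0, 10²) | N(0, 0.5²) truncated to (−1, 1) |
| locations (intercepts, trends, regressions) | N(0, 10²) | N(0, 1) |
| Sigma_u, Sigma_alpha | IW(p+2, 0.01 I) | IW(p+4, 0.1 I) |
| slope variances | IG(0.5, 0.002) | IG(2, 0.05) |

The reference regime is near-flat and used to test convergence; the
admissible-range regime concentrates mass on the stationary/plausible region
and produces slightly more conservative estimates, shifted toward zero
(`prior_sensitivity` quantifies the shift).  The original analysis's exact
prior settings are not public; these are the package's own choices, with
inverse-Wishart/inverse-gamma scale priors preferred over half-normal scales
to retain conjugacy — at these sample sizes (~2,600 transitions, 164
persons) the scale prior contributes well under 1% of the posterior
precision, so the substitution is immaterial.  In both regimes the model
itself restricts `Phi` to the stationary region, since the stationary
initial density is undefined otherwise.

## Sampler

`fit_mcmc` runs a blocked Gibbs sampler with data augmentation:

1. **Missing/phantom cells** — per time slice, the full conditional of
   `eps_t` given its neighbours is Gaussian with one of three precisions
   (first / interior / last occasion); missing components are drawn
   conditioned on the observed components of the same slice by Schur
   complement.  Slices are updated in a red/black (even/odd) order — under
   the lag-1 Markov structure all even slices are conditionally independent
   given the odd ones — which lets every cell with the same missingness
   pattern be drawn in one vectorized batch.
2. **Person effects** — `(alpha_i, beta_i)` jointly per person.
   Quasi-differencing the within model (a stationary term for the first
   occasion, innovation terms for transitions) makes the likelihood linear
   in the effects with a 6×6 posterior precision common to all persons, so
   the draw is batched across the cohort.
3. **Lagged coefficients** — the free entries of `Phi` jointly.  The
   conditional from the transition terms is conjugate normal and serves as
   an independence proposal; a Metropolis step corrects for the stationary
   initial density (ratio of the first-occasion densities under old/new
   `Sigma_eps`), and non-stationary proposals are rejected.  Under the
   admissible-range regime, proposals outside (−1, 1) are redrawn
   (truncation by rejection).  Acceptance rates run around 0.9.
4. **Innovation covariance** — inverse-Wishart from the transition
   residuals, with the same Metropolis correction for the initial density
   (acceptance ≈ 0.7).
5. **Between level** — multivariate-normal regression coefficients,
   inverse-Wishart intercept covariance, conjugate slope regressions and
   inverse-gamma slope variances.

**Scan design.**  Blocks 1–4 are scanned `inner_scans` times (default 8) per
stored iteration.  With roughly 36–53% of outcome cells latent, the
augmented residual paths and the dynamic parameters are strongly coupled and
single scans leave the lagged-coefficient chains with effective sample sizes
of a few hundred per 10,000 stored draws; repeated scans restore ESS well
above the package's reporting threshold at modest cost (the default
recovery-size fit takes about five minutes on one CPU).  All post-warmup
draws are stored — there is no post-hoc thinning — and ESS/Rhat are computed
on the stored draws with `arviz` (multi-chain bulk ESS; rank-normalized
split-chain Rhat).

Warmup defaults to half the iterations.  Chains are initialized from
person-level OLS fits on mean-imputed data with seed-controlled
overdispersion.  Convergence is flagged, never silently assumed: a fit whose
split-chain Rhat exceeds 1.05 for any parameter carries
`converged = False` and logs a warning.  The package's working thresholds
are Rhat < 1.05 and ESS > 400 per reported parameter.

**Exactness.**  The sampler targets exactly the posterior implied by
`complete_data_log_density` × prior: the initial-condition terms that break
conjugacy in blocks 3–4 are handled by Metropolis correction rather than
dropped.  The density itself is unit-tested against a brute-force joint
multivariate normal (stacking all occasions with
`Cov(eps_t, eps_s) = Phi^(t−s) Sigma_eps`) to 1e−8, and the imputation
kernel against exact Schur conditioning of that joint covariance.

## Standardization (STDYX) and R²

Within-level coefficients are standardized per cluster and averaged over
clusters.  The within-cluster total variance of outcome v in cluster i is

    W_vi = beta_vi^2 * Var(tau) + Sigma_eps[v, v],

the trend contribution plus the stationary residual variance, with
`Var(tau)` taken over the lattice occasions.  Conventions:

- trend effect: `beta_vi * SD(tau) / sqrt(W_vi)`, averaged over clusters;
- lagged path v←w: `Phi[v,w] * SD(eps_w) / sqrt(W_vi)`, averaged;
- standardized innovation variance: `Sigma_u[v,v] / W_vi`, averaged — so
  the within-level R² = 1 − standardized innovation variance holds *per
  draw, exactly*, and is enforced as a test invariant;
- within and between covariances: residual (innovation) correlations;
- between-level regressions and intercepts: standardized by the
  model-implied total between SD (explained-by-covariates plus residual).

A pooled-variance alternative (standardize by the cluster-averaged `W_v`)
is available via `cluster_average=False`.  Equal-tailed 95% credible
intervals; a parameter is flagged credible exactly when its interval
excludes zero; formatted tables round to 3 decimals.

The reported estimates this package is validated against contain one
internal inconsistency: the printed within-level R² values for life
satisfaction (0.298) and distress (0.262) are the complements of each
*other's* standardized residual variances (1 − 0.738 = 0.262,
1 − 0.702 = 0.298).  The package enforces the identity, which implies the
two printed rows are swapped; the residual-variance rows are taken as
authoritative.

## Calibration of the generator

`calibrate_to_stdyx` inverts the standardization map: given the published
standardized table it solves for unstandardized `(Phi, Sigma_u,` trend
means/variances, between covariances, regressions`)` such that the implied
STDYX values reproduce every target (achieved to ~1e−12; anything worse
than 5e−3 raises).  Because a standardized table fixes no scales, two
constants per outcome are design choices: the total outcome variance on the
rescaled metric (DUDIT 0.25, SWLS 0.3844, GSI 0.49 — from reported baseline
SDs where available) and its between-person share (0.29 / 0.45 / 0.49, the
reported intraclass correlations).  The fixed point iterates: standardized
lagged paths and innovation-variance shares → `(Phi, Sigma_u)` → stationary
variances via the Lyapunov equation → the trend variance share
`W − Sigma_eps[v,v]` → the slope mean/SD split that reproduces the
cluster-averaged standardized trend (a bracketed 1-D root solve per outcome,
with cluster averages computed by 64-node Gauss–Hermite quadrature over the
slope distribution).  Deterministic throughout.

Two target rows are deliberately not matched.  The standardized *between*
trend intercepts are overdetermined once the within-level trend effects and
the variance decomposition are fixed; the within-level rows (which carry the
scientific claims) win.  And the generated data's sample ICC1 exceeds the
design between-share constants, because trend dispersion adds
between-person variance over the follow-up window — the ICC constants are a
variance-partition convention at the residual level, not a prediction of
the sample ICC.

## Synthetic cohort: what it emulates, what it does not

The generator reproduces: the N=164 / 11-occasion design; truncated-normal
baseline age whose *post-truncation* mean and SD are 27.1 / 7.1 (the
underlying location/scale are solved for, since the reported moments
describe already-truncated ages ≥ 16); 62.2% male; the empirical
cluster-size law (75% attend all 11 occasions, minimum 5); per-outcome item
non-response at rates derived from the reported marginal missing fractions
(substance use 0.322, distress 0.507, life satisfaction 0.091 within
attended occasions); and a missing-at-random dependence in which the odds of
a missing life-satisfaction score double per SD of the *observed*
substance-use score — so the observed substance-use distribution genuinely
differs by life-satisfaction missingness, as the QC screen detects.  An
attended occasion always retains at least one observed outcome, keeping the
attendance law exact.  A near-constant binary drug-free-friends covariate is
included solely so the low-variance screen has something to drop.

It does **not** emulate: ordinal/discrete instrument scores (outcomes are
continuous Gaussians on the rescaled metric; clipping to instrument ranges
exists but is off by default because it biases recovery); informative
(MNAR) dropout; the full joint missingness-pattern table (only the marginal
rates, the cluster-size law, and the one dependence are calibrated — the
reported pattern counts overlap ambiguously and cannot all be honoured);
or item-level scale construction.  Passing tests therefore show that the
estimation machinery recovers the truth *under the model's own assumptions
with realistic incompleteness*; they do not show robustness to ordinal
measurement, non-Gaussian tails, or informative dropout.

## What recovery does and does not show

The recovery harness regenerates a 164-person cohort and compares
standardized posterior means to the calibration targets within ±2 reported
posterior SDs.  Two sources of dispersion enter: posterior uncertainty
(comparable to the reported SDs, since the design matches) and cohort-level
sampling variability from re-drawing 164 persons (comparable in size; for
the substance-use trend the realized mean of 164 heterogeneous slopes alone
contributes ~0.04 on the standardized scale).  The total scatter is thus
roughly 1.4× the reported posterior SD, so an individual anchor is expected
to land outside its ±2-SD band in roughly one of six cohorts, typically
marginally; the 20-replicate null-dynamics suite verifies credible-interval
coverage directly at its nominal level.  A
single-cohort miss on one anchor is expected behaviour of a correctly
calibrated pipeline, not evidence of bias; the test suite pins the cohort
seed to the package default and reports each anchor separately so such a
miss is visible rather than averaged away.

## Numerical choices and degenerate inputs

- Lyapunov equation solved in vec form (9×9 linear solve); non-stationary
  `Phi` (spectral radius ≥ 1 − 1e−10) is refused everywhere.
- Covariance draws and Schur complements are symmetrized before Cholesky.
- ICC(1) uses the unbalanced-design correction
  `n0 = (N − Σn_i²/N)/(k−1)` and is clipped at zero; zero within-person
  variance returns exactly 1.
- `distribution_by_missingness` raises on an empty stratum rather than
  returning a vacuous p-value.
- Rescaling is exactly invertible; double rescaling and dichotomizing
  rescaled scores are state errors.
- Degenerate slope variances in calibration are floored at 1e−12 (the
  all-zero-targets case); an attended-occasion spare rule prevents item
  missingness from erasing whole occasions.
- Problem sizes in the validation suite: the recovery experiment uses the
  full N=164 with 2×5000 iterations; the null-coverage suite scales down to
  N=80 with 2×2000 iterations and 20 replicates; the structural checks use
  10,000 simulated persons.

## Known limitations

- Fixed (not random) lagged effects; no measurement-error submodel; no
  model-comparison criteria (DIC/WAIC) — all out of scope by design.
- The sampler is exact but single-threaded; very large cohorts (≫10³
  persons) would benefit from a compiled imputation kernel.
- The admissible-range regime enforces per-coefficient truncation plus
  stationarity rejection, not a reparameterized stationarity prior; at the
  observed acceptance rates this is harmless, but a process near the unit
  root would mix poorly.
- Between-level standardization uses the sample covariate moments of the
  fitted cohort; with 164 persons the gender/age SDs carry sampling noise
  that propagates into the standardized between rows.
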