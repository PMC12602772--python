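# Methods

## The model

Each analysis unit is a site-year ("stacked" design): a recorder (ARU) or a
400-ha hexagon, in one survey season. Latent occupancy z_i ~ Bernoulli(ψ_i)
with

    logit ψ_i = x_i' β + μ1[year_t] + μ2[site_i],
    μ1 ~ Normal(0, σ_year²),  μ2 ~ Normal(0, σ_site²),

where the random effects absorb the dependence created by stacking the same
physical site across seasons. Weekly detections within a season are
conditionally independent given z (closure assumed within season):

    y_it | z_i ~ Bernoulli(z_i · p_it),  logit p_it = w_it' α.

The latent state is marginalized analytically, so the sampler never imputes
z: a site with at least one detection contributes
log ψ + Σ_t [y log p + (1−y) log(1−p)]; an all-zero site contributes
log(ψ Π_t (1−p_it) + 1 − ψ); unsurveyed weeks contribute nothing (a fully
missing row has likelihood 1).

Six fixed-effect structures express the BACI design (see
`occupancy.MODEL_COLUMNS`): fire and removal effects, each time-constant or
time-dependent, plus two interaction models for removals followed by fire.
Fire severity enters as the fraction of the home-range buffer burned at high
severity (a 0–1 proportion, per-year-offset in the time-dependent model);
removal terms are indicators; the interaction terms are indicators even
where the marginal fire terms carry fractions — the asymmetry is
deliberate and matches the design the models encode. Occupancy covariates
enter raw (indicators and proportions are already interpretable);
continuous detection covariates (ordinal date, ruggedness, weekly hours)
are standardized, and survey year enters detection as a categorical fixed
effect independent of the occupancy year random effect.

## Priors and sampling

Priors are weakly informative: Normal(0, 2.5²) on all coefficients,
half-Normal(0, 1) on random-effect SDs (a common default for occupancy
models on this scale; the protocol itself does not pin priors down). A
`flat` option (improper uniform on coefficients) exists for conjugate
cross-checks in the tests.

The sampler is an adaptive random-walk Metropolis-within-Gibbs:
single-coordinate updates for β and α (with the detection linear predictor
cached and updated incrementally), vectorized element-wise updates for the
year and site effects (each group touches a disjoint row set, so per-group
accept/reject is exact), a log-scale random-walk update for each σ, and a
joint rescale move (u, σ) → (cu, cσ) whose acceptance ratio reduces to the
data-likelihood ratio times the σ prior ratio on the log scale — this move
is what lets σ_site mix when individual site effects move slowly. Proposal
scales adapt toward 44% acceptance during burn-in only (first half of the
chain, discarded), with a t^(-1/2) decay; after burn-in the kernels are
fixed. The default protocol is 4 chains × 2600 iterations. Convergence is
judged by the Gelman–Rubin potential scale reduction factor (flag > 1.1).

Parameter-recovery behaviour at the package's reference problem size
(~500 site-years, fire model with β = (−1, 0.5, −3), σ = 0.3): posterior
means land within 3 posterior SDs of truth and the 85% intervals for the
severity coefficient cover it at ≈0.85–0.90 across replicates (the
acceptance suite measures both).

## Goodness of fit

The MacKenzie–Bailey check is posterior predictive: for each sampled draw,
compute the Pearson chi-square of observed vs expected encounter-history
frequencies and compare with the same statistic on a replicate dataset
simulated from that draw; the p-value is P(T_rep ≥ T_obs). Rows are
cohorted by missingness pattern. Within a cohort the expected count of
every *observed* history is computed exactly; unobserved histories need no
enumeration because Σ_unobserved (O−E)²/E = N − Σ_observed E. Observed
histories with expected count < 2 are pooled together with that unobserved
remainder into a single cell per cohort (chi-square validity); the pooling
threshold is exposed for testing. Under the generating model the p-value
averages near 0.5; strong unmodeled detection heterogeneity (per-site p
split 0.05/0.95) drives it below 0.05.

## Detector calibration

Validation hours (hours with at least one prediction scoring ≥ 0.1) are
labelled 1 if they contain a confirmed true positive. For each threshold in
the ladder 0.1, 0.2, …, 0.9, 0.91, …, 0.99, a logistic regression of
false-positive status (FP = 1) on the count of predictions above the
threshold yields an hourly FP probability, evaluated at count = 1 — the
minimal flagged hour (a config option evaluates at the mean observed
count). The weekly rate is 1 − (1 − FP)^84 (12 nocturnal hours × 7 nights)
and the smallest threshold with weekly rate < 1% is selected, maximizing
retained detections subject to the bound.

Two numerical cases need care. With a constant predictor the two-parameter
MLE is singular, so the fit collapses to intercept-only (slope ≡ 0, FP =
the observed FP fraction). Under (quasi-)complete separation — the typical
situation at high thresholds, where no labelled FP hour has any prediction
left — the MLE diverges; the fallback is an L2-penalized logistic solved by
Newton iteration with a deliberately small penalty (1e-4·‖β‖²/2), flagged
in the output. The penalty must be small: the selected threshold's
estimate is an extrapolation, and a strong ridge caps the slope so hard
that no threshold ever qualifies. Evaluating at count = 1 conditions on a
flagged hour, which upper-bounds the marginal flagged-FP-hour probability,
so the procedure errs conservative: re-simulated weekly FP rates at the
selected threshold land well under the 1% target.

## Synthetic data

The generator emulates the study design, not any particular landscape:

- **Landscape** — elevation is a smoothed Gaussian random field (default
  relief SD 250 m, smoothing 400 m) on a planar grid (default 20-m cells;
  the ruggedness definition is resolution-configurable). The seral layer is
  a second smoothed field thresholded at a target areal fraction. Fire
  footprints are circles; severe cells inside a footprint are the upper
  quantile of a clumped random field, so the realized high-severity
  fraction matches the request exactly at cell resolution (the two default
  fires use 0.49 and 0.56).
- **Survey** — 400-ha hexagon centers on a lattice; sampled cells are
  rejected if they share an edge with an already-selected cell; two ARUs
  per hexagon placed 300–480 m from the center on opposite bearings
  (separation 600–960 m ≥ 500 m, inside the ~1075-m inradius). Default
  scale: 60 hexagons × 4 seasons (2018, 2021–2023). Deployments follow a
  per-season plan: "pulsed" (3 × 1 week, 14-day gaps; the first season) or
  "continuous" (one 35-day interval, start staggered across units over the
  first 7 weeks so all 11 periods receive effort).
- **Disturbances** — removal locations (default 12, year 2019) are sampled
  preferentially in high-seral, low-ruggedness hexagons (softmax on
  3·seral − ruggedness_z), mirroring the invader's niche; a uniform switch
  exists. Removal overlap uses the 2004-ha invader buffer.
- **Truth** — occupancy coefficients per model (defaults chosen to give
  plausible rates, e.g. removal model (−1.2, −1.1, 0.8) ⇒ ψ ≈ 0.09 pre- and
  0.18 post-removal at removal sites), σ_year = σ_site = 0.3, and the
  five-predictor detection model (date −1.3, ruggedness 0.28, hours 0.57,
  invader 0.34 on standardized scales). Invader occurrence uses intercept
  −3.4, elevation −0.28, ruggedness −0.61, seral 4.21 (proportion scale),
  weekly detection 0.7, and a −4 logit drop after removal. An optional
  extra within-season detection-noise SD exists and defaults to 0 (the five
  predictors are the stated heterogeneity sources).
- **Score streams** — true calls arrive Poisson (default 0.08/h) with
  Beta(5, 1.5) scores; false predictions arrive Poisson (5/h) with
  Beta(1, 5) scores, giving an analytic hourly FP probability
  1 − exp(−λ(1−τ)⁵) used as the independent truth in tests.

What the generator does **not** emulate: spatial autocorrelation in
occupancy beyond the random effects, animal movement or territoriality,
audio-level phenomena (the score distributions are stylized), and
observer/weather effects on detection. Passing tests therefore demonstrate
that the estimators are correct for the stated data-generating process, not
that field data meet its assumptions.

## Geometry and overlap indices

Home-range buffers are circles of the species' area (r = √(area/π));
raster cells count by center inclusion; tangent circles count as
non-overlapping (strict inequality; a measure-zero case). The posterior
overlapping index uses Gaussian KDEs (Silverman bandwidth) on a shared
512-point grid spanning both samples ± 3 bandwidths, each density
renormalized on the grid; on 5000-draw samples it reproduces the analytic
normal-shift overlap 2Φ(−1) within ±0.02. Standard ellipses are parametric
Gaussian quantile ellipses (center = mean, shape = sample covariance ×
χ²₂(level)); overlap is computed by clipping 512-gon boundary
approximations (shapely), accurate to <0.1% against the circular-lens
closed form. Niche breadth/overlap is reported per covariate pair (three
pairs over standardized elevation, standardized ruggedness, seral
fraction) without aggregation across pairs.

## Encounter-history conventions

Weekly bins are half-open 7-day intervals anchored at May 7 00:00; "ending
July 23" is read as the exclusive end (11 × 7 = 77 days — an inclusive
reading gives 78 days, incompatible with 11 whole weeks). Only events
between 20:00 and 08:00 count as surveys. Hexagon-level histories union the
two units' detections and sum their hours (0–336; a max rule is available —
the choice is a convention, with hours entering detection as a standardized
covariate either way). Great horned owls are analyzed at hexagon level
(larger home range, louder calls); the small species at ARU level.

## Problem sizes and runtime

Desk-scale defaults keep every stage minutes-fast on one CPU: the
acceptance suite fits the reference recovery problem (504 site-years) with
4 × 1300 iterations, runs the 50-replicate coverage study at 2 × 600, the
20-run GOF calibration at 120 sites × 6 weeks, and the calibration bound on
3000 validation hours with 2000 re-simulated weeks. The full-protocol
settings (4 × 2600, 60 hexagons, six models) remain the config defaults.

## Known limitations

- The hourly FP logistic extrapolates beyond the validated sample at high
  thresholds; the reported hourly FP there reflects the penalized fit, not
  a directly observed frequency (hence the conservative design).
- The stacked design estimates regional patterns; it does not model
  colonization/extinction dynamics, and site random effects only partially
  correct the pseudo-replication of stacking.
- Random-effect marginalization in prediction draws fresh effects from the
  posterior SDs (option: set to zero); neither reproduces a specific site.
- Interaction models are estimable only when the synthetic disturbance
  layout actually produces removal-then-fire sites; small grids may yield
  constant interaction columns, which the sampler rejects explicitly.
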