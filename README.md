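# owlbaci

Before-After-Control-Impact (BACI) occupancy analysis of forest owls facing
two simultaneous stressors — severe wildfire and an invading apex-predator
owl that is experimentally removed — built for passive acoustic monitoring
data. The package covers the full analysis chain:

1. **Detector-score calibration** — pick a per-species classifier score
   threshold whose expected false-positive rate per weekly survey period,
   `1 − (1 − FP)ⁿ` with `n = 84` nocturnal hours, stays under 1%. The hourly
   FP probability comes from a logistic model of validated hours
   (FP status ~ number of predictions above the threshold).
2. **Encounter histories** — detection events and deployment records become
   site × week 0/1/missing matrices over 11 one-week secondary periods
   (May 7 – July 23), with recording hours as a detection covariate, at
   recorder (ARU) or hexagon level.
3. **Covariates** — circular home-range buffers (50/300/700/2004 ha),
   high-severity burn fraction, removal-overlap indicators, time-since-fire
   and time-since-removal codings, terrain ruggedness (mean 8-neighbor
   |Δelevation| within 390 m), elevation, and seral-forest fraction.
4. **Occupancy inference** — six Bayesian stacked single-season occupancy
   models with imperfect detection,

   logit ψᵢ = β₀ + β'xᵢ + μ₁[yearₜ] + μ₂[siteᵢ],   logit pᵢₜ = α'wᵢₜ,

   where x encodes the fire / removal / interaction BACI structure
   (time-constant or time-dependent) and w holds five detection predictors
   (ordinal date, year, ruggedness, weekly survey hours, invader presence).
   The marginal likelihood over the latent occupancy state is written
   explicitly and sampled with an adaptive Metropolis-within-Gibbs MCMC;
   convergence via Gelman–Rubin R̂, fit via a MacKenzie–Bailey posterior
   predictive check, summaries as 85% credible intervals.
5. **Contrasts & niche** — the overlapping index (∫ min of two posterior
   densities, KDE-based) compares pre- vs post-removal occupancy on the
   logit scale (<15% overlap = a meaningful difference); habitat niche
   segregation uses a logistic occurrence model with average marginal
   effects plus 85% standard ellipses, their areas (niche breadth) and
   pairwise intersections (niche overlap).

Because real recorder locations are sensitive, the `synthetic` module
generates every input — landscape rasters, a hexagonal survey grid with two
recorders per 400-ha cell (≥500 m apart), deployments, fire footprints with
a controlled high-severity fraction, removal locations, latent occupancy
with known parameters, and hourly classifier score streams — so the whole
pipeline runs on a desktop with no downloads and full ground truth.

## Worked example

`examples/` holds one short script per capability. Threshold calibration
(`python examples/01_calibrate_detector.py`):

```
 threshold  fp_hourly  fp_weekly  separation_flag
      0.91   0.000030   0.002536             True
      0.99   0.000937   0.075720             True

selected threshold: 0.9
re-simulated weekly FP rate at that threshold: 0.50%
```

The calibration picks 0.9 — the smallest threshold whose expected weekly
false-positive rate is under the 1% target — and an independent
re-simulation of 5,000 84-hour weeks confirms the realized rate (0.50%)
respects the bound.

Fitting the removal model and contrasting posteriors
(`python examples/03_fit_occupancy.py`):

```
              param      mean       sd   ci85_lo   ci85_hi
  beta[(intercept)] -1.600398 0.370260 -2.131984 -1.133817
    beta[site_type] -1.335449 0.837689 -2.587154 -0.160279
beta[allpostlethal]  0.426692 0.887835 -0.883324  1.712638
MacKenzie-Bailey GOF p-value: 0.41
pre vs allpostlethal: overlap 68.6% (not meaningful)
occupancy at removal sites: pre 0.07 (0.01, 0.15) -> post 0.08 (0.04, 0.14)
```

`site_type` is the removal-site indicator (occupancy deficit where the
invader was present), `allpostlethal` the post-removal recovery term; the
posterior-overlap contrast asks whether the pre- and post-removal occupancy
distributions are distinct enough (<15% overlap) to call the change real —
at this small example scale they are not.

The end-to-end pipeline (`owlbaci run --config config.yaml` or
`examples/05_full_pipeline.py`) chains simulate → calibrate → build → fit →
contrast → niche, writing plain CSV/JSON artifacts per stage.

## Layout

- `src/owlbaci/` — `synthetic` (generator), `calibration`, `encounters`,
  `covariates`, `occupancy` (likelihood + MCMC + diagnostics), `contrast`
  (overlap, occurrence model, ellipses), `pipeline` + `cli`.
- `docs/methods.md` — model details, assumptions, numerical choices.
- `examples/` — runnable narrative scripts.
- `tests/` — unit, property, and end-to-end acceptance tests.
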