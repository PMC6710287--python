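# Methods

## The scientific setting

Scandinavian brown bears are hunted in fall (season opening 21 August);
hunters mostly work from the road network with baying dogs during legal
hours, one hour before sunrise to two hours before sunset. If individual
bears differ consistently in movement rate, diel activity timing, or road
avoidance, and those differences change the odds of dying in the hunt,
hunting is a selective pressure on behavior. The package implements the
analysis chain for that question: derive the three behavioral traits from
telemetry, model each trait against two survival proxies, and quantify how
repeatable the traits are across individuals.

## Trait derivation rules

* **Screening.** GPS fixes with dilution of precision strictly greater than
  10 are discarded (a fix at exactly 10 is kept). Every fix must carry a DOP;
  a missing value is a data error, not a silent pass.
* **Window.** All traits use 1 August–30 September, local civil dates
  (Europe/Stockholm, DST honored). `julian_date` 0 is 21 August, the season
  opening; the window spans −20…+40.
* **Movement rate.** The Euclidean displacement between two consecutive fixes
  of the same bear whose time gap is 60 ± 5 min, stamped at the interval
  start. Gaps outside the tolerance (e.g., after a screened fix) produce no
  rate. Rates are floored at 1 m/h before the log so resting bouts stay in
  the data with bounded influence (`log 1 = 0`); the floor is configurable.
  The movement model uses interval starts 02:00–11:00 (the 02:00–12:00
  window), the diel span containing the morning mortality-risk peak.
* **Activity index.** Each 5-minute accelerometer window belongs to the
  period (hunting/non-hunting hours) containing its midpoint. A day with no
  coverage of one period, or with all-zero activity (undefined ratio), is
  dropped and counted. Hunting hours come from the NOAA solar-position
  equations evaluated at the study centroid (61°N 15°E) — per-fix coordinates
  would move the boundary by under two minutes at study scale. The index is
  bounded in [−1, 1] by construction; D_h + D_nh = 24 h exactly.
* **Distance to road.** Per-fix minimum Euclidean distance to the road
  polylines, averaged per bear per local date, log-transformed (1 m floor).
  Road density is the clipped road length (km) inside the bear-year's 100%
  minimum convex polygon divided by polygon area (km²). The MCP was chosen
  over kernel estimators because it is deterministic and parameter-free; a
  bear-year with fewer than three non-collinear fixes is excluded from the
  distance analysis.
* Only bear-years in which the bear was legally harvestable (not in a family
  group) enter any trait table.

## The models

All candidates are Gaussian mixed models with random intercepts for bear-year
nested in bear identity and an AR1 correlation between time-ordered residuals
within a bear-year (hourly for movement, daily otherwise; gaps count as unit
steps — a continuous-time AR1 was rejected for simplicity). Smooth terms are
cubic B-spline bases (dimension 8; 6 for by-fate and age smooths) with a
second-order difference penalty, centered for identifiability and fit in
their mixed-model representation: the penalty's range space becomes an
i.i.d. random-coefficient block with one smoothing variance per term
(by-factor levels share that variance), the null space (linear trend) stays
fixed. Distance to road uses purely linear fixed effects.

Two longevity variables are never in one model: hunting-season fate (factor:
died/survived this season) and remaining lifespan (death year − data year,
defined only for hunting-killed bears). Because remaining lifespan restricts
the dataset to hunting-killed bears while fate does not, and AICc is not
comparable across datasets, the pipeline runs two ladders per trait and sex —
intercept / controls / +fate on all harvestable bear-years, and intercept /
controls / +remaining-lifespan on hunting-killed bears — each ranked
internally.

**Estimation.** Maximum likelihood, profiled over the fixed effects and the
residual variance, optimized over log variance ratios and atanh(φ) with
L-BFGS-B (numerical gradients, parameter bounds e^±12 and |φ| ≤ 0.9993, 200
iterations, Nelder-Mead polish if the line search stalls). ML rather than
REML so that likelihoods — and hence AICc — are comparable across candidates
with different fixed effects; with ~80 grouping levels the ML downward bias
in variance components is negligible for the ratios reported. All algebra is
O(q³) per likelihood evaluation (q = random-effect columns) via the Woodbury
identity and the fact that the AR1 precision is quadratic in φ, so fits are
effectively independent of n after one pass over the data.

**Reported quantities.**

* Linear coefficients with Wald 95% CIs from the joint posterior covariance
  of the penalized system.
* Smooth effective degrees of freedom: the trace of the corresponding block
  of the penalized hat matrix; smooth p-values are Wald-type chi-square tests
  of the smooth's coefficients on round(edf) degrees of freedom — an
  approximation adequate for screening, not exact frequentist inference.
* AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = fixed linear coefficients +
  summed smooth edf + variance/correlation parameters (two intercept
  variances, φ, σ²). Ranking is ascending AICc; candidates within ΔAICc < 2
  of the best resolve to the fewest effective parameters ("most
  parsimonious"). Non-converged candidates are excluded with a warning.
* Marginal R² = Var(fixed-effect predictions, smooths included) / (that
  variance + S²_bear + S²_bear-year + S²_residual).
* Adjusted repeatability R = S²_bear / (S²_bear + S²_bear-year +
  S²_residual). Its p-value defaults to a likelihood-ratio test of the
  bear-level intercept against the model without it, referred to the
  boundary-corrected null (equal mixture of a point mass at zero and χ²₁);
  how the original study computed its repeatability p-values is not stated,
  so a permutation alternative (shuffling bear identities across bear-years,
  refitting) is provided as an option.
* Prediction curves are fixed-effect predictions along a covariate grid,
  other covariates held at training means (reference level for fate), with
  pointwise 95% CIs, back-transformed to m/h for log responses.

## The synthetic study

The generator reproduces the data *structure* the analysis assumes, not
Scandinavian landscape ecology:

* **Roads** are a deterministic rectangular grid (default spacing 2.5 km)
  over a 20 km arena.
* **Movement**: hourly log step lengths are Gaussian around
  `base + log diel(hour) + log season(julian) + b_bear + b_bear-year` with
  stationary AR1 residuals (φ = 0.3, SD 1.0); the diel profile is
  crepuscular with morning and evening peaks, the seasonal trend a gentle
  hyperphagia bump. Defaults put median rates at 10²–10³ m/h, the observed
  order of magnitude; no movement-process parameters were reported for the
  bears, so these are order-of-magnitude choices, fixed once. Headings are a
  biased random walk around a bear-year center. The wander radius (600 m)
  is deliberately smaller than the typical center-to-road distance so that
  distance to road is a *persistent* individual trait, as the harvest model
  requires — with a wander radius much larger than the center distance the
  daily means collapse toward a common value and the generator no longer
  produces the among-individual road-avoidance differences it promises.
* **Distance trait**: each bear-year's center sits at distance
  `exp(6.0 + b_dist)` m (≈ 400 m) from its nearest road, mid-cell in the
  other axis, capped below 0.38 × spacing so that road remains the nearest.
* **Activity**: 5-minute values follow the same diel × season profile times
  `exp(gain · s(t) · B_day)` with multiplicative log-normal noise, where
  s(t) = ±1 inside/outside hunting hours and `B_day = b_act + b_act,year +
  ε_day`. The daily index is then `tanh(gain · B_day + c_date)`; with the
  default gain 0.25 the transform is nearly linear, so the latent variance
  ratios — hence the generating repeatability — carry over to the index.
  Activity is deliberately driven by the *expected* hourly intensity rather
  than the realized step length: realized coupling would leak movement's AR1
  noise into the index and make its variance components uncontrolled; the
  positive activity–step-length correlation the collars show survives through
  the shared diel profile.
* **Latents**: each trait's bear intercepts have SD 0.377, bear-year
  deviations SD 0.2, residual SD 1.0 — implied repeatability 0.120, the
  regime of the movement trait in the field; `with_repeatability(r)` rescales
  the among-bear SD for other regimes.
* **Harvest** is a season-level logistic hazard: per harvestable bear-year,
  logit p = logit(0.25) − 1.0·z(mean distance to road) − 0.5·z(mean activity
  index), z-scored across that year's candidates — bears living near roads
  and (for males) inactive during hunting hours die sooner, the directions
  inferred in the field; the activity term applies to males only because
  selection on activity and movement was reported for males only. The
  distance slope is calibrated so the recovered remaining-lifespan effect on
  log distance (≈ 0.01–0.06 per year across replicates) brackets the
  published point estimates (0.037 and 0.053). The default span of five
  seasons is itself a scale-down of the 14-season field study chosen as the
  shortest span that still yields enough harvested bears and lifespan spread
  for the selection signal to be identifiable. Years run chronologically; a
  harvested bear contributes no later data (its death-year season is kept
  whole — within-season truncation is ignored). All generator deaths are
  hunting deaths. With female protection on, each female-year is
  non-harvestable (family group) with probability 0.5, emulating the
  2–3-year legal cycle. 3% of fixes get DOP > 10 (the reported 2–4%
  screening loss).
* **Determinism**: one master seed; every bear-year and stage draws from a
  child stream keyed by fixed offsets, so identical configs give
  byte-identical outputs.

What passing recovery tests does **not** show: robustness to fix loss beyond
DOP screening, collar failure, irregular sampling, habitat-driven movement,
within-season harvest truncation, or non-Gaussian trait distributions — real
data carry all of these.

## Simulation sizes used in the checks

Variance-component and repeatability recovery runs the full generator at the
study's cohort size over three seasons (40 bears per sex): 12 replicates for
the movement regime (truth R ≈ 0.12) and 8 for the high-repeatability (0.30)
activity regime; the Monte-Carlo error of the replicate mean (~0.01) is well
inside the ±0.05 recovery band. Selection-direction recovery runs 20
replicates at the full default conditions (five seasons). Slope recovery
(100 replicates) and AR1 recovery (n = 5000) use direct simulation from the
distance-model structure; AICc selection consistency uses 20 direct
simulations from the fate-interaction movement model at 14 bears × 2 years ×
30 days. `scripts/acceptance.py` runs one full default study plus 8
sign-recovery and 10 selection-consistency replicates.

## Trait-table column dictionary

All three tables carry `bear_id`, `bear_year` (`<bear>_<year>`), `year`,
`sex`, `age`, `harvestable`, `fate` (`died`/`survived` this season),
`death_year`, `death_cause` (`hunting`/`other`/`unknown`/empty),
`remaining_lifespan`, `julian_date` (0 = 21 Aug), `date`. In addition:

* `movement.csv`: `timestamp` (interval start, ISO-8601), `hour` (local
  interval-start hour), `log_rate` (log m/h).
* `activity.csv`: `activity_index` ∈ [−1, 1], `sa_h`, `sa_nh` (summed
  activity in/out of hunting hours), `d_h`, `d_nh` (hours).
* `distance.csv`: `mean_dist` (m), `log_dist` (log m), `road_density`
  (km/km²).

`harvestsel reproduce` accepts these tables directly, or raw
`relocations.csv` (bear_id, timestamp, x, y, dop), `activity_raw.csv`
(bear_id, timestamp, value), `roads.geojson` (LineStrings, same projected
CRS, meters), `bear_years.csv` (the metadata columns above).

## Known limitations

* The smooth p-values and the CI coverage of penalized terms are
  approximations; coverage for variance-parameter-heavy designs at few
  individuals runs slightly anticonservative (~93% at 20 bears for a nominal
  95%, restored at 40).
* AR1 treats gaps as unit steps; with hourly data and a 14-hour overnight
  gap the overnight correlation is overstated when φ is large.
* The exact candidate ladders of the original analysis are not public; the
  hierarchical sets here (intercept / controls / longevity variable) are a
  reconstruction, and age enters as a smooth in the smooth-capable models
  but linearly in the distance model.
* `reproduce_paper` compares counts exactly and coefficients at a relative
  tolerance (default 10% + 0.01) because penalized-fit implementations
  differ.
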