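# harvestsel

Hunters do not harvest animals at random. In a heavily hunted brown bear
(*Ursus arctos*) population, individual differences in behavior — how much a
bear moves, when it is active, how close to roads it lives — change the odds
of meeting a hunter, so hunting can act as a selective pressure on behavior
itself. `harvestsel` is a tested, reusable implementation of the analysis
behind that question, for movement ecologists and quantitative wildlife
biologists:

1. **Trait extraction.** From hourly GPS relocations (screened at dilution
   of precision ≤ 10, windowed to 1 Aug–30 Sep per "bear-year") it derives
   three behavioral traits: hourly movement rate (log m/h, 02:00–12:00),
   a daily hunting-hour activity index from 5-minute accelerometer data,

   $$\mathrm{index} = \frac{SA_h/D_h - SA_{nh}/D_{nh}}{SA_h/D_h + SA_{nh}/D_{nh}} \in [-1, 1],$$

   where $SA_h$, $SA_{nh}$ are summed activity inside/outside legal hunting
   hours (one hour before sunrise to two hours before sunset, from a NOAA
   solar ephemeris) and $D_h$, $D_{nh}$ the period durations; and the daily
   mean distance to the nearest road (log m), with road density inside the
   bear-year's 100% minimum convex polygon as covariate.

2. **Models.** Each trait is related to two survival proxies — hunting-season
   fate (harvested or not) and remaining lifespan (years until the bear was
   harvested; defined only for hunting-killed bears) — with Gaussian additive
   mixed models (penalized cubic P-splines; linear for distance), always with
   bear-year nested in bear identity as random intercepts and an AR1 residual
   correlation within bear-year. Hierarchical candidate sets are ranked by
   AICc; marginal $R^2$ and prediction curves with 95% CIs come with each fit.
   The fitting engine is written here (maximum likelihood, Woodbury-profiled;
   validated against R's `nlme` in the test suite).

3. **Repeatability.** From the best model's variance components the adjusted
   among-individual repeatability

   $$R = \frac{S^2_{\mathrm{bear}}}{S^2_{\mathrm{bear}} + S^2_{\mathrm{bear\text{-}year}} + S^2_{\mathrm{residual}}}$$

   with a boundary-corrected likelihood-ratio test (permutation alternative
   available).

4. **Synthetic study.** A generator that emulates the field design — ~40
   collared bears per sex, hourly fixes, 5-minute activity, a road grid, and
   season-level harvest whose log-odds depend on standardized behavior — with
   full ground truth, so every estimator above can be checked by
   parameter-recovery simulation.

## Worked example

```python
from harvestsel import SyntheticConfig, generate_dataset, run_analysis

report = run_analysis(generate_dataset(SyntheticConfig(seed=1)))
print(report.summary_frame()[
    ["sex", "trait", "n_obs", "best_fate_model", "repeatability", "marginal_r2"]
].to_string(index=False))
```

```
   sex    trait  n_obs          best_fate_model  repeatability  marginal_r2
  male movement  60398   male_movement_controls       0.135252     0.307660
  male activity   6405       male_activity_fate       0.083099     0.090289
  male distance   6405       male_distance_null       0.468148     0.000000
female movement  47058 female_movement_controls       0.131585     0.297288
female activity   5002 female_activity_controls       0.122765     0.070754
female distance   5002 female_distance_controls       0.472084     0.012559
```

Each row is one sex × trait analysis: `n_obs` counts modeled observations
(hourly rates for movement, daily values otherwise), `best_fate_model` is the
AICc-selected candidate on all harvestable bear-years, `repeatability` is the
adjusted $R$ from its variance components (the generating value for movement
and activity here is 0.120; distance is more repeatable because home-range
placement persists across years), and `marginal_r2` the share of variance
explained by fixed effects. The same frame carries the remaining-lifespan
effects from the hunting-killed-bears ladder: with this seed the distance
coefficients are +0.012 (males) and +0.033 (females) log-m per year of
remaining life — bears that lived farther from roads survived more hunting
seasons, the direction the generator's harvest hazard imposes.

The same pipeline runs from the shell:

```bash
harvestsel simulate --out sim/ --seed 1        # telemetry + roads + truth
harvestsel traits --fixes sim/relocations.csv --activity sim/activity_raw.csv \
    --roads sim/roads.geojson --meta sim/bear_years.csv --out traits/
harvestsel run --traits traits/ --out report/
harvestsel show-config                         # every generator default
```

`harvestsel reproduce --dataset DIR --out report/` accepts a real dataset
(either raw telemetry or pre-derived trait tables; see `docs/methods.md` for
the column dictionary) and emits a side-by-side comparison with the published
reference estimates from the original field study.

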