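"""Synthetic telemetry with the statistical structure the analysis assumes.

The generator emulates the study design: ~30-40 GPS-collared bears per sex
followed over several 1 Aug - 30 Sep windows, hourly fixes, 5-minute
accelerometer summaries, a road network, and season-level harvest fates that
depend on behavior. It is built so that the quantities the analysis
estimates have known generating values:

* log movement rate is exactly Gaussian around a diel x seasonal profile
  with bear and bear-year random intercepts and AR1 residuals, so the fitted
  variance components and repeatability have configured truths;
* the daily activity index is ``tanh(gain * B)`` of a latent day-activity
  trait ``B`` with the same two-level structure; with a small gain the
  transform is essentially linear and the latent variance ratios (hence
  repeatability) carry over to the index;
* each bear-year's home-range center sits at a controlled distance from the
  nearest road, giving a persistent distance-to-road trait;
* harvest is a season-level logistic hazard on the standardized bear-year
  mean distance to road and mean activity index, so negative selection
  slopes make road-hugging, hunting-hour-inactive bears die sooner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .errors import ConfigurationError, DataError
from .traits import BearYear, RoadNetwork, daily_activity, distance_to_road, STUDY_TZ


def default_diel_profile(hour):
    """Crepuscular relative movement intensity: early-morning and evening
    activity peaks, low movement at midday and night."""
    h = np.asarray(hour, dtype=float)
    return 0.15 + np.exp(-((h - 5.0) / 2.5) ** 2) + np.exp(-((h - 20.0) / 2.5) ** 2)


def default_season_trend(julian_date):
    """Gentle hyperphagia bump peaking just before the hunting season."""
    jd = np.asarray(julian_date, dtype=float)
    return 1.0 + 0.2 * np.exp(-((jd + 5.0) / 20.0) ** 2)


@dataclass(frozen=True)
class SyntheticConfig:
    n_bears_per_sex: int = 40
    years: tuple[int, ...] = (2012, 2013, 2014, 2015, 2016)
    fixes_per_hour: int = 1
    activity_interval: int = 5          # minutes
    home_range_radius: float = 600.0    # m
    road_spacing: float = 2500.0        # m, grid spacing
    arena_size: float = 20000.0         # m
    diel_profile: Callable = default_diel_profile
    season_trend: Callable = default_season_trend
    base_log_rate: float = 5.0          # log m/h at unit profile
    mean_log_dist: float = 6.0          # log m: typical center-to-road distance
    sd_bear: float = 0.377              # among-bear SD of latent intercepts
    sd_bearyear: float = 0.2            # within-bear among-year SD
    sd_resid: float = 1.0               # residual SD (stationary AR1 SD)
    ar1_phi: float = 0.3
    activity_gain: float = 0.25         # latent -> index compression
    selection_dist: float = -1.0        # log-hazard slope on z(mean distance)
    selection_act: float = -0.5         # log-hazard slope on z(mean activity index)
    selection_act_males_only: bool = True  # activity selection reported in males only
    base_harvest_prob: float = 0.25     # per-season harvest probability
    female_protection: bool = True
    female_protect_frac: float = 0.5    # fraction of female-years in family groups
    dop_noise_frac: float = 0.03        # fraction of fixes with DOP > 10
    seed: int = 1

    def __post_init__(self):
        if self.road_spacing <= 0:
            raise ConfigurationError("road_spacing must be positive")
        if not self.years:
            raise ConfigurationError("years must be non-empty")
        if self.n_bears_per_sex < 1:
            raise ConfigurationError("need at least one bear per sex")
        if min(self.sd_bear, self.sd_bearyear, self.sd_resid) < 0:
            raise ConfigurationError("SDs must be non-negative")
        if not (0.0 < self.base_harvest_prob < 1.0):
            raise ConfigurationError("base_harvest_prob must lie in (0, 1)")
        if not (-1.0 < self.ar1_phi < 1.0):
            raise ConfigurationError("ar1_phi must lie in (-1, 1)")

    def with_repeatability(self, r: float) -> "SyntheticConfig":
        """Same config with sd_bear rescaled so the implied repeatability of
        the latent traits equals ``r`` (other components held fixed)."""
        if not (0.0 <= r < 1.0):
            raise ConfigurationError("repeatability must lie in [0, 1)")
        rest = self.sd_bearyear**2 + self.sd_resid**2
        return replace(self, sd_bear=math.sqrt(r / (1.0 - r) * rest))


_TRAITS = ("move", "act", "dist")


@dataclass
class SyntheticTruth:
    """Generating values needed by recovery tests."""

    bears: pd.DataFrame        # bear_id, sex, age_start, b_move, b_act, b_dist
    bear_years: pd.DataFrame   # bear_id, year, d_move, d_act, d_dist
    sd_bear: float
    sd_bearyear: float
    sd_resid: float
    ar1_phi: float
    selection_dist: float
    selection_act: float
    harvest_year: dict = field(default_factory=dict)  # bear_id -> year

    def implied_repeatability(self) -> float:
        tot = self.sd_bear**2 + self.sd_bearyear**2 + self.sd_resid**2
        return self.sd_bear**2 / tot if tot > 0 else 0.0


@dataclass
class Population:
    bear_years: list[BearYear]
    truth: SyntheticTruth


def generate_roads(config: SyntheticConfig) -> RoadNetwork:
    """Deterministic rectangular road grid over the arena, lines offset half
    a spacing from the edges."""
    a, s = config.arena_size, config.road_spacing
    offsets = np.arange(s / 2.0, a, s)
    lines = [LineString([(o, 0.0), (o, a)]) for o in offsets]
    lines += [LineString([(0.0, o), (a, o)]) for o in offsets]
    return RoadNetwork(lines)


def generate_population(config: SyntheticConfig) -> Population:
    rng = np.random.default_rng([config.seed, 0])
    rows, yrows, bys = [], [], []
    years = list(config.years)
    for sex, tag in (("male", "M"), ("female", "F")):
        for i in range(config.n_bears_per_sex):
            bear_id = f"{tag}{i:03d}"
            age_start = int(rng.integers(4, 16))
            lat = {t: rng.normal(0.0, config.sd_bear) for t in _TRAITS}
            rows.append(dict(bear_id=bear_id, sex=sex, age_start=age_start,
                             **{f"b_{t}": lat[t] for t in _TRAITS}))
            for j, year in enumerate(years):
                dev = {t: rng.normal(0.0, config.sd_bearyear) for t in _TRAITS}
                yrows.append(dict(bear_id=bear_id, year=year,
                                  **{f"d_{t}": dev[t] for t in _TRAITS}))
                bys.append(BearYear(bear_id=bear_id, year=year, sex=sex,
                                    age=age_start + j))
    truth = SyntheticTruth(
        bears=pd.DataFrame(rows), bear_years=pd.DataFrame(yrows),
        sd_bear=config.sd_bear, sd_bearyear=config.sd_bearyear,
        sd_resid=config.sd_resid, ar1_phi=config.ar1_phi,
        selection_dist=config.selection_dist, selection_act=config.selection_act,
    )
    return Population(bear_years=bys, truth=truth)


def _season_times(year: int, freq_minutes: int) -> pd.DatetimeIndex:
    start = pd.Timestamp(year=year, month=8, day=1, tz=STUDY_TZ)
    end = pd.Timestamp(year=year, month=10, day=1, tz=STUDY_TZ)
    return pd.date_range(start, end, freq=f"{freq_minutes}min", inclusive="left")


def _julian(ts: pd.DatetimeIndex) -> np.ndarray:
    season = pd.Timestamp(year=ts[0].year, month=8, day=21, tz=str(ts.tz))
    return (ts.normalize() - season.normalize()).days.to_numpy(float)


def simulate_tracks(
    population: Population, roads: RoadNetwork, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly GPS fixes and 5-minute activity values for every bear-year.

    Step lengths are log-normal around the diel x seasonal profile plus the
    bear/bear-year latents, with AR1 log-scale residuals; headings are a
    biased random walk around the bear-year's center. Activity follows the
    same profile modulated by the latent day-activity trait.
    """
    if not population.bear_years:
        raise DataError("empty population")
    bears = population.truth.bears.set_index("bear_id")
    devs = population.truth.bear_years.set_index(["bear_id", "year"])
    cfg = config
    s = cfg.road_spacing
    offsets = np.arange(s / 2.0, cfg.arena_size, s)
    cap = max(20.0, 0.38 * s)

    reloc_parts, act_parts = [], []
    for k, by in enumerate(population.bear_years):
        rng = np.random.default_rng([cfg.seed, 1, k])
        b = bears.loc[by.bear_id]
        d = devs.loc[(by.bear_id, by.year)]

        # center at distance exp(latent) from its nearest road, mid-cell in
        # the other axis so that road is genuinely the nearest one
        target = float(np.clip(np.exp(cfg.mean_log_dist + b.b_dist + d.d_dist), 20.0, cap))
        vertical = rng.random() < 0.5
        line_off = float(rng.choice(offsets))
        ncells = max(1, len(offsets) - 1)
        other = float(
            offsets[0] + (rng.integers(0, ncells) + 0.5) * s
            if len(offsets) > 1 else cfg.arena_size / 2.0
        )
        other += float(rng.uniform(-0.05, 0.05)) * s
        side = 1.0 if rng.random() < 0.5 else -1.0
        cx, cy = (line_off + side * target, other) if vertical else (other, line_off + side * target)

        ts = _season_times(by.year, 60)
        nh = len(ts)
        hours = ts.hour.to_numpy(float)
        jd = _julian(ts)
        with np.errstate(divide="ignore"):
            mu = (
                cfg.base_log_rate
                + np.log(np.asarray(cfg.diel_profile(hours), dtype=float))
                + np.log(np.asarray(cfg.season_trend(jd), dtype=float))
                + float(b.b_move) + float(d.d_move)
            )
        eta = np.empty(nh)
        eta[0] = rng.normal(0.0, cfg.sd_resid)
        innov = rng.normal(0.0, cfg.sd_resid * math.sqrt(1.0 - cfg.ar1_phi**2), nh)
        for t in range(1, nh):
            eta[t] = cfg.ar1_phi * eta[t - 1] + innov[t]
        step = np.exp(mu + eta)
        step[~np.isfinite(step)] = 0.0

        headings = rng.uniform(0.0, 2.0 * math.pi, nh)
        xs = np.empty(nh + 1)
        ys = np.empty(nh + 1)
        xs[0], ys[0] = cx, cy
        r_home = cfg.home_range_radius
        x, y = cx, cy
        for t in range(nh):
            dxc, dyc = cx - x, cy - y
            dist = math.hypot(dxc, dyc)
            w = min(1.0, dist / r_home) if r_home > 0 else 1.0
            ux = w * (dxc / dist if dist > 0 else 0.0) + (1.0 - w) * math.cos(headings[t])
            uy = w * (dyc / dist if dist > 0 else 0.0) + (1.0 - w) * math.sin(headings[t])
            norm = math.hypot(ux, uy)
            if norm == 0.0:
                ux, uy, norm = math.cos(headings[t]), math.sin(headings[t]), 1.0
            ell = step[t]
            x += ell * ux / norm
            y += ell * uy / norm
            xs[t + 1], ys[t + 1] = x, y

        fix_ts, fix_x, fix_y = ts, xs[:-1], ys[:-1]
        if cfg.fixes_per_hour > 1:
            frac = np.arange(cfg.fixes_per_hour) / cfg.fixes_per_hour
            fix_ts = (ts[:, None] + pd.to_timedelta(frac * 60.0, unit="min")).ravel()
            fix_x = (xs[:-1, None] + (xs[1:] - xs[:-1])[:, None] * frac).ravel()
            fix_y = (ys[:-1, None] + (ys[1:] - ys[:-1])[:, None] * frac).ravel()
        nfix = len(fix_x)
        dop = rng.uniform(1.0, 6.0, nfix)
        noisy = rng.random(nfix) < cfg.dop_noise_frac
        dop[noisy] = rng.uniform(10.5, 15.0, int(noisy.sum()))
        reloc_parts.append(pd.DataFrame(dict(
            bear_id=by.bear_id, timestamp=pd.DatetimeIndex(fix_ts), x=fix_x, y=fix_y, dop=dop,
        )))

        # activity: shared diel/season profile, hunting-hour modulation by the
        # latent day-activity trait, multiplicative positive noise
        ats = _season_times(by.year, cfg.activity_interval)
        na = len(ats)
        ajd = _julian(ats)
        adates = ats.normalize()
        day_code = pd.factorize(adates)[0]
        nday = day_code.max() + 1
        b_day = float(b.b_act) + float(d.d_act) + rng.normal(0.0, cfg.sd_resid, nday)
        sgn = _hunting_sign(ats)
        base = np.asarray(cfg.diel_profile(ats.hour.to_numpy(float)), dtype=float)
        base = base * np.asarray(cfg.season_trend(ajd), dtype=float)
        value = (
            40.0 * base
            * np.exp(cfg.activity_gain * sgn * b_day[day_code])
            * np.exp(rng.normal(0.0, 0.3, na))
        )
        act_parts.append(pd.DataFrame(dict(
            bear_id=by.bear_id, timestamp=pd.DatetimeIndex(ats), value=value,
        )))

    relocations = pd.concat(reloc_parts, ignore_index=True)
    activity = pd.concat(act_parts, ignore_index=True)
    return relocations, activity


_SIGN_CACHE: dict = {}


def _hunting_sign(ts: pd.DatetimeIndex) -> np.ndarray:
    """+1 for 5-min windows whose midpoint falls inside legal hunting hours,
    -1 outside, computed from the real solar rule per date. Cached per
    (year, length): the grid is identical for every bear of a season."""
    from .traits import STUDY_LAT, STUDY_LON, _hunting_interval

    key = (ts[0].year, len(ts))
    if key in _SIGN_CACHE:
        return _SIGN_CACHE[key]
    mid = ts + pd.Timedelta(minutes=2.5)
    dates = ts.normalize()
    sgn = np.full(len(ts), -1.0)
    starts = dates.searchsorted(dates.unique(), side="left")
    bounds = np.append(starts, len(ts))
    for i, day in enumerate(dates.unique()):
        start, end, _, _ = _hunting_interval(day.date(), STUDY_LAT, STUDY_LON, STUDY_TZ)
        sl = slice(bounds[i], bounds[i + 1])
        sgn[sl] = np.where((mid[sl] >= start) & (mid[sl] < end), 1.0, -1.0)
    _SIGN_CACHE[key] = sgn
    return sgn


def bear_year_trait_summaries(
    relocations: pd.DataFrame, activity: pd.DataFrame, roads: RoadNetwork
) -> pd.DataFrame:
    """Per bear-year mean daily distance to road and mean daily activity
    index — the behavioral summaries the harvest hazard acts on."""
    _, daily = distance_to_road(relocations, roads)
    daily["year"] = pd.to_datetime(daily["date"]).dt.year
    dist = daily.groupby(["bear_id", "year"])["mean_dist"].mean().rename("mean_dist")
    idx, _ = daily_activity(activity)
    idx["year"] = pd.to_datetime(idx["date"]).dt.year
    act = idx.groupby(["bear_id", "year"])["index"].mean().rename("mean_activity")
    return pd.concat([dist, act], axis=1).reset_index()


def _invlogit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def assign_fates(
    population: Population,
    trait_summaries: pd.DataFrame,
    config: SyntheticConfig,
) -> list[BearYear]:
    """Season-level logistic harvest hazard on standardized trait summaries.

    Years are processed chronologically; a harvested bear contributes no
    later bear-years. With ``female_protection`` a configurable fraction of
    female-years is non-harvestable (family groups). Harvested bears get a
    death year; fate and remaining lifespan follow.
    """
    rng = np.random.default_rng([config.seed, 2])
    key = trait_summaries.set_index(["bear_id", "year"])
    years = sorted(config.years)
    by_map = {(b.bear_id, b.year): b for b in population.bear_years}
    dead: dict[str, int] = {}
    alpha = math.log(config.base_harvest_prob / (1.0 - config.base_harvest_prob))

    protected: dict[tuple[str, int], bool] = {}
    for by in population.bear_years:
        protected[(by.bear_id, by.year)] = bool(
            config.female_protection
            and by.sex == "female"
            and rng.random() < config.female_protect_frac
        )

    for year in years:
        candidates = [
            by for by in population.bear_years
            if by.year == year and by.bear_id not in dead
            and not protected[(by.bear_id, by.year)]
        ]
        if not candidates:
            continue
        try:
            zd = np.array([key.loc[(b.bear_id, b.year), "mean_dist"] for b in candidates])
            za = np.array([key.loc[(b.bear_id, b.year), "mean_activity"] for b in candidates])
        except KeyError as exc:
            raise DataError(f"missing trait summary for bear-year {exc}") from exc
        zd = (zd - zd.mean()) / zd.std() if zd.std() > 0 else np.zeros(len(zd))
        za = (za - za.mean()) / za.std() if za.std() > 0 else np.zeros(len(za))
        for b, z1, z2 in zip(candidates, zd, za):
            s_act = config.selection_act
            if config.selection_act_males_only and b.sex != "male":
                s_act = 0.0
            p = _invlogit(alpha + config.selection_dist * z1 + s_act * z2)
            if rng.random() < p:
                dead[b.bear_id] = year

    out: list[BearYear] = []
    for (bear_id, year), by in by_map.items():
        death_year = dead.get(bear_id)
        if death_year is not None and year > death_year:
            continue  # no data after death
        harvestable = not protected[(bear_id, year)]
        fate = "died" if death_year == year else "survived"
        remaining = None
        cause = None
        if death_year is not None:
            cause = "hunting"
            remaining = float(death_year - year)
        out.append(BearYear(
            bear_id=bear_id, year=year, sex=by.sex, age=by.age,
            harvestable=harvestable, fate=fate, death_year=death_year,
            death_cause=cause, remaining_lifespan=remaining,
        ))
    population.truth.harvest_year = dict(dead)
    return out


def simulate_fate_interaction_movement(
    seed: int,
    n_bears: int = 14,
    n_years: int = 2,
    n_days: int = 30,
    p_died: float = 0.4,
    sd_bear: float = 0.3,
    sd_bearyear: float = 0.2,
    sd_resid: float = 0.8,
    ar1_phi: float = 0.3,
) -> pd.DataFrame:
    """Movement-trait data simulated directly from the fate-interaction
    model: harvested and surviving bear-years follow different diel curves
    (harvested bears peak early and fast, survivors later and flatter), on
    top of the usual nested intercepts and AR1 residuals.

    Used by model-selection consistency checks: AICc should prefer the
    by-fate candidate on data generated from it.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_bears):
        ub = rng.normal(0.0, sd_bear)
        age = float(rng.integers(4, 15))
        for t in range(n_years):
            fate = "died" if rng.random() < p_died else "survived"
            ut = rng.normal(0.0, sd_bearyear)
            e = rng.normal(0.0, sd_resid)
            for d in range(n_days):
                jd = d - n_days / 2.0
                for h in range(2, 12):
                    e = ar1_phi * e + rng.normal(
                        0.0, sd_resid * math.sqrt(1.0 - ar1_phi**2))
                    if fate == "died":
                        mu = 5.3 - 0.10 * (h - 4.0) ** 2 + 0.01 * jd
                    else:
                        mu = 4.4 - 0.03 * (h - 8.0) ** 2 - 0.01 * jd
                    rows.append(dict(
                        bear_id=f"B{b}", bear_year=f"B{b}_{t}",
                        date=d, hour=float(h), julian_date=jd, age=age + t,
                        fate=fate, log_rate=mu + ub + ut + e,
                    ))
    df = pd.DataFrame(rows)
    if df[df["fate"] == "died"]["bear_year"].nunique() < 2:
        df.loc[df["bear_year"] == "B0_0", "fate"] = "died"
    return df


@dataclass
class SyntheticDataset:
    relocations: pd.DataFrame
    activity: pd.DataFrame
    roads: RoadNetwork
    bear_years: list[BearYear]
    truth: SyntheticTruth
    config: SyntheticConfig


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full generator: roads, population, tracks, behavior-dependent fates.

    Bear-years after a bear's death are removed from the telemetry so the
    dataset has the same structure as the field data.
    """
    roads = generate_roads(config)
    population = generate_population(config)
    relocations, activity = simulate_tracks(population, roads, config)
    summaries = bear_year_trait_summaries(relocations, activity, roads)
    bear_years = assign_fates(population, summaries, config)

    alive = {(b.bear_id, b.year) for b in bear_years}
    for df in (relocations, activity):
        yr = df["timestamp"].dt.year
        df["__keep"] = [(b, y) in alive for b, y in zip(df["bear_id"], yr)]
    relocations = relocations.loc[relocations.pop("__keep")].reset_index(drop=True)
    activity = activity.loc[activity.pop("__keep")].reset_index(drop=True)

    return SyntheticDataset(
        relocations=relocations, activity=activity, roads=roads,
        bear_years=bear_years, truth=population.truth, config=config,
    )
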