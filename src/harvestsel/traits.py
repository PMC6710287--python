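"""Behavioral traits from raw telemetry.

Three traits are derived per bear-year (one bear's 1 Aug - 30 Sep window in
one year, restricted to years in which the bear could legally be harvested):

* **movement rate** — Euclidean displacement over consecutive hourly GPS
  fixes (m/h), log-transformed, restricted to 02:00-12:00 local time for
  modeling (the daily period of highest hunting mortality risk);
* **hunting-hour activity index** — a daily duty-cycle-corrected contrast of
  summed accelerometer activity inside vs outside legal hunting hours,
  bounded in [-1, 1];
* **distance to road** — daily mean Euclidean distance from fixes to the
  nearest road (log meters), with road density inside the bear-year's
  minimum-convex-polygon home range as a covariate.

GPS fixes with dilution of precision (DOP) > 10 are discarded first.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiLineString, MultiPoint

from .errors import ConfigurationError, DataError
from .solar import hunting_hours

STUDY_LAT = 61.0
STUDY_LON = 15.0
STUDY_TZ = "Europe/Stockholm"
SEASON_START = (8, 21)   # 21 August: julian_date 0
WINDOW_START = (8, 1)
WINDOW_END = (9, 30)
MOVEMENT_HOURS = (2, 12)  # interval-start hours kept for the movement model
DOP_MAX = 10.0
STEP_TOL_MIN = 5.0        # a 60 +/- 5 min gap counts as a 1-h interval
ZERO_RATE_FLOOR = 1.0     # m/h floor before log (keeps resting bouts)


@dataclass
class RoadNetwork:
    """Road polylines in the same projected coordinate system as the fixes."""

    lines: list[LineString]

    def __post_init__(self):
        if any(line.length <= 0 for line in self.lines):
            raise ConfigurationError("road network contains zero-length segments")

    @property
    def geometry(self) -> MultiLineString:
        return MultiLineString(self.lines)

    def total_length(self) -> float:
        return sum(line.length for line in self.lines)


@dataclass
class BearYear:
    """Per-animal-year metadata row."""

    bear_id: str
    year: int
    sex: str
    age: float
    harvestable: bool = True
    fate: str = "survived"          # "died" (harvested this season) | "survived"
    death_year: int | None = None
    death_cause: str | None = None  # "hunting" | "other" | "unknown" | None
    remaining_lifespan: float | None = None

    def __post_init__(self):
        if self.remaining_lifespan is not None:
            if self.death_cause != "hunting":
                raise DataError("remaining_lifespan defined only for hunting deaths")
            if self.remaining_lifespan < 0:
                raise DataError("remaining_lifespan must be >= 0")
            if (self.remaining_lifespan == 0) != (self.fate == "died"):
                raise DataError("fate 'died' must coincide with remaining_lifespan 0")


@dataclass
class ScreenResult:
    fixes: pd.DataFrame
    n_removed: int
    fraction_removed: float


@dataclass
class TraitTable:
    """The modeling dataset: three trait sub-tables joined to metadata."""

    movement: pd.DataFrame
    activity: pd.DataFrame
    distance: pd.DataFrame
    dropped_activity_days: int = 0
    excluded_bear_years: list = field(default_factory=list)

    def counts(self) -> pd.DataFrame:
        rows = []
        for name, df in (("movement", self.movement), ("activity", self.activity),
                         ("distance", self.distance)):
            rows.append(dict(trait=name, observations=len(df),
                             bears=df["bear_id"].nunique() if len(df) else 0,
                             bear_years=df["bear_year"].nunique() if len(df) else 0))
        return pd.DataFrame(rows)


def _local_ts(ts: pd.Series, tz: str = STUDY_TZ) -> pd.Series:
    ts = pd.to_datetime(ts)
    if ts.dt.tz is None:
        return ts.dt.tz_localize(tz)
    return ts.dt.tz_convert(tz)


def screen_fixes(relocations: pd.DataFrame, dop_max: float = DOP_MAX) -> ScreenResult:
    """Drop fixes with DOP strictly above ``dop_max`` (boundary retained)."""
    if "dop" not in relocations.columns or relocations["dop"].isna().any():
        raise DataError("every fix must carry a DOP value")
    keep = relocations["dop"] <= dop_max
    n_removed = int((~keep).sum())
    frac = n_removed / len(relocations) if len(relocations) else 0.0
    return ScreenResult(relocations.loc[keep].reset_index(drop=True), n_removed, frac)


def window_study_period(
    rows: pd.DataFrame, year: int | None = None, tz: str = STUDY_TZ
) -> pd.DataFrame:
    """Keep rows whose local date falls in 1 Aug - 30 Sep (inclusive)."""
    if rows.empty:
        return rows
    local = _local_ts(rows["timestamp"], tz)
    month_day = local.dt.month * 100 + local.dt.day
    lo = WINDOW_START[0] * 100 + WINDOW_START[1]
    hi = WINDOW_END[0] * 100 + WINDOW_END[1]
    keep = (month_day >= lo) & (month_day <= hi)
    if year is not None:
        keep &= local.dt.year == year
    return rows.loc[keep.to_numpy()].reset_index(drop=True)


def movement_rates(relocations: pd.DataFrame, tz: str = STUDY_TZ) -> pd.DataFrame:
    """Hourly movement rates: displacement between consecutive fixes of the
    same bear whose gap is 60 +/- 5 minutes, stamped at the interval start."""
    out = []
    for bear, grp in relocations.groupby("bear_id", sort=True):
        grp = grp.sort_values("timestamp")
        ts = _local_ts(grp["timestamp"], tz)
        x, y = grp["x"].to_numpy(float), grp["y"].to_numpy(float)
        gap_min = ts.diff().dt.total_seconds().to_numpy() / 60.0
        ok = np.abs(gap_min[1:] - 60.0) <= STEP_TOL_MIN
        dist = np.hypot(np.diff(x), np.diff(y))[ok]
        starts = ts.iloc[:-1][ok]
        out.append(pd.DataFrame(dict(
            bear_id=bear, timestamp=starts.values, hour=starts.dt.hour.values,
            rate=dist,
        )))
    if not out:
        return pd.DataFrame(columns=["bear_id", "timestamp", "hour", "rate"])
    return pd.concat(out, ignore_index=True)


@lru_cache(maxsize=4096)
def _hunting_interval(date: dt.date, lat: float, lon: float, tz: str):
    return hunting_hours(date, lat, lon, tz)


def activity_index(samples_of_day: pd.DataFrame, hunting_interval) -> dict | None:
    """Daily hunting-hour activity index.

    ``(SA_h/D_h - SA_nh/D_nh) / (SA_h/D_h + SA_nh/D_nh)`` where SA are summed
    activity values inside/outside hunting hours and D the period durations.
    A 5-minute window belongs to the period containing its midpoint. Returns
    None (day dropped) when the index is undefined (all-zero activity) or a
    period has no coverage.
    """
    start, end, d_h, d_nh = hunting_interval
    mid = _local_ts(samples_of_day["timestamp"]) + pd.Timedelta(minutes=2.5)
    in_h = (mid >= start) & (mid < end)
    if not in_h.any() or in_h.all():
        return None  # no coverage of one period
    value = samples_of_day["value"].to_numpy(float)
    if (value < 0).any():
        raise DataError("activity values must be non-negative")
    sa_h = float(value[in_h.to_numpy()].sum())
    sa_nh = float(value[~in_h.to_numpy()].sum())
    num = sa_h / d_h - sa_nh / d_nh
    den = sa_h / d_h + sa_nh / d_nh
    if den == 0:
        return None
    return dict(index=num / den, sa_h=sa_h, sa_nh=sa_nh, d_h=d_h, d_nh=d_nh)


def daily_activity(
    activity: pd.DataFrame,
    lat: float = STUDY_LAT,
    lon: float = STUDY_LON,
    tz: str = STUDY_TZ,
) -> tuple[pd.DataFrame, int]:
    """Per bear per local date activity index; returns (table, days dropped).

    Vectorized equivalent of applying :func:`activity_index` to every
    (bear, date) group (the equivalence is exercised in the test suite).
    """
    cols = ["bear_id", "date", "index", "sa_h", "sa_nh", "d_h", "d_nh"]
    if activity.empty:
        return pd.DataFrame(columns=cols), 0
    act = activity[["bear_id", "timestamp", "value"]].copy()
    if (act["value"] < 0).any():
        raise DataError("activity values must be non-negative")
    act["timestamp"] = _local_ts(act["timestamp"], tz)
    act["date"] = act["timestamp"].dt.tz_localize(None).dt.normalize()
    ivals = pd.DataFrame(
        [dict(zip(("start", "end", "d_h", "d_nh"),
                  _hunting_interval(pd.Timestamp(d).date(), lat, lon, tz)),
              date=d)
         for d in act["date"].unique()]
    )
    act = act.merge(ivals, on="date")
    mid = act["timestamp"] + pd.Timedelta(minutes=2.5)
    in_h = ((mid >= act["start"]) & (mid < act["end"])).to_numpy()
    val = act["value"].to_numpy(float)
    act["_sa_h"] = np.where(in_h, val, 0.0)
    act["_sa_nh"] = np.where(in_h, 0.0, val)
    act["_n_h"] = in_h.astype(int)
    act["_n_nh"] = (~in_h).astype(int)
    g = act.groupby(["bear_id", "date"], sort=True)
    tab = g.agg(
        sa_h=("_sa_h", "sum"), sa_nh=("_sa_nh", "sum"),
        n_h=("_n_h", "sum"), n_nh=("_n_nh", "sum"),
        d_h=("d_h", "first"), d_nh=("d_nh", "first"),
    ).reset_index()
    rate_h = tab["sa_h"] / tab["d_h"]
    rate_nh = tab["sa_nh"] / tab["d_nh"]
    den = rate_h + rate_nh
    ok = (tab["n_h"] > 0) & (tab["n_nh"] > 0) & (den > 0)
    tab["index"] = (rate_h - rate_nh) / den
    dropped = int((~ok).sum())
    return tab.loc[ok, cols].reset_index(drop=True), dropped


def distance_to_road(
    relocations: pd.DataFrame, roads: RoadNetwork, tz: str = STUDY_TZ
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fix distance to the nearest road and per bear-date daily means."""
    if not roads.lines:
        raise ConfigurationError("empty road network")
    fixes = relocations.copy()
    pts = shapely.points(fixes["x"].to_numpy(float), fixes["y"].to_numpy(float))
    fixes["dist_road"] = shapely.distance(pts, roads.geometry)
    local = _local_ts(fixes["timestamp"], tz)
    fixes["date"] = local.dt.tz_localize(None).dt.normalize()
    daily = (
        fixes.groupby(["bear_id", "date"], sort=True)["dist_road"]
        .mean().reset_index().rename(columns={"dist_road": "mean_dist"})
    )
    return fixes, daily


def home_range_and_density(
    relocations: pd.DataFrame, roads: RoadNetwork
) -> tuple[shapely.Geometry, float]:
    """100% minimum convex polygon and road density (km/km^2) within it."""
    pts = MultiPoint(list(zip(relocations["x"], relocations["y"])))
    hull = pts.convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0:
        raise DataError("need >= 3 non-collinear fixes for a home-range polygon")
    clipped = roads.geometry.intersection(hull)
    density = (clipped.length / 1000.0) / (hull.area / 1e6)
    return hull, density


def _julian_date(dates, year_series) -> np.ndarray:
    """Days since 21 August (start of the hunting season) of the same year."""
    d = pd.to_datetime(pd.Series(dates))
    season = pd.to_datetime(dict(
        year=np.asarray(year_series, dtype=int),
        month=SEASON_START[0], day=SEASON_START[1],
    ))
    return (d.values - season.values).astype("timedelta64[D]").astype(float)


def build_trait_table(
    relocations: pd.DataFrame,
    activity: pd.DataFrame,
    roads: RoadNetwork,
    bear_years: pd.DataFrame | list,
    dop_max: float = DOP_MAX,
    movement_hours: tuple[int, int] = MOVEMENT_HOURS,
    zero_rate_floor: float = ZERO_RATE_FLOOR,
    lat: float = STUDY_LAT,
    lon: float = STUDY_LON,
    tz: str = STUDY_TZ,
) -> TraitTable:
    """Screen, window, derive, and join the three trait tables.

    Only legally harvestable bear-years contribute rows. Movement rows are
    restricted to interval starts in ``movement_hours``; movement and
    distance responses are log-transformed with a configurable floor before
    the log (default 1 m, so a zero rate maps to log-rate 0).
    """
    meta = _bear_year_frame(bear_years)
    meta = meta.loc[meta["harvestable"]].reset_index(drop=True)
    if meta.empty:
        raise DataError("no harvestable bear-years in metadata")

    screened = screen_fixes(relocations, dop_max).fixes
    screened = window_study_period(screened, tz=tz)
    act = window_study_period(activity, tz=tz)

    local = _local_ts(screened["timestamp"], tz)
    screened = screened.assign(year=local.dt.year)

    known = set(zip(meta["bear_id"], meta["year"]))
    observed = set(zip(screened["bear_id"], screened["year"]))
    unknown = observed - known - _nonharvestable(bear_years)
    if unknown:
        raise DataError(f"telemetry without bear-year metadata: {sorted(unknown)[:5]}")

    def attach(df: pd.DataFrame, year_col: str) -> pd.DataFrame:
        df = df.merge(
            meta.assign(year=meta["year"].astype(int)),
            left_on=["bear_id", year_col], right_on=["bear_id", "year"],
            how="inner",
        )
        df["bear_year"] = df["bear_id"].astype(str) + "_" + df["year"].astype(str)
        return df

    # --- movement ---
    rates = movement_rates(screened, tz)
    if len(rates):
        ts = _local_ts(rates["timestamp"], tz)
        rates["year"] = ts.dt.year
        rates["date"] = ts.dt.tz_localize(None).dt.normalize()
        lo, hi = movement_hours
        rates = rates.loc[(rates["hour"] >= lo) & (rates["hour"] < hi)]
        rates["log_rate"] = np.log(np.maximum(rates["rate"], zero_rate_floor))
        movement = attach(rates.drop(columns=["rate"]), "year")
        movement["julian_date"] = _julian_date(movement["date"], movement["year"])
    else:
        movement = pd.DataFrame()

    # --- activity ---
    daily_idx, dropped = daily_activity(act, lat, lon, tz)
    if len(daily_idx):
        daily_idx["year"] = pd.to_datetime(daily_idx["date"]).dt.year
        activity_tab = attach(daily_idx.rename(columns={"index": "activity_index"}), "year")
        activity_tab["julian_date"] = _julian_date(activity_tab["date"], activity_tab["year"])
    else:
        activity_tab = pd.DataFrame()

    # --- distance to road + home-range road density ---
    _, daily_dist = distance_to_road(screened, roads, tz)
    daily_dist["year"] = pd.to_datetime(daily_dist["date"]).dt.year
    densities, excluded = {}, []
    for (bear, year), grp in screened.groupby(["bear_id", "year"]):
        if (bear, int(year)) not in known:
            continue
        try:
            _, dens = home_range_and_density(grp, roads)
            densities[(bear, int(year))] = dens
        except DataError:
            excluded.append((bear, int(year)))
    if len(daily_dist):
        daily_dist["log_dist"] = np.log(np.maximum(daily_dist["mean_dist"], 1.0))
        distance = attach(daily_dist, "year")
        distance["road_density"] = [
            densities.get((b, int(y)), np.nan)
            for b, y in zip(distance["bear_id"], distance["year"])
        ]
        distance = distance.dropna(subset=["road_density"]).reset_index(drop=True)
        distance["julian_date"] = _julian_date(distance["date"], distance["year"])
    else:
        distance = pd.DataFrame()

    return TraitTable(
        movement=movement.reset_index(drop=True),
        activity=activity_tab.reset_index(drop=True),
        distance=distance,
        dropped_activity_days=dropped,
        excluded_bear_years=excluded,
    )


def _bear_year_frame(bear_years) -> pd.DataFrame:
    if isinstance(bear_years, pd.DataFrame):
        df = bear_years.copy()
    else:
        df = pd.DataFrame([vars(by) for by in bear_years])
    required = {"bear_id", "year", "sex", "age", "harvestable", "fate"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"bear-year metadata lacks columns {sorted(missing)}")
    for col in ("death_year", "death_cause", "remaining_lifespan"):
        if col not in df.columns:
            df[col] = None
    df["year"] = df["year"].astype(int)
    return df


def _nonharvestable(bear_years) -> set:
    df = _bear_year_frame(bear_years)
    bad = df.loc[~df["harvestable"]]
    return set(zip(bad["bear_id"], bad["year"]))
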