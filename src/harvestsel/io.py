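"""Reading and writing the pipeline's file formats.

Telemetry travels as Movebank-like CSV (individual id, ISO-8601 timestamp,
projected x/y in meters, DOP or activity value), roads as GeoJSON
LineStrings, bear-year metadata and trait tables as CSV, ground truth as
JSON. Column dictionary for the trait tables is in ``docs/methods.md``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import LineString

from .errors import DataError
from .traits import BearYear, RoadNetwork, TraitTable


def write_relocations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def read_relocations(path, kind: str = "fixes") -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"bear_id", "timestamp", "x", "y", "dop"} if kind == "fixes" else {
        "bear_id", "timestamp", "value"}
    missing = need - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return df


write_activity = write_relocations


def read_activity(path) -> pd.DataFrame:
    return read_relocations(path, kind="activity")


def write_roads(roads: RoadNetwork, path) -> None:
    features = [
        dict(type="Feature", properties={},
             geometry=dict(type="LineString",
                           coordinates=[list(c) for c in line.coords]))
        for line in roads.lines
    ]
    with open(path, "w") as fh:
        json.dump(dict(type="FeatureCollection", features=features), fh)


def read_roads(path) -> RoadNetwork:
    with open(path) as fh:
        gj = json.load(fh)
    lines = []
    for feat in gj.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") == "LineString":
            lines.append(LineString(geom["coordinates"]))
    if not lines:
        raise DataError(f"{path}: no LineString features")
    return RoadNetwork(lines)


_BY_COLS = ["bear_id", "year", "sex", "age", "harvestable", "fate",
            "death_year", "death_cause", "remaining_lifespan"]


def write_bear_years(bear_years: list[BearYear] | pd.DataFrame, path) -> None:
    if not isinstance(bear_years, pd.DataFrame):
        bear_years = pd.DataFrame([vars(b) for b in bear_years])
    bear_years[_BY_COLS].to_csv(path, index=False)


def read_bear_years(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_BY_COLS[:6]) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    df["harvestable"] = df["harvestable"].astype(bool)
    return df


def write_trait_table(table: TraitTable, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    table.movement.to_csv(out / "movement.csv", index=False)
    table.activity.to_csv(out / "activity.csv", index=False)
    table.distance.to_csv(out / "distance.csv", index=False)


def read_trait_table(path) -> TraitTable:
    path = Path(path)
    frames = {}
    for name in ("movement", "activity", "distance"):
        f = path / f"{name}.csv"
        if not f.exists():
            raise DataError(f"missing trait table {f}")
        frames[name] = pd.read_csv(f, dtype={"bear_id": str, "bear_year": str})
    return TraitTable(**frames)


def write_truth(truth, path) -> None:
    payload = dict(
        sd_bear=truth.sd_bear, sd_bearyear=truth.sd_bearyear,
        sd_resid=truth.sd_resid, ar1_phi=truth.ar1_phi,
        selection_dist=truth.selection_dist, selection_act=truth.selection_act,
        implied_repeatability=truth.implied_repeatability(),
        harvest_year=truth.harvest_year,
        bears=truth.bears.to_dict(orient="records"),
        bear_years=truth.bear_years.to_dict(orient="records"),
    )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
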