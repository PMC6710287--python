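"""Sunrise/sunset times from the NOAA solar-position equations.

Legal hunting hours for Scandinavian brown bears are defined in civil time
relative to sunrise and sunset, so trait extraction needs a solar ephemeris.
The implementation follows the NOAA General Solar Position Calculations
(the equations behind the NOAA sunrise/sunset calculator), accurate to
roughly one minute for the latitudes and dates of the study window.
"""

from __future__ import annotations

import datetime as dt
import math
from zoneinfo import ZoneInfo

# zenith of the sun's center at rise/set: 90 deg + refraction + semi-diameter
_ZENITH_DEG = 90.833


class PolarDayNightError(ValueError):
    """The sun does not rise or does not set on this date at this latitude."""


def _solar_params(jc: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians) at Julian
    century ``jc`` from J2000."""
    gml = math.radians((280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0)
    gma = math.radians(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eqc = (
        math.sin(gma) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * gma) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * gma) * 0.000289
    )
    true_long = math.degrees(gml) + eqc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    decl = math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    y = math.tan(math.radians(obliq / 2.0)) ** 2
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * gml)
        - 2 * ecc * math.sin(gma)
        + 4 * ecc * y * math.sin(gma) * math.cos(2 * gml)
        - 0.5 * y * y * math.sin(4 * gml)
        - 1.25 * ecc * ecc * math.sin(2 * gma)
    )
    return eqtime, decl


def _julian_day(date: dt.date) -> float:
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _rise_set_utc_minutes(date: dt.date, latitude: float, longitude: float) -> tuple[float, float]:
    """Minutes past UTC midnight of sunrise and sunset."""
    jd = _julian_day(date)
    lat = math.radians(latitude)

    def hour_angle(decl: float) -> float:
        cos_ha = (
            math.cos(math.radians(_ZENITH_DEG)) / (math.cos(lat) * math.cos(decl))
            - math.tan(lat) * math.tan(decl)
        )
        if cos_ha > 1.0 or cos_ha < -1.0:
            raise PolarDayNightError(
                f"sun does not cross the horizon on {date} at latitude {latitude}"
            )
        return math.degrees(math.acos(cos_ha))

    # first pass at local solar noon, then refine at the event times
    minutes = {"rise": 720.0, "set": 720.0}
    for _ in range(2):
        out = {}
        for key, sign in (("rise", -1.0), ("set", 1.0)):
            jc = (jd + minutes[key] / 1440.0 - 2451545.0) / 36525.0
            eqtime, decl = _solar_params(jc)
            ha = hour_angle(decl)
            noon = 720.0 - 4.0 * longitude - eqtime
            out[key] = noon + sign * 4.0 * ha
        minutes = out
    return minutes["rise"], minutes["set"]


def sunrise_sunset(
    date: dt.date,
    latitude: float = 61.0,
    longitude: float = 15.0,
    tz: str = "Europe/Stockholm",
) -> tuple[dt.datetime, dt.datetime]:
    """Local civil sunrise and sunset (timezone-aware, DST honored)."""
    rise_min, set_min = _rise_set_utc_minutes(date, latitude, longitude)
    zone = ZoneInfo(tz)
    midnight_utc = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    rise = (midnight_utc + dt.timedelta(minutes=rise_min)).astimezone(zone)
    sset = (midnight_utc + dt.timedelta(minutes=set_min)).astimezone(zone)
    return rise, sset


def hunting_hours(
    date: dt.date,
    latitude: float = 61.0,
    longitude: float = 15.0,
    tz: str = "Europe/Stockholm",
) -> tuple[dt.datetime, dt.datetime, float, float]:
    """Legal hunting hours: one hour before sunrise until two hours before
    sunset.

    Returns ``(start, end, D_h, D_nh)`` where the durations are in hours and
    ``D_h + D_nh == 24``.
    """
    rise, sset = sunrise_sunset(date, latitude, longitude, tz)
    start = rise - dt.timedelta(hours=1)
    end = sset - dt.timedelta(hours=2)
    d_h = (end - start).total_seconds() / 3600.0
    if d_h <= 0:
        raise PolarDayNightError(f"empty hunting window on {date}")
    return start, end, d_h, 24.0 - d_h
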