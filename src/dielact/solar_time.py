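"""Solar times and double-anchoring of detection clock times.

Clock times live on the diel circle: 24 h = 2*pi radians, 0 = local
midnight. Double-anchoring rescales each day's clock times piecewise-
linearly so that that day's sunrise and sunset land on the study-average
("anchor") sunrise and sunset. This removes day-to-day and site-to-site
drift in photoperiod before times from many camera-days are pooled into
one circular sample — essential for crepuscular species, whose activity
tracks the sun rather than the clock.

Sunrise and sunset are computed with the NOAA solar-position
approximation (equation of time + solar declination from Julian
centuries, zenith 90.833 deg), accurate to within a few minutes away
from polar latitudes.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * math.pi

#: Circular time-of-day in radians, 0 = local midnight, 1 h = pi/12.
ClockTime = float

#: Latitude beyond which polar day/night can occur; unsupported.
POLAR_LATITUDE = 66.5


def clock_time(radians: float) -> ClockTime:
    """Reduce a time-of-day angle into [0, 2*pi)."""
    r = float(radians)
    if not math.isfinite(r):
        raise ValueError("clock time must be finite")
    return r % TWO_PI


def hours_to_radians(hours):
    """Convert hours-since-midnight to circular radians."""
    return np.asarray(hours, dtype=float) * (math.pi / 12.0) % TWO_PI


def radians_to_hours(radians):
    """Convert circular radians to hours-since-midnight in [0, 24)."""
    return np.asarray(radians, dtype=float) % TWO_PI * (12.0 / math.pi)


@dataclass(frozen=True)
class SolarDay:
    """Sunrise and sunset (circular radians) for one date at one site."""

    date: _dt.date
    sunrise: ClockTime
    sunset: ClockTime

    def __post_init__(self):
        object.__setattr__(self, "sunrise", clock_time(self.sunrise))
        object.__setattr__(self, "sunset", clock_time(self.sunset))
        if math.isclose(self.sunrise, self.sunset, abs_tol=1e-12):
            raise ValueError("degenerate solar day: sunrise == sunset")


@dataclass(frozen=True)
class SolarAnchors:
    """Study-average sunrise and sunset used as anchoring targets."""

    mean_sunrise: ClockTime
    mean_sunset: ClockTime

    def __post_init__(self):
        object.__setattr__(self, "mean_sunrise", clock_time(self.mean_sunrise))
        object.__setattr__(self, "mean_sunset", clock_time(self.mean_sunset))
        if math.isclose(self.mean_sunrise, self.mean_sunset, abs_tol=1e-12):
            raise ValueError("anchors coincide: mean_sunrise == mean_sunset")


def solar_events(
    latitude: float,
    longitude: float,
    date: _dt.date,
    utc_offset: float,
) -> SolarDay:
    """Local sunrise and sunset by the NOAA solar-position approximation.

    Parameters
    ----------
    latitude, longitude
        Site coordinates in decimal degrees (east and north positive).
    date
        Calendar date (local).
    utc_offset
        Local standard-time offset from UTC in hours (e.g. -5 for EST).

    Returns
    -------
    SolarDay
        Sunrise/sunset as circular clock times, accurate to ~3 min.

    Raises
    ------
    ValueError
        For latitudes poleward of 66.5 deg (polar day/night possible)
        or if the sun does not rise/set on the given date.
    """
    if abs(latitude) >= POLAR_LATITUDE:
        raise ValueError(
            f"latitude {latitude} is poleward of {POLAR_LATITUDE} deg; "
            "polar day/night is unsupported"
        )
    if isinstance(date, _dt.datetime):
        date = date.date()

    # Julian day at local noon, converted to UT.
    jd = date.toordinal() + 1721424.5 + 0.5 - utc_offset / 24.0
    jc = (jd - 2451545.0) / 36525.0

    geom_mean_long = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)

    m = math.radians(geom_mean_anom)
    eq_of_center = (
        math.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * m) * 0.000289
    )
    true_long = geom_mean_long + eq_of_center
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)

    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(omega)
    obliq_r = math.radians(obliq)

    declination = math.asin(math.sin(obliq_r) * math.sin(math.radians(app_long)))

    var_y = math.tan(obliq_r / 2.0) ** 2
    l0 = math.radians(geom_mean_long)
    # Equation of time in minutes.
    eot = 4.0 * math.degrees(
        var_y * math.sin(2 * l0)
        - 2.0 * ecc * math.sin(m)
        + 4.0 * ecc * var_y * math.sin(m) * math.cos(2 * l0)
        - 0.5 * var_y**2 * math.sin(4 * l0)
        - 1.25 * ecc**2 * math.sin(2 * m)
    )

    lat_r = math.radians(latitude)
    cos_ha = (
        math.cos(math.radians(90.833)) / (math.cos(lat_r) * math.cos(declination))
        - math.tan(lat_r) * math.tan(declination)
    )
    if not -1.0 < cos_ha < 1.0:
        raise ValueError("sun does not rise/set at this latitude on this date")
    ha = math.degrees(math.acos(cos_ha))  # half the day arc, degrees

    solar_noon_min = 720.0 - 4.0 * longitude - eot + utc_offset * 60.0
    sunrise_min = solar_noon_min - 4.0 * ha
    sunset_min = solar_noon_min + 4.0 * ha

    to_rad = TWO_PI / 1440.0
    return SolarDay(
        date=date,
        sunrise=clock_time(sunrise_min * to_rad),
        sunset=clock_time(sunset_min * to_rad),
    )


def _circular_mean(angles: np.ndarray) -> float:
    s = np.sin(angles).sum()
    c = np.cos(angles).sum()
    if s == 0.0 and c == 0.0:
        raise ValueError("circular mean undefined: angles perfectly balanced")
    return float(math.atan2(s, c) % TWO_PI)


def mean_anchors(days) -> SolarAnchors:
    """Circular means of sunrise and sunset over a collection of days.

    The circular (not arithmetic) mean averages midnight-spanning times
    correctly — e.g. sunrises at 23:30 and 00:30 average to 00:00.
    """
    days = list(days)
    if not days:
        raise ValueError("mean_anchors requires at least one SolarDay")
    sunrises = np.array([d.sunrise for d in days])
    sunsets = np.array([d.sunset for d in days])
    return SolarAnchors(
        mean_sunrise=_circular_mean(sunrises),
        mean_sunset=_circular_mean(sunsets),
    )


def _anchor_map(t, src_rise, src_set, dst_rise, dst_set):
    """Piecewise-linear circular map sending src day/night arcs onto dst arcs."""
    t = np.asarray(t, dtype=float) % TWO_PI
    day_src = (src_set - src_rise) % TWO_PI
    day_dst = (dst_set - dst_rise) % TWO_PI
    if day_src == 0.0:
        raise ValueError("degenerate day: sunrise == sunset")
    night_src = TWO_PI - day_src
    night_dst = TWO_PI - day_dst

    u = (t - src_rise) % TWO_PI
    in_day = u < day_src
    out = np.where(
        in_day,
        dst_rise + u * (day_dst / day_src),
        dst_set + (u - day_src) * (night_dst / night_src),
    )
    out = out % TWO_PI
    if out.ndim == 0:
        return float(out)
    return out


def double_anchor(t, day: SolarDay, anchors: SolarAnchors):
    """Map clock time(s) of one day onto the double-anchored scale.

    ``day.sunrise`` maps to ``anchors.mean_sunrise`` and ``day.sunset``
    to ``anchors.mean_sunset``; the daylight arc is rescaled linearly
    onto the mean daylight arc and the night arc onto its complement.
    The map is a continuous bijection of the circle. Accepts a scalar or
    array of radians.
    """
    return _anchor_map(t, day.sunrise, day.sunset, anchors.mean_sunrise, anchors.mean_sunset)


def inverse_double_anchor(t, day: SolarDay, anchors: SolarAnchors):
    """Inverse of :func:`double_anchor` (anchored time back to clock time)."""
    return _anchor_map(t, anchors.mean_sunrise, anchors.mean_sunset, day.sunrise, day.sunset)
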