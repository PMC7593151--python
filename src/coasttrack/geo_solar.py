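"""Geodesic distance/bearing and solar-event computation.

Distances and bearings are great-circle quantities on a sphere of radius
6371 km, which is accurate to well under 0.5% at the ~10-100 km scale of a
coastal receiver array. Sunrise/sunset use the NOAA solar position
algorithm with the standard refraction zenith of 90.833 degrees.

The ``night_fraction`` axis rescales clock time per night so that 0 falls
at sunset and 1 at the following sunrise; daytime instants extend the axis
continuously below 0 (afternoon, before sunset) and above 1 (morning,
after sunrise), each scaled by the length of the adjacent night.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "SolarDay",
    "NoSunEventError",
    "UndefinedBearingError",
    "great_circle_distance",
    "initial_bearing",
    "sun_events",
    "night_fraction",
]

EARTH_RADIUS_KM = 6371.0

#: Solar zenith angle (degrees) at sunrise/sunset including standard
#: atmospheric refraction and the solar disc radius.
SUNRISE_SUNSET_ZENITH = 90.833


class NoSunEventError(ValueError):
    """Sun does not rise or set on the requested date/latitude (polar day/night)."""


class UndefinedBearingError(ValueError):
    """Bearing requested between two identical points."""


@dataclass(frozen=True)
class GeoPoint:
    """A point on the Earth's surface in decimal degrees (WGS-style lat/lon)."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat!r} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon!r} outside [-180, 180]")


@dataclass(frozen=True)
class SolarDay:
    """Sunrise and sunset (UTC) for one calendar date at one location."""

    date: date
    sunrise_utc: datetime
    sunset_utc: datetime


def great_circle_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Haversine great-circle distance between two points, in km."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon - a.lon)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def initial_bearing(a: GeoPoint, b: GeoPoint) -> float:
    """Forward azimuth of the great circle from ``a`` to ``b``.

    Returns degrees in [0, 360), 0 = north, clockwise positive.

    Raises
    ------
    UndefinedBearingError
        If the two points coincide.
    """
    if a.lat == b.lat and a.lon == b.lon:
        raise UndefinedBearingError(f"bearing undefined for identical points {a}")
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dlam = math.radians(b.lon - a.lon)
    x = math.sin(dlam) * math.cos(phi2)
    y = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    return math.degrees(math.atan2(x, y)) % 360.0


# --- NOAA solar position -----------------------------------------------------

def _julian_day(t: datetime) -> float:
    t = _as_utc(t)
    y, m = t.year, t.month
    d = t.day + (t.hour + (t.minute + t.second / 60.0) / 60.0) / 24.0
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _solar_params(jd: float) -> tuple[float, float]:
    """Return (declination degrees, equation of time minutes) at Julian day jd."""
    t = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + t * (36000.76983 + t * 0.0003032)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * t)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * t)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    decl = math.degrees(math.asin(math.sin(eps) * math.sin(math.radians(app_long))))
    y = math.tan(eps / 2.0) ** 2
    l0r = math.radians(l0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2.0 * ecc * math.sin(mrad)
        + 4.0 * ecc * y * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mrad)
    )
    return decl, eot


def _hour_angle_deg(lat: float, decl: float) -> float:
    phi = math.radians(lat)
    drad = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(SUNRISE_SUNSET_ZENITH)) / (math.cos(phi) * math.cos(drad))
        - math.tan(phi) * math.tan(drad)
    )
    if cos_ha < -1.0 or cos_ha > 1.0:
        raise NoSunEventError(
            f"sun does not cross the horizon at latitude {lat} (declination {decl:.2f})"
        )
    return math.degrees(math.acos(cos_ha))


def sun_events(day: date, p: GeoPoint) -> SolarDay:
    """Sunrise and sunset (UTC) on calendar date ``day`` at point ``p``.

    Implements the NOAA solar position algorithm (zenith 90.833 deg), with
    one refinement pass evaluating the solar parameters at the event times
    themselves. Accurate to ~1 minute at mid-latitudes.

    Raises
    ------
    NoSunEventError
        During polar day or polar night at the requested latitude.
    """
    jd_noon = _julian_day(datetime(day.year, day.month, day.day, 12, tzinfo=timezone.utc))

    def event_minutes(jd_guess: float, rising: bool) -> float:
        decl, eot = _solar_params(jd_guess)
        ha = _hour_angle_deg(p.lat, decl)
        noon_min = 720.0 - 4.0 * p.lon - eot
        return noon_min - 4.0 * ha if rising else noon_min + 4.0 * ha

    jd0 = jd_noon - 0.5  # midnight UTC of `day`
    out = {}
    for rising in (True, False):
        minutes = event_minutes(jd_noon, rising)
        for _ in range(2):  # refine at the event time
            minutes = event_minutes(jd0 + minutes / 1440.0, rising)
        out[rising] = datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + timedelta(
            minutes=minutes
        )
    return SolarDay(date=day, sunrise_utc=out[True], sunset_utc=out[False])


def _as_utc(t: datetime) -> datetime:
    if t.tzinfo is None:
        return t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc)


def night_fraction(t: datetime, p: GeoPoint) -> float:
    """Position of instant ``t`` on the per-night rescaled time axis at ``p``.

    0 at the most recent sunset, 1 at the following sunrise, linear in
    between. Afternoon instants (after local solar midday, before sunset)
    map below 0 against the upcoming night; morning instants (after
    sunrise, before midday) map above 1 against the night just ended, so
    the axis is continuous across the day/night boundaries.
    """
    t = _as_utc(t)
    d = t.date()
    today = sun_events(d, p)

    def frac_for_night(night_start_date: date) -> float:
        ss = sun_events(night_start_date, p).sunset_utc
        sr = sun_events(night_start_date + timedelta(days=1), p).sunrise_utc
        return (t - ss).total_seconds() / (sr - ss).total_seconds()

    if t >= today.sunset_utc:
        return frac_for_night(d)
    if t < today.sunrise_utc:
        return frac_for_night(d - timedelta(days=1))
    # daytime: attach to the nearer night, split at solar midday
    midday = today.sunrise_utc + (today.sunset_utc - today.sunrise_utc) / 2
    if t >= midday:
        return frac_for_night(d)
    return frac_for_night(d - timedelta(days=1))
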