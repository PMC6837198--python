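"""Low-precision self-contained moon and sun ephemeris.

Truncated trigonometric series (Keplerian elements plus the dominant
lunar perturbation terms — evection, variation, annual equation, ...)
give geocentric ecliptic positions; conversion through equatorial
coordinates and local sidereal time yields azimuth/altitude at a site.
A simple parallax-in-altitude correction makes the lunar altitude
topocentric. Accuracy over 1950-2050 is well inside 1 deg for the moon
and 0.1 deg for the sun, which is more than the orientation analysis
needs (orientation effects are tens of degrees wide).

TT - UTC is fixed at 69 s, appropriate for the mid-2010s validity window
of the analyses this package targets.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Optional

from driftorient.angles import wrap_deg, wrap_signed_deg

#: Fixed TT-UTC offset (seconds); adequate across the supported window.
DELTA_T_SECONDS = 69.0

GRAVITATIONAL_CONSTANT = 6.674e-11  # m^3 kg^-1 s^-2
LUNAR_MASS_KG = 7.342e22
MEAN_EARTH_MOON_DISTANCE_M = 3.844e8
EARTH_SURFACE_G = 9.81  # m s^-2

_J2000 = datetime(2000, 1, 1, 12, 0, 0, tzinfo=timezone.utc)

_VALID_YEARS = (1950, 2050)


class Body(str, enum.Enum):
    MOON = "moon"
    SUN = "sun"


class PhaseLabel(str, enum.Enum):
    NEW = "new"
    FIRST_QUARTER = "first_quarter"
    FULL = "full"
    THIRD_QUARTER = "third_quarter"
    WAXING = "waxing"
    WANING = "waning"


@dataclass(frozen=True)
class Site:
    """Observation site; longitude east-positive, declination east-positive."""

    latitude: float
    longitude: float
    magnetic_declination: float = 0.0

    def __post_init__(self):
        if abs(self.latitude) > 90.0:
            raise ValueError("latitude out of range")
        lon = wrap_signed_deg(self.longitude)
        if lon == -180.0:
            lon = 180.0
        object.__setattr__(self, "longitude", lon)


@dataclass(frozen=True)
class EphemerisState:
    """Horizontal position (and, for the moon, phase data) at one instant."""

    body: Body
    azimuth: float  # degrees from true north, clockwise
    altitude: float  # degrees above the horizon
    illuminated_fraction: Optional[float]  # moon only
    phase_label: Optional[PhaseLabel]  # moon only
    above_horizon: bool


# ---------------------------------------------------------------------------
# time scales
# ---------------------------------------------------------------------------

def _as_utc(utc: datetime) -> datetime:
    if utc.tzinfo is None:
        return utc.replace(tzinfo=timezone.utc)
    return utc.astimezone(timezone.utc)


def _check_window(utc: datetime) -> datetime:
    utc = _as_utc(utc)
    if not (_VALID_YEARS[0] <= utc.year <= _VALID_YEARS[1]):
        raise ValueError("ephemeris validity: date outside 1950-2050")
    return utc


def _days_since_j2000(utc: datetime, terrestrial: bool = False) -> float:
    dt = _as_utc(utc) - _J2000
    days = dt.total_seconds() / 86400.0
    if terrestrial:
        days += DELTA_T_SECONDS / 86400.0
    return days


def _sind(x):
    return math.sin(math.radians(x))


def _cosd(x):
    return math.cos(math.radians(x))


# ---------------------------------------------------------------------------
# geocentric ecliptic positions
# ---------------------------------------------------------------------------

def _sun_ecliptic(d_tt: float) -> tuple[float, float]:
    """Apparent geocentric ecliptic longitude (deg) and distance (AU)."""
    t = d_tt / 36525.0
    l0 = 280.46646 + 36000.76983 * t + 0.0003032 * t * t
    m = 357.52911 + 35999.05029 * t - 0.0001537 * t * t
    e = 0.016708634 - 0.000042037 * t
    c = (
        (1.914602 - 0.004817 * t - 0.000014 * t * t) * _sind(m)
        + (0.019993 - 0.000101 * t) * _sind(2 * m)
        + 0.000289 * _sind(3 * m)
    )
    true_lon = l0 + c
    nu = m + c
    dist = 1.000001018 * (1 - e * e) / (1 + e * _cosd(nu))
    omega = 125.04 - 1934.136 * t
    apparent = true_lon - 0.00569 - 0.00478 * _sind(omega)
    return wrap_deg(apparent), dist


def _moon_ecliptic(d_tt: float) -> tuple[float, float, float]:
    """Geocentric ecliptic lon, lat (deg) and distance (Earth radii)."""
    # mean elements; their epoch is 1999 Dec 31 00:00 (1.5 d before J2000)
    d = d_tt + 1.5
    n_node = 125.1228 - 0.0529538083 * d
    incl = 5.1454
    w = 318.0634 + 0.1643573223 * d
    a = 60.2666
    ecc = 0.054900
    m = wrap_deg(115.3654 + 13.0649929509 * d)

    # eccentric anomaly by Newton iteration
    e_anom = m + math.degrees(ecc) * _sind(m) * (1.0 + ecc * _cosd(m))
    for _ in range(10):
        delta = (e_anom - math.degrees(ecc) * _sind(e_anom) - m) / (
            1 - ecc * _cosd(e_anom)
        )
        e_anom -= delta
        if abs(delta) < 1e-9:
            break

    xv = a * (_cosd(e_anom) - ecc)
    yv = a * math.sqrt(1 - ecc * ecc) * _sind(e_anom)
    v = math.degrees(math.atan2(yv, xv))
    r = math.hypot(xv, yv)

    # position in ecliptic coordinates
    xh = r * (_cosd(n_node) * _cosd(v + w)
              - _sind(n_node) * _sind(v + w) * _cosd(incl))
    yh = r * (_sind(n_node) * _cosd(v + w)
              + _cosd(n_node) * _sind(v + w) * _cosd(incl))
    zh = r * (_sind(v + w) * _sind(incl))
    lon = wrap_deg(math.degrees(math.atan2(yh, xh)))
    lat = math.degrees(math.atan2(zh, math.hypot(xh, yh)))

    # fundamental arguments for the perturbation series
    ms = wrap_deg(356.0470 + 0.9856002585 * d)  # sun mean anomaly
    ws = wrap_deg(282.9404 + 4.70935e-5 * d)  # sun argument of perihelion
    ls = wrap_deg(ms + ws)  # sun mean longitude
    lm = wrap_deg(n_node + w + m)  # moon mean longitude
    dd = wrap_deg(lm - ls)  # mean elongation
    f = wrap_deg(lm - n_node)  # argument of latitude

    lon += (
        -1.274 * _sind(m - 2 * dd)      # evection
        + 0.658 * _sind(2 * dd)         # variation
        - 0.186 * _sind(ms)             # yearly equation
        - 0.059 * _sind(2 * m - 2 * dd)
        - 0.057 * _sind(m - 2 * dd + ms)
        + 0.053 * _sind(m + 2 * dd)
        + 0.046 * _sind(2 * dd - ms)
        + 0.041 * _sind(m - ms)
        - 0.035 * _sind(dd)             # parallactic equation
        - 0.031 * _sind(m + ms)
        - 0.015 * _sind(2 * f - 2 * dd)
        + 0.011 * _sind(m - 4 * dd)
    )
    lat += (
        -0.173 * _sind(f - 2 * dd)
        - 0.055 * _sind(m - f - 2 * dd)
        - 0.046 * _sind(m + f - 2 * dd)
        + 0.033 * _sind(f + 2 * dd)
        + 0.017 * _sind(2 * m + f)
    )
    dist = r - 0.58 * _cosd(m - 2 * dd) - 0.46 * _cosd(2 * dd)
    return wrap_deg(lon), lat, dist


def _obliquity(d_tt: float) -> float:
    return 23.4393 - 3.563e-7 * d_tt


def _ecliptic_to_equatorial(lon: float, lat: float, d_tt: float
                            ) -> tuple[float, float]:
    """Ecliptic lon/lat (deg) to right ascension / declination (deg)."""
    eps = _obliquity(d_tt)
    x = _cosd(lon) * _cosd(lat)
    y = _sind(lon) * _cosd(lat) * _cosd(eps) - _sind(lat) * _sind(eps)
    z = _sind(lon) * _cosd(lat) * _sind(eps) + _sind(lat) * _cosd(eps)
    ra = wrap_deg(math.degrees(math.atan2(y, x)))
    dec = math.degrees(math.asin(z))
    return ra, dec


def _gmst_deg(d_ut: float) -> float:
    return wrap_deg(280.46061837 + 360.98564736629 * d_ut)


def _horizontal(ra: float, dec: float, utc: datetime, site: Site
                ) -> tuple[float, float]:
    """Right ascension/declination to azimuth (from true north) / altitude."""
    d_ut = _days_since_j2000(utc)
    lst = _gmst_deg(d_ut) + site.longitude
    h = wrap_deg(lst - ra)  # hour angle
    phi = site.latitude
    east = -_cosd(dec) * _sind(h)
    north = _cosd(phi) * _sind(dec) - _sind(phi) * _cosd(dec) * _cosd(h)
    z = _sind(phi) * _sind(dec) + _cosd(phi) * _cosd(dec) * _cosd(h)
    az = wrap_deg(math.degrees(math.atan2(east, north)))
    alt = math.degrees(math.asin(max(-1.0, min(1.0, z))))
    return az, alt


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def moon_position(utc: datetime, site: Site) -> EphemerisState:
    """Topocentric moon azimuth/altitude plus phase data at a site."""
    utc = _check_window(utc)
    d_tt = _days_since_j2000(utc, terrestrial=True)
    lon, lat, dist = _moon_ecliptic(d_tt)
    ra, dec = _ecliptic_to_equatorial(lon, lat, d_tt)
    az, alt = _horizontal(ra, dec, utc, site)
    # parallax in altitude: the moon is close enough that the geocentric
    # altitude overstates the topocentric one by up to ~1 degree
    parallax = math.degrees(math.asin(1.0 / dist))
    alt -= parallax * _cosd(alt)
    return EphemerisState(
        body=Body.MOON,
        azimuth=az,
        altitude=alt,
        illuminated_fraction=illuminated_fraction(utc),
        phase_label=phase_label(utc),
        above_horizon=alt > 0.0,
    )


def sun_position(utc: datetime, site: Site) -> EphemerisState:
    """Apparent sun azimuth/altitude at a site."""
    utc = _check_window(utc)
    d_tt = _days_since_j2000(utc, terrestrial=True)
    lon, dist = _sun_ecliptic(d_tt)
    ra, dec = _ecliptic_to_equatorial(lon, 0.0, d_tt)
    az, alt = _horizontal(ra, dec, utc, site)
    return EphemerisState(
        body=Body.SUN,
        azimuth=az,
        altitude=alt,
        illuminated_fraction=None,
        phase_label=None,
        above_horizon=alt > 0.0,
    )


def elongation_deg(utc: datetime) -> float:
    """Signed sun-to-moon elongation in ecliptic longitude, [0, 360)."""
    utc = _check_window(utc)
    d_tt = _days_since_j2000(utc, terrestrial=True)
    moon_lon, _, _ = _moon_ecliptic(d_tt)
    sun_lon, _ = _sun_ecliptic(d_tt)
    return wrap_deg(moon_lon - sun_lon)


def illuminated_fraction(utc: datetime) -> float:
    """Fraction of the lunar disc illuminated, k = (1 - cos psi) / 2."""
    utc = _check_window(utc)
    d_tt = _days_since_j2000(utc, terrestrial=True)
    moon_lon, moon_lat, _ = _moon_ecliptic(d_tt)
    sun_lon, _ = _sun_ecliptic(d_tt)
    cos_psi = _cosd(moon_lat) * _cosd(moon_lon - sun_lon)
    k = (1.0 - cos_psi) / 2.0
    return min(max(k, 0.0), 1.0)


def phase_label(utc: datetime) -> PhaseLabel:
    """Classify the lunar phase from the signed elongation.

    Principal phases occupy +/- 22.5 deg windows around 0 (new), 90
    (first quarter), 180 (full) and 270 (third quarter) degrees of
    elongation; the remaining arcs are waxing (< 180) or waning.
    """
    e = elongation_deg(utc)
    if e <= 22.5 or e >= 337.5:
        return PhaseLabel.NEW
    if 67.5 <= e <= 112.5:
        return PhaseLabel.FIRST_QUARTER
    if 157.5 <= e <= 202.5:
        return PhaseLabel.FULL
    if 247.5 <= e <= 292.5:
        return PhaseLabel.THIRD_QUARTER
    return PhaseLabel.WAXING if e < 180.0 else PhaseLabel.WANING


def local_noon_utc(date, longitude: float) -> datetime:
    """Mean solar noon (UTC) for a calendar date at an east longitude."""
    base = datetime(date.year, date.month, date.day, 12, 0, 0,
                    tzinfo=timezone.utc)
    return base - timedelta(hours=longitude / 15.0)


def gravitational_pull(mass_kg: float, body: str) -> float:
    """Newtonian pull (N) of the moon at mean distance, or Earth surface weight."""
    if mass_kg < 0:
        raise ValueError("mass must be non-negative")
    body = str(getattr(body, "value", body)).lower()
    if body == "moon":
        return (GRAVITATIONAL_CONSTANT * LUNAR_MASS_KG * mass_kg
                / MEAN_EARTH_MOON_DISTANCE_M**2)
    if body == "earth":
        return mass_kg * EARTH_SURFACE_G
    raise ValueError(f"unknown body: {body!r}")
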