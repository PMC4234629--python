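"""Solar ephemeris and sunrise/sunset prediction for light-based geolocation.

Event times are expressed in minutes UT from midnight, on the circle
``[0, 1440)``.  The solver combines a low-precision solar position series
(apparent declination and right ascension) with Greenwich mean sidereal time,
iterating the hour angle of the sun until it matches the twilight geometry

    cos(omega) = (sin(h0) - sin(phi) sin(delta)) / (cos(phi) cos(delta))

where ``h0`` is the configurable twilight altitude of the sun (default
-0.833 deg: geometric horizon plus standard refraction and semi-diameter).

All prediction functions are vectorized over longitude/latitude so that a
whole grid can be evaluated for one calendar day in a single call.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_TWILIGHT_DEG",
    "STATUS_NORMAL",
    "STATUS_POLAR_DAY",
    "STATUS_POLAR_NIGHT",
    "EventTimes",
    "julian_day",
    "solar_declination",
    "solar_right_ascension_hours",
    "gmst_hours",
    "predict_event_times",
    "circular_residual_minutes",
    "event_log_likelihood",
]

DEFAULT_TWILIGHT_DEG = -0.833

STATUS_NORMAL = 0
STATUS_POLAR_DAY = 1
STATUS_POLAR_NIGHT = 2

#: apparent sidereal rate, degrees of hour angle per UT hour
_SIDEREAL_DEG_PER_HOUR = 15.04106864

_J2000 = dt.datetime(2000, 1, 1, 12, tzinfo=dt.timezone.utc)

_MIN_YEAR, _MAX_YEAR = 1940, 2100


@dataclass
class EventTimes:
    """Predicted sunrise/sunset in minutes UT plus a polar-condition status.

    Fields are scalars or arrays matching the broadcast shape of the
    ``lon``/``lat`` inputs; times are NaN wherever ``status != STATUS_NORMAL``.
    """

    sunrise_ut: np.ndarray
    sunset_ut: np.ndarray
    status: np.ndarray

    @property
    def is_normal(self) -> np.ndarray:
        return self.status == STATUS_NORMAL


def _as_utc(t: dt.datetime) -> dt.datetime:
    if t.tzinfo is None:
        return t.replace(tzinfo=dt.timezone.utc)
    return t.astimezone(dt.timezone.utc)


def julian_day(t: dt.datetime) -> float:
    """Julian day number (UT) of a datetime."""
    t = _as_utc(t)
    return 2451545.0 + (t - _J2000).total_seconds() / 86400.0


def _check_epoch(t: dt.datetime) -> None:
    if not (_MIN_YEAR <= t.year <= _MAX_YEAR):
        raise ValueError(
            f"epoch {t.isoformat()} outside supported range "
            f"[{_MIN_YEAR}, {_MAX_YEAR}]"
        )


def _sun_position(jd):
    """Apparent declination (deg) and right ascension (deg) of the sun.

    Low-precision series: geometric mean longitude, equation of center,
    apparent longitude (aberration + nutation-in-longitude term) and true
    obliquity.  Accurate to ~0.01 deg, ample for event times at minute level.
    """
    jd = np.asarray(jd, dtype=float)
    T = (jd - 2451545.0) / 36525.0
    L0 = 280.46646 + 36000.76983 * T + 0.0003032 * T * T
    M = np.deg2rad(357.52911 + 35999.05029 * T - 0.0001537 * T * T)
    C = (
        (1.914602 - 0.004817 * T - 0.000014 * T * T) * np.sin(M)
        + (0.019993 - 0.000101 * T) * np.sin(2.0 * M)
        + 0.000289 * np.sin(3.0 * M)
    )
    true_lon = L0 + C
    omega = np.deg2rad(125.04 - 1934.136 * T)
    lam = np.deg2rad(true_lon - 0.00569 - 0.00478 * np.sin(omega))
    eps0 = 23.439291111 - 0.013004167 * T - 1.639e-7 * T * T + 5.036e-7 * T**3
    eps = np.deg2rad(eps0 + 0.00256 * np.cos(omega))
    decl = np.rad2deg(np.arcsin(np.sin(eps) * np.sin(lam)))
    ra = np.rad2deg(np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))) % 360.0
    return decl, ra


def _gmst_deg(jd):
    """Greenwich mean sidereal time in degrees (IAU 1982)."""
    jd = np.asarray(jd, dtype=float)
    d = jd - 2451545.0
    T = d / 36525.0
    theta = (
        280.46061837
        + 360.98564736629 * d
        + 0.000387933 * T * T
        - T**3 / 38710000.0
    )
    return theta % 360.0


def solar_declination(t: dt.datetime) -> float:
    """Solar declination in degrees at an instant; always in [-23.45, 23.45]."""
    _check_epoch(t)
    decl, _ = _sun_position(julian_day(t))
    return float(decl)


def solar_right_ascension_hours(t: dt.datetime) -> float:
    """Apparent right ascension of the sun, in hours [0, 24)."""
    _check_epoch(t)
    _, ra = _sun_position(julian_day(t))
    return float(ra) / 15.0


def gmst_hours(t: dt.datetime) -> float:
    """Greenwich mean sidereal time in hours [0, 24)."""
    return float(_gmst_deg(julian_day(t))) / 15.0


def _wrap180(x):
    return (np.asarray(x) + 180.0) % 360.0 - 180.0


def _jd_midnight(date: dt.date) -> float:
    return julian_day(dt.datetime(date.year, date.month, date.day))


def _solve_event(lon, lat, jd0, h0, sign, n_iter):
    """Iterate UT (hours) for one solar event.

    ``sign`` is -1 for sunrise (hour angle -omega) and +1 for sunset.
    Returns (ut_hours, polar_day_mask, polar_night_mask).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon, lat = np.broadcast_arrays(lon, lat)
    phi = np.deg2rad(lat)
    sin_h0 = np.sin(np.deg2rad(h0))

    # start from approximate local noon +/- 6 h
    ut = 12.0 - lon / 15.0 + sign * 6.0
    cosw = np.zeros_like(ut)
    for _ in range(max(1, n_iter)):
        jd = jd0 + ut / 24.0
        decl, ra = _sun_position(jd)
        d = np.deg2rad(decl)
        with np.errstate(divide="ignore", invalid="ignore"):
            cosw = (sin_h0 - np.sin(phi) * np.sin(d)) / (np.cos(phi) * np.cos(d))
        w = np.rad2deg(np.arccos(np.clip(cosw, -1.0, 1.0)))
        h_target = sign * w
        h_now = _wrap180(_gmst_deg(jd) + lon - ra)
        ut = ut + _wrap180(h_target - h_now) / _SIDEREAL_DEG_PER_HOUR
    polar_day = cosw < -1.0
    polar_night = cosw > 1.0
    return ut, polar_day, polar_night


def predict_event_times(
    lon,
    lat,
    date: dt.date,
    h0: float = DEFAULT_TWILIGHT_DEG,
    n_iter: int = 3,
) -> EventTimes:
    """Predict sunrise and sunset (minutes UT) for positions on one day.

    Parameters
    ----------
    lon, lat
        Scalars or broadcastable arrays; lon in [-180, 180), |lat| <= 89.
    date
        Calendar day (UT).
    h0
        Twilight sun altitude in degrees, in [-18, 0].
    n_iter
        Hour-angle refinement iterations.  ``n_iter=1`` evaluates the solar
        position only at the provisional time (noon-style approximation);
        the default refines declination/right ascension at the event time.
    """
    if not (-18.0 <= h0 <= 0.0):
        raise ValueError(f"h0 must be within [-18, 0] deg, got {h0}")
    _check_epoch(dt.datetime(date.year, date.month, date.day))
    lat_arr = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat_arr) > 89.0):
        raise ValueError("latitudes beyond +/-89 deg are not supported")

    jd0 = _jd_midnight(date)
    ut_sr, pd1, pn1 = _solve_event(lon, lat, jd0, h0, -1, n_iter)
    ut_ss, pd2, pn2 = _solve_event(lon, lat, jd0, h0, +1, n_iter)

    polar_day = pd1 | pd2
    polar_night = pn1 | pn2
    status = np.where(
        polar_day, STATUS_POLAR_DAY, np.where(polar_night, STATUS_POLAR_NIGHT, STATUS_NORMAL)
    )
    sunrise = (ut_sr % 24.0) * 60.0
    sunset = (ut_ss % 24.0) * 60.0
    sunrise = np.where(status == STATUS_NORMAL, sunrise, np.nan)
    sunset = np.where(status == STATUS_NORMAL, sunset, np.nan)
    if np.ndim(lon) == 0 and np.ndim(lat) == 0:
        return EventTimes(float(sunrise), float(sunset), int(status))
    return EventTimes(sunrise, sunset, status)


def circular_residual_minutes(obs_min, pred_min):
    """Minimal signed residual obs - pred on the 1440-minute circle."""
    return (np.asarray(obs_min, dtype=float) - np.asarray(pred_min, dtype=float) + 720.0) % 1440.0 - 720.0


def event_log_likelihood(obs_min, pred_min, sigma_min: float, floor_nats: float = 8.0):
    """Gaussian log-density of an observed event time given a prediction.

    Residuals are taken on the circle.  Where ``pred_min`` is NaN (polar day
    or night at the candidate position) the contribution is floored at
    ``mode - floor_nats`` (default exp(-8), a ~4-sigma tail), strongly but
    not infinitely penalizing such positions.
    """
    if sigma_min <= 0:
        raise ValueError("sigma_min must be > 0")
    pred = np.asarray(pred_min, dtype=float)
    mode = -np.log(sigma_min * np.sqrt(2.0 * np.pi))
    r = circular_residual_minutes(obs_min, np.where(np.isnan(pred), 0.0, pred))
    ll = mode - 0.5 * (r / sigma_min) ** 2
    out = np.where(np.isnan(pred), mode - floor_nats, ll)
    if np.ndim(out) == 0:
        return float(out)
    return out
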