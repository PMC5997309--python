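"""Low-precision solar geometry (NOAA formulas).

Declination and equation of time are functions of day-of-year only, which keeps
the forward model (simulated twilight times) and the inverse model (threshold
geolocation) numerically consistent: a noise-free twilight pair inverts to the
position it was generated from, up to solver tolerance.

All angles are degrees unless noted; times are fractional UTC hours.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

__all__ = [
    "day_of_year",
    "solar_declination",
    "equation_of_time",
    "solar_noon_utc",
    "twilight_hour_angle",
    "twilight_times",
    "longitude_from_noon",
    "latitude_from_day_length",
    "equinox_dates",
]


def day_of_year(date: dt.date | np.ndarray) -> np.ndarray:
    """Ordinal day within the year (1 for 1 January)."""
    if isinstance(date, dt.date):
        return np.asarray(date.timetuple().tm_yday)
    dates = np.asarray(date, dtype="datetime64[D]")
    years = dates.astype("datetime64[Y]")
    return (dates - years).astype(int) + 1


def _fractional_year(doy) -> np.ndarray:
    # gamma in radians; mid-day convention (hour term fixed at 12 UTC)
    return 2.0 * np.pi / 365.0 * (np.asarray(doy, dtype=float) - 1.0)


def solar_declination(doy) -> np.ndarray:
    """Solar declination in degrees for a day of year."""
    g = _fractional_year(doy)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    return np.degrees(decl)


def equation_of_time(doy) -> np.ndarray:
    """Equation of time in minutes (apparent minus mean solar time)."""
    g = _fractional_year(doy)
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )


def solar_noon_utc(longitude, doy, apply_eot: bool = True) -> np.ndarray:
    """UTC hour of local apparent solar noon at a longitude."""
    eot = equation_of_time(doy) if apply_eot else 0.0
    return 12.0 - np.asarray(longitude, dtype=float) / 15.0 - eot / 60.0


def twilight_hour_angle(latitude, doy, sun_elevation: float) -> np.ndarray:
    """Half-day arc (degrees) at which the sun crosses ``sun_elevation``.

    NaN where the sun never crosses the elevation (polar day/night).
    """
    lat = np.radians(np.asarray(latitude, dtype=float))
    decl = np.radians(solar_declination(doy))
    h0 = np.radians(sun_elevation)
    cos_h = (np.sin(h0) - np.sin(lat) * np.sin(decl)) / (np.cos(lat) * np.cos(decl))
    cos_h = np.where(np.abs(cos_h) > 1.0, np.nan, cos_h)
    return np.degrees(np.arccos(cos_h))


def twilight_times(
    latitude,
    longitude,
    doy,
    sun_elevation: float = -3.0,
    apply_eot: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Dawn and dusk as fractional UTC hours for a position and day of year.

    Hours may fall outside [0, 24) near the date line; callers wanting
    wall-clock times should wrap modulo 24 while keeping the date anchored.
    Returns NaN pairs during polar day/night.
    """
    noon = solar_noon_utc(longitude, doy, apply_eot)
    ha = twilight_hour_angle(latitude, doy, sun_elevation)
    return noon - ha / 15.0, noon + ha / 15.0


def longitude_from_noon(noon_utc_hours, doy, apply_eot: bool = True) -> np.ndarray:
    """Longitude whose apparent solar noon falls at the given UTC hour."""
    eot = equation_of_time(doy) if apply_eot else 0.0
    lon = 15.0 * (12.0 - np.asarray(noon_utc_hours, dtype=float) - eot / 60.0)
    return (lon + 180.0) % 360.0 - 180.0


def latitude_from_day_length(
    day_length_hours,
    doy,
    sun_elevation: float = -3.0,
    lat_bounds: tuple[float, float] = (-85.0, 85.0),
    tol: float = 1e-10,
) -> np.ndarray:
    """Latitude consistent with an observed twilight-to-twilight day length.

    Solves cos H = (sin h0 - sin lat sin decl) / (cos lat cos decl) for
    latitude by bisection; day length is a monotone function of latitude for
    nonzero declination, so the root is unique when it exists. Returns NaN
    where no latitude in ``lat_bounds`` reproduces the day length (equinox
    indeterminacy or out-of-range geometry).
    """
    day_len = np.atleast_1d(np.asarray(day_length_hours, dtype=float))
    doy_arr = np.broadcast_to(np.atleast_1d(doy), day_len.shape).astype(float)
    decl = np.radians(solar_declination(doy_arr))
    h0 = np.radians(sun_elevation)
    cos_h_obs = np.cos(np.radians(day_len * 15.0 / 2.0))

    def g(lat_deg):
        lat = np.radians(lat_deg)
        return (np.sin(h0) - np.sin(lat) * np.sin(decl)) / (
            np.cos(lat) * np.cos(decl)
        ) - cos_h_obs

    lo = np.full_like(day_len, lat_bounds[0])
    hi = np.full_like(day_len, lat_bounds[1])
    g_lo = g(lo)
    g_hi = g(hi)
    solvable = np.isfinite(g_lo) & np.isfinite(g_hi) & (np.sign(g_lo) != np.sign(g_hi))
    # ~60 bisection steps shrink the 170-degree bracket below any practical tol
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        g_mid = g(mid)
        take_low = np.sign(g_mid) == np.sign(g_lo)
        lo = np.where(take_low, mid, lo)
        g_lo = np.where(take_low, g_mid, g_lo)
        hi = np.where(take_low, hi, mid)
        if np.all(hi - lo < tol):
            break
    out = np.where(solvable, 0.5 * (lo + hi), np.nan)
    return out if np.ndim(day_length_hours) else float(out[0])


def equinox_dates(year: int) -> tuple[dt.date, dt.date]:
    """March and September equinoxes of a year, from the declination zero-crossings."""
    days = np.arange(1, 366)
    decl = solar_declination(days)
    crossings = np.nonzero(np.diff(np.sign(decl)) != 0)[0]
    # first crossing is upward (March), second downward (September)
    result = []
    for idx in crossings[:2]:
        d0, d1 = decl[idx], decl[idx + 1]
        frac = -d0 / (d1 - d0)
        doy = days[idx] + frac
        result.append(dt.date(year, 1, 1) + dt.timedelta(days=float(doy) - 1))
    return result[0], result[1]
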