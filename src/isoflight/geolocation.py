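"""Threshold light-level geolocation and track filtering.

From archival-logger light series, twilights are detected at a fixed light
threshold (default 20) by linear interpolation between samples. Each
dawn/dusk pair yields one position: longitude from the offset of the
light-midday from apparent solar noon (equation of time applied), latitude
from the day length given the solar declination. The standard pathologies of
the method are handled as flags, never deletions:

* ``short_dark``   — dusk-to-dawn dark span under 4 h (device near constant
  daylight; transition unreliable)
* ``equinox``      — within 20 days of an equinox, where day length carries
  no latitude information
* ``latitude_indeterminate`` — no latitude solves the observed day length
* ``speed_reject`` — removed by the iterative forward/backward-averaging
  speed filter at the cohort's 95th-percentile maximum travel speed

Phenology (departure to and arrival from the non-breeding grounds) is scored
from colony distance with a directed-movement rule, falling back to the
saltwater-immersion "dry all night = in the burrow" rule when the positional
arrival is masked by an equinox gap.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import solar
from .space_use import haversine_km

__all__ = [
    "PhenologyDates",
    "detect_twilights",
    "drop_dark_days",
    "position_from_twilight_pair",
    "positions_from_twilights",
    "filter_transitions",
    "cohort_speed_threshold",
    "speed_filter",
    "nonbreeding_window",
]

LIGHT_THRESHOLD = 20.0


@dataclass
class PhenologyDates:
    """Departure/arrival of the non-breeding period for one bird."""

    bird_id: str
    status: str  # "migrant" or "resident"
    departure: dt.date | None = None
    arrival: dt.date | None = None
    arrival_method: str | None = None  # "positional" or "immersion"


def detect_twilights(
    light: pd.DataFrame, threshold: float = LIGHT_THRESHOLD
) -> pd.DataFrame:
    """Twilight events from a raw light series at a fixed threshold.

    ``light`` needs columns timestamp_utc (monotone) and light. Each upward
    crossing of the threshold is a dawn, each downward crossing a dusk, with
    the crossing time linearly interpolated between the bracketing samples.
    """
    t = pd.to_datetime(light["timestamp_utc"]).to_numpy()
    y = light["light"].to_numpy(dtype=float)
    if len(y) < 2:
        return pd.DataFrame(columns=["time", "kind"])
    if np.all(y == y[0]):
        warnings.warn("constant light series: no twilights detected")
        return pd.DataFrame(columns=["time", "kind"])
    above = y >= threshold
    change = np.nonzero(above[1:] != above[:-1])[0]
    rows = []
    for i in change:
        frac = (threshold - y[i]) / (y[i + 1] - y[i])
        when = t[i] + frac * (t[i + 1] - t[i])
        rows.append({"time": when, "kind": "dawn" if above[i + 1] else "dusk"})
    return pd.DataFrame(rows)


def drop_dark_days(light: pd.DataFrame, threshold: float = LIGHT_THRESHOLD) -> pd.DataFrame:
    """Drop whole days whose maximum light never reaches the threshold.

    Used to exclude incubation shifts spent inside the burrow, where the
    logger records darkness around the clock.
    """
    ts = pd.to_datetime(light["timestamp_utc"])
    daymax = light.groupby(ts.dt.date)["light"].transform("max")
    return light[daymax >= threshold].reset_index(drop=True)


def _hours_since(day: np.datetime64, when) -> float:
    return (np.datetime64(when, "s") - np.datetime64(day, "s")) / np.timedelta64(1, "h")


def position_from_twilight_pair(
    dawn,
    dusk,
    sun_elevation: float = -3.0,
    apply_eot: bool = True,
    min_half_day_offset_deg: float = 0.5,
) -> tuple[float, float, set[str]]:
    """(longitude, latitude, flags) from one dawn/dusk pair.

    Longitude comes from the midpoint of the pair versus apparent solar noon;
    latitude from the day length and the day's solar declination. When the
    geometry pins no latitude (day length indistinguishable from the
    equinoctial half-day) the ``latitude_indeterminate`` flag is set and
    latitude is NaN; longitude is always returned.
    """
    dawn = np.datetime64(dawn, "s")
    dusk = np.datetime64(dusk, "s")
    if dusk <= dawn:
        raise ValueError("dusk must follow dawn")
    day = dawn.astype("datetime64[D]")
    doy = int(solar.day_of_year(np.asarray(day)))
    dawn_h = _hours_since(day, dawn)
    dusk_h = _hours_since(day, dusk)
    lon = float(solar.longitude_from_noon(0.5 * (dawn_h + dusk_h), doy, apply_eot))
    flags: set[str] = set()
    lat = solar.latitude_from_day_length(dusk_h - dawn_h, doy, sun_elevation)
    if not np.isfinite(lat):
        flags.add("latitude_indeterminate")
        lat = float("nan")
    else:
        # a solution on the search boundary means the geometry did not pin it
        if abs(lat) > 85.0 - min_half_day_offset_deg:
            flags.add("latitude_indeterminate")
            lat = float("nan")
        else:
            lat = float(lat)
    return lon, lat, flags


def positions_from_twilights(
    twilights: pd.DataFrame,
    sun_elevation: float = -3.0,
    apply_eot: bool = True,
) -> pd.DataFrame:
    """Daily midday positions from a per-day dawn/dusk table.

    ``twilights`` needs columns bird_id, date, dawn_utc, dusk_utc (the layout
    the synthetic generator writes). Rows with missing twilights are skipped.
    One position per day is produced (the midday fix); flags are
    semicolon-joined in the ``flags`` column.
    """
    rows = []
    for rec in twilights.itertuples(index=False):
        if pd.isna(rec.dawn_utc) or pd.isna(rec.dusk_utc):
            continue
        dawn = np.datetime64(rec.dawn_utc, "s")
        dusk = np.datetime64(rec.dusk_utc, "s")
        if dusk <= dawn:
            continue
        lon, lat, flags = position_from_twilight_pair(dawn, dusk, sun_elevation, apply_eot)
        rows.append(
            {
                "bird_id": rec.bird_id,
                "date": pd.Timestamp(rec.date),
                "timestamp_utc": pd.Timestamp(dawn + (dusk - dawn) // 2),
                "kind": "midday",
                "lon": lon,
                "lat": lat,
                "flags": ";".join(sorted(flags)),
            }
        )
    return pd.DataFrame(rows)


def _nearest_equinox_distance(dates: pd.Series) -> np.ndarray:
    """Days to the nearest equinox for each date (absolute)."""
    dates = pd.to_datetime(dates)
    out = np.empty(len(dates), dtype=float)
    eq_cache: dict[int, list[np.datetime64]] = {}
    arr = dates.to_numpy().astype("datetime64[D]")
    for i, d in enumerate(arr):
        year = d.astype("datetime64[Y]").astype(int) + 1970
        cands = []
        for y in (year - 1, year, year + 1):
            if y not in eq_cache:
                eq_cache[y] = [np.datetime64(e, "D") for e in solar.equinox_dates(y)]
            cands.extend(eq_cache[y])
        out[i] = min(abs((d - e).astype(int)) for e in cands)
    return out


def filter_transitions(
    positions: pd.DataFrame,
    twilights: pd.DataFrame | None = None,
    min_dark_hours: float = 4.0,
    equinox_window_days: int = 20,
) -> pd.DataFrame:
    """Flag positions with short dark spans or near-equinox dates.

    ``short_dark``: the dusk-to-next-dawn span (from ``twilights``, if given)
    is under ``min_dark_hours``. ``equinox``: the date lies within
    ``equinox_window_days`` of an equinox (boundary inclusive). Flagged rows
    keep their longitude but lose latitude credibility downstream; nothing is
    deleted.
    """
    pos = positions.copy()
    flags = [set(f.split(";")) - {""} for f in pos.get("flags", pd.Series([""] * len(pos)))]

    near = _nearest_equinox_distance(pos["date"]) <= equinox_window_days
    for i, hit in enumerate(near):
        if hit:
            flags[i].add("equinox")

    if twilights is not None and len(twilights):
        tw = twilights.dropna(subset=["dawn_utc", "dusk_utc"]).sort_values("date")
        dark = {}
        prev_dusk = None
        for rec in tw.itertuples(index=False):
            if prev_dusk is not None:
                span = (np.datetime64(rec.dawn_utc, "s") - prev_dusk) / np.timedelta64(1, "h")
                dark[pd.Timestamp(rec.date)] = span
            prev_dusk = np.datetime64(rec.dusk_utc, "s")
        for i, d in enumerate(pd.to_datetime(pos["date"])):
            span = dark.get(pd.Timestamp(d))
            if span is not None and span < min_dark_hours:
                flags[i].add("short_dark")

    pos["flags"] = [";".join(sorted(f)) for f in flags]
    return pos


def _fb_speeds(lons, lats, days) -> np.ndarray:
    """Forward/backward-averaged speed (km/day) at each retained fix."""
    n = len(lons)
    seg = haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:]) / np.maximum(
        np.diff(days), 1e-9
    )
    v = np.zeros(n)
    if n == 1:
        return v
    v[0] = seg[0]
    v[-1] = seg[-1]
    if n > 2:
        v[1:-1] = 0.5 * (seg[:-1] + seg[1:])
    return v


def cohort_speed_threshold(tracks: list[pd.DataFrame], percentile: float = 95.0) -> float:
    """Rejection threshold: the ``percentile`` of per-bird maximum travel speeds.

    Each track contributes its own maximum consecutive-fix speed (km/day over
    usable, unflagged fixes); the threshold is the cohort percentile of those
    maxima. With a single bird the percentile degenerates to that bird's
    maximum.
    """
    maxima = []
    for trk in tracks:
        ok = _usable(trk)
        if ok.sum() < 2:
            continue
        sub = trk[ok]
        days = pd.to_datetime(sub["date"]).map(pd.Timestamp.toordinal).to_numpy(dtype=float)
        seg = haversine_km(
            sub["lon"].to_numpy()[:-1],
            sub["lat"].to_numpy()[:-1],
            sub["lon"].to_numpy()[1:],
            sub["lat"].to_numpy()[1:],
        ) / np.maximum(np.diff(days), 1e-9)
        if seg.size:
            maxima.append(seg.max())
    if not maxima:
        raise ValueError("no usable track segments in cohort")
    return float(np.percentile(maxima, percentile))


def _usable(trk: pd.DataFrame) -> pd.Series:
    f = trk.get("flags", pd.Series([""] * len(trk), index=trk.index)).fillna("")
    bad = f.str.contains("equinox|speed_reject|latitude_indeterminate|short_dark")
    return trk["lat"].notna() & ~bad


def speed_filter(
    track: pd.DataFrame,
    threshold_km_day: float,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Iteratively flag the worst over-speed fix until none exceeds the threshold.

    At each pass, forward/backward-averaged speeds over currently retained
    fixes are recomputed and the single fastest fix above ``threshold_km_day``
    gains a ``speed_reject`` flag. Removals are flags only; the input rows
    are all preserved.
    """
    trk = track.copy().reset_index(drop=True)
    if _usable(trk).sum() < 3:
        raise ValueError("track exhausted: fewer than 3 usable positions")
    flags = [set(f.split(";")) - {""} for f in trk.get("flags", pd.Series([""] * len(trk)))]
    for _ in range(max_iter):
        keep = np.array(
            [
                bool(trk["lat"].notna().iloc[i])
                and not (flags[i] & {"equinox", "latitude_indeterminate", "short_dark", "speed_reject"})
                for i in range(len(trk))
            ]
        )
        idx = np.nonzero(keep)[0]
        if idx.size < 3:
            raise ValueError("track exhausted by speed filter")
        days = (
            pd.to_datetime(trk["date"]).iloc[idx].map(pd.Timestamp.toordinal).to_numpy(dtype=float)
        )
        v = _fb_speeds(
            trk["lon"].to_numpy()[idx], trk["lat"].to_numpy()[idx], days
        )
        worst = int(np.argmax(v))
        if v[worst] <= threshold_km_day:
            break
        flags[idx[worst]].add("speed_reject")
    trk["flags"] = [";".join(sorted(f)) for f in flags]
    return trk


def _runs_of_monotone(dist: np.ndarray, increasing: bool) -> np.ndarray:
    """Length of the (strictly) monotone run starting at each index."""
    n = len(dist)
    runs = np.ones(n, dtype=int)
    for i in range(n - 2, -1, -1):
        step_ok = dist[i + 1] > dist[i] if increasing else dist[i + 1] < dist[i]
        runs[i] = runs[i + 1] + 1 if step_ok else 1
    return runs


def nonbreeding_window(
    track: pd.DataFrame,
    colony_lon: float,
    colony_lat: float,
    immersion: pd.DataFrame | None = None,
    radius_km: float = 200.0,
    directed_days: int = 3,
    min_trip_days: int = 30,
) -> PhenologyDates:
    """Departure and arrival dates of the non-breeding trip.

    Departure: first date outside the colony radius followed by at least
    ``directed_days`` consecutive days of increasing colony distance.
    Arrival: first date back inside the radius preceded by the mirrored
    directed approach. If no positional arrival is found (e.g. the return is
    masked by an equinox gap), the first post-departure all-dry night in the
    immersion record is used instead (``arrival_method="immersion"``).
    """
    bird = str(track["bird_id"].iloc[0]) if len(track) else "unknown"
    ok = _usable(track)
    sub = track[ok].sort_values("date")
    if len(sub) < directed_days + 2:
        raise ValueError("track too short for phenology detection")
    dates = pd.to_datetime(sub["date"]).dt.date.to_numpy()
    dist = haversine_km(
        sub["lon"].to_numpy(), sub["lat"].to_numpy(), colony_lon, colony_lat
    )
    outside = dist > radius_km
    inc_runs = _runs_of_monotone(dist, increasing=True)

    departure = None
    for i in range(len(sub)):
        if outside[i] and inc_runs[min(i, len(sub) - 1)] >= directed_days:
            departure = dates[i]
            break
    if departure is None:
        return PhenologyDates(bird_id=bird, status="resident")

    arrival = None
    for i in range(len(sub)):
        if dates[i] <= departure + dt.timedelta(days=min_trip_days):
            continue
        if not outside[i]:
            # count decreasing steps ending at i
            j = i
            steps = 0
            while j > 0 and dist[j] < dist[j - 1]:
                steps += 1
                j -= 1
            if steps >= directed_days:
                arrival = dates[i]
                break
    if arrival is not None:
        return PhenologyDates(bird, "migrant", departure, arrival, "positional")

    if immersion is not None and len(immersion):
        arr = _first_all_dry_night(immersion, departure + dt.timedelta(days=min_trip_days))
        if arr is not None:
            return PhenologyDates(bird, "migrant", departure, arr, "immersion")
    return PhenologyDates(bird, "migrant", departure, None, None)


def _first_all_dry_night(
    immersion: pd.DataFrame,
    after: dt.date,
    night_start_hour: int = 22,
    night_end_hour: int = 4,
) -> dt.date | None:
    """First date after ``after`` whose night block is entirely dry (wet_count 0).

    The night block is the UTC window [night_start_hour, night_end_hour);
    colony attendance in this system is nocturnal, so an all-dry night means
    the bird sat in the burrow rather than on the water.
    """
    ts = pd.to_datetime(immersion["timestamp_utc"])
    hours = ts.dt.hour
    night = (hours >= night_start_hour) | (hours < night_end_hour)
    # assign night records to the morning date so a night spans one label
    night_date = (ts + pd.Timedelta(hours=24 - night_start_hour)).dt.date
    sub = immersion[night]
    grouped = sub.groupby(night_date[night])["wet_count"].max()
    for date, wet in grouped.items():
        if date > after and wet == 0:
            return date
    return None
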