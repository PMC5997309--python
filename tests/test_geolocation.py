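"""Threshold geolocation: twilight detection, position inversion against the
forward solar model, the dark-span/equinox exclusions at their exact
boundaries, the iterative speed filter, and phenology detection including the
dry-night immersion fallback."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from isoflight import geolocation as geo
from isoflight import solar
from isoflight import synthetic as syn
from isoflight.space_use import haversine_km


def _square_wave_day(date="2012-06-01", dawn_h=6, dusk_h=18, step_min=10):
    times = pd.date_range(f"{date} 00:00", f"{date} 23:50", freq=f"{step_min}min")
    light = np.where((times.hour >= dawn_h) & (times.hour < dusk_h), 64.0, 0.0)
    return pd.DataFrame({"timestamp_utc": times, "light": light})


class TestDetectTwilights:
    def test_square_wave_yields_one_dawn_one_dusk(self):
        ev = geo.detect_twilights(_square_wave_day())
        assert list(ev["kind"]) == ["dawn", "dusk"]

    def test_crossing_time_linearly_interpolated(self):
        # light steps 0 -> 64 between 05:50 and 06:00; threshold 20 crosses
        # at 20/64 of the interval
        ev = geo.detect_twilights(_square_wave_day())
        dawn = pd.Timestamp(ev.loc[ev["kind"] == "dawn", "time"].iloc[0])
        expect = pd.Timestamp("2012-06-01 05:50") + pd.Timedelta(minutes=10 * 20 / 64)
        assert abs((dawn - expect).total_seconds()) < 1.0

    def test_all_dark_series_empty(self):
        df = _square_wave_day()
        df["light"] = 0.0
        df.loc[0, "light"] = 1.0  # non-constant but never crossing
        assert len(geo.detect_twilights(df)) == 0

    def test_constant_series_warns(self):
        df = _square_wave_day()
        df["light"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            geo.detect_twilights(df)

    def test_burrow_days_dropped(self):
        bright = _square_wave_day("2012-06-01")
        dark = _square_wave_day("2012-06-02")
        dark["light"] = np.minimum(dark["light"], 10.0)
        kept = geo.drop_dark_days(pd.concat([bright, dark], ignore_index=True))
        assert set(pd.to_datetime(kept["timestamp_utc"]).dt.day) == {1}


class TestPositionInversion:
    def test_symmetric_pair_at_greenwich(self):
        lon, lat, flags = geo.position_from_twilight_pair(
            "2012-06-21T06:00", "2012-06-21T18:00", apply_eot=False
        )
        assert lon == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_recovers_position_within_half_degree(self):
        # forward model at (20 N, 30 W) on 21 June, no noise
        doy = solar.day_of_year(dt.date(2012, 6, 21))
        dawn, dusk = solar.twilight_times(20.0, -30.0, doy)
        day = np.datetime64("2012-06-21", "s")
        to_t = lambda h: day + np.timedelta64(int(round(h * 3600)), "s")
        lon, lat, flags = geo.position_from_twilight_pair(to_t(dawn), to_t(dusk))
        assert lon == pytest.approx(-30.0, abs=0.5)
        assert lat == pytest.approx(20.0, abs=0.5)
        assert not flags

    def test_equinoctial_day_length_flags_latitude(self):
        lon, lat, flags = geo.position_from_twilight_pair(
            "2012-03-20T06:14", "2012-03-20T18:14"  # 12 h around an equinox
        )
        assert "latitude_indeterminate" in flags
        assert np.isnan(lat)
        assert np.isfinite(lon)

    def test_dusk_before_dawn_rejected(self):
        with pytest.raises(ValueError):
            geo.position_from_twilight_pair("2012-06-21T18:00", "2012-06-21T06:00")

    def test_noise_free_latitude_rmse_below_tenth_degree(self, small_tracks):
        track = small_tracks[0]
        tw = syn.simulate_twilights(track, noise_sd_min=0.0)
        pos = geo.filter_transitions(geo.positions_from_twilights(tw), tw)
        truth = track.positions_frame()
        truth["date"] = pd.to_datetime(truth["date"])
        m = pos.merge(truth, on="date", suffixes=("_est", "_true"))
        clean = m[m["flags"] == ""]
        assert len(clean) > 50
        rmse = np.sqrt(((clean["lat_est"] - clean["lat_true"]) ** 2).mean())
        assert rmse < 0.1


class TestTransitionFilters:
    def _positions(self, dates):
        return pd.DataFrame(
            {
                "bird_id": "b",
                "date": pd.to_datetime(dates),
                "lon": 0.0,
                "lat": 10.0,
                "flags": "",
            }
        )

    def test_short_dark_boundary_under_four_hours(self):
        tw = pd.DataFrame(
            {
                "bird_id": "b",
                "date": pd.to_datetime(["2012-06-01", "2012-06-02", "2012-06-03"]),
                "dawn_utc": pd.to_datetime(
                    ["2012-06-01 06:00", "2012-06-02 02:59", "2012-06-03 06:01"]
                ),
                "dusk_utc": pd.to_datetime(
                    ["2012-06-01 23:00", "2012-06-02 22:00", "2012-06-03 20:00"]
                ),
            }
        )
        pos = self._positions(["2012-06-01", "2012-06-02", "2012-06-03"])
        out = geo.filter_transitions(pos, tw)
        # dark span before 2 June dawn = 3 h 59 m -> flagged; before 3 June = 8 h 01 m -> kept
        assert "short_dark" in out.loc[1, "flags"]
        assert "short_dark" not in out.loc[2, "flags"]

    def test_equinox_window_boundary_inclusive_at_twenty_days(self):
        out = geo.filter_transitions(
            self._positions(["2012-03-20", "2012-04-09", "2012-04-10"])
        )
        assert "equinox" in out.loc[0, "flags"]  # the equinox itself
        assert "equinox" in out.loc[1, "flags"]  # exactly 20 days after
        assert "equinox" not in out.loc[2, "flags"]  # 21 days after


class TestSpeedFilter:
    def _track(self, n=30, lat=5.0):
        return pd.DataFrame(
            {
                "bird_id": "b",
                "date": pd.date_range("2012-01-01", periods=n),
                "lon": np.linspace(-20.0, -21.0, n),
                "lat": np.full(n, lat),
                "flags": "",
            }
        )

    def test_stationary_track_unflagged(self):
        out = geo.speed_filter(self._track(), 500.0)
        assert (out["flags"] == "").all()

    def test_single_teleported_fix_flagged(self):
        trk = self._track()
        trk.loc[15, "lat"] = 50.0  # ~5000 km jump
        out = geo.speed_filter(trk, 500.0)
        flagged = out.index[out["flags"].str.contains("speed_reject")]
        assert list(flagged) == [15]

    def test_idempotent(self):
        trk = self._track()
        trk.loc[15, "lat"] = 50.0
        once = geo.speed_filter(trk, 500.0)
        twice = geo.speed_filter(once, 500.0)
        assert (once["flags"] == twice["flags"]).all()

    def test_threshold_above_all_speeds_vacuous(self):
        trk = self._track()
        trk.loc[15, "lat"] = 50.0
        out = geo.speed_filter(trk, 1e9)
        assert (out["flags"] == "").all()

    def test_exhausted_track_raises(self):
        trk = self._track(n=4)
        trk["lat"] = np.nan
        with pytest.raises(ValueError, match="exhausted"):
            geo.speed_filter(trk, 500.0)

    def test_flags_preserve_rows(self):
        trk = self._track()
        trk.loc[15, "lat"] = 50.0
        out = geo.speed_filter(trk, 500.0)
        assert len(out) == len(trk)  # removals are flags, not deletions
        assert (out["lat"] == trk["lat"]).all()

    def test_cohort_threshold_is_percentile_of_per_bird_maxima(self):
        tracks = []
        for vmax in (100.0, 200.0, 300.0, 400.0):
            t = self._track()
            # one step of vmax km/day: move along a meridian by vmax/111.19 deg
            t.loc[10, "lat"] = t.loc[9, "lat"] + vmax / 111.19
            t.loc[11:, "lat"] = t.loc[10, "lat"]
            tracks.append(t)
        thr = geo.cohort_speed_threshold(tracks, percentile=95.0)
        maxima = [100.0, 200.0, 300.0, 400.0]
        assert thr == pytest.approx(np.percentile(maxima, 95), rel=0.05)


@pytest.fixture(scope="module")
def estimated(small_tracks):
    track = small_tracks[0]
    tw = syn.simulate_twilights(track, noise_sd_min=0.0)
    pos = geo.filter_transitions(geo.positions_from_twilights(tw), tw)
    return track, pos


class TestPhenology:
    def test_scripted_departure_recovered_within_two_days(self, estimated):
        track, pos = estimated
        ph = geo.nonbreeding_window(pos, track.colony.longitude, track.colony.latitude)
        assert ph.status == "migrant"
        assert abs((ph.departure - track.departure).days) <= 2

    def test_resident_bird_yields_resident_result(self):
        pos = pd.DataFrame(
            {
                "bird_id": "stay",
                "date": pd.date_range("2012-06-01", periods=40),
                "lon": -25.17 + 0.01 * np.sin(np.arange(40)),
                "lat": 36.94 + 0.01 * np.cos(np.arange(40)),
                "flags": "",
            }
        )
        ph = geo.nonbreeding_window(pos, -25.17, 36.94)
        assert ph.status == "resident"
        assert ph.departure is None and ph.arrival is None

    def test_equinox_masked_return_uses_dry_night(self, estimated):
        track, pos = estimated
        # mask all positional fixes after mid-trip: forces the immersion rule
        cut = pd.Timestamp(track.departure + dt.timedelta(days=80))
        masked = pos.copy()
        masked.loc[pd.to_datetime(masked["date"]) >= cut, "flags"] = "equinox"
        imm = syn.simulate_immersion(track, rng_seed=4)
        ph = geo.nonbreeding_window(
            masked, track.colony.longitude, track.colony.latitude, immersion=imm
        )
        assert ph.arrival_method == "immersion"
        assert abs((ph.arrival - track.arrival).days) <= 2
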