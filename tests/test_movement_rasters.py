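import numpy as np
import pytest

from darkfleet import geo
from darkfleet.rasters import (
    DT_OFFSETS_MIN,
    RASTER_CLASSES,
    RasterKey,
    all_keys,
    build_raster_set,
    dt_bin,
    extrapolated_origin,
    pixel_width,
    raster_extent_km,
    relative_displacement,
    speed_bin,
)
from darkfleet.simulate import SimConfig, simulate_tracks

from conftest import make_ping, make_track


class TestPixelWidth:
    @pytest.mark.parametrize(
        "dm,expected_px_km,expected_extent_km",
        [
            (10.0, 0.010, 10.0),    # 10 m pixels, 10 km raster
            (0.5, 0.001, 1.0),      # sub-minute: 1 m pixels, 1 km raster
            (448.0, 0.448, 448.0),
        ],
    )
    def test_scaling(self, dm, expected_px_km, expected_extent_km):
        assert pixel_width(dm) == pytest.approx(expected_px_km)
        assert raster_extent_km(dm) == pytest.approx(expected_extent_km)

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            pixel_width(bad)


class TestBins:
    def test_full_key_set_is_1296(self):
        keys = all_keys()
        assert len(keys) == 1296
        assert len(set(keys)) == 1296
        assert len(RASTER_CLASSES) == 6
        assert len(DT_OFFSETS_MIN) == 36

    @pytest.mark.parametrize("sog,center", [(0.5, 1.0), (3.9, 3.0), (9.0, 9.0), (25.0, 12.5)])
    def test_speed_bins(self, sog, center):
        assert speed_bin(sog) == center

    @pytest.mark.parametrize("dt,center", [(10.0, 10.0), (-9.0, -10.0), (100.0, 112.0), (0.6, 0.5)])
    def test_dt_bins_nearest_in_log_space(self, dt, center):
        assert dt_bin(dt) == center

    def test_dt_zero_and_overlong_unbinned(self):
        assert dt_bin(0.0) is None
        assert dt_bin(1000.0) is None
        assert dt_bin(1000.0, clamp=True) == 448.0


class TestExtrapolatedOrigin:
    def test_seven_knots_112_minutes(self):
        # the canonical worked example: 7 kn for 112 min is 13.07 nmi ahead
        ping = make_ping(sog=7.0, cog=90.0)
        lat, lon = extrapolated_origin(ping, 112.0)
        d_nmi = geo.km_to_nmi(geo.haversine_km(ping.lat, ping.lon, lat, lon))
        assert d_nmi == pytest.approx(7.0 * 112.0 / 60.0, abs=1e-6)
        assert lon > ping.lon and abs(lat - ping.lat) < 1e-6

    def test_zero_speed_stays_put(self):
        ping = make_ping(sog=0.0)
        lat, lon = extrapolated_origin(ping, 448.0)
        assert (lat, lon) == pytest.approx((ping.lat, ping.lon))

    def test_negative_offset_goes_backward(self):
        ping = make_ping(sog=10.0, cog=0.0)
        lat, lon = extrapolated_origin(ping, -30.0)
        d_nmi = geo.km_to_nmi(geo.haversine_km(ping.lat, ping.lon, lat, lon))
        assert d_nmi == pytest.approx(5.0, abs=1e-6)
        assert lat < ping.lat  # behind a north-bound vessel


class TestRelativeDisplacement:
    def test_extrapolated_point_maps_to_frame_origin(self):
        ping = make_ping(sog=6.0, cog=37.0)
        olat, olon = extrapolated_origin(ping, 20.0)
        x, y = relative_displacement(ping, 20.0, olat, olon)
        assert float(x) == pytest.approx(0.0, abs=1e-9)
        assert float(y) == pytest.approx(0.0, abs=1e-9)

    def test_one_km_further_along_course_is_plus_x(self):
        ping = make_ping(sog=5.0, cog=90.0)
        olat, olon = extrapolated_origin(ping, 10.0)
        plat, plon = geo.destination(olat, olon, 90.0, 1.0)
        x, y = relative_displacement(ping, 10.0, plat, plon)
        assert float(x) == pytest.approx(1.0, abs=1e-6)
        assert float(y) == pytest.approx(0.0, abs=1e-6)

    def test_starboard_is_negative_y(self):
        # y is positive to port (right-handed frame with x forward)
        ping = make_ping(sog=5.0, cog=0.0)
        olat, olon = extrapolated_origin(ping, 10.0)
        plat, plon = geo.destination(olat, olon, 90.0, 1.0)  # starboard of north
        x, y = relative_displacement(ping, 10.0, plat, plon)
        assert float(x) == pytest.approx(0.0, abs=1e-6)
        assert float(y) == pytest.approx(-1.0, abs=1e-6)


def _straight_tracks(n=30, sog=5.0, cog=45.0, interval_min=10.0, n_pings=8):
    """Vessels moving dead straight at constant speed: extrapolation exact."""
    tracks = []
    for i in range(n):
        lat0, lon0 = 1.0 + 0.1 * i, 2.0
        pings = []
        for k in range(n_pings):
            d_km = geo.nmi_to_km(sog * interval_min * k / 60.0)
            lat, lon = geo.destination(lat0, lon0, cog, d_km)
            pings.append(
                make_ping(vessel_id=f"2{i:08d}", minutes=interval_min * k,
                          lat=float(lat), lon=float(lon), sog=sog, cog=cog)
            )
        tracks.append(make_track(pings))
    return tracks


class TestBuildRasterSet:
    def test_straight_line_fleet_concentrates_mass_at_centre(self):
        tracks = _straight_tracks()
        rs = build_raster_set(
            tracks, keys=[RasterKey("drifting_longline", 5.0, 10.0)],
            min_samples=10, n_pixels=51, smooth_px=0.0,
        )
        r = rs.get(RasterKey("drifting_longline", 5.0, 10.0))
        assert r.n_samples > 100
        center = r.grid[25, 25] * r.da
        assert center == pytest.approx(1.0, abs=1e-9)

    def test_rasters_are_normalized(self, small_rasters):
        owned = [r for r in small_rasters.values() if r.fallback_from is None and r.n_samples > 0]
        assert owned, "no trained rasters"
        for r in owned:
            assert r.total_mass() == pytest.approx(1.0, abs=1e-6)

    def test_rotation_invariance_of_relative_frame(self):
        # the same manoeuvres rotated 90 degrees give the same raster
        def zigzag(base_cog):
            pings = []
            lat, lon = 0.5, 0.5
            for k in range(40):
                cog = (base_cog + (15.0 if k % 2 else -15.0)) % 360.0
                pings.append(make_ping(vessel_id="212345678", minutes=10.0 * k,
                                       lat=float(lat), lon=float(lon), sog=5.0, cog=cog))
                lat, lon = geo.destination(lat, lon, cog, geo.nmi_to_km(5.0 * 10 / 60))
                lat, lon = float(lat), float(lon)
            return [make_track(pings)]

        key = RasterKey("drifting_longline", 5.0, 10.0)
        rs_a = build_raster_set(zigzag(0.0), keys=[key], min_samples=5, n_pixels=41, smooth_px=0)
        rs_b = build_raster_set(zigzag(90.0), keys=[key], min_samples=5, n_pixels=41, smooth_px=0)
        assert np.allclose(rs_a.get(key).grid, rs_b.get(key).grid, atol=1e-6)

    def test_spread_grows_with_time_offset(self):
        cfg = SimConfig(n_vessels=60, duration_hours=24, dark_fraction=0.0,
                        ping_interval_min=10.0, gap_prob=0.0, seed=3)
        world = simulate_tracks(cfg)
        rs = build_raster_set(world.tracks, keys=all_keys(), min_samples=100, n_pixels=101)
        spreads = {}
        for dt in (10.0, 40.0, 112.0):
            key = RasterKey("drifting_longline", 5.0, dt)
            r = rs.get(key)
            if r.fallback_from is not None or r.n_samples < 100:
                continue
            c = r.axis_centers()
            xx, yy = np.meshgrid(c, c)
            spreads[dt] = float((r.grid * (xx**2 + yy**2)).sum() * r.da)
        assert len(spreads) >= 2
        dts = sorted(spreads)
        assert all(spreads[a] < spreads[b] for a, b in zip(dts, dts[1:]))

    def test_sparse_keys_borrow_and_are_flagged(self):
        tracks = _straight_tracks(n=5, n_pings=4)
        keys = [RasterKey("drifting_longline", 5.0, 10.0), RasterKey("drifting_longline", 9.0, 10.0)]
        rs = build_raster_set(tracks, keys=keys, min_samples=10, n_pixels=31)
        donor = rs.get(keys[0])
        borrowed = rs.get(keys[1])
        assert donor.fallback_from is None
        assert borrowed.sparse and borrowed.fallback_from == keys[0]
        assert borrowed.grid is donor.grid


class TestRasterStore:
    def test_round_trip_is_bitwise(self, tmp_path):
        tracks = _straight_tracks(n=10)
        keys = [RasterKey("drifting_longline", 5.0, 10.0), RasterKey("drifting_longline", 5.0, -10.0)]
        rs = build_raster_set(tracks, keys=keys, min_samples=5, n_pixels=31)
        rs.save(tmp_path / "store")
        rs2 = type(rs).load(tmp_path / "store")
        for k in keys:
            a, b = rs.get(k), rs2.get(k)
            assert np.array_equal(a.grid, b.grid)
            assert a.pixel_width_km == b.pixel_width_km
            assert a.n_samples == b.n_samples

    def test_missing_key_is_explicit_error(self, tmp_path):
        tracks = _straight_tracks(n=5)
        key = RasterKey("drifting_longline", 5.0, 10.0)
        rs = build_raster_set(tracks, keys=[key], min_samples=5, n_pixels=31)
        with pytest.raises(KeyError):
            rs.get(RasterKey("tug", 1.0, 0.5))

    def test_corrupt_manifest_shape_refused(self, tmp_path):
        import json

        tracks = _straight_tracks(n=5)
        key = RasterKey("drifting_longline", 5.0, 10.0)
        rs = build_raster_set(tracks, keys=[key], min_samples=5, n_pixels=31)
        rs.save(tmp_path / "store")
        mpath = tmp_path / "store" / "manifest.json"
        manifest = json.loads(mpath.read_text())
        manifest["entries"][0]["shape"] = [7, 7]
        mpath.write_text(json.dumps(manifest))
        with pytest.raises(ValueError):
            rs.load(tmp_path / "store")

    def test_version_mismatch_refused(self, tmp_path):
        import json

        tracks = _straight_tracks(n=5)
        key = RasterKey("drifting_longline", 5.0, 10.0)
        rs = build_raster_set(tracks, keys=[key], min_samples=5, n_pixels=31)
        rs.save(tmp_path / "store")
        mpath = tmp_path / "store" / "manifest.json"
        manifest = json.loads(mpath.read_text())
        manifest["version"] = 999
        mpath.write_text(json.dumps(manifest))
        with pytest.raises(ValueError):
            rs.load(tmp_path / "store")
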