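import numpy as np
import pandas as pd
import pytest
import shapely

from darkfleet import geo
from darkfleet.ais import PingRecord, VesselRecord, VesselTrack
from darkfleet.rasters import build_raster_set
from darkfleet.scenes import Scene
from darkfleet.simulate import SimConfig, simulate_world

T0 = pd.Timestamp("2020-01-01T12:00:00Z")


def make_ping(vessel_id="412000001", minutes=0.0, lat=0.0, lon=0.0, sog=5.0, cog=0.0):
    return PingRecord(
        vessel_id=vessel_id, t=T0 + pd.Timedelta(minutes=minutes),
        lat=lat, lon=lon, sog=sog, cog=cog,
    )


def make_track(pings, vclass="drifting_longline", length_m=35.0, names=()):
    vid = pings[0].vessel_id
    rec = VesselRecord(vessel_id=vid, vclass=vclass, length_m=length_m, names_seen=list(names))
    return VesselTrack(vessel=rec, pings=list(pings))


def square_scene(scene_id="S0", t=T0, center=(0.0, 0.0), half_km=200.0):
    """Square footprint centred at (lat, lon) with the given half-width."""
    lat0, lon0 = center
    e = np.array([-half_km, half_km, half_km, -half_km])
    n = np.array([-half_km, -half_km, half_km, half_km])
    lat, lon = geo.from_local_en(lat0, lon0, e, n)
    return Scene(scene_id=scene_id, t=t, footprint=shapely.Polygon(np.column_stack([lon, lat])))


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by matching/pipeline tests."""
    cfg = SimConfig(n_vessels=120, n_scenes=3, duration_hours=24, seed=1)
    return simulate_world(cfg)


@pytest.fixture(scope="session")
def small_rasters(small_world):
    return build_raster_set(
        small_world.world.tracks, min_samples=200, n_pixels=150
    )
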