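"""Synthetic worlds with known ground truth.

Generates a fleet of correlated-random-walk vessels (a fraction of them
dark, i.e. never broadcasting), AIS pings with realistic intervals and
occasional multi-hour gaps, square radar scenes, and detections drawn from
the observation model the estimator assumes: detection is Bernoulli in a
length-dependent rate (linear ramp up to a 60 m plateau), radar length is
lognormal around true length, and false detections arrive as a uniform
Poisson field over the footprint.

Everything is reproducible from the config seed; every stage draws from a
named child stream so stages can be re-run independently.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import shapely

from . import geo
from .ais import PingRecord, VesselRecord, VesselTrack
from .scenes import Detection, Scene, save_scenes

#: Default class mix: mostly drifting longlines (the emulated regions are
#: longline grounds with ~83–94% fishing vessels), some carriers/others.
DEFAULT_CLASS_MIX = {
    "drifting_longline": 0.83,
    "cargo_or_tanker": 0.10,
    "other": 0.07,
}

#: Per-class length distributions (lognormal, metres) and cruise speeds.
DEFAULT_CLASS_PARAMS = {
    "drifting_longline": {"log_len_mean": np.log(35.0), "log_len_sd": 0.35, "len_clip": (12.0, 120.0), "speed_mean": 5.0, "speed_sd": 1.5},
    "cargo_or_tanker": {"log_len_mean": np.log(150.0), "log_len_sd": 0.30, "len_clip": (60.0, 350.0), "speed_mean": 11.0, "speed_sd": 2.0},
    "other": {"log_len_mean": np.log(30.0), "log_len_sd": 0.40, "len_clip": (10.0, 200.0), "speed_mean": 6.0, "speed_sd": 2.0},
    "trawler": {"log_len_mean": np.log(30.0), "log_len_sd": 0.30, "len_clip": (12.0, 90.0), "speed_mean": 4.0, "speed_sd": 1.5},
    "purse_seine": {"log_len_mean": np.log(40.0), "log_len_sd": 0.30, "len_clip": (15.0, 110.0), "speed_mean": 6.0, "speed_sd": 2.0},
    "tug": {"log_len_mean": np.log(28.0), "log_len_sd": 0.25, "len_clip": (12.0, 60.0), "speed_mean": 4.0, "speed_sd": 1.0},
}


@dataclass
class TrueDetectionCurve:
    """Generating detectability: linear ramp then plateau.

    Defaults mirror the regime the models are fitted to: ~20% at 20 m
    rising to ~90% at 60 m, roughly constant (0.91) above.
    """

    ramp_lo_m: float = 20.0
    ramp_lo_p: float = 0.2
    ramp_hi_m: float = 60.0
    ramp_hi_p: float = 0.9
    plateau: float = 0.91

    def at(self, length_m) -> np.ndarray:
        x = np.asarray(length_m, dtype=float)
        slope = (self.ramp_hi_p - self.ramp_lo_p) / (self.ramp_hi_m - self.ramp_lo_m)
        ramp = np.clip(self.ramp_lo_p + slope * (x - self.ramp_lo_m), 0.0, 1.0)
        return np.where(x >= self.ramp_hi_m, self.plateau, ramp)


@dataclass
class SimConfig:
    n_vessels: int = 500
    dark_fraction: float = 0.2
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    class_params: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_PARAMS.items()})
    # movement (correlated random walk, 1-minute steps)
    turn_sd_deg: float = 2.0          # heading innovation sd per step
    speed_ar: float = 0.98            # AR(1) pull of speed to the class mean
    speed_innov_sd: float = 0.2       # knots per step
    # fishing fleets work a ground rather than dispersing: outside this
    # radius headings are nudged back toward the region centre
    home_radius_km: float = 250.0
    home_pull: float = 0.05           # fraction of the bearing error per step
    # AIS sampling
    # AIS reception: with these defaults the vast majority of scene passes
    # have a ping shortly before and after the image, and long outages are
    # the exception — the regime the 10-minute fusion rule expects
    ping_interval_min: float = 8.0    # mean of exponential ping intervals
    gap_prob: float = 0.01            # chance a ping starts a long outage
    gap_hours: tuple = (1.0, 4.0)     # uniform outage duration range
    # geometry / timing
    region_lat: float = -9.0
    region_lon: float = 55.0
    region_half_km: float = 230.0     # vessels start uniform in this half-width box
    duration_hours: float = 48.0
    step_min: float = 1.0
    n_scenes: int = 8
    scene_size_km: float = 420.0
    # observation model
    detection_curve: TrueDetectionCurve = field(default_factory=TrueDetectionCurve)
    sar_length_sigma: float = 0.2     # lognormal log-sd of radar length
    detection_pos_sd_km: float = 0.05
    false_rate_per_km2: float = 2e-6
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not 0.0 <= self.dark_fraction <= 1.0:
            raise ValueError("dark_fraction must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class World:
    cfg: SimConfig
    t0: pd.Timestamp
    times: pd.DatetimeIndex
    east_km: np.ndarray            # (n_vessels, n_steps)
    north_km: np.ndarray
    speeds: np.ndarray             # knots
    headings: np.ndarray           # degrees
    vessels: list                  # VesselRecord
    lengths_m: np.ndarray
    dark: np.ndarray               # bool
    tracks: list                   # broadcasting vessels only

    def true_position(self, idx: int, t: pd.Timestamp):
        """True lat/lon of vessel ``idx`` at (the step nearest to) t."""
        step = int(round((t - self.t0).total_seconds() / 60.0 / self.cfg.step_min))
        step = int(np.clip(step, 0, len(self.times) - 1))
        lat, lon = geo.from_local_en(
            self.cfg.region_lat, self.cfg.region_lon,
            self.east_km[idx, step], self.north_km[idx, step],
        )
        return float(lat), float(lon)


def _rng(seed: int, name: str) -> np.random.Generator:
    # named substream: stable across runs and platforms
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(sum(name.encode()),))
    return np.random.default_rng(ss)


def simulate_tracks(cfg: SimConfig, seed: Optional[int] = None) -> World:
    """Simulate the fleet's continuous trajectories and AIS pings.

    Movement is a correlated random walk: heading gains Gaussian
    innovations each minute, speed follows an AR(1) around the class
    cruise speed. Broadcasting vessels emit pings at exponential
    intervals with occasional multi-hour gaps; dark vessels emit nothing.
    """
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, "tracks")
    n = cfg.n_vessels
    n_steps = int(cfg.duration_hours * 60.0 / cfg.step_min) + 1
    t0 = pd.Timestamp("2019-10-01T00:00:00Z")
    times = t0 + pd.to_timedelta(np.arange(n_steps) * cfg.step_min, unit="m")

    classes = rng.choice(
        list(cfg.class_mix.keys()), size=n, p=list(cfg.class_mix.values())
    )
    lengths = np.empty(n)
    base_speed = np.empty(n)
    for c in sorted(set(classes)):
        p = cfg.class_params[c]
        m = classes == c
        raw = rng.lognormal(p["log_len_mean"], p["log_len_sd"], size=m.sum())
        lengths[m] = np.clip(raw, *p["len_clip"])
        base_speed[m] = np.maximum(rng.normal(p["speed_mean"], p["speed_sd"], size=m.sum()), 0.5)
    dark = rng.random(n) < cfg.dark_fraction

    east = np.empty((n, n_steps))
    north = np.empty((n, n_steps))
    speeds = np.empty((n, n_steps))
    headings = np.empty((n, n_steps))
    east[:, 0] = rng.uniform(-cfg.region_half_km, cfg.region_half_km, n)
    north[:, 0] = rng.uniform(-cfg.region_half_km, cfg.region_half_km, n)
    speeds[:, 0] = base_speed
    headings[:, 0] = rng.uniform(0.0, 360.0, n)
    dt_h = cfg.step_min / 60.0
    for t in range(1, n_steps):
        h = headings[:, t - 1] + rng.normal(0.0, cfg.turn_sd_deg, n)
        if cfg.home_pull > 0:
            dist = np.hypot(east[:, t - 1], north[:, t - 1])
            to_home = np.degrees(np.arctan2(-east[:, t - 1], -north[:, t - 1]))
            err = (to_home - h + 180.0) % 360.0 - 180.0
            h = h + np.where(dist > cfg.home_radius_km, cfg.home_pull * err, 0.0)
        headings[:, t] = h % 360.0
        speeds[:, t] = np.maximum(
            base_speed + cfg.speed_ar * (speeds[:, t - 1] - base_speed)
            + rng.normal(0.0, cfg.speed_innov_sd, n),
            0.0,
        )
        d_km = speeds[:, t - 1] * dt_h * geo.KM_PER_NMI
        th = np.radians(headings[:, t - 1])
        east[:, t] = east[:, t - 1] + d_km * np.sin(th)
        north[:, t] = north[:, t - 1] + d_km * np.cos(th)

    vessels = []
    tracks = []
    ping_rng = _rng(seed, "pings")
    for i in range(n):
        rec = VesselRecord(
            vessel_id=f"{400000000 + i}",
            vclass=classes[i],
            length_m=float(lengths[i]),
        )
        vessels.append(rec)
        if dark[i]:
            continue
        # exponential ping times with occasional gaps
        t_min = float(ping_rng.exponential(cfg.ping_interval_min))
        ping_steps = []
        while t_min < cfg.duration_hours * 60.0:
            ping_steps.append(int(round(t_min / cfg.step_min)))
            if ping_rng.random() < cfg.gap_prob:
                t_min += float(ping_rng.uniform(*cfg.gap_hours)) * 60.0
            else:
                t_min += float(ping_rng.exponential(cfg.ping_interval_min))
        ping_steps = sorted(set(s for s in ping_steps if 0 <= s < n_steps))
        lat, lon = geo.from_local_en(
            cfg.region_lat, cfg.region_lon, east[i, ping_steps], north[i, ping_steps]
        )
        pings = [
            PingRecord(
                vessel_id=rec.vessel_id,
                t=times[s],
                lat=float(lat[k]),
                lon=float(lon[k]),
                sog=float(speeds[i, s]),
                cog=float(headings[i, s]),
            )
            for k, s in enumerate(ping_steps)
        ]
        if pings:
            tracks.append(VesselTrack(vessel=rec, pings=pings))
    return World(
        cfg=cfg, t0=t0, times=times, east_km=east, north_km=north,
        speeds=speeds, headings=headings, vessels=vessels,
        lengths_m=lengths, dark=dark, tracks=tracks,
    )


def build_scenes(cfg: SimConfig, seed: Optional[int] = None) -> list:
    """Square scene footprints near the region centre at staggered times."""
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, "scenes")
    t0 = pd.Timestamp("2019-10-01T00:00:00Z")
    scenes = []
    span_h = cfg.duration_hours - 8.0
    for k in range(cfg.n_scenes):
        tc = t0 + pd.Timedelta(hours=4.0 + span_h * (k / max(cfg.n_scenes - 1, 1)))
        ce = float(rng.uniform(-0.15, 0.15) * cfg.region_half_km)
        cn = float(rng.uniform(-0.15, 0.15) * cfg.region_half_km)
        h = cfg.scene_size_km / 2.0
        corners_en = [(ce - h, cn - h), (ce + h, cn - h), (ce + h, cn + h), (ce - h, cn + h)]
        lat, lon = geo.from_local_en(
            cfg.region_lat, cfg.region_lon,
            np.array([c[0] for c in corners_en]), np.array([c[1] for c in corners_en]),
        )
        scenes.append(
            Scene(
                scene_id=f"S{k:02d}",
                t=tc,
                footprint=shapely.Polygon(np.column_stack([lon, lat])),
                region="synthetic",
            )
        )
    return scenes


def simulate_scene_pass(world: World, scene: Scene, seed: Optional[int] = None):
    """Observe one scene: who was inside, who was detected, with what
    radar length; plus uniform false detections.

    Returns (detections, truth) where truth is a per-vessel DataFrame
    with true position, dark status, detection outcome and radar length.
    """
    cfg = world.cfg
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, f"scene-{scene.scene_id}")
    step = int(round((scene.t - world.t0).total_seconds() / 60.0 / cfg.step_min))
    step = int(np.clip(step, 0, len(world.times) - 1))
    lat, lon = geo.from_local_en(
        cfg.region_lat, cfg.region_lon, world.east_km[:, step], world.north_km[:, step]
    )
    inside = shapely.contains_xy(scene.footprint, np.asarray(lon), np.asarray(lat))
    p_det = cfg.detection_curve.at(world.lengths_m)
    detected = inside & (rng.random(len(lat)) < p_det)
    sar_len = world.lengths_m * np.exp(rng.normal(0.0, cfg.sar_length_sigma, len(lat)))

    detections = []
    rows = []
    for i in range(len(lat)):
        det_id = None
        if detected[i]:
            de, dn = rng.normal(0.0, cfg.detection_pos_sd_km, 2)
            dlat, dlon = geo.from_local_en(float(lat[i]), float(lon[i]), de, dn)
            det_id = f"{scene.scene_id}-d{len(detections):04d}"
            detections.append(
                Detection(
                    scene_id=scene.scene_id,
                    detect_id=det_id,
                    lat=float(dlat),
                    lon=float(dlon),
                    sar_length_m=float(sar_len[i]),
                )
            )
        rows.append(
            {
                "scene_id": scene.scene_id,
                "vessel_id": world.vessels[i].vessel_id,
                "true_lat": float(lat[i]),
                "true_lon": float(lon[i]),
                "length_m": float(world.lengths_m[i]),
                "vclass": world.vessels[i].vclass,
                "dark": bool(world.dark[i]),
                "inside": bool(inside[i]),
                "detected": bool(detected[i]),
                "sar_length_m": float(sar_len[i]) if detected[i] else np.nan,
                "detect_id": det_id,
            }
        )
    # false detections: uniform Poisson field over the footprint
    vx, vy = scene.footprint.exterior.coords.xy
    pe, pn = geo.to_local_en(cfg.region_lat, cfg.region_lon, np.asarray(vy), np.asarray(vx))
    area = shapely.Polygon(np.column_stack([pe, pn])).area
    n_false = rng.poisson(cfg.false_rate_per_km2 * area)
    e_lo, e_hi = pe.min(), pe.max()
    n_lo, n_hi = pn.min(), pn.max()
    made = 0
    while made < n_false:
        fe = rng.uniform(e_lo, e_hi)
        fn = rng.uniform(n_lo, n_hi)
        flat, flon = geo.from_local_en(cfg.region_lat, cfg.region_lon, fe, fn)
        if not scene.footprint.contains(shapely.Point(float(flon), float(flat))):
            continue
        fl = float(
            np.clip(rng.lognormal(np.log(35.0), 0.4), 5.0, 399.0)
        )
        detections.append(
            Detection(
                scene_id=scene.scene_id,
                detect_id=f"{scene.scene_id}-f{made:03d}",
                lat=float(flat),
                lon=float(flon),
                sar_length_m=fl,
            )
        )
        made += 1
    return detections, pd.DataFrame(rows)


@dataclass
class WorldBundle:
    world: World
    scenes: list
    detections: list
    truth: pd.DataFrame


def simulate_world(cfg: SimConfig) -> WorldBundle:
    """Full synthetic world: tracks, scenes, detections, truth table."""
    world = simulate_tracks(cfg)
    scenes = build_scenes(cfg)
    all_dets = []
    truths = []
    for sc in scenes:
        dets, truth = simulate_scene_pass(world, sc)
        all_dets.extend(dets)
        truths.append(truth)
    return WorldBundle(world=world, scenes=scenes, detections=all_dets, truth=pd.concat(truths, ignore_index=True))


def make_recovery_case(cfg: SimConfig, out_dir) -> WorldBundle:
    """Write a ready-to-run fixture (AIS CSV, registry CSV, scenes GeoJSON,
    detections CSV, truth JSON) whose dark-fleet truth is recorded."""
    os.makedirs(out_dir, exist_ok=True)
    bundle = simulate_world(cfg)
    rows = []
    for tr in bundle.world.tracks:
        for p in tr.pings:
            rows.append(
                {
                    "mmsi": p.vessel_id,
                    "timestamp": p.t.isoformat(),
                    "lat": p.lat,
                    "lon": p.lon,
                    "sog": p.sog,
                    "cog": p.cog,
                }
            )
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "ais.csv"), index=False)
    pd.DataFrame(
        [
            {
                "vessel_id": v.vessel_id,
                "vclass": v.vclass,
                "length_m": v.length_m,
                "flag": v.flag,
            }
            for i, v in enumerate(bundle.world.vessels)
            if not bundle.world.dark[i]
        ]
    ).to_csv(os.path.join(out_dir, "registry.csv"), index=False)
    save_scenes(bundle.scenes, os.path.join(out_dir, "scenes.geojson"))
    det_rows = [
        {
            "scene_id": d.scene_id,
            "detect_id": d.detect_id,
            "lat": d.lat,
            "lon": d.lon,
            "sar_length_m": d.sar_length_m,
        }
        for d in bundle.detections
    ]
    pd.DataFrame(det_rows).to_csv(os.path.join(out_dir, "detections.csv"), index=False)

    dark_truth = bundle.truth[bundle.truth["dark"] & bundle.truth["inside"]]
    hist, _ = np.histogram(dark_truth["length_m"], bins=np.arange(401))
    truth_doc = {
        "n_dark_instances": int(len(dark_truth)),
        "n_dark_detected": int(dark_truth["detected"].sum()),
        "per_scene_dark": {
            s: int(g["dark"].sum())
            for s, g in bundle.truth[bundle.truth["inside"]].groupby("scene_id")
        },
        "dark_length_histogram": hist.tolist(),
        "seed": cfg.seed,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth_doc, fh)
    return bundle
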