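"""SAR scene footprints and shipboard detections.

Scenes arrive as a GeoJSON FeatureCollection (one polygon per acquisition,
properties ``scene_id`` and ``timestamp``); detections as a CSV with
``scene_id, lat, lon, sar_length_m``. Radar-estimated lengths are noisy —
that noise is modelled downstream, not cleaned here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import pandas as pd
import shapely
import shapely.geometry


@dataclass(frozen=True)
class Scene:
    scene_id: str
    t: pd.Timestamp
    footprint: shapely.Polygon
    region: Optional[str] = None

    def __post_init__(self):
        if not self.footprint.is_valid or self.footprint.area <= 0:
            raise ValueError(f"scene {self.scene_id}: invalid footprint")


@dataclass(frozen=True)
class Detection:
    scene_id: str
    detect_id: str
    lat: float
    lon: float
    sar_length_m: float

    def __post_init__(self):
        if not self.sar_length_m > 0:
            raise ValueError("sar_length_m must be positive")


def load_scenes(path) -> list:
    """Read scenes from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        fc = json.load(fh)
    scenes = []
    for feat in fc["features"]:
        props = feat["properties"]
        scenes.append(
            Scene(
                scene_id=str(props["scene_id"]),
                t=pd.to_datetime(props["timestamp"], utc=True),
                footprint=shapely.geometry.shape(feat["geometry"]),
                region=props.get("region"),
            )
        )
    return scenes


def save_scenes(scenes, path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": shapely.geometry.mapping(s.footprint),
                "properties": {
                    "scene_id": s.scene_id,
                    "timestamp": s.t.isoformat(),
                    "region": s.region,
                },
            }
            for s in scenes
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def load_detections(path) -> list:
    """Read the detection CSV (scene_id, lat, lon, sar_length_m)."""
    df = pd.read_csv(path, dtype={"scene_id": str})
    dets = []
    for i, row in df.iterrows():
        dets.append(
            Detection(
                scene_id=str(row["scene_id"]),
                detect_id=str(row.get("detect_id", i)),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                sar_length_m=float(row["sar_length_m"]),
            )
        )
    return dets


def detections_frame(dets) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scene_id": d.scene_id,
                "detect_id": d.detect_id,
                "lat": d.lat,
                "lon": d.lon,
                "sar_length_m": d.sar_length_m,
            }
            for d in dets
        ]
    )
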