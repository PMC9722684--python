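"""AIS ingest: parse position feeds, separate vessels from gear beacons,
and select candidate tracks around a radar scene.

Longline fleets attach AIS beacons to their gear; those beacons outnumber
vessels several-fold and must be excluded before matching. Gear is
recognised by MMSI prefix (1, 8 or 9), by broadcast names (standard buoy
names or a voltage reading), or by an explicit ``gear`` class label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from . import geo

VESSEL_CLASSES = (
    "trawler",
    "purse_seine",
    "tug",
    "cargo_or_tanker",
    "drifting_longline",
    "other",
    "gear",
)

#: Editable gear-name patterns: voltage readings ("3.7V") and common buoy
#: vocabulary. The authoritative vocabulary is not public, so this list is
#: configuration, not a contract.
DEFAULT_GEAR_NAME_PATTERNS = (
    r"\d+(\.\d+)?\s*V\b",
    r"\bBUOY\b",
    r"\bNET\b",
    r"\bGEAR\b",
    r"\bFLOAT\b",
)

_GEAR_MMSI_PREFIXES = ("1", "8", "9")


class ConfigurationError(ValueError):
    """A required column or setting is missing."""


@dataclass(frozen=True)
class PingRecord:
    vessel_id: str
    t: pd.Timestamp        # UTC
    lat: float
    lon: float
    sog: float             # knots
    cog: float             # degrees clockwise from north

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat out of range: {self.lat}")
        if not (-180.0 < self.lon <= 180.0):
            raise ValueError(f"lon out of range: {self.lon}")
        if self.sog < 0:
            raise ValueError(f"negative speed over ground: {self.sog}")
        if not (0.0 <= self.cog < 360.0):
            raise ValueError(f"course out of range: {self.cog}")


@dataclass
class VesselRecord:
    vessel_id: str
    vclass: str = "other"
    length_m: Optional[float] = None
    flag: Optional[str] = None
    names_seen: list = field(default_factory=list)

    def __post_init__(self):
        if self.vclass not in VESSEL_CLASSES:
            raise ValueError(f"unknown vessel class: {self.vclass!r}")
        if self.length_m is not None and not self.length_m > 0:
            raise ValueError(f"length must be positive: {self.length_m}")


@dataclass
class VesselTrack:
    vessel: VesselRecord
    pings: list  # time-sorted PingRecords

    def __post_init__(self):
        ts = [p.t for p in self.pings]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("pings must have strictly increasing timestamps")
        if any(p.vessel_id != self.vessel.vessel_id for p in self.pings):
            raise ValueError("ping vessel_id mismatch")

    def __len__(self):
        return len(self.pings)


@dataclass
class ParseResult:
    tracks: list
    n_rejected: int
    rejection_reasons: dict


DEFAULT_SCHEMA = {
    "vessel_id": "mmsi",
    "t": "timestamp",
    "lat": "lat",
    "lon": "lon",
    "sog": "sog",
    "cog": "cog",
}

_MANDATORY = ("vessel_id", "t", "lat", "lon", "sog", "cog")


def parse_positions(
    stream,
    schema: Mapping[str, str] | None = None,
    registry: Mapping[str, VesselRecord] | None = None,
    name_column: str | None = None,
) -> ParseResult:
    """Read a delimited AIS position table into per-vessel tracks.

    Parameters
    ----------
    stream
        Path or file-like object of a CSV with a header row.
    schema
        Maps the canonical field names (vessel_id, t, lat, lon, sog, cog)
        to column names in the file. Defaults to :data:`DEFAULT_SCHEMA`.
    registry
        Optional vessel_id -> :class:`VesselRecord` sidecar; vessels absent
        from it get class ``other``.
    name_column
        Optional column holding broadcast names, accumulated per vessel
        into ``names_seen`` (used by gear classification).

    Malformed rows (unparseable timestamp, out-of-range coordinates or
    kinematics) are dropped and counted, never fatal. A missing mandatory
    column is a :class:`ConfigurationError`.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    df = pd.read_csv(stream)
    missing = [schema[k] for k in _MANDATORY if schema[k] not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s): {missing}")

    reasons: dict = {}

    def _count(reason, mask):
        n = int(mask.sum())
        if n:
            reasons[reason] = reasons.get(reason, 0) + n
        return mask

    t = pd.to_datetime(df[schema["t"]], utc=True, errors="coerce", format="mixed")
    bad = _count("bad_timestamp", t.isna())
    for fld, lo, hi, closed_lo in (
        ("lat", -90.0, 90.0, True),
        ("lon", -180.0, 180.0, False),
    ):
        v = pd.to_numeric(df[schema[fld]], errors="coerce")
        ok = (v >= lo) if closed_lo else (v > lo)
        ok &= v <= hi
        bad |= _count(f"bad_{fld}", ~ok.fillna(False))
    sog = pd.to_numeric(df[schema["sog"]], errors="coerce")
    bad |= _count("bad_sog", ~(sog >= 0).fillna(False))
    cog = pd.to_numeric(df[schema["cog"]], errors="coerce")
    bad |= _count("bad_cog", ~((cog >= 0) & (cog < 360)).fillna(False))

    kept = df.loc[~bad.values]
    tracks = []
    for vid, grp in kept.groupby(kept[schema["vessel_id"]].astype(str), sort=True):
        grp = grp.sort_values(schema["t"], key=lambda s: pd.to_datetime(s, utc=True, format="mixed"))
        names: list = []
        if name_column and name_column in grp.columns:
            names = sorted(set(str(n) for n in grp[name_column].dropna().unique()))
        if registry is not None and vid in registry:
            rec = registry[vid]
            if names:
                rec.names_seen = sorted(set(rec.names_seen) | set(names))
        else:
            rec = VesselRecord(vessel_id=vid, names_seen=names)
        pings = []
        seen_t = set()
        for _, row in grp.iterrows():
            ts = pd.to_datetime(row[schema["t"]], utc=True, format="mixed")
            if ts in seen_t:  # duplicate timestamp: keep first
                reasons["duplicate_timestamp"] = reasons.get("duplicate_timestamp", 0) + 1
                continue
            seen_t.add(ts)
            pings.append(
                PingRecord(
                    vessel_id=vid,
                    t=ts,
                    lat=float(row[schema["lat"]]),
                    lon=float(row[schema["lon"]]),
                    sog=float(row[schema["sog"]]),
                    cog=float(row[schema["cog"]]),
                )
            )
        tracks.append(VesselTrack(vessel=rec, pings=pings))
    return ParseResult(tracks=tracks, n_rejected=int(bad.sum()), rejection_reasons=reasons)


def load_registry(path) -> dict:
    """Load the vessel sidecar CSV (vessel_id, vclass, length_m, flag)."""
    df = pd.read_csv(path, dtype={"vessel_id": str})
    out = {}
    for _, row in df.iterrows():
        length = row.get("length_m")
        out[str(row["vessel_id"])] = VesselRecord(
            vessel_id=str(row["vessel_id"]),
            vclass=str(row["vclass"]),
            length_m=None if pd.isna(length) else float(length),
            flag=None if pd.isna(row.get("flag")) else str(row.get("flag")),
        )
    return out


def is_gear(
    vessel: VesselRecord,
    name_patterns: Sequence[str] = DEFAULT_GEAR_NAME_PATTERNS,
) -> bool:
    """Whether an AIS device is a gear beacon rather than a vessel.

    True when the MMSI starts with 1, 8 or 9, when any broadcast name
    matches the gear-name pattern set, or when the class label is ``gear``.
    Total function: never raises for a well-formed record.
    """
    if not vessel.vessel_id:
        raise ValueError("vessel_id must be non-empty")
    if vessel.vessel_id[0] in _GEAR_MMSI_PREFIXES:
        return True
    if vessel.vclass == "gear":
        return True
    pats = [re.compile(p, re.IGNORECASE) for p in name_patterns]
    return any(p.search(name) for name in vessel.names_seen for p in pats)


def distance_to_footprint_km(lat, lon, footprint: shapely.Polygon) -> np.ndarray:
    """Great-circle distance from points to a scene footprint (0 inside).

    The footprint is projected onto a tangent plane at its centroid; the
    200 nmi candidate gate is coarse, so tangent-plane distortion at these
    ranges is irrelevant.
    """
    c = footprint.centroid
    vx, vy = footprint.exterior.coords.xy
    e, n = geo.to_local_en(c.y, c.x, np.asarray(vy), np.asarray(vx))
    poly = shapely.Polygon(np.column_stack([e, n]))
    pe, pn = geo.to_local_en(c.y, c.x, np.asarray(lat, dtype=float), np.asarray(lon, dtype=float))
    pts = shapely.points(np.column_stack([np.atleast_1d(pe), np.atleast_1d(pn)]))
    return shapely.distance(pts, poly)


def candidate_tracks(
    tracks: Iterable[VesselTrack],
    scene,
    max_hours: float = 12.0,
    max_nmi: float = 200.0,
    name_patterns: Sequence[str] = DEFAULT_GEAR_NAME_PATTERNS,
) -> list:
    """Tracks with at least one ping within `max_hours` and `max_nmi` of the
    scene footprint; gear beacons are dropped. Idempotent."""
    max_km = geo.nmi_to_km(max_nmi)
    out = []
    dt_max = pd.Timedelta(hours=max_hours)
    for tr in tracks:
        if not tr.pings or is_gear(tr.vessel, name_patterns):
            continue
        near_t = [p for p in tr.pings if abs(p.t - scene.t) <= dt_max]
        if not near_t:
            continue
        lat = [p.lat for p in near_t]
        lon = [p.lon for p in near_t]
        d = distance_to_footprint_km(lat, lon, scene.footprint)
        if np.any(d <= max_km):
            out.append(tr)
    return out


def bracket_positions(track: VesselTrack, t_scene: pd.Timestamp):
    """Latest ping at or before the scene time and earliest ping after it.

    A ping exactly at the scene time is returned on the *before* side (the
    time offset is zero either way, so the choice only fixes determinism).
    Either side may be absent; both absent (empty track) is an error.
    """
    if not track.pings:
        raise ValueError("empty track has no bracketing positions")
    before = None
    after = None
    for p in track.pings:
        if p.t <= t_scene:
            before = p
        elif after is None:
            after = p
            break
    return before, after
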