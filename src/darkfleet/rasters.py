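"""Empirical displacement probability rasters.

For each vessel class, speed bin and signed time offset, a raster records
where vessels of that class actually ended up relative to a straight-line
extrapolation of their last known position — a vessel-relative utilization
distribution. The frame is centred on the extrapolated point with +x along
the course over ground and +y to port; units are probability per km², so
cell value × cell area sums to 1.

Raster geometry follows a fixed scaling: pixel width max(1, Δm)/1000
km for a 1000-pixel-wide grid, i.e. the raster always spans max(1, Δm) km.
A coarser pixel count may be configured for desk-scale runs; the spanned
extent is unchanged.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage

from . import geo
from .ais import PingRecord, VesselTrack

#: The six non-gear vessel classes rasters are built for.
RASTER_CLASSES = (
    "trawler",
    "purse_seine",
    "tug",
    "cargo_or_tanker",
    "drifting_longline",
    "other",
)

#: Speed-bin centres (knots) and their half-open edges.
SPEED_BIN_CENTERS = (1.0, 3.0, 5.0, 7.0, 9.0, 12.5)
SPEED_BIN_EDGES = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, np.inf)

#: The 36 signed time offsets (minutes), an approximately geometric grid.
DT_OFFSETS_MIN = tuple(
    -v for v in (448, 320, 224, 160, 112, 80, 56, 40, 28, 20, 14, 10, 7, 5, 3.5, 2.5, 1.5, 0.5)
) + (0.5, 1.5, 2.5, 3.5, 5, 7, 10, 14, 20, 28, 40, 56, 80, 112, 160, 224, 320, 448)

_ABS_OFFSETS = np.array(sorted({abs(v) for v in DT_OFFSETS_MIN}))
_LOG_ABS = np.log(_ABS_OFFSETS)

#: Pairs with |Δt| beyond this are not assigned to any bin when training.
MAX_TRAIN_GAP_MIN = 530.0

RASTER_STORE_VERSION = 1
DEFAULT_N_PIXELS = 1000


@dataclass(frozen=True, order=True)
class RasterKey:
    vclass: str
    speed_kn: float   # bin centre
    dt_min: float     # signed bin centre, minutes

    def __post_init__(self):
        if self.vclass not in RASTER_CLASSES:
            raise ValueError(f"not a raster class: {self.vclass!r}")
        if self.speed_kn not in SPEED_BIN_CENTERS:
            raise ValueError(f"not a speed bin centre: {self.speed_kn}")
        if self.dt_min not in DT_OFFSETS_MIN:
            raise ValueError(f"not a time-offset bin: {self.dt_min}")


def all_keys() -> list:
    """The full key set: 6 classes × 6 speeds × 36 offsets = 1296 keys."""
    return [
        RasterKey(c, s, d)
        for c in RASTER_CLASSES
        for s in SPEED_BIN_CENTERS
        for d in DT_OFFSETS_MIN
    ]


def pixel_width(dm: float) -> float:
    """Pixel width in km for a time interval of ``dm`` minutes: max(1, dm)/1000.

    At 10 minutes each pixel is 10 m and the full raster spans 10 km; under
    one minute the raster is 1 km wide with 1 m pixels.
    """
    if not dm > 0:
        raise ValueError(f"time interval must be positive, got {dm}")
    return max(1.0, dm) / 1000.0


def raster_extent_km(dm: float) -> float:
    """Full side length of the raster for interval ``dm`` minutes."""
    return pixel_width(abs(dm)) * DEFAULT_N_PIXELS


def speed_bin(sog: float) -> float:
    """Speed-bin centre for a speed over ground in knots."""
    if sog < 0:
        raise ValueError("speed must be non-negative")
    idx = int(np.searchsorted(SPEED_BIN_EDGES[1:-1], sog, side="right"))
    return SPEED_BIN_CENTERS[idx]


def dt_bin(dt: float, clamp: bool = False) -> Optional[float]:
    """Signed time-offset bin centre nearest to ``dt`` in log-|Δt| space.

    Returns None for dt == 0 or, unless ``clamp`` is set, |dt| beyond
    :data:`MAX_TRAIN_GAP_MIN`. With ``clamp`` the outermost bin is used.
    """
    if dt == 0:
        return None
    if abs(dt) > MAX_TRAIN_GAP_MIN and not clamp:
        return None
    a = min(max(abs(dt), _ABS_OFFSETS[0]), _ABS_OFFSETS[-1])
    idx = int(np.argmin(np.abs(np.log(a) - _LOG_ABS)))
    return float(np.sign(dt) * _ABS_OFFSETS[idx])


@dataclass
class ProbabilityRaster:
    """One displacement density grid: probability per km² on an n×n grid.

    ``grid[iy, ix]`` with x (columns) along the extrapolated course and
    y (rows) positive to port; cell centres at
    ``(index − (n−1)/2) · pixel_width_km``.
    """

    key: RasterKey
    grid: np.ndarray
    pixel_width_km: float
    n_samples: int
    sparse: bool = False
    fallback_from: Optional[RasterKey] = None
    n_discarded: int = 0

    @property
    def da(self) -> float:
        return self.pixel_width_km ** 2

    @property
    def n_pixels(self) -> int:
        return self.grid.shape[0]

    @property
    def extent_km(self) -> float:
        return self.pixel_width_km * self.n_pixels

    def axis_centers(self) -> np.ndarray:
        n = self.n_pixels
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_width_km

    def total_mass(self) -> float:
        return float(self.grid.sum() * self.da)

    def sample(self, x_km, y_km) -> np.ndarray:
        """Bilinear density lookup at frame coordinates; 0 outside extent."""
        n = self.n_pixels
        ix = np.asarray(x_km, dtype=float) / self.pixel_width_km + (n - 1) / 2.0
        iy = np.asarray(y_km, dtype=float) / self.pixel_width_km + (n - 1) / 2.0
        return ndimage.map_coordinates(
            self.grid, [np.atleast_1d(iy), np.atleast_1d(ix)], order=1, mode="constant", cval=0.0
        )


def extrapolated_origin(ping: PingRecord, dt_min: float):
    """Straight-line dead-reckoned position ``dt_min`` minutes from a ping.

    Distance is speed (knots) × time (hours) in nautical miles, applied
    along the course for positive offsets and back along the reciprocal
    for negative ones.
    """
    dist_km = geo.nmi_to_km(ping.sog * dt_min / 60.0)
    return geo.destination(ping.lat, ping.lon, ping.cog, dist_km)


def relative_displacement(p0: PingRecord, dt_min: float, lat, lon):
    """Coordinates of a point in the extrapolation-centred course frame.

    +x along ``p0.cog``, +y to port (right-handed with x forward); the
    origin is the dead-reckoned position at ``dt_min``. Uses a local
    azimuthal-equidistant tangent plane at the origin.
    """
    olat, olon = extrapolated_origin(p0, dt_min)
    e, n = geo.to_local_en(olat, olon, lat, lon)
    th = np.radians(p0.cog)
    x = e * np.sin(th) + n * np.cos(th)
    y = -e * np.cos(th) + n * np.sin(th)
    return x, y


def _gaussian_fallback_grid(n: int, pw: float) -> np.ndarray:
    """Isotropic Gaussian blob, σ = 15% of the raster half-width.

    Terminal fallback when no trained raster can be borrowed for a key;
    encodes only "near the extrapolated point, uncertainty grows with the
    raster scale".
    """
    c = (np.arange(n) - (n - 1) / 2.0) * pw
    sd = 0.15 * (n * pw / 2.0)
    g1 = np.exp(-0.5 * (c / sd) ** 2)
    g = np.outer(g1, g1)
    return g / (g.sum() * pw * pw)


class RasterSet:
    """The keyed collection of displacement rasters with fallback wiring."""

    def __init__(self, rasters: dict, n_pixels: int = DEFAULT_N_PIXELS):
        self._rasters = dict(rasters)
        self.n_pixels = n_pixels

    def __len__(self):
        return len(self._rasters)

    def __contains__(self, key):
        return key in self._rasters

    def keys(self):
        return self._rasters.keys()

    def values(self):
        return self._rasters.values()

    def get(self, key: RasterKey) -> ProbabilityRaster:
        if key not in self._rasters:
            raise KeyError(f"no raster for key {key}")
        return self._rasters[key]

    def lookup(self, vclass: str, sog: float, dt: float) -> ProbabilityRaster:
        """Raster for an actual speed/offset, clamping the offset bin."""
        binned = dt_bin(dt, clamp=True)
        if binned is None:
            raise ValueError("zero time offset has no raster bin")
        vc = vclass if vclass in RASTER_CLASSES else "other"
        return self.get(RasterKey(vc, speed_bin(sog), binned))

    # ---- persistence -------------------------------------------------

    def save(self, path) -> None:
        os.makedirs(path, exist_ok=True)
        entries = []
        for i, (key, r) in enumerate(sorted(self._rasters.items())):
            owned = r.fallback_from is None
            fname = f"raster_{i:05d}.npy" if owned else None
            if owned:
                np.save(os.path.join(path, fname), r.grid)
            entries.append(
                {
                    "vclass": key.vclass,
                    "speed_kn": key.speed_kn,
                    "dt_min": key.dt_min,
                    "pixel_width_km": r.pixel_width_km,
                    "n_samples": r.n_samples,
                    "sparse": r.sparse,
                    "n_discarded": r.n_discarded,
                    "fallback_from": None
                    if owned
                    else [r.fallback_from.vclass, r.fallback_from.speed_kn, r.fallback_from.dt_min],
                    "file": fname,
                    "shape": list(r.grid.shape),
                }
            )
        manifest = {
            "version": RASTER_STORE_VERSION,
            "n_pixels": self.n_pixels,
            "frame": "x along course, y positive to port, origin at extrapolated point",
            "entries": entries,
        }
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh)

    @classmethod
    def load(cls, path) -> "RasterSet":
        with open(os.path.join(path, "manifest.json")) as fh:
            manifest = json.load(fh)
        if manifest.get("version") != RASTER_STORE_VERSION:
            raise ValueError(
                f"raster store version {manifest.get('version')} != {RASTER_STORE_VERSION}"
            )
        rasters: dict = {}
        deferred = []
        for e in manifest["entries"]:
            key = RasterKey(e["vclass"], e["speed_kn"], e["dt_min"])
            if e["file"] is not None:
                grid = np.load(os.path.join(path, e["file"]))
                if list(grid.shape) != e["shape"]:
                    raise ValueError(f"grid shape {grid.shape} != manifest {e['shape']}")
                rasters[key] = ProbabilityRaster(
                    key=key,
                    grid=grid,
                    pixel_width_km=e["pixel_width_km"],
                    n_samples=e["n_samples"],
                    sparse=e["sparse"],
                    n_discarded=e.get("n_discarded", 0),
                )
            else:
                deferred.append((key, e))
        for key, e in deferred:
            src = RasterKey(*e["fallback_from"])
            donor = rasters[src]
            rasters[key] = ProbabilityRaster(
                key=key,
                grid=donor.grid,
                pixel_width_km=e["pixel_width_km"],
                n_samples=e["n_samples"],
                sparse=True,
                fallback_from=src,
            )
        return cls(rasters, n_pixels=manifest["n_pixels"])


def _collect_displacements(tracks: Iterable[VesselTrack], max_gap_min: float):
    """Per-key (x, y) displacement sample arrays from all ordered ping
    pairs within the time window, vectorised per track."""
    samples: dict = {}
    for tr in tracks:
        vc = tr.vessel.vclass if tr.vessel.vclass in RASTER_CLASSES else "other"
        n = len(tr.pings)
        if n < 2:
            continue
        t_min = np.array([p.t.value for p in tr.pings], dtype=np.int64) / 60e9
        lat = np.array([p.lat for p in tr.pings])
        lon = np.array([p.lon for p in tr.pings])
        sog = np.array([p.sog for p in tr.pings])
        cog = np.array([p.cog for p in tr.pings])
        lo = np.searchsorted(t_min, t_min - max_gap_min, side="left")
        hi = np.searchsorted(t_min, t_min + max_gap_min, side="right")
        ii = np.repeat(np.arange(n), hi - lo)
        jj = np.concatenate([np.arange(lo[i], hi[i]) for i in range(n)])
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
        if ii.size == 0:
            continue
        dt = t_min[jj] - t_min[ii]
        a = np.clip(np.abs(dt), _ABS_OFFSETS[0], _ABS_OFFSETS[-1])
        k = np.argmin(np.abs(np.log(a)[:, None] - _LOG_ABS[None, :]), axis=1)
        sb_idx = np.searchsorted(SPEED_BIN_EDGES[1:-1], sog[ii], side="right")
        dist_km = geo.nmi_to_km(sog[ii] * dt / 60.0)
        olat, olon = geo.destination(lat[ii], lon[ii], cog[ii], dist_km)
        e, nn = geo.to_local_en(olat, olon, lat[jj], lon[jj])
        th = np.radians(cog[ii])
        x = e * np.sin(th) + nn * np.cos(th)
        y = -e * np.cos(th) + nn * np.sin(th)
        code = sb_idx * 100 + k * 2 + (dt > 0).astype(int)
        for cval in np.unique(code):
            m = code == cval
            sb = SPEED_BIN_CENTERS[int(cval // 100)]
            kk = int((cval % 100) // 2)
            sign = 1.0 if cval % 2 else -1.0
            key = RasterKey(vc, sb, float(sign * _ABS_OFFSETS[kk]))
            samples.setdefault(key, []).append((x[m], y[m]))
    return samples


def build_raster_set(
    training: Iterable[VesselTrack],
    keys: Optional[list] = None,
    min_samples: int = 500,
    n_pixels: int = DEFAULT_N_PIXELS,
    max_gap_min: float = MAX_TRAIN_GAP_MIN,
    smooth_px: float = 1.0,
) -> RasterSet:
    """Build displacement rasters from historical tracks.

    Every ordered ping pair contributes one sample to the raster keyed by
    the first ping's class and speed bin and the pair's signed time-offset
    bin. Counts are divided by (in-raster sample count × cell area) so each
    raster integrates to 1. Samples landing outside the raster extent are
    discarded and counted.

    Keys with fewer than ``min_samples`` in-raster samples are flagged
    sparse and filled by borrowing: same class at the nearest trained speed
    bin, then class "other", then any class at that offset, finally an
    isotropic Gaussian.

    ``smooth_px`` applies a Gaussian blur (σ in pixels) to the count
    histogram before normalization. With modest training sets the raw
    histograms are patchy point clouds whose products vanish spuriously;
    a one-pixel blur restores contiguous support while barely widening
    the distribution. Set 0 to disable.
    """
    tracks = list(training)
    if keys is None:
        keys = all_keys()
    samples = _collect_displacements(tracks, max_gap_min)

    built: dict = {}
    for key, chunks in samples.items():
        ext = pixel_width(abs(key.dt_min)) * DEFAULT_N_PIXELS
        pw = ext / n_pixels
        edges = np.linspace(-ext / 2.0, ext / 2.0, n_pixels + 1)
        xs = np.concatenate([c[0] for c in chunks])
        ys = np.concatenate([c[1] for c in chunks])
        counts, _, _ = np.histogram2d(ys, xs, bins=[edges, edges])
        n_in = int(counts.sum())
        n_out = len(xs) - n_in
        if n_in == 0:
            continue
        if smooth_px > 0:
            counts = ndimage.gaussian_filter(counts, smooth_px, mode="constant")
            counts *= n_in / counts.sum()
        built[key] = ProbabilityRaster(
            key=key,
            grid=counts / (n_in * pw * pw),
            pixel_width_km=pw,
            n_samples=n_in,
            sparse=n_in < min_samples,
            n_discarded=n_out,
        )

    out: dict = {}
    gaussians: dict = {}
    trained = {k: r for k, r in built.items() if r.n_samples >= min_samples}
    for key in keys:
        if key in trained:
            out[key] = built[key]
            continue
        donor = _find_donor(key, trained)
        ext = pixel_width(abs(key.dt_min)) * DEFAULT_N_PIXELS
        pw = ext / n_pixels
        if donor is not None:
            out[key] = ProbabilityRaster(
                key=key,
                grid=trained[donor].grid,
                pixel_width_km=pw,
                n_samples=built[key].n_samples if key in built else 0,
                sparse=True,
                fallback_from=donor,
            )
        elif key in built:  # some samples, below min, nothing to borrow
            r = built[key]
            r.sparse = True
            out[key] = r
        else:
            if n_pixels not in gaussians:
                gaussians[n_pixels] = {}
            cache = gaussians[n_pixels]
            if pw not in cache:
                cache[pw] = _gaussian_fallback_grid(n_pixels, pw)
            out[key] = ProbabilityRaster(
                key=key, grid=cache[pw], pixel_width_km=pw, n_samples=0, sparse=True
            )
    return RasterSet(out, n_pixels=n_pixels)


def _find_donor(key: RasterKey, trained: dict) -> Optional[RasterKey]:
    """Borrowing chain for sparse keys, restricted to the same offset bin."""
    same_class = [
        k for k in trained if k.vclass == key.vclass and k.dt_min == key.dt_min
    ]
    if same_class:
        return min(same_class, key=lambda k: (abs(k.speed_kn - key.speed_kn), k))
    other = [k for k in trained if k.vclass == "other" and k.dt_min == key.dt_min]
    if other:
        return min(other, key=lambda k: (abs(k.speed_kn - key.speed_kn), k))
    any_class = [k for k in trained if k.dt_min == key.dt_min]
    if any_class:
        return min(any_class, key=lambda k: (abs(k.speed_kn - key.speed_kn), k))
    return None
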