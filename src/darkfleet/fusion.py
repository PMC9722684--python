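"""Combine before- and after-scene displacement rasters into one
location-probability field.

Each side's raster lives in its own course-aligned frame anchored at a
dead-reckoned origin. Both are resampled (bilinear) onto a shared
east/north grid at the finer of the two pixel widths, then combined:

* closest bracketing ping within 10 minutes of the image — weighted
  average, each raster weighted by the integral of its squared density
  (concentrated evidence counts more);
* otherwise — cell-wise product, renormalized.

The product of two near-identical rasters just squares the density, which
is why the short-interval case switches to averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import shapely
from scipy import ndimage

from . import geo
from .rasters import ProbabilityRaster, extrapolated_origin

#: Closest-ping cutoff (minutes) below which rasters are averaged.
AVERAGING_CUTOFF_MIN = 10.0

#: Cap on common-grid cells; the pixel is coarsened to stay under it.
MAX_COMMON_CELLS = 2_000_000


class IncompatibleEvidenceError(ValueError):
    """The two rasters have no overlapping support: the track contradicts
    itself at the scene and no meaningful score exists."""


@dataclass
class AnchoredRaster:
    """A displacement raster placed on the globe: frame origin at the
    dead-reckoned point, +x axis along ``cog``."""

    raster: ProbabilityRaster
    origin_lat: float
    origin_lon: float
    cog: float

    @classmethod
    def from_ping(cls, raster: ProbabilityRaster, ping, dt_min: float) -> "AnchoredRaster":
        olat, olon = extrapolated_origin(ping, dt_min)
        return cls(raster=raster, origin_lat=float(olat), origin_lon=float(olon), cog=ping.cog)


@dataclass
class GeoRaster:
    """Axis-aligned east/north density grid anchored at a reference point.

    ``grid[iy, ix]`` in probability per km²; cell centres at
    ``e_min + (ix + ½)·pw`` east and ``n_min + (iy + ½)·pw`` north of the
    reference latitude/longitude.
    """

    ref_lat: float
    ref_lon: float
    e_min: float
    n_min: float
    pixel_width_km: float
    grid: np.ndarray
    method: Optional[str] = None  # multiplied | weighted_average | single

    @property
    def da(self) -> float:
        return self.pixel_width_km ** 2

    def total_mass(self) -> float:
        return float(self.grid.sum() * self.da)

    def cell_centers_en(self):
        ny, nx = self.grid.shape
        e = self.e_min + (np.arange(nx) + 0.5) * self.pixel_width_km
        n = self.n_min + (np.arange(ny) + 0.5) * self.pixel_width_km
        return e, n

    def sample_en(self, e, n) -> np.ndarray:
        ix = (np.asarray(e, dtype=float) - self.e_min) / self.pixel_width_km - 0.5
        iy = (np.asarray(n, dtype=float) - self.n_min) / self.pixel_width_km - 0.5
        return ndimage.map_coordinates(
            self.grid, [np.atleast_1d(iy), np.atleast_1d(ix)], order=1, mode="constant", cval=0.0
        )

    def sample_latlon(self, lat, lon) -> np.ndarray:
        e, n = geo.to_local_en(self.ref_lat, self.ref_lon, lat, lon)
        return self.sample_en(e, n)

    def mass_in_polygon(self, footprint: shapely.Polygon) -> float:
        """Σ p·da over cells whose centres fall inside a lat/lon polygon,
        clipped to [0, 1]."""
        vx, vy = footprint.exterior.coords.xy
        pe, pn = geo.to_local_en(self.ref_lat, self.ref_lon, np.asarray(vy), np.asarray(vx))
        poly = shapely.Polygon(np.column_stack([pe, pn]))
        e, n = self.cell_centers_en()
        ee, nn = np.meshgrid(e, n)
        inside = shapely.contains_xy(poly, ee.ravel(), nn.ravel()).reshape(ee.shape)
        return float(np.clip((self.grid * inside).sum() * self.da, 0.0, 1.0))


def _frame_axes(cog: float):
    th = np.radians(cog)
    course = np.array([np.sin(th), np.cos(th)])   # east, north
    port = np.array([-np.cos(th), np.sin(th)])
    return course, port


def _corners_en(a: AnchoredRaster, ref_lat, ref_lon):
    oe, on = geo.to_local_en(ref_lat, ref_lon, a.origin_lat, a.origin_lon)
    course, port = _frame_axes(a.cog)
    h = a.raster.extent_km / 2.0
    signs = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float) * h
    return np.array([oe, on]) + signs[:, :1] * course + signs[:, 1:] * port


def _sample_anchored(a: AnchoredRaster, ref_lat, ref_lon, e_cells, n_cells):
    oe, on = geo.to_local_en(ref_lat, ref_lon, a.origin_lat, a.origin_lon)
    course, port = _frame_axes(a.cog)
    ee, nn = np.meshgrid(e_cells, n_cells)
    rel_e = ee - oe
    rel_n = nn - on
    x = rel_e * course[0] + rel_n * course[1]
    y = rel_e * port[0] + rel_n * port[1]
    return a.raster.sample(x.ravel(), y.ravel()).reshape(ee.shape)


def resample_to_common_grid(
    a: AnchoredRaster,
    b: Optional[AnchoredRaster] = None,
    renormalize: bool = True,
    max_cells: int = MAX_COMMON_CELLS,
    extent: str = "union",
):
    """Place one or two anchored rasters on a shared east/north grid.

    The shared plane is tangent at the midpoint of the anchoring origins;
    the grid uses the finer of the two pixel widths and covers the union
    (or, with ``extent="intersection"``, the overlap — all that a product
    needs) of the rotated raster footprints. Values are bilinearly
    interpolated, zero outside a raster's own extent. With ``renormalize``
    each output is rescaled to integrate to exactly 1 (bilinear resampling
    conserves mass only approximately); intersection grids are never
    renormalized since they deliberately truncate support.
    """
    if b is None:
        ref_lat, ref_lon = a.origin_lat, a.origin_lon
        corners = _corners_en(a, ref_lat, ref_lon)
        pw = a.raster.pixel_width_km
        extent = "union"
    else:
        eb, nb = geo.to_local_en(a.origin_lat, a.origin_lon, b.origin_lat, b.origin_lon)
        ref_lat, ref_lon = geo.from_local_en(a.origin_lat, a.origin_lon, eb / 2.0, nb / 2.0)
        ref_lat, ref_lon = float(ref_lat), float(ref_lon)
        ca = _corners_en(a, ref_lat, ref_lon)
        cb = _corners_en(b, ref_lat, ref_lon)
        corners = np.vstack([ca, cb])
        pw = min(a.raster.pixel_width_km, b.raster.pixel_width_km)
        if extent == "intersection":
            lo = np.maximum(ca.min(axis=0), cb.min(axis=0))
            hi = np.minimum(ca.max(axis=0), cb.max(axis=0))
            if (hi <= lo).any():
                raise IncompatibleEvidenceError(
                    "before/after rasters have disjoint extents"
                )
            corners = np.vstack([lo, hi])
            renormalize = False

    e_lo, n_lo = corners.min(axis=0)
    e_hi, n_hi = corners.max(axis=0)
    n_cells_est = ((e_hi - e_lo) / pw) * ((n_hi - n_lo) / pw)
    if n_cells_est > max_cells:
        pw *= float(np.sqrt(n_cells_est / max_cells))
    nx = max(int(np.ceil((e_hi - e_lo) / pw)), 1)
    ny = max(int(np.ceil((n_hi - n_lo) / pw)), 1)
    e_cells = e_lo + (np.arange(nx) + 0.5) * pw
    n_cells = n_lo + (np.arange(ny) + 0.5) * pw

    out = []
    for anch in (a,) if b is None else (a, b):
        grid = _sample_anchored(anch, ref_lat, ref_lon, e_cells, n_cells)
        gr = GeoRaster(
            ref_lat=ref_lat, ref_lon=ref_lon, e_min=e_lo, n_min=n_lo,
            pixel_width_km=pw, grid=grid,
        )
        if renormalize:
            m = gr.total_mass()
            if m > 0:
                gr.grid = gr.grid / m
        out.append(gr)
    return out[0] if b is None else tuple(out)


def _check_same_grid(a: GeoRaster, b: GeoRaster):
    if a.grid.shape != b.grid.shape or a.pixel_width_km != b.pixel_width_km:
        raise ValueError("rasters are not on a common grid")


def multiply_renormalize(a: GeoRaster, b: GeoRaster) -> GeoRaster:
    """Cell-wise product renormalized to a density: treats the two rasters
    as independent evidence about the same location."""
    _check_same_grid(a, b)
    prod = a.grid * b.grid
    denom = prod.sum() * a.da
    if denom == 0:
        raise IncompatibleEvidenceError("rasters have disjoint support")
    return GeoRaster(
        ref_lat=a.ref_lat, ref_lon=a.ref_lon, e_min=a.e_min, n_min=a.n_min,
        pixel_width_km=a.pixel_width_km, grid=prod / denom, method="multiplied",
    )


def raster_weight(a: GeoRaster) -> float:
    """Concentration weight: Σ p² · da. Uniform density over area A gives
    1/A; a point mass in one cell gives 1/da."""
    return float((a.grid ** 2).sum() * a.da)


def weighted_average(a: GeoRaster, b: GeoRaster) -> GeoRaster:
    """Average the rasters, weighting each by its concentration."""
    _check_same_grid(a, b)
    wa = raster_weight(a)
    wb = raster_weight(b)
    if wa + wb == 0:
        raise ValueError("both rasters are empty")
    grid = (a.grid * wa + b.grid * wb) / (wa + wb)
    return GeoRaster(
        ref_lat=a.ref_lat, ref_lon=a.ref_lon, e_min=a.e_min, n_min=a.n_min,
        pixel_width_km=a.pixel_width_km, grid=grid, method="weighted_average",
    )


def fuse(
    before: Optional[AnchoredRaster],
    after: Optional[AnchoredRaster],
    t_scene,
    t_before=None,
    t_after=None,
    averaging_cutoff_min: float = AVERAGING_CUTOFF_MIN,
) -> GeoRaster:
    """Produce the single location-probability field for one vessel.

    One-sided evidence is used as-is; with both sides, the closest ping
    decides the rule — average within ``averaging_cutoff_min`` of the
    image, multiply beyond it.
    """
    if before is None and after is None:
        raise ValueError("at least one side must be present")
    if before is None or after is None:
        gr = resample_to_common_grid(before if after is None else after)
        gr.method = "single"
        return gr
    closest_min = min(
        abs((t_scene - t_before).total_seconds()),
        abs((t_after - t_scene).total_seconds()),
    ) / 60.0
    if closest_min <= averaging_cutoff_min:
        ga, gb = resample_to_common_grid(before, after, extent="union")
        return weighted_average(ga, gb)
    ga, gb = resample_to_common_grid(before, after, extent="intersection")
    return multiply_renormalize(ga, gb)
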