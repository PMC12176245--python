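"""Trailing-window kernel utilization distributions and territory polygons.

A pack's space use over a trailing window (7, 14, 30 or 90 days before an
anchor time) is summarized by a Gaussian kernel density estimate on a
regular grid, normalized to unit mass.  The territory is the isopleth of
that density enclosing a stated fraction of the mass — 95% by convention —
and a lower isopleth (default 50%) defines the territory core.  Boundary
distances are signed: negative inside the polygon, positive outside,
matching the convention that "inside the core" plots at negative distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import reduce

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, mapping
from shapely.ops import unary_union
from skimage import measure

__all__ = [
    "UDGrid",
    "TerritoryPolygon",
    "InsufficientWindowDataError",
    "fit_ud",
    "isopleth",
    "signed_boundary_distance",
    "count_overlapping_neighbors",
]

DEFAULT_GRID_SIZE = 256
TERRITORY_LEVEL = 0.95
CORE_LEVEL = 0.50


class InsufficientWindowDataError(ValueError):
    """Raised when a trailing window holds too few fixes for a KDE."""

    def __init__(self, pack_id, n_fixes: int, minimum: int):
        self.pack_id, self.n_fixes, self.minimum = pack_id, n_fixes, minimum
        super().__init__(
            f"pack {pack_id!r}: {n_fixes} fixes in window, need >= {minimum}"
        )


@dataclass
class UDGrid:
    """Kernel utilization distribution on a regular grid.

    ``density[i, j]`` is probability density (1/m^2) at node
    ``(x0 + j*res, y0 + i*res)``; densities integrate to one over the grid.
    """

    pack_id: object
    window_days: int
    anchor_time: pd.Timestamp
    density: np.ndarray
    origin: tuple[float, float]
    resolution: float
    bandwidth: float

    @property
    def cell_area(self) -> float:
        return self.resolution ** 2

    @property
    def x_nodes(self) -> np.ndarray:
        return self.origin[0] + self.resolution * np.arange(self.density.shape[1])

    @property
    def y_nodes(self) -> np.ndarray:
        return self.origin[1] + self.resolution * np.arange(self.density.shape[0])

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)

    def mass_inside(self, polygon: "TerritoryPolygon") -> float:
        """UD mass enclosed by a polygon, by grid integration over nodes."""
        xx, yy = np.meshgrid(self.x_nodes, self.y_nodes)
        pts = shapely.points(xx.ravel(), yy.ravel())
        geom = getattr(polygon, "geometry", polygon)
        inside = shapely.covers(geom, pts).reshape(self.density.shape)
        return float(self.density[inside].sum() * self.cell_area)

    def to_tiff(self, path) -> None:
        from .covariates import LandscapeLayer

        LandscapeLayer(
            name=f"ud_{self.pack_id}_{self.window_days}d",
            grid=self.density, origin=self.origin,
            resolution=self.resolution, kind="index",
        ).to_tiff(path)


@dataclass
class TerritoryPolygon:
    """Isopleth polygon(s) of a UD at a mass level (0.95 = territory)."""

    pack_id: object
    window_days: int
    level: float
    geometry: shapely.Geometry  # Polygon or MultiPolygon
    anchor_time: pd.Timestamp
    degenerate: bool = False

    @property
    def rings(self) -> list[Polygon]:
        geom = self.geometry
        if geom.geom_type == "Polygon":
            return [geom]
        return list(geom.geoms)

    def contains(self, point) -> bool:
        """Containment with boundary points counting as inside."""
        return bool(self.geometry.covers(Point(point)))

    def area(self) -> float:
        return float(self.geometry.area)

    def to_geojson(self) -> dict:
        return {
            "type": "Feature",
            "geometry": mapping(self.geometry),
            "properties": {
                "pack_id": str(self.pack_id),
                "window_days": int(self.window_days),
                "level": float(self.level),
                "anchor_time": str(self.anchor_time),
            },
        }


def reference_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Isotropic multivariate reference ("href") bandwidth.

    h = sigma * n^(-1/6) with sigma^2 the mean of the two coordinate
    variances — the deterministic default of standard home-range workflows.
    """
    n = len(x)
    sigma = np.sqrt(0.5 * (np.var(x, ddof=1) + np.var(y, ddof=1)))
    return float(sigma * n ** (-1.0 / 6.0))


def fit_ud(
    fixes: pd.DataFrame,
    pack_id,
    anchor_time,
    window_days: int,
    grid_size: int = DEFAULT_GRID_SIZE,
    min_fixes: int = 5,
    season: str | None = None,
    bandwidth: float | None = None,
) -> UDGrid:
    """Gaussian-kernel UD from a pack's fixes in (anchor - window, anchor].

    ``season`` optionally restricts the window to fixes whose timestamp
    falls in that flooding season (used for the 90-day availability domain,
    which is seasonally restricted).  Bandwidth defaults to the reference
    rule; the grid covers the windowed fixes padded by 3.5 bandwidths so
    essentially all kernel mass is on the grid, and the density is
    renormalized to integrate to exactly one.
    """
    anchor_time = pd.Timestamp(anchor_time)
    sel = fixes[fixes["pack_id"] == pack_id].copy()
    t = pd.to_datetime(sel["timestamp"])
    lo = anchor_time - pd.Timedelta(days=window_days)
    sel = sel[(t > lo) & (t <= anchor_time)]
    if season is not None:
        from .covariates import assign_season

        keep = pd.to_datetime(sel["timestamp"]).map(assign_season) == season
        sel = sel[keep]
    if len(sel) < min_fixes:
        raise InsufficientWindowDataError(pack_id, len(sel), min_fixes)

    x = sel["x"].to_numpy(dtype=float)
    y = sel["y"].to_numpy(dtype=float)
    h = bandwidth if bandwidth is not None else reference_bandwidth(x, y)
    if h <= 0:  # all fixes coincident: fall back to a token kernel width
        h = 1.0

    pad = 3.5 * h
    x0, x1 = x.min() - pad, x.max() + pad
    y0, y1 = y.min() - pad, y.max() + pad
    side = max(x1 - x0, y1 - y0)
    res = side / (grid_size - 1)
    xs = x0 + res * np.arange(grid_size)
    ys = y0 + res * np.arange(grid_size)

    # direct kernel sum, vectorized one axis at a time to bound memory
    gx = np.exp(-0.5 * ((xs[:, None] - x[None, :]) / h) ** 2)  # (gx, n)
    gy = np.exp(-0.5 * ((ys[:, None] - y[None, :]) / h) ** 2)  # (gy, n)
    dens = gy @ gx.T  # (gy, gx): sum_k gy[i,k] gx[j,k]
    dens /= len(x) * 2.0 * np.pi * h * h
    dens /= dens.sum() * res * res  # renormalize truncated tails to unit mass

    return UDGrid(
        pack_id=pack_id, window_days=window_days, anchor_time=anchor_time,
        density=dens, origin=(x0, y0), resolution=res, bandwidth=h,
    )


def _isopleth_threshold(ud: UDGrid, level: float) -> float:
    """Density threshold of the smallest-area region holding `level` mass."""
    flat = np.sort(ud.density.ravel())[::-1]
    cum = np.cumsum(flat) * ud.cell_area
    idx = int(np.searchsorted(cum, level))
    idx = min(idx, len(flat) - 1)
    return float(flat[idx])


def isopleth(ud: UDGrid, level: float) -> TerritoryPolygon:
    """Extract the isopleth polygon enclosing `level` of the UD mass.

    The threshold is found by descending cumulative cell mass; the contour
    at that threshold is traced by marching squares on a zero-padded copy
    of the grid (so rings always close).  Rings are combined by even-odd
    filling, which turns interior low-density rings into holes.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    thr = _isopleth_threshold(ud, level)

    if (ud.density >= thr).sum() <= 1:
        i, j = np.unravel_index(np.argmax(ud.density), ud.density.shape)
        cx = ud.origin[0] + j * ud.resolution
        cy = ud.origin[1] + i * ud.resolution
        half = ud.resolution / 2.0
        warnings.warn(
            f"degenerate UD for pack {ud.pack_id!r}: single cell above "
            "isopleth threshold", stacklevel=2,
        )
        square = Polygon(
            [(cx - half, cy - half), (cx + half, cy - half),
             (cx + half, cy + half), (cx - half, cy + half)]
        )
        return TerritoryPolygon(
            pack_id=ud.pack_id, window_days=ud.window_days, level=level,
            geometry=square, anchor_time=ud.anchor_time, degenerate=True,
        )

    padded = np.pad(ud.density, 1, mode="constant")
    contours = measure.find_contours(padded, thr)
    rings = []
    for c in contours:
        # padded (row, col) -> (x, y); the pad shifts indices by one
        xy = np.column_stack(
            [ud.origin[0] + (c[:, 1] - 1) * ud.resolution,
             ud.origin[1] + (c[:, 0] - 1) * ud.resolution]
        )
        if len(xy) >= 4:
            poly = Polygon(xy)
            if poly.is_valid and poly.area > 0:
                rings.append(poly)
    if not rings:
        raise RuntimeError("isopleth contouring produced no rings")
    geom = reduce(lambda a, b: a.symmetric_difference(b), rings)
    geom = unary_union(geom)  # normalize
    return TerritoryPolygon(
        pack_id=ud.pack_id, window_days=ud.window_days, level=level,
        geometry=geom, anchor_time=ud.anchor_time,
    )


def signed_boundary_distance(point, polygon: TerritoryPolygon | shapely.Geometry) -> float:
    """Signed Euclidean distance to the polygon boundary, in meters.

    Negative inside the polygon, positive outside, zero on the boundary.
    """
    geom = polygon.geometry if isinstance(polygon, TerritoryPolygon) else polygon
    if geom.is_empty:
        raise ValueError("empty polygon")
    p = Point(point)
    d = float(p.distance(geom.boundary))
    return -d if geom.covers(p) else d


def count_overlapping_neighbors(point, neighbor_polys) -> int:
    """Number of neighbor territory polygons covering the point.

    Boundary points count as inside.
    """
    p = Point(point)
    total = 0
    for poly in neighbor_polys:
        geom = poly.geometry if isinstance(poly, TerritoryPolygon) else poly
        total += bool(geom.covers(p))
    return total
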