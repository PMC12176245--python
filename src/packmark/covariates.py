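"""Landscape and territorial covariates.

Points (scent marks, behavioral observations, available locations) are
joined to raster distance surfaces by bilinear interpolation and to
territory polygons by signed boundary distance / containment.  Columns are
standardized (mean-centered, unit SD) before model fitting, and screened
pairwise for collinearity: two terms may enter the same model only when
their Pearson correlation satisfies |r| < 0.6.

Seasons follow the Okavango Delta flooding calendar: early flood
(April-July), late flood (August-November), rainy (December-March).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "LandscapeLayer",
    "CovariateMatrix",
    "sample_covariates",
    "standardize",
    "back_transform",
    "collinearity_screen",
    "assign_season",
    "SEASONS",
]

SEASONS = ("early_flood", "late_flood", "rainy")

_MONTH_TO_SEASON = {
    4: "early_flood", 5: "early_flood", 6: "early_flood", 7: "early_flood",
    8: "late_flood", 9: "late_flood", 10: "late_flood", 11: "late_flood",
    12: "rainy", 1: "rainy", 2: "rainy", 3: "rainy",
}


@dataclass
class LandscapeLayer:
    """A single-band raster covariate surface in projected meters.

    ``grid[i, j]`` is the value at node ``(x0 + j*res, y0 + i*res)``;
    for ``kind == "distance"`` values are Euclidean distance in meters to
    the nearest feature of the layer, for ``kind == "index"`` they are a
    unitless index (e.g. terrain roughness).
    """

    name: str
    grid: np.ndarray
    origin: tuple[float, float]  # (x0, y0) of the grid node [0, 0]
    resolution: float  # node spacing, meters
    kind: str = "distance"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError(f"layer {self.name!r}: grid must be 2-D")
        if self.kind == "distance" and (self.grid < 0).any():
            raise ValueError(f"layer {self.name!r}: negative distances")

    @property
    def x_nodes(self) -> np.ndarray:
        return self.origin[0] + self.resolution * np.arange(self.grid.shape[1])

    @property
    def y_nodes(self) -> np.ndarray:
        return self.origin[1] + self.resolution * np.arange(self.grid.shape[0])

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.y_nodes, self.x_nodes), self.grid,
            method="linear", bounds_error=True,
        )

    def sample(self, x, y) -> np.ndarray:
        """Bilinear interpolation at arbitrary points inside the extent."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        try:
            return self.interpolator()(np.column_stack([y, x]))
        except ValueError as exc:
            xs, ys = self.x_nodes, self.y_nodes
            bad = (x < xs[0]) | (x > xs[-1]) | (y < ys[0]) | (y > ys[-1])
            if bad.any():
                i = int(np.argmax(bad))
                raise ValueError(
                    f"point ({x[i]:.1f}, {y[i]:.1f}) outside extent of "
                    f"layer {self.name!r}"
                ) from exc
            raise

    def to_tiff(self, path: str | Path) -> None:
        """Write as a single-band float TIFF with a sidecar JSON of the
        georeferencing (origin, resolution) since tags are not embedded."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.grid.astype(np.float32))
        meta = {
            "name": self.name,
            "origin": list(self.origin),
            "resolution": self.resolution,
            "kind": self.kind,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=1)
        )


@dataclass
class CovariateMatrix:
    """Point-by-term covariate table with an optional standardization record.

    ``center``/``scale`` are per-column mean and SD recorded at
    standardization time so fitted coefficients can be mapped back to
    natural units.
    """

    data: pd.DataFrame
    center: pd.Series | None = None
    scale: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return list(self.data.columns)

    @property
    def standardized(self) -> bool:
        return self.center is not None

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        if self.standardized:
            sidecar = {
                "center": {k: float(v) for k, v in self.center.items()},
                "scale": {k: float(v) for k, v in self.scale.items()},
            }
            path.with_suffix(".standardization.json").write_text(
                json.dumps(sidecar, indent=1, sort_keys=True)
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CovariateMatrix":
        path = Path(path)
        data = pd.read_csv(path)
        center = scale = None
        sidecar = path.with_suffix(".standardization.json")
        if sidecar.exists():
            d = json.loads(sidecar.read_text())
            center = pd.Series(d["center"])
            scale = pd.Series(d["scale"])
        return cls(data=data, center=center, scale=scale)


def assign_season(t) -> str:
    """Map a timestamp to the flooding season of its calendar month."""
    return _MONTH_TO_SEASON[pd.Timestamp(t).month]


def sample_covariates(
    points: pd.DataFrame,
    layers: dict[str, LandscapeLayer],
    own_territory=None,
    own_core=None,
    neighbor_territories=(),
) -> CovariateMatrix:
    """Spatially join points to raster layers and territory polygons.

    Parameters
    ----------
    points
        Table with ``x``/``y`` columns (projected meters).
    layers
        Mapping of layer name to :class:`LandscapeLayer`; each contributes
        one column named ``dist_<name>`` (distance layers) or ``<name>``
        (index layers).
    own_territory, own_core
        The focal pack's 95% territory and core polygons
        (:class:`~packmark.territory.TerritoryPolygon`); contribute a
        residency indicator and the signed distance to the core boundary
        (negative inside).
    neighbor_territories
        Iterable of neighbor territory polygons; contribute the signed
        distance to the nearest neighbor boundary and the count of
        overlapping neighbors at the point.
    """
    from .territory import count_overlapping_neighbors, signed_boundary_distance

    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {}
    for name, layer in layers.items():
        col = name if layer.kind == "index" else f"dist_{name}"
        cols[col] = layer.sample(x, y)

    if own_core is not None:
        cols["own_core_dist"] = np.array(
            [signed_boundary_distance((xi, yi), own_core) for xi, yi in zip(x, y)]
        )
    if own_territory is not None:
        cols["residency"] = np.array(
            [float(own_territory.contains((xi, yi))) for xi, yi in zip(x, y)]
        )
    neighbor_territories = list(neighbor_territories)
    if neighbor_territories:
        cols["neighbor_boundary_dist"] = np.array(
            [
                min(
                    signed_boundary_distance((xi, yi), p)
                    for p in neighbor_territories
                )
                for xi, yi in zip(x, y)
            ]
        )
        cols["n_neighbors"] = np.array(
            [
                float(count_overlapping_neighbors((xi, yi), neighbor_territories))
                for xi, yi in zip(x, y)
            ]
        )
    return CovariateMatrix(data=pd.DataFrame(cols, index=points.index))


def standardize(matrix: CovariateMatrix, columns=None) -> CovariateMatrix:
    """Mean-center and scale columns to unit SD (ddof=1).

    Raises on zero-variance columns, which carry no information and would
    divide by zero.
    """
    data = matrix.data.copy()
    columns = list(columns) if columns is not None else list(data.columns)
    center = data[columns].mean()
    scale = data[columns].std(ddof=1)
    zero = scale[scale == 0]
    if len(zero):
        raise ValueError(f"zero-variance column(s): {list(zero.index)}")
    data[columns] = (data[columns] - center) / scale
    return CovariateMatrix(data=data, center=center, scale=scale,
                           meta=dict(matrix.meta))


def back_transform(matrix: CovariateMatrix) -> CovariateMatrix:
    """Invert :func:`standardize` using the recorded center and scale."""
    if not matrix.standardized:
        raise ValueError("matrix carries no standardization record")
    data = matrix.data.copy()
    cols = list(matrix.center.index)
    data[cols] = data[cols] * matrix.scale + matrix.center
    return CovariateMatrix(data=data, meta=dict(matrix.meta))


def collinearity_screen(matrix: CovariateMatrix, threshold: float = 0.6) -> pd.DataFrame:
    """Pairwise Pearson correlations with an admissibility flag.

    Returns one row per unordered column pair with columns ``term_a``,
    ``term_b``, ``r`` and ``admissible`` (|r| < threshold).  The candidate
    set builder refuses to co-include inadmissible pairs.
    """
    data = matrix.data.select_dtypes(include=[np.number])
    if len(data) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    corr = data.corr()
    rows = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = float(corr.loc[a, b])
            rows.append(
                {"term_a": a, "term_b": b, "r": r,
                 "admissible": bool(abs(r) < threshold)}
            )
    return pd.DataFrame(rows)


def inadmissible_pairs(report: pd.DataFrame) -> set[frozenset]:
    """Set of flagged column pairs from a collinearity report."""
    bad = report.loc[~report["admissible"]]
    return {frozenset((a, b)) for a, b in zip(bad["term_a"], bad["term_b"])}
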