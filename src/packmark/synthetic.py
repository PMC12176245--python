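"""Synthetic landscapes, pack trajectories and behavioral follows.

The field data behind these analyses (GPS collars and behavioral follows
of an endangered carnivore) are restricted, so every downstream stage is
exercised on simulated inputs with known ground truth instead:

* a square landscape with distance-to-feature surfaces (roads, seasonal
  pans, grassland, permanent water, covered habitat) and a terrain index,
* one mean-reverting Gaussian (discrete-time Ornstein-Uhlenbeck) movement
  track per pack, whose stationary distribution is closed-form so spread
  and overlap are exactly testable,
* behavioral follows whose scent-mark probability at each step follows the
  logistic model logit(p) = alpha_j + beta . z with configurable true
  coefficients on standardized covariates, and hunts drawn among the
  remaining steps at a fixed rate.

All randomness flows from one root seed through named substreams
(landscape / fixes / follows), so each stage can be regenerated
independently and a fixed seed yields byte-identical output.

Defaults are sized to the study system: packs hold territories of a few
hundred km^2 with substantial neighbor overlap, fixes arrive every 3 h for
90 days, pack sizes are 3-16 adults with pup presence roughly even.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point

from .covariates import LandscapeLayer

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_landscape",
    "simulate_fixes",
    "simulate_follows",
    "simulate",
    "distance_layer",
    "simulate_rsf_points",
    "simulate_aggregates",
    "stationary_sd",
]

_SUBSTREAMS = {"landscape": 0, "fixes": 1, "follows": 2, "misc": 3}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of the root seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAMS[name],))
    return np.random.default_rng(ss)


@dataclass
class SimConfig:
    """Ground-truth parameters of one simulation.

    ``truth_beta`` maps covariate term names (matching the columns that
    :func:`packmark.covariates.sample_covariates` produces) to the true
    logistic coefficients on standardized covariates; ``truth_intercepts``
    maps pack ids to the true baseline log-odds of scent marking.
    """

    seed: int = 0
    extent: float = 60_000.0  # square side, meters
    n_packs: int = 3
    fixes_per_pack: int = 720  # 90 days at 3-h resolution
    fix_interval: float = 3.0  # hours
    n_follows_per_pack: int = 12
    truth_beta: dict = field(
        default_factory=lambda: {"dist_road": -0.8, "dist_pan": -0.5}
    )
    truth_intercepts: dict = field(default_factory=dict)
    landscape_spec: dict = field(
        default_factory=lambda: {
            "road": 10, "pan": 30, "grassland": 25, "water": 15,
            "woodland_mixed": 18, "woodland_mopane": 18,
        }
    )
    # movement: discrete-time mean-reverting Gaussian walk per pack
    home_sigma: float = 4_000.0  # stationary SD of position, meters
    reversion: float = 0.7  # AR(1) coefficient phi in (0, 1)
    center_spacing_sigma: float = 2.2  # center spacing in units of sigma
    # follows
    events_per_follow: int = 25
    event_step_minutes: float = 6.0
    follow_step_sd: float = 350.0  # per-event displacement SD, meters
    base_mark_logit: float = -1.5
    hunt_prob: float = 0.2  # among non-mark events
    grid_size: int = 128
    start_time: str = "2020-01-01T00:00:00"

    def __post_init__(self):
        if self.n_packs < 2:
            raise ValueError("need n_packs >= 2 so neighbor covariates exist")
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be positive")
        if not self.truth_intercepts:
            self.truth_intercepts = {
                f"pack_{k}": self.base_mark_logit for k in range(self.n_packs)
            }

    @property
    def pack_ids(self) -> list[str]:
        return [f"pack_{k}" for k in range(self.n_packs)]


@dataclass
class SimOutput:
    fixes: pd.DataFrame
    events: pd.DataFrame
    layers: dict[str, LandscapeLayer]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fixes = self.fixes.copy()
        fixes["timestamp"] = pd.to_datetime(fixes["timestamp"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
        fixes.to_csv(outdir / "fixes.csv", index=False)
        events = self.events.copy()
        events["timestamp"] = pd.to_datetime(events["timestamp"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
        events.to_csv(outdir / "events.csv", index=False)
        for name, layer in self.layers.items():
            layer.to_tiff(outdir / f"layer_{name}.tif")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=1, sort_keys=True, default=str)
        )


def stationary_sd(config: SimConfig) -> float:
    """Closed-form stationary SD of the movement process (= home_sigma)."""
    return config.home_sigma


def distance_layer(name, geoms, extent, grid_size=128, origin=(0.0, 0.0)) -> LandscapeLayer:
    """Exact Euclidean distance-to-nearest-feature raster for geometries."""
    if not geoms:
        raise ValueError(f"layer {name!r}: no features supplied")
    res = extent / (grid_size - 1)
    xs = origin[0] + res * np.arange(grid_size)
    ys = origin[1] + res * np.arange(grid_size)
    xx, yy = np.meshgrid(xs, ys)
    pts = shapely.points(xx.ravel(), yy.ravel())
    union = shapely.union_all(list(geoms))
    d = shapely.distance(pts, union).reshape(grid_size, grid_size)
    return LandscapeLayer(
        name=name, grid=d, origin=origin, resolution=res, kind="distance"
    )


def _random_points(rng, n, extent) -> list[Point]:
    return [Point(x, y) for x, y in rng.uniform(0.05, 0.95, (n, 2)) * extent]


def _random_roads(rng, n, extent) -> list[LineString]:
    """Random chords across the extent emulating the sand-track network."""
    roads = []
    for _ in range(n):
        theta = rng.uniform(0, np.pi)
        cx, cy = rng.uniform(0.2, 0.8, 2) * extent
        dx, dy = np.cos(theta), np.sin(theta)
        half = extent  # long enough to cross the square
        roads.append(
            LineString(
                [(cx - half * dx, cy - half * dy), (cx + half * dx, cy + half * dy)]
            )
        )
    return roads


def _terrain_layer(rng, extent, grid_size) -> LandscapeLayer:
    """Smooth synthetic terrain roughness/elevation index in [0, 1]."""
    res = extent / (grid_size - 1)
    xs = res * np.arange(grid_size)
    ys = res * np.arange(grid_size)
    xx, yy = np.meshgrid(xs, ys)
    z = np.zeros_like(xx)
    for _ in range(12):
        cx, cy = rng.uniform(0, extent, 2)
        s = rng.uniform(0.1, 0.3) * extent
        a = rng.uniform(0.3, 1.0)
        z += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s * s))
    z = (z - z.min()) / (z.max() - z.min())
    return LandscapeLayer(
        name="terrain", grid=z, origin=(0.0, 0.0), resolution=res, kind="index"
    )


def simulate_landscape(config: SimConfig) -> dict[str, LandscapeLayer]:
    """Distance surfaces plus the terrain index and derived cover layer.

    Covered habitat is the minimum of the two woodland distance surfaces
    (distance to the nearest woodland of either type).
    """
    rng = substream(config.seed, "landscape")
    spec = config.landscape_spec
    for key, n in spec.items():
        if n <= 0:
            raise ValueError(f"layer {key!r}: at least one feature required")
    gs = config.grid_size
    ext = config.extent
    layers = {
        "road": distance_layer("road", _random_roads(rng, spec["road"], ext), ext, gs),
        "pan": distance_layer("pan", _random_points(rng, spec["pan"], ext), ext, gs),
        "grassland": distance_layer(
            "grassland", _random_points(rng, spec["grassland"], ext), ext, gs
        ),
        "water": distance_layer(
            "water", _random_points(rng, spec["water"], ext), ext, gs
        ),
    }
    mixed = distance_layer(
        "woodland_mixed", _random_points(rng, spec["woodland_mixed"], ext), ext, gs
    )
    mopane = distance_layer(
        "woodland_mopane", _random_points(rng, spec["woodland_mopane"], ext), ext, gs
    )
    layers["cover"] = LandscapeLayer(
        name="cover", grid=np.minimum(mixed.grid, mopane.grid),
        origin=(0.0, 0.0), resolution=ext / (gs - 1), kind="distance",
    )
    layers["terrain"] = _terrain_layer(rng, ext, gs)
    return layers


def pack_centers(config: SimConfig) -> dict[str, tuple[float, float]]:
    """Deterministic pack centers on a ring, spaced so territories overlap."""
    spacing = config.center_spacing_sigma * config.home_sigma
    n = config.n_packs
    cx = cy = config.extent / 2.0
    if n == 1:
        return {config.pack_ids[0]: (cx, cy)}
    # ring radius giving chord length = spacing between adjacent centers
    radius = spacing / (2.0 * np.sin(np.pi / n)) if n > 2 else spacing / 2.0
    centers = {}
    for k, pid in enumerate(config.pack_ids):
        ang = 2.0 * np.pi * k / n
        centers[pid] = (cx + radius * np.cos(ang), cy + radius * np.sin(ang))
    return centers


def simulate_fixes(config: SimConfig) -> pd.DataFrame:
    """Regular 3-h fixes per pack from a mean-reverting Gaussian walk.

    x_{t+1} = c + phi (x_t - c) + eps with eps ~ N(0, sigma^2 (1 - phi^2)),
    so the stationary distribution is exactly N(c, sigma^2) per axis
    whatever the reversion strength.
    """
    rng = substream(config.seed, "fixes")
    centers = pack_centers(config)
    phi = config.reversion
    sigma = config.home_sigma
    step_sd = sigma * np.sqrt(1.0 - phi * phi)
    t0 = pd.Timestamp(config.start_time)
    dt = pd.Timedelta(hours=config.fix_interval)
    frames = []
    for pid in config.pack_ids:
        c = np.asarray(centers[pid])
        n = config.fixes_per_pack
        pos = np.empty((n, 2))
        pos[0] = c + rng.normal(0.0, sigma, 2)  # start at stationarity
        noise = rng.normal(0.0, step_sd, (n - 1, 2))
        for i in range(1, n):
            pos[i] = c + phi * (pos[i - 1] - c) + noise[i - 1]
        frames.append(
            pd.DataFrame(
                {
                    "pack_id": pid,
                    "timestamp": [t0 + k * dt for k in range(n)],
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def layer_standardization(layers: dict[str, LandscapeLayer]) -> tuple[dict, dict]:
    """Grid-wide mean and SD per covariate column (the truth scale).

    The generator evaluates its logistic model on covariates standardized
    by these constants, which are echoed in the truth record so recovery
    tests can fit on the same scale.
    """
    center, scale = {}, {}
    for name, layer in layers.items():
        col = name if layer.kind == "index" else f"dist_{name}"
        center[col] = float(layer.grid.mean())
        scale[col] = float(layer.grid.std(ddof=1))
    return center, scale


def _standardized_covariates(points_xy, layers, center, scale, terms):
    from .covariates import sample_covariates

    pts = pd.DataFrame({"x": points_xy[:, 0], "y": points_xy[:, 1]})
    cm = sample_covariates(pts, layers)
    Z = np.column_stack(
        [
            (cm.data[t].to_numpy() - center[t]) / scale[t]
            for t in terms
        ]
    )
    return Z


def simulate_follows(
    config: SimConfig,
    layers: dict[str, LandscapeLayer],
    territories: dict | None = None,
) -> pd.DataFrame:
    """Behavioral follows with Bernoulli scent marks from the truth model.

    Each follow starts inside the pack's territory (uniform rejection
    sample; falls back to the stationary Gaussian around the pack center
    when no territory polygon is given) and wanders by a Gaussian step
    walk.  At each event the scent-mark probability is
    logistic(alpha_j + beta . z); non-mark events are hunts with
    probability ``hunt_prob``, otherwise moves or rests.  Pack social
    attributes (adults 3-16, pup presence fair coin, pack age 0-8 years)
    are drawn once per pack and held constant within follows.
    """
    rng = substream(config.seed, "follows")
    centers = pack_centers(config)
    center, scale = layer_standardization(layers)
    terms = list(config.truth_beta.keys())
    beta = np.array([config.truth_beta[t] for t in terms])
    t0 = pd.Timestamp(config.start_time) + pd.Timedelta(days=91)
    lo, hi = 0.0, config.extent

    social = {}
    for pid in config.pack_ids:
        social[pid] = {
            "pack_size": int(rng.integers(3, 17)),
            "pup_presence": bool(rng.random() < 0.5),
            "pack_age": float(rng.uniform(0.0, 8.0)),
        }

    rows = []
    follow_counter = 0
    for pid in config.pack_ids:
        geom = None
        if territories and pid in territories:
            tp = territories[pid]
            geom = getattr(tp, "geometry", tp)
        for _ in range(config.n_follows_per_pack):
            follow_counter += 1
            fid = f"F{follow_counter:04d}"
            if geom is not None:
                minx, miny, maxx, maxy = geom.bounds
                while True:
                    cand = rng.uniform([minx, miny], [maxx, maxy])
                    if geom.covers(Point(cand)):
                        start = cand
                        break
            else:
                start = np.asarray(centers[pid]) + rng.normal(
                    0.0, config.home_sigma, 2
                )
            n_ev = config.events_per_follow
            steps = rng.normal(0.0, config.follow_step_sd, (n_ev - 1, 2))
            pos = np.vstack([start, start + np.cumsum(steps, axis=0)])
            pos = np.clip(pos, lo + 1.0, hi - 1.0)
            gaps_min = rng.uniform(
                0.5 * config.event_step_minutes,
                1.5 * config.event_step_minutes,
                n_ev - 1,
            )
            times = t0 + pd.to_timedelta(
                np.concatenate([[0.0], np.cumsum(gaps_min)]), unit="m"
            ) + pd.Timedelta(days=int(rng.integers(0, 300)))

            Z = _standardized_covariates(pos, layers, center, scale, terms)
            eta = config.truth_intercepts[pid] + Z @ beta
            p_mark = 1.0 / (1.0 + np.exp(-eta))
            is_mark = rng.random(n_ev) < p_mark
            behavior = np.where(is_mark, "scent_mark", "move")
            others = ~is_mark
            u = rng.random(n_ev)
            behavior[others & (u < config.hunt_prob)] = "hunt"
            behavior[others & (u >= config.hunt_prob) & (u < 0.6)] = "move"
            behavior[others & (u >= 0.6)] = "rest"

            for i in range(n_ev):
                rows.append(
                    {
                        "pack_id": pid,
                        "follow_id": fid,
                        "timestamp": times[i],
                        "x": pos[i, 0],
                        "y": pos[i, 1],
                        "behavior_class": behavior[i],
                        **social[pid],
                    }
                )
    return pd.DataFrame(rows)


def simulate(config: SimConfig, with_territories: bool = True) -> SimOutput:
    """Full simulation: landscape -> fixes -> territories -> follows."""
    from .territory import TERRITORY_LEVEL, fit_ud, isopleth

    layers = simulate_landscape(config)
    fixes = simulate_fixes(config)
    territories = None
    if with_territories:
        anchor = pd.to_datetime(fixes["timestamp"]).max()
        territories = {}
        for pid in config.pack_ids:
            ud = fit_ud(fixes, pid, anchor, window_days=90)
            territories[pid] = isopleth(ud, TERRITORY_LEVEL)
    events = simulate_follows(config, layers, territories)
    center, scale = layer_standardization(layers)
    truth = {
        "config": asdict(config),
        "cov_center": center,
        "cov_scale": scale,
        "pack_centers": {k: list(v) for k, v in pack_centers(config).items()},
    }
    return SimOutput(fixes=fixes, events=events, layers=layers, truth=truth)


def simulate_rsf_points(
    rng: np.random.Generator,
    layers: dict[str, LandscapeLayer],
    territory,
    beta: dict[str, float],
    n_used: int,
    ratio: int = 15,
) -> pd.DataFrame:
    """Used/available design points with used intensity exp(beta . z).

    Used points are rejection-sampled inside the territory with acceptance
    proportional to exp(beta . z) (z standardized by grid-wide constants);
    available points are uniform in the territory.  Returns a weighted
    design table (used W=1, available W=100) ready for the RSF fit, with
    the standardized covariates as columns.
    """
    geom = getattr(territory, "geometry", territory)
    center, scale = layer_standardization(layers)
    terms = list(beta.keys())
    b = np.array([beta[t] for t in terms])
    minx, miny, maxx, maxy = geom.bounds

    def draw_inside(m):
        out = np.empty((0, 2))
        while len(out) < m:
            cand = rng.uniform([minx, miny], [maxx, maxy], (4 * m, 2))
            ok = shapely.covers(geom, shapely.points(cand[:, 0], cand[:, 1]))
            out = np.vstack([out, cand[ok]])
        return out[:m]

    # envelope constant: max of exp(beta.z) over candidate draws
    probe = draw_inside(2000)
    Zp = _standardized_covariates(probe, layers, center, scale, terms)
    log_m = (Zp @ b).max() + 0.5

    used = np.empty((0, 2))
    while len(used) < n_used:
        cand = draw_inside(4 * n_used)
        Z = _standardized_covariates(cand, layers, center, scale, terms)
        acc = rng.random(len(cand)) < np.exp(Z @ b - log_m)
        used = np.vstack([used, cand[acc]])
    used = used[:n_used]
    avail = draw_inside(ratio * n_used)

    pts = np.vstack([used, avail])
    Z = _standardized_covariates(pts, layers, center, scale, terms)
    df = pd.DataFrame(Z, columns=terms)
    df["response"] = [1] * n_used + [0] * (ratio * n_used)
    df["weight"] = np.where(df["response"] == 1, 1.0, 100.0)
    df["pack_id"] = getattr(territory, "pack_id", "pack_0")
    df["x"] = pts[:, 0]
    df["y"] = pts[:, 1]
    return df


def simulate_aggregates(
    rng: np.random.Generator,
    n_packs: int,
    follows_per_pack: int,
    beta: dict[str, float],
    intercept: float = 0.0,
    sigma: float = 0.6,
    tau: float = 0.4,
) -> pd.DataFrame:
    """Aggregated-follow table drawn from the trade-off mixed model.

    y_ij = intercept + u_j + x . beta + e, u_j ~ N(0, tau^2),
    e ~ N(0, sigma^2), covariates standard normal.  Ground truth for the
    REML recovery checks.
    """
    terms = list(beta.keys())
    b = np.array([beta[t] for t in terms])
    rows = []
    for j in range(n_packs):
        u = rng.normal(0.0, tau)
        for i in range(follows_per_pack):
            x = rng.normal(0.0, 1.0, len(terms))
            y = intercept + u + x @ b + rng.normal(0.0, sigma)
            row = {"pack_id": f"pack_{j}", "follow_id": f"F{j}_{i}",
                   "log_ratio": float(y)}
            row.update(dict(zip(terms, x.tolist())))
            rows.append(row)
    return pd.DataFrame(rows)
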