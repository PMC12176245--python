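"""Behavioral follows: segmentation, interpolation and design construction.

A follow is one continuous field observation session of a pack, from first
sighting to loss of contact, recorded by critical-incident sampling: a
location is logged only when a behavior occurs, so the behavioral state is
carried forward until the next recorded incident.  This module turns raw
fixes and behavioral events into the three analysis-ready shapes:

* regularized GPS tracks (3-hour resolution by default),
* used/unused design points (scent marks vs. other behaviors along follows,
  follows without any scent mark removed),
* aggregated follows: per-hour marking and hunting rates, their log ratio,
  and first-minus-last covariate deltas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BEHAVIOR_CLASSES",
    "Follow",
    "FollowAggregate",
    "regularize_track",
    "segment_follows",
    "interpolate_follow",
    "label_used_unused",
    "sample_availability",
    "aggregate_follow",
    "aggregate_follows",
]

BEHAVIOR_CLASSES = ("scent_mark", "hunt", "rest", "move", "other")

#: social attribute columns carried constant within a follow
SOCIAL_COLUMNS = ("pack_size", "pup_presence", "pack_age")


@dataclass
class Follow:
    """One observation session: time-ordered behavioral events of one pack."""

    pack_id: object
    follow_id: object
    events: pd.DataFrame

    @property
    def start(self) -> pd.Timestamp:
        return self.events["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.events["timestamp"].iloc[-1]

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)

    def count(self, behavior: str) -> int:
        return int((self.events["behavior_class"] == behavior).sum())


@dataclass
class FollowAggregate:
    """One follow collapsed to behavior rates and covariate deltas.

    ``log_ratio`` is ln(marks-per-hour / hunts-per-hour); a continuity
    constant added to both counts keeps it finite for zero-count follows.
    ``delta_<term>`` is covariate value at the first event minus at the
    last; ``delta_<term>_bin`` is 1 when that difference is positive, else
    0 (so e.g. a follow ending closer to a neighbor's boundary than it
    started has a positive "entering" delta).
    """

    follow_id: object
    pack_id: object
    duration_hours: float
    n_marks: int
    n_hunts: int
    marks_per_hour: float
    hunts_per_hour: float
    log_ratio: float
    deltas: dict[str, float] = field(default_factory=dict)
    deltas_bin: dict[str, int] = field(default_factory=dict)
    social: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "follow_id": self.follow_id,
            "pack_id": self.pack_id,
            "duration_hours": self.duration_hours,
            "n_marks": self.n_marks,
            "n_hunts": self.n_hunts,
            "marks_per_hour": self.marks_per_hour,
            "hunts_per_hour": self.hunts_per_hour,
            "log_ratio": self.log_ratio,
        }
        row.update({f"delta_{k}": v for k, v in self.deltas.items()})
        row.update({f"delta_{k}_bin": v for k, v in self.deltas_bin.items()})
        row.update(self.social)
        return row


def regularize_track(fixes: pd.DataFrame, interval_hours: float = 3.0) -> pd.DataFrame:
    """Resample a pack trajectory onto a regular time grid.

    Grid slots (first fix + k*interval) take the nearest fix within half an
    interval; empty slots are filled by linear interpolation across gaps of
    up to two intervals, and longer gaps are left missing (rows absent).
    An already-regular track passes through unchanged.
    """
    if len(fixes) == 0:
        return fixes.copy()
    if interval_hours <= 0:
        raise ValueError("interval must be positive")
    out_frames = []
    for pack_id, grp in fixes.groupby("pack_id", sort=False):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        t = pd.to_datetime(grp["timestamp"])
        t0 = t.iloc[0]
        sec = (t - t0).dt.total_seconds().to_numpy()
        step = interval_hours * 3600.0
        n_slots = int(np.floor(sec[-1] / step)) + 1
        slots = np.arange(n_slots) * step

        # nearest fix within tolerance per slot
        idx = np.searchsorted(sec, slots)
        idx = np.clip(idx, 0, len(sec) - 1)
        prev = np.clip(idx - 1, 0, len(sec) - 1)
        pick = np.where(
            np.abs(sec[idx] - slots) <= np.abs(sec[prev] - slots), idx, prev
        )
        ok = np.abs(sec[pick] - slots) <= step / 2.0

        xs = np.full(n_slots, np.nan)
        ys = np.full(n_slots, np.nan)
        xs[ok] = grp["x"].to_numpy()[pick[ok]]
        ys[ok] = grp["y"].to_numpy()[pick[ok]]

        # fill holes bounded by assigned slots no more than 2 intervals apart
        assigned = np.flatnonzero(ok)
        for a, b in zip(assigned[:-1], assigned[1:]):
            if 1 < b - a <= 2:
                for k in range(a + 1, b):
                    w = (k - a) / (b - a)
                    xs[k] = xs[a] * (1 - w) + xs[b] * w
                    ys[k] = ys[a] * (1 - w) + ys[b] * w

        keep = ~np.isnan(xs)
        out_frames.append(
            pd.DataFrame(
                {
                    "pack_id": pack_id,
                    "timestamp": t0 + pd.to_timedelta(slots[keep], unit="s"),
                    "x": xs[keep],
                    "y": ys[keep],
                }
            )
        )
    return pd.concat(out_frames, ignore_index=True)


def segment_follows(events: pd.DataFrame, min_events: int = 2) -> list[Follow]:
    """Split behavioral events into follows by (pack_id, follow_id).

    Follows with fewer than ``min_events`` events carry no usable track and
    are dropped with a warning.
    """
    follows = []
    for (pack_id, follow_id), grp in events.groupby(
        ["pack_id", "follow_id"], sort=True
    ):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        if len(grp) < min_events:
            warnings.warn(
                f"follow {follow_id!r} of pack {pack_id!r} has "
                f"{len(grp)} event(s); dropped", stacklevel=2,
            )
            continue
        follows.append(Follow(pack_id=pack_id, follow_id=follow_id, events=grp))
    return follows


def interpolate_follow(follow: Follow, step_minutes: float = 1.0) -> pd.DataFrame:
    """Evenly-spaced behavioral track over the follow.

    Positions are linearly interpolated between events; the behavioral
    state at each track point is the most recent recorded incident
    (critical-incident sampling implies the state persists until the next
    recorded behavior).
    """
    if step_minutes <= 0:
        raise ValueError("step must be positive")
    ev = follow.events
    t = pd.to_datetime(ev["timestamp"])
    sec = (t - t.iloc[0]).dt.total_seconds().to_numpy()
    grid = np.arange(0.0, sec[-1] + 1e-9, step_minutes * 60.0)
    x = np.interp(grid, sec, ev["x"].to_numpy(dtype=float))
    y = np.interp(grid, sec, ev["y"].to_numpy(dtype=float))
    state_idx = np.searchsorted(sec, grid, side="right") - 1
    state_idx = np.clip(state_idx, 0, len(sec) - 1)
    return pd.DataFrame(
        {
            "pack_id": follow.pack_id,
            "follow_id": follow.follow_id,
            "timestamp": t.iloc[0] + pd.to_timedelta(grid, unit="s"),
            "x": x,
            "y": y,
            "behavior_class": ev["behavior_class"].to_numpy()[state_idx],
        }
    )


def label_used_unused(follows: list[Follow]) -> pd.DataFrame:
    """Used/unused design points for the scent-marking probability model.

    Scent-mark events are used points (response 1); every other behavioral
    event along the same follows is an unused point (response 0).  Follows
    with no scent mark at all are removed entirely — with one intercept per
    pack-follow combination they would pin that intercept at minus
    infinity and contribute nothing.
    """
    rows = []
    for f in follows:
        if f.count("scent_mark") == 0:
            continue
        ev = f.events.copy()
        ev["response"] = (ev["behavior_class"] == "scent_mark").astype(int)
        rows.append(ev)
    if not rows:
        return pd.DataFrame(
            columns=["pack_id", "follow_id", "timestamp", "x", "y",
                     "behavior_class", "response"]
        )
    return pd.concat(rows, ignore_index=True)


def sample_availability(
    used: pd.DataFrame,
    territory,
    ratio: int = 15,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Uniform available points inside a territory polygon.

    Emits ``ratio`` available points per used point by rejection sampling
    from the polygon's bounding box.  The availability domain is the
    pack's trailing-window (90-day, season-restricted) 95% territory.
    """
    from shapely.geometry import Point

    geom = getattr(territory, "geometry", territory)
    if geom.is_empty or geom.area <= 0:
        raise ValueError("territory polygon has zero area")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = ratio * len(used)
    minx, miny, maxx, maxy = geom.bounds
    xs = np.empty(n)
    ys = np.empty(n)
    got = 0
    while got < n:
        m = max(2 * (n - got), 64)
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        import shapely

        inside = shapely.covers(geom, shapely.points(cx, cy))
        take = min(int(inside.sum()), n - got)
        xs[got:got + take] = cx[inside][:take]
        ys[got:got + take] = cy[inside][:take]
        got += take
    return pd.DataFrame({"x": xs, "y": ys})


def _covariates_at(point_xy, layers, territory_kwargs) -> dict[str, float]:
    from .covariates import sample_covariates

    pts = pd.DataFrame({"x": [point_xy[0]], "y": [point_xy[1]]})
    cm = sample_covariates(pts, layers, **territory_kwargs)
    return {k: float(v) for k, v in cm.data.iloc[0].items()}


def aggregate_follow(
    follow: Follow,
    layers=None,
    territory_kwargs: dict | None = None,
    c: float = 0.5,
) -> FollowAggregate:
    """Collapse one follow to the marking-vs-hunting trade-off record.

    Rates are (count + c) / duration with continuity constant ``c`` added
    to both behavior counts so the log ratio is finite when either count
    is zero; c cancels exactly when counts are equal.  With ``c = 0`` raw
    ratios are returned and zero-count follows raise.  Covariate deltas
    are first-event value minus last-event value, plus the binarized form
    (positive difference -> 1, otherwise 0).
    """
    dur = follow.duration_hours
    if dur <= 0:
        raise ValueError(
            f"follow {follow.follow_id!r} has zero duration; cannot form rates"
        )
    n_marks = follow.count("scent_mark")
    n_hunts = follow.count("hunt")
    if c == 0 and (n_marks == 0 or n_hunts == 0):
        raise ValueError(
            f"follow {follow.follow_id!r}: zero marks or hunts with c=0 "
            "makes the log ratio undefined"
        )
    marks_per_hour = (n_marks + c) / dur
    hunts_per_hour = (n_hunts + c) / dur
    log_ratio = float(np.log(marks_per_hour / hunts_per_hour))

    deltas: dict[str, float] = {}
    deltas_bin: dict[str, int] = {}
    if layers is not None:
        territory_kwargs = territory_kwargs or {}
        ev = follow.events
        first = _covariates_at(
            (ev["x"].iloc[0], ev["y"].iloc[0]), layers, territory_kwargs
        )
        last = _covariates_at(
            (ev["x"].iloc[-1], ev["y"].iloc[-1]), layers, territory_kwargs
        )
        for term in first:
            d = first[term] - last[term]
            deltas[term] = d
            deltas_bin[term] = 1 if d > 0 else 0

    social = {}
    for col in SOCIAL_COLUMNS:
        if col in follow.events.columns:
            social[col] = follow.events[col].iloc[0]
    return FollowAggregate(
        follow_id=follow.follow_id,
        pack_id=follow.pack_id,
        duration_hours=dur,
        n_marks=n_marks,
        n_hunts=n_hunts,
        marks_per_hour=marks_per_hour,
        hunts_per_hour=hunts_per_hour,
        log_ratio=log_ratio,
        deltas=deltas,
        deltas_bin=deltas_bin,
        social=social,
    )


def aggregate_follows(follows, layers=None, territory_kwargs=None, c: float = 0.5) -> pd.DataFrame:
    """Table of :func:`aggregate_follow` rows over a list of follows."""
    return pd.DataFrame(
        [aggregate_follow(f, layers, territory_kwargs, c).as_row() for f in follows]
    )
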