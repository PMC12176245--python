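"""Follow processing: regularization, segmentation, interpolation,
used/unused labeling, availability sampling, and follow aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import Polygon

from packmark.follows import (
    Follow,
    aggregate_follow,
    interpolate_follow,
    label_used_unused,
    regularize_track,
    sample_availability,
    segment_follows,
)


def _fixes(times_h, pack="p1"):
    t0 = pd.Timestamp("2020-01-01")
    return pd.DataFrame(
        {
            "pack_id": pack,
            "timestamp": [t0 + pd.Timedelta(hours=h) for h in times_h],
            "x": [10.0 * h for h in times_h],
            "y": [0.0 for _ in times_h],
        }
    )


def _make_follow(behaviors, minutes=None, pack="p1", fid="F1", xy=None):
    minutes = minutes if minutes is not None else list(range(len(behaviors)))
    t0 = pd.Timestamp("2020-06-01 08:00")
    xy = xy or [(float(m), 0.0) for m in minutes]
    return Follow(
        pack_id=pack,
        follow_id=fid,
        events=pd.DataFrame(
            {
                "pack_id": pack,
                "follow_id": fid,
                "timestamp": [t0 + pd.Timedelta(minutes=m) for m in minutes],
                "x": [p[0] for p in xy],
                "y": [p[1] for p in xy],
                "behavior_class": behaviors,
            }
        ),
    )


class TestRegularize:
    def test_already_regular_unchanged(self):
        fx = _fixes([0, 3, 6, 9, 12])
        out = regularize_track(fx, 3.0)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), fx.reset_index(drop=True),
            check_dtype=False,
        )

    def test_irregular_track_modal_interval_is_3h(self, rng):
        # activity-based fixes: gaps 0.5-6 h over ten days
        gaps = rng.uniform(0.5, 6.0, 200)
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        times = times[times <= 240.0]
        out = regularize_track(_fixes(times), 3.0)
        dt = pd.to_datetime(out["timestamp"]).diff().dropna()
        modal = dt.mode().iloc[0]
        assert modal == pd.Timedelta(hours=3)

    def test_single_gap_midpoint_is_linear(self):
        # fixes at 0 and 6 h: slot at 3 h interpolates to the midpoint
        fx = _fixes([0, 6, 9])
        out = regularize_track(fx, 3.0)
        mid = out[out["timestamp"] == pd.Timestamp("2020-01-01 03:00")]
        assert len(mid) == 1
        assert mid["x"].iloc[0] == pytest.approx((0.0 + 60.0) / 2)

    def test_long_gaps_left_missing(self):
        fx = _fixes([0, 3, 18, 21])  # 15-h hole: 4 empty slots
        out = regularize_track(fx, 3.0)
        hours = (pd.to_datetime(out["timestamp"])
                 - pd.Timestamp("2020-01-01")) / pd.Timedelta(hours=1)
        assert set(hours) == {0.0, 3.0, 18.0, 21.0}

    def test_empty_input_empty_output(self):
        fx = _fixes([])
        assert len(regularize_track(fx, 3.0)) == 0

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            regularize_track(_fixes([0, 3]), 0.0)


class TestSegment:
    def test_two_follow_ids_give_two_follows(self):
        a = _make_follow(["move", "hunt"], fid="F1").events
        b = _make_follow(["move", "rest"], fid="F2").events
        follows = segment_follows(pd.concat([a, b]))
        assert len(follows) == 2
        assert {f.follow_id for f in follows} == {"F1", "F2"}

    def test_start_is_earliest_event(self):
        f = _make_follow(["move", "hunt", "rest"], minutes=[5, 0, 10])
        ev = f.events.sample(frac=1.0, random_state=1)
        out = segment_follows(ev)[0]
        assert out.start == pd.Timestamp("2020-06-01 08:00")

    def test_durations_match_hand_computation(self):
        frames = [
            _make_follow(["move", "hunt"], minutes=[0, 90], fid="A").events,
            _make_follow(["move", "rest", "hunt"], minutes=[0, 30, 45], fid="B").events,
            _make_follow(["move", "move"], minutes=[10, 130], fid="C").events,
        ]
        follows = segment_follows(pd.concat(frames))
        durations = {f.follow_id: f.duration_hours for f in follows}
        assert durations == pytest.approx({"A": 1.5, "B": 0.75, "C": 2.0})

    def test_single_event_follow_dropped_with_warning(self):
        ev = pd.concat(
            [
                _make_follow(["move"], minutes=[0], fid="solo").events,
                _make_follow(["move", "hunt"], fid="ok").events,
            ]
        )
        with pytest.warns(UserWarning, match="solo"):
            follows = segment_follows(ev)
        assert [f.follow_id for f in follows] == ["ok"]


class TestInterpolate:
    def test_point_count(self):
        f = _make_follow(["move", "hunt", "rest"], minutes=[0, 10, 20])
        track = interpolate_follow(f, step_minutes=5)
        assert len(track) == 5

    def test_state_carried_forward_between_incidents(self):
        f = _make_follow(["move", "scent_mark"], minutes=[0, 10])
        track = interpolate_follow(f, step_minutes=2)
        # every point before minute 10 is in the "move" state
        before = track[track["timestamp"] < f.events["timestamp"].iloc[1]]
        assert (before["behavior_class"] == "move").all()
        assert track["behavior_class"].iloc[-1] == "scent_mark"

    def test_midpoint_position_is_coordinate_mean(self):
        f = _make_follow(["move", "hunt"], minutes=[0, 10],
                         xy=[(0.0, 0.0), (100.0, 40.0)])
        track = interpolate_follow(f, step_minutes=5)
        mid = track.iloc[1]
        assert mid["x"] == pytest.approx(50.0)
        assert mid["y"] == pytest.approx(20.0)


class TestLabelUsedUnused:
    def test_zero_mark_follow_contributes_no_rows(self):
        f = _make_follow(["move", "hunt", "rest"])
        assert len(label_used_unused([f])) == 0

    def test_three_marks_seven_others(self):
        beh = ["scent_mark"] * 3 + ["move", "hunt", "rest", "move",
                                    "hunt", "rest", "move"]
        f = _make_follow(beh)
        out = label_used_unused([f])
        assert int(out["response"].sum()) == 3
        assert int((out["response"] == 0).sum()) == 7

    def test_all_mark_follow_all_ones(self):
        f = _make_follow(["scent_mark"] * 4)
        out = label_used_unused([f])
        assert (out["response"] == 1).all()

    def test_conserves_events_of_retained_follows(self, events):
        follows = segment_follows(events)
        out = label_used_unused(follows)
        retained = [f for f in follows if f.count("scent_mark") > 0]
        assert len(out) == sum(len(f.events) for f in retained)


class TestSampleAvailability:
    SQUARE = Polygon([(0, 0), (400, 0), (400, 400), (0, 400)])

    def test_ratio_and_containment(self):
        used = pd.DataFrame({"x": np.full(20, 10.0), "y": np.full(20, 10.0)})
        pts = sample_availability(used, self.SQUARE, ratio=15, seed=5)
        assert len(pts) == 300
        assert pts["x"].between(0, 400).all() and pts["y"].between(0, 400).all()

    def test_same_seed_identical(self):
        used = pd.DataFrame({"x": [1.0], "y": [1.0]})
        a = sample_availability(used, self.SQUARE, ratio=15, seed=3)
        b = sample_availability(used, self.SQUARE, ratio=15, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_uniformity_chi2_over_grid_partition(self):
        used = pd.DataFrame({"x": np.zeros(1000), "y": np.zeros(1000)})
        pts = sample_availability(used, self.SQUARE, ratio=16, seed=9)
        ix = np.minimum((pts["x"] // 100).astype(int), 3)
        iy = np.minimum((pts["y"] // 100).astype(int), 3)
        counts = np.bincount(ix * 4 + iy, minlength=16)
        chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
        p = stats.chi2.sf(chi2, df=15)
        assert p > 0.001

    def test_zero_area_polygon_rejected(self):
        line_like = Polygon([(0, 0), (1, 0), (0, 0)])
        with pytest.raises(ValueError, match="zero area"):
            sample_availability(
                pd.DataFrame({"x": [0.0], "y": [0.0]}), line_like, 15, 1
            )


class TestAggregateFollow:
    def test_hand_arithmetic_with_c_zero(self):
        beh = (["scent_mark"] * 4 + ["hunt"] * 2 + ["move"] * 2)
        f = _make_follow(beh, minutes=[0, 10, 20, 40, 60, 80, 100, 120])
        agg = aggregate_follow(f, c=0.0)
        assert agg.marks_per_hour == pytest.approx(2.0)
        assert agg.hunts_per_hour == pytest.approx(1.0)
        assert agg.log_ratio == pytest.approx(np.log(2.0), abs=1e-4)

    def test_equal_counts_log_ratio_zero_for_any_c(self):
        beh = ["scent_mark", "hunt", "scent_mark", "hunt", "move"]
        f = _make_follow(beh, minutes=[0, 10, 20, 30, 60])
        for c in (0.0, 0.5, 1.0):
            assert aggregate_follow(f, c=c).log_ratio == pytest.approx(0.0)

    def test_exp_log_ratio_identity(self):
        f = _make_follow(["scent_mark", "hunt", "hunt", "move"],
                         minutes=[0, 15, 30, 90])
        agg = aggregate_follow(f, c=0.5)
        assert np.exp(agg.log_ratio) == pytest.approx(
            agg.marks_per_hour / agg.hunts_per_hour
        )

    def test_delta_sign_and_binarization(self, layers, territories):
        terr = territories["pack_0"]
        nbrs = [territories[p]["territory"] for p in territories if p != "pack_0"]
        c0 = terr["territory"].geometry.centroid
        # first point at the centroid, last point 2 km east
        f = _make_follow(
            ["scent_mark", "hunt"], minutes=[0, 60],
            xy=[(c0.x, c0.y), (c0.x + 2000.0, c0.y)],
        )
        agg = aggregate_follow(
            f, layers,
            {"own_territory": terr["territory"], "own_core": terr["core"],
             "neighbor_territories": nbrs},
        )
        for term, d in agg.deltas.items():
            expected_bin = 1 if d > 0 else 0
            assert agg.deltas_bin[term] == expected_bin

    def test_invariant_to_event_reordering_except_endpoints(self):
        beh = ["scent_mark", "hunt", "move", "hunt", "rest"]
        f1 = _make_follow(beh, minutes=[0, 10, 20, 30, 40])
        shuffled = ["scent_mark", "move", "hunt", "hunt", "rest"]
        f2 = _make_follow(shuffled, minutes=[0, 10, 20, 30, 40])
        a1, a2 = aggregate_follow(f1), aggregate_follow(f2)
        assert a1.log_ratio == pytest.approx(a2.log_ratio)
        assert a1.duration_hours == a2.duration_hours

    def test_zero_duration_rejected(self):
        f = _make_follow(["scent_mark", "hunt"], minutes=[0, 0])
        with pytest.raises(ValueError, match="zero duration"):
            aggregate_follow(f)

    def test_c_zero_with_zero_hunts_rejected(self):
        f = _make_follow(["scent_mark", "move"], minutes=[0, 30])
        with pytest.raises(ValueError, match="undefined"):
            aggregate_follow(f, c=0.0)
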