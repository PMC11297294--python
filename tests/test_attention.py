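import numpy as np
import pandas as pd
import pytest

from clingaze.attention import (
    actual_to_chance_ratio,
    assign_point,
    box_at,
    chance_gaze_proportion,
    summarize_attention,
)
from clingaze.events import detect_blinks, detect_fixations
from clingaze.io import RoiDefinition, RoiHierarchy
from clingaze.synthetic import generate_uniform_gaze
from conftest import make_gaze, make_static_tracks
from _oracles import tally_attention_oracle

TRIAL = {"participant_id": "P01", "scenario_id": 1, "condition": "safe"}


def two_roi_hierarchy():
    return RoiHierarchy([
        RoiDefinition("left", "Left"),
        RoiDefinition("right", "Right"),
    ])


class TestBoxAt:
    def _tracks(self):
        return pd.DataFrame({
            "t_ms": [100.0, 200.0, 300.0],
            "roi_id": "ai_screen",
            "x_min": [0.1, 0.2, 0.3], "y_min": 0.1,
            "x_max": [0.5, 0.6, 0.7], "y_max": 0.5,
            "visible": [True, True, False],
        })

    def test_query_at_observation_time(self):
        assert box_at("ai_screen", 200.0, self._tracks())[0] == pytest.approx(0.2)

    def test_query_between_frames_holds_earlier(self):
        assert box_at("ai_screen", 250.0, self._tracks())[0] == pytest.approx(0.2)

    def test_query_before_first_frame_not_visible(self):
        assert box_at("ai_screen", 50.0, self._tracks()) is None

    def test_invisible_frame(self):
        assert box_at("ai_screen", 350.0, self._tracks()) is None

    def test_unknown_roi(self):
        with pytest.raises(KeyError):
            box_at("nope", 200.0, self._tracks())


class TestAssignPoint:
    def test_panel_point_also_counts_as_screen(self, hierarchy):
        tracks = make_static_tracks({
            "ai_screen": (0.5, 0.0, 1.0, 0.5),
            "xai_features": (0.6, 0.1, 0.8, 0.3),
        })
        got = assign_point(0.7, 0.2, 1000.0, tracks, hierarchy)
        assert got == {"xai_features", "ai_screen"}

    def test_screen_outside_panels(self, hierarchy):
        tracks = make_static_tracks({
            "ai_screen": (0.5, 0.0, 1.0, 0.5),
            "xai_features": (0.6, 0.1, 0.8, 0.3),
        })
        assert assign_point(0.55, 0.05, 1000.0, tracks, hierarchy) == {"ai_screen"}

    def test_outside_everything(self, hierarchy):
        tracks = make_static_tracks({"ai_screen": (0.5, 0.0, 1.0, 0.5)})
        assert assign_point(0.1, 0.9, 1000.0, tracks, hierarchy) == set()

    def test_overlap_prefers_smaller_area(self):
        h = two_roi_hierarchy()
        tracks = make_static_tracks({
            "left": (0.0, 0.0, 0.8, 0.8),       # large
            "right": (0.3, 0.3, 0.5, 0.5),      # small, nested in overlap
        })
        assert assign_point(0.4, 0.4, 1000.0, tracks, h) == {"right"}

    def test_area_tie_breaks_lexicographically(self):
        h = two_roi_hierarchy()
        tracks = make_static_tracks({
            "left": (0.2, 0.2, 0.6, 0.6),
            "right": (0.3, 0.3, 0.7, 0.7),      # same area, overlapping
        })
        assert assign_point(0.4, 0.4, 1000.0, tracks, h) == {"left"}

    def test_half_open_containment_partitions_abutting_panels(self):
        h = two_roi_hierarchy()
        tracks = make_static_tracks({
            "left": (0.0, 0.0, 0.5, 1.0),
            "right": (0.5, 0.0, 1.0, 1.0),
        })
        assert assign_point(0.5, 0.4, 1000.0, tracks, h) == {"right"}


class TestSummarize:
    def test_static_single_roi_gaze_time_and_blink_rate(self, hierarchy):
        # 60 s of gaze in the chart with 12 planted blinks
        t = np.arange(0, 60_000, 10.0)
        conf = np.ones(len(t))
        for k in range(12):
            start = 2000.0 + k * 4800.0
            conf[(t >= start) & (t < start + 150.0)] = 0.1
        g = make_gaze(t, 0.5, 0.65, conf)
        tracks = make_static_tracks({"icu_chart": (0.35, 0.55, 0.65, 0.80)})
        blinks, _ = detect_blinks(g)
        fix = detect_fixations(g)
        att, _ = summarize_attention(g, fix, blinks, tracks, hierarchy, TRIAL)
        row = att[att["roi_id"] == "icu_chart"].iloc[0]
        assert row["gaze_time_ms"] == pytest.approx(60_000, rel=0.001)
        assert row["blink_rate_bpm"] == pytest.approx(12.0, rel=0.001)
        assert row["actual_gaze_proportion"] == pytest.approx(1.0, rel=0.001)

    def test_roi_without_fixations_has_missing_mean_duration(self, hierarchy):
        g = make_gaze(np.arange(0, 5000, 10.0), 0.5, 0.65)
        tracks = make_static_tracks({"icu_chart": (0.35, 0.55, 0.65, 0.80),
                                     "vitals_monitor": (0.05, 0.08, 0.25, 0.18)})
        fix = detect_fixations(g)
        blinks, _ = detect_blinks(g)
        att, _ = summarize_attention(g, fix, blinks, tracks, hierarchy, TRIAL)
        row = att[att["roi_id"] == "vitals_monitor"].iloc[0]
        assert row["n_fixations"] == 0
        assert np.isnan(row["mean_fixation_duration_ms"])

    def test_matches_per_sample_tally_oracle(self, hierarchy):
        rng = np.random.default_rng(9)
        t = np.arange(20) * 50.0
        g = make_gaze(t, rng.uniform(0, 1, 20), rng.uniform(0, 1, 20))
        tracks = make_static_tracks({
            "icu_chart": (0.0, 0.0, 0.5, 1.0),
            "ai_screen": (0.5, 0.0, 1.0, 1.0),
            "xai_qdiff": (0.6, 0.1, 0.9, 0.4),
        }, t_end=1000.0, dt=100.0)
        fix = detect_fixations(g)
        blinks, _ = detect_blinks(g)
        att, _ = summarize_attention(g, fix, blinks, tracks, hierarchy, TRIAL)
        expect = tally_attention_oracle(g, tracks, hierarchy, period_cap=100.0)
        got = dict(zip(att["roi_id"], att["gaze_time_ms"]))
        for rid, gt_ms in expect.items():
            assert got[rid] == pytest.approx(gt_ms), rid

    def test_invariant_to_track_row_order(self, hierarchy, small_experiment):
        key = next(iter(small_experiment.gaze))
        g = small_experiment.gaze[key]
        tracks = small_experiment.tracks[key]
        fix = detect_fixations(g)
        blinks, _ = detect_blinks(g)
        a1, _ = summarize_attention(g, fix, blinks, tracks, hierarchy, TRIAL)
        shuffled = tracks.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a2, _ = summarize_attention(g, fix, blinks, shuffled, hierarchy, TRIAL)
        pd.testing.assert_frame_equal(a1, a2)

    def test_parent_gaze_time_bounds(self, hierarchy, small_experiment):
        key = next(iter(small_experiment.gaze))
        g = small_experiment.gaze[key]
        tracks = small_experiment.tracks[key]
        fix = detect_fixations(g)
        blinks, _ = detect_blinks(g)
        att, _ = summarize_attention(g, fix, blinks, tracks, hierarchy, TRIAL)
        by = dict(zip(att["roi_id"], att["gaze_time_ms"]))
        children = hierarchy.children("ai_screen")
        assert by["ai_screen"] >= max(by[c] for c in children) - 1e-9
        assert by["ai_screen"] <= sum(by[c] for c in children) + by["ai_screen"] + 1e-9
        # leaf gaze + elsewhere partitions the exposure
        leaf_total = sum(by[r] for r in hierarchy.leaves()) + by["elsewhere"]
        span = g["t_ms"].iloc[-1] - g["t_ms"].iloc[0]
        assert leaf_total <= span * 1.05


class TestChanceGaze:
    def test_full_world_view_roi(self):
        tracks = make_static_tracks({"ai_screen": (0.0, 0.0, 1.0, 1.0)})
        assert chance_gaze_proportion("ai_screen", tracks, (0, 60_000)) == pytest.approx(1.0)

    def test_static_small_box(self):
        tracks = make_static_tracks({"ai_screen": (0.4, 0.45, 0.6, 0.55)})
        assert chance_gaze_proportion("ai_screen", tracks, (0, 60_000)) == pytest.approx(0.02)

    def test_half_visible_halves_the_proportion(self):
        rows = []
        for t in np.arange(0, 61_000, 1000.0):
            vis = t < 30_000
            rows.append((t, "ai_screen", 0.4, 0.4, 0.6, 0.6, vis))
        tracks = pd.DataFrame(rows, columns=[
            "t_ms", "roi_id", "x_min", "y_min", "x_max", "y_max", "visible"])
        got = chance_gaze_proportion("ai_screen", tracks, (0, 60_000))
        assert got == pytest.approx(0.02, rel=1e-6)

    def test_box_clipped_to_world_view(self):
        tracks = make_static_tracks({"ai_screen": (0.8, 0.8, 1.4, 1.4)})
        got = chance_gaze_proportion("ai_screen", tracks, (0, 60_000))
        assert got == pytest.approx(0.04)


class TestRatio:
    @pytest.mark.parametrize("actual,chance,expected", [
        (0.25, 0.02, 12.5),
        (0.02, 0.02, 1.0),
    ])
    def test_values(self, actual, chance, expected):
        assert actual_to_chance_ratio(actual, chance) == pytest.approx(expected)

    def test_zero_chance_is_missing(self):
        assert np.isnan(actual_to_chance_ratio(0.1, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            actual_to_chance_ratio(-0.1, 0.5)

    def test_uniform_gaze_gives_chance_level_ratio(self, hierarchy):
        # moderate n here; the large-n check lives in the acceptance suite
        g = generate_uniform_gaze(200.0, 120.0, seed=21)
        tracks = make_static_tracks({
            "ai_screen": (0.68, 0.05, 0.96, 0.27),
            "icu_chart": (0.35, 0.55, 0.65, 0.80),
            "patient_mannequin": (0.30, 0.15, 0.70, 0.40),
        }, t_end=200_000.0)
        fix = detect_fixations(g)
        blinks, _ = detect_blinks(g)
        att, _ = summarize_attention(g, fix, blinks, tracks, hierarchy, TRIAL)
        for rid in ("ai_screen", "icu_chart", "patient_mannequin"):
            row = att[att["roi_id"] == rid].iloc[0]
            p = row["chance_gaze_proportion"]
            se = np.sqrt(p * (1 - p) / 24_000)
            assert abs(row["actual_gaze_proportion"] - p) < 4 * se + 1e-3, rid
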