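"""Pose filtering, immobility detection, aligned activity, DS metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fearcal as fc
from fearcal import behaviour as bhv
from fearcal import synth
from fearcal.protocol import TEST_EXT1


def simple_pose(xy_by_part, likes=None, frame_rate=20.0):
    n = len(next(iter(xy_by_part.values())))
    likes = likes or {p: np.full(n, 0.99) for p in xy_by_part}
    return bhv.PoseTrack(bhv.make_pose_frame(xy_by_part, likes), frame_rate)


class TestFilterPose:
    def test_confident_frames_unchanged(self, rng):
        xy = {p: rng.uniform(0, 100, (50, 2)) for p in bhv.BODY_PARTS}
        pose = simple_pose(xy)
        out = bhv.filter_pose(pose)
        for p in bhv.BODY_PARTS:
            assert np.array_equal(out.xy(p), xy[p])

    def test_dropout_holds_last_confident_position(self):
        xy = np.array([[0.0, 0], [1, 1], [99, 99], [3, 3]])
        likes = np.array([0.99, 0.99, 0.1, 0.99])
        parts = {p: xy.copy() for p in bhv.BODY_PARTS}
        lk = {p: likes.copy() for p in bhv.BODY_PARTS}
        out = bhv.filter_pose(simple_pose(parts, lk))
        assert np.array_equal(out.xy("nose")[2], [1, 1])

    def test_leading_dropouts_backfilled(self):
        xy = np.array([[99.0, 99], [98, 98], [5, 5], [6, 6]])
        likes = np.array([0.1, 0.1, 0.99, 0.99])
        out = bhv.filter_pose(simple_pose({p: xy.copy() for p in bhv.BODY_PARTS},
                                          {p: likes.copy() for p in bhv.BODY_PARTS}))
        assert np.array_equal(out.xy("nose")[0], [5, 5])

    def test_never_confident_part_named(self):
        parts = {p: np.zeros((10, 2)) for p in bhv.BODY_PARTS}
        likes = {p: np.full(10, 0.99) for p in bhv.BODY_PARTS}
        likes["tail_base"] = np.full(10, 0.2)
        with pytest.raises(ValueError, match="tail_base"):
            bhv.filter_pose(simple_pose(parts, likes))


class TestDisplacement:
    def test_static_pose_zero(self):
        pose = simple_pose({p: np.ones((20, 2)) for p in bhv.BODY_PARTS})
        assert np.allclose(bhv.displacement(pose), 0.0)

    def test_three_four_five_step(self):
        xy = np.zeros((3, 2))
        xy[2] = [3.0, 4.0]
        pose = simple_pose({p: xy.copy() for p in bhv.BODY_PARTS})
        d = bhv.displacement(pose)
        assert d.iloc[0].eq(0).all()
        assert d.iloc[2].eq(5.0).all()

    def test_offset_invariance(self, rng):
        xy = rng.uniform(0, 50, (30, 2))
        a = bhv.displacement(simple_pose({p: xy.copy() for p in bhv.BODY_PARTS}))
        b = bhv.displacement(simple_pose({p: xy + 1000 for p in bhv.BODY_PARTS}))
        assert np.allclose(a, b)

    def test_unknown_point_rejected(self):
        pose = simple_pose({p: np.zeros((5, 2)) for p in bhv.BODY_PARTS})
        with pytest.raises(ValueError, match="unknown"):
            bhv.displacement(pose, points=("whisker",))


class TestDetectImmobility:
    @staticmethod
    def disp_frame(values):
        return pd.DataFrame({p: values for p in bhv.DISPLACEMENT_POINTS})

    def test_long_quiet_run_is_one_bout(self):
        vals = np.full(200, 5.0)
        vals[40:160] = 0.0             # 6 s quiet at 20 Hz
        bouts = bhv.detect_immobility(self.disp_frame(vals), 20.0)
        assert len(bouts.bouts) == 1
        b = bouts.bouts.iloc[0]
        assert b["stop_s"] - b["start_s"] == pytest.approx(6.0)

    def test_short_run_rejected(self):
        vals = np.full(200, 5.0)
        vals[50:80] = 0.0              # 1.5 s
        bouts = bhv.detect_immobility(self.disp_frame(vals), 20.0)
        assert len(bouts.bouts) == 0

    def test_all_points_must_be_quiet(self):
        df = self.disp_frame(np.zeros(100))
        df.loc[:, "tail_base"] = 5.0   # one restless point blocks detection
        bouts = bhv.detect_immobility(df, 20.0)
        assert len(bouts.bouts) == 0

    def test_cs_overlap_flagged_and_excluded(self, protocols):
        events = protocols[TEST_EXT1]
        n = int(events.duration_s * 20)
        vals = np.full(n, 5.0)
        onset = events.onsets("CS_PLUS")[0]
        vals[int((onset + 5) * 20): int((onset + 10) * 20)] = 0.0   # inside a CS+
        vals[0:100] = 0.0                                            # outside any CS
        bouts = bhv.detect_immobility(self.disp_frame(vals), 20.0, events=events)
        assert len(bouts.bouts) == 2
        assert bouts.bouts["overlaps_cs"].sum() == 1
        assert len(bouts.usable()) == 1

    def test_planted_bout_recovery(self, protocols):
        """Generated behaviour: planted bouts recovered at high precision/recall."""
        cfg = synth.SynthConfig(seed=31)
        events = protocols[TEST_EXT1]
        pose, planted = synth.generate_behaviour(cfg, events, seed=31)
        filtered = bhv.filter_pose(pose, 0.9)
        disp = bhv.displacement(filtered)
        bouts = bhv.detect_immobility(disp, pose.frame_rate, 2.0, 2.0)
        detected = bouts.bouts[["start_s", "stop_s"]].to_numpy()
        tol = 2 / pose.frame_rate

        def matches(a, b):
            return abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol

        recall = np.mean([any(matches(p, d) for d in detected) for p in planted])
        precision = np.mean([any(matches(d, p) for p in planted) for d in detected])
        assert recall >= 0.95
        assert precision >= 0.95


class TestImmobilityAlignedActivity:
    def test_state_suppressed_cells_show_negative_onset_auc(self, protocols):
        cfg = synth.SynthConfig(cells_per_animal=40, seed=23,
                                state_suppressed_fraction=0.5,
                                state_enhanced_fraction=0.0, state_amplitude=2.0)
        cfg.us_proportions = {"null": 1.0}
        cfg.cs_plus_proportions = {"null": 1.0}
        cfg.cs_minus_proportions = {"null": 1.0}
        cfg.xday_proportions = {"null": 1.0}
        events = protocols[TEST_EXT1]
        pose, planted = synth.generate_behaviour(cfg, events, seed=23)
        pop, gt = synth.generate_population(cfg, {TEST_EXT1: events}, seed=24,
                                            bouts={TEST_EXT1: planted})
        bouts = bhv.detect_immobility(
            bhv.displacement(bhv.filter_pose(pose)), pose.frame_rate, events=events)
        act = bhv.immobility_aligned_activity(pop, {TEST_EXT1: bouts},
                                              sessions=(TEST_EXT1,))
        suppressed = (gt.labels["state_sign"] == -1).to_numpy()
        assert act.onset_auc[suppressed].mean() < -0.3
        assert act.offset_auc[suppressed].mean() > 0.3
        # unmodulated cells stay near zero
        assert abs(act.onset_auc[~suppressed].mean()) < 0.15

    def test_pooling_identical_sessions_equals_single(self, protocols, rng):
        events = protocols[TEST_EXT1]
        n_bins = int(events.duration_s / 0.25)
        traces = rng.normal(size=(3, n_bins))
        pop = fc.TracePopulation("a", ["c0", "c1", "c2"],
                                 {"test_ext1": traces, "ext2": traces.copy()})
        bouts = bhv.ImmobilityBouts(
            pd.DataFrame({"start_s": [200.0, 400.0], "stop_s": [210.0, 408.0],
                          "overlaps_cs": [False, False]}), 2.0, 2.0, 20.0)
        both = bhv.immobility_aligned_activity(pop, {"test_ext1": bouts, "ext2": bouts})
        one = bhv.immobility_aligned_activity(pop, {"test_ext1": bouts},
                                              sessions=("test_ext1",))
        assert np.allclose(both.onset.data.mean(axis=1), one.onset.data.mean(axis=1))

    def test_no_usable_bouts_rejected(self, protocols, rng):
        events = protocols[TEST_EXT1]
        pop = fc.TracePopulation("a", ["c0"],
                                 {"test_ext1": rng.normal(size=(1, int(events.duration_s * 4)))})
        empty = bhv.ImmobilityBouts(pd.DataFrame(columns=["start_s", "stop_s", "overlaps_cs"]),
                                    2.0, 2.0, 20.0)
        with pytest.raises(ValueError, match="bout"):
            bhv.immobility_aligned_activity(pop, {"test_ext1": empty})


class TestStability:
    def test_identical_aucs_give_rho_one(self):
        auc = np.arange(10.0)
        out = bhv.stability_across_sessions({"a": {"d1": auc, "d2": auc.copy()}})
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        auc = rng.normal(size=20)
        out = bhv.stability_across_sessions({"a": {"d1": auc, "d2": np.exp(auc)}})
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_independent_aucs_average_near_zero(self, rng):
        data = {f"m{i}": {"d1": rng.normal(size=50), "d2": rng.normal(size=50)}
                for i in range(12)}
        out = bhv.stability_across_sessions(data)
        assert abs(out["rho"].mean()) < 0.15
        tests = out.attrs["group_tests"]
        assert tests["p"].iloc[0] > 0.01

    def test_small_animals_excluded(self):
        out = bhv.stability_across_sessions({"tiny": {"d1": np.array([1.0, 2.0]),
                                                      "d2": np.array([2.0, 1.0])}})
        assert out.empty


class TestDiscriminationScore:
    @pytest.mark.parametrize("plus,minus,expected", [
        (60.0, 20.0, 0.5), (50.0, 0.0, 1.0), (0.0, 50.0, -1.0), (7.0, 7.0, 0.0),
    ])
    def test_worked_examples(self, plus, minus, expected):
        assert fc.discrimination_score(plus, minus) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        assert np.isnan(fc.discrimination_score(0.0, 0.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(0.001, 1e3), b=st.floats(0.001, 1e3), c=st.floats(0.001, 1e3))
    def test_scale_invariance(self, a, b, c):
        assert fc.discrimination_score(c * a, c * b) == pytest.approx(
            fc.discrimination_score(a, b), abs=1e-9)


class TestCountBehaviourCorrelation:
    def test_rank_aligned_counts_give_rho_one(self):
        ds = pd.Series([0.1, 0.4, 0.2, 0.9], index=list("abcd"))
        counts = pd.DataFrame({"fear": [1, 4, 2, 9], "flat": [5, 5, 5, 5]},
                              index=list("abcd"))
        out = fc.correlate_counts_with_behaviour(counts, ds)
        assert out.loc["fear", "rho"] == pytest.approx(1.0)
        assert not out.loc["flat", "defined"]

    def test_sign_flip(self, rng):
        ds = pd.Series(rng.normal(size=6), index=list("abcdef"))
        counts = pd.DataFrame({"c": rng.integers(0, 20, 6)}, index=list("abcdef"))
        a = fc.correlate_counts_with_behaviour(counts, ds)
        b = fc.correlate_counts_with_behaviour(counts, -ds)
        assert a.loc["c", "rho"] == pytest.approx(-b.loc["c", "rho"])

    def test_too_few_animals_rejected(self):
        ds = pd.Series([0.1, 0.2], index=["a", "b"])
        counts = pd.DataFrame({"c": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="animals"):
            fc.correlate_counts_with_behaviour(counts, ds)
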