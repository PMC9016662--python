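import numpy as np
import pytest
from scipy import stats as sstats

from gazediff import (FrameStat, detect_runs, distance_test_frame,
                      group_centre, pooled_t, position_test_frame,
                      summarize_all, summarize_video, video_framewise_stats)
from gazediff.framewise import (SIGN_A, SIGN_B, SIGN_TIE, EmptyGroupError,
                                UnsummarizableVideoError)


def oracle_pooled_t(a, b):
    """Textbook pooled two-sample t, coded independently of the package."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp = ((ssa + ssb) / df) ** 0.5
    t = (ma - mb) / (sp * (1.0 / na + 1.0 / nb) ** 0.5)
    p = 2.0 * sstats.t.sf(abs(t), df)
    return t, p


class TestGroupCentre:
    def test_singleton(self):
        assert group_centre([(100.0, 200.0)]) == (100.0, 200.0)

    def test_midpoint(self):
        assert group_centre([(0.0, 0.0), (2.0, 0.0)]) == (1.0, 0.0)

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 1000, size=(5, 2))
        cx = sum(p[0] for p in pts) / 5
        cy = sum(p[1] for p in pts) / 5
        got = group_centre(pts)
        assert got == pytest.approx((cx, cy), rel=1e-12)

    def test_empty_group_signals(self):
        with pytest.raises(EmptyGroupError):
            group_centre(np.empty((0, 2)))


class TestPooledT:
    def test_hand_worked_example(self):
        # samples (1,1,2) vs (5,6,7): t = -7 exactly, df = 4
        t, p = pooled_t([1.0, 1.0, 2.0], [5.0, 6.0, 7.0])
        assert t == pytest.approx(-7.0, rel=1e-12)
        assert p == pytest.approx(2 * sstats.t.sf(7.0, 4), rel=1e-12)

    def test_matches_scipy_and_textbook_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            na, nb = rng.integers(2, 11, size=2)
            a = rng.normal(0, 1, na)
            b = rng.normal(0.3, 1.5, nb)
            t, p = pooled_t(a, b)
            t_o, p_o = oracle_pooled_t(a, b)
            res = sstats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(t_o, rel=1e-10)
            assert p == pytest.approx(p_o, rel=1e-10)
            assert t == pytest.approx(res.statistic, rel=1e-10)
            assert p == pytest.approx(res.pvalue, rel=1e-10)

    def test_zero_pooled_variance_is_undefined(self):
        t, p = pooled_t([1.0, 1.0], [1.0, 1.0])
        assert np.isnan(t) and np.isnan(p)


class TestDistanceTestFrame:
    def test_matches_distance_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 500, (6, 2))
        b = rng.uniform(0, 500, (7, 2))
        fs = distance_test_frame(a, b)
        da = [np.hypot(*(p - a.mean(0))) for p in a]
        db = [np.hypot(*(p - b.mean(0))) for p in b]
        t_o, p_o = oracle_pooled_t(da, db)
        assert fs.testable
        assert fs.t == pytest.approx(t_o, rel=1e-10)
        assert fs.p == pytest.approx(p_o, rel=1e-10)
        assert fs.mean_dist_a == pytest.approx(np.mean(da), rel=1e-12)
        assert fs.n_a == 6 and fs.n_b == 7

    def test_identical_points_untestable(self):
        pts = [(100.0, 100.0)] * 4
        fs = distance_test_frame(pts, pts)
        assert not fs.testable

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 500, (5, 2))
        b = rng.uniform(0, 500, (5, 2)) * 1.8
        ab = distance_test_frame(a, b)
        ba = distance_test_frame(b, a)
        assert ab.t == pytest.approx(-ba.t, rel=1e-12)
        assert ab.p == pytest.approx(ba.p, rel=1e-12)
        assert {ab.sign, ba.sign} == {SIGN_A, SIGN_B}

    def test_min_n_gate(self):
        a = [(0.0, 0.0), (1.0, 1.0)]
        b = [(5.0, 5.0), (6.0, 6.0), (7.0, 7.0)]
        assert not distance_test_frame(a, b, min_n=3).testable
        fs = distance_test_frame(a + [(2.0, 0.0)], b, min_n=3)
        assert fs.testable


class TestPositionTestFrame:
    def test_separated_groups_significant(self):
        a = [(100.0, 10.0), (110.0, 20.0)]
        b = [(500.0, 15.0), (510.0, 25.0)]
        fs = position_test_frame(a, b, "horizontal", min_n=2)
        assert fs.testable and fs.p < 0.05
        assert fs.sign == SIGN_B
        t_o, p_o = oracle_pooled_t([100, 110], [500, 510])
        assert fs.t == pytest.approx(t_o, rel=1e-10)

    def test_identical_coordinate_multisets(self):
        a = [(1.0, 5.0), (2.0, 6.0), (3.0, 7.0)]
        b = [(3.0, 9.0), (1.0, 8.0), (2.0, 7.5)]
        fs = position_test_frame(a, b, "horizontal", min_n=2)
        assert fs.t == pytest.approx(0.0, abs=1e-12)
        assert fs.p == pytest.approx(1.0, rel=1e-12)

    def test_vertical_test_ignores_x(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 500, (5, 2))
        b = rng.uniform(0, 500, (5, 2))
        base = position_test_frame(a, b, "vertical")
        a2, b2 = a.copy(), b.copy()
        a2[:, 0] = rng.uniform(0, 500, 5)
        b2[:, 0] = rng.uniform(0, 500, 5)
        moved = position_test_frame(a2, b2, "vertical")
        assert moved.t == pytest.approx(base.t, rel=1e-12)
        assert moved.p == pytest.approx(base.p, rel=1e-12)


class TestVideoFramewiseStats:
    def test_output_shape_and_ordering(self, tiny_null_setup):
        ds, groups, _ = tiny_null_setup
        stats = video_framewise_stats(ds, groups)
        assert len(stats) == int(ds.n_frames.sum())
        keys = [(s.video_id, s.frame) for s in stats]
        assert keys == sorted(keys)

    def test_vectorised_path_matches_scalar_path(self, tiny_null_setup):
        ds, groups, _ = tiny_null_setup
        stats = video_framewise_stats(ds, groups)
        ia = ds.participant_index(groups.members("group_a"))
        ib = ds.participant_index(groups.members("group_b"))
        rng = np.random.default_rng(0)
        for s in rng.choice(len(stats), size=25, replace=False):
            st = stats[s]
            vi = ds.video_ids.index(st.video_id)
            pa = ds.positions[ia, vi, st.frame][ds.validity[ia, vi, st.frame]]
            pb = ds.positions[ib, vi, st.frame][ds.validity[ib, vi, st.frame]]
            ref = distance_test_frame(pa, pb, video_id=st.video_id,
                                      frame=st.frame)
            assert st.testable == ref.testable
            if st.testable:
                assert st.t == pytest.approx(ref.t, rel=1e-9)
                assert st.p == pytest.approx(ref.p, rel=1e-9)
                assert st.sign == ref.sign

    def test_frame_with_one_group_blinking_untestable(self, handmade_dataset):
        ds, groups = handmade_dataset
        ds.validity[0, 0, 2] = False
        ds.validity[1, 0, 2] = False  # whole group_a gone at frame 2
        stats = video_framewise_stats(ds, groups, min_n=2)
        assert stats[2].testable is False
        assert stats[2].n_a == 0

    def test_label_swap_flips_every_sign(self, tiny_null_setup):
        ds, groups, _ = tiny_null_setup
        from gazediff import GroupAssignment
        swapped = GroupAssignment({
            p: ("group_b" if g == "group_a" else "group_a")
            for p, g in groups.labels.items()})
        st1 = video_framewise_stats(ds, groups)
        st2 = video_framewise_stats(ds, swapped)
        for a, b in zip(st1, st2):
            assert a.testable == b.testable
            if a.testable:
                assert a.t == pytest.approx(-b.t, rel=1e-9)
                assert a.p == pytest.approx(b.p, rel=1e-9)

    def test_rigid_motion_leaves_distance_stats_unchanged(self, tiny_null_setup):
        ds, groups, _ = tiny_null_setup
        base = video_framewise_stats(ds, groups)
        theta = 0.3
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = ds.subset_participants(ds.participant_ids)
        moved.positions[:] = ds.positions @ rot.T + np.array([37.0, -12.0])
        after = video_framewise_stats(moved, groups)
        for a, b in zip(base, after):
            if a.testable:
                assert b.p == pytest.approx(a.p, abs=1e-9)


def _mk_stat(frame, p, sign=SIGN_A, testable=True, video="v1"):
    return FrameStat(video, frame, "distance", 5, 5, (0, 0), (0, 0),
                     1.0 if sign == SIGN_A else 0.5,
                     0.5 if sign == SIGN_A else 1.0,
                     1.0, p, sign if testable else SIGN_TIE, testable)


class TestSummarize:
    def test_no_significant_frames(self):
        stats = [_mk_stat(i, 1.0) for i in range(10)]
        assert summarize_video(stats).pct_significant == 0.0

    def test_exact_count_fraction(self):
        stats = [_mk_stat(i, 0.01 if i < 48 else 0.5) for i in range(480)]
        assert summarize_video(stats).pct_significant == pytest.approx(10.0)

    def test_direction_share(self):
        stats = [_mk_stat(i, 0.2, sign=SIGN_A) for i in range(8)]
        summ = summarize_video(stats)
        assert summ.direction_share_a == 1.0
        assert summ.n_testable == 8

    def test_untestable_frames_excluded(self):
        stats = ([_mk_stat(i, 0.01) for i in range(2)]
                 + [_mk_stat(2, 0.01, testable=False)])
        summ = summarize_video(stats)
        assert summ.n_testable == 2
        assert summ.pct_significant == 100.0

    def test_zero_testable_frames_signals(self):
        with pytest.raises(UnsummarizableVideoError):
            summarize_video([_mk_stat(0, 0.01, testable=False)])


class TestDetectRuns:
    def test_no_significant_frames_gives_empty_list(self):
        stats = [_mk_stat(i, 0.5) for i in range(5)]
        assert detect_runs(stats) == []

    def test_near_significant_frame_merges_into_run(self):
        ps = [0.01, 0.08, 0.02, 0.50]
        stats = [_mk_stat(i, p) for i, p in enumerate(ps)]
        runs = detect_runs(stats, alpha=0.05, near_alpha=0.10)
        assert len(runs) == 1
        assert (runs[0].start_frame, runs[0].end_frame) == (0, 2)
        assert runs[0].n_frames == 3

    def test_opposite_sign_near_frame_splits_runs(self):
        ps = [0.01, 0.08, 0.02]
        signs = [SIGN_A, SIGN_B, SIGN_A]
        stats = [_mk_stat(i, p, sign=s) for i, (p, s) in enumerate(zip(ps, signs))]
        runs = detect_runs(stats, alpha=0.05, near_alpha=0.10)
        assert [(r.start_frame, r.end_frame) for r in runs] == [(0, 0), (2, 2)]

    def test_near_frames_alone_never_form_a_run(self):
        stats = [_mk_stat(i, 0.07) for i in range(4)]
        assert detect_runs(stats) == []

    def test_runs_are_disjoint_ordered_single_signed(self, tiny_effect_setup):
        ds, groups, _ = tiny_effect_setup
        stats = video_framewise_stats(ds, groups)
        from gazediff.framewise import group_stats_by_video
        for vstats in group_stats_by_video(stats).values():
            runs = detect_runs(vstats)
            last_end = -1
            for r in runs:
                assert r.start_frame > last_end
                assert r.sign in (SIGN_A, SIGN_B)
                last_end = r.end_frame
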