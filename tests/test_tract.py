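"""Streamline selection, bend filtering, labeling, statistics, reliability."""

import numpy as np
import pandas as pd
import pytest

from lobetract import synth, tract as tr
from lobetract.tract import (IccResult, LabelVolume, ScalarVolume, Tractogram,
                             filter_bend, icc, label_points, round_half_away,
                             segment_by_label, segment_stats, select_and,
                             select_not, streamline_touches)


def _slab_mask(shape, affine, x_lo, x_hi):
    data = np.zeros(shape, dtype=np.int32)
    data[x_lo:x_hi, :, :] = 1
    return LabelVolume(data, affine)


def _brute_force_touches(tractogram, mask_vol):
    """Independent per-point voxel-lookup oracle."""
    inv = np.linalg.inv(tractogram.affine)
    shape = mask_vol.data.shape
    out = []
    for sl in tractogram.streamlines:
        hit = False
        for p in sl:
            v = inv[:3, :3] @ p + inv[:3, 3]
            ijk = tuple(int(np.sign(c) * np.floor(abs(c) + 0.5)) for c in v)
            if all(0 <= ijk[d] < shape[d] for d in range(3)):
                if mask_vol.data[ijk] > 0:
                    hit = True
                    break
        out.append(hit)
    return np.array(out)


class TestSelection:
    def test_and_identity_when_all_cross(self, noiseless_phantom):
        spec, tract, *_ , labels = noiseless_phantom
        nx = spec.grid_shape[0]
        roi_a = _slab_mask(spec.grid_shape, tract.affine, 0, 3)
        roi_b = _slab_mask(spec.grid_shape, tract.affine, nx - 3, nx)
        assert len(select_and(tract, roi_a, roi_b)) == len(tract)

    def test_and_with_empty_roi_is_empty(self, noiseless_phantom):
        spec, tract, *_ = noiseless_phantom
        roi_a = _slab_mask(spec.grid_shape, tract.affine, 0, 3)
        empty = _slab_mask(spec.grid_shape, tract.affine, 0, 0)
        assert len(select_and(tract, roi_a, empty)) == 0

    def test_and_matches_brute_force_oracle(self, noiseless_phantom):
        spec, tract, *_ = noiseless_phantom
        ny = spec.grid_shape[1]
        roi_a = _slab_mask(spec.grid_shape, tract.affine, 0, 5)
        # half-height slab that only some arcs reach
        data = np.zeros(spec.grid_shape, dtype=np.int32)
        data[:, ny // 2 + 2:, :] = 1
        roi_b = LabelVolume(data, tract.affine)
        expected = (_brute_force_touches(tract, roi_a)
                    & _brute_force_touches(tract, roi_b))
        got = select_and(tract, roi_a, roi_b)
        assert len(got) == expected.sum()
        kept = streamline_touches(tract, roi_a) & streamline_touches(tract, roi_b)
        assert np.array_equal(kept, expected)

    def test_not_empty_roi_is_identity(self, noiseless_phantom):
        spec, tract, *_ = noiseless_phantom
        empty = _slab_mask(spec.grid_shape, tract.affine, 0, 0)
        assert len(select_not(tract, empty)) == len(tract)

    def test_not_whole_grid_removes_all(self, noiseless_phantom):
        spec, tract, *_ = noiseless_phantom
        full = _slab_mask(spec.grid_shape, tract.affine, 0, spec.grid_shape[0])
        assert len(select_not(tract, full)) == 0

    def test_not_partitions_tractogram(self, noiseless_phantom):
        # kept-by-NOT plus touches-mask partitions the bundle exactly
        spec, tract, *_ = noiseless_phantom
        ny = spec.grid_shape[1]
        data = np.zeros(spec.grid_shape, dtype=np.int32)
        data[:, ny // 2 + 3:, :] = 1
        roi = LabelVolume(data, tract.affine)
        kept = select_not(tract, roi)
        touches = streamline_touches(tract, roi)
        assert len(kept) + int(touches.sum()) == len(tract)

    def test_selection_idempotent(self, noiseless_phantom):
        spec, tract, *_ = noiseless_phantom
        ny = spec.grid_shape[1]
        data = np.zeros(spec.grid_shape, dtype=np.int32)
        data[:, ny // 2 + 2:, :] = 1
        roi = LabelVolume(data, tract.affine)
        once = select_not(tract, roi)
        twice = select_not(once, roi)
        assert len(once) == len(twice)

    def test_affine_mismatch_raises(self, noiseless_phantom):
        spec, tract, *_ = noiseless_phantom
        other = np.eye(4)
        roi = _slab_mask(spec.grid_shape, other, 0, 3)
        with pytest.raises(ValueError, match="affine mismatch"):
            streamline_touches(tract, roi)


class TestBendFilter:
    def _tract(self, streamlines):
        return Tractogram(streamlines, np.eye(4), shape=(10, 10, 10),
                          voxel_size=(1, 1, 1))

    def test_straight_line_unchanged(self):
        sl = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        out = filter_bend(self._tract([sl]), 30.0)
        assert np.array_equal(out.streamlines[0], sl)

    def test_right_angle_truncates_at_corner(self):
        sl = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0],
                       [2, 1, 0], [2, 2, 0]], dtype=float)
        out = filter_bend(self._tract([sl]), 30.0)
        # 90-degree turn between segments (1->2) and (2->3): keep points 0..2
        assert np.array_equal(out.streamlines[0], sl[:3])

    def test_gentle_circle_passes_threshold(self):
        # adjacent segments of a regular 36-gon turn exactly 10 degrees
        theta = np.radians(np.arange(0, 200, 10))
        sl = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        out = filter_bend(self._tract([sl]), 30.0)
        assert len(out.streamlines[0]) == len(sl)
        assert len(filter_bend(self._tract([sl]), 9.0).streamlines[0]) < len(sl)

    def test_never_longer_and_identity_at_180(self):
        rng = np.random.default_rng(0)
        sls = [np.cumsum(rng.normal(size=(20, 3)), axis=0) for _ in range(10)]
        t = self._tract(sls)
        out = filter_bend(t, 45.0)
        assert all(len(o) <= len(s) for o, s in zip(out.streamlines, sls))
        out180 = filter_bend(t, 180.0)
        assert all(np.array_equal(o, s)
                   for o, s in zip(out180.streamlines, sls))

    def test_drop_mode_discards(self):
        sl = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        assert len(filter_bend(self._tract([sl]), 30.0, drop=True)) == 0


class TestLabeling:
    def test_round_half_away_from_zero(self):
        assert np.array_equal(round_half_away(np.array([0.5, -0.5, 1.49, -1.5])),
                              [1, -1, 1, -2])

    def test_point_at_voxel_center_gets_that_label(self):
        data = np.zeros((4, 4, 4), dtype=np.int32)
        data[2, 1, 3] = 4
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [10, -5, 3]
        vol = LabelVolume(data, affine)
        world = affine[:3, :3] @ np.array([2.0, 1.0, 3.0]) + affine[:3, 3]
        sl = np.vstack([world, world + [0.1, 0.1, 0.1]])
        t = Tractogram([sl], affine)
        labs = label_points(t, vol)[0]
        assert labs[0] == 4

    def test_point_outside_grid_is_background(self):
        vol = LabelVolume(np.ones((4, 4, 4), dtype=np.int32), np.eye(4))
        sl = np.array([[100.0, 0, 0], [0.0, 0, 0]])
        t = Tractogram([sl], np.eye(4))
        labs = label_points(t, vol)[0]
        assert labs[0] == 0 and labs[1] == 1

    def test_agrees_with_brute_force_on_phantom(self, noiseless_phantom):
        spec, tract, _, _, labels = noiseless_phantom
        fast = label_points(tract, labels)
        inv = np.linalg.inv(tract.affine)
        shape = labels.data.shape
        for sl, lab in zip(tract.streamlines, fast):
            for p, l_fast in zip(sl, lab):
                v = inv[:3, :3] @ p + inv[:3, 3]
                ijk = tuple(int(np.sign(c) * np.floor(abs(c) + 0.5)) for c in v)
                expected = labels.data[ijk] if all(
                    0 <= ijk[d] < shape[d] for d in range(3)) else 0
                assert l_fast == expected


class TestSegments:
    def test_single_label_single_segment(self):
        vol = LabelVolume(np.ones((5, 5, 5), dtype=np.int32), np.eye(4))
        sl = np.column_stack([np.linspace(0, 4, 8), np.full(8, 2.0),
                              np.full(8, 2.0)])
        t = Tractogram([sl], np.eye(4))
        segs = segment_by_label(t, label_points(t, vol))
        assert segs.present_labels == [1]
        pts, _ = segs.segment(1)
        assert len(pts) == 8

    def test_all_background_warns_and_empty(self):
        vol = LabelVolume(np.zeros((5, 5, 5), dtype=np.int32), np.eye(4))
        sl = np.array([[1.0, 1, 1], [2.0, 2, 2]])
        t = Tractogram([sl], np.eye(4))
        with pytest.warns(UserWarning, match="background"):
            segs = segment_by_label(t, label_points(t, vol))
        assert segs.present_labels == []

    def test_noiseless_phantom_exact_band_means(self, noiseless_phantom):
        spec, tract, fa, md, labels = noiseless_phantom
        segs = segment_by_label(tract, label_points(tract, labels))
        st = segment_stats(segs, fa, md, interp="nearest")
        truth = spec.ground_truth()
        for _, row in st.per_segment.iterrows():
            assert row.mean_fa == pytest.approx(truth[row.label]["fa"], abs=1e-12)
            assert row.mean_md == pytest.approx(truth[row.label]["md"], abs=1e-12)

    def test_whole_tract_mean_is_point_weighted_average(self, noiseless_phantom):
        spec, tract, fa, md, labels = noiseless_phantom
        segs = segment_by_label(tract, label_points(tract, labels))
        st = segment_stats(segs, fa, md, interp="nearest")
        w = st.per_segment.n_points
        assert w.sum() == st.n_points_total  # no background points here
        expected = float((st.per_segment.mean_fa * w).sum() / w.sum())
        assert st.tract_mean_fa == pytest.approx(expected, abs=1e-12)

    def test_constant_field_any_interp(self, noiseless_phantom):
        spec, tract, _, _, labels = noiseless_phantom
        const = ScalarVolume(np.full(spec.grid_shape, 0.5), tract.affine)
        segs = segment_by_label(tract, label_points(tract, labels))
        for interp in ("nearest", "trilinear"):
            st = segment_stats(segs, const, const, interp=interp)
            assert np.allclose(st.per_segment.mean_fa, 0.5)
            assert st.tract_mean_fa == pytest.approx(0.5)

    def test_trilinear_close_to_nearest_on_smooth_field(self, noiseless_phantom):
        spec, tract, _, _, labels = noiseless_phantom
        nx = spec.grid_shape[0]
        ramp = np.broadcast_to(
            np.linspace(0.2, 0.8, nx)[:, None, None], spec.grid_shape).copy()
        vol = ScalarVolume(ramp, tract.affine)
        segs = segment_by_label(tract, label_points(tract, labels))
        st_n = segment_stats(segs, vol, vol, interp="nearest")
        st_t = segment_stats(segs, vol, vol, interp="trilinear")
        voxel_step = (0.8 - 0.2) / (nx - 1)
        assert abs(st_n.tract_mean_fa - st_t.tract_mean_fa) < voxel_step

    def test_low_confidence_flag(self):
        vol = LabelVolume(np.ones((5, 5, 5), dtype=np.int32), np.eye(4))
        fa = ScalarVolume(np.full((5, 5, 5), 0.4), np.eye(4))
        sl = np.array([[1.0, 1, 1], [2.0, 2, 2]])
        t = Tractogram([sl], np.eye(4))
        segs = segment_by_label(t, label_points(t, vol))
        st = segment_stats(segs, fa, fa)
        assert bool(st.per_segment.low_confidence.iloc[0])


class TestIcc:
    def test_identical_columns_icc_one(self):
        x = np.arange(10.0)
        res = icc(np.column_stack([x, x]))
        assert res.value == pytest.approx(1.0)

    def test_independent_noise_icc_near_zero(self):
        rng = np.random.default_rng(42)
        res = icc(rng.normal(size=(2000, 2)))
        assert abs(res.value) < 0.08
        assert res.ci_low < 0 < res.ci_high or abs(res.ci_low) < 0.1

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        subj = rng.normal(size=30)
        X = subj[:, None] + rng.normal(scale=0.4, size=(30, 3)) \
            + np.array([0.0, 0.1, -0.05])
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(30), 3),
            "raters": np.tile(np.arange(3), 30),
            "ratings": X.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="ratings").set_index("Type")
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        ours_a = icc(X, form="A-1")
        assert ours_a.value == pytest.approx(ref.loc["ICC(A,1)", "ICC"],
                                             abs=1e-6)
        assert ours_a.ci_low == pytest.approx(ref.loc["ICC(A,1)", ci_col][0],
                                              abs=0.01)
        assert ours_a.ci_high == pytest.approx(ref.loc["ICC(A,1)", ci_col][1],
                                               abs=0.01)
        ours_c = icc(X, form="C-1")
        assert ours_c.value == pytest.approx(ref.loc["ICC(C,1)", "ICC"],
                                             abs=1e-6)

    def test_phantom_repeat_extraction_reliability(self):
        # per-subject tract FA re-measured on independently noisy volumes:
        # between-subject spread >> noise, so reliability should be high
        rng = np.random.default_rng(99)
        ratings = []
        for subj in range(15):
            base = 0.40 + float(rng.normal(scale=0.03))
            band_fa = tuple(np.clip(base + np.linspace(0.04, -0.04, 5), 0, 1))
            reps = []
            for rep in range(2):
                spec = synth.PhantomSpec(grid_shape=(30, 12, 12),
                                         n_streamlines=8,
                                         points_per_streamline=40,
                                         band_fa=band_fa, noise_sd=0.005,
                                         seed=1000 + 10 * subj + rep)
                tract, fa, md, labels = synth.gen_tract_phantom(spec)
                segs = segment_by_label(tract, label_points(tract, labels))
                st = segment_stats(segs, fa, md, interp="trilinear")
                reps.append(st.tract_mean_fa)
            ratings.append(reps)
        res = icc(np.array(ratings))
        assert isinstance(res, IccResult)
        assert res.value > 0.9

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            icc(np.ones((5, 2)))
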