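"""Nucleus segmentation: thresholding, watershed splitting, filtering, measurement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from confine_track.registration import PillarCircle, build_geometry
from confine_track.segmentation import (
    binarize_nuclei,
    filter_objects,
    measure_objects,
    segment_frame,
    split_touching,
    suppress_splitting_in_constrictions,
)
from confine_track.preprocess import smooth_fluorescence
from confine_track.synth import (
    DeviceSpec,
    NucleusScript,
    Scenario,
    render_scenario,
    touching_pair_mask,
)


def _ellipse(shape, cx, cy, a, b):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _three_row_geometry(pixel_size_um=1.0):
    pillars = [
        PillarCircle(38.0 + 24.0 * j, 40.0 + 55.0 * i, 8.0)
        for i in range(3)
        for j in range(6)
    ]
    return build_geometry(pillars, boundary_offset_um=7.0, pixel_size_um=pixel_size_um)


class TestBinarize:
    def test_uniform_image_gives_empty_mask(self):
        assert not binarize_nuclei(np.full((80, 80), 42.0)).any()

    def test_five_ellipses_recovered_with_good_iou(self):
        scripts = [
            NucleusScript(nucleus_id=i, frames=[0], centers=np.array([[40.0 + 40 * (i % 3), 60.0 + 70 * (i // 3)]]),
                          marker_level=600.0 + 40 * i, allow_dumbbell=False)
            for i in range(5)
        ]
        sc = Scenario(name="b", shape=(220, 200), n_frames=1, nuclei=scripts, noise_sigma=8.0, seed=11)
        seq, gt = render_scenario(sc)
        sm = smooth_fluorescence(seq.frame(0, "nuclear_marker"))
        mask = binarize_nuclei(sm)
        labels, n = ndimage.label(mask)
        assert n == 5
        for i in range(5):
            g = gt.tracks[i][0]
            x0, y0, x1, y1 = g.bbox
            truth = np.zeros(mask.shape, bool)
            cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
            truth |= _ellipse(mask.shape, cx - 0.5, cy - 0.5, (x1 - x0) / 2, (y1 - y0) / 2)
            lab = labels[int(g.y), int(g.x)]
            assert lab > 0
            det = labels == lab
            iou = (det & truth).sum() / (det | truth).sum()
            assert iou >= 0.7

    def test_robust_to_linear_illumination_gradient(self):
        scripts = [
            NucleusScript(nucleus_id=i, frames=[0], centers=np.array([[40.0 + 60 * i, 122.0]]),
                          marker_level=650.0, allow_dumbbell=False)
            for i in range(3)
        ]
        sc = Scenario(name="g", shape=(220, 200), n_frames=1, nuclei=scripts, noise_sigma=8.0, seed=4)
        seq, _ = render_scenario(sc)
        frame = seq.frame(0, "nuclear_marker")
        gradient = np.linspace(1.0, 2.0, frame.shape[1])[None, :]
        n_plain = ndimage.label(binarize_nuclei(smooth_fluorescence(frame)))[1]
        n_grad = ndimage.label(binarize_nuclei(smooth_fluorescence(frame * gradient)))[1]
        assert n_plain == n_grad == 3


class TestSplitTouching:
    def test_two_overlapping_ellipses_split_with_fair_division(self):
        mask, centers = touching_pair_mask(sep_px=21.0, angle_deg=0.0)
        labels = split_touching(mask, h_depth=1.0)
        assert labels.max() == 2
        l1 = labels[int(centers[0, 1]), int(centers[0, 0])]
        l2 = labels[int(centers[1, 1]), int(centers[1, 0])]
        assert l1 != l2 and l1 > 0 and l2 > 0
        # division line within 2 px of the perpendicular bisector
        border_cols = [np.max(np.nonzero(labels == l1)[1]), np.min(np.nonzero(labels == l2)[1])]
        mid = (centers[0, 0] + centers[1, 0]) / 2
        assert all(abs(c - mid) <= 2.0 for c in border_cols)

    def test_single_ellipse_stays_single(self):
        mask = _ellipse((60, 60), 30, 30, 12, 9)
        assert split_touching(mask, h_depth=1.0).max() == 1

    def test_boundary_dent_oversegmentation_controlled_by_h(self):
        # a deep notch carves two shallow basins into one ellipse: without
        # minima suppression the watershed cuts it, with it the object stays whole
        mask = _ellipse((60, 80), 40, 30, 16, 10)
        mask[20:32, 31:34] = False
        mask = ndimage.binary_fill_holes(mask)
        assert split_touching(mask, h_depth=3.0).max() == 1
        assert split_touching(mask, h_depth=0.0).max() > 1

    def test_foreground_conserved_up_to_cut_lines(self):
        mask, _ = touching_pair_mask()
        labels = split_touching(mask, h_depth=1.0)
        lost = mask.sum() - (labels > 0).sum()
        assert 0 <= lost <= mask.sum() * 0.05  # only thin watershed lines removed
        assert not ((labels > 0) & ~mask).any()

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        sep=st.floats(12.0, 23.0),
        angle=st.floats(0.0, 180.0),
        h1=st.floats(0.0, 1.5),
        h2=st.floats(1.5, 6.0),
    )
    def test_label_count_monotone_in_h(self, sep, angle, h1, h2):
        """Raising the h-minima depth can only merge objects, never split more."""
        mask, _ = touching_pair_mask(sep_px=sep, angle_deg=angle)
        assert split_touching(mask, h2).max() <= split_touching(mask, h1).max()

    def test_labels_partition_foreground(self):
        mask, _ = touching_pair_mask()
        labels = split_touching(mask, h_depth=1.0)
        assert labels.min() == 0
        ids = np.unique(labels[labels > 0])
        assert list(ids) == list(range(1, len(ids) + 1))


class TestConstrictionSuppression:
    def test_dumbbell_in_band_kept_single(self):
        dev = DeviceSpec()
        script = NucleusScript(nucleus_id=0, frames=[0], centers=np.array([[50.0, 40.0]]))
        sc = Scenario(name="d", n_frames=1, device=dev, nuclei=[script], noise_sigma=6.0, seed=2)
        seq, gt = render_scenario(sc)
        geom = _three_row_geometry()
        sm = smooth_fluorescence(seq.frame(0, "nuclear_marker"))
        _, obs = segment_frame(
            sm, seq.frame(0, "nuclear_marker"), seq.frame(0, "reporter"), 0, 1.0, geometry=geom
        )
        near = [o for o in obs if abs(o.centroid_x - 50) < 20 and abs(o.centroid_y - 40) < 20]
        assert len(near) == 1
        assert near[0].in_constriction

    def test_suppression_inactive_away_from_bands(self):
        mask, _ = touching_pair_mask(sep_px=21.0)
        # place the pair so its content sits mid-corridor, far from every band
        frame_mask = np.zeros((220, 200), bool)
        frame_mask[86:158, 60:132] = mask
        labels = split_touching(frame_mask, h_depth=1.0)
        out = suppress_splitting_in_constrictions(labels, _three_row_geometry(), frame_mask)
        assert out.max() == labels.max() == 2

    def test_distinct_pair_outside_band_not_merged(self):
        geom = _three_row_geometry()
        labels = np.zeros((220, 200), np.int32)
        labels[_ellipse((220, 200), 60, 122, 10, 7)] = 1
        labels[_ellipse((220, 200), 90, 122, 10, 7)] = 2
        out = suppress_splitting_in_constrictions(labels, geom, labels > 0)
        assert out.max() == 2


class TestFilterObjects:
    def test_small_speck_removed_nominal_kept_streak_removed(self):
        labels = np.zeros((220, 200), np.int32)
        labels[_ellipse((220, 200), 60, 122, 12, 8)] = 1  # nominal nucleus
        labels[100, 20:22] = 2  # 2-px speck
        labels[180:182, 20:180] = 3  # thin debris streak
        out = filter_objects(labels, pixel_size_um=1.0, geometry=_three_row_geometry())
        kept = {labels[r, c] for r, c in zip(*np.nonzero(out))}
        assert kept == {1}

    def test_circularity_exemption_inside_band(self):
        geom = _three_row_geometry()
        labels = np.zeros((220, 200), np.int32)
        # elongated low-circularity object straddling row 0's band at a pore
        labels[34:46, 38:62] = 1
        labels[38:42, 30:70] = 1
        no_geom = filter_objects(labels, 1.0, geometry=None, min_circularity=0.9)
        with_geom = filter_objects(labels, 1.0, geometry=geom, min_circularity=0.9)
        assert no_geom.max() == 0
        assert with_geom.max() == 1


class TestMeasureObjects:
    def test_square_patch_hand_values(self):
        labels = np.zeros((60, 60), np.int32)
        labels[30:40, 20:30] = 1  # min_x=20, min_y=30, 10x10
        marker = np.full((60, 60), 100.0)
        reporter = np.full((60, 60), 50.0)
        obs = measure_objects(labels, marker, reporter, frame_index=3)
        assert len(obs) == 1
        o = obs[0]
        assert o.area == 100.0
        assert (o.centroid_x, o.centroid_y) == (24.5, 34.5)
        assert o.bbox == (20, 30, 30, 40)
        assert o.mean_nuclear_marker == 100.0
        assert o.mean_reporter == 50.0
        assert o.frame_index == 3

    def test_empty_labels_give_empty_list(self):
        z = np.zeros((30, 30), np.int32)
        assert measure_objects(z, z, z, 0) == []

    def test_generator_frame_centroid_and_area_accuracy(self):
        script = NucleusScript(nucleus_id=0, frames=[0], centers=np.array([[100.0, 122.0]]),
                               marker_level=700.0, allow_dumbbell=False)
        sc = Scenario(name="m", n_frames=1, nuclei=[script], noise_sigma=8.0, seed=5)
        seq, gt = render_scenario(sc)
        sm = smooth_fluorescence(seq.frame(0, "nuclear_marker"))
        _, obs = segment_frame(
            sm, seq.frame(0, "nuclear_marker"), seq.frame(0, "reporter"), 0, 1.0
        )
        g = gt.tracks[0][0]
        o = min(obs, key=lambda o: (o.centroid_x - g.x) ** 2 + (o.centroid_y - g.y) ** 2)
        assert abs(o.centroid_x - g.x) <= 1.0 and abs(o.centroid_y - g.y) <= 1.0
        assert abs(o.area - g.area) <= 0.1 * g.area
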