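"""Device registration: pillar detection, rotation estimation, geometry."""

import json

import numpy as np
import pytest

from confine_track.registration import (
    DeviceGeometry,
    PillarCircle,
    RegistrationError,
    build_geometry,
    detect_pillars,
    estimate_rotation,
    rotate_sequence,
)
from confine_track.synth import DeviceSpec, Scenario, render_scenario


def _device_frame(rotation=0.0, per_row=4, seed=0, noise=5.0):
    dev = DeviceSpec(pillars_per_row=per_row, rotation_deg=rotation)
    sc = Scenario(name="reg", n_frames=1, device=dev, noise_sigma=noise, seed=seed)
    seq, gt = render_scenario(sc)
    return seq, gt


class TestDetectPillars:
    def test_recovers_all_centers_within_two_px(self):
        seq, gt = _device_frame(per_row=4)  # 12 pillars
        circles = detect_pillars(seq.frame(0, "transmitted"))
        assert len(circles) == 12
        det = np.array([[c.center_x, c.center_y] for c in circles])
        for tx, ty in gt.pillar_centers_rendered:
            assert np.min(np.hypot(det[:, 0] - tx, det[:, 1] - ty)) <= 2.0

    def test_sorted_and_radius_positive(self):
        seq, _ = _device_frame()
        circles = detect_pillars(seq.frame(0, "transmitted"))
        keys = [(c.center_y, c.center_x) for c in circles]
        assert keys == sorted(keys)
        assert all(c.radius > 0 for c in circles)

    def test_blank_frame_raises_registration_failure(self):
        with pytest.raises(RegistrationError, match="registration failure"):
            detect_pillars(np.full((100, 100), 500.0))

    def test_single_circle_raises(self):
        frame = np.full((100, 100), 1000.0)
        yy, xx = np.mgrid[0:100, 0:100]
        frame[(xx - 50) ** 2 + (yy - 50) ** 2 <= 64] = 300.0
        with pytest.raises(RegistrationError):
            detect_pillars(frame)

    def test_deterministic(self):
        seq, _ = _device_frame(rotation=2.5)
        a = detect_pillars(seq.frame(0, "transmitted"))
        b = detect_pillars(seq.frame(0, "transmitted"))
        assert a == b


class TestEstimateRotation:
    def test_horizontal_rows_give_zero(self):
        pillars = [PillarCircle(x, y, 8.0) for y in (40, 95) for x in (30, 60, 90)]
        assert estimate_rotation(pillars) == pytest.approx(0.0)

    def test_two_pillar_arctangent(self):
        pillars = [PillarCircle(0, 0, 8.0), PillarCircle(100, 10, 8.0)]
        assert estimate_rotation(pillars) == pytest.approx(-5.71, abs=0.01)

    @pytest.mark.parametrize("rotation", [-5.0, -3.0, 3.0, 5.0])
    def test_recovers_generator_rotation(self, rotation):
        seq, _ = _device_frame(rotation=rotation, per_row=6)
        circles = detect_pillars(seq.frame(0, "transmitted"))
        assert estimate_rotation(circles) == pytest.approx(-rotation, abs=0.2)

    def test_degenerate_coincident_pillars_raise(self):
        pillars = [PillarCircle(50, 50, 8.0), PillarCircle(50, 50, 8.0)]
        with pytest.raises(ValueError):
            estimate_rotation(pillars)


class TestRotateSequence:
    def test_zero_angle_is_identity(self):
        seq, _ = _device_frame()
        out = rotate_sequence(seq, 0.0)
        np.testing.assert_array_equal(out.frames, seq.frames)

    def test_inverse_composition_small_error(self):
        seq, _ = _device_frame(noise=0.0)
        out = rotate_sequence(rotate_sequence(seq, 3.0), -3.0)
        span = np.ptp(seq.frames)
        inner = (slice(None), slice(None), slice(30, -30), slice(30, -30))
        err = np.abs(out.frames[inner] - seq.frames[inner]).mean()
        assert err <= 0.02 * span

    def test_correction_levels_rows(self):
        seq, _ = _device_frame(rotation=4.0, per_row=6)
        circles = detect_pillars(seq.frame(0, "transmitted"))
        rotated = rotate_sequence(seq, estimate_rotation(circles))
        re_det = detect_pillars(rotated.frame(0, "transmitted"))
        # fit a line per row; residual slope must be < 0.5 px RMS
        ys = np.array([c.center_y for c in re_det])
        xs = np.array([c.center_x for c in re_det])
        order = np.argsort(ys)
        for row in np.array_split(order, 3):
            fit = np.polyfit(xs[row], ys[row], 1)
            resid = ys[row] - np.polyval(fit, xs[row])
            assert np.sqrt(np.mean(resid**2)) < 0.5
        assert abs(estimate_rotation(re_det)) < 0.2

    def test_finite_angle_required(self):
        seq, _ = _device_frame()
        with pytest.raises(ValueError):
            rotate_sequence(seq, float("nan"))


class TestBuildGeometry:
    def test_boundary_arithmetic(self):
        pillars = [PillarCircle(x, 100.0, 8.0) for x in (30, 60, 90)]
        with pytest.warns(UserWarning):  # single-row device
            geom = build_geometry(pillars, boundary_offset_um=7.0, pixel_size_um=0.5)
        row = geom.rows[0]
        assert row.centerline_y == pytest.approx(100.0)
        assert row.upper_boundary_y == pytest.approx(86.0)
        assert row.lower_boundary_y == pytest.approx(114.0)
        assert row.constriction_x_centers == (45.0, 75.0)

    def test_boundary_symmetry_exact(self, registration_scenes):
        for seq, _, _ in registration_scenes:
            circles = detect_pillars(seq.frame(0, "transmitted"))
            rotated = rotate_sequence(seq, estimate_rotation(circles))
            geom = build_geometry(
                detect_pillars(rotated.frame(0, "transmitted")),
                boundary_offset_um=7.0,
                pixel_size_um=seq.pixel_size_um,
            )
            for row in geom.rows:
                up = row.centerline_y - row.upper_boundary_y
                down = row.lower_boundary_y - row.centerline_y
                assert up == down == pytest.approx(7.0 / seq.pixel_size_um)

    def test_zero_offset_rejected(self):
        pillars = [PillarCircle(30, 100, 8.0), PillarCircle(60, 100, 8.0)]
        with pytest.raises(ValueError):
            build_geometry(pillars, boundary_offset_um=0.0, pixel_size_um=1.0)

    def test_non_three_rows_warns(self):
        pillars = [PillarCircle(x, 100.0, 8.0) for x in (30, 60, 90)]
        with pytest.warns(UserWarning, match="3 constriction rows"):
            build_geometry(pillars, boundary_offset_um=7.0, pixel_size_um=1.0)

    def test_json_roundtrip(self, tmp_path):
        pillars = [PillarCircle(x, y, 8.0) for y in (40, 95, 150) for x in (30, 60)]
        geom = build_geometry(pillars, boundary_offset_um=7.0, pixel_size_um=1.0)
        path = tmp_path / "geometry.json"
        geom.to_json(path)
        loaded = DeviceGeometry.from_json(path)
        assert loaded.pillars == geom.pillars
        assert loaded.rows == geom.rows
        assert loaded.boundary_offset_um == geom.boundary_offset_um
        assert json.loads(path.read_text())["pixel_size_um"] == 1.0
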