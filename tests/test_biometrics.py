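"""Biometric parameters: landmark construction, CTAR, axis, situs, point P."""

import numpy as np
import pytest

from conftest import make_disk, make_ellipse, mask_set_from, mirror_mask_set
from fourcv import biometrics, geometry as geo
from fourcv.biometrics import AnatomicalLandmarks
from fourcv.exceptions import EmptyRegionError, IndeterminateSideError
from fourcv.geometry import ContourPolyline, OrientedLine, PlanarPoint
from fourcv.phantom import PhantomSpec, generate_phantom


class TestComputeCtar:
    def test_empty_heart_is_zero(self):
        masks = {"whole_thorax": make_ellipse((256, 256), 128, 128, 100, 80)}
        assert biometrics.compute_ctar(mask_set_from(masks)) == 0.0

    def test_heart_equal_to_thorax_is_one(self):
        ellipse = make_ellipse((256, 256), 128, 128, 100, 80)
        masks = {"whole_thorax": ellipse, "heart": ellipse}
        assert biometrics.compute_ctar(mask_set_from(masks)) == 1.0

    def test_disk_in_ellipse_matches_analytic_ratio(self):
        masks = {
            "whole_thorax": make_ellipse((256, 256), 128, 128, 100, 80),
            "heart": make_disk((256, 256), 118, 120, 32),
        }
        expected = np.pi * 32**2 / (np.pi * 100 * 80)
        assert biometrics.compute_ctar(mask_set_from(masks)) == pytest.approx(
            expected, abs=0.01
        )

    def test_empty_thorax_raises(self):
        masks = {"heart": make_disk((64, 64), 32, 32, 10)}
        with pytest.raises(EmptyRegionError):
            biometrics.compute_ctar(mask_set_from(masks))


class TestLocateLandmarks:
    def test_upright_phantom(self, normal_phantom):
        mask_set, truth = normal_phantom
        lm = biometrics.locate_landmarks(mask_set)
        assert abs(lm.theta) < 0.5
        assert np.hypot(
            lm.O_prime.x - truth.thorax_center[0],
            lm.O_prime.y - truth.thorax_center[1],
        ) < 0.5
        assert np.hypot(
            lm.S.x - truth.spine_center[0], lm.S.y - truth.spine_center[1]
        ) < 1.5
        # R sits on the thoracic contour, farther from S than any other hit
        d = [np.hypot(p[0] - lm.S.x, p[1] - lm.S.y) for p in lm.thorax_contour.vertices]
        assert np.hypot(lm.R.x - lm.S.x, lm.R.y - lm.S.y) <= max(d) + 1.0

    def test_rotated_phantom_theta(self):
        mask_set, truth = generate_phantom(PhantomSpec(thorax_rotation=20.0))
        lm = biometrics.locate_landmarks(mask_set)
        assert lm.theta == pytest.approx(20.0, abs=0.7)

    def test_missing_aorta_leaves_A_absent(self, normal_phantom):
        mask_set, _ = normal_phantom
        masks = {k: v.copy() for k, v in mask_set.masks.items()}
        masks["descending_aorta"][:] = False
        lm = biometrics.locate_landmarks(mask_set_from(masks))
        assert lm.A is None
        assert lm.V is not None and lm.R is not None

    def test_I_on_both_lines(self, normal_record):
        lm = normal_record.landmarks
        assert abs(lm.rs_line.signed_offset(lm.I)) < 1e-6
        assert abs(lm.septal_line.signed_offset(lm.I)) < 1e-6


class TestCardiacAxis:
    def test_phantom_axis_recovered(self, normal_record, normal_phantom):
        _, truth = normal_phantom
        assert normal_record.cardiac_axis == pytest.approx(truth.axis_true, abs=2.0)

    def test_septum_parallel_to_rs_gives_small_angle(self):
        spec = PhantomSpec(
            heart_axis_angle=0.5,
            ctar_target=0.21,
            heart_eccentricity=0.92,
            point_p_target=(0.05, -0.62),
            thorax_semi_axes=(100.0, 86.0),
        )
        mask_set, _ = generate_phantom(spec)
        lm = biometrics.locate_landmarks(mask_set)
        assert biometrics.compute_cardiac_axis(lm) <= 2.0

    def test_mirror_invariance(self, normal_phantom, normal_record):
        mask_set, _ = normal_phantom
        mirrored = biometrics.compute_biometrics(mirror_mask_set(mask_set))
        assert mirrored.cardiac_axis == pytest.approx(
            normal_record.cardiac_axis, abs=0.5
        )


def _toy_landmarks(V: PlanarPoint, A: PlanarPoint | None = None) -> AnatomicalLandmarks:
    """Hand-built landmark set on an upright 200x160 thorax frame."""
    S, R = PlanarPoint(128.0, 198.0), PlanarPoint(128.0, 48.0)
    rs = OrientedLine(S, (0.0, -1.0))
    septal = OrientedLine(V, (V.x - S.x + 1e-12, V.y - S.y))
    ring = make_ellipse((256, 256), 128, 128, 100, 80)
    contour = geo.extract_outer_contour(ring)
    return AnatomicalLandmarks(
        S=S, R=R, I=PlanarPoint(128.0, 128.0), V=V, A=A,
        O_prime=PlanarPoint(128.0, 128.0), theta=0.0,
        B1=PlanarPoint(28.0, 128.0), B2=PlanarPoint(228.0, 128.0),
        A1=PlanarPoint(128.0, 48.0), A2=PlanarPoint(128.0, 208.0),
        rs_line=rs, septal_line=septal, thorax_contour=contour,
    )


class TestApexPresentation:
    def test_phantom_apex_left_is_cephalic(self, normal_record):
        assert normal_record.apex_side == "left_of_RS"
        assert normal_record.inferred_presentation == "cephalic"

    def test_mirrored_phantom_is_breech(self, normal_phantom):
        mask_set, _ = normal_phantom
        record = biometrics.compute_biometrics(mirror_mask_set(mask_set))
        assert record.apex_side == "right_of_RS"
        assert record.inferred_presentation == "breech"

    def test_v_on_line_is_indeterminate(self):
        lm = _toy_landmarks(V=PlanarPoint(128.0, 58.0))  # on line RS
        with pytest.raises(IndeterminateSideError):
            biometrics.classify_apex_presentation(lm)


class TestLaterality:
    def test_aorta_on_apex_side_is_solitus(self, normal_record):
        assert normal_record.laterality == "solitus"
        vsa, rsv_plus_rsa = biometrics.laterality_angles(normal_record.landmarks)
        assert vsa < rsv_plus_rsa - 1.0

    def test_contralateral_aorta_is_inversus(self):
        mask_set, _ = generate_phantom(PhantomSpec(aorta_side="contralateral"))
        record = biometrics.compute_biometrics(mask_set)
        assert record.laterality == "inversus"
        vsa, rsv_plus_rsa = biometrics.laterality_angles(record.landmarks)
        assert abs(vsa - rsv_plus_rsa) <= 1.0

    def test_no_aorta_is_indeterminate(self, normal_phantom):
        mask_set, _ = normal_phantom
        masks = {k: v.copy() for k, v in mask_set.masks.items()}
        masks["descending_aorta"][:] = False
        record = biometrics.compute_biometrics(mask_set_from(masks))
        assert record.laterality == "indeterminate"


class TestPointP:
    def _fixture(self, heart_cx: float, heart_r: float):
        """Upright frame, horizontal septal line through the heart center."""
        masks = {"heart": make_disk((256, 256), heart_cx, 128.0, heart_r)}
        mask_set = mask_set_from(masks)
        lm = _toy_landmarks(V=PlanarPoint(28.0, 128.0))
        lm.septal_line = OrientedLine(PlanarPoint(heart_cx, 128.0), (1.0, 0.0))
        return mask_set, lm

    def test_origin_maps_to_origin(self):
        # Heart boundary crossing at O' itself: disk center (98, 128), r=30.
        mask_set, lm = self._fixture(98.0, 30.0)
        gx, gy = biometrics.compute_point_p(mask_set, lm)
        assert gx == pytest.approx(0.0, abs=0.1)
        assert gy == pytest.approx(0.0, abs=0.1)

    def test_halfway_point_scales_to_two_units(self):
        # Crossing opposite V at (178, 128): halfway from O' to the contour,
        # d_x = |B1B2|/8 = 25, so gx = 50/25 = 2.
        mask_set, lm = self._fixture(118.0, 60.0)
        gx, gy = biometrics.compute_point_p(mask_set, lm)
        assert gx == pytest.approx(2.0, abs=0.1)
        assert gy == pytest.approx(0.0, abs=0.1)

    def test_divisions_knob_rescales(self):
        mask_set, lm = self._fixture(118.0, 60.0)
        gx4, _ = biometrics.compute_point_p(mask_set, lm, divisions=4)
        gx8, _ = biometrics.compute_point_p(mask_set, lm, divisions=8)
        assert gx4 == pytest.approx(gx8 / 2.0, abs=0.05)

    def test_mirror_folding_invariance(self, normal_phantom, normal_record):
        mask_set, _ = normal_phantom
        mirrored = biometrics.compute_biometrics(mirror_mask_set(mask_set))
        assert mirrored.point_p[0] == pytest.approx(
            normal_record.point_p[0], abs=0.1
        )
        assert mirrored.point_p[1] == pytest.approx(
            normal_record.point_p[1], abs=0.1
        )


class TestPhantomScaleAndRotation:
    def test_scale_invariance(self, normal_record):
        mask_set, _ = generate_phantom(PhantomSpec().scaled(2.0))
        big = biometrics.compute_biometrics(mask_set)
        assert abs(big.ctar - normal_record.ctar) < 0.01
        assert abs(big.cardiac_axis - normal_record.cardiac_axis) < 1.0
        assert abs(big.point_p[0] - normal_record.point_p[0]) < 0.1
        assert abs(big.point_p[1] - normal_record.point_p[1]) < 0.1

    @pytest.mark.parametrize("rotation", [90.0, 180.0, 270.0])
    def test_quarter_turn_equivariance(self, rotation, normal_record):
        mask_set, _ = generate_phantom(PhantomSpec(thorax_rotation=rotation))
        rec = biometrics.compute_biometrics(mask_set)
        assert abs(rec.ctar - normal_record.ctar) < 0.01
        assert abs(rec.cardiac_axis - normal_record.cardiac_axis) < 1.0
        assert abs(abs(rec.point_p[0]) - abs(normal_record.point_p[0])) < 0.1
        assert abs(abs(rec.point_p[1]) - abs(normal_record.point_p[1])) < 0.1
        assert rec.laterality == normal_record.laterality


def test_record_serialization_roundtrip(normal_record):
    payload = normal_record.to_dict()
    assert payload["ctar"] == normal_record.ctar
    assert payload["point_p"]["gx"] == normal_record.point_p[0]
    assert payload["landmarks"]["S"] is not None
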