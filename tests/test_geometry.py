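"""Reference-plane construction, reflection, and reorientation geometry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mandisym import (
    DegenerateGeometryError,
    GeometryError,
    GeometryInconsistencyError,
    LandmarkSet,
    MissingLandmarkError,
    Plane,
    RigidTransform,
    plane_from_points,
    plane_through_two_points_perpendicular_to,
    reflect_point,
    reorientation_transform,
    signed_distance,
)

Z0 = Plane(np.array([0.0, 0.0, 1.0]), 0.0)

coords = st.floats(-100, 100, allow_nan=False, allow_infinity=False)
points = arrays(np.float64, 3, elements=coords)


class TestPlaneFromPoints:
    @pytest.mark.parametrize(
        "p1, p2, p3, normal, offset",
        [
            ((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), 0.0),
            ((1, 1, 1), (2, 1, 1), (1, 2, 1), (0, 0, 1), 1.0),
        ],
    )
    def test_canonical_planes(self, p1, p2, p3, normal, offset):
        plane = plane_from_points(p1, p2, p3)
        np.testing.assert_allclose(plane.normal, normal, atol=1e-12)
        assert plane.offset == pytest.approx(offset, abs=1e-12)

    @pytest.mark.parametrize(
        "pts",
        [
            ((0, 0, 0), (1, 1, 1), (2, 2, 2)),  # collinear
            ((1, 2, 3), (1, 2, 3), (4, 5, 6)),  # coincident
        ],
    )
    def test_degenerate_points_rejected(self, pts):
        with pytest.raises(DegenerateGeometryError):
            plane_from_points(*pts)

    def test_contains_inputs_random_triples(self, rng):
        """The constructed plane passes through all three defining points."""
        count = 0
        while count < 1000:
            p = rng.uniform(-100, 100, (3, 3))
            if np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])) < 1e-6:
                continue
            plane = plane_from_points(*p)
            for q in p:
                assert abs(signed_distance(q, plane)) < 1e-9
            count += 1


class TestPerpendicularPlane:
    @pytest.mark.parametrize(
        "p1, p2, expected_abs_normal, offset_mag",
        [
            ((0, 0, 0), (0, 1, 0), (1, 0, 0), 0.0),
            ((1, 0, 0), (1, 3, 0), (1, 0, 0), 1.0),
        ],
    )
    def test_midsagittal_construction(self, p1, p2, expected_abs_normal, offset_mag):
        plane = plane_through_two_points_perpendicular_to(p1, p2, Z0)
        np.testing.assert_allclose(np.abs(plane.normal), expected_abs_normal, atol=1e-12)
        assert abs(plane.offset) == pytest.approx(offset_mag, abs=1e-12)

    def test_direction_parallel_to_reference_normal_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            plane_through_two_points_perpendicular_to((0, 0, 0), (0, 0, 5), Z0)

    def test_perpendicularity_and_anchors(self, rng):
        for _ in range(200):
            p1, p2 = rng.uniform(-50, 50, (2, 3))
            n = rng.normal(size=3)
            ref = Plane(n / np.linalg.norm(n), float(rng.uniform(-10, 10)))
            if np.linalg.norm(np.cross(p2 - p1, ref.normal)) < 1e-6:
                continue
            out = plane_through_two_points_perpendicular_to(p1, p2, ref)
            assert abs(float(out.normal @ ref.normal)) < 1e-9
            assert abs(signed_distance(p1, out)) < 1e-9
            assert abs(signed_distance(p2, out)) < 1e-9


class TestSignedDistanceAndReflection:
    X0 = Plane(np.array([1.0, 0.0, 0.0]), 0.0)

    @pytest.mark.parametrize(
        "p, expected",
        [((3, 0, 0), 3.0), ((0, 7, 2), 0.0), ((-4.5, 1, 1), -4.5)],
    )
    def test_signed_distance_to_x0(self, p, expected):
        assert signed_distance(p, self.X0) == pytest.approx(expected, abs=1e-12)

    def test_reflect_across_x0(self):
        np.testing.assert_allclose(
            reflect_point((3, 2, 1), self.X0), (-3, 2, 1), atol=1e-12
        )

    def test_point_on_plane_fixed(self):
        np.testing.assert_allclose(
            reflect_point((0, 5, -2), self.X0), (0, 5, -2), atol=1e-12
        )

    @given(p=points, n=points, d=st.floats(-50, 50))
    def test_involution_and_sign_flip(self, p, n, d):
        if np.linalg.norm(n) < 1e-3:
            return
        plane = Plane(n / np.linalg.norm(n), d)
        q = reflect_point(p, plane)
        assert signed_distance(q, plane) == pytest.approx(
            -signed_distance(p, plane), abs=1e-9
        )
        np.testing.assert_allclose(reflect_point(q, plane), p, atol=1e-9)

    def test_isometry(self, rng):
        """Reflection preserves pairwise distances."""
        n = rng.normal(size=3)
        plane = Plane(n / np.linalg.norm(n), 3.7)
        pts = rng.uniform(-50, 50, (20, 3))
        ref = np.array([reflect_point(p, plane) for p in pts])
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestRigidTransform:
    def test_apply_then_invert_recovers(self, rng):
        # random rotation via QR with positive determinant
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = RigidTransform(q, rng.uniform(-10, 10, 3))
        pts = rng.uniform(-50, 50, (10, 3))
        back = t.inverse().apply_points(t.apply_points(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_reflection_matrix_rejected(self):
        R = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(GeometryError):
            RigidTransform(R, np.zeros(3))

    def test_plane_transforms_consistently(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = RigidTransform(q, rng.uniform(-5, 5, 3))
        plane = Plane(np.array([0.0, 1.0, 0.0]), 2.0)
        p = np.array([3.0, 2.0, -1.0])  # on the plane
        assert abs(signed_distance(t.apply_point(p), t.apply_plane(plane))) < 1e-9


class TestReorientation:
    def test_identity_when_already_standard(self):
        fhp = Plane(np.array([0.0, 0.0, 1.0]), 0.0)
        msp = Plane(np.array([1.0, 0.0, 0.0]), 0.0)
        t = reorientation_transform(fhp, msp, (0, 0, 0))
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0, atol=1e-12)

    def test_translation_only(self):
        fhp = Plane(np.array([0.0, 0.0, 1.0]), 0.0)
        msp = Plane(np.array([1.0, 0.0, 0.0]), 2.0)
        t = reorientation_transform(fhp, msp, (0, 0, 0))
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        assert t.translation[0] == pytest.approx(-2.0, abs=1e-12)

    def test_random_plane_pair_maps_to_standard_frame(self, rng):
        for _ in range(50):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            ez, ex = q[:, 2], q[:, 0]
            fhp = Plane(ez, float(rng.uniform(-10, 10)))
            msp = Plane(ex, float(rng.uniform(-10, 10)))
            tangent = rng.normal(size=3)
            tangent -= (tangent @ msp.normal) * msp.normal  # keep origin on the MSP
            origin = msp.offset * msp.normal + tangent
            t = reorientation_transform(fhp, msp, origin)
            new_msp = t.apply_plane(msp)
            new_fhp = t.apply_plane(fhp)
            np.testing.assert_allclose(np.abs(new_msp.normal), (1, 0, 0), atol=1e-9)
            assert abs(new_msp.offset) < 1e-9
            np.testing.assert_allclose(np.abs(new_fhp.normal), (0, 0, 1), atol=1e-9)
            # composed with its inverse: identity
            both = t.compose(t.inverse())
            np.testing.assert_allclose(both.rotation, np.eye(3), atol=1e-9)
            np.testing.assert_allclose(both.translation, 0, atol=1e-9)
            # origin lands on the new midsagittal plane
            assert abs(t.apply_point(origin)[0]) < 1e-9

    def test_non_perpendicular_pair_rejected(self):
        fhp = Plane(np.array([0.0, 0.0, 1.0]), 0.0)
        n = np.array([1.0, 0.0, 0.2])
        msp = Plane(n / np.linalg.norm(n), 0.0)
        with pytest.raises(GeometryInconsistencyError):
            reorientation_transform(fhp, msp, (0, 0, 0))


class TestLandmarkSet:
    def test_missing_names_reported(self):
        lm = LandmarkSet({"Me": (0, 1, 2)})
        with pytest.raises(MissingLandmarkError, match="Go_mid_left"):
            lm.require(["Me", "Go_mid_left", "Con_left"])

    def test_coincident_bilateral_pair_rejected(self):
        with pytest.raises(GeometryError, match="coincide"):
            LandmarkSet({"Po_left": (1, 2, 3), "Po_right": (1, 2, 3)})

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(GeometryError):
            LandmarkSet({"Me": (np.nan, 0, 0)})

    def test_json_roundtrip(self, tmp_path):
        lm = LandmarkSet({"Me": (0.5, 1.25, -3.0), "N": (0, 40, 58)})
        lm.to_json(tmp_path / "lm.json")
        back = LandmarkSet.from_json(tmp_path / "lm.json")
        np.testing.assert_allclose(back["Me"], lm["Me"])
        np.testing.assert_allclose(back["N"], lm["N"])

    def test_csv_reader(self, tmp_path):
        (tmp_path / "lm.csv").write_text(
            "name,x,y,z\nMe,0.5,1.25,-3.0\nunknown_extra,1,2,3\n"
        )
        lm = LandmarkSet.from_file(tmp_path / "lm.csv")
        np.testing.assert_allclose(lm["Me"], (0.5, 1.25, -3.0))
        assert "unknown_extra" in lm  # preserved but ignored by computations
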