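"""Geometry of the neck-axis projections and the closed-form angle relations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from stemver import (
    AnatomicalFrame,
    DegenerateInputError,
    FemoralLandmarks,
    FrameConstructionError,
    InconsistentAnglesError,
    NeckAxis,
    OrientationAngles,
    PlaneMisalignment,
    angles_from_axis,
    apparent_angles_nonorthogonal,
    apparent_tv,
    axis_from_angles,
    ci_from_tv_si,
    mechanical_frame,
    si_from_tv_ci,
    tv_from_ci_si,
)

# angle strategies kept strictly inside the guarded open domains
ci_deg = st.floats(0.02, 89.98)
tv_deg = st.floats(-89.98, 89.98)


class TestClosedFormEquations:
    @pytest.mark.parametrize(
        "func, args, expected, tol",
        [
            (tv_from_ci_si, (45.0, 45.0), 45.0, 1e-12),
            (tv_from_ci_si, (63.2, 0.0), 0.0, 1e-12),
            (tv_from_ci_si, (50.0, 11.3), 13.3947, 0.01),
            (ci_from_tv_si, (45.0, 45.0), 45.0, 1e-12),
            (ci_from_tv_si, (13.3947, 11.3), 50.0, 0.01),
            (ci_from_tv_si, (10.8, 9.094), 50.0, 0.05),
            (si_from_tv_ci, (45.0, 45.0), 45.0, 1e-12),
            (si_from_tv_ci, (0.0, 37.0), 0.0, 1e-12),
            (si_from_tv_ci, (10.8, 50.0), 9.094, 0.01),
        ],
    )
    def test_worked_values(self, func, args, expected, tol):
        assert func(*args) == pytest.approx(expected, abs=tol)

    def test_vectorized(self):
        ci = np.array([30.0, 50.0, 70.0])
        si = np.array([5.0, 11.3, -8.0])
        out = tv_from_ci_si(ci, si)
        assert out.shape == (3,)
        assert out[1] == pytest.approx(13.3947, abs=0.01)
        assert out[2] < 0  # retroversion keeps its sign

    @pytest.mark.parametrize(
        "func, args",
        [
            (tv_from_ci_si, (0.0, 10.0)),
            (tv_from_ci_si, (90.0, 10.0)),
            (tv_from_ci_si, (0.005, 10.0)),
            (si_from_tv_ci, (10.0, 90.0)),
            (ci_from_tv_si, (10.0, 0.0)),
            (ci_from_tv_si, (10.0, 0.005)),
        ],
    )
    def test_degenerate_inputs_rejected(self, func, args):
        with pytest.raises(DegenerateInputError):
            func(*args)

    def test_sign_mismatch_rejected(self):
        with pytest.raises(InconsistentAnglesError):
            ci_from_tv_si(10.0, -5.0)
        with pytest.raises(InconsistentAnglesError):
            ci_from_tv_si(0.0, 5.0)

    @given(ci=st.floats(0.02, 89.0), si=st.floats(-89.0, 89.0))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_through_inverses(self, ci, si):
        tv = tv_from_ci_si(ci, si)
        assert si_from_tv_ci(tv, ci) == pytest.approx(si, abs=1e-9)
        if abs(si) > 0.02 and abs(tv) > 1e-6:
            assert ci_from_tv_si(tv, si) == pytest.approx(ci, abs=1e-9)

    @given(ci=st.floats(1.0, 89.0), si1=st.floats(0.1, 80.0), dsi=st.floats(0.01, 9.0))
    @settings(max_examples=200, derandomize=True)
    def test_strictly_increasing_in_si(self, ci, si1, dsi):
        assert tv_from_ci_si(ci, si1 + dsi) > tv_from_ci_si(ci, si1)

    @given(ci1=st.floats(1.0, 80.0), dci=st.floats(0.01, 9.0), si=st.floats(0.1, 89.0))
    @settings(max_examples=200, derandomize=True)
    def test_strictly_increasing_in_ci(self, ci1, dci, si):
        assert tv_from_ci_si(ci1 + dci, si) > tv_from_ci_si(ci1, si)


class TestAxisConversions:
    def test_symmetric_axis(self):
        ang = angles_from_axis(NeckAxis.from_vector([1.0, 1.0, 1.0]))
        assert ang.as_tuple() == pytest.approx((45.0, 45.0, 45.0))

    def test_horizontal_axis_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            angles_from_axis(NeckAxis(1.0, 0.0, 0.0))

    def test_axis_parallel_to_plane_normal(self):
        frame = AnatomicalFrame.scanner()
        with pytest.raises(DegenerateInputError, match="coronal"):
            # anterior-pointing axis: coronal projection collapses
            angles_from_axis(NeckAxis.from_vector([1e-8, 1.0, 1e-8]), frame)

    def test_worked_axis(self):
        axis = NeckAxis(0.6380091912413902, 0.12170676233851183, 0.7603497457700531)
        ang = angles_from_axis(axis)
        assert ang.ci == pytest.approx(50.0, abs=0.05)
        assert ang.si == pytest.approx(9.09, abs=0.05)
        assert ang.tv == pytest.approx(10.8, abs=0.05)

    def test_axis_from_angles_worked(self):
        axis = axis_from_angles(50.0, 10.8)
        assert axis.as_array() == pytest.approx([0.6380, 0.1217, 0.7603], abs=1e-3)

    def test_zero_version_has_no_anterior_component(self):
        for ci in (10.0, 45.0, 80.0):
            assert axis_from_angles(ci, 0.0).y == 0.0

    def test_axis_from_angles_domain(self):
        with pytest.raises(DegenerateInputError):
            axis_from_angles(0.0, 10.0)
        with pytest.raises(DegenerateInputError):
            axis_from_angles(45.0, 90.0)

    @given(ci=st.floats(0.1, 89.9), tv=st.floats(-89.9, 89.9))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_axis_angles(self, ci, tv):
        ang = angles_from_axis(axis_from_angles(ci, tv))
        assert ang.ci == pytest.approx(ci, abs=1e-9)
        assert ang.tv == pytest.approx(tv, abs=1e-9)

    @given(ci=st.floats(20.0, 70.0), tv=st.floats(-20.0, 20.0),
           rx=st.floats(-10.0, 10.0), ry=st.floats(-10.0, 10.0), rz=st.floats(-10.0, 10.0))
    @settings(max_examples=100, derandomize=True)
    def test_frame_equivariance(self, ci, tv, rx, ry, rz):
        """Angles are unchanged when axis and frame rotate together."""
        rot = Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()
        axis = axis_from_angles(ci, tv)
        frame = AnatomicalFrame.scanner()
        rot_axis = NeckAxis.from_vector(rot @ axis.as_array())
        rot_frame = AnatomicalFrame(
            origin=rot @ frame.origin, e_x=rot @ frame.e_x, e_y=rot @ frame.e_y, e_z=rot @ frame.e_z
        )
        base = angles_from_axis(axis, frame)
        moved = angles_from_axis(rot_axis, rot_frame)
        assert moved.ci == pytest.approx(base.ci, abs=1e-9)
        assert moved.si == pytest.approx(base.si, abs=1e-9)
        assert moved.tv == pytest.approx(base.tv, abs=1e-9)


class TestOrientationAngles:
    def test_consistent_triple_accepted(self):
        OrientationAngles(50.0, 9.09400956143727, 10.8)

    def test_identity_violation_rejected(self):
        with pytest.raises(InconsistentAnglesError):
            OrientationAngles(50.0, 11.3, 10.8)

    def test_range_violation_rejected(self):
        with pytest.raises(InconsistentAnglesError):
            OrientationAngles(-5.0, 1.0, 1.0)


class TestNeckAxis:
    def test_must_be_unit(self):
        with pytest.raises(ValueError):
            NeckAxis(1.0, 1.0, 1.0)

    def test_must_point_medially(self):
        with pytest.raises(ValueError):
            NeckAxis.from_vector([-1.0, 0.2, 0.5])


class TestMechanicalFrame:
    def _landmarks(self):
        return FemoralLandmarks(
            head_center=[0.0, 0.0, 400.0],
            knee_center=[0.0, 0.0, 0.0],
            medial_posterior_condyle=[30.0, 0.0, 0.0],
            lateral_posterior_condyle=[-30.0, 0.0, 0.0],
        )

    def test_aligned_landmarks_give_identity_axes(self):
        frame = mechanical_frame(self._landmarks())
        assert frame.e_x == pytest.approx([1.0, 0.0, 0.0])
        assert frame.e_y == pytest.approx([0.0, 1.0, 0.0])
        assert frame.e_z == pytest.approx([0.0, 0.0, 1.0])
        assert frame.origin == pytest.approx([0.0, 0.0, 400.0])

    def test_rotation_equivariance(self):
        rot = Rotation.from_euler("xyz", [12.0, -7.0, 25.0], degrees=True).as_matrix()
        lm = self._landmarks()
        rotated = FemoralLandmarks(
            head_center=rot @ lm.head_center,
            knee_center=rot @ lm.knee_center,
            medial_posterior_condyle=rot @ lm.medial_posterior_condyle,
            lateral_posterior_condyle=rot @ lm.lateral_posterior_condyle,
        )
        base = mechanical_frame(lm)
        moved = mechanical_frame(rotated)
        for name in ("e_x", "e_y", "e_z"):
            assert getattr(moved, name) == pytest.approx(rot @ getattr(base, name), abs=1e-10)

    def test_oblique_mechanical_axis_gram_schmidt(self):
        lm = FemoralLandmarks(
            head_center=[20.0, 10.0, 400.0],
            knee_center=[0.0, 0.0, 0.0],
            medial_posterior_condyle=[30.0, 0.0, 0.0],
            lateral_posterior_condyle=[-30.0, 0.0, 0.0],
        )
        frame = mechanical_frame(lm)
        e_z = np.array([20.0, 10.0, 400.0])
        e_z = e_z / np.linalg.norm(e_z)
        raw = np.array([1.0, 0.0, 0.0])
        e_x = raw - np.dot(raw, e_z) * e_z
        e_x = e_x / np.linalg.norm(e_x)
        assert frame.e_z == pytest.approx(e_z, abs=1e-12)
        assert frame.e_x == pytest.approx(e_x, abs=1e-12)

    def test_degenerate_landmarks(self):
        with pytest.raises(FrameConstructionError):
            FemoralLandmarks(
                head_center=[0, 0, 0],
                knee_center=[0, 0, 0],
                medial_posterior_condyle=[1, 0, 0],
                lateral_posterior_condyle=[-1, 0, 0],
            )
        with pytest.raises(FrameConstructionError):
            mechanical_frame(
                FemoralLandmarks(
                    head_center=[0, 0, 400],
                    knee_center=[0, 0, 0],
                    medial_posterior_condyle=[0, 0, 10],
                    lateral_posterior_condyle=[0, 0, -10],
                )
            )


class TestNonOrthogonalModel:
    def test_zero_misalignment_matches_forward_model(self):
        axis = axis_from_angles(50.0, 10.8)
        base = angles_from_axis(axis)
        app = apparent_angles_nonorthogonal(axis, mis=PlaneMisalignment(0.0))
        assert app.as_tuple() == pytest.approx(base.as_tuple())

    def test_worked_apparent_version(self):
        assert apparent_tv(10.8, 5.0) == pytest.approx(5.87, abs=0.01)

    def test_misalignment_equal_to_version_cancels(self):
        # tan 45 * cos 45 - sin 45 = 0
        assert apparent_tv(44.999999, 44.999999) == pytest.approx(0.0, abs=1e-4)

    def test_rotation_matrix_oracle(self):
        """The apparent angles equal re-projection of the axis rotated by
        -delta about the vertical axis."""
        delta = 5.0
        axis = axis_from_angles(50.0, 10.8)
        rot = Rotation.from_euler("z", -delta, degrees=True).as_matrix()
        v = rot @ axis.as_array()
        si_oracle = np.degrees(np.arctan2(v[1], v[2]))
        app = apparent_angles_nonorthogonal(axis, mis=PlaneMisalignment(delta))
        assert app.si == pytest.approx(si_oracle, abs=1e-9)
        assert app.tv == pytest.approx(5.873842504726907, abs=1e-6)

    @given(ci=st.floats(20.0, 70.0), tv=st.floats(-30.0, 30.0), delta=st.floats(-9.99, 9.99))
    @settings(max_examples=200, derandomize=True)
    def test_closed_form_matches_vector_path(self, ci, tv, delta):
        axis = axis_from_angles(ci, tv)
        app = apparent_angles_nonorthogonal(axis, mis=PlaneMisalignment(delta))
        closed = apparent_tv(tv, delta)
        assert app.tv == pytest.approx(closed, abs=1e-9)

    def test_positive_delta_reduces_anteversion(self):
        assert apparent_tv(10.8, 5.0) < 10.8

    def test_misalignment_bounds(self):
        with pytest.raises(ValueError):
            PlaneMisalignment(45.0)


class TestProjectionIdentity:
    def test_identity_holds_for_random_axes(self, rng):
        """tan(tv) = tan(si) * tan(ci) across 10,000 random valid axes."""
        ci = rng.uniform(0.02, 89.98, 10_000)
        tv = rng.uniform(-89.98, 89.98, 10_000)
        v = np.stack([np.ones_like(ci), np.tan(np.radians(tv)), np.tan(np.radians(ci))])
        v /= np.linalg.norm(v, axis=0)
        ci_p = np.degrees(np.arctan2(v[2], v[0]))
        si_p = np.degrees(np.arctan2(v[1], v[2]))
        tv_p = np.degrees(np.arctan2(v[1], v[0]))
        resid = np.tan(np.radians(tv_p)) - np.tan(np.radians(si_p)) * np.tan(np.radians(ci_p))
        assert np.max(np.abs(resid) / np.maximum(1.0, np.abs(np.tan(np.radians(tv_p))))) < 1e-9
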