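"""Geometric engine: angle primitive, pelvic parameters, incidences, identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinemetrics.geometry import (
    DegenerateGeometryError,
    FrameConvention,
    IncidenceAngles,
    LandmarkSet,
    PelvicParameters,
    Point2D,
    TEST_PARAMETER_NAMES,
    compute_direct_parameters,
    compute_incidence_angles,
    compute_pelvic_parameters,
    compute_slopes,
    derive_test_parameters,
    full_report,
    pt_line,
    signed_angle_between,
)
from spinemetrics.phantom import PhantomSpec, generate_landmark_set

from conftest import random_feasible_specs, rotate_about

FRAME = FrameConvention("+x")


def _flat_spine_landmarks() -> LandmarkSet:
    """Vertical pelvic-tilt line, all endplates horizontal: every angle zero."""
    coords = {
        "femoral_head_1": (-3.0, 500.0),
        "femoral_head_2": (3.0, 500.0),
        "sacrum_center": (0.0, 420.0),
        "s1_sup_ant": (20.0, 400.0),
        "s1_sup_post": (-20.0, 400.0),
        "l1_sup_ant": (18.0, 300.0),
        "l1_sup_post": (-18.0, 300.0),
        "t1_sup_ant": (15.0, 150.0),
        "t1_sup_post": (-15.0, 150.0),
        "c2_inf_ant": (10.0, 50.0),
        "c2_inf_post": (-10.0, 50.0),
    }
    return LandmarkSet.from_dict(coords)


class TestSignedAngle:
    def test_identity_is_zero(self):
        assert signed_angle_between((1, 0), (1, 0), FRAME) == 0.0

    def test_orthogonal_magnitude(self):
        assert abs(signed_angle_between((1, 0), (0, 1), FRAME)) == pytest.approx(90.0)

    def test_rotation_matrix_oracle_45deg(self):
        # rotate (1,0) by +45deg in the anatomical frame and check the
        # primitive returns exactly that rotation, magnitude and sign
        t = math.radians(45.0)
        v_anat = np.array([math.cos(t) * 1 - math.sin(t) * 0, math.sin(t) * 1 + math.cos(t) * 0])
        v_img = FRAME.to_image(v_anat)
        ang = signed_angle_between((1, 0), v_img, FRAME)
        assert ang == pytest.approx(45.0, abs=1e-12)

    def test_magnitude_matches_extended_precision_arccos(self):
        """Magnitude equals arccos of the normalized dot product (longdouble oracle)."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            v1, v2 = rng.normal(size=2), rng.normal(size=2)
            if np.allclose(v1, 0) or np.allclose(v2, 0):
                continue
            a, b = np.longdouble(v1), np.longdouble(v2)
            cosang = (a @ b) / (np.sqrt(a @ a) * np.sqrt(b @ b))
            expected = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            got = abs(signed_angle_between(v1, v2, FRAME))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_antisymmetric_in_frame_flip(self):
        a = signed_angle_between((1, 0), (1, 1), FrameConvention("+x"))
        b = signed_angle_between((1, 0), (1, 1), FrameConvention("-x"))
        assert a == pytest.approx(-b)

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateGeometryError):
            signed_angle_between((0, 0), (1, 0), FRAME)

    @given(
        st.floats(-1e3, 1e3), st.floats(-1e3, 1e3), st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)
    )
    @settings(derandomize=True, max_examples=200)
    def test_range_property(self, x1, y1, x2, y2):
        if (x1 == 0 and y1 == 0) or (x2 == 0 and y2 == 0):
            return
        ang = signed_angle_between((x1, y1), (x2, y2), FRAME)
        assert -180.0 < ang <= 180.0


class TestPtLine:
    def test_vertical_line(self):
        lm = _flat_spine_landmarks()
        v = pt_line(lm)
        assert v == pytest.approx([0.0, -100.0])

    def test_asymmetric_midpoint_arithmetic(self):
        # manual midpoint computation as the oracle
        coords = _flat_spine_landmarks().as_dict()
        coords["femoral_head_1"] = (10.0, 520.0)
        coords["femoral_head_2"] = (30.0, 480.0)
        coords["s1_sup_ant"] = (37.0, 402.0)
        coords["s1_sup_post"] = (-3.0, 398.0)
        lm = LandmarkSet.from_dict(coords)
        assert pt_line(lm) == pytest.approx([17.0 - 20.0, 400.0 - 500.0])

    def test_degenerate_raises(self):
        coords = _flat_spine_landmarks().as_dict()
        coords["femoral_head_1"] = (0.0, 400.0)
        coords["femoral_head_2"] = (0.0, 400.0)
        with pytest.raises(DegenerateGeometryError):
            LandmarkSet.from_dict(coords)


class TestPelvicParameters:
    def test_all_zero_configuration(self):
        p = compute_pelvic_parameters(_flat_spine_landmarks(), FRAME)
        assert (p.PI, p.PT, p.SS) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_reference_mean_recovery(self, mean_phantom):
        lm, _ = mean_phantom
        p = compute_pelvic_parameters(lm, FRAME)
        assert p.PI == pytest.approx(52.16, abs=1e-6)
        assert p.PT == pytest.approx(14.99, abs=1e-6)
        assert p.SS == pytest.approx(37.17, abs=1e-6)

    def test_rotation_shifts_pt_not_pi(self, mean_phantom):
        lm, _ = mean_phantom
        before = compute_pelvic_parameters(lm, FRAME)
        rotated = rotate_about(lm, lm.femoral_midpoint(), 5.0, FRAME)
        after = compute_pelvic_parameters(rotated, FRAME)
        assert after.PI == pytest.approx(before.PI, abs=1e-9)
        assert after.PT == pytest.approx(before.PT + 5.0, abs=1e-9)
        assert after.SS == pytest.approx(before.SS - 5.0, abs=1e-9)


class TestIncidences:
    def test_parallel_endplates_equal_pi(self):
        lm, _ = generate_landmark_set(PhantomSpec(pi=50.0, pt=12.0, l1i=50.0, t1i=50.0, c2i=50.0))
        inc = compute_incidence_angles(lm, FRAME)
        pi = compute_pelvic_parameters(lm, FRAME).PI
        for val in (inc.L1I, inc.T1I, inc.C2I):
            assert val == pytest.approx(pi, abs=1e-9)

    def test_reference_mean_recovery(self, mean_phantom):
        lm, _ = mean_phantom
        inc = compute_incidence_angles(lm, FRAME)
        assert inc.L1I == pytest.approx(2.46, abs=1e-6)
        assert inc.T1I == pytest.approx(39.77, abs=1e-6)
        assert inc.C2I == pytest.approx(26.87, abs=1e-6)

    def test_perpendicular_on_pt_line_gives_zero(self):
        lm, _ = generate_landmark_set(PhantomSpec(pi=45.0, pt=10.0, l1i=0.0, t1i=40.0, c2i=25.0))
        assert compute_incidence_angles(lm, FRAME).L1I == pytest.approx(0.0, abs=1e-9)


class TestDirectParameters:
    def test_all_horizontal_endplates_zero(self):
        t = compute_direct_parameters(_flat_spine_landmarks(), FRAME)
        for name in TEST_PARAMETER_NAMES:
            assert getattr(t, name) == pytest.approx(0.0, abs=1e-12)

    def test_straight_spine_slopes_equal_ss(self):
        """All endplates parallel: regional angles vanish, slopes all equal SS."""
        lm, _ = generate_landmark_set(PhantomSpec(pi=50.0, pt=12.0, l1i=50.0, t1i=50.0, c2i=50.0))
        t = compute_direct_parameters(lm, FRAME)
        ss = compute_pelvic_parameters(lm, FRAME).SS
        assert t.LL == pytest.approx(0.0, abs=1e-9)
        assert t.TK == pytest.approx(0.0, abs=1e-9)
        assert t.C2_7L == pytest.approx(0.0, abs=1e-9)
        for name in ("L1S", "T1S", "C2S"):
            assert getattr(t, name) == pytest.approx(ss, abs=1e-9)

    def test_known_construction_angles(self, mean_phantom):
        lm, _ = mean_phantom
        t = compute_direct_parameters(lm, FRAME)
        assert t.LL == pytest.approx(2.46 - 52.16, abs=1e-6)
        assert t.TK == pytest.approx(39.77 - 2.46, abs=1e-6)
        assert t.C2_7L == pytest.approx(39.77 - 26.87, abs=1e-6)
        assert t.L1S == pytest.approx(2.46 - 14.99, abs=1e-6)


class TestDeriveEquations:
    def test_reference_mean_worked_examples(self):
        """Incidence-difference equations on the published cohort means."""
        derived = derive_test_parameters(
            PelvicParameters(PI=52.16, PT=14.99, SS=37.17),
            IncidenceAngles(L1I=2.46, T1I=39.77, C2I=26.87),
        )
        assert round(derived.TK, 2) == 37.31
        assert round(derived.C2_7L, 2) == 12.90
        assert round(derived.L1S, 2) == -12.53
        assert round(derived.T1S, 2) == 24.78
        assert round(derived.C2S, 2) == 11.88

    def test_all_zero(self):
        derived = derive_test_parameters(
            PelvicParameters(PI=0, PT=0, SS=0), IncidenceAngles(L1I=0, T1I=0, C2I=0)
        )
        assert all(v == 0.0 for v in derived.as_dict().values())

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            derive_test_parameters(
                PelvicParameters(PI=float("nan"), PT=0, SS=0),
                IncidenceAngles(L1I=0, T1I=0, C2I=0),
            )


@pytest.fixture(scope="module")
def cohort():
    return [generate_landmark_set(s) for s in random_feasible_specs(200, seed=7)]


class TestIdentities:
    """The signed identities that make the derivation equations exact."""

    def test_pi_equals_pt_plus_ss(self, cohort):
        for lm, _ in cohort:
            p = compute_pelvic_parameters(lm, FRAME)
            assert p.PI == pytest.approx(p.PT + p.SS, abs=1e-6)

    def test_incidence_equals_slope_plus_pt(self, cohort):
        for lm, _ in cohort:
            p = compute_pelvic_parameters(lm, FRAME)
            inc = compute_incidence_angles(lm, FRAME)
            slopes = compute_slopes(lm, FRAME)
            assert inc.L1I == pytest.approx(slopes["L1S"] + p.PT, abs=1e-6)
            assert inc.T1I == pytest.approx(slopes["T1S"] + p.PT, abs=1e-6)
            assert inc.C2I == pytest.approx(slopes["C2S"] + p.PT, abs=1e-6)

    def test_derived_equals_direct(self, cohort):
        for lm, _ in cohort:
            rep = full_report(lm, FRAME)
            assert max(rep.discrepancy.values()) < 1e-6

    def test_translation_and_scale_invariance(self, mean_phantom):
        lm, _ = mean_phantom
        ref = full_report(lm, FRAME)

        def all12(r):
            return [
                r.pelvic.PI, r.pelvic.PT, r.pelvic.SS,
                r.incidences.L1I, r.incidences.T1I, r.incidences.C2I,
                *(getattr(r.direct, n) for n in TEST_PARAMETER_NAMES),
            ]

        shifted = lm.transformed(lambda a: a + [37.5, -12.25])
        scaled = lm.transformed(lambda a: a * 2.75)
        for other in (shifted, scaled):
            assert all12(full_report(other, FRAME)) == pytest.approx(all12(ref), abs=1e-9)

    def test_rotation_invariance_split(self, mean_phantom):
        """Shape parameters survive rotation; positional ones shift by the angle."""
        lm, _ = mean_phantom
        ref = full_report(lm, FRAME)
        rot = full_report(rotate_about(lm, lm.femoral_midpoint(), 7.0, FRAME), FRAME)
        assert rot.pelvic.PI == pytest.approx(ref.pelvic.PI, abs=1e-9)
        for name in ("LL", "TK", "C2_7L"):
            assert getattr(rot.direct, name) == pytest.approx(
                getattr(ref.direct, name), abs=1e-9
            )
        assert rot.pelvic.PT == pytest.approx(ref.pelvic.PT + 7.0, abs=1e-9)
        for name in ("L1S", "T1S", "C2S"):
            assert getattr(rot.direct, name) == pytest.approx(
                getattr(ref.direct, name) - 7.0, abs=1e-9
            )


class TestFullReport:
    def test_discrepancy_nonnegative_and_tiny(self, mean_phantom):
        lm, _ = mean_phantom
        rep = full_report(lm, FRAME)
        assert all(v >= 0 for v in rep.discrepancy.values())
        assert max(rep.discrepancy.values()) < 1e-6

    def test_whole_pixel_quantization_keeps_identity(self, mean_phantom):
        """Rounding landmarks to integer pixels perturbs the angles but the
        direct and equation-derived routes stay in lock-step."""
        lm, _ = mean_phantom
        quantized = lm.transformed(np.round)
        rep = full_report(quantized, FRAME)
        assert max(rep.discrepancy.values()) < 0.05

    def test_degenerate_endplate_names_vertebra(self):
        coords = _flat_spine_landmarks().as_dict()
        coords["t1_sup_ant"] = coords["t1_sup_post"]
        with pytest.raises(DegenerateGeometryError, match="T1"):
            LandmarkSet.from_dict(coords)


class TestLandmarkSet:
    def test_missing_name_rejected(self):
        coords = _flat_spine_landmarks().as_dict()
        del coords["c2_inf_post"]
        with pytest.raises(ValueError, match="c2_inf_post"):
            LandmarkSet.from_dict(coords)

    def test_unknown_name_rejected(self):
        coords = _flat_spine_landmarks().as_dict()
        coords["c7_sup_ant"] = (0.0, 0.0)
        with pytest.raises(ValueError, match="c7_sup_ant"):
            LandmarkSet.from_dict(coords)

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            Point2D(float("inf"), 0.0)

    def test_array_round_trip(self, mean_phantom):
        lm, _ = mean_phantom
        assert LandmarkSet.from_array(lm.as_array()).as_dict() == lm.as_dict()
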