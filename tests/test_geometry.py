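"""Landmarking and chord morphometry on silhouette masks."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wbconform.geometry import (
    Conformation,
    DegenerateSilhouetteError,
    Landmarks,
    MaskInvariantError,
    SilhouetteMask,
    conformation_from_table,
    locate_landmarks,
    measure_conformation,
)
from wbconform.synthdata import render_silhouette


def rect_mask(rows=401, cols=201, scale=0.05):
    return SilhouetteMask(np.ones((rows, cols), bool), scale)


class TestMaskInvariants:
    def test_empty_mask_rejected(self):
        with pytest.raises(MaskInvariantError):
            SilhouetteMask(np.zeros((50, 50), bool), 0.05)

    def test_small_foreground_rejected(self):
        px = np.zeros((50, 50), bool)
        px[10:13, 10:13] = True
        with pytest.raises(MaskInvariantError, match="px"):
            SilhouetteMask(px, 0.05)

    def test_multiple_components_rejected(self):
        px = np.zeros((60, 60), bool)
        px[2:20, 2:20] = True
        px[40:58, 40:58] = True
        with pytest.raises(MaskInvariantError, match="components"):
            SilhouetteMask(px, 0.05)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(MaskInvariantError, match="scale"):
            SilhouetteMask(np.ones((20, 20), bool), 0.0)


class TestLandmarks:
    def test_rectangle_extremes_with_tie_break(self):
        lm = locate_landmarks(rect_mask())
        assert lm.keel_tip == (400.0, 0.0)  # leftmost bottom-row pixel
        assert lm.cranial_end == (0.0, 0.0)  # leftmost top-row pixel

    def test_triangle_apex_is_keel_tip(self):
        # apex-down isosceles triangle: unique caudal extreme point
        rows, cols = np.mgrid[0:200, 0:161]
        px = np.abs(cols - 80) <= 0.4 * (199 - rows)
        lm = locate_landmarks(SilhouetteMask(px, 0.05))
        assert lm.keel_tip == (199.0, 80.0)

    def test_rendered_apex_recovered_within_one_pixel(self, rendered):
        lm = locate_landmarks(rendered.mask)
        assert abs(lm.keel_tip[0] - rendered.keel_tip[0]) <= 1.0
        assert abs(lm.keel_tip[1] - rendered.keel_tip[1]) <= 1.0

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(DegenerateSilhouetteError):
            Landmarks((5.0, 5.0), (5.0, 5.0))


@pytest.fixture(scope="module")
def rect_conf():
    """20 cm x 10 cm rectangle, axis along the length, keel tip centred."""
    mask = rect_mask()
    lm = Landmarks(keel_tip=(400.0, 100.0), cranial_end=(0.0, 100.0))
    return measure_conformation(mask, lm)


class TestRectangleClosedForm:

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("M0", 20.0),
            ("M1", 10.0),
            ("M2", 4.0),
            ("M3", 10.0),
            ("M5", 20.0),
            ("M6", 40.0),
            ("M7", 20.0),
            ("M9", 2.5),
            ("M11", 0.5),
        ],
    )
    def test_lengths_and_areas_within_2_percent(self, rect_conf, name, expected):
        assert rect_conf[name] == pytest.approx(expected, rel=0.02)

    def test_apex_angle_within_half_degree(self, rect_conf):
        expected = 2.0 * math.degrees(math.atan(5.0 / 4.0))  # 102.68
        assert rect_conf["M4"] == pytest.approx(expected, abs=0.5)


class TestRoundTrip:
    def test_rendered_dimensions_recovered(self, rendered):
        conf = measure_conformation(rendered.mask)
        assert conf["M0"] == pytest.approx(rendered.m0, rel=0.02)
        assert conf["M1"] == pytest.approx(rendered.m1, rel=0.02)
        assert conf["M3"] == pytest.approx(rendered.m3, rel=0.02)
        m4_true = 2 * math.degrees(math.atan(rendered.m3 / (2 * rendered.m0 / 5)))
        assert conf["M4"] == pytest.approx(m4_true, abs=1.0)

    def test_m7_identity_exact_on_measured_masks(self, rendered):
        for mask in (rendered.mask, rect_mask()):
            conf = measure_conformation(mask)
            assert conf["M7"] == pytest.approx(conf["M6"] - conf["M5"], abs=1e-9)

    def test_symmetric_closure_of_apex_angle(self, rendered):
        conf = measure_conformation(rendered.mask)
        closed_form = 2 * math.degrees(math.atan(conf["M3"] / (2 * conf["M2"])))
        assert conf["M4"] == pytest.approx(closed_form, abs=0.5)

    def test_scale_equivariance(self, rendered):
        c1 = measure_conformation(rendered.mask)
        doubled = SilhouetteMask(rendered.mask.pixels, 2 * rendered.mask.scale_cm_per_px)
        c2 = measure_conformation(doubled)
        for name in ("M0", "M1", "M2", "M3"):
            assert c2[name] == pytest.approx(2 * c1[name], rel=1e-9)
        for name in ("M5", "M6", "M7"):
            assert c2[name] == pytest.approx(4 * c1[name], rel=1e-9)
        for name in ("M4", "M8", "M9", "M10", "M11"):
            assert c2[name] == pytest.approx(c1[name], rel=1e-9)


class TestDegenerateMeasurement:
    def test_chord_in_background_rejected(self):
        # axis pointing out of the raster: the scanline at the M2 offset
        # crosses background only, which must be signalled, not silently
        # measured as a zero-width chord
        mask = rect_mask()
        lm = Landmarks(keel_tip=(400.0, 100.0), cranial_end=(800.0, 100.0))
        with pytest.raises(DegenerateSilhouetteError):
            measure_conformation(mask, lm)


class TestConformationFromTable:
    def test_published_group_mean_row_m7(self):
        # 6-wk HBY female group means
        conf = conformation_from_table(
            {"M0": 20.3, "M1": 14.4, "M2": 4.1, "M3": 9.2, "M4": 96.3,
             "M5": 18.7, "M6": 24.8}
        )
        assert conf["M7"] == pytest.approx(24.8 - 18.7)
        assert conf["M7"] == pytest.approx(6.1)

    def test_ratio_fill(self):
        conf = conformation_from_table({"M0": 30.0, "M1": 15.0, "M3": 9.0, "M6": 40.0})
        assert conf["M11"] == pytest.approx(0.5)
        assert conf["M8"] == pytest.approx(9.0 / 15.0)

    def test_m9_from_tabulated_offset(self):
        conf = conformation_from_table({"M2": 4.1, "M1": 14.4, "M3": 9.2})
        assert conf["M9"] == pytest.approx(9.2 / 4.1, abs=1e-4)

    def test_inconsistent_m7_warns_and_recomputes(self):
        with pytest.warns(UserWarning, match="M7"):
            conf = conformation_from_table(
                {"M0": 20.3, "M1": 14.4, "M3": 9.2, "M5": 18.7, "M6": 24.8,
                 "M7": 9.0}
            )
        assert conf["M7"] == pytest.approx(6.1)

    def test_missing_required_column_rejected(self):
        with pytest.raises(ValueError, match="M1"):
            conformation_from_table({"M0": 20.0, "M3": 9.0})

    @given(
        m0=st.floats(15.0, 30.0),
        m1=st.floats(10.0, 20.0),
        m3=st.floats(6.0, 9.9),
        bulge=st.floats(0.0, 15.0),
    )
    def test_identities_hold_for_any_table_row(self, m0, m1, m3, bulge):
        m2 = m0 / 5.0
        m5 = 0.5 * m3 * m2
        conf = conformation_from_table(
            {"M0": m0, "M1": m1, "M3": m3, "M6": m5 + bulge}
        )
        assert conf["M2"] == pytest.approx(m0 / 5.0)
        assert conf["M7"] == pytest.approx(conf["M6"] - conf["M5"], abs=1e-9)
        assert conf["M8"] == pytest.approx(m3 / m1)
        assert conf["M9"] == pytest.approx(m3 / m2)
        assert conf["M11"] == pytest.approx(m1 / m0)

    def test_validation_flags_bad_angle(self):
        with pytest.raises(DegenerateSilhouetteError):
            Conformation(
                m0=20, m1=14, m2=4, m3=9, m4=185.0, m5=18, m6=24, m7=6,
                m8=0.64, m9=2.25, m10=0.33, m11=0.7,
            ).validate()
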