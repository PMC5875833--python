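"""Projection-geometry algebra: factors, lever arms, identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from focalspot import (
    CentroidSeparation,
    LinacGeometry,
    ic_lever_arm,
    jaw_plane_shift,
    load_geometry,
    offset_from_separation,
    project_center,
    proportionality_factor,
)
from focalspot.errors import DegenerateGeometryError


def raytrace_center(source_offset, d_col, d_epi, half_width=50.0, n=100_000):
    """Independent oracle: trace rays through both aperture edges.

    Samples points across an aperture centred on the rotation axis and
    projects each through the displaced point source; the field centre is
    the midpoint of the extreme projected positions.
    """
    pts = np.linspace(-half_width, half_width, n)
    det = source_offset + (pts - source_offset) * d_epi / d_col
    return (det.min() + det.max()) / 2.0


class TestProportionalityFactor:
    @pytest.mark.parametrize(
        "d_epi, jaw_axis, expected, sig",
        [
            (1000.0, "X", 2.368, 4),
            (1050.0, "X", 2.2556, 5),
            (1000.0, "Y", 0.9141, 4),
            (1050.0, "Y", 0.8706, 4),
        ],
    )
    def test_published_factors(self, d_epi, jaw_axis, expected, sig):
        """The four machine factors at SID 100/105 cm match to printed precision."""
        geom = LinacGeometry(d_epi=d_epi)
        a = proportionality_factor(geom, jaw_axis)
        assert a == pytest.approx(expected, abs=0.5 * 10.0 ** -(sig - 1))

    def test_near_degenerate_planes_raise(self):
        geom = LinacGeometry(d_jaw_x=490.0 - 1e-10)
        with pytest.raises(DegenerateGeometryError):
            proportionality_factor(geom, "X")

    def test_equal_jaw_and_mlc_planes_rejected_at_construction(self):
        with pytest.raises(ValueError):
            LinacGeometry(d_jaw_x=490.0, d_mlc=490.0)

    def test_scale_invariance(self):
        """Dimensionless factors are unchanged under a global rescaling."""
        g1 = LinacGeometry(d_epi=1000, d_jaw_x=406, d_jaw_y=319, d_mlc=490, d_ic=750)
        g2 = LinacGeometry(
            d_epi=2500, d_jaw_x=1015, d_jaw_y=797.5, d_mlc=1225, d_ic=1875, sad=2500
        )
        for axis in ("X", "Y"):
            assert proportionality_factor(g2, axis) == pytest.approx(
                proportionality_factor(g1, axis), rel=1e-12
            )
            assert ic_lever_arm(g2, axis) == pytest.approx(
                ic_lever_arm(g1, axis), rel=1e-12
            )


class TestLeverArmAndJawShift:
    @pytest.mark.parametrize("jaw_axis, expected", [("Y", 1.74), ("X", 2.18)])
    def test_published_lever_arms(self, jaw_axis, expected, default_geometry):
        assert ic_lever_arm(default_geometry, jaw_axis) == pytest.approx(expected, abs=0.005)

    def test_chamber_above_jaw_rejected(self):
        with pytest.raises(ValueError):
            LinacGeometry(d_ic=300.0)

    @pytest.mark.parametrize(
        "shift, d_jaw, expected", [(1.0, 406.0, 0.406), (1.0, 319.0, 0.319), (0.0, 406.0, 0.0)]
    )
    def test_jaw_plane_shift(self, shift, d_jaw, expected):
        assert jaw_plane_shift(shift, d_jaw, 1000.0) == pytest.approx(expected, abs=1e-12)


class TestProjectCenter:
    def test_zero_offset_projects_to_zero(self):
        assert project_center(0.0, 490.0, 1000.0) == 0.0

    def test_against_raytrace_oracle(self):
        """Analytic centre equals the brute-force two-edge ray trace."""
        for s, d_col in [(0.1, 490.0), (-0.35, 406.0), (0.5, 319.0)]:
            assert project_center(s, d_col, 1000.0) == pytest.approx(
                raytrace_center(s, d_col, 1000.0), abs=1e-9
            )

    def test_known_value(self):
        # -0.1 * (1000 - 490) / 490, frozen from the ray-trace oracle
        assert project_center(0.1, 490.0, 1000.0) == pytest.approx(-0.104082, abs=1e-6)

    def test_collimator_plane_bounds(self):
        with pytest.raises(ValueError):
            project_center(0.1, 1200.0, 1000.0)


class TestRoundTripIdentity:
    @given(
        s=st.floats(-0.5, 0.5),
        d_epi=st.floats(900.0, 1600.0),
        d_jaw=st.floats(250.0, 450.0),
        d_mlc=st.floats(460.0, 600.0),
    )
    def test_forward_then_inverse_recovers_offset(self, s, d_epi, d_jaw, d_mlc):
        """project -> separate -> multiply by *a* is the identity in s."""
        geom = LinacGeometry(d_epi=d_epi, d_jaw_x=d_jaw, d_mlc=d_mlc)
        a = proportionality_factor(geom, "X")
        sep = project_center(s, d_mlc, d_epi) - project_center(s, d_jaw, d_epi)
        assert offset_from_separation(sep, a) == pytest.approx(s, abs=1e-9)

    def test_offset_from_separation_values(self):
        assert offset_from_separation(CentroidSeparation("u", 0.0), 2.368) == 0.0
        assert offset_from_separation(CentroidSeparation("u", 0.1), 2.368) == pytest.approx(
            0.2368
        )


class TestSidInsensitivity:
    def test_one_mm_sid_error_shifts_result_below_two_microns(self):
        """A 1 mm SID calibration error changes a 0.5 mm offset by < 0.002 mm."""
        s = 0.5
        true_geom = LinacGeometry(d_epi=1000.0)
        sep = project_center(s, true_geom.d_mlc, 1000.0) - project_center(
            s, true_geom.d_jaw_x, 1000.0
        )
        for sid_believed in (999.0, 1001.0):
            a_wrong = proportionality_factor(true_geom.with_sid(sid_believed), "X")
            assert abs(a_wrong * sep - s) < 0.002


class TestGeometryConfig:
    def test_load_mm_and_cm_units(self, tmp_path):
        mm = tmp_path / "g_mm.yaml"
        mm.write_text(
            "units: mm\nd_epi: 1050\nd_jaw_x: 406\nd_jaw_y: 319\nd_mlc: 490\nd_ic: 750\n"
        )
        cm = tmp_path / "g_cm.yaml"
        cm.write_text(
            "units: cm\nd_epi: 105\nd_jaw_x: 40.6\nd_jaw_y: 31.9\nd_mlc: 49\nd_ic: 75\n"
        )
        g1, g2 = load_geometry(mm), load_geometry(cm)
        assert g1 == g2
        assert g1.d_epi == 1050.0

    def test_unknown_key_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("units: mm\nd_epi: 1000\nd_weird: 3\n")
        with pytest.raises(ValueError, match="unknown"):
            load_geometry(bad)
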