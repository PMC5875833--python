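"""Field-centre extraction and the four-image measurement pipeline."""

import numpy as np
import pytest

from focalspot import (
    AnalysisParams,
    EpidImage,
    FieldCenter,
    OffsetVector,
    centroid_separation,
    find_field_center,
    measure_focal_spot,
    pair_centroid,
    preprocess,
    proportionality_factor,
    render_image,
)
from focalspot.errors import DegenerateImageError, FieldClippedError, NoFieldError
from focalspot.simulate import analytic_center

from conftest import fast_config, run_pipeline


def flat_field(shape=(64, 80), pitch=0.784, lo=(20, 24), hi=(44, 56)):
    """Binary rectangle image: rows [lo[0], hi[0]), cols [lo[1], hi[1])."""
    px = np.zeros(shape)
    px[lo[0] : hi[0], lo[1] : hi[1]] = 60000.0
    return EpidImage(px, pitch, 1000.0, 90, "JAW")


class TestPreprocess:
    @pytest.mark.parametrize("pitch, factor", [(0.784, 20), (0.392, 10)])
    def test_upsample_reaches_common_effective_pitch(self, pitch, factor):
        img = flat_field(pitch=pitch)
        up, eff = preprocess(img)
        assert up.shape == (img.shape[0] * factor, img.shape[1] * factor)
        assert eff == pytest.approx(0.0392, abs=1e-12)
        assert up.min() >= 0.0 and up.max() <= 1.0

    def test_constant_image_is_degenerate(self):
        img = EpidImage(np.full((32, 32), 500.0), 0.392, 1000.0, 90, "JAW")
        with pytest.raises(DegenerateImageError):
            preprocess(img)


class TestFindFieldCenter:
    def test_centered_binary_rectangle_is_exact_zero(self):
        P = np.zeros((512, 512))
        P[106:406, 156:356] = 1.0
        c = find_field_center(P, 0.0392)
        assert c.u == pytest.approx(0.0, abs=1e-12)
        assert c.v == pytest.approx(0.0, abs=1e-12)

    def test_offset_binary_rectangle_matches_enumeration(self):
        """Mean of extreme above-threshold positions, pixel-centred origin."""
        P = np.zeros((512, 512))
        P[150:350, 100:355] = 1.0
        c = find_field_center(P, 0.0392)
        assert c.u == pytest.approx(((100 + 354) / 2 + 0.5 - 256) * 0.0392, abs=1e-9)
        assert c.v == pytest.approx(((150 + 349) / 2 + 0.5 - 256) * 0.0392, abs=1e-9)

    def test_translation_equivariance(self):
        """Shifting the field by k upsampled pixels moves the centre k pitches."""
        P = np.zeros((400, 400))
        P[100:300, 80:260] = 1.0
        base = find_field_center(P, 0.0392)
        k = 17
        shifted = find_field_center(np.roll(P, k, axis=1), 0.0392)
        assert shifted.u - base.u == pytest.approx(k * 0.0392, abs=1e-9)
        assert shifted.v == pytest.approx(base.v, abs=1e-9)

    def test_penumbra_field_recovered_within_hundredth_mm(self):
        """Erf-penumbra simulation: centre recovered to < 0.01 mm."""
        cfg = fast_config(true_offset=OffsetVector(0.25, 0.1))
        img = render_image(cfg, "JAW", 90)
        up, eff = preprocess(img)
        c = find_field_center(up, eff)
        u_true, v_true = analytic_center(cfg, "JAW", 90)
        assert c.u == pytest.approx(u_true, abs=0.01)
        assert c.v == pytest.approx(v_true, abs=0.01)

    def test_no_field_when_region_too_small(self):
        P = np.zeros((400, 400))
        P[200:202, 200:202] = 1.0  # far below the 1% size floor
        with pytest.raises(NoFieldError):
            find_field_center(P, 0.0392)

    def test_clipped_field_rejected(self):
        P = np.zeros((400, 400))
        P[0:220, 100:300] = 1.0  # touches the top border
        with pytest.raises(FieldClippedError):
            find_field_center(P, 0.0392)


class TestCentroidAlgebra:
    def test_pair_centroid_cancels_and_averages(self):
        a = pair_centroid(FieldCenter(0.1, 0.0), FieldCenter(-0.1, 0.0))
        assert (a.u, a.v) == (0.0, 0.0)
        b = pair_centroid(FieldCenter(0.08, -0.02), FieldCenter(0.06, -0.04))
        assert b.u == pytest.approx(0.07)
        assert b.v == pytest.approx(-0.03)

    def test_centroid_separation_is_mlc_minus_jaw(self):
        seps = centroid_separation(FieldCenter(0.0, 0.2), FieldCenter(0.10, 0.2))
        assert seps["u"].value == pytest.approx(0.10)
        assert seps["v"].value == pytest.approx(0.0)

    def test_simulated_separation_matches_projection_inverse(self):
        """For a pure inplane offset s, the v separation equals s / a_X."""
        s = 0.2
        cfg = fast_config(true_offset=OffsetVector(0.0, s))
        res = run_pipeline(cfg)
        a_x = proportionality_factor(cfg.geometry, "X")
        assert abs(res.separations["v"].value) == pytest.approx(s / a_x, abs=0.01)


class TestMeasureFocalSpot:
    def test_zero_offset_yields_null_result(self):
        res = run_pipeline(fast_config())
        assert res.offset.crossplane == pytest.approx(0.0, abs=0.002)
        assert res.offset.inplane == pytest.approx(0.0, abs=0.002)

    def test_known_offset_recovered_under_noise(self):
        """Half-percent noise: a (-0.029, -0.433) mm truth returns within 0.01 mm."""
        cfg = fast_config(true_offset=OffsetVector(-0.029, -0.433), noise=0.005, seed=11)
        res = run_pipeline(cfg)
        assert res.offset.crossplane == pytest.approx(-0.029, abs=0.01)
        assert res.offset.inplane == pytest.approx(-0.433, abs=0.01)

    def test_bank_miscalibration_cancels(self):
        """A 1 mm single-bank error moves the result by < 0.01 mm."""
        clean = run_pipeline(fast_config(true_offset=OffsetVector(0.2, 0.2)))
        skewed = run_pipeline(
            fast_config(true_offset=OffsetVector(0.2, 0.2), miscal_x1=1.0, miscal_mlc_b=-1.0)
        )
        assert skewed.offset.crossplane == pytest.approx(clean.offset.crossplane, abs=0.01)
        assert skewed.offset.inplane == pytest.approx(clean.offset.inplane, abs=0.01)

    def test_threshold_robustness(self):
        """Thresholds 0.45 / 0.55 move the offset by < 0.01 mm (symmetric penumbra)."""
        cfg = fast_config(true_offset=OffsetVector(0.3, -0.2))
        mset = run_pipeline(cfg).model.measurement_set
        results = {
            thr: measure_focal_spot(mset, cfg.geometry, AnalysisParams(threshold=thr))
            for thr in (0.45, 0.5, 0.55)
        }
        for thr in (0.45, 0.55):
            assert results[thr].offset.crossplane == pytest.approx(
                results[0.5].offset.crossplane, abs=0.01
            )
            assert results[thr].offset.inplane == pytest.approx(
                results[0.5].offset.inplane, abs=0.01
            )

    def test_detector_position_independence(self):
        """A common lateral detector shift leaves the offset unchanged."""
        cfg = fast_config(true_offset=OffsetVector(0.15, -0.1))
        base = run_pipeline(cfg)
        mset = base.model.measurement_set
        shifted = type(mset)(
            **{
                slot: EpidImage(
                    np.roll(np.roll(img.pixels, 3, axis=1), -2, axis=0),
                    img.pixel_pitch,
                    img.sid,
                    img.collimator_angle,
                    img.defining_system,
                )
                for slot, img in mset.images().items()
            }
        )
        res = measure_focal_spot(shifted, cfg.geometry)
        assert res.offset.crossplane == pytest.approx(base.offset.crossplane, abs=1e-3)
        assert res.offset.inplane == pytest.approx(base.offset.inplane, abs=1e-3)

    def test_summary_and_report_dict(self):
        res = run_pipeline(fast_config())
        text = res.summary()
        assert "crossplane offset" in text and "factor a" in text
        body = res.to_dict()
        assert set(body["separation_mm"]) == {"u", "v"}
        assert body["factors"]["v"] == pytest.approx(2.368, abs=5e-4)
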