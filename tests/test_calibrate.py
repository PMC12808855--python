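"""Calibration fitting: ROI sampling, the cortical window rule, phantom and
internal fits, drift cancellation, and the QC table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qctstiff import (CTImage, ScannerModel, TissueSample, apply_calibration,
                      cortical_reference, default_reference_table,
                      fit_internal, fit_phantom, generate_specimen,
                      sample_roi, validate_samples)
from qctstiff.calibrate import COMBINATIONS, ReferenceTable, _fit_line
from qctstiff.errors import (ConfigError, CorticalReferenceError,
                             DegenerateFitError, ROIError)
from qctstiff.pipeline import RunConfig, calibrate_specimen
from qctstiff.synthdata import TRABECULAR


def _img(values):
    """Tiny CTImage whose voxel values are exactly `values` repeated to fill
    a valid (>=2 per axis) grid."""
    a = np.asarray(values, float)
    while a.ndim < 3:
        a = a[..., None]
    reps = [2 if s < 2 else 1 for s in a.shape]
    return CTImage(np.tile(a, reps))


class TestSampleRoi:
    def test_uniform_region(self):
        img = CTImage(np.full((4, 4, 4), -1000.0))
        s = sample_roi(img, np.ones((4, 4, 4), bool), "air")
        assert s.mean_hu == -1000.0 and s.sd_hu == 0.0 and s.voxel_count == 64

    def test_two_voxel_sample_sd(self):
        img = CTImage(np.zeros((2, 2, 2)))
        img.voxels[0, 0, 0], img.voxels[1, 0, 0] = 0.0, 20.0
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = mask[1, 0, 0] = True
        s = sample_roi(img, mask, "muscle")
        assert s.mean_hu == pytest.approx(10.0)
        assert s.sd_hu == pytest.approx(14.142135623730951)  # n-1 denominator

    def test_incongruent_mask_rejected(self):
        img = CTImage(np.zeros((4, 4, 4)))
        with pytest.raises(ROIError):
            sample_roi(img, np.ones((5, 5, 5), bool), "air")

    def test_empty_mask_rejected(self):
        img = CTImage(np.zeros((4, 4, 4)))
        with pytest.raises(ROIError):
            sample_roi(img, np.zeros((4, 4, 4), bool), "air")


class TestCorticalReference:
    def _bone_img(self, values):
        img = _img(np.array(values))
        mask = np.ones(img.shape, bool)
        return img, mask

    def test_windowed_max(self):
        img, mask = self._bone_img([900.0, 1100.0, 1300.0, 1600.0])
        s = cortical_reference(img, mask)
        assert s.mean_hu == 1300.0 and s.tissue == "cortical"

    def test_uniform_cortex(self):
        img, mask = self._bone_img([1200.0, 1200.0])
        assert cortical_reference(img, mask).mean_hu == 1200.0

    def test_all_below_window_raises(self):
        img, mask = self._bone_img([800.0, 950.0])
        with pytest.raises(CorticalReferenceError):
            cortical_reference(img, mask)

    def test_mean_mode(self):
        img, mask = self._bone_img([1000.0, 1400.0, 1600.0])
        s = cortical_reference(img, mask, mode="mean")
        assert s.mean_hu == pytest.approx(1200.0)


def _rods(hu):
    return [TissueSample(f"rod_{i}", h, 0.0, 100) for i, h in enumerate(hu)]


class TestFitPhantom:
    def test_two_point_line_through_origin(self):
        m = fit_phantom(_rods([0.0, 1000.0]), [0.0, 750.0])
        assert m.slope == pytest.approx(0.75) and m.intercept == pytest.approx(0.0)

    def test_two_point_line_with_offset(self):
        m = fit_phantom(_rods([100.0, 1100.0]), [0.0, 750.0])
        assert m.slope == pytest.approx(0.75)
        assert m.intercept == pytest.approx(-75.0)

    def test_collinear_rods_r2_one(self):
        hu = [0.0, 250.0, 500.0, 750.0, 1000.0]
        m = fit_phantom(_rods(hu), [0.75 * h for h in hu])
        assert m.r_squared == pytest.approx(1.0)

    def test_identical_hu_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_phantom(_rods([500.0, 500.0]), [0.0, 750.0])

    def test_water_correction_shifts_density_axis(self):
        # rods with water-equivalent density 1050 -> densities reduced by 50
        ref = [(0.0, 1050.0), (750.0, 1050.0)]
        m = fit_phantom(_rods([0.0, 1000.0]), ref, water_correction=True)
        assert m.predict(0.0) == pytest.approx(-50.0)
        assert m.predict(1000.0) == pytest.approx(700.0)

    def test_round_trip_recovers_rod_densities(self):
        hu = [10.0, 400.0, 900.0]
        dens = [5.0, 300.0, 680.0]
        # make collinear points for exactness
        dens = [0.75 * h - 2.5 for h in hu]
        m = fit_phantom(_rods(hu), dens)
        np.testing.assert_allclose(m.predict(hu), dens, rtol=1e-12)


class TestFitInternal:
    table = default_reference_table()

    def _samples(self, combo, hu_map):
        return [TissueSample(t, hu_map[t], 0.0, 10) for t in COMBINATIONS[combo]]

    def test_two_tissue_exact_line(self):
        # degenerate two-point fit: line passes exactly through both tissues
        m = _fit_line(np.array([-1000.0, 1200.0]), np.array([-750.0, 900.0]),
                      "AC", [])
        assert m.predict(-1000.0) == pytest.approx(-750.0)
        assert m.predict(1200.0) == pytest.approx(900.0)
        assert m.r_squared == 1.0

    def test_table_without_needed_tissue_rejected(self):
        table = ReferenceTable({"air": (-1000.0, -750.0),
                                "cortical": (1200.0, 900.0)})
        samples = [TissueSample(t, h, 0.0, 10) for t, h in
                   [("air", -1000.0), ("adipose", -60.0), ("cortical", 1200.0)]]
        with pytest.raises(ConfigError):
            fit_internal(samples, table, "AAdC")

    def test_missing_tissue_rejected(self):
        samples = [TissueSample("air", -1000.0, 0.0, 10)]
        with pytest.raises(ConfigError):
            fit_internal(samples, self.table, "ACM")

    def test_collinear_acm_matches_two_point_line(self):
        hu = {"air": -1000.0, "cortical": 1200.0, "muscle": 40.0}
        m = fit_internal(self._samples("ACM", hu), self.table, "ACM")
        assert m.r_squared == pytest.approx(1.0)
        assert m.slope == pytest.approx(0.75)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)

    def test_same_points_give_identical_model_to_phantom_fit(self):
        hu = {"air": -1000.0, "cortical": 1200.0, "muscle": 40.0}
        mi = fit_internal(self._samples("ACM", hu), self.table, "ACM")
        order = COMBINATIONS["ACM"]
        mp = fit_phantom(_rods([hu[t] for t in order]),
                         [self.table.reference_density(t) for t in order])
        assert mi.slope == pytest.approx(mp.slope, rel=1e-12)
        assert mi.intercept == pytest.approx(mp.intercept, rel=1e-12, abs=1e-12)

    def test_noiseless_specimen_round_trip(self, small_spec, noiseless_specimen):
        """All calibration routes recover the ground-truth law to 1e-9."""
        img, truth = noiseless_specimen
        cfg = RunConfig(n_specimens=1, spec=small_spec, cortical_mode="max",
                        with_fem=False)
        models, _ = calibrate_specimen(img, truth.tissue_labels, cfg,
                                       small_spec.phantom_rod_densities)
        assert set(models) == {"PHANTOM", "AAdC", "AAdCM", "ACM"}
        for m in models.values():
            assert m.slope == pytest.approx(small_spec.density_hu_slope, rel=1e-9)
            assert m.intercept == pytest.approx(small_spec.density_hu_intercept,
                                                abs=1e-6)


class TestApplyCalibration:
    def test_identity_model(self):
        img = _img([[1.0, 2.0], [3.0, 4.0]])
        m = _fit_line(np.array([0.0, 1.0]), np.array([0.0, 1.0]), "PHANTOM", [])
        d = apply_calibration(img, m)
        np.testing.assert_allclose(d.voxels, img.voxels)
        assert d.calibration == "PHANTOM"

    def test_rod_maps_to_reference_density(self):
        m = fit_phantom(_rods([0.0, 1000.0]), [0.0, 750.0])
        assert m.predict(1000.0) == pytest.approx(750.0)

    def test_monotone_in_hu(self):
        m = fit_phantom(_rods([0.0, 1000.0]), [0.0, 750.0])
        hu = np.linspace(-1000, 1500, 100)
        assert np.all(np.diff(m.predict(hu)) > 0)


@settings(deadline=None, max_examples=20)
@given(gain=st.floats(0.5, 2.0), offset=st.floats(-100.0, 100.0))
def test_affine_drift_cancellation(gain, offset):
    """Refit on a gain/offset-drifted scan maps voxels to identical densities."""
    hu = np.array([-1000.0, -60.0, 40.0, 1200.0])
    dens = 0.75 * hu
    img = _img(np.linspace(-500, 1400, 8))
    m0 = _fit_line(hu, dens, "ACM", [])
    m1 = _fit_line(gain * hu + offset, dens, "ACM", [])
    drifted = CTImage(gain * img.voxels + offset, img.spacing, img.origin)
    d0 = apply_calibration(img, m0).voxels
    d1 = apply_calibration(drifted, m1).voxels
    np.testing.assert_allclose(d1, d0, rtol=1e-9, atol=1e-6)


def test_validate_samples_flags_out_of_range():
    table = default_reference_table()
    samples = [TissueSample("air", -997.75, 1.6, 50),
               TissueSample("muscle", 10.98, 30.0, 50)]
    rep = validate_samples(samples, table, tolerance_hu=10.0)
    by = {r["tissue"]: r for r in rep}
    assert by["air"]["ok"] is True          # within 10 HU of -1000
    assert by["muscle"]["ok"] is False      # 29 HU below the expected 40

    exact = validate_samples([TissueSample("air", -1000.0, 0.0, 5)], table,
                             tolerance_hu=0.0)
    assert exact[0]["ok"] is True
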