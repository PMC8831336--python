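"""BMD contracts: trabecular extraction, calibration arithmetic, lumbar
averaging with fracture/missing exclusions, correction fitting and the
noiseless phantom round trip."""

import numpy as np
import pytest

from phasebmd.anatomy import LUMBAR_BMD_LEVELS
from phasebmd.bmd import (
    CalibrationModel,
    apply_correction,
    bmd_to_hu,
    extract_bmd,
    fit_correction,
    hu_to_bmd,
    lumbar_mean,
    trabecular_mean_hu,
)
from phasebmd.errors import (
    CorrectionError,
    CoverageError,
    ExtractionError,
    FitError,
    ValidationError,
)
from phasebmd.io_ct import CtVolume, LabelMask


def tiny_vol_mask(values=(100.0,)):
    """A little volume whose L1 trabecular compartment holds `values`."""
    vox = np.zeros((4, 4, 4), dtype=np.float32)
    mask = np.zeros((4, 4, 4), dtype=np.int32)
    flat = list(np.ndindex(4, 4, 4))
    for idx, v in zip(flat, values):
        vox[idx] = v
        mask[idx] = 120  # L1 trabecular code
    return CtVolume(vox, np.eye(4)), LabelMask(mask, np.eye(4))


class TestExtraction:
    def test_constant_region_mean(self):
        vol, mask = tiny_vol_mask([100.0] * 10)
        assert trabecular_mean_hu(vol, mask, "L1") == 100.0

    def test_single_voxel_region(self):
        vol, mask = tiny_vol_mask([42.0])
        assert trabecular_mean_hu(vol, mask, "L1") == 42.0

    def test_empty_region_rejected(self):
        vol, mask = tiny_vol_mask([100.0])
        with pytest.raises(ExtractionError):
            trabecular_mean_hu(vol, mask, "L2")

    def test_shape_mismatch_rejected(self):
        vol, _ = tiny_vol_mask([100.0])
        bad = LabelMask(np.zeros((5, 5, 5), dtype=np.int32), np.eye(4))
        with pytest.raises(ValidationError):
            trabecular_mean_hu(vol, bad, "L1")

    def test_noiseless_phantom_extraction_matches_generator(self, noiseless_cases, noiseless_spec):
        case = noiseless_cases[0]
        calib = CalibrationModel(noiseless_spec.calib_slope, noiseless_spec.calib_intercept)
        got = extract_bmd(case.volumes["NE"], case.mask, calib)
        for lv in LUMBAR_BMD_LEVELS:
            assert got[lv] == pytest.approx(case.truth.bmd[lv], abs=1e-9)


class TestCalibration:
    def test_identity_calibration(self):
        assert hu_to_bmd(120.0, CalibrationModel(1.0, 0.0)) == 120.0

    def test_affine_calibration_arithmetic(self):
        assert hu_to_bmd(150.0, CalibrationModel(0.8, 2.0)) == pytest.approx(122.0)

    def test_inverse_after_forward_is_identity(self):
        calib = CalibrationModel(0.73, -4.2)
        assert bmd_to_hu(hu_to_bmd(157.3, calib), calib) == pytest.approx(157.3, abs=1e-9)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValidationError):
            CalibrationModel(0.0, 1.0)


class TestLumbarMean:
    def test_plain_mean_over_l1_l3(self):
        mean, excl = lumbar_mean({"L1": 100.0, "L2": 110.0, "L3": 120.0},
                                 {"L1": 0, "L2": 0, "L3": 0})
        assert mean == 110.0 and excl == []

    def test_grade_two_fracture_excluded(self):
        mean, excl = lumbar_mean({"L1": 100.0, "L2": 300.0, "L3": 120.0},
                                 {"L1": 0, "L2": 2, "L3": 0})
        assert mean == 110.0
        assert excl == [("L2", "fracture")]

    def test_grade_one_kept_under_default_threshold(self):
        mean, _ = lumbar_mean({"L1": 100.0, "L2": 110.0, "L3": 120.0},
                              {"L1": 1, "L2": 0, "L3": 0})
        assert mean == 110.0

    def test_stricter_threshold_excludes_grade_one(self):
        mean, excl = lumbar_mean({"L1": 100.0, "L2": 110.0, "L3": 120.0},
                                 {"L1": 1, "L2": 0, "L3": 0}, exclude_grade_above=0)
        assert mean == 115.0 and excl == [("L1", "fracture")]

    def test_missing_level_itemized(self):
        mean, excl = lumbar_mean({"L2": 110.0, "L3": 120.0}, {"L2": 0, "L3": 0})
        assert mean == 115.0 and excl == [("L1", "missing")]

    def test_unknown_grade_is_included(self):
        mean, _ = lumbar_mean({"L1": 100.0, "L2": 110.0, "L3": 120.0},
                              {"L1": None, "L2": 0, "L3": 0})
        assert mean == 110.0

    def test_everything_excluded_raises(self):
        with pytest.raises(CoverageError):
            lumbar_mean({"L1": 100.0}, {"L1": 3})

    def test_result_invariant_to_dict_order(self):
        a = lumbar_mean({"L3": 120.0, "L1": 100.0, "L2": 110.0}, {"L1": 0, "L2": 0, "L3": 0})
        b = lumbar_mean({"L1": 100.0, "L2": 110.0, "L3": 120.0}, {"L3": 0, "L2": 0, "L1": 0})
        assert a == b


class TestCorrection:
    def test_exact_line_recovered(self, rng):
        pv = rng.uniform(80, 220, size=12)
        ne = 0.9 * pv - 5.0
        model = fit_correction(list(zip(pv, ne)), "PV")
        assert model.slope == pytest.approx(0.9, abs=1e-9)
        assert model.intercept == pytest.approx(-5.0, abs=1e-9)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-7)
        assert model.n_pairs == 12

    def test_two_pairs_rejected(self):
        with pytest.raises(FitError):
            fit_correction([(100.0, 90.0), (120.0, 105.0)], "PV")

    def test_degenerate_enhanced_values_rejected(self):
        with pytest.raises(FitError):
            fit_correction([(100.0, 90.0), (100.0, 95.0), (100.0, 92.0)], "AR")

    def test_fixed_slope_constant_offset_variant(self):
        pairs = [(110.0, 100.0), (130.0, 120.0), (150.0, 140.0)]
        model = fit_correction(pairs, "PV", fixed_slope=1.0)
        assert model.slope == 1.0
        assert model.intercept == pytest.approx(-10.0)

    def test_ne_needs_no_model(self):
        assert apply_correction(137.5, "NE", {}) == 137.5

    def test_pv_printed_example(self):
        from phasebmd.bmd import CorrectionModel

        models = {"PV": CorrectionModel("PV", 1.0, -17.5, 10, 0.5)}
        assert apply_correction(150.0, "PV", models) == pytest.approx(132.5)

    def test_missing_model_for_enhanced_phase_rejected(self):
        with pytest.raises(CorrectionError):
            apply_correction(150.0, "PV", {})

    def test_strictly_increasing_when_slope_positive(self, rng):
        from phasebmd.bmd import CorrectionModel

        models = {"AR": CorrectionModel("AR", 0.97, -5.5, 9, 1.0)}
        xs = np.sort(rng.uniform(60, 240, size=20))
        ys = [apply_correction(x, "AR", models) for x in xs]
        assert np.all(np.diff(ys) > 0)


class TestNoiselessRoundTrip:
    """Extract -> calibrate -> correct reproduces ground truth on noiseless phantoms."""

    def test_corrected_enhanced_bmd_equals_truth(self, noiseless_cases, noiseless_spec):
        calib = CalibrationModel(noiseless_spec.calib_slope, noiseless_spec.calib_intercept)
        lumbar = {}
        for case in noiseless_cases:
            grades = {a.level: a.fracture_grade for a in case.annotations}
            for ph in ("NE", "AR", "PV"):
                per_v = extract_bmd(case.volumes[ph], case.mask, calib)
                lumbar[(case.patient_id, ph)], _ = lumbar_mean(per_v, grades)
        models = {
            ph: fit_correction(
                [(lumbar[(c.patient_id, ph)], lumbar[(c.patient_id, "NE")])
                 for c in noiseless_cases],
                ph,
            )
            for ph in ("AR", "PV")
        }
        assert models["PV"].slope == pytest.approx(1.0, abs=1e-6)
        assert models["PV"].intercept == pytest.approx(-17.5, abs=1e-6)
        assert models["AR"].intercept == pytest.approx(-5.68, abs=1e-6)
        for case in noiseless_cases:
            truth_mean = np.mean([case.truth.bmd[lv] for lv in LUMBAR_BMD_LEVELS])
            for ph in ("AR", "PV"):
                corrected = apply_correction(lumbar[(case.patient_id, ph)], ph, models)
                assert corrected == pytest.approx(truth_mean, abs=1e-6)
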