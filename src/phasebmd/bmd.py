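"""Trabecular BMD extraction, lumbar averaging, and phase-specific correction.

BMD (mg/ml calcium-hydroxyapatite equivalent) is the mean HU over the
trabecular compartment of a vertebral body pushed through a scanner-specific
linear calibration ``bmd = slope * HU + intercept`` obtained from density
reference phantoms. Scan-level BMD is the unweighted mean over the included
lumbar vertebrae L1-L3, excluding vertebrae with a fracture grade above the
configured threshold (default: grade > 1) and vertebrae missing from the
segmentation.

Contrast enhancement inflates trabecular HU, so BMD from AR/PV scans is
biased upward. The correction is a per-phase ordinary-least-squares line
predicting the NE-equivalent BMD from the enhanced BMD, fitted on training
patients for whom both scans exist; at inference the detected phase selects
which line to apply (NE maps to identity). A constant-offset variant (slope
fixed at 1) is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .anatomy import LUMBAR_BMD_LEVELS, check_phase
from .errors import CorrectionError, CoverageError, ExtractionError, FitError, ValidationError
from .io_ct import CtVolume, LabelMask


@dataclass(frozen=True)
class CalibrationModel:
    """Scanner-specific linear HU -> BMD map."""

    slope: float  # mg/ml per HU
    intercept: float = 0.0  # mg/ml
    scanner_id: str = "default"

    def __post_init__(self) -> None:
        if self.slope == 0 or not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValidationError("calibration slope must be finite and non-zero")


@dataclass(frozen=True)
class CorrectionModel:
    """Per-phase linear map from contrast-enhanced BMD to NE-equivalent BMD."""

    phase: str
    slope: float  # dimensionless
    intercept: float  # mg/ml
    n_pairs: int
    residual_sd: float  # mg/ml

    def __post_init__(self) -> None:
        check_phase(self.phase)
        if self.phase == "NE":
            raise ValidationError("NE needs no correction model (identity)")


@dataclass
class BmdResult:
    """Per-scan BMD outcome: per-vertebra values, exclusions, lumbar mean."""

    scan_id: str
    per_vertebra: dict[str, float]
    excluded: list[tuple[str, str]]  # (level, reason in {"fracture", "missing"})
    lumbar_mean_bmd: float
    phase_used: str
    corrected_bmd: float = np.nan


def trabecular_mean_hu(vol: CtVolume, mask: LabelMask, vertebra: str) -> float:
    """Mean HU over the trabecular compartment of one vertebra."""
    if vol.voxels.shape != mask.voxels.shape:
        raise ValidationError(
            f"mask shape {mask.voxels.shape} does not match volume {vol.voxels.shape}"
        )
    region = mask.region(vertebra, trabecular=True)
    if not region.any():
        raise ExtractionError(f"trabecular compartment of {vertebra} is empty in the mask")
    return float(vol.voxels[region].mean())


def hu_to_bmd(mean_hu: float, calib: CalibrationModel) -> float:
    """Apply the scanner calibration: bmd = slope * HU + intercept."""
    return calib.slope * float(mean_hu) + calib.intercept


def bmd_to_hu(bmd: float, calib: CalibrationModel) -> float:
    return (float(bmd) - calib.intercept) / calib.slope


def extract_bmd(
    vol: CtVolume,
    mask: LabelMask,
    calib: CalibrationModel,
    levels=LUMBAR_BMD_LEVELS,
) -> dict[str, float]:
    """Per-vertebra BMD for every requested level present in the mask."""
    out: dict[str, float] = {}
    for lv in levels:
        try:
            out[lv] = hu_to_bmd(trabecular_mean_hu(vol, mask, lv), calib)
        except ExtractionError:
            continue
    return out


def lumbar_mean(
    per_vertebra_bmd: dict[str, float],
    grades: dict[str, int | None],
    include_levels=LUMBAR_BMD_LEVELS,
    exclude_grade_above: int = 1,
) -> tuple[float, list[tuple[str, str]]]:
    """Unweighted mean BMD over included lumbar vertebrae, with exclusions.

    A level is excluded as "missing" when absent from ``per_vertebra_bmd``
    and as "fracture" when its grade exceeds ``exclude_grade_above``
    (ungraded vertebrae are included). Raises when nothing remains.
    """
    included, exclusions = [], []
    for lv in include_levels:
        if lv not in per_vertebra_bmd or not np.isfinite(per_vertebra_bmd[lv]):
            exclusions.append((lv, "missing"))
            continue
        grade = grades.get(lv)
        if grade is not None and grade > exclude_grade_above:
            exclusions.append((lv, "fracture"))
            continue
        included.append(per_vertebra_bmd[lv])
    if not included:
        raise CoverageError(
            f"no includable vertebra among {tuple(include_levels)}: {exclusions}"
        )
    return float(np.mean(included)), exclusions


def fit_correction(pairs, phase: str, fixed_slope: float | None = None) -> CorrectionModel:
    """Fit the NE-equivalent-from-enhanced OLS line for one contrast phase.

    ``pairs`` is a sequence of (enhanced_bmd, ne_bmd). With ``fixed_slope``
    the slope is pinned (1.0 gives a constant-offset correction) and only
    the intercept is estimated.
    """
    check_phase(phase)
    if phase == "NE":
        raise FitError("the nonenhanced phase needs no correction")
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise FitError(f"need >= 3 (enhanced, ne) pairs, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise FitError("pairs contain non-finite values")
    enhanced, ne = arr[:, 0], arr[:, 1]
    if fixed_slope is not None:
        slope = float(fixed_slope)
        intercept = float(np.mean(ne - slope * enhanced))
    else:
        if np.ptp(enhanced) == 0:
            raise FitError("degenerate fit: all enhanced BMD values are equal")
        res = stats.linregress(enhanced, ne)
        slope, intercept = float(res.slope), float(res.intercept)
    residuals = ne - (slope * enhanced + intercept)
    dof = max(len(residuals) - 2, 1)
    residual_sd = float(np.sqrt((residuals**2).sum() / dof))
    return CorrectionModel(phase=phase, slope=slope, intercept=intercept,
                           n_pairs=len(residuals), residual_sd=residual_sd)


def apply_correction(bmd: float, phase: str, models: dict[str, CorrectionModel]) -> float:
    """Correct a BMD value for its contrast phase; NE is the identity."""
    check_phase(phase)
    if phase == "NE":
        return float(bmd)
    model = models.get(phase)
    if model is None:
        raise CorrectionError(f"no correction model available for phase {phase}")
    return model.slope * float(bmd) + model.intercept
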