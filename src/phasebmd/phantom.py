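"""Synthetic triphasic abdominal CT phantom cohorts.

Each synthetic patient is scanned three times (nonenhanced NE, arterial AR,
portal-venous PV) with identical anatomy and identical ground-truth
trabecular BMD; the contrast phase manifests purely as additive HU
enhancement per tissue compartment plus i.i.d. Gaussian voxel noise:

* aorta — strongly enhanced in AR (default +200 HU, motivated by bolus
  tracking that triggers the arterial scan once an aortic ROI exceeds
  120 HU), moderately enhanced in PV;
* liver / portal compartment — enhanced in PV only;
* trabecular bone — small AR offset and a larger PV offset, chosen by
  default so that the induced BMD bias through the HU-to-BMD calibration is
  +5.68 mg/ml (AR) and +17.5 mg/ml (PV), the biases reported for real
  triphasic abdominal MDCT.

The anatomy is deliberately parametric and simple (stacked elliptic-cylinder
vertebral bodies with a cortical shell, a tubular aorta, a liver ellipsoid,
soft-tissue background, air outside the body): the classifier only needs a
phase-discriminative signal and the BMD stages need exact ground truth, not
photorealism. Fractured vertebrae get a height-reduction deformation and a
Genant-style grade flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import PHASES, check_level, trabecular_label, vertebra_label
from .errors import GeometryError, ValidationError
from .io_ct import (
    CtVolume,
    LabelMask,
    VertebraAnnotation,
    write_annotations,
    write_mask,
    write_volume,
)

DEFAULT_LEVELS: tuple[str, ...] = ("T8", "T9", "T10", "T11", "T12", "L1", "L2", "L3", "L4")

#: Genant grade -> simulated vertebral height loss fraction (midpoints of
#: the 20-25%, 25-40%, >=40% grading bands).
HEIGHT_LOSS = {0: 0.0, 1: 0.225, 2: 0.325, 3: 0.45}

# Base tissue attenuation (HU) before contrast enhancement.
HU_AIR = -1000.0
HU_SOFT = 40.0
HU_LIVER = 60.0
HU_BLOOD = 45.0
HU_CORTICAL = 400.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic triphasic cohort.

    ``enh_trab_ar`` / ``enh_trab_pv`` are the additive trabecular HU offsets
    in the two enhanced phases; when left as None they default to the HU
    equivalents of BMD biases of +5.68 and +17.5 mg/ml through the
    calibration (offset = bias / calib_slope).
    """

    n_patients: int = 30
    vertebral_levels: tuple[str, ...] = DEFAULT_LEVELS
    bmd_mean: float = 130.0  # mg/ml, typical non-osteoporotic lumbar cohort
    bmd_sd: float = 35.0
    calib_slope: float = 0.8  # mg/ml per HU
    calib_intercept: float = 0.0  # mg/ml
    bias_trab_ar: float = 5.68  # mg/ml BMD bias induced by AR enhancement
    bias_trab_pv: float = 17.5  # mg/ml BMD bias induced by PV enhancement
    enh_trab_ar: float | None = None  # HU; None -> bias_trab_ar / calib_slope
    enh_trab_pv: float | None = None  # HU; None -> bias_trab_pv / calib_slope
    enh_aorta_ar: float = 200.0  # HU, well above the 120 HU trigger
    enh_aorta_pv: float = 90.0  # HU, residual aortic enhancement in PV
    enh_liver_pv: float = 60.0  # HU, portal-venous hepatic enhancement
    noise_sd: float = 20.0  # HU, i.i.d. Gaussian voxel noise
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    fov_size: tuple[int, int, int] | None = None  # voxels; None -> 96x96x(16*levels)
    fracture_rate: float = 0.1  # per-vertebra probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for lv in self.vertebral_levels:
            check_level(lv)
        if len(set(self.vertebral_levels)) != len(self.vertebral_levels):
            raise ValidationError("vertebral_levels contains duplicates")
        if self.bmd_mean - 3.0 * self.bmd_sd <= 0:
            raise ValidationError("bmd_mean - 3*bmd_sd must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.calib_slope == 0:
            raise ValidationError("calib_slope must be non-zero")
        for name in ("enh_aorta_ar", "enh_aorta_pv", "enh_liver_pv"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if not 0.0 <= self.fracture_rate <= 1.0:
            raise ValidationError("fracture_rate must be in [0, 1]")
        if any(s <= 0 for s in self.voxel_spacing):
            raise GeometryError("voxel_spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        if self.fov_size is not None:
            return tuple(int(v) for v in self.fov_size)  # type: ignore[return-value]
        return (96, 96, 16 * len(self.vertebral_levels))

    def trab_offset_hu(self, phase: str) -> float:
        """Additive trabecular HU offset of a contrast phase."""
        if phase == "NE":
            return 0.0
        if phase == "AR":
            v = self.enh_trab_ar
            return float(v) if v is not None else self.bias_trab_ar / self.calib_slope
        if phase == "PV":
            v = self.enh_trab_pv
            return float(v) if v is not None else self.bias_trab_pv / self.calib_slope
        raise ValidationError(f"unknown phase {phase!r}")


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic patient (shared by the three scans)."""

    patient_id: str
    bmd: dict[str, float]  # vertebra -> mg/ml
    fracture_grade: dict[str, int]
    trab_offset_hu: dict[str, float]  # phase -> realized HU offset


@dataclass
class PatientCase:
    """One generated patient: three phase volumes plus shared mask/annotations."""

    patient_id: str
    volumes: dict[str, CtVolume]
    mask: LabelMask
    annotations: list[VertebraAnnotation]
    truth: PhantomTruth


def _rng(spec: PhantomSpec, patient_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, patient_index, stream]))


def _ellipse(nx: int, ny: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


def generate_patient(spec: PhantomSpec, patient_index: int) -> PatientCase:
    """Generate the three phase scans, mask, annotations, and truth of one patient.

    Deterministic: the same (spec, patient_index) always yields byte-identical
    voxel arrays. Trabecular voxels of vertebra ``v`` have mean HU
    ``(bmd_v - calib_intercept)/calib_slope + trab_offset_hu(phase)`` plus
    zero-mean noise.
    """
    if not 0 <= patient_index < spec.n_patients:
        raise ValidationError(f"patient_index {patient_index} outside 0..{spec.n_patients - 1}")
    nx, ny, nz = spec.shape
    levels = spec.vertebral_levels
    band = nz // len(levels)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    rvx, rvy = 0.14 * nx, 0.11 * ny  # vertebral body outer radii (voxels)
    shell = 2.5
    if band < 6 or min(rvx, rvy) - shell < 2:
        raise GeometryError(
            f"field of view {spec.shape} too small for {len(levels)} vertebral levels"
        )

    rng_bmd = _rng(spec, patient_index, 0)
    rng_frac = _rng(spec, patient_index, 1)

    pid = f"p{patient_index:03d}"
    bmd = {
        lv: float(np.clip(rng_bmd.normal(spec.bmd_mean, spec.bmd_sd), 10.0, None))
        for lv in levels
    }
    grades: dict[str, int] = {}
    for lv in levels:
        if rng_frac.random() < spec.fracture_rate:
            grades[lv] = int(rng_frac.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
        else:
            grades[lv] = 0

    # --- shared anatomy ---------------------------------------------------
    body = _ellipse(nx, ny, cx, cy, 0.45 * nx, 0.42 * ny)
    cy_sp = 0.30 * ny  # spine sits posteriorly (low y in RAS)
    aorta2d = _ellipse(nx, ny, cx - 0.06 * nx, cy_sp + rvy + 0.08 * ny, 0.05 * nx, 0.05 * nx)

    base = np.full((nx, ny, nz), HU_AIR, dtype=np.float64)
    base[body] = HU_SOFT

    # liver ellipsoid in the upper right abdomen
    lz_c, lz_r = 0.78 * nz, 0.18 * nz
    liver2d = _ellipse(nx, ny, cx + 0.20 * nx, 0.55 * ny, 0.20 * nx, 0.25 * ny)
    z = np.arange(nz)
    liver_z = np.abs(z - lz_c) <= lz_r
    liver3d = liver2d[:, :, None] & liver_z[None, None, :] & body[:, :, None]
    base[liver3d] = HU_LIVER

    aorta3d = aorta2d[:, :, None] & np.ones(nz, dtype=bool)[None, None, :]
    base[aorta3d] = HU_BLOOD

    mask = np.zeros((nx, ny, nz), dtype=np.int32)
    outer2d = _ellipse(nx, ny, cx, cy_sp, rvx, rvy)
    inner2d = _ellipse(nx, ny, cx, cy_sp, rvx - shell, rvy - shell)
    trab_regions: dict[str, np.ndarray] = {}
    annotations: list[VertebraAnnotation] = []
    for i, lv in enumerate(levels):
        # cranial (superior, high z) levels first
        z_hi = nz - i * band
        z_lo = z_hi - band
        vh = max(3, int(round(0.75 * band * (1.0 - HEIGHT_LOSS[grades[lv]]))))
        zc = (z_lo + z_hi - 1) / 2.0
        z0, z1 = int(round(zc - vh / 2.0)), int(round(zc - vh / 2.0)) + vh
        z0, z1 = max(z0, 0), min(z1, nz)
        zsel = np.zeros(nz, dtype=bool)
        zsel[z0:z1] = True
        vert3d = outer2d[:, :, None] & zsel[None, None, :]
        trab3d = inner2d[:, :, None] & zsel[None, None, :]
        base[vert3d] = HU_CORTICAL
        hu_trab = (bmd[lv] - spec.calib_intercept) / spec.calib_slope
        base[trab3d] = hu_trab
        mask[vert3d] = vertebra_label(lv)
        mask[trab3d] = trabecular_label(lv)
        trab_regions[lv] = trab3d

        com = np.array(np.nonzero(trab3d), dtype=float).mean(axis=1)
        centroid_world = com * np.asarray(spec.voxel_spacing)
        annotations.append(
            VertebraAnnotation(level=lv, centroid_world=centroid_world, fracture_grade=grades[lv])
        )

    affine = np.diag(list(spec.voxel_spacing) + [1.0])
    offsets = {ph: spec.trab_offset_hu(ph) for ph in PHASES}

    volumes: dict[str, CtVolume] = {}
    for k, ph in enumerate(PHASES):
        vox = base.copy()
        if ph == "AR":
            vox[aorta3d] += spec.enh_aorta_ar
        elif ph == "PV":
            vox[aorta3d] += spec.enh_aorta_pv
            vox[liver3d] += spec.enh_liver_pv
        if offsets[ph] != 0.0:
            for lv in levels:
                vox[trab_regions[lv]] += offsets[ph]
        if spec.noise_sd > 0:
            noise_rng = _rng(spec, patient_index, 2 + k)
            vox += noise_rng.normal(0.0, spec.noise_sd, size=vox.shape)
        volumes[ph] = CtVolume(
            voxels=vox,
            affine=affine,
            patient_id=pid,
            scan_id=f"{pid}_{ph}",
            phase_label=ph,
        )

    truth = PhantomTruth(
        patient_id=pid, bmd=bmd, fracture_grade=grades, trab_offset_hu=offsets
    )
    return PatientCase(
        patient_id=pid,
        volumes=volumes,
        mask=LabelMask(voxels=mask, affine=affine),
        annotations=annotations,
        truth=truth,
    )


def generate_cohort(spec: PhantomSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write a full cohort to disk and return the per-scan manifest.

    Layout: ``out_dir/pNNN/{ne,ar,pv}.nii.gz``, ``mask.nii.gz``,
    ``annotations.json``, plus ``manifest.csv`` (one row per scan) and
    ``truth.csv`` (one row per patient x vertebra). The write is atomic: the
    cohort is built in a temporary sibling directory and renamed into place,
    so a failed generation leaves no dangling files.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        raise ValidationError(f"output directory {out_dir} exists and is not empty")
    tmp = out_dir.parent / (out_dir.name + ".tmp")
    if tmp.exists():
        import shutil

        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    try:
        man_rows, truth_rows = [], []
        for idx in range(spec.n_patients):
            case = generate_patient(spec, idx)
            pdir = tmp / case.patient_id
            write_mask(case.mask, pdir / "mask.nii.gz")
            write_annotations(case.annotations, pdir / "annotations.json")
            for ph in PHASES:
                scan_rel = f"{case.patient_id}/{ph.lower()}.nii.gz"
                write_volume(case.volumes[ph], tmp / scan_rel)
                man_rows.append(
                    {
                        "patient_id": case.patient_id,
                        "scan_id": f"{case.patient_id}_{ph}",
                        "phase": ph,
                        "scan_path": scan_rel,
                        "mask_path": f"{case.patient_id}/mask.nii.gz",
                        "annotations_path": f"{case.patient_id}/annotations.json",
                    }
                )
                for lv in spec.vertebral_levels:
                    truth_rows.append(
                        {
                            "patient_id": case.patient_id,
                            "scan_path": scan_rel,
                            "phase": ph,
                            "vertebra": lv,
                            "bmd_truth": case.truth.bmd[lv],
                            "fracture_grade": case.truth.fracture_grade[lv],
                        }
                    )
        manifest = pd.DataFrame(man_rows)
        truth = pd.DataFrame(truth_rows)
        manifest.to_csv(tmp / "manifest.csv", index=False)
        truth.to_csv(tmp / "truth.csv", index=False)
    except BaseException:
        import shutil

        shutil.rmtree(tmp, ignore_errors=True)
        raise
    if out_dir.exists():
        out_dir.rmdir()
    tmp.rename(out_dir)
    return manifest


def load_manifest(data_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a generated cohort's manifest and truth tables."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    truth = pd.read_csv(data_dir / "truth.csv")
    return manifest, truth
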