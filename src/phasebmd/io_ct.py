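"""Reading and writing of every on-disk artifact the pipeline touches.

Volumes and label masks are NIfTI (via nibabel) and are reoriented to a
canonical right-anterior-superior (RAS) axes order on load, so "axial slice"
means the same thing for every input. Vertebral annotations are JSON sidecars
with VerSe-style fields (``label``, ``X``, ``Y``, ``Z`` in world mm, optional
``fracture_grade``). Reports are CSV files with fixed schemas and a
deterministic row order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .anatomy import check_level, check_phase, level_index, trabecular_label, vertebra_label
from .errors import FormatError, GeometryError, ValidationError

UNKNOWN_GRADE: int | None = None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CtVolume:
    """A 3-D CT volume in Hounsfield units with its voxel-to-world affine.

    Parameters
    ----------
    voxels
        3-D float32 array of HU values, axes ordered (x, y, z) = RAS;
        the third axis is axial (superior = increasing index).
    affine
        4x4 voxel-to-world map in mm.
    phase_label
        Optional ground-truth contrast phase ("NE", "AR" or "PV").
    """

    voxels: np.ndarray
    affine: np.ndarray
    patient_id: str = ""
    scan_id: str = ""
    phase_label: str | None = None

    def __post_init__(self) -> None:
        # float64 arrays (e.g. in-memory phantoms) keep full precision;
        # everything else becomes float32, the working dtype for images
        self.voxels = np.asarray(self.voxels)
        if self.voxels.dtype != np.float64:
            self.voxels = self.voxels.astype(np.float32)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3-D volume, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("volume contains non-finite HU values")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is not invertible")
        if np.any(self.spacing <= 0):
            raise GeometryError(f"non-positive voxel spacing {self.spacing}")
        if self.phase_label is not None:
            check_phase(self.phase_label)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm along each array axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return np.squeeze(xyz)

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
        return np.squeeze(ijk)


@dataclass
class VertebraAnnotation:
    """One labelled vertebra: level code, world-mm centroid, fracture grade.

    ``fracture_grade`` is 0 (intact) to 3 (severe height loss), or None when
    ungraded.
    """

    level: str
    centroid_world: np.ndarray
    fracture_grade: int | None = UNKNOWN_GRADE

    def __post_init__(self) -> None:
        check_level(self.level)
        self.centroid_world = np.asarray(self.centroid_world, dtype=float)
        if self.centroid_world.shape != (3,):
            raise ValidationError("centroid must be a 3-vector (world mm)")
        if not np.all(np.isfinite(self.centroid_world)):
            raise ValidationError("centroid contains non-finite values")
        if self.fracture_grade is not None and self.fracture_grade not in (0, 1, 2, 3):
            raise ValidationError(f"fracture grade must be 0-3 or None, got {self.fracture_grade}")


@dataclass
class LabelMask:
    """Integer segmentation mask aligned voxel-for-voxel with a CtVolume.

    Whole vertebrae carry their anatomical label (C1=1 .. L5=24); the
    trabecular compartment carries label + 100.
    """

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise FormatError("label mask must be an integer array")
        if self.voxels.ndim != 3:
            raise FormatError("label mask must be 3-D")
        self.affine = np.asarray(self.affine, dtype=float)

    def region(self, level: str, trabecular: bool = True) -> np.ndarray:
        """Boolean mask of one vertebra's voxels (trabecular subregion or shell)."""
        lab = trabecular_label(level) if trabecular else vertebra_label(level)
        return self.voxels == lab

    def present_levels(self) -> list[str]:
        """Vertebra codes with a non-empty trabecular compartment, cranial to caudal."""
        labels = set(np.unique(self.voxels).tolist())
        from .anatomy import VERTEBRA_CODES

        return [c for c in VERTEBRA_CODES if trabecular_label(c) in labels]


# ---------------------------------------------------------------------------
# NIfTI volumes and masks
# ---------------------------------------------------------------------------

def _load_canonical(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)
        data = np.asanyarray(img.dataobj)
    except FormatError:
        raise
    except Exception as exc:  # truncated / non-NIfTI input
        raise FormatError(f"could not read NIfTI file {path}: {exc}") from exc
    return data, np.asarray(img.affine, dtype=float)


def read_volume(
    path: str | Path,
    patient_id: str = "",
    scan_id: str = "",
    phase_label: str | None = None,
) -> CtVolume:
    """Read a NIfTI CT volume, reorient to RAS, and convert to float32 HU."""
    data, affine = _load_canonical(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D volume, got ndim={data.ndim}")
    return CtVolume(
        voxels=data.astype(np.float32),
        affine=affine,
        patient_id=patient_id,
        scan_id=scan_id,
        phase_label=phase_label,
    )


def write_volume(vol: CtVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), vol.affine)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> LabelMask:
    """Read a NIfTI multi-label segmentation mask (integer labels)."""
    data, affine = _load_canonical(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D mask, got ndim={data.ndim}")
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"{path}: mask voxels are not integral")
    return LabelMask(voxels=np.round(data).astype(np.int32), affine=affine)


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.voxels.astype(np.int16), mask.affine)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# annotation sidecars
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[VertebraAnnotation]:
    """Read a JSON centroid sidecar; entries are returned cranial to caudal.

    Schema: a list of objects with keys ``label`` (vertebra code), ``X``,
    ``Y``, ``Z`` (world mm) and optional ``fracture_grade``. A missing grade
    means "unknown" (None). Duplicate levels are rejected.
    """
    path = Path(path)
    try:
        entries = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"could not read annotation sidecar {path}: {exc}") from exc
    if not isinstance(entries, list):
        raise ValidationError(f"{path}: annotation sidecar must be a JSON list")
    annos: list[VertebraAnnotation] = []
    seen: set[str] = set()
    for e in entries:
        if not isinstance(e, dict) or not {"label", "X", "Y", "Z"} <= set(e):
            raise ValidationError(f"{path}: entry missing label/X/Y/Z: {e!r}")
        level = check_level(str(e["label"]))
        if level in seen:
            raise ValidationError(f"{path}: duplicate vertebra level {level}")
        seen.add(level)
        grade = e.get("fracture_grade", UNKNOWN_GRADE)
        annos.append(
            VertebraAnnotation(
                level=level,
                centroid_world=np.array([e["X"], e["Y"], e["Z"]], dtype=float),
                fracture_grade=None if grade is None else int(grade),
            )
        )
    annos.sort(key=lambda a: level_index(a.level))
    return annos


def write_annotations(annotations: list[VertebraAnnotation], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    entries = [
        {
            "label": a.level,
            "X": float(a.centroid_world[0]),
            "Y": float(a.centroid_world[1]),
            "Z": float(a.centroid_world[2]),
            "fracture_grade": a.fracture_grade,
        }
        for a in annotations
    ]
    path.write_text(json.dumps(entries, indent=1))
    return path


# ---------------------------------------------------------------------------
# CSV reports
# ---------------------------------------------------------------------------

REPORT_SCHEMAS: dict[str, tuple[str, ...]] = {
    "phase_predictions": (
        "patient_id",
        "scan_id",
        "true_phase",
        "n_slices_used",
        "p_NE",
        "p_AR",
        "p_PV",
        "call_mean",
        "call_majority",
        "disagree_flag",
    ),
    "bmd": (
        "patient_id",
        "scan_id",
        "phase_called",
        "bmd_L1",
        "bmd_L2",
        "bmd_L3",
        "lumbar_mean_bmd",
        "corrected_bmd",
        "exclusions",
    ),
    "metrics": ("metric", "value"),
}


def write_report(rows, path: str | Path, kind: str) -> Path:
    """Write a report CSV with a fixed header and deterministic row order.

    ``rows`` is a list of dicts or a DataFrame whose columns must match the
    schema of ``kind`` exactly. Rows are sorted by (patient_id, scan_id)
    where those columns exist.
    """
    if kind not in REPORT_SCHEMAS:
        raise ValidationError(f"unknown report kind {kind!r}; expected one of {sorted(REPORT_SCHEMAS)}")
    schema = REPORT_SCHEMAS[kind]
    df = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows.copy()
    if set(df.columns) != set(schema):
        raise ValidationError(
            f"report columns {sorted(df.columns)} do not match the {kind!r} schema {sorted(schema)}"
        )
    df = df[list(schema)]
    sort_cols = [c for c in ("patient_id", "scan_id", "metric") if c in df.columns]
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_report(path: str | Path, kind: str) -> pd.DataFrame:
    if kind not in REPORT_SCHEMAS:
        raise ValidationError(f"unknown report kind {kind!r}")
    df = pd.read_csv(path)
    if tuple(df.columns) != REPORT_SCHEMAS[kind]:
        raise ValidationError(f"{path}: header does not match the {kind!r} schema")
    return df
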