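"""Classifier input preparation.

Fixed pipeline order (the order is part of the contract, because slice
extraction commutes with neither step):

1. resample the whole volume to isotropic spacing (linear interpolation),
2. z-score normalize the whole volume (population SD, volume-level so that
   inter-slice contrast cues survive),
3. select axial slices — anatomy-guided at the vertebral centroids of the
   requested levels, or uniformly at random,
4. crop-pad each slice to a fixed in-plane size (default 224 x 224), padding
   with the slice minimum (air-equivalent after normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .anatomy import DEFAULT_INPUT_LEVELS, check_level, level_index
from .errors import CoverageError, GeometryError, NormalizationError, ValidationError
from .io_ct import CtVolume, VertebraAnnotation


@dataclass
class SliceStack:
    """Ordered preprocessed axial slices of one scan, one per selected level.

    ``levels`` holds the vertebra code of each image for anatomy-guided
    selection, or ``random-<axial index>`` tags for random selection.
    """

    images: list[np.ndarray]
    levels: list[str]
    scan_id: str = ""

    def __post_init__(self) -> None:
        if len(self.images) != len(self.levels):
            raise ValidationError("images and levels must have equal length")
        if not self.images:
            raise CoverageError("a slice stack must contain at least one image")
        s = self.images[0].shape
        for im in self.images:
            if im.ndim != 2 or im.shape != s or im.shape[0] != im.shape[1]:
                raise ValidationError("all stack images must be square and equally sized")
            if not np.all(np.isfinite(im)):
                raise ValidationError("stack images must be finite")

    @property
    def size(self) -> int:
        return self.images[0].shape[0]

    def as_array(self) -> np.ndarray:
        return np.stack(self.images).astype(np.float32)


def resample_isotropic(vol: CtVolume, target_mm: float = 1.0) -> CtVolume:
    """Resample a volume to isotropic spacing with linear interpolation.

    The new grid size per axis is ``round(old_size * old_spacing / target)``
    (at least 1), which preserves the physical extent to within one voxel.
    A volume already at the target spacing is returned unchanged.
    """
    if target_mm <= 0:
        raise GeometryError("target_mm must be positive")
    spacing = vol.spacing
    if np.any(spacing <= 0):
        raise GeometryError("degenerate input spacing")
    if np.allclose(spacing, target_mm, rtol=0, atol=1e-9):
        return vol
    factors = spacing / target_mm
    new_shape = np.maximum(1, np.round(np.array(vol.shape) * factors)).astype(int)
    zoom = new_shape / np.array(vol.shape)
    data = ndimage.zoom(vol.voxels, zoom, order=1, mode="nearest", grid_mode=True)
    direction = vol.affine[:3, :3] / spacing  # unit direction cosines
    new_affine = np.eye(4)
    new_affine[:3, :3] = direction * target_mm
    new_affine[:3, 3] = vol.affine[:3, 3]
    return CtVolume(
        voxels=data.astype(np.float32),
        affine=new_affine,
        patient_id=vol.patient_id,
        scan_id=vol.scan_id,
        phase_label=vol.phase_label,
    )


def znormalize(vol: CtVolume) -> CtVolume:
    """Z-score normalize a whole volume (population SD convention)."""
    mu = float(vol.voxels.mean())
    sd = float(vol.voxels.std())
    if sd < 1e-8:
        raise NormalizationError("cannot z-normalize a (near-)constant volume")
    data = (vol.voxels - mu) / sd
    return CtVolume(
        voxels=data,
        affine=vol.affine,
        patient_id=vol.patient_id,
        scan_id=vol.scan_id,
        phase_label=vol.phase_label,
    )


def crop_pad(image: np.ndarray, size: int = 224, center: tuple[float, float] | None = None) -> np.ndarray:
    """Crop/pad a 2-D image to ``size x size`` about ``center``.

    Total function: any 2-D input works. Padding uses the image minimum.
    Idempotent when the image is already ``size x size`` and centered.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError("crop_pad expects a 2-D image")
    if center is None:
        center = (image.shape[0] / 2.0, image.shape[1] / 2.0)
    fill = float(image.min()) if image.size else 0.0
    out = np.full((size, size), fill, dtype=np.float32)
    starts = [int(round(c - size / 2.0)) for c in center]
    for_src, for_dst = [], []
    for ax, start in enumerate(starts):
        s0 = max(start, 0)
        s1 = min(start + size, image.shape[ax])
        if s1 <= s0:
            return out  # window entirely outside the image
        for_src.append(slice(s0, s1))
        for_dst.append(slice(s0 - start, s1 - start))
    out[tuple(for_dst)] = image[tuple(for_src)]
    return out


def _nearest_axial_index(zc: float, nz: int) -> int | None:
    """Nearest axial index to a (fractional) voxel z; ties break caudally (-z)."""
    zi = int(np.ceil(zc - 0.5))  # round half down = toward caudal
    if zi < 0 or zi >= nz:
        return None
    return zi


def select_slices_anatomy(
    vol: CtVolume,
    annotations: list[VertebraAnnotation],
    levels: tuple[str, ...] = DEFAULT_INPUT_LEVELS,
    image_size: int = 224,
) -> SliceStack:
    """Extract one axial slice per requested vertebral level.

    For each requested level present in the annotations, the axial slice
    nearest to the centroid's world z is taken and crop-padded about the
    centroid's in-plane position. Levels missing from the annotations or
    whose centroid falls outside the volume are silently skipped; downstream
    aggregation uses all available predictions. Invariant to annotation order.
    """
    for lv in levels:
        check_level(lv)
    by_level: dict[str, VertebraAnnotation] = {}
    for a in annotations:
        if a.level in by_level:
            raise ValidationError(f"duplicate annotation for level {a.level}")
        by_level[a.level] = a
    images, used = [], []
    for lv in sorted(levels, key=level_index):
        a = by_level.get(lv)
        if a is None:
            continue
        ijk = vol.world_to_voxel(a.centroid_world)
        zi = _nearest_axial_index(float(ijk[2]), vol.shape[2])
        if zi is None:
            continue
        if not (0 <= ijk[0] < vol.shape[0] and 0 <= ijk[1] < vol.shape[1]):
            continue
        sl = vol.voxels[:, :, zi]
        images.append(crop_pad(sl, image_size, center=(float(ijk[0]), float(ijk[1]))))
        used.append(lv)
    if not images:
        raise CoverageError(
            f"none of the requested levels {levels} are available inside the volume"
        )
    return SliceStack(images=images, levels=used, scan_id=vol.scan_id)


def select_slices_random(
    vol: CtVolume,
    k: int = 7,
    seed: int | np.random.Generator | None = 0,
    image_size: int = 224,
) -> SliceStack:
    """Extract ``k`` distinct axial slices drawn uniformly without replacement."""
    nz = vol.shape[2]
    if k < 1:
        raise ValidationError("k must be >= 1")
    if nz < k:
        raise CoverageError(f"volume has {nz} axial slices, fewer than k={k}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(nz, size=k, replace=False))
    images = [crop_pad(vol.voxels[:, :, int(z)], image_size) for z in idx]
    return SliceStack(
        images=images, levels=[f"random-{int(z)}" for z in idx], scan_id=vol.scan_id
    )


def preprocess_scan(
    vol: CtVolume,
    annotations: list[VertebraAnnotation] | None = None,
    *,
    target_mm: float = 1.0,
    image_size: int = 224,
    selection_mode: str = "anatomy",
    levels: tuple[str, ...] = DEFAULT_INPUT_LEVELS,
    k_random: int = 7,
    seed: int | np.random.Generator | None = 0,
) -> SliceStack:
    """Full preprocessing pipeline: resample -> z-normalize -> select -> crop-pad."""
    if vol.voxels.dtype != np.float32:  # classifier input is float32 throughout
        vol = CtVolume(vol.voxels.astype(np.float32), vol.affine, vol.patient_id,
                       vol.scan_id, vol.phase_label)
    vol = resample_isotropic(vol, target_mm)
    vol = znormalize(vol)
    if selection_mode == "anatomy":
        if annotations is None:
            raise ValidationError("anatomy-guided selection requires annotations")
        return select_slices_anatomy(vol, annotations, levels=levels, image_size=image_size)
    if selection_mode == "random":
        return select_slices_random(vol, k=k_random, seed=seed, image_size=image_size)
    raise ValidationError(f"unknown selection_mode {selection_mode!r}")
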