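"""NIfTI input/output for PET volumes and lesion masks.

All arrays inside the package follow one fixed anatomical axis convention:

* axis 0 - left-right (LR),
* axis 1 - anterior-posterior (AP),
* axis 2 - inferior-superior (IS),

i.e. the RAS+ voxel order nibabel calls "closest canonical".  Files stored in
any other orientation are reoriented on read; the original orientation is kept
on the object so a file can be written back the way it came in.  Spacing is in
millimetres and is never resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["PetVolume", "LesionMask3D", "read_volume", "read_mask", "write_volume"]

#: axis codes of the internal convention (nibabel orientation labels)
CANONICAL_AXCODES = ("R", "A", "S")

#: tolerance (mm) for spacing agreement between a mask and its reference volume
SPACING_ATOL_MM = 1e-3


def _validate_grid(data: np.ndarray, spacing, *, what: str) -> None:
    if data.ndim != 3:
        raise ValueError(f"{what}: expected a 3D grid, got {data.ndim} dimensions")
    if any(s < 2 for s in data.shape):
        raise ValueError(f"{what}: every axis needs >= 2 planes, got shape {data.shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"{what}: spacing must be 3 positive values in mm, got {spacing}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{what}: grid contains non-finite values")


@dataclass
class PetVolume:
    """3D PET intensity grid with physical spacing.

    Parameters
    ----------
    data
        Non-negative intensities (SUV-like, unit-agnostic), axes (LR, AP, IS).
    spacing
        Voxel size ``(sx, sy, sz)`` in mm along (LR, AP, IS).
    source_orientation
        Axis codes of the file this volume was read from, for round-tripping.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    source_orientation: tuple[str, str, str] = field(default=CANONICAL_AXCODES)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        _validate_grid(self.data, self.spacing, what="PetVolume")
        if self.data.min() < 0:
            raise ValueError("PetVolume: intensities must be >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class LesionMask3D:
    """Binary lesion mask aligned voxel-for-voxel to a :class:`PetVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    source_orientation: tuple[str, str, str] = field(default=CANONICAL_AXCODES)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        _validate_grid(arr, self.spacing, what="LesionMask3D")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"LesionMask3D: values must be binary, found {uniq[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


def _load_canonical(path) -> tuple[np.ndarray, tuple[float, float, float], tuple[str, str, str]]:
    """Load a NIfTI file and reorient to the internal (LR, AP, IS) axes."""
    img = nib.load(str(path))
    ndim = len(img.shape)
    if ndim != 3:
        raise ValueError(f"{path}: expected a 3D payload, header reports dim={ndim}")
    source_axcodes = nib.aff2axcodes(img.affine)
    canonical = nib.as_closest_canonical(img)
    data = np.asanyarray(canonical.dataobj).astype(np.float64)
    zooms = canonical.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: header pixdim must be positive and finite, got {zooms}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: image contains non-finite voxels")
    return data, tuple(float(z) for z in zooms), source_axcodes


def read_volume(path) -> PetVolume:
    """Read a 3D PET volume from a NIfTI-1 file.

    The grid is reoriented to the internal (LR, AP, IS) convention and spacing
    is taken from the header ``pixdim`` fields.  Raises ``ValueError`` for
    non-3D payloads, non-finite voxels, or non-positive spacings.
    """
    data, spacing, src = _load_canonical(path)
    if data.min() < 0:
        raise ValueError(f"{path}: PET intensities must be non-negative")
    return PetVolume(data=data, spacing=spacing, source_orientation=src)


def read_mask(path, reference: PetVolume) -> LesionMask3D:
    """Read a binary lesion mask and check alignment with *reference*.

    Values are binarized at 0.5 (a ``{0, 255}`` encoding is accepted with a
    warning).  Shape or spacing disagreement beyond ``SPACING_ATOL_MM`` is an
    error — masks are never silently resampled.
    """
    data, spacing, src = _load_canonical(path)
    if data.shape != reference.shape:
        raise ValueError(
            f"{path}: mask shape {data.shape} does not match reference {reference.shape}"
        )
    if not np.allclose(spacing, reference.spacing, atol=SPACING_ATOL_MM, rtol=0):
        raise ValueError(
            f"{path}: mask spacing {spacing} differs from reference {reference.spacing} "
            f"by more than {SPACING_ATOL_MM} mm"
        )
    uniq = np.unique(data)
    if not np.isin(uniq, (0, 1)).all():
        binarized = (data > 0.5 * data.max()).astype(np.uint8) if data.max() > 1 else (data > 0.5)
        # accept scaled encodings ({0,255}, {0,1000}...) only when exactly two levels
        if len(uniq) > 2 or uniq[0] != 0:
            raise ValueError(f"{path}: mask values {uniq[:10]} are not binarizable")
        warnings.warn(
            f"{path}: mask encoded as {{0, {uniq[-1]:g}}}; binarizing at 0.5 x max",
            stacklevel=2,
        )
        data = binarized
    return LesionMask3D(data=data, spacing=spacing, source_orientation=src)


def write_volume(obj: PetVolume | LesionMask3D, path) -> None:
    """Write a volume or mask as NIfTI-1 with a diagonal RAS+ affine.

    Masks round-trip bit-exactly (uint8); intensities round-trip within 1e-6
    relative (float32 storage).
    """
    if isinstance(obj, LesionMask3D):
        data = obj.data.astype(np.uint8)
    else:
        data = obj.data.astype(np.float32)
    affine = np.diag(list(obj.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(obj.spacing)
    nib.save(img, str(path))
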