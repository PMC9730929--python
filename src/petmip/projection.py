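"""Coronal and sagittal maximum-intensity projections (MIPs).

A MIP collapses the 3D volume along one horizontal axis, keeping for every ray
the maximum intensity encountered.  With the internal (LR, AP, IS) axis order:

* the **coronal** view projects along AP (axis 1) -> image axes (LR, IS);
* the **sagittal** view projects along LR (axis 0) -> image axes (AP, IS).

The two views are 90 degrees apart by construction.  Lesion masks are projected
with the same operator, which for binary rays is a logical OR; the resulting
binary images are called MIP masks.  Pixel spacing is inherited from the two
retained volume axes, so pixels may be anisotropic and pixel area is u*v mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from petmip.volume_io import LesionMask3D, PetVolume

__all__ = ["MipImage", "MipMask", "MipPair", "mip_project", "mip_project_mask", "make_mip_pair", "save_qc_png"]

#: projection axis per view, in internal (LR, AP, IS) axis order
_VIEW_AXIS = {"coronal": 1, "sagittal": 0}


def _check_view(view: str) -> int:
    try:
        return _VIEW_AXIS[view]
    except KeyError:
        raise ValueError(f"unknown view {view!r}; expected 'coronal' or 'sagittal'") from None


def _retained_spacing(spacing, axis: int) -> tuple[float, float]:
    kept = [s for i, s in enumerate(spacing) if i != axis]
    return (kept[0], kept[1])


@dataclass
class MipImage:
    """2D MIP of PET intensities.

    ``data`` axes are (horizontal, vertical) = (LR, IS) for coronal and
    (AP, IS) for sagittal; ``pixel_spacing`` is (u, v) mm for those axes.
    """

    data: np.ndarray
    pixel_spacing: tuple[float, float]
    view: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("MipImage data must be 2D")
        _check_view(self.view)
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]


@dataclass
class MipMask:
    """Binary 2D projection of a 3D lesion mask (a MIP mask)."""

    data: np.ndarray
    pixel_spacing: tuple[float, float]
    view: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("MipMask data must be 2D")
        if not np.isin(np.unique(arr), (0, 1)).all():
            raise ValueError("MipMask values must be binary")
        self.data = arr.astype(np.uint8)
        _check_view(self.view)
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]

    @property
    def pixel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class MipPair:
    """The coronal and sagittal (image, mask) projections of one patient."""

    coronal: tuple[MipImage, MipMask]
    sagittal: tuple[MipImage, MipMask]

    def view(self, name: str) -> tuple[MipImage, MipMask]:
        _check_view(name)
        return self.coronal if name == "coronal" else self.sagittal


def mip_project(volume: PetVolume, view: str) -> MipImage:
    """Project a PET volume into the requested view.

    Every output pixel is the maximum intensity along the ray normal to the
    projection plane (AP rays for coronal, LR rays for sagittal).
    """
    axis = _check_view(view)
    return MipImage(
        data=volume.data.max(axis=axis),
        pixel_spacing=_retained_spacing(volume.spacing, axis),
        view=view,
    )


def mip_project_mask(mask: LesionMask3D, view: str) -> MipMask:
    """Project a binary lesion mask: pixel = 1 iff any voxel on the ray is 1."""
    axis = _check_view(view)
    return MipMask(
        data=mask.data.max(axis=axis),
        pixel_spacing=_retained_spacing(mask.spacing, axis),
        view=view,
    )


def make_mip_pair(volume: PetVolume, mask: LesionMask3D) -> MipPair:
    """Bundle the four projections (two views x intensity/mask) of one case."""
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    if not np.allclose(volume.spacing, mask.spacing):
        raise ValueError(f"volume spacing {volume.spacing} != mask spacing {mask.spacing}")
    return MipPair(
        coronal=(mip_project(volume, "coronal"), mip_project_mask(mask, "coronal")),
        sagittal=(mip_project(volume, "sagittal"), mip_project_mask(mask, "sagittal")),
    )


def save_qc_png(pair: MipPair, path, overlay: MipPair | None = None) -> None:
    """Export a quality-control panel: both MIP views with mask contours.

    Intended for visual checks only; images are displayed head-up (IS axis
    vertical) with an inverted gray colormap as is customary for FDG PET.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(7, 5))
    for ax, name in zip(axes, ("coronal", "sagittal")):
        img, msk = pair.view(name)
        ax.imshow(img.data.T, origin="lower", cmap="gray_r", aspect=img.pixel_spacing[1] / img.pixel_spacing[0])
        if msk.pixel_count:
            ax.contour(msk.data.T, levels=[0.5], colors="tab:blue", linewidths=0.8)
        if overlay is not None:
            _, omsk = overlay.view(name)
            if omsk.pixel_count:
                ax.contour(omsk.data.T, levels=[0.5], colors="tab:red", linewidths=0.8)
        ax.set_title(name)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
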