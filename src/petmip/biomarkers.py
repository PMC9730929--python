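"""Reference (3D) and surrogate (2D MIP) lymphoma biomarkers.

Reference biomarkers, computed from the expert/ground-truth 3D lesion mask:

* **TMTV** (cm^3): total metabolic tumor volume — lesion voxel count times the
  voxel volume.
* **Dmax** (cm): tumor dissemination — the largest Euclidean distance between
  the centroids of any two lesions (26-connected components).  Patients with
  fewer than two lesions get Dmax = 0 and a flag; excluding them is a
  pipeline-level policy, the function stays total.

Surrogate biomarkers, computed from the coronal and sagittal MIP masks only:

* **sTMTV** (cm^2): per view, lesion pixel count times pixel area; the total is
  the sum of the coronal and sagittal components.
* **sDmax** (cm): per view, the mask is reduced to an x profile (column sums)
  and a y profile (row sums); the span between the 2% and the 98% percentile of
  each profile's cumulative mass is computed, and the view component is
  (x98-x2) + (y98-y2).  The total is again coronal + sagittal.  The 2%/98%
  percentiles make the distance robust to outlying stray pixels.

Internally everything is in mm; reported values are cm / cm^2 / cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import pdist

from petmip.projection import MipMask, MipPair
from petmip.volume_io import LesionMask3D

__all__ = [
    "ViewBiomarkers",
    "BiomarkerRecord",
    "ProfilePair",
    "compute_tmtv",
    "label_lesions",
    "compute_dmax",
    "compute_stmtv",
    "mask_profiles",
    "percentile_span",
    "compute_sdmax",
    "biomarker_table",
]

#: 26-connectivity structuring element for 3D component labelling
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ViewBiomarkers:
    """Per-view surrogate components."""

    view: str
    stmtv_component_cm2: float
    sdmax_component_cm: float
    x_span_mm: float
    y_span_mm: float


@dataclass
class BiomarkerRecord:
    """All biomarkers of one patient."""

    patient_id: str
    tmtv_cm3: float
    dmax_cm: float
    stmtv_cm2: float
    sdmax_cm: float
    per_view: dict[str, ViewBiomarkers]
    n_lesions: int
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "TMTV_cm3": self.tmtv_cm3,
            "Dmax_cm": self.dmax_cm,
            "sTMTV_cm2": self.stmtv_cm2,
            "sDmax_cm": self.sdmax_cm,
            "n_lesions": self.n_lesions,
            "flags": ";".join(self.flags),
        }
        for name, vb in self.per_view.items():
            row[f"sTMTV_{name}_cm2"] = vb.stmtv_component_cm2
            row[f"sDmax_{name}_cm"] = vb.sdmax_component_cm
        return row


@dataclass
class ProfilePair:
    """Column (x) and row (y) pixel-sum profiles of a MIP mask."""

    x_profile: np.ndarray
    y_profile: np.ndarray
    x_spacing_mm: float
    y_spacing_mm: float


def compute_tmtv(mask: LesionMask3D) -> float:
    """Total metabolic tumor volume in cm^3 (voxel count x voxel volume)."""
    return float(mask.data.sum()) * mask.voxel_volume_mm3 / 1000.0


def label_lesions(mask: LesionMask3D) -> tuple[np.ndarray, np.ndarray]:
    """Label 26-connected lesions and return (labels, centroids).

    ``labels`` is an int grid (0 = background, 1..n = lesions); ``centroids``
    is an (n, 3) array of physical mm coordinates (mean of member voxel
    centers, voxel i mapping to (i + 0.5) * spacing).
    """
    labels, n = ndimage.label(mask.data, structure=_STRUCT_26)
    if n == 0:
        return labels, np.empty((0, 3))
    coms = np.asarray(ndimage.center_of_mass(mask.data, labels, index=range(1, n + 1)))
    centroids = (coms + 0.5) * np.asarray(mask.spacing)
    return labels, centroids


def compute_dmax(mask: LesionMask3D) -> tuple[float, int, list[str]]:
    """Largest centroid-pair distance in cm, with lesion count and flags.

    With fewer than two lesions the distance is 0 and the record is flagged
    ``n_lesions<2`` (cohorts typically exclude such patients from dissemination
    analysis; that exclusion is left to the pipeline).
    """
    _, centroids = label_lesions(mask)
    n = len(centroids)
    if n < 2:
        return 0.0, n, ["n_lesions<2"]
    return float(pdist(centroids).max()) / 10.0, n, []


def compute_stmtv(pair: MipPair) -> tuple[float, dict[str, float]]:
    """Surrogate tumor volume: per-view pixel count x pixel area, in cm^2.

    Returns the total (coronal + sagittal) and the per-view components.
    """
    components = {}
    for name in ("coronal", "sagittal"):
        _, msk = pair.view(name)
        components[name] = msk.pixel_count * msk.pixel_area_mm2 / 100.0
    return components["coronal"] + components["sagittal"], components


def mask_profiles(mask: MipMask) -> ProfilePair:
    """Reduce a MIP mask to x (per-column) and y (per-row) pixel-sum profiles.

    Image axis 0 (horizontal) indexes columns, axis 1 (vertical) rows, so the
    x profile is the sum over axis 1 and vice versa.  Both profiles sum to the
    mask pixel count.
    """
    return ProfilePair(
        x_profile=mask.data.sum(axis=1).astype(np.int64),
        y_profile=mask.data.sum(axis=0).astype(np.int64),
        x_spacing_mm=mask.pixel_spacing[0],
        y_spacing_mm=mask.pixel_spacing[1],
    )


def percentile_span(profile: np.ndarray, spacing_mm: float, lo: float = 0.02, hi: float = 0.98) -> float:
    """Distance in mm between the *lo* and *hi* percentiles of a profile.

    The profile is treated as a discrete mass function over bin indices.  With
    cumulative fraction F(k) = (sum through bin k) / total, the percentile
    position q(p) is the smallest bin index with F(k) >= p (left-continuous
    discrete quantile, no interpolation), and the span is
    ``(q(hi) - q(lo)) * spacing_mm``.  A profile with all mass in one bin —
    and an empty profile — yields 0.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if (profile < 0).any():
        raise ValueError("profile entries must be >= 0")
    total = profile.sum()
    if total == 0:
        return 0.0
    frac = np.cumsum(profile) / total
    q_lo = int(np.searchsorted(frac, lo, side="left"))
    q_hi = int(np.searchsorted(frac, hi, side="left"))
    return (q_hi - q_lo) * float(spacing_mm)


def compute_sdmax(pair: MipPair) -> tuple[float, dict[str, ViewBiomarkers]]:
    """Surrogate dissemination in cm, with per-view components.

    Per view: sDmax_view = (x98% - x2%) + (y98% - y2%) of the mask profiles;
    the total is the coronal plus the sagittal component.
    """
    per_view: dict[str, ViewBiomarkers] = {}
    stmtv_total, stmtv_parts = compute_stmtv(pair)
    for name in ("coronal", "sagittal"):
        _, msk = pair.view(name)
        prof = mask_profiles(msk)
        x_span = percentile_span(prof.x_profile, prof.x_spacing_mm)
        y_span = percentile_span(prof.y_profile, prof.y_spacing_mm)
        per_view[name] = ViewBiomarkers(
            view=name,
            stmtv_component_cm2=stmtv_parts[name],
            sdmax_component_cm=(x_span + y_span) / 10.0,
            x_span_mm=x_span,
            y_span_mm=y_span,
        )
    total = per_view["coronal"].sdmax_component_cm + per_view["sagittal"].sdmax_component_cm
    return total, per_view


def compute_record(patient_id: str, mask3d: LesionMask3D, pair: MipPair) -> BiomarkerRecord:
    """Assemble the full biomarker record of one patient."""
    tmtv = compute_tmtv(mask3d)
    dmax, n_lesions, flags = compute_dmax(mask3d)
    stmtv, _ = compute_stmtv(pair)
    sdmax, per_view = compute_sdmax(pair)
    return BiomarkerRecord(
        patient_id=patient_id,
        tmtv_cm3=tmtv,
        dmax_cm=dmax,
        stmtv_cm2=stmtv,
        sdmax_cm=sdmax,
        per_view=per_view,
        n_lesions=n_lesions,
        flags=flags,
    )


def biomarker_table(records: list[BiomarkerRecord]) -> pd.DataFrame:
    """Tabulate records, one row per patient, units in the column names."""
    return pd.DataFrame([r.as_row() for r in records])


def describe_biomarkers(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics (mean, SD, min, quartiles, median, max) per biomarker."""
    cols = [c for c in table.columns if c not in ("patient_id", "flags", "n_lesions")]
    desc = table[cols].describe(percentiles=[0.25, 0.5, 0.75]).T
    return desc.rename(columns={"std": "SD", "50%": "median", "25%": "Q1", "75%": "Q3"})
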