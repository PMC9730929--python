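"""Synthetic whole-body FDG-PET phantoms with known ground truth.

No public imaging exists for the cohorts this kind of analysis is run on, so
every downstream stage is exercised on phantoms: a warm body envelope (trunk +
head), hot physiologic organs (brain, heart and bladder analogues — tracer-avid
structures that must *not* count as lesions), multiple ellipsoidal lesions of
varying uptake, and additive Gaussian noise truncated at zero.  The phantom is
a geometric/statistical testbed, not a scanner simulation: there is no point
spread function, scatter or reconstruction physics.

Geometry is defined in physical mm; a voxel belongs to an ellipsoid iff its
center (index + 0.5 times spacing) lies inside it.  Ground truth carries the
analytic ellipsoid volumes (4/3*pi*a*b*c), the lesion centers, and the analytic
largest pairwise center distance, so discretization error is measurable.

Survival outcomes are simulated from an exponential proportional-hazards model
h(x) = h0 * exp(sum beta_j x_j) with independent uniform censoring, giving
closed-form checks for the survival module.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from petmip.biomarkers import biomarker_table
from petmip.survival import SurvivalRecord
from petmip.volume_io import LesionMask3D, PetVolume, write_volume

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "GroundTruth",
    "PhantomCase",
    "SurvivalSimSpec",
    "default_organs",
    "generate_phantom",
    "generate_cohort",
    "simulate_survival",
    "write_case",
]

logger = logging.getLogger(__name__)

# default acquisition geometry: a compact whole-body grid at PET-typical 4 mm
DEFAULT_GRID = (64, 48, 160)
DEFAULT_SPACING = (4.0, 4.0, 4.0)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center (mm), radii (mm), uptake (a.u.)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    uptake: float

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.radii
        return 4.0 / 3.0 * math.pi * a * b * c


def default_organs(grid_shape=DEFAULT_GRID, spacing=DEFAULT_SPACING) -> list[Ellipsoid]:
    """Physiologic hot-region analogues: brain, heart, bladder.

    Uptakes are multiples of the unit body background chosen to mimic the
    typical FDG pattern (brain and bladder markedly hotter than lesions can
    be confused with, heart moderately hot).
    """
    ex = [g * s for g, s in zip(grid_shape, spacing)]
    cx, cy = ex[0] / 2, ex[1] / 2
    return [
        Ellipsoid((cx, cy, 0.90 * ex[2]), (38.0, 36.0, 40.0), 8.0),  # brain
        Ellipsoid((cx - 0.1 * ex[0], cy - 0.05 * ex[1], 0.62 * ex[2]), (28.0, 28.0, 30.0), 5.0),  # heart
        Ellipsoid((cx, cy - 0.05 * ex[1], 0.12 * ex[2]), (20.0, 20.0, 24.0), 10.0),  # bladder
    ]


@dataclass
class PhantomSpec:
    """Full description of one synthetic patient."""

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    body_uptake: float = 1.0
    organ_specs: list[Ellipsoid] = field(default_factory=default_organs)
    lesion_specs: list[Ellipsoid] = field(default_factory=list)
    noise_sigma: float = 0.1
    seed: int = 0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(g * s for g, s in zip(self.grid_shape, self.spacing))


@dataclass
class GroundTruth:
    """Analytic truth of a phantom, independent of voxelization."""

    lesion_volumes_mm3: list[float]
    lesion_centroids_mm: np.ndarray  # (n, 3)
    analytic_dmax_cm: float
    organ_mask: np.ndarray  # 3D bool, physiologic regions (not lesions)


@dataclass
class PhantomCase:
    """One generated cohort member."""

    patient_id: str
    spec: PhantomSpec
    volume: PetVolume
    mask: LesionMask3D
    truth: GroundTruth


def _voxel_centers(grid_shape, spacing):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(grid_shape, spacing)]
    return axes


def _ellipsoid_mask(grid_shape, spacing, ell: Ellipsoid) -> np.ndarray:
    """Boolean voxelization (voxel-center-inside rule), bounding-box limited."""
    out = np.zeros(grid_shape, dtype=bool)
    lo = [max(0, int((c - r) / s) - 1) for c, r, s in zip(ell.center, ell.radii, spacing)]
    hi = [min(n, int((c + r) / s) + 2) for c, r, s, n in zip(ell.center, ell.radii, spacing, grid_shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return out
    xs = [(np.arange(l, h) + 0.5) * s for l, h, s in zip(lo, hi, spacing)]
    gx, gy, gz = np.meshgrid(*xs, indexing="ij", sparse=True)
    q = (
        ((gx - ell.center[0]) / ell.radii[0]) ** 2
        + ((gy - ell.center[1]) / ell.radii[1]) ** 2
        + ((gz - ell.center[2]) / ell.radii[2]) ** 2
    )
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = q <= 1.0
    return out


def _body_envelope(grid_shape, spacing) -> np.ndarray:
    """Trunk (elliptic cylinder) plus head (ellipsoid)."""
    ex = [g * s for g, s in zip(grid_shape, spacing)]
    cx, cy = ex[0] / 2, ex[1] / 2
    ax_, ay = 0.42 * ex[0], 0.38 * ex[1]
    xs, ys, zs = _voxel_centers(grid_shape, spacing)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)
    trunk = (((gx - cx) / ax_) ** 2 + ((gy - cy) / ay) ** 2 <= 1.0) & (gz <= 0.84 * ex[2])
    head = _ellipsoid_mask(grid_shape, spacing, Ellipsoid((cx, cy, 0.90 * ex[2]), (52.0, 50.0, 58.0), 1.0))
    return trunk | head


def generate_phantom(spec: PhantomSpec) -> tuple[PetVolume, LesionMask3D, GroundTruth]:
    """Render a phantom: intensities, binary lesion mask, analytic truth.

    Lesion uptake wins where a lesion overlaps an organ (logged); organ voxels
    are excluded from the lesion mask, mirroring the clinical rule that
    physiologic uptake is not tumor.  Noise is Gaussian, truncated at zero.
    """
    rng = np.random.default_rng(spec.seed)
    extent = spec.extent_mm
    for les in spec.lesion_specs:
        if les.uptake <= spec.body_uptake:
            raise ValueError(f"lesion uptake {les.uptake} must exceed body uptake {spec.body_uptake}")
        for c, r, e in zip(les.center, les.radii, extent):
            if c - r < 0 or c + r > e:
                raise ValueError(f"lesion at {les.center} mm with radii {les.radii} exceeds grid extent {extent}")

    body = _body_envelope(spec.grid_shape, spec.spacing)
    intensity = np.where(body, spec.body_uptake, 0.0)

    organ_mask = np.zeros(spec.grid_shape, dtype=bool)
    for org in spec.organ_specs:
        m = _ellipsoid_mask(spec.grid_shape, spec.spacing, org)
        intensity[m] = org.uptake
        organ_mask |= m

    lesion_mask = np.zeros(spec.grid_shape, dtype=bool)
    for les in spec.lesion_specs:
        m = _ellipsoid_mask(spec.grid_shape, spec.spacing, les)
        overlap = int((m & organ_mask).sum())
        if overlap:
            logger.info("lesion at %s overlaps %d organ voxels; lesion wins", les.center, overlap)
            organ_mask &= ~m
        intensity[m] = les.uptake
        lesion_mask |= m

    if spec.noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sigma, size=spec.grid_shape)
    np.clip(intensity, 0.0, None, out=intensity)

    centroids = np.array([les.center for les in spec.lesion_specs], dtype=float).reshape(-1, 3)
    if len(centroids) >= 2:
        from scipy.spatial.distance import pdist

        analytic_dmax_cm = float(pdist(centroids).max()) / 10.0
    else:
        analytic_dmax_cm = 0.0

    truth = GroundTruth(
        lesion_volumes_mm3=[les.volume_mm3 for les in spec.lesion_specs],
        lesion_centroids_mm=centroids,
        analytic_dmax_cm=analytic_dmax_cm,
        organ_mask=organ_mask,
    )
    volume = PetVolume(data=intensity, spacing=spec.spacing)
    mask = LesionMask3D(data=lesion_mask.astype(np.uint8), spacing=spec.spacing)
    return volume, mask, truth


def sample_spec(
    rng: np.random.Generator,
    *,
    grid_shape=DEFAULT_GRID,
    spacing=DEFAULT_SPACING,
    n_lesions: int | None = None,
    noise_sigma: float = 0.1,
) -> PhantomSpec:
    """Draw a random patient: 1-10 lesions of log-uniform size, spread in the trunk.

    Lesion radii span 6-24 mm so true TMTV covers more than an order of
    magnitude across a cohort; uptake is 4-9x background, within the range of
    the physiologic organs so segmentation is non-trivial.
    """
    ex = [g * s for g, s in zip(grid_shape, spacing)]
    cx, cy = ex[0] / 2, ex[1] / 2
    if n_lesions is None:
        n_lesions = int(rng.integers(1, 11))
    lesions = []
    for _ in range(n_lesions):
        radii = tuple(float(np.exp(rng.uniform(np.log(6.0), np.log(24.0)))) for _ in range(3))
        # place inside the trunk ellipse (scaled so the lesion fits) and z band
        for _attempt in range(100):
            u, v = rng.uniform(-1, 1), rng.uniform(-1, 1)
            if u * u + v * v > 1:
                continue
            center = (
                cx + u * (0.42 * ex[0] - radii[0]) * 0.8,
                cy + v * (0.38 * ex[1] - radii[1]) * 0.8,
                float(rng.uniform(0.15 * ex[2] + radii[2], 0.80 * ex[2] - radii[2])),
            )
            break
        uptake = float(rng.uniform(4.0, 9.0))
        lesions.append(Ellipsoid(center, radii, uptake))
    return PhantomSpec(
        grid_shape=grid_shape,
        spacing=spacing,
        lesion_specs=lesions,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(n: int, spec_sampler=None, seed: int = 0) -> list[PhantomCase]:
    """Generate *n* reproducible phantom patients.

    ``spec_sampler(rng) -> PhantomSpec`` may be supplied to constrain the
    population (e.g. force single lesions); the default is :func:`sample_spec`.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        spec = spec_sampler(rng) if spec_sampler is not None else sample_spec(rng)
        volume, mask, truth = generate_phantom(spec)
        cases.append(PhantomCase(f"P{i:03d}", spec, volume, mask, truth))
    return cases


@dataclass
class SurvivalSimSpec:
    """Exponential proportional-hazards simulation settings.

    ``log_hr_per_unit`` maps covariate names to Cox log-hazard coefficients.
    A name prefixed ``zlog:`` is transformed to the cohort z-score of
    log1p(value) before entering the hazard, which keeps coefficients
    comparable across biomarkers of different scales.
    """

    baseline_hazard: float = 0.01  # events per month
    log_hr_per_unit: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.2
    horizon_months: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


_RECORD_COLUMNS = {
    "tmtv_cm3": "TMTV_cm3",
    "dmax_cm": "Dmax_cm",
    "stmtv_cm2": "sTMTV_cm2",
    "sdmax_cm": "sDmax_cm",
}


def _covariate_frame(biomarkers) -> pd.DataFrame:
    if isinstance(biomarkers, pd.DataFrame):
        return biomarkers.copy()
    table = biomarker_table(list(biomarkers))
    table = table.rename(columns={v: k for k, v in _RECORD_COLUMNS.items()})
    return table


def simulate_survival(biomarkers, spec: SurvivalSimSpec, endpoint: str = "PFS") -> list[SurvivalRecord]:
    """Draw event/censoring times whose hazard increases with the biomarkers.

    Event times are exponential with rate h0 * exp(sum beta_j x_j).  Each
    subject is independently censored with probability ``censoring_rate`` at a
    Uniform(0, horizon] time; otherwise follow-up is complete and event = 1.
    Accepts a list of :class:`~petmip.biomarkers.BiomarkerRecord` or any
    DataFrame of covariates (must then contain the named columns).
    """
    frame = _covariate_frame(biomarkers)
    if "patient_id" not in frame.columns:
        frame["patient_id"] = [f"P{i:03d}" for i in range(len(frame))]
    rng = np.random.default_rng(spec.seed)
    eta = np.zeros(len(frame))
    for name, beta in spec.log_hr_per_unit.items():
        if name.startswith("zlog:"):
            raw = np.log1p(frame[name[5:]].to_numpy(dtype=float))
            sd = raw.std(ddof=0)
            x = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
        else:
            x = frame[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"covariate {name!r} contains non-finite values")
        eta = eta + beta * x
    hazard = spec.baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.uniform(size=len(frame)) < spec.censoring_rate
    censor_time = np.where(censored, rng.uniform(0.0, spec.horizon_months, size=len(frame)), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    # exponential draws can be arbitrarily small but must stay positive
    time = np.maximum(time, 1e-9)
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        biom = {k: getattr(row, k) for k in _RECORD_COLUMNS if hasattr(row, k)}
        records.append(
            SurvivalRecord(
                patient_id=getattr(row, "patient_id"),
                time_months=float(time[i]),
                event=int(event[i]),
                endpoint=endpoint,
                biomarkers=biom,
            )
        )
    return records


def write_case(case: PhantomCase, out_dir) -> dict:
    """Write one case as NIfTI pair + JSON ground-truth sidecar; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pet_path = out / f"{case.patient_id}_pet.nii.gz"
    mask_path = out / f"{case.patient_id}_mask.nii.gz"
    truth_path = out / f"{case.patient_id}_truth.json"
    write_volume(case.volume, pet_path)
    write_volume(case.mask, mask_path)
    truth_path.write_text(
        json.dumps(
            {
                "patient_id": case.patient_id,
                "lesion_volumes_mm3": case.truth.lesion_volumes_mm3,
                "lesion_centroids_mm": case.truth.lesion_centroids_mm.tolist(),
                "analytic_dmax_cm": case.truth.analytic_dmax_cm,
                "n_lesions": len(case.truth.lesion_volumes_mm3),
                "seed": case.spec.seed,
            },
            indent=2,
        )
    )
    return {"pet": str(pet_path), "mask": str(mask_path), "truth": str(truth_path)}
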