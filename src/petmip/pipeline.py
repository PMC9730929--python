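"""End-to-end orchestration: phantoms -> MIPs -> segmentation -> biomarkers -> survival.

The library functions are total (a single-lesion patient gets Dmax = 0 with a
flag); cohort-level policy lives here: patients with fewer than two lesions
are excluded from the survival analysis with the reason logged, matching the
usual study flow.  Every stochastic stage takes an explicit seed and the run
manifest records config, seeds and package version so a run can be reproduced
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import petmip
from petmip.biomarkers import BiomarkerRecord, biomarker_table, compute_record
from petmip.evaluation import median_concordance, risk_agreement, seg_metrics, spearman
from petmip.phantom import PhantomCase, SurvivalSimSpec, generate_cohort, simulate_survival
from petmip.projection import MipPair, make_mip_pair, mip_project_mask, save_qc_png
from petmip.segmentation import BaselineConfig, baseline_segment
from petmip.survival import CutoffRule, cox_hr, stratify, td_auc
from petmip.volume_io import LesionMask3D

__all__ = ["RunConfig", "run_pipeline", "compare_modes", "organ_templates", "reference_pair", "segmented_pair"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    n_phantoms: int = 20
    seed: int = 0
    segmentation_mode: str = "reference-mask"  # reference-mask | baseline
    baseline_threshold: float = 0.5
    cutoff_method: str = "median"
    survival: SurvivalSimSpec | None = None
    out_dir: str = "petmip_run"
    write_qc_images: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def reference_pair(case: PhantomCase) -> MipPair:
    """Projections with the ground-truth (expert-analogue) mask."""
    return make_mip_pair(case.volume, case.mask)


def organ_templates(case: PhantomCase, dilate: int = 1) -> dict[str, np.ndarray]:
    """Project the phantom's physiologic organ mask into both views.

    Used as the physiologic-region templates of the baseline segmenter; a
    small dilation absorbs the blur of organ boundaries.
    """
    from scipy import ndimage

    organ = LesionMask3D(data=case.truth.organ_mask.astype(np.uint8), spacing=case.spec.spacing)
    out = {}
    for view in ("coronal", "sagittal"):
        t = mip_project_mask(organ, view).data.astype(bool)
        if dilate:
            t = ndimage.binary_dilation(t, iterations=dilate)
        out[view] = t
    return out


def segmented_pair(case: PhantomCase, threshold: float = 0.5) -> MipPair:
    """Projections with the baseline-segmenter mask replacing the reference."""
    ref = reference_pair(case)
    cfg = BaselineConfig(threshold=threshold, physiologic_templates=organ_templates(case))
    coronal_img, _ = ref.coronal
    sagittal_img, _ = ref.sagittal
    return MipPair(
        coronal=(coronal_img, baseline_segment(coronal_img, cfg)),
        sagittal=(sagittal_img, baseline_segment(sagittal_img, cfg)),
    )


def _case_pair(case: PhantomCase, config: RunConfig) -> MipPair:
    if config.segmentation_mode == "reference-mask":
        return reference_pair(case)
    if config.segmentation_mode == "baseline":
        return segmented_pair(case, config.baseline_threshold)
    raise ValueError(f"unknown segmentation mode {config.segmentation_mode!r}")


def _records_for(cases: list[PhantomCase], config: RunConfig) -> list[BiomarkerRecord]:
    records = []
    for case in cases:
        try:
            records.append(compute_record(case.patient_id, case.mask, _case_pair(case, config)))
        except Exception as exc:  # pragma: no cover - abort policy
            raise RuntimeError(f"stage biomarkers failed for patient {case.patient_id}") from exc
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write the output bundle.

    Writes biomarkers.csv (units in headers), exclusions.csv, survival.json
    (hazard ratio and time-dependent AUC of the surrogate burden biomarker),
    and manifest.json; returns the bundle as a dict as well.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cases = generate_cohort(config.n_phantoms, seed=config.seed)
    records = _records_for(cases, config)
    table = biomarker_table(records)
    table.to_csv(out / "biomarkers.csv", index=False)

    exclusions = [
        {"patient_id": r.patient_id, "reason": "less than 2 lesions"} for r in records if r.n_lesions < 2
    ]
    pd.DataFrame(exclusions, columns=["patient_id", "reason"]).to_csv(out / "exclusions.csv", index=False)
    kept = [r for r in records if r.n_lesions >= 2]
    for e in exclusions:
        logger.info("excluded %s: %s", e["patient_id"], e["reason"])

    survival_out: dict = {"n_included": len(kept), "n_excluded": len(exclusions)}
    sim = config.survival or SurvivalSimSpec(
        log_hr_per_unit={"zlog:tmtv_cm3": 0.8, "zlog:dmax_cm": 0.5}, seed=config.seed + 1
    )
    if len(kept) >= 10:
        surv = simulate_survival(kept, sim)
        stmtv = np.array([r.stmtv_cm2 for r in kept])
        rule = CutoffRule(float(np.median(stmtv)), 1.0, method="median")
        group = (stmtv > rule.tmtv_cutoff).astype(float)
        hz = cox_hr(surv, group, n_bootstrap=200, seed=config.seed + 2)
        auc = td_auc(surv, stmtv, horizon_months=48.0)
        survival_out.update(
            {
                "sTMTV_cutoff_cm2": rule.tmtv_cutoff,
                "HR_high_vs_low_sTMTV": hz.hr,
                "HR_CI95": [hz.ci_low, hz.ci_high],
                "td_AUC_48mo_sTMTV": auc.auc,
                "flags": hz.flags + auc.flags,
            }
        )
    (out / "survival.json").write_text(json.dumps(survival_out, indent=2))

    if config.write_qc_images:
        for case in cases[:4]:
            save_qc_png(reference_pair(case), out / f"{case.patient_id}_qc.png")

    cfg_dict = config.to_dict()
    manifest = {
        "petmip_version": petmip.__version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest(),
        "seeds": {"cohort": config.seed, "survival": sim.seed},
        "n_patients": len(records),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"records": records, "table": table, "exclusions": exclusions, "survival": survival_out, "manifest": manifest}


def compare_modes(config: RunConfig) -> dict:
    """Reference-mask vs segmenter-derived surrogate biomarkers, paired.

    Returns the per-patient paired table plus Spearman correlations,
    median-split concordance and 3-category risk agreement between the two
    routes.
    """
    if config.n_phantoms < 3:
        raise ValueError("need at least 3 phantoms to compare modes")
    cases = generate_cohort(config.n_phantoms, seed=config.seed)
    ref_records = [compute_record(c.patient_id, c.mask, reference_pair(c)) for c in cases]
    seg_records = [
        compute_record(c.patient_id, c.mask, segmented_pair(c, config.baseline_threshold)) for c in cases
    ]
    ref_stmtv = np.array([r.stmtv_cm2 for r in ref_records])
    seg_stmtv = np.array([r.stmtv_cm2 for r in seg_records])
    ref_sdmax = np.array([r.sdmax_cm for r in ref_records])
    seg_sdmax = np.array([r.sdmax_cm for r in seg_records])
    dice = [
        seg_metrics(segmented_pair(c, config.baseline_threshold), reference_pair(c), c.patient_id).dice
        for c in cases
    ]
    rule_ref = CutoffRule(float(np.median(ref_stmtv)), float(np.median(ref_sdmax)))
    rule_seg = CutoffRule(float(np.median(seg_stmtv)), float(np.median(seg_sdmax)))
    cat_ref = [stratify(t, d, rule_ref) for t, d in zip(ref_stmtv, ref_sdmax)]
    cat_seg = [stratify(t, d, rule_seg) for t, d in zip(seg_stmtv, seg_sdmax)]
    r_stmtv, _ = spearman(ref_stmtv, seg_stmtv)
    r_sdmax, _ = spearman(ref_sdmax, seg_sdmax)
    conc, _, _ = median_concordance(ref_stmtv, seg_stmtv)
    agreement = risk_agreement(cat_ref, cat_seg)
    paired = pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in cases],
            "sTMTV_ref_cm2": ref_stmtv,
            "sTMTV_seg_cm2": seg_stmtv,
            "sDmax_ref_cm": ref_sdmax,
            "sDmax_seg_cm": seg_sdmax,
            "dice": dice,
        }
    )
    return {
        "paired": paired,
        "spearman_stmtv": r_stmtv,
        "spearman_sdmax": r_sdmax,
        "median_concordance_stmtv": conc,
        "risk_accuracy": agreement.accuracy,
        "confusion_matrix": agreement.confusion_matrix,
        "median_dice": float(np.median(dice)),
    }
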