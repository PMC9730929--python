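"""Agreement statistics between segmentations and between biomarker rankings.

Segmentation quality is reported patientwise: true/false positive/negative
pixel counts are pooled over the coronal and sagittal views of a patient
before the ratios are formed (not averaged per-view), so each patient
contributes one Dice, one sensitivity and one specificity.  When both the
reference and the prediction are empty, Dice is defined as 1 (perfect
agreement on absence) and the patient is flagged.

Biomarker agreement uses tie-aware Spearman rank correlation, a median-split
concordance fraction (share of patients above the median of one biomarker that
are also above the median of the other), and a 3x3 risk-category confusion
matrix with its accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import stats

from petmip.projection import MipMask, MipPair

__all__ = [
    "SegmentationMetrics",
    "AgreementResult",
    "seg_metrics",
    "wilcoxon_paired",
    "spearman",
    "median_concordance",
    "risk_agreement",
]

RISK_CATEGORIES = (1, 2, 3)  # low, intermediate, high


@dataclass
class SegmentationMetrics:
    patient_id: str
    dice: float
    sensitivity: float
    specificity: float
    per_view: dict[str, dict[str, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


@dataclass
class AgreementResult:
    spearman_r: float
    p_value: float
    concordance_fraction: float
    confusion_matrix: np.ndarray | None = None
    accuracy: float | None = None


def _counts(pred: np.ndarray, ref: np.ndarray) -> tuple[int, int, int, int]:
    pred = pred.astype(bool)
    ref = ref.astype(bool)
    tp = int((pred & ref).sum())
    fp = int((pred & ~ref).sum())
    fn = int((~pred & ref).sum())
    tn = int((~pred & ~ref).sum())
    return tp, fp, fn, tn


def _ratios(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float]:
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    sens = tp / (tp + fn) if (tp + fn) else 1.0
    spec = tn / (tn + fp) if (tn + fp) else 1.0
    return dice, sens, spec


def seg_metrics(pred, ref, patient_id: str = "") -> SegmentationMetrics:
    """Patientwise Dice/sensitivity/specificity of predicted vs reference masks.

    *pred* and *ref* may be :class:`~petmip.projection.MipPair`, mappings from
    view name to :class:`~petmip.projection.MipMask`, or single masks.
    """

    def masks_of(obj) -> dict[str, np.ndarray]:
        if isinstance(obj, MipPair):
            return {v: obj.view(v)[1].data for v in ("coronal", "sagittal")}
        if isinstance(obj, MipMask):
            return {obj.view: obj.data}
        if isinstance(obj, dict):
            return {v: (m.data if isinstance(m, MipMask) else np.asarray(m)) for v, m in obj.items()}
        return {"image": np.asarray(obj)}

    pred_m, ref_m = masks_of(pred), masks_of(ref)
    if pred_m.keys() != ref_m.keys():
        raise ValueError(f"views differ: {sorted(pred_m)} vs {sorted(ref_m)}")
    pooled = np.zeros(4, dtype=np.int64)
    per_view = {}
    flags = []
    for view in pred_m:
        if pred_m[view].shape != ref_m[view].shape:
            raise ValueError(f"{view}: shape mismatch {pred_m[view].shape} vs {ref_m[view].shape}")
        c = _counts(pred_m[view], ref_m[view])
        pooled += c
        d, s, sp = _ratios(*c)
        per_view[view] = {"dice": d, "sensitivity": s, "specificity": sp}
    tp, fp, fn, tn = (int(v) for v in pooled)
    if tp + fn == 0:  # empty reference
        flags.append("empty-reference")
        dice = 1.0 if fp == 0 else 0.0
        sens = 1.0 if fp == 0 else 0.0
    else:
        dice, sens, _ = _ratios(tp, fp, fn, tn)
    _, _, spec = _ratios(tp, fp, fn, tn)
    return SegmentationMetrics(patient_id, dice, sens, spec, per_view, flags)


def _wilcoxon_exact(diff: np.ndarray) -> tuple[float, float]:
    """Two-sided signed-rank p by full enumeration of the 2^n sign patterns.

    Mid-ranks are used for tied absolute differences, so the enumeration
    remains exact under ties (the rank magnitudes are held fixed and only the
    signs are permuted, which is the exact permutation null).
    """
    n = len(diff)
    ranks = stats.rankdata(np.abs(diff))
    w_plus = ranks[diff > 0].sum()
    w_minus = ranks[diff < 0].sum()
    w_obs = min(w_plus, w_minus)
    count = 0
    total = 2**n
    for bits in range(total):
        signs = np.array([(bits >> k) & 1 for k in range(n)])
        wp = ranks[signs == 1].sum()
        wm = ranks.sum() - wp
        if min(wp, wm) <= w_obs + 1e-12:
            count += 1
    return float(w_obs), count / total


def wilcoxon_paired(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon's convention).  For n <= 12 the
    p-value is exact (full sign-pattern enumeration, valid under ties);
    beyond that the tie-corrected normal approximation with continuity
    correction is used.  All-zero differences give statistic 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    diff = diff[diff != 0]
    n = len(diff)
    if n == 0:
        import warnings

        warnings.warn("all paired differences are zero", stacklevel=2)
        return 0.0, 1.0
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")
    if n <= 12:
        return _wilcoxon_exact(diff)
    stat, p = stats.wilcoxon(diff, correction=True, method="approx")
    return float(stat), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant sample")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def median_concordance(x, y) -> tuple[float, int, int]:
    """Median-split concordance: of the observations with x above its median,
    the fraction that also lie above the median of y.

    Returns ``(fraction, n_concordant, n_above_x)``.  Medians use the midpoint
    convention for even n; "above" is strictly greater.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    above_x = x > np.median(x)
    n_above = int(above_x.sum())
    if n_above == 0:
        return float("nan"), 0, 0
    both = int((above_x & (y > np.median(y))).sum())
    return both / n_above, both, n_above


def risk_agreement(cat_ref, cat_pred) -> AgreementResult:
    """3x3 risk-category agreement: confusion matrix (rows = reference) + accuracy."""
    cat_ref = np.asarray(cat_ref)
    cat_pred = np.asarray(cat_pred)
    if cat_ref.shape != cat_pred.shape:
        raise ValueError("category vectors must have equal length")
    for v in np.unique(np.concatenate([cat_ref, cat_pred])):
        if v not in RISK_CATEGORIES:
            raise ValueError(f"unknown risk category {v!r}; expected {RISK_CATEGORIES}")
    cm = np.zeros((3, 3), dtype=int)
    for r, p in zip(cat_ref, cat_pred):
        cm[int(r) - 1, int(p) - 1] += 1
    acc = float(np.trace(cm) / cm.sum()) if cm.sum() else float("nan")
    r, pv = (np.nan, np.nan)
    try:
        r, pv = spearman(cat_ref.astype(float), cat_pred.astype(float))
    except ValueError:
        pass
    frac = float(np.mean(cat_ref == cat_pred))
    return AgreementResult(spearman_r=r, p_value=pv, concordance_fraction=frac, confusion_matrix=cm, accuracy=acc)
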