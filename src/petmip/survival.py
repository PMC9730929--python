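"""Prognostic analysis: risk stratification, Kaplan-Meier, Cox, time-dependent AUC.

The biomarkers are turned into risk groups by cutoff dichotomization:

* a single biomarker splits the cohort at a cutoff (value <= cutoff is "low");
* the burden/dissemination pair (TMTV-like, Dmax-like) defines three risk
  categories: 1 = both low, 3 = both high, 2 = otherwise.

Group prognostic value is quantified with the Cox proportional-hazards hazard
ratio (single covariate, Breslow tie handling, Newton on the partial
likelihood — vectorized because the bootstrap protocol refits it thousands of
times), with percentile bootstrap confidence intervals resampled over
patients, and with an IPCW (inverse probability of censoring weighting)
cumulative/dynamic time-dependent AUC at a fixed horizon.  Kaplan-Meier
estimation and the log-rank statistic go through lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "SurvivalRecord",
    "CutoffRule",
    "HazardResult",
    "TdAucResult",
    "stratify",
    "stratify_records",
    "km_estimate",
    "cox_hr",
    "td_auc",
    "bootstrap_ci",
    "select_cutoff",
]


@dataclass
class SurvivalRecord:
    """One patient's follow-up: time (months), event flag, biomarker values."""

    patient_id: str
    time_months: float
    event: int
    endpoint: str = "PFS"
    biomarkers: dict[str, float] = field(default_factory=dict)
    risk_category: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_months) or self.time_months <= 0:
            raise ValueError(f"time_months must be finite and > 0, got {self.time_months}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass
class CutoffRule:
    """Dichotomization cutoffs for a burden/dissemination biomarker pair.

    ``tmtv_cutoff`` is in cm^3 for the 3D biomarker or cm^2 for the MIP
    surrogate; ``dmax_cutoff`` is in cm.  A value <= cutoff is "low".
    """

    tmtv_cutoff: float
    dmax_cutoff: float
    method: str = "supplied"

    def __post_init__(self) -> None:
        if self.tmtv_cutoff <= 0 or self.dmax_cutoff <= 0:
            raise ValueError("cutoffs must be > 0")


@dataclass
class HazardResult:
    hr: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int
    flags: list[str] = field(default_factory=list)


@dataclass
class TdAucResult:
    auc: float
    ci: tuple[float, float] | None
    horizon_months: float
    flags: list[str] = field(default_factory=list)


def stratify(tmtv_like: float, dmax_like: float, rule: CutoffRule) -> int:
    """Three-category risk: 1 both low, 3 both high, 2 otherwise."""
    low_t = tmtv_like <= rule.tmtv_cutoff
    low_d = dmax_like <= rule.dmax_cutoff
    if low_t and low_d:
        return 1
    if not low_t and not low_d:
        return 3
    return 2


def stratify_records(
    records: list[SurvivalRecord], rule: CutoffRule, burden_key: str = "tmtv_cm3", spread_key: str = "dmax_cm"
) -> list[SurvivalRecord]:
    """Assign a risk category to every record in place and return the list."""
    for rec in records:
        rec.risk_category = stratify(rec.biomarkers[burden_key], rec.biomarkers[spread_key], rule)
    return records


def _times_events(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time_months for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def km_estimate(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival estimate with the number at risk per event time.

    Returns a DataFrame indexed by time with columns ``survival`` and
    ``at_risk``.  Censored subjects leave the risk set without contributing an
    event factor.
    """
    if not records:
        raise ValueError("need at least one record")
    t, e = _times_events(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    out = kmf.survival_function_.rename(columns={"KM_estimate": "survival"})
    out["at_risk"] = kmf.event_table["at_risk"].reindex(out.index)
    return out


def _fit_cox_beta(t: np.ndarray, e: np.ndarray, x: np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Newton maximization of the single-covariate Breslow partial likelihood.

    The risk-set sums S0 = sum e^{bx}, S1 = sum x e^{bx}, S2 = sum x^2 e^{bx}
    over subjects still at risk at each event time are cumulative sums after
    sorting by descending time, so one iteration is O(n log n); steps are
    clipped to +-2 and |beta| capped at 20 (monotone likelihood under complete
    separation).  Vectorized on purpose: the bootstrap protocol refits the
    model thousands of times.
    """
    x = np.asarray(x, dtype=float)
    order = np.argsort(-t, kind="stable")
    t_s, e_s, x_s = t[order], e[order], x[order]
    event_idx = np.flatnonzero(e_s == 1)
    if event_idx.size == 0:
        raise ValueError("no events: Cox model non-estimable")
    # last index whose time >= each event time (ties share the full risk set)
    pos = np.searchsorted(-t_s, -t_s[event_idx], side="right") - 1
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x_s)
        s0 = np.cumsum(w)[pos]
        s1 = np.cumsum(w * x_s)[pos]
        s2 = np.cumsum(w * x_s * x_s)[pos]
        mean = s1 / s0
        grad = float(np.sum(x_s[event_idx] - mean))
        hess = -float(np.sum(s2 / s0 - mean**2))
        if hess >= -1e-300:
            break
        step = np.clip(-grad / hess, -2.0, 2.0)
        beta += step
        if abs(beta) > 20.0:  # separation: likelihood monotone in beta
            beta = float(np.sign(beta) * 20.0)
            break
        if abs(step) < tol:
            break
    return beta


def cox_hr(
    records: list[SurvivalRecord],
    group: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> HazardResult:
    """Univariate Cox hazard ratio of *group* (0/1 or continuous covariate).

    The point estimate maximizes the Breslow partial likelihood; the 95% CI is
    a percentile bootstrap over patients (seeded).  When one group of a binary
    covariate has no events the result is flagged ``non-estimable``.
    """
    group = np.asarray(group, dtype=float)
    t, e = _times_events(records)
    if len(group) != len(t):
        raise ValueError("group indicator length must match records")
    flags: list[str] = []
    binary = set(np.unique(group)) <= {0.0, 1.0}
    if binary:
        for g in (0.0, 1.0):
            sel = group == g
            if not sel.any() or e[sel].sum() == 0:
                return HazardResult(np.nan, np.nan, np.nan, 0, seed, ["non-estimable: no events in a group"])
    beta = _fit_cox_beta(t, e, group)
    hr = float(np.exp(beta))

    rng = np.random.default_rng(seed)
    n = len(t)
    boots = []
    failures = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            boots.append(np.exp(_fit_cox_beta(t[idx], e[idx], group[idx])))
        except Exception:
            failures += 1
    if n_bootstrap and failures > 0.2 * n_bootstrap:
        flags.append(f"bootstrap failed on {failures}/{n_bootstrap} resamples")
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = np.nan
    if np.isfinite(lo) and not (lo <= hr <= hi):
        flags.append("point estimate outside percentile CI")
    return HazardResult(hr, float(lo), float(hi), n_bootstrap, seed, flags)


def _censoring_km(t: np.ndarray, e: np.ndarray):
    """Kaplan-Meier of the censoring distribution G(t) (events flipped)."""
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=1 - e)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def G(q: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(times, q, side="right") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)
        return out

    def G_minus(q: np.ndarray) -> np.ndarray:
        # left limit G(t-): survival just before t
        idx = np.searchsorted(times, q, side="left") - 1
        return np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)

    return G, G_minus


def td_auc(records: list[SurvivalRecord], marker: np.ndarray, horizon_months: float = 48.0) -> TdAucResult:
    """Cumulative/dynamic time-dependent AUC at a horizon, IPCW weighted.

    Cases are subjects with an observed event at or before the horizon;
    controls are subjects still under observation past the horizon.  Case i
    gets weight 1/G(T_i-) and control j weight 1/G(tau), with G the
    Kaplan-Meier estimate of the censoring survival function.  Ties in the
    marker count one half.  With zero censoring all weights are 1 and the
    statistic reduces exactly to the pairwise rank AUC.
    """
    marker = np.asarray(marker, dtype=float)
    t, e = _times_events(records)
    if len(marker) != len(t):
        raise ValueError("marker length must match records")
    case = (t <= horizon_months) & (e == 1)
    control = t > horizon_months
    if not case.any() or not control.any():
        return TdAucResult(np.nan, None, horizon_months, ["non-estimable: no cases or no controls at horizon"])
    G, G_minus = _censoring_km(t, e)
    w_case = 1.0 / G_minus(t[case])
    w_ctrl = np.full(control.sum(), 1.0 / max(G(np.array([horizon_months]))[0], 1e-12))
    mi = marker[case][:, None]
    mj = marker[control][None, :]
    wij = w_case[:, None] * w_ctrl[None, :]
    conc = np.where(mi > mj, 1.0, np.where(mi == mj, 0.5, 0.0))
    auc = float((wij * conc).sum() / wij.sum())
    return TdAucResult(auc, None, horizon_months)


def bootstrap_ci(statistic, records: list[SurvivalRecord], n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Percentile 95% bootstrap CI of ``statistic(list_of_records)``.

    Patients are resampled with replacement.  If the statistic fails on more
    than 20% of resamples a ``RuntimeError`` is raised rather than returning a
    silently biased interval.
    """
    rng = np.random.default_rng(seed)
    n = len(records)
    vals = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            v = statistic([records[i] for i in idx])
            if not np.isfinite(v):
                raise ValueError("non-finite statistic")
            vals.append(v)
        except Exception:
            failures += 1
    if failures > 0.2 * n_boot:
        raise RuntimeError(f"statistic failed on {failures}/{n_boot} bootstrap resamples")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def select_cutoff(values: np.ndarray, records: list[SurvivalRecord] | None, method: str = "median") -> float:
    """Choose a dichotomization cutoff.

    ``median``: the sample median.  ``max_logrank``: the candidate cutoff (at
    the inner deciles, 10%..90%) maximizing the two-group log-rank statistic —
    requires *records*.  ``supplied`` is handled by the caller passing its own
    :class:`CutoffRule`.
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("cannot select a cutoff: all values identical")
    if method == "median":
        return float(np.median(values))
    if method == "max_logrank":
        if records is None:
            raise ValueError("max_logrank needs survival records")
        t, e = _times_events(records)
        best, best_stat = None, -np.inf
        for q in np.arange(0.1, 0.91, 0.1):
            c = float(np.quantile(values, q))
            hi = values > c
            if hi.all() or (~hi).all():
                continue
            res = logrank_test(t[hi], t[~hi], event_observed_A=e[hi], event_observed_B=e[~hi])
            if res.test_statistic > best_stat:
                best, best_stat = c, res.test_statistic
        if best is None:
            raise ValueError("no admissible cutoff candidate")
        return best
    raise ValueError(f"unknown cutoff method {method!r}")
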