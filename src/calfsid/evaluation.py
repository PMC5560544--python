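"""Predictive-performance evaluation: ROC/AUC, Youden cutpoints, rule
sensitivity/specificity, and the decile survival analysis.

The decile analysis mirrors the study design: a laboratory variable is cut
into equal-frequency deciles, the decile whose value range best overlaps
the analyte's reference interval serves as the comparison group, and each
other decile's survival proportion is compared to it with a Pearson
chi-square (df = 1, no continuity correction) at a Bonferroni-adjusted
significance level of 0.05/9 (displayed as P <= 0.006).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "RocCurve",
    "CutpointResult",
    "DecileTable",
    "roc_curve",
    "youden_optimal",
    "binary_rule_performance",
    "decile_survival",
    "REFERENCE_INTERVALS",
]

#: Reference intervals / cut-points used to anchor the decile analysis.
#: GGT uses the failure-of-passive-transfer cut-point (< 50 U/L abnormal)
#: rather than a two-sided interval.
REFERENCE_INTERVALS = {
    "ph": (7.35, 7.45),
    "pco2": (35.0, 45.0),
    "hco3": (25.0, 30.0),
    "base_excess": (-2.0, 2.0),
    "anion_gap": (10.0, 20.0),
    "sig": (-5.0, 5.0),
    "usi": (-5.0, 5.0),
    "na": (135.0, 145.0),
    "k": (3.9, 5.2),
    "cl": (95.0, 105.0),
    "d_lactate": (0.0, 3.96),
    "l_lactate": (0.5, 2.2),
    "glucose": (3.9, 5.6),
    "total_protein": (55.0, 75.0),
    "urea": (2.0, 6.6),
    "creatinine": (50.0, 130.0),
    "ggt": (50.0, float("inf")),
    "leukocytes": (5.0, 12.0),
    "rectal_temp": (38.5, 39.5),
}


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # ascending distinct score values (+inf sentinel)
    sensitivity: np.ndarray  # P(score >= threshold | event)
    specificity: np.ndarray  # P(score < threshold | non-event)
    auc: float
    auc_ci: tuple


@dataclass(frozen=True)
class CutpointResult:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


def _delong_auc_variance(scores, labels):
    """DeLong variance of the AUC via midrank placement values."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = len(x), len(y)
    all_ = np.concatenate([x, y])
    rank_all = stats.rankdata(all_)
    rank_x = stats.rankdata(x)
    rank_y = stats.rankdata(y)
    v10 = (rank_all[:m] - rank_x) / n  # placement of each event among non-events
    v01 = 1.0 - (rank_all[m:] - rank_y) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_curve(scores: Sequence[float], labels: Sequence[int], z: float = 1.96) -> RocCurve:
    """ROC over all distinct score thresholds, with trapezoidal AUC.

    Higher scores must indicate the event class (label 1).  The AUC equals
    the tie-corrected rank statistic P(score_event > score_nonevent) +
    0.5·P(equal); its CI is the DeLong (paired-components) normal interval
    truncated to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores", "scores and labels must be equal-length 1-D")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("labels", "both classes must be present")

    thr = np.unique(s)
    thresholds = np.concatenate([thr, [np.inf]])
    # classify positive when score >= t
    sens = np.array([(s[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(s[y == 0] < t).mean() for t in thresholds])
    auc, var = _delong_auc_variance(s, y)
    half = z * math.sqrt(var)
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        auc_ci=(max(0.0, auc - half), min(1.0, auc + half)),
    )


def youden_optimal(roc: RocCurve) -> CutpointResult:
    """Cutpoint maximizing Youden's J = sensitivity + specificity − 1.

    Ties are broken toward the lowest threshold.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    i = int(np.argmax(j))  # argmax takes first maximum; thresholds ascend
    return CutpointResult(
        threshold=float(roc.thresholds[i]),
        sensitivity=float(roc.sensitivity[i]),
        specificity=float(roc.specificity[i]),
        youden_j=float(j[i]),
    )


def binary_rule_performance(flags, outcomes, z_conf: float = 0.95):
    """Sensitivity/specificity of a binary high-risk rule, with exact CIs.

    ``flags`` is the rule output (1 = flagged high-risk), ``outcomes`` the
    event indicator (1 = non-survival).  Rows with a missing flag are
    excluded and counted.  Returns a dict with the confusion counts,
    sensitivity/specificity and their Clopper-Pearson intervals.
    """
    f = np.asarray(flags, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    ok = ~np.isnan(f) & ~np.isnan(y)
    f, y = f[ok].astype(int), y[ok].astype(int)
    n_excluded = int((~ok).sum())
    events = int((y == 1).sum())
    nonevents = int((y == 0).sum())
    if events == 0:
        raise ValidationError("outcomes", "no events present; sensitivity undefined")
    tp = int(((f == 1) & (y == 1)).sum())
    tn = int(((f == 0) & (y == 0)).sum())

    def clopper_pearson(k, n):
        if n == 0:
            return (float("nan"), float("nan"))
        alpha = 1.0 - z_conf
        lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
        hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
        return (float(lo), float(hi))

    return {
        "sensitivity": tp / events,
        "specificity": tn / nonevents if nonevents else float("nan"),
        "sensitivity_ci": clopper_pearson(tp, events),
        "specificity_ci": clopper_pearson(tn, nonevents),
        "tp": tp,
        "fn": events - tp,
        "tn": tn,
        "fp": nonevents - tn,
        "n_excluded_missing": n_excluded,
    }


@dataclass
class DecileTable:
    """Per-decile survival with chi-square comparisons to a reference decile."""

    table: pd.DataFrame  # decile, low, high, n, survivors, survival, chi2, p, significant
    reference_decile: int
    adjusted_alpha: float
    displayed_alpha: float = 0.006
    notes: list = field(default_factory=list)


def _pearson_chi2_2x2(a_surv, a_tot, b_surv, b_tot):
    table = np.array(
        [[a_surv, a_tot - a_surv], [b_surv, b_tot - b_surv]], dtype=float
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def decile_survival(
    values: Sequence[float],
    outcomes: Sequence[int],
    reference_interval: tuple,
    n_deciles: int = 10,
) -> DecileTable:
    """Equal-frequency decile survival analysis against a reference decile.

    ``outcomes`` is 1 for non-survival.  Deciles are assigned by rank
    (ties fall in a single bin via stable ordering); the reference decile
    is the one whose observed value range has the greatest overlap
    fraction with ``reference_interval`` (ties resolved by the decile
    median closest to the interval midpoint).  Each decile's survival is
    compared to the reference with a df = 1 Pearson chi-square; the
    significance flag uses the Bonferroni-adjusted alpha 0.05/9.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    ok = ~np.isnan(v) & ~np.isnan(y)
    v, y = v[ok], y[ok].astype(int)
    if len(v) < n_deciles:
        raise ValidationError("values", f"need at least {n_deciles} non-missing values")

    order = np.argsort(v, kind="stable")
    bins = np.empty(len(v), dtype=int)
    # rank-based equal-frequency assignment
    bins[order] = (np.arange(len(v)) * n_deciles) // len(v)

    notes = []
    rows = []
    for d in range(n_deciles):
        sel = bins == d
        vals = v[sel]
        n = int(sel.sum())
        surv = int((y[sel] == 0).sum())
        if len(np.unique(vals)) == 1:
            notes.append(f"decile {d + 1} spans the single repeated value {vals[0]:g}")
        rows.append(
            {
                "decile": d + 1,
                "low": float(vals.min()),
                "high": float(vals.max()),
                "n": n,
                "survivors": surv,
                "survival": surv / n,
            }
        )
    tab = pd.DataFrame(rows)

    lo_ref, hi_ref = reference_interval
    overlaps = []
    for r in tab.itertuples():
        width = r.high - r.low
        inter = max(0.0, min(r.high, hi_ref) - max(r.low, lo_ref))
        if width > 0:
            frac = inter / width
        else:  # zero-width decile: in or out of the interval
            frac = 1.0 if lo_ref <= r.low <= hi_ref else 0.0
        overlaps.append(frac)
    overlaps = np.asarray(overlaps)
    if overlaps.max() == 0.0:
        raise ValidationError(
            "reference_interval",
            f"interval {reference_interval} is disjoint from every decile range "
            f"[{tab['low'].min():g}, {tab['high'].max():g}]; check units or the interval",
        )
    best = np.flatnonzero(overlaps == overlaps.max())
    if len(best) > 1:
        mid = (lo_ref + hi_ref) / 2.0
        medians = np.array(
            [float(np.median(v[bins == d])) for d in best]
        )
        best = [best[int(np.argmin(np.abs(medians - mid)))]]
    ref = int(best[0])

    chi2s, ps, sig = [], [], []
    adjusted_alpha = 0.05 / (n_deciles - 1)
    ref_row = tab.iloc[ref]
    for i, r in enumerate(tab.itertuples()):
        if i == ref:
            chi2s.append(float("nan"))
            ps.append(float("nan"))
            sig.append(False)
            continue
        chi2, p = _pearson_chi2_2x2(r.survivors, r.n, ref_row["survivors"], ref_row["n"])
        chi2s.append(chi2)
        ps.append(p)
        sig.append(bool(p <= adjusted_alpha) if not math.isnan(p) else False)
    tab["chi_square"] = chi2s
    tab["p_value"] = ps
    tab["significant"] = sig
    return DecileTable(
        table=tab,
        reference_decile=ref + 1,
        adjusted_alpha=adjusted_alpha,
        notes=notes,
    )
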