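"""ROC construction, AUC, Youden-optimal cutoffs, and Muller AUC banding.

ROC curves are built over marker expression percentages with candidate
cutoffs at the midpoints between consecutive distinct observed values (plus
sentinels below the minimum and above the maximum), which is why optimal
cutoffs on percentages scored on a 5% grid come out as half-integers such as
22.5.  With ``lower_predicts_positive`` (the usual orientation for marker
deficiency in lymphoma), sensitivity at cutoff c is the fraction of
positive-class values strictly below c and specificity the fraction of
negative-class values at or above c.

The AUC is computed by the trapezoidal rule over the full curve, which for
midpoint cutoffs coincides with the Mann-Whitney rank statistic
(concordant pairs plus half ties over all positive/negative pairs).  The
standard error defaults to DeLong's estimator (the empirical variance of
the rank-statistic placements); a Hanley-McNeil SE is available as an
option.  Youden's index J = sensitivity + specificity - 1 selects the
operating point; ties are broken toward higher specificity, then toward the
cutoff nearest the positive-class median, and all near-optimal points are
reported as alternatives so that a slightly sub-optimal, higher-sensitivity
cutoff remains visible.

Muller's value bands the AUC into qualitative discriminative-ability
categories on the conventional 0.1 grid, closed on the left:
fail < 0.6 <= poor < 0.7 <= fair < 0.8 <= good < 0.9 <= excellent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np

from .cohort_model import Label, ValidationError

__all__ = [
    "Direction",
    "MullerBand",
    "OperatingPoint",
    "ROCCurve",
    "CutoffReport",
    "candidate_cutoffs",
    "roc_curve",
    "youden_optimal",
    "muller_band",
]


class Direction(str, Enum):
    LOWER = "lower_predicts_positive"
    HIGHER = "higher_predicts_positive"


class MullerBand(str, Enum):
    FAIL = "fail"
    POOR = "poor"
    FAIR = "fair"
    GOOD = "good"
    EXCELLENT = "excellent"


@dataclass(frozen=True)
class OperatingPoint:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class ROCCurve:
    direction: Direction
    operating_points: tuple[OperatingPoint, ...]
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    n_positive: int
    n_negative: int
    positive_median: float


@dataclass(frozen=True)
class CutoffReport:
    """Youden-optimal operating point with near-optimal alternatives."""

    optimal_cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    auc: float
    muller_band: MullerBand
    alternatives: tuple[OperatingPoint, ...] = ()

    def to_report(self) -> dict:
        return {
            "optimal_cutoff": self.optimal_cutoff,
            "youden_j": self.youden_j,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "muller_band": self.muller_band.value,
            "alternatives": [
                {"cutoff": p.cutoff, "sensitivity": p.sensitivity, "specificity": p.specificity, "youden_j": p.youden_j}
                for p in self.alternatives
            ],
        }


def candidate_cutoffs(values: Sequence[float]) -> np.ndarray:
    """Candidate cutoffs: midpoints between consecutive distinct sorted values,
    plus one sentinel below the minimum and one above the maximum.

    With a single distinct value the cutoff grid degenerates to that value
    and a warning is issued.
    """
    v = np.unique(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValidationError("no values supplied")
    if np.any(~np.isfinite(v)):
        raise ValidationError("values must be finite")
    if v.size == 1:
        warnings.warn("all values identical: degenerate single cutoff", stacklevel=2)
        return v.copy()
    mids = (v[1:] + v[:-1]) / 2.0
    lo = v[0] - (v[1] - v[0]) / 2.0
    hi = v[-1] + (v[-1] - v[-2]) / 2.0
    return np.concatenate([[lo], mids, [hi]])


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong SE of the rank-statistic AUC (higher score = more positive)."""
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    m, n = pos.size, neg.size
    left = np.searchsorted(neg_sorted, pos, side="left")
    right = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (left + 0.5 * (right - left)) / n
    left_p = np.searchsorted(pos_sorted, neg, side="left")
    right_p = np.searchsorted(pos_sorted, neg, side="right")
    v01 = ((m - right_p) + 0.5 * (right_p - left_p)) / m
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return math.sqrt(s10 / m + s01 / n)


def _hanley_mcneil_se(auc: float, m: int, n: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
    return math.sqrt(max(var, 0.0))


def roc_curve(
    values: Sequence[float],
    labels: Sequence[Union[Label, str]],
    direction: Union[Direction, str] = Direction.LOWER,
    positive_label: Union[Label, str] = Label.EARLY_MF,
    se_method: str = "delong",
) -> ROCCurve:
    """Build an ROC curve for one marker over a labeled cohort.

    ``values`` are expression percentages; cases whose label equals
    ``positive_label`` form the positive class, all others the negative
    class.  Both classes must be represented.
    """
    direction = Direction(direction)
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or np.any(~np.isfinite(v)):
        raise ValidationError("values must be a 1-D array of finite numbers")
    positive_label = Label(positive_label) if not isinstance(positive_label, Label) else positive_label
    lab = np.asarray([Label(l).value if not isinstance(l, Label) else l.value for l in labels])
    if lab.shape != v.shape:
        raise ValidationError("values and labels must have the same length")
    is_pos = lab == positive_label.value
    pos, neg = v[is_pos], v[~is_pos]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be represented")

    cuts = candidate_cutoffs(v)
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    if direction is Direction.LOWER:
        sens = np.searchsorted(pos_sorted, cuts, side="left") / pos.size
        spec = 1.0 - np.searchsorted(neg_sorted, cuts, side="left") / neg.size
    else:
        sens = 1.0 - np.searchsorted(pos_sorted, cuts, side="left") / pos.size
        spec = np.searchsorted(neg_sorted, cuts, side="left") / neg.size
    points = tuple(
        OperatingPoint(float(c), float(s), float(sp)) for c, s, sp in zip(cuts, sens, spec)
    )

    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))

    score_pos = -pos if direction is Direction.LOWER else pos
    score_neg = -neg if direction is Direction.LOWER else neg
    if se_method == "delong":
        se = _delong_se(score_pos, score_neg)
    elif se_method == "hanley":
        se = _hanley_mcneil_se(auc, pos.size, neg.size)
    else:
        raise ValidationError(f"unknown se_method {se_method!r}; expected 'delong' or 'hanley'")
    ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))

    return ROCCurve(
        direction=direction,
        operating_points=points,
        auc=auc,
        auc_se=se,
        ci95=ci,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
        positive_median=float(np.median(pos)),
    )


def youden_optimal(curve: ROCCurve, j_margin: float = 0.05) -> CutoffReport:
    """Operating point maximizing Youden's J, with near-optimal alternatives.

    Ties on J are broken toward higher specificity, then toward the cutoff
    nearest the positive-class median.  Every other point whose J lies
    within ``j_margin`` of the optimum is listed as an alternative, ordered
    by decreasing J then decreasing sensitivity.
    """
    if not curve.operating_points:
        raise ValidationError("curve has no operating points")
    best = max(
        curve.operating_points,
        key=lambda p: (p.youden_j, p.specificity, -abs(p.cutoff - curve.positive_median)),
    )
    alternatives = tuple(
        sorted(
            (p for p in curve.operating_points if p is not best and p.youden_j >= best.youden_j - j_margin),
            key=lambda p: (-p.youden_j, -p.sensitivity, p.cutoff),
        )
    )
    return CutoffReport(
        optimal_cutoff=best.cutoff,
        youden_j=best.youden_j,
        sensitivity=best.sensitivity,
        specificity=best.specificity,
        auc=curve.auc,
        muller_band=muller_band(curve.auc),
        alternatives=alternatives,
    )


def muller_band(auc: float) -> MullerBand:
    """Qualitative discriminative-ability band for an AUC.

    Bands are 0.1-wide and closed on the left: an AUC of exactly 0.6 is
    'poor', 0.9 is 'excellent'.
    """
    if not (0.0 <= auc <= 1.0) or not math.isfinite(auc):
        raise ValidationError(f"auc={auc!r}: must be in [0, 1]")
    if auc < 0.6:
        return MullerBand.FAIL
    if auc < 0.7:
        return MullerBand.POOR
    if auc < 0.8:
        return MullerBand.FAIR
    if auc < 0.9:
        return MullerBand.GOOD
    return MullerBand.EXCELLENT
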