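"""Confusion rates, ROC sweeps and enrichment tests.

A feature's predictive value for splice-site identification is assessed
by sweeping a cutoff over its range, classifying sites on each side
according to the feature's orientation (e.g. small distances or large SVM
scores predict "splice"), and tracing the true-positive rate
TPR = TP/(TP+FN) against the false-positive rate FPR = FP/(FP+TN).  The
area under the curve (AUC) is integrated by the trapezoid rule with the
(0,0) and (1,1) anchor points; the operating cutoff reported is the
Youden point, the cutoff maximising TPR - FPR (equivalently, the ROC
point furthest from the chance diagonal).

Distribution shifts between native-site and background feature values use
the two-sided Wilcoxon rank-sum test; category-frequency differences use
Pearson's chi-squared test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import InteinSiteError

__all__ = [
    "Orientation",
    "ROCCurve",
    "confusion_rates",
    "roc_sweep",
    "data_cutoff_grid",
    "wilcoxon_rank_sum",
    "chi_squared",
]

#: How feature values map to positive calls at a cutoff c:
#: ``greater``: value > c; ``less``: value < c; ``geq``: value >= c;
#: ``leq``: value <= c.
Orientation = Literal["greater", "less", "geq", "leq"]

_POSITIVE_CALL = {
    "greater": lambda v, c: v > c,
    "less": lambda v, c: v < c,
    "geq": lambda v, c: v >= c,
    "leq": lambda v, c: v <= c,
}


def confusion_rates(
    labels: Sequence[bool], predictions: Sequence[bool]
) -> dict:
    """TP/FP/TN/FN counts and TPR/FPR for boolean labels vs predictions.

    ``TPR = TP/(TP+FN)`` and ``FPR = FP/(FP+TN)``; a rate whose
    denominator is zero is reported as ``None`` (missing), never 0.
    """
    if len(labels) != len(predictions):
        raise InteinSiteError(
            f"labels ({len(labels)}) and predictions ({len(predictions)}) "
            "differ in length"
        )
    if len(labels) == 0:
        raise InteinSiteError("empty label vector")
    tp = fp = tn = fn = 0
    for lab, pred in zip(labels, predictions):
        if pred:
            if lab:
                tp += 1
            else:
                fp += 1
        else:
            if lab:
                fn += 1
            else:
                tn += 1
    tpr = tp / (tp + fn) if tp + fn else None
    fpr = fp / (fp + tn) if fp + tn else None
    return {"TP": tp, "FP": fp, "TN": tn, "FN": fn, "TPR": tpr, "FPR": fpr}


@dataclass(frozen=True)
class ROCCurve:
    """Cutoff sweep of one feature: (cutoff, TPR, FPR) points + summary."""

    points: tuple[tuple[float, float, float], ...]
    auc: float
    youden_cutoff: float
    orientation: Orientation

    def __post_init__(self) -> None:
        if not -1e-12 <= self.auc <= 1 + 1e-12:
            raise InteinSiteError(f"AUC {self.auc} outside [0, 1]")
        for _, tpr, fpr in self.points:
            if not (0 <= tpr <= 1 and 0 <= fpr <= 1):
                raise InteinSiteError("TPR/FPR outside [0, 1]")

    @property
    def youden_j(self) -> float:
        best = max(tpr - fpr for _, tpr, fpr in self.points)
        return best

    def to_rows(self) -> list[tuple[float, float, float]]:
        return list(self.points)


def data_cutoff_grid(
    values: Sequence[float], orientation: Orientation
) -> np.ndarray:
    """A cutoff grid from the data itself: midpoints between unique values
    plus sentinels beyond both extremes, so every achievable confusion
    table appears exactly once in the sweep."""
    vals = np.unique(np.asarray(values, dtype=float))
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return np.array([0.0, 1.0])
    mids = (finite[:-1] + finite[1:]) / 2.0
    lo, hi = finite[0] - 1.0, finite[-1] + 1.0
    return np.sort(np.concatenate([[lo], finite, mids, [hi]]))


def roc_sweep(
    values: Sequence[float],
    labels: Sequence[bool],
    cutoffs: Sequence[float],
    orientation: Orientation,
) -> ROCCurve:
    """Sweep ``cutoffs`` over one feature and build the ROC curve.

    At each cutoff, sites are called positive per ``orientation`` (strict
    comparisons for ``greater``/``less``, closed for ``geq``/``leq``) and
    the (TPR, FPR) pair recorded.  AUC is the trapezoid integral of TPR
    over FPR after sorting by (FPR, TPR) and anchoring at (0,0) and (1,1).
    The Youden cutoff maximises TPR - FPR; ties go to the more stringent
    cutoff (the one calling fewer sites positive).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise InteinSiteError("values and labels differ in length")
    if labels.all() or not labels.any():
        raise InteinSiteError(
            "ROC requires at least one positive and one negative label"
        )
    if orientation not in _POSITIVE_CALL:
        raise InteinSiteError(f"unknown orientation {orientation!r}")
    call = _POSITIVE_CALL[orientation]

    points = []
    for c in cutoffs:
        preds = call(values, c)
        r = confusion_rates(labels, preds)
        points.append((float(c), r["TPR"], r["FPR"]))

    # AUC: trapezoid over (FPR, TPR), anchored
    fpr_tpr = sorted({(fpr, tpr) for _, tpr, fpr in points})
    fpr_tpr = [(0.0, 0.0)] + fpr_tpr + [(1.0, 1.0)]
    xs = np.array([p[0] for p in fpr_tpr])
    ys = np.array([p[1] for p in fpr_tpr])
    auc = float(np.trapezoid(ys, xs))

    # Youden point; stringent = fewer positive calls on tie
    stringent_high = orientation in ("greater", "geq")
    best = None
    for c, tpr, fpr in points:
        j = tpr - fpr
        if (
            best is None
            or j > best[0] + 1e-15
            or (
                abs(j - best[0]) <= 1e-15
                and ((c > best[1]) if stringent_high else (c < best[1]))
            )
        ):
            best = (j, c)
    return ROCCurve(
        points=tuple(points),
        auc=auc,
        youden_cutoff=best[1],
        orientation=orientation,
    )


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a location shift.

    Exact enumeration for small tie-free samples (both n <= 20), otherwise
    the normal approximation with tie correction (and continuity
    correction), via the equivalent Mann-Whitney U statistic.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InteinSiteError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact" if (x.size <= 20 and y.size <= 20 and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def chi_squared(table: Sequence[Sequence[float]]) -> float:
    """Upper-tail p-value of Pearson's chi-squared test of independence.

    ``table`` is an r x c array of observed counts (r, c >= 2); expected
    counts come from the marginals and the statistic is referred to the
    chi-squared distribution with (r-1)(c-1) degrees of freedom, without
    continuity correction.
    """
    from scipy import stats

    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise InteinSiteError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise InteinSiteError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise InteinSiteError("every row and column must have a positive sum")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.pvalue)
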