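"""Test-set evaluation: ROC/AUC, precision-recall/average precision, the
F1-optimal threshold, operating points under a false-positive-rate budget,
score group comparison and a calibration table.

Curves are built by scanning every distinct score as a threshold (a subject
is called positive when score >= threshold), with tied scores grouped so that
ties never split a threshold.  AUC is the trapezoidal area, which on these
thresholds equals the Mann-Whitney rank statistic; average precision is the
step-wise sum Σ (R_k − R_{k−1})·P_k.  Both are invariant under strictly
increasing transforms of the scores, so logits and probabilities give
identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu


def _validate(scores, labels, need_both: bool = True):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same shape")
    if need_both and (y.sum() == 0 or y.sum() == len(y)):
        raise ValueError("both outcome classes must be present")
    return s, y


def _threshold_counts(s: np.ndarray, y: np.ndarray):
    """Cumulative tp/fp after each distinct-score group, scores descending.

    Returns (thresholds, tp, fp): calling everything with score >= thresholds[i]
    positive yields tp[i] true and fp[i] false positives.
    """
    order = np.argsort(-s, kind="mergesort")
    s_ord, y_ord = s[order], y[order]
    # last index of each tied group
    last = np.r_[np.nonzero(np.diff(s_ord))[0], len(s_ord) - 1]
    tp = np.cumsum(y_ord)[last]
    fp = np.cumsum(1 - y_ord)[last]
    return s_ord[last], tp, fp


def roc_points(scores, labels):
    """ROC curve on all distinct-score thresholds plus the (0, 0) origin.

    Returns ``(fpr, tpr, thresholds)``; thresholds[0] is +inf for the empty
    prediction set.
    """
    s, y = _validate(scores, labels)
    thr, tp, fp = _threshold_counts(s, y)
    P, N = y.sum(), len(y) - y.sum()
    fpr = np.r_[0.0, fp / N]
    tpr = np.r_[0.0, tp / P]
    return fpr, tpr, np.r_[np.inf, thr]


def roc_auc(scores, labels) -> float:
    """Trapezoidal area under the ROC curve."""
    fpr, tpr, _ = roc_points(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def pr_points(scores, labels):
    """Precision-recall points at all distinct-score thresholds (descending).

    Returns ``(recall, precision, thresholds)`` without interpolation.
    """
    s, y = _validate(scores, labels, need_both=False)
    if y.sum() == 0:
        raise ValueError("average precision needs at least one positive")
    thr, tp, fp = _threshold_counts(s, y)
    recall = tp / y.sum()
    precision = tp / (tp + fp)
    return recall, precision, thr


def average_precision(scores, labels) -> float:
    """Step-wise AP: Σ_k (R_k − R_{k−1})·P_k over descending thresholds."""
    recall, precision, _ = pr_points(scores, labels)
    dr = np.diff(np.r_[0.0, recall])
    return float((dr * precision).sum())


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fpr: float
    precision: Optional[float]

    def to_dict(self) -> dict:
        return asdict(self)


def operating_point(scores, labels, target_fpr: float) -> OperatingPoint:
    """Best achievable operating point under an FPR budget.

    Among all distinct-score thresholds whose empirical false-positive rate
    does not exceed ``target_fpr``, the one maximizing the true-positive rate
    is returned; ties go to the larger threshold (fewer false positives).
    The empty prediction set (threshold +inf, fpr 0) is always feasible.
    """
    if not (0.0 <= target_fpr <= 1.0):
        raise ValueError("target_fpr must lie in [0, 1]")
    s, y = _validate(scores, labels)
    thr, tp, fp = _threshold_counts(s, y)
    P, N = int(y.sum()), int(len(y) - y.sum())
    best = (math.inf, 0, 0)  # threshold, tp, fp
    for t, tpi, fpi in zip(thr, tp, fp):
        if fpi / N <= target_fpr and tpi > best[1]:
            best = (float(t), int(tpi), int(fpi))
    t, tpi, fpi = best
    return OperatingPoint(
        threshold=t, tp=tpi, fp=fpi, tn=N - fpi, fn=P - tpi,
        tpr=tpi / P, fpr=fpi / N,
        precision=tpi / (tpi + fpi) if tpi + fpi > 0 else None,
    )


def best_f1(scores, labels):
    """Threshold maximizing the harmonic mean of precision and recall.

    All distinct scores are scanned; exact ties in F1 resolve to the lower
    threshold (higher recall).  Returns ``(threshold, f1)``.
    """
    s, y = _validate(scores, labels, need_both=False)
    if y.sum() == 0:
        raise ValueError("F1 needs at least one positive")
    thr, tp, fp = _threshold_counts(s, y)
    P = y.sum()
    f1 = 2 * tp / (P + tp + fp)  # == 2PR/(P+R) with no 0/0 risk (tp+fp >= 1)
    best = int(np.flatnonzero(f1 == f1.max())[-1])  # lowest tied threshold
    return float(thr[best]), float(f1[best])


def compare_groups(logits, labels):
    """Two-sided Mann-Whitney U comparing event vs non-event score
    distributions: exact null when the combined sample is at most 25 and
    tie-free, tie-corrected normal approximation otherwise.

    Returns ``(U statistic, p value)``.
    """
    s, y = _validate(logits, labels)
    a, b = s[y == 1], s[y == 0]
    exact = len(s) <= 25 and len(np.unique(s)) == len(s)
    res = mannwhitneyu(a, b, alternative="two-sided",
                       method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def calibration_table(probabilities, labels, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width reliability table on [0, 1].

    One row per bin with its occupancy, mean predicted probability and
    observed event rate (NaN for empty bins, which are still reported).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        cnt = int(sel.sum())
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1], "count": cnt,
            "mean_predicted": float(p[sel].mean()) if cnt else math.nan,
            "observed_rate": float(y[sel].mean()) if cnt else math.nan,
        })
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Everything the test-set evaluation produces, JSON-serializable."""

    auc: float
    average_precision: float
    best_f1_threshold: float
    best_f1: float
    operating: OperatingPoint
    group_statistic: float
    group_p_value: float
    roc: dict
    pr: dict
    calibration: list

    def to_dict(self) -> dict:
        d = asdict(self)
        d["operating"] = self.operating.to_dict()
        return d


def evaluate_scores(logits, labels, target_fpr: float = 1.0 / 15.0,
                    n_calibration_bins: int = 10) -> EvaluationReport:
    """Full evaluation of logit scores against binary labels.

    Probabilities for the calibration table are the logistic of the logits;
    every ranking metric is computed on the logits (equivalently on the
    probabilities, by monotone invariance).
    """
    from scipy.special import expit

    s, y = _validate(logits, labels)
    fpr, tpr, roc_thr = roc_points(s, y)
    recall, precision, pr_thr = pr_points(s, y)
    thr_f1, f1 = best_f1(s, y)
    op = operating_point(s, y, target_fpr)
    stat, p = compare_groups(s, y)
    cal = calibration_table(expit(s), y, n_bins=n_calibration_bins)
    return EvaluationReport(
        auc=roc_auc(s, y),
        average_precision=average_precision(s, y),
        best_f1_threshold=thr_f1, best_f1=f1, operating=op,
        group_statistic=stat, group_p_value=p,
        roc={"fpr": fpr.tolist(), "tpr": tpr.tolist(),
             "thresholds": [float(t) for t in roc_thr]},
        pr={"recall": recall.tolist(), "precision": precision.tolist(),
            "thresholds": pr_thr.tolist()},
        calibration=calibration_table(expit(s), y, n_bins=n_calibration_bins)
        .to_dict(orient="records"),
    )
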