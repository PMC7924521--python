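"""Model assessment: ROC/AUC, accuracy, calibration curve and error.

Discrimination is summarized by the area under the ROC curve (probability
of concordance with half credit for ties) and by accuracy at the risk-0.5
operating point.  Calibration compares predicted risks with empirical
risks grouped by distinct predicted value: a weighted least-squares line
``empirical = a_cal * predicted + b_cal`` (ideal: slope 1, bias 0), and the
scalar calibration error

    e = integral_0^1 | (a_cal - 1) p + b_cal | dp,

the L1 distance between the fitted and the ideal calibration line over the
unit risk range, evaluated in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn import metrics as _skm


@dataclass
class AssessmentReport:
    auc: float
    accuracy: float
    roc: list  # ordered (fpr, tpr) pairs from (0,0) to (1,1)
    a_cal: float
    b_cal: float
    calibration_error: float
    n_intervals: int
    n_variables: int
    split: str = "train"

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        lines = [
            f"[{self.split}] AUC       {self.auc:.3f}",
            f"[{self.split}] accuracy  {self.accuracy:.3f}",
            f"[{self.split}] slope     {self.a_cal:.3f}" if np.isfinite(self.a_cal)
            else f"[{self.split}] slope     n/a",
            f"[{self.split}] bias      {self.b_cal:.3f}" if np.isfinite(self.b_cal)
            else f"[{self.split}] bias      n/a",
            f"[{self.split}] cal.err   {self.calibration_error:.4f}"
            if np.isfinite(self.calibration_error)
            else f"[{self.split}] cal.err   n/a",
            f"[{self.split}] intervals {self.n_intervals}  variables {self.n_variables}",
        ]
        return "\n".join(lines)


def roc_auc(scores: np.ndarray, y: np.ndarray):
    """ROC curve by threshold sweep and Mann-Whitney AUC.

    Returns ``(roc, auc)`` where ``roc`` is an (m, 2) array of (fpr, tpr)
    points starting at (0, 0) and ending at (1, 1).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    pos = y > 0
    if pos.all() or (~pos).all():
        raise ValueError("ROC needs at least one positive and one negative")
    auc = float(_skm.roc_auc_score(pos, scores))
    fpr, tpr, _ = _skm.roc_curve(pos, scores)
    roc = np.column_stack([fpr, tpr])
    return roc, auc


def accuracy(scores: np.ndarray, y: np.ndarray, threshold: float) -> float:
    """Fraction of sign-correct classifications: predict +1 iff
    ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    pred = np.where(scores >= threshold, 1.0, -1.0)
    return float(np.mean(pred == y))


def calibration_curve(pred_risk: np.ndarray, y: np.ndarray):
    """Weighted LS fit of empirical on predicted risk.

    Observations are grouped by distinct predicted risk; each group's
    empirical risk is its positive fraction and its weight its size.
    """
    pred_risk = np.asarray(pred_risk, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    levels = np.unique(pred_risk)
    if len(levels) < 2:
        raise ValueError(
            "calibration slope undefined with fewer than 2 distinct risks"
        )
    emp = np.array([np.mean(y[pred_risk == p] > 0) for p in levels])
    wts = np.array([np.sum(pred_risk == p) for p in levels], dtype=float)
    a_cal, b_cal = np.polyfit(levels, emp, 1, w=np.sqrt(wts))
    return float(a_cal), float(b_cal)


def calibration_error(a_cal: float, b_cal: float) -> float:
    """Closed-form integral of |(a_cal - 1) p + b_cal| over p in [0, 1].

    The integrand is affine; if it changes sign inside [0, 1] the integral
    splits at the root into two triangle areas.
    """
    c = a_cal - 1.0
    if c == 0.0:
        return abs(b_cal)
    p_star = -b_cal / c
    f0, f1 = b_cal, c + b_cal
    if 0.0 < p_star < 1.0 and f0 * f1 < 0:
        # two triangles with heights |f0| and |f1|
        return 0.5 * (abs(f0) * p_star + abs(f1) * (1.0 - p_star))
    return abs(0.5 * c + b_cal)


def assess(model, X: np.ndarray, y: np.ndarray, split: str = "train") -> AssessmentReport:
    """Full report for a fitted :class:`~intervalscore.pipeline.ScoreModel`
    on data with labels in the original or {-1,+1} coding."""
    scores, risks, _ = model.apply(X)
    y_pm = model.map_labels(y)
    roc, auc = roc_auc(scores.astype(float), y_pm)
    acc = accuracy(risks, y_pm, 0.5)
    try:
        a_cal, b_cal = calibration_curve(risks, y_pm)
        e = calibration_error(a_cal, b_cal)
    except ValueError:
        a_cal = b_cal = e = float("nan")
    return AssessmentReport(
        auc=auc,
        accuracy=acc,
        roc=roc.tolist(),
        a_cal=a_cal,
        b_cal=b_cal,
        calibration_error=e,
        n_intervals=model.n_intervals,
        n_variables=model.n_variables,
        split=split,
    )
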