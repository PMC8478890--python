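"""Per-volunteer ROC thresholding of the heart-rate change rate.

For each volunteer the labeled walking intervals give a score (HR%) and a
binary state (safe 0 / risk 1).  Sweeping a threshold grid at a fixed
spacing yields confusion counts

    Z_TP, Z_FN, Z_FP, Z_TN    (an interval is judged "risk" iff HR% ≥ θ)

from which sensitivity T = Z_TP/(Z_TP+Z_FN), false-positive rate
F = Z_FP/(Z_FP+Z_TN) and the Youden index J = T − F follow.  The threshold
maximising J (ties broken toward the upper-left of the curve: smaller F,
then smaller θ) is the volunteer's HR% risk cutpoint; the trapezoidal area
under the (F, T) curve gates reliability (AUC > 0.9).  The HR% cutpoint is
mapped to a PM2.5 concentration by averaging the PM2.5 of intervals whose
HR% lies within a tolerance of the cutpoint.

Everything here is computed per volunteer, never pooled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import VolunteerProfile

__all__ = [
    "DEFAULT_STEP",
    "DEFAULT_AUC_GATE",
    "RocCurve",
    "ThresholdResult",
    "confusion_counts",
    "roc_curve",
    "optimal_threshold",
    "map_hr_to_pm25",
    "cohort_thresholds",
]

logger = logging.getLogger(__name__)

#: default HR% grid spacing for the threshold sweep (fraction scale)
DEFAULT_STEP = 0.005
#: AUC above which a volunteer's curve counts as reliable
DEFAULT_AUC_GATE = 0.9

_POINT_COLUMNS = ("threshold", "tpr", "fpr", "youden", "tp", "fn", "fp", "tn")


@dataclass
class RocCurve:
    """Threshold sweep for one volunteer.

    ``points`` has one row per grid threshold (ascending) with columns
    threshold, tpr, fpr, youden, tp, fn, fp, tn.  ``auc`` is NaN when the
    labels contain a single class.
    """

    volunteer_id: str
    points: pd.DataFrame
    auc: float
    reliable: bool
    single_class: bool = False


@dataclass
class ThresholdResult:
    """Selected HR% cutpoint and its PM2.5 image for one volunteer."""

    volunteer_id: str
    hr_threshold: float
    pm25_threshold: float
    youden_max: float
    auc: float
    reliable: bool


def confusion_counts(scores, labels, threshold: float) -> tuple[int, int, int, int]:
    """Cross-tabulate judgment (HR% ≥ θ ⇒ risk) against the labels.

    Returns ``(Z_TP, Z_FN, Z_FP, Z_TN)``; the four counts always sum to the
    number of records.  Single-class inputs are allowed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("need at least one labeled record")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 (safe) or 1 (risk)")
    judged = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(judged & pos))
    fn = int(np.sum(~judged & pos))
    fp = int(np.sum(judged & ~pos))
    tn = int(np.sum(~judged & ~pos))
    return tp, fn, fp, tn


def _grid(scores: np.ndarray, step: float) -> np.ndarray:
    """Threshold grid at spacing ``step`` spanning [min − step, max + step]."""
    lo = scores.min() - step
    hi = scores.max() + step
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def roc_curve(
    scores,
    labels,
    step: float = DEFAULT_STEP,
    volunteer_id: str = "",
    auc_gate: float = DEFAULT_AUC_GATE,
) -> RocCurve:
    """Sweep the threshold grid and build the ROC curve.

    AUC is the trapezoidal area over the (F, T) points sorted by F with
    (0,0) and (1,1) anchors appended.  If the labels contain one class the
    curve is returned flagged, with NaN rates/AUC and ``reliable=False``.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    thresholds = _grid(scores, step)

    judged = scores[None, :] >= thresholds[:, None]
    pos = labels == 1
    tp = (judged & pos).sum(axis=1)
    fp = (judged & ~pos).sum(axis=1)
    n_pos = int(pos.sum())
    n_neg = int(scores.size - n_pos)
    fn = n_pos - tp
    tn = n_neg - fp

    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(n_pos > 0, tp / max(n_pos, 1), np.nan)
        fpr = np.where(n_neg > 0, fp / max(n_neg, 1), np.nan)
    youden = tpr - fpr

    points = pd.DataFrame(
        {
            "threshold": thresholds,
            "tpr": tpr,
            "fpr": fpr,
            "youden": youden,
            "tp": tp,
            "fn": fn,
            "fp": fp,
            "tn": tn,
        },
        columns=list(_POINT_COLUMNS),
    )

    single_class = n_pos == 0 or n_neg == 0
    if single_class:
        warnings.warn(
            f"{volunteer_id or 'records'}: single-class labels; ROC undefined (AUC=NaN)"
        )
        return RocCurve(volunteer_id, points, float("nan"), False, single_class=True)

    order = np.lexsort((tpr, fpr))
    fx = np.concatenate([[0.0], fpr[order], [1.0]])
    ty = np.concatenate([[0.0], tpr[order], [1.0]])
    auc = float(np.trapezoid(ty, fx))
    return RocCurve(volunteer_id, points, auc, bool(auc > auc_gate))


def optimal_threshold(curve: RocCurve) -> tuple[float, float]:
    """Youden-optimal threshold of a curve.

    Returns ``(threshold, youden_max)``; ties at the maximal Youden index
    are broken by smaller FPR, then by smaller threshold (the upper-left
    preference).  Raises if every point has an undefined Youden index.
    """
    pts = curve.points
    youden = pts["youden"].to_numpy()
    finite = np.isfinite(youden)
    if not finite.any():
        raise ValueError(f"{curve.volunteer_id or 'curve'}: Youden index undefined at every point")
    jmax = np.nanmax(youden[finite])
    cand = pts.loc[finite & (youden >= jmax - 1e-12)]
    cand = cand.sort_values(["fpr", "threshold"], kind="mergesort")
    best = cand.iloc[0]
    return float(best["threshold"]), float(jmax)


def map_hr_to_pm25(
    hr_percent,
    mean_pm25,
    hr_threshold: float,
    tolerance: float = DEFAULT_STEP / 2.0,
) -> float:
    """Average PM2.5 of intervals whose HR% lies near the HR% cutpoint.

    The cutpoint may correspond to several PM2.5 values; their arithmetic
    mean is the concentration threshold.  If no interval falls within the
    tolerance, the tolerance doubles (logged) until at least one matches.
    """
    hr_percent = np.asarray(hr_percent, dtype=float)
    mean_pm25 = np.asarray(mean_pm25, dtype=float)
    if hr_percent.size == 0:
        raise ValueError("no records to map the HR% threshold onto")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    tol = float(tolerance)
    while True:
        match = np.abs(hr_percent - hr_threshold) <= tol
        if match.any():
            return float(mean_pm25[match].mean())
        tol *= 2.0
        logger.info("no interval within %.4g of HR%% threshold; widening tolerance to %.4g", tol / 2, tol)


def cohort_thresholds(
    intervals: pd.DataFrame,
    profiles: Iterable[VolunteerProfile] | None = None,
    step: float = DEFAULT_STEP,
    auc_gate: float = DEFAULT_AUC_GATE,
) -> tuple[pd.DataFrame, dict]:
    """Per-volunteer threshold estimation over a labeled interval table.

    ``intervals`` needs columns volunteer_id, hr_percent, mean_pm25, state.
    Volunteers whose labeled records are missing, single-class, or fewer
    than two are excluded and listed in the summary.  Returns
    ``(thresholds, summary)`` where ``thresholds`` has one row per
    evaluated volunteer (volunteer_id, hr_threshold, pm25_threshold,
    youden_max, auc, reliable) and ``summary`` reports reliability counts
    and, when profiles are supplied, group-wise mean PM2.5 thresholds by
    gender, age group and BMI band.
    """
    results: list[ThresholdResult] = []
    excluded: list[str] = []
    for vid, sub in intervals.groupby("volunteer_id", sort=True):
        labeled = sub.dropna(subset=["state"])
        if len(labeled) < 2 or labeled["state"].nunique() < 2:
            excluded.append(str(vid))
            continue
        curve = roc_curve(
            labeled["hr_percent"].to_numpy(),
            labeled["state"].to_numpy().astype(int),
            step=step,
            volunteer_id=str(vid),
            auc_gate=auc_gate,
        )
        thr, jmax = optimal_threshold(curve)
        pm = map_hr_to_pm25(
            labeled["hr_percent"].to_numpy(), labeled["mean_pm25"].to_numpy(), thr, step / 2.0
        )
        results.append(ThresholdResult(str(vid), thr, pm, jmax, curve.auc, curve.reliable))
    if excluded:
        warnings.warn(f"{len(excluded)} volunteer(s) excluded (unlabeled or single-class labels)")

    thresholds = pd.DataFrame(
        [
            {
                "volunteer_id": r.volunteer_id,
                "hr_threshold": r.hr_threshold,
                "pm25_threshold": r.pm25_threshold,
                "youden_max": r.youden_max,
                "auc": r.auc,
                "reliable": r.reliable,
            }
            for r in results
        ],
        columns=["volunteer_id", "hr_threshold", "pm25_threshold", "youden_max", "auc", "reliable"],
    )

    summary: dict = {
        "n_volunteers": int(intervals["volunteer_id"].nunique()),
        "n_evaluated": int(len(thresholds)),
        "n_reliable": int(thresholds["reliable"].sum()) if len(thresholds) else 0,
        "excluded": excluded,
    }
    summary["frac_reliable"] = (
        summary["n_reliable"] / summary["n_evaluated"] if summary["n_evaluated"] else float("nan")
    )

    if profiles is not None and len(thresholds):
        by_id = {p.volunteer_id: p for p in profiles}
        meta = pd.DataFrame(
            [
                {
                    "volunteer_id": vid,
                    "gender": by_id[vid].gender,
                    "age_group": by_id[vid].age_group,
                    "bmi_healthy": by_id[vid].bmi_healthy,
                }
                for vid in thresholds["volunteer_id"]
                if vid in by_id
            ]
        )
        merged = thresholds.merge(meta, on="volunteer_id")
        summary["group_mean_pm25_threshold"] = {
            "by_gender": merged.groupby("gender")["pm25_threshold"].mean().to_dict(),
            "by_age_group": merged.groupby("age_group")["pm25_threshold"].mean().to_dict(),
            "by_bmi_healthy": {
                str(bool(k)): v
                for k, v in merged.groupby("bmi_healthy")["pm25_threshold"].mean().to_dict().items()
            },
        }
        summary["hr_threshold_percent"] = {
            "min": float(100 * merged["hr_threshold"].min()),
            "mean": float(100 * merged["hr_threshold"].mean()),
            "max": float(100 * merged["hr_threshold"].max()),
        }
    return thresholds, summary
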