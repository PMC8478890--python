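"""Interval aggregation and exposure diagnostics.

Aligns the 1 Hz heart-rate series and the 1-min particulate series onto
half-open windows [k·Δ, (k+1)·Δ), computes the heart-rate change rate

    HR% = (t_i − t) / t

(interval-mean heart rate t_i relative to the resting baseline t), the
body-mass index BMI = weight / height², the window-length diagnostic
(pooled regression F of heart rate on PM2.5), and the absolute Pearson
correlation screen over the logit design variables.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import VolunteerProfile, WalkRecording

__all__ = [
    "BMI_HEALTHY_RANGE",
    "DEFAULT_INTERVAL_S",
    "CANDIDATE_INTERVALS",
    "INTERVAL_COLUMNS",
    "compute_hr_percent",
    "compute_bmi",
    "aggregate_intervals",
    "aggregate_cohort",
    "interval_diagnostics",
    "join_profiles",
    "pearson_matrix",
    "correlation_strength",
]

BMI_HEALTHY_RANGE = (18.5, 24.0)
DEFAULT_INTERVAL_S = 60.0
#: candidate aggregation windows screened by the F diagnostic (s)
CANDIDATE_INTERVALS = (30.0, 60.0, 120.0, 180.0, 240.0, 300.0)

#: schema of the interval table; ``state`` is 0 (safe), 1 (risk) or NaN
INTERVAL_COLUMNS = (
    "volunteer_id",
    "interval_index",
    "mean_hr",
    "hr_percent",
    "mean_pm25",
    "mean_pm10",
    "state",
)


def compute_hr_percent(mean_hr, baseline_hr):
    """Heart-rate change rate (t_i − t)/t as a dimensionless fraction.

    May be negative (heart rate below baseline).  Accepts scalars or
    arrays; ``baseline_hr`` must be strictly positive.
    """
    baseline = np.asarray(baseline_hr, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline_hr must be > 0 bpm")
    out = (np.asarray(mean_hr, dtype=float) - baseline) / baseline
    return float(out) if np.ndim(out) == 0 else out


def compute_bmi(weight: float, height: float) -> tuple[float, bool]:
    """BMI = weight/height² (kg/m²) and whether it lies in [18.5, 24]."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be > 0")
    bmi = weight / height**2
    lo, hi = BMI_HEALTHY_RANGE
    return bmi, bool(lo <= bmi <= hi)


def aggregate_intervals(
    recording: WalkRecording,
    profile: VolunteerProfile,
    interval_s: float = DEFAULT_INTERVAL_S,
) -> pd.DataFrame:
    """Aggregate one recording into fixed half-open windows.

    Windows tile the recording as [k·Δ, (k+1)·Δ); a trailing partial window
    is kept only if it spans at least Δ/2.  ``mean_hr`` averages the 1 Hz
    samples in the window, ``mean_pm25``/``mean_pm10`` average the PM
    samples whose timestamps fall in the window.  Windows containing no PM
    sample are excluded with a warning.  ``state`` carries the subjective
    label when the window grid coincides with the label grid (the PM
    sampling interval); otherwise the interval is unlabeled (NaN).

    Returns a DataFrame with :data:`INTERVAL_COLUMNS`.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be > 0")
    if recording.hr_time.size == 0 or recording.pm_time.size == 0:
        raise ValueError("empty heart-rate or PM series")

    hr_t = np.asarray(recording.hr_time, dtype=float)
    pm_t = np.asarray(recording.pm_time, dtype=float)
    duration = hr_t[-1] + 1.0  # 1 Hz samples stamp the start of each second
    n_windows = int(np.ceil(duration / interval_s))

    hr_idx = (hr_t // interval_s).astype(int)
    pm_idx = (pm_t // interval_s).astype(int)

    label_spacing = pm_t[1] - pm_t[0] if pm_t.size > 1 else None
    labels_align = (
        recording.labels is not None
        and recording.labels.size == pm_t.size
        and (label_spacing is None or np.isclose(label_spacing, interval_s))
        and np.isclose(pm_t[0] % interval_s, 0.0)
    )

    rows = []
    for k in range(n_windows):
        start = k * interval_s
        span = min(duration, (k + 1) * interval_s) - start
        if span < interval_s and span < interval_s / 2.0:
            continue  # drop short trailing window
        hr_in = recording.hr_bpm[hr_idx == k]
        if hr_in.size == 0:
            continue
        pm_sel = pm_idx == k
        if not np.any(pm_sel):
            warnings.warn(
                f"{recording.volunteer_id}: window {k} has no PM sample; interval excluded"
            )
            continue
        mean_hr = float(hr_in.mean())
        if labels_align and k < recording.labels.size and recording.labels[k] in (0, 1):
            state = float(recording.labels[k])
        else:
            state = np.nan
        rows.append(
            {
                "volunteer_id": recording.volunteer_id,
                "interval_index": k,
                "mean_hr": mean_hr,
                "hr_percent": compute_hr_percent(mean_hr, profile.baseline_hr),
                "mean_pm25": float(recording.pm25[pm_sel].mean()),
                "mean_pm10": float(recording.pm10[pm_sel].mean()),
                "state": state,
            }
        )
    df = pd.DataFrame(rows, columns=list(INTERVAL_COLUMNS))
    df["interval_index"] = df["interval_index"].astype(int)
    return df


def aggregate_cohort(
    recordings: Iterable[WalkRecording],
    profiles: Iterable[VolunteerProfile],
    interval_s: float = DEFAULT_INTERVAL_S,
) -> pd.DataFrame:
    """Aggregate every recording; concatenated interval table."""
    by_id = {p.volunteer_id: p for p in profiles}
    frames = []
    for rec in recordings:
        prof = by_id.get(rec.volunteer_id)
        if prof is None:
            warnings.warn(f"recording {rec.volunteer_id} has no profile; skipped")
            continue
        frames.append(aggregate_intervals(rec, prof, interval_s))
    if not frames:
        return pd.DataFrame(columns=list(INTERVAL_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def interval_diagnostics(
    recordings: Sequence[WalkRecording],
    profiles: Sequence[VolunteerProfile],
    candidate_intervals: Sequence[float] = CANDIDATE_INTERVALS,
) -> pd.DataFrame:
    """Window-length screen: pooled regression F of mean HR on mean PM2.5.

    For each candidate window length the cohort is re-aggregated, interval
    mean heart rate is regressed on interval mean PM2.5 pooled across
    volunteers, and the overall regression F statistic with its p-value
    (``sig_f``) is reported.  Degenerate regressions (constant PM) are
    omitted with a warning.  Rows are ordered by window length.
    """
    if len(recordings) < 2:
        raise ValueError("need at least two recordings for the interval diagnostic")
    rows = []
    for interval in sorted(candidate_intervals):
        df = aggregate_cohort(recordings, profiles, interval)
        x = df["mean_pm25"].to_numpy()
        y = df["mean_hr"].to_numpy()
        if x.size < 3 or np.ptp(x) == 0:
            warnings.warn(f"interval {interval} s: degenerate regression; diagnostic omitted")
            continue
        res = stats.linregress(x, y)
        n = x.size
        r2 = res.rvalue**2
        with np.errstate(divide="ignore"):
            f_value = r2 * (n - 2) / (1.0 - r2) if r2 < 1.0 else np.inf
        rows.append(
            {
                "interval_s": float(interval),
                "f_value": float(f_value),
                "sig_f": float(res.pvalue),
                "n_intervals": int(n),
            }
        )
    return pd.DataFrame(rows)


def join_profiles(intervals: pd.DataFrame, profiles: Iterable[VolunteerProfile]) -> pd.DataFrame:
    """Attach logit design covariates to an interval table.

    Adds ``gender_male``, ``age_youth``, ``bmi_healthy`` (0/1 dummies
    coded as in the risk model: female, middle-aged, non-healthy BMI are
    the reference levels), ``bmi`` and ``baseline_hr``.
    """
    pdf = pd.DataFrame(
        [
            {
                "volunteer_id": p.volunteer_id,
                "gender_male": int(p.gender == "male"),
                "age_youth": int(p.age_group == "youth"),
                "bmi": p.bmi,
                "bmi_healthy": int(p.bmi_healthy),
                "baseline_hr": p.baseline_hr,
            }
            for p in profiles
        ]
    )
    return intervals.merge(pdf, on="volunteer_id", how="inner")


_DEFAULT_SCREEN = ("hr_percent", "mean_pm25", "gender_male", "age_youth", "bmi_healthy")
_STRENGTH_BANDS = (
    (0.8, "very strong"),
    (0.6, "strong"),
    (0.4, "moderate"),
    (0.2, "weak"),
    (0.0, "very weak"),
)


def correlation_strength(r: float) -> str:
    """Verbal strength band of |r| at 0.2 steps."""
    a = abs(r)
    if not 0.0 <= a <= 1.0 + 1e-12:
        raise ValueError("correlation must lie in [-1, 1]")
    for cut, label in _STRENGTH_BANDS:
        if a >= cut:
            return label
    return "very weak"


def pearson_matrix(
    records: pd.DataFrame, columns: Sequence[str] = _DEFAULT_SCREEN
) -> pd.DataFrame:
    """Absolute Pearson correlations between explanatory variables.

    Symmetric with unit diagonal; the absolute-value convention mirrors the
    published correlation screen.  Zero-variance columns yield NaN
    off-diagonals and a warning.  Needs at least 3 records.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for a correlation screen")
    data = records.loc[:, list(columns)].to_numpy(dtype=float)
    sd = data.std(axis=0)
    degenerate = [c for c, s in zip(columns, sd) if s == 0]
    if degenerate:
        warnings.warn(f"zero-variance columns {degenerate}: correlations undefined (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    out = np.abs(corr)
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=list(columns), columns=list(columns))
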