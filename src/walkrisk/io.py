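"""CSV schemas shared by the simulator and the ingest path.

Four input tables describe a cohort (real or synthetic); all files are
UTF-8 CSV with a header row and units embedded in column names:

- ``profiles.csv``:   volunteer_id, gender, age_group, height_m, weight_kg, baseline_hr_bpm
- ``heart_rate.csv``: volunteer_id, timestamp_s, hr_bpm            (1 Hz)
- ``pm.csv``:         volunteer_id, timestamp_s, pm25_ugm3, pm10_ugm3  (1-min)
- ``labels.csv``:     volunteer_id, interval_index, state          (0 safe / 1 risk)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AGE_GROUPS, GENDERS, VolunteerProfile, WalkRecording

__all__ = ["SCHEMAS", "INPUT_FILES", "write_cohort", "read_cohort"]

#: required columns of each input table
SCHEMAS = {
    "profiles": ["volunteer_id", "gender", "age_group", "height_m", "weight_kg", "baseline_hr_bpm"],
    "heart_rate": ["volunteer_id", "timestamp_s", "hr_bpm"],
    "pm": ["volunteer_id", "timestamp_s", "pm25_ugm3", "pm10_ugm3"],
    "labels": ["volunteer_id", "interval_index", "state"],
}

INPUT_FILES = {name: f"{name}.csv" for name in SCHEMAS}


def write_cohort(profiles, recordings, outdir) -> dict[str, Path]:
    """Write the four cohort tables under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in INPUT_FILES.items()}

    pd.DataFrame(
        [
            {
                "volunteer_id": p.volunteer_id,
                "gender": p.gender,
                "age_group": p.age_group,
                "height_m": p.height,
                "weight_kg": p.weight,
                "baseline_hr_bpm": p.baseline_hr,
            }
            for p in profiles
        ]
    ).to_csv(paths["profiles"], index=False)

    hr_frames, pm_frames, label_frames = [], [], []
    for rec in recordings:
        hr_frames.append(
            pd.DataFrame(
                {
                    "volunteer_id": rec.volunteer_id,
                    "timestamp_s": rec.hr_time,
                    "hr_bpm": rec.hr_bpm,
                }
            )
        )
        pm_frames.append(
            pd.DataFrame(
                {
                    "volunteer_id": rec.volunteer_id,
                    "timestamp_s": rec.pm_time,
                    "pm25_ugm3": rec.pm25,
                    "pm10_ugm3": rec.pm10,
                }
            )
        )
        label_frames.append(
            pd.DataFrame(
                {
                    "volunteer_id": rec.volunteer_id,
                    "interval_index": np.arange(rec.labels.size),
                    "state": rec.labels,
                }
            )
        )
    pd.concat(hr_frames, ignore_index=True).to_csv(paths["heart_rate"], index=False)
    pd.concat(pm_frames, ignore_index=True).to_csv(paths["pm"], index=False)
    pd.concat(label_frames, ignore_index=True).to_csv(paths["labels"], index=False)
    return paths


def read_cohort(paths: dict) -> tuple[list[VolunteerProfile], list[WalkRecording]]:
    """Load the four cohort tables back into profiles and recordings.

    ``paths`` maps the schema names to file paths (as produced by
    :func:`write_cohort`, or user-supplied files with the same columns).
    """
    frames = {}
    for name, cols in SCHEMAS.items():
        df = pd.read_csv(paths[name])
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{paths[name]}: missing required column(s) {missing}")
        frames[name] = df

    profiles = []
    for _, row in frames["profiles"].iterrows():
        if row["gender"] not in GENDERS:
            raise ValueError(f"profiles: unknown gender {row['gender']!r}")
        if row["age_group"] not in AGE_GROUPS:
            raise ValueError(f"profiles: unknown age_group {row['age_group']!r}")
        profiles.append(
            VolunteerProfile(
                volunteer_id=str(row["volunteer_id"]),
                gender=str(row["gender"]),
                age_group=str(row["age_group"]),
                height=float(row["height_m"]),
                weight=float(row["weight_kg"]),
                baseline_hr=float(row["baseline_hr_bpm"]),
            )
        )

    hr_by = dict(tuple(frames["heart_rate"].groupby("volunteer_id", sort=False)))
    pm_by = dict(tuple(frames["pm"].groupby("volunteer_id", sort=False)))
    lab_by = dict(tuple(frames["labels"].groupby("volunteer_id", sort=False)))
    recordings = []
    for p in profiles:
        vid = p.volunteer_id
        if vid not in hr_by or vid not in pm_by:
            raise ValueError(f"volunteer {vid}: missing heart-rate or PM series")
        hr = hr_by[vid].sort_values("timestamp_s")
        pm = pm_by[vid].sort_values("timestamp_s")
        if vid in lab_by:
            lab = lab_by[vid].sort_values("interval_index")
            labels = lab["state"].to_numpy(dtype=np.int64)
        else:
            labels = np.full(len(pm), -1, dtype=np.int64)  # unlabeled sentinel
        recordings.append(
            WalkRecording(
                volunteer_id=vid,
                hr_time=hr["timestamp_s"].to_numpy(dtype=float),
                hr_bpm=hr["hr_bpm"].to_numpy(dtype=float),
                pm_time=pm["timestamp_s"].to_numpy(dtype=float),
                pm25=pm["pm25_ugm3"].to_numpy(dtype=float),
                pm10=pm["pm10_ugm3"].to_numpy(dtype=float),
                labels=labels,
            )
        )
    return profiles, recordings
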