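"""End-to-end orchestration: simulate/ingest → intervals → thresholds → logit → curves.

A :class:`RunConfig` fully determines a run; identical (config, seed)
pairs yield byte-identical output files.  Stage failures abort with the
failing stage named.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SimulationConfig, simulate_cohort
from .io import SCHEMAS, read_cohort, write_cohort
from .logit import build_design, classify_states, fit_logit, risk_curves, wald_and_or
from .preprocessing import aggregate_cohort, interval_diagnostics, join_profiles
from .roc import DEFAULT_AUC_GATE, DEFAULT_STEP, cohort_thresholds

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline", "validate_inputs"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of the two input modes applies: ``mode="simulate"`` uses
    ``simulation`` (a :class:`SimulationConfig`); ``mode="ingest"`` reads
    the four cohort CSVs from ``input_paths``.
    """

    mode: str = "simulate"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_paths: dict | None = None
    interval_s: float = 60.0
    roc_step: float = DEFAULT_STEP
    auc_gate: float = DEFAULT_AUC_GATE
    exclude_unreliable: bool = False
    hr_for_curves: float = 35.0  # percentage points substituted into the risk curves
    outdir: str = "walkrisk_out"
    seed: int | None = None
    run_diagnostics: bool = False

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"mode must be 'simulate' or 'ingest', got {self.mode!r}")
        if self.mode == "ingest":
            if not self.input_paths:
                raise ValueError("ingest mode requires input_paths")
            missing = [k for k in SCHEMAS if k not in self.input_paths]
            if missing:
                raise ValueError(f"input_paths missing entries for {missing}")
        if self.interval_s <= 0:
            raise ValueError("interval_s must be > 0")
        if self.roc_step <= 0:
            raise ValueError("roc_step must be > 0")
        if not 0.5 <= self.auc_gate <= 1.0:
            raise ValueError("auc_gate must lie in [0.5, 1]")
        if self.mode == "simulate":
            self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("simulation", None)
        cfg = cls(**data)
        if sim is not None:
            cfg.simulation = SimulationConfig.from_dict(sim)
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    """What a run did and where it wrote its artifacts."""

    version: str
    config: dict
    n_volunteers: int
    n_intervals: int
    n_labeled: int
    reliability: dict
    fit: dict
    artifacts: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "n_volunteers": self.n_volunteers,
                "n_intervals": self.n_intervals,
                "n_labeled": self.n_labeled,
                "reliability": self.reliability,
                "fit": self.fit,
                "artifacts": self.artifacts,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and write the artifact files.

    Stages: acquire (simulate or ingest) → aggregate → thresholds →
    classify → fit → curves → report.  Returns the :class:`RunReport`.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    with _stage("acquire"):
        if config.mode == "simulate":
            sim = config.simulation
            if config.seed is not None:
                sim = sim.copy(seed=config.seed)
            profiles, recordings = simulate_cohort(sim)
            paths = write_cohort(profiles, recordings, outdir / "cohort")
            artifacts.update({k: str(v) for k, v in paths.items()})
        else:
            profiles, recordings = read_cohort(config.input_paths)

    with _stage("aggregate"):
        intervals = aggregate_cohort(recordings, profiles, config.interval_s)
        if intervals.empty:
            raise ValueError("aggregation produced no intervals")
        intervals = join_profiles(intervals, profiles)
        ipath = outdir / "intervals.csv"
        intervals.to_csv(ipath, index=False)
        artifacts["intervals"] = str(ipath)

    if config.run_diagnostics:
        with _stage("diagnostics"):
            diag = interval_diagnostics(recordings, profiles)
            dpath = outdir / "interval_diagnostics.csv"
            diag.to_csv(dpath, index=False)
            artifacts["interval_diagnostics"] = str(dpath)

    with _stage("thresholds"):
        thresholds, summary = cohort_thresholds(
            intervals, profiles, step=config.roc_step, auc_gate=config.auc_gate
        )
        if thresholds.empty:
            raise ValueError("no volunteer produced a usable ROC curve")
        tpath = outdir / "thresholds.csv"
        thresholds.to_csv(tpath, index=False)
        spath = outdir / "threshold_summary.json"
        spath.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
        artifacts["thresholds"] = str(tpath)
        artifacts["threshold_summary"] = str(spath)

    with _stage("classify"):
        used = thresholds[thresholds["reliable"]] if config.exclude_unreliable else thresholds
        classified = classify_states(intervals, used)
        if classified.empty:
            raise ValueError("no intervals left after classification")

    with _stage("fit"):
        X, y = build_design(classified)
        fit = fit_logit(X, y)
        table = wald_and_or(fit)
        cpath = outdir / "coefficients.csv"
        table.to_csv(cpath, index=False)
        artifacts["coefficients"] = str(cpath)

    with _stage("curves"):
        curves = risk_curves(fit.beta, hr_percent=config.hr_for_curves)
        rpath = outdir / "risk_curves.csv"
        curves.to_csv(rpath, index=False, float_format="%.10g")
        artifacts["risk_curves"] = str(rpath)

    report = RunReport(
        version=__version__,
        config={
            "mode": config.mode,
            "interval_s": config.interval_s,
            "roc_step": config.roc_step,
            "auc_gate": config.auc_gate,
            "exclude_unreliable": config.exclude_unreliable,
            "hr_for_curves": config.hr_for_curves,
            "seed": config.seed if config.seed is not None else (
                config.simulation.seed if config.mode == "simulate" else None
            ),
        },
        n_volunteers=len(profiles),
        n_intervals=int(len(intervals)),
        n_labeled=int(intervals["state"].notna().sum()),
        reliability=summary,
        fit={
            "beta": fit.beta.tolist(),
            "se": fit.se.tolist(),
            "odds_ratio": fit.exp_beta.tolist(),
            "loglik": fit.loglik,
            "converged": fit.converged,
            "iterations": fit.iterations,
            "n": fit.n,
            "class_balance": float(np.mean(y)),
        },
        artifacts=artifacts,
    )
    report.to_json(outdir / "report.json")
    return report


def validate_inputs(paths: dict) -> dict:
    """Schema and unit-sanity checks on the four cohort CSVs.

    Returns ``{"errors": [...], "warnings": [...], "n_rows": {...}}``.
    Errors: missing columns, non-numeric or negative measurements,
    non-monotone timestamps.  Warnings: values outside the sanity bands
    (PM 0–1000 μg/m³, HR 30–220 bpm) and PM10 < PM2.5 rows (retained,
    flagged).
    """
    errors: list[str] = []
    warns: list[str] = []
    n_rows: dict[str, int] = {}
    frames = {}
    for name, cols in SCHEMAS.items():
        path = paths.get(name)
        if path is None or not Path(path).exists():
            errors.append(f"{name}: file missing")
            continue
        df = pd.read_csv(path)
        n_rows[name] = len(df)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            errors.append(f"{name}: missing required column(s) {missing}")
            continue
        frames[name] = df

    hr = frames.get("heart_rate")
    if hr is not None:
        bad = hr.index[pd.to_numeric(hr["hr_bpm"], errors="coerce").isna() | (hr["hr_bpm"] < 0)]
        for i in bad[:5]:
            errors.append(f"heart_rate: invalid hr_bpm at row {int(i)}")
        out = hr[(hr["hr_bpm"] < 30) | (hr["hr_bpm"] > 220)]
        if len(out):
            warns.append(f"heart_rate: {len(out)} value(s) outside the 30-220 bpm sanity band")
        for vid, sub in hr.groupby("volunteer_id"):
            if not sub["timestamp_s"].is_monotonic_increasing:
                errors.append(f"heart_rate: non-monotone timestamps for volunteer {vid}")

    pm = frames.get("pm")
    if pm is not None:
        for col in ("pm25_ugm3", "pm10_ugm3"):
            bad = pm.index[pd.to_numeric(pm[col], errors="coerce").isna() | (pm[col] < 0)]
            for i in bad[:5]:
                errors.append(f"pm: invalid {col} at row {int(i)}")
            out = pm[pm[col] > 1000]
            if len(out):
                warns.append(f"pm: {len(out)} {col} value(s) above 1000 μg/m³")
        inverted = pm[pm["pm10_ugm3"] < pm["pm25_ugm3"]]
        for i in inverted.index[:10]:
            warns.append(f"pm: PM10 < PM2.5 at row {int(i)} (row retained, flagged)")
        for vid, sub in pm.groupby("volunteer_id"):
            if not sub["timestamp_s"].is_monotonic_increasing:
                errors.append(f"pm: non-monotone timestamps for volunteer {vid}")

    lab = frames.get("labels")
    if lab is not None:
        bad = lab[~lab["state"].isin([0, 1])]
        if len(bad):
            warns.append(f"labels: {len(bad)} row(s) with state outside {{0,1}} (treated as unlabeled)")

    prof = frames.get("profiles")
    if prof is not None:
        if (prof["height_m"] <= 0).any() or (prof["weight_kg"] <= 0).any():
            errors.append("profiles: non-positive height or weight")
        if (prof["baseline_hr_bpm"] <= 0).any():
            errors.append("profiles: non-positive baseline heart rate")

    return {"errors": errors, "warnings": warns, "n_rows": n_rows}
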