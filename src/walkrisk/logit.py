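"""Binary logit model of walking health risk.

The risk state of a walking interval (y = 1 iff the interval's HR% reaches
the volunteer's risk cutpoint) is modelled as

    ln(p / (1 − p)) = β₀ + β₁γ₁ + β₂γ₂ + β₃γ₃ + β₄γ₄ + β₅γ₅

with γ₁ the PM2.5 concentration (μg/m³), γ₂ = 1 for male, γ₃ = 1 for
youth, γ₄ = 1 for BMI in the healthy band [18.5, 24], and γ₅ the
heart-rate change rate in percentage points (reference levels: female,
middle-aged, non-healthy BMI).  The maximum-likelihood fit is a
Newton–Raphson / IRLS iteration written out in full here — it is the
centrepiece of the package, not delegated to a stats library — with
standard errors from the inverse observed information, Wald statistics in
both the z = β/SE and χ² = (β/SE)² conventions, and odds ratios exp(β).

``CALIBRATED_COEFFICIENTS`` is the published field calibration of this
model (n = 368 walking volunteers); it drives the preset risk curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "COEF_NAMES",
    "CALIBRATED_COEFFICIENTS",
    "SeparationError",
    "LogitFit",
    "classify_states",
    "build_design",
    "fit_logit",
    "wald_and_or",
    "predict_risk",
    "risk_curves",
    "simulate_from_model",
]

logger = logging.getLogger(__name__)

#: coefficient order: intercept then γ₁…γ₅
COEF_NAMES = ("intercept", "pm25", "male", "youth", "bmi_healthy", "hr_percent")

#: published field calibration of the model (β₀…β₅)
CALIBRATED_COEFFICIENTS = np.array([-6.323, 0.056, -0.264, -0.393, -0.327, 0.108])

_GROUPS = (
    ("female", "middle_aged"),
    ("male", "middle_aged"),
    ("female", "youth"),
    ("male", "youth"),
)


class SeparationError(RuntimeError):
    """Complete (quasi-)separation detected during the fit."""


@dataclass
class LogitFit:
    """Maximum-likelihood fit of the six-coefficient binary logit."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    iterations: int
    n: int
    names: tuple = COEF_NAMES

    @property
    def wald_z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def wald_chisq(self) -> np.ndarray:
        return (self.beta / self.se) ** 2

    @property
    def p_values(self) -> np.ndarray:
        return stats.chi2.sf(self.wald_chisq, df=1)

    @property
    def exp_beta(self) -> np.ndarray:
        return np.exp(self.beta)


def classify_states(intervals: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Assign the model outcome y from per-volunteer HR% cutpoints.

    y = 1 iff the interval's hr_percent is at or above its volunteer's
    hr_threshold (the boundary counts as risk, matching the ROC judgment
    convention).  Intervals whose volunteer has no threshold are dropped
    and logged.
    """
    thr = thresholds.set_index("volunteer_id")["hr_threshold"]
    known = intervals["volunteer_id"].isin(thr.index)
    dropped = int((~known).sum())
    if dropped:
        logger.warning("%d interval(s) dropped: volunteer has no threshold", dropped)
    out = intervals.loc[known].copy()
    cut = out["volunteer_id"].map(thr)
    out["y"] = (out["hr_percent"] >= cut).astype(int)
    return out


def build_design(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Covariate matrix (γ₁…γ₅, no intercept column) and outcome vector.

    Expects columns mean_pm25, gender_male, age_youth, bmi_healthy,
    hr_percent (fraction; converted here to percentage points) and y.
    """
    X = np.column_stack(
        [
            records["mean_pm25"].to_numpy(dtype=float),
            records["gender_male"].to_numpy(dtype=float),
            records["age_youth"].to_numpy(dtype=float),
            records["bmi_healthy"].to_numpy(dtype=float),
            100.0 * records["hr_percent"].to_numpy(dtype=float),
        ]
    )
    y = records["y"].to_numpy(dtype=float)
    return X, y


def _loglik(y, eta):
    # sum y·η − log(1 + exp(η)), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol_loglik: float = 1e-8,
    tol_grad: float = 1e-6,
    separation_bound: float = 50.0,
    names: Sequence[str] | None = None,
) -> LogitFit:
    """Newton–Raphson (IRLS) maximum likelihood for the binary logit.

    ``X`` holds the covariates (no intercept column — one is prepended),
    ``y`` the 0/1 outcomes.  Convergence when the log-likelihood change
    drops below ``tol_loglik`` or the gradient max-norm below ``tol_grad``,
    capped at ``max_iter`` iterations; the step is halved whenever a full
    Newton step would decrease the log-likelihood.  Standard errors come
    from the inverse observed information at the optimum.  A coefficient
    escaping ``separation_bound`` while the likelihood still improves
    raises :class:`SeparationError` naming the covariate.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y have incompatible shapes")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be 0/1")
    if y.min() == y.max():
        raise ValueError("single-class outcome: the logit model is not identifiable")
    for j in range(X.shape[1]):
        if X[:, j].min() == X[:, j].max():
            label = (names or COEF_NAMES)[j + 1] if j + 1 < len(names or COEF_NAMES) else f"x{j+1}"
            raise ValueError(f"covariate {label!r} is constant: coefficient not identifiable")
    Xd = np.column_stack([np.ones(n), X])
    p_params = Xd.shape[1]
    if n < p_params + 1:
        raise ValueError(f"need at least {p_params + 1} rows to fit {p_params} coefficients")
    if names is None:
        names = COEF_NAMES if p_params == len(COEF_NAMES) else tuple(
            ["intercept"] + [f"x{j}" for j in range(1, p_params)]
        )

    beta = np.zeros(p_params)
    eta = Xd @ beta
    ll = _loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = special.expit(eta)
        grad = Xd.T @ (y - p)
        if np.max(np.abs(grad)) < tol_grad:
            converged = True
            break
        w = p * (1.0 - p)
        H = Xd.T @ (Xd * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-10 * np.eye(p_params), grad)
        # step-halving line search
        scale = 1.0
        for _ in range(30):
            trial = beta + scale * step
            ll_new = _loglik(y, Xd @ trial)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        improving = ll_new > ll + tol_loglik
        beta = beta + scale * step
        eta = Xd @ beta
        if np.max(np.abs(beta)) > separation_bound and improving:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"complete separation suspected: coefficient {names[j]!r} "
                f"exceeded {separation_bound} while the likelihood still improved"
            )
        if abs(ll_new - ll) < tol_loglik:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    p = special.expit(eta)
    w = p * (1.0 - p)
    H = Xd.T @ (Xd * w[:, None])
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    return LogitFit(
        beta=beta,
        se=se,
        loglik=ll,
        converged=converged,
        iterations=it,
        n=n,
        names=tuple(names),
    )


def wald_and_or(fit: LogitFit) -> pd.DataFrame:
    """Coefficient table: β, SE, Wald (both conventions), p, Exp(β).

    The Wald statistic is reported as z = β/SE and as χ² = (β/SE)² with
    1 degree of freedom; the χ² convention is primary and supplies the
    p-value.  Exp(β) is the odds ratio per unit of the covariate.
    Requires a converged fit.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; Wald table not meaningful")
    return pd.DataFrame(
        {
            "variable": list(fit.names),
            "beta": fit.beta,
            "se": fit.se,
            "wald_z": fit.wald_z,
            "wald_chisq": fit.wald_chisq,
            "df": 1,
            "p_value": fit.p_values,
            "odds_ratio": fit.exp_beta,
        }
    )


def predict_risk(coefficients, gamma, method: str = "logistic"):
    """Risk probability p for covariate vector(s) γ₁…γ₅.

    ``coefficients`` is (β₀…β₅); ``gamma`` is a length-5 vector or an
    (n, 5) array.  ``method="logistic"`` evaluates the logistic transform
    of the linear predictor; ``method="odds"`` evaluates the equivalent
    odds form exp(η)/(1 + exp(η)) — the two agree to floating precision
    and exist as separate code paths for verification.
    """
    beta = np.asarray(coefficients, dtype=float)
    if beta.shape != (6,):
        raise ValueError("coefficient vector must have length 6 (intercept + 5 slopes)")
    g = np.atleast_2d(np.asarray(gamma, dtype=float))
    if g.shape[1] != 5:
        raise ValueError("covariate vectors must have length 5 (γ₁…γ₅)")
    eta = beta[0] + g @ beta[1:]
    if method == "logistic":
        p = special.expit(eta)
    elif method == "odds":
        odds = np.exp(eta)
        p = odds / (1.0 + odds)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(p[0]) if np.ndim(gamma) == 1 else p


def risk_curves(
    coefficients=CALIBRATED_COEFFICIENTS,
    pm_grid=None,
    hr_percent: float = 35.0,
    bmi_healthy: bool = True,
) -> pd.DataFrame:
    """Risk probability vs PM2.5 for the four (gender, age) groups.

    ``hr_percent`` (percentage points) and ``bmi_healthy`` are held fixed;
    the value of HR% used for display must be chosen explicitly since the
    curves are conditional on it.  Returns a tidy frame (group, gender,
    age_group, pm25_ugm3, probability).
    """
    if pm_grid is None:
        pm_grid = np.linspace(0.0, 300.0, 301)
    pm_grid = np.asarray(pm_grid, dtype=float)
    if pm_grid.size == 0:
        raise ValueError("pm_grid is empty")
    if np.any(np.diff(pm_grid) <= 0):
        raise ValueError("pm_grid must be strictly increasing")
    frames = []
    for gender, age in _GROUPS:
        g = np.column_stack(
            [
                pm_grid,
                np.full(pm_grid.size, float(gender == "male")),
                np.full(pm_grid.size, float(age == "youth")),
                np.full(pm_grid.size, float(bool(bmi_healthy))),
                np.full(pm_grid.size, float(hr_percent)),
            ]
        )
        frames.append(
            pd.DataFrame(
                {
                    "group": f"{gender}_{age}",
                    "gender": gender,
                    "age_group": age,
                    "pm25_ugm3": pm_grid,
                    "probability": predict_risk(coefficients, g),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_from_model(
    coefficients,
    n: int,
    rng: np.random.Generator,
    pm_range: tuple[float, float] = (53.0, 113.0),
    hr_range: tuple[float, float] = (10.0, 30.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Draw interval-style covariates and Bernoulli outcomes from the model.

    Used for parameter-recovery and Wald-coverage studies: PM2.5 and HR%
    are uniform on moderate bands and the three dummies are fair
    Bernoullis, which keeps most fitted probabilities away from 0/1 so the
    Fisher information per observation is high.  Returns ``(X, y)`` with X
    shaped (n, 5) in γ₁…γ₅ order.
    """
    beta = np.asarray(coefficients, dtype=float)
    X = np.column_stack(
        [
            rng.uniform(*pm_range, size=n),
            rng.integers(0, 2, size=n).astype(float),
            rng.integers(0, 2, size=n).astype(float),
            rng.integers(0, 2, size=n).astype(float),
            rng.uniform(*hr_range, size=n),
        ]
    )
    p = special.expit(beta[0] + X @ beta[1:])
    y = (rng.random(n) < p).astype(float)
    return X, y
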