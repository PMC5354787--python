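"""Weibull progression-free-survival model and Kaplan-Meier curve fitting.

The cohort model extrapolates progression-free survival with a two-parameter
Weibull model, S(t) = exp(-lambda * t^gamma).  Treatment effects enter as
hazard ratios applied multiplicatively to the scale parameter (the shape is
shared), the standard proportional-hazards adjustment for Weibull survival
curves.  The fitter recovers (lambda, gamma) from a Kaplan-Meier curve by
least squares on the complementary-log-log linearization
ln(-ln S) = ln(lambda) + gamma * ln(t), which also yields the r^2 commonly
reported for such fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WeibullPFS",
    "KMCurve",
    "FitError",
    "survival_at",
    "cycle_transition_prob",
    "apply_hazard_ratio",
    "fit_weibull",
    "read_km_csv",
    "write_km_csv",
]

#: Days per model cycle and (mean Gregorian) month; used to convert a cycle
#: index into the Weibull model's native time unit.
CYCLE_DAYS = 21.0
MONTH_DAYS = 365.25 / 12.0


class FitError(ValueError):
    """Kaplan-Meier curve unusable for Weibull fitting."""


@dataclass(frozen=True)
class WeibullPFS:
    """Weibull PFS model with scale ``lam`` and shape ``gamma``.

    ``time_unit`` records the unit ``t`` is measured in: ``"cycle"`` (21-day
    model cycles, the default model-wide convention) or ``"month"``.
    """

    lam: float
    gamma: float
    time_unit: str = "cycle"

    def __post_init__(self) -> None:
        if not (self.lam > 0 and self.gamma > 0):
            raise ValueError(f"Weibull parameters must be positive, got ({self.lam}, {self.gamma})")
        if self.time_unit not in ("cycle", "month"):
            raise ValueError(f"unknown time unit {self.time_unit!r}")

    @property
    def cycle_length(self) -> float:
        """Length of one 21-day model cycle in this model's time unit."""
        return 1.0 if self.time_unit == "cycle" else CYCLE_DAYS / MONTH_DAYS

    def median(self) -> float:
        """Median survival time in the model's time unit: (ln 2 / lam)^(1/gamma)."""
        return (math.log(2.0) / self.lam) ** (1.0 / self.gamma)


def survival_at(w: WeibullPFS, t) -> float | np.ndarray:
    """S(t) = exp(-lam * t^gamma); accepts scalars or arrays, t >= 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival time must be non-negative")
    out = np.exp(-w.lam * t_arr**w.gamma)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def cycle_transition_prob(w: WeibullPFS, t: int) -> float:
    """Probability of leaving PFS during cycle ``t`` (1-based), conditional on
    being progression-free at its start.

    P(t) = 1 - exp(lam*(t-1)^gamma - lam*t^gamma) = 1 - S(t)/S(t-1), with the
    cycle index converted to the model's native time unit first.
    """
    if t < 1:
        raise ValueError("cycle index must be >= 1")
    u = w.cycle_length
    return 1.0 - math.exp(w.lam * ((t - 1) * u) ** w.gamma - w.lam * (t * u) ** w.gamma)


def apply_hazard_ratio(w: WeibullPFS, hr: float) -> WeibullPFS:
    """Proportional-hazards adjustment: scale lam by ``hr``, shape unchanged."""
    if hr <= 0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    return replace(w, lam=w.lam * hr)


@dataclass(frozen=True)
class KMCurve:
    """A Kaplan-Meier survival curve as parallel arrays."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", surv)
        if times.shape != surv.shape or times.ndim != 1:
            raise ValueError("times and survival must be 1-D arrays of equal length")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any((surv < 0) | (surv > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(surv) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def __len__(self) -> int:
        return len(self.times)


def fit_weibull(km: KMCurve, time_unit: str = "cycle") -> tuple[WeibullPFS, float]:
    """Least-squares Weibull fit to a KM curve on the log-log scale.

    Points with S in {0, 1} or t <= 0 are excluded (the transform is undefined
    there); at least 3 usable points are required.  Returns the fitted model
    and the coefficient of determination of the linearized regression.
    """
    t = km.times
    s = km.survival
    mask = (t > 0) & (s > 0) & (s < 1)
    t, s = t[mask], s[mask]
    if len(t) < 3:
        raise FitError(f"need >= 3 points with 0 < S < 1 and t > 0, have {len(t)}")
    x = np.log(t)
    y = np.log(-np.log(s))
    res = stats.linregress(x, y)
    lam = math.exp(res.intercept)
    gamma = res.slope
    if gamma <= 0:
        raise FitError(f"fitted shape is non-positive ({gamma:.4g}); curve is not Weibull-like")
    return WeibullPFS(lam=lam, gamma=gamma, time_unit=time_unit), float(res.rvalue**2)


def read_km_csv(path) -> KMCurve:
    """Read a KM curve from a 2-column CSV (time, survival; header required)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns (time, survival)")
    at_risk = df["at_risk"].to_numpy(float) if "at_risk" in df.columns else None
    return KMCurve(
        times=df.iloc[:, 0].to_numpy(float),
        survival=df.iloc[:, 1].to_numpy(float),
        at_risk=at_risk,
    )


def write_km_csv(km: KMCurve, path) -> None:
    df = pd.DataFrame({"time": km.times, "survival": km.survival})
    if km.at_risk is not None:
        df["at_risk"] = km.at_risk
    df.to_csv(path, index=False)
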