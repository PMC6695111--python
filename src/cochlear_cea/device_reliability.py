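"""Internal-device reliability: cumulative survival and annual failure hazards.

Manufacturers publish cumulative survival of the implanted (internal) device
by year of use.  The model needs the annual, time-since-implantation-dependent
probability of internal failure q(t) = (S(t-1) - S(t)) / S(t-1), with the
clock reset whenever the device is replaced.  Beyond observed follow-up the
cumulative survival is extrapolated with an ordinary-least-squares line.

Sign convention: the survival line is S(t) = intercept - slope_per_year * t,
i.e. ``slope_per_year`` is the annual *decline* in cumulative survival.  The
default coefficients (0.998749, 0.002911) keep S near 1 in early years and
bring it to about 0.77 by the 80th year of use; read with a positive slope
the same coefficients would exceed 1 and cannot describe survival data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

SURVIVAL_FLOOR = 0.01  # keeps hazards defined if users extend past year 80


class ReliabilityFormatError(ValueError):
    pass


@dataclass
class LinearSurvivalModel:
    intercept: float = 0.998749
    slope_per_year: float = 0.002911
    valid_from_year: int = 20
    valid_to_year: int = 80

    def survival(self, t: float) -> float:
        if t <= 0:
            return 1.0
        return max(min(self.intercept - self.slope_per_year * t, 1.0),
                   SURVIVAL_FLOOR)


@dataclass
class ReliabilityCurve:
    """Observed cumulative survival points (year of use >= 1, proportion]."""

    points: list[tuple[int, float]]
    observed_max_year: int = 0
    _model: LinearSurvivalModel = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.points = sorted((int(y), float(s)) for y, s in self.points)
        if not self.observed_max_year and self.points:
            self.observed_max_year = self.points[-1][0]

    def extrapolation(self) -> LinearSurvivalModel:
        if self._model is None:
            self._model = fit_linear_extrapolation(self)
        return self._model


ModelOrCurve = Union[LinearSurvivalModel, ReliabilityCurve]


def read_reliability_curve(table_text: str) -> ReliabilityCurve:
    """Parse a ``year,cumulative_survival`` CSV into a ReliabilityCurve."""
    try:
        df = pd.read_csv(io.StringIO(table_text))
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ReliabilityFormatError(f"unreadable reliability file: {exc}") from exc
    for col in ("year", "cumulative_survival"):
        if col not in df.columns:
            raise ReliabilityFormatError(f"missing column '{col}'")
    years = df["year"].to_numpy()
    surv = df["cumulative_survival"].to_numpy(dtype=float)
    if len(df) == 0:
        raise ReliabilityFormatError("reliability file has no rows")
    if len(set(years.tolist())) != len(years):
        raise ReliabilityFormatError("duplicate years in reliability file")
    order = np.argsort(years)
    years, surv = years[order], surv[order]
    for i, (y, s) in enumerate(zip(years, surv)):
        if y < 1:
            raise ReliabilityFormatError(f"row {i}: year must be >= 1, got {y}")
        if not (0.0 < s <= 1.0):
            raise ReliabilityFormatError(
                f"row {i}: cumulative survival {s} outside (0, 1]")
    if np.any(np.diff(surv) > 1e-12):
        raise ReliabilityFormatError("cumulative survival must be non-increasing")
    return ReliabilityCurve(points=list(zip(years.tolist(), surv.tolist())))


def fit_linear_extrapolation(curve: ReliabilityCurve) -> LinearSurvivalModel:
    """OLS line through the observed (year, cumulative survival) pairs."""
    if len(curve.points) < 2:
        raise ValueError("need at least two points to fit an extrapolation line")
    years = np.array([p[0] for p in curve.points], dtype=float)
    surv = np.array([p[1] for p in curve.points], dtype=float)
    if np.ptp(years) == 0:
        raise ValueError("all observation years identical; cannot fit a line")
    slope, intercept = np.polyfit(years, surv, 1)
    return LinearSurvivalModel(intercept=float(intercept),
                               slope_per_year=float(-slope),
                               valid_from_year=curve.observed_max_year + 1)


def cumulative_survival(obj: ModelOrCurve, t: float) -> float:
    """S(t): probability the internal device is still functioning after
    ``t`` years of use.  S(0) = 1 by definition.  For a curve, years within
    follow-up are linearly interpolated and years beyond use the fitted line,
    floored at a small positive constant."""
    if t < 0:
        raise ValueError("years since implantation must be non-negative")
    if isinstance(obj, LinearSurvivalModel):
        return obj.survival(t)
    if t == 0:
        return 1.0
    if t <= obj.observed_max_year:
        years = [0.0] + [float(p[0]) for p in obj.points]
        surv = [1.0] + [p[1] for p in obj.points]
        return float(np.interp(t, years, surv))
    return obj.extrapolation().survival(t)


def annual_failure_probability(obj: ModelOrCurve, t: int) -> float:
    """q(t) = (S(t-1) - S(t)) / S(t-1) for year of use t >= 1, in [0, 1]."""
    if t < 1:
        raise ValueError("year of device use must be >= 1")
    s_prev = cumulative_survival(obj, t - 1)
    if s_prev <= 0.0:
        return 1.0
    q = (s_prev - cumulative_survival(obj, t)) / s_prev
    return float(min(max(q, 0.0), 1.0))


def failure_probability_vector(obj: ModelOrCurve, max_t: int) -> np.ndarray:
    """q(t) for t = 1..max_t as an array (index 0 unused, set to 0)."""
    q = np.zeros(max_t + 1)
    for t in range(1, max_t + 1):
        q[t] = annual_failure_probability(obj, t)
    return q
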