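"""ICERs with dominance handling, one-way DSA (tornado), PSA and CEACs.

The two bilateral strategies are each compared pairwise against bimodal
hearing.  The probabilistic sensitivity analysis is second-order: each draw
samples one parameter set (gamma for costs, beta for utility increments,
both by method of moments with SD = CV x mean, CV = 1 by default per the
source analysis's literal statement) and evaluates every arm in cohort mode;
first-order variability is integrated out exactly.  Because transition
probabilities are held fixed across draws, the cohort model is linear in
unit costs and utility-band cells, so each draw is evaluated by reweighting
one cohort run's loadings -- numerically identical to re-running the cohort,
which a test verifies draw by draw.

CEAC optimality is net-monetary-benefit ranking: at willingness-to-pay w a
strategy is optimal in a draw when w x QALY - cost is strictly highest
(ties split equally).
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .life_table import LifeTable
from .markov_engine import ArmResult, run_cohort
from .parameters import (Arm, ModelParameters, StrategyDefinition,
                         apply_override, strategy_for)
from .parameters import _numeric_cost_fields


class Dominance(enum.Enum):
    NONE = "none"
    INTERVENTION_DOMINANT = "intervention_dominant"
    INTERVENTION_DOMINATED = "intervention_dominated"


@dataclass
class IcerResult:
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    dominance: Dominance

    def to_dict(self) -> dict:
        return {"delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly,
                "icer": self.icer, "dominance": self.dominance.value}


def compute_icer(control: ArmResult, intervention: ArmResult) -> IcerResult:
    """Pairwise incremental comparison; the ICER is reported only when both
    increments share a sign (otherwise one strategy dominates, or the ratio
    is undefined)."""
    dc = intervention.discounted_cost - control.discounted_cost
    dq = intervention.discounted_qaly - control.discounted_qaly
    if dc <= 0 and dq >= 0 and (dc < 0 or dq > 0):
        return IcerResult(dc, dq, None, Dominance.INTERVENTION_DOMINANT)
    if dc >= 0 and dq <= 0 and (dc > 0 or dq < 0):
        return IcerResult(dc, dq, None, Dominance.INTERVENTION_DOMINATED)
    if dq == 0:
        return IcerResult(dc, dq, None, Dominance.NONE)
    return IcerResult(dc, dq, dc / dq, Dominance.NONE)


# --------------------------------------------------------------------------
# one-way deterministic sensitivity analysis

@dataclass
class TornadoEntry:
    parameter_path: str
    low_value: float
    high_value: float
    icer_at_low: Optional[float]
    icer_at_high: Optional[float]

    @property
    def bar_width(self) -> float:
        vals = [v for v in (self.icer_at_low, self.icer_at_high) if v is not None]
        return abs(max(vals) - min(vals)) if len(vals) == 2 else float("inf")


def default_dsa_plan(params: ModelParameters) -> list[tuple[str, float, float]]:
    """The published one-way plan: utility gain of the second implant over
    its feasible literature range (0.015 halved .. 0.06), the initial
    bilateral acquisition cost and the remaining named cost drivers at
    +/-10%."""
    c = params.costs

    def pm10(x):
        return (0.9 * x, 1.1 * x)

    return [
        ("utilities.base_increment_bilateral_extra", 0.015, 0.06),
        ("costs.bilateral_acquisition_multiplier", 0.9, 1.1),
        ("costs.hearing_aid", *pm10(c.hearing_aid)),
        ("costs.surgery_implantation", *pm10(c.surgery_implantation)),
        ("costs.surgery_explant_reimplant", *pm10(c.surgery_explant_reimplant)),
    ]


def one_way_dsa(params: ModelParameters,
                plan: Sequence[tuple[str, float, float]],
                pair: tuple[StrategyDefinition, StrategyDefinition],
                lt: LifeTable) -> list[TornadoEntry]:
    """Re-run cohort mode at each parameter's low/high, all else at base;
    entries come back sorted by descending ICER range (tornado ordering)."""
    control, intervention = pair
    entries = []
    for path, low, high in plan:
        icers = []
        for value in (low, high):
            p = apply_override(params, path, value)
            res = compute_icer(run_cohort(p, control, lt).totals,
                               run_cohort(p, intervention, lt).totals)
            icers.append(res.icer)
        entries.append(TornadoEntry(path, low, high, icers[0], icers[1]))
    entries.sort(key=lambda e: e.bar_width, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter_path, "low_value": e.low_value,
        "high_value": e.high_value, "icer_at_low": e.icer_at_low,
        "icer_at_high": e.icer_at_high, "bar_width": e.bar_width,
    } for e in entries])


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis

_UTILITY_PATHS = ("utilities.base_increment_bimodal",
                  "utilities.base_increment_bilateral_extra")


def _gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape k and scale theta from mean and SD."""
    return (mean / sd) ** 2, sd ** 2 / mean


def _beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Alpha and beta from mean and SD; SD is truncated to 95% of the
    feasible bound when the requested moments are unattainable."""
    feasible = np.sqrt(mean * (1 - mean))
    if sd >= feasible:
        warnings.warn(f"beta SD {sd} infeasible for mean {mean}; truncated")
        sd = 0.95 * feasible
    nu = mean * (1 - mean) / sd ** 2 - 1
    return mean * nu, (1 - mean) * nu


def sample_psa_parameters(params: ModelParameters, rng: np.random.Generator,
                          cv: float = 1.0) -> dict[str, float]:
    """One second-order draw: every unit cost from a gamma and every utility
    base increment from a beta, each with mean = base value and
    SD = cv x mean.  cv = 0 returns the base values exactly."""
    draws: dict[str, float] = {}
    for name in _numeric_cost_fields():
        mean = getattr(params.costs, name)
        if mean is None:
            raise ValueError(f"cost '{name}' unset; cannot sample")
        if cv == 0 or mean == 0:
            draws[f"costs.{name}"] = float(mean)
        else:
            k, theta = _gamma_moments(mean, cv * mean)
            draws[f"costs.{name}"] = float(rng.gamma(k, theta))
    for path in _UTILITY_PATHS:
        mean = getattr(params.utilities, path.split(".")[1])
        if not (0 < mean < 1):
            raise ValueError(f"utility mean {mean} outside (0, 1)")
        if cv == 0:
            draws[path] = float(mean)
        else:
            a, b = _beta_moments(mean, cv * mean)
            draws[path] = float(rng.beta(a, b))
    return draws


@dataclass
class PsaDraw:
    draw_index: int
    sampled_parameters: dict
    arm_results: dict  # Arm -> ArmResult


def _current_value(params: ModelParameters, path: str) -> float:
    section, name = path.split(".", 1)
    return getattr(getattr(params, section), name)


def _apply_draw(params: ModelParameters, draws: dict[str, float]) -> ModelParameters:
    p = params
    for path, value in draws.items():
        p = apply_override(p, path, value)
    return p


def run_psa(params: ModelParameters, arms: Sequence[StrategyDefinition],
            n_draws: int, seed: int, lt: LifeTable, cv: float = 1.0,
            method: str = "loadings") -> list[PsaDraw]:
    """Second-order PSA: each draw is one sampled parameter set evaluated in
    cohort mode for every arm.  ``method='loadings'`` reweights one cohort
    run per arm (exact, fast); ``method='direct'`` re-runs the cohort per
    draw (identical results, used as the cross-check)."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    base_traces = {id(a): run_cohort(params, a, lt) for a in arms}
    out: list[PsaDraw] = []
    for i in range(n_draws):
        draws = sample_psa_parameters(params, rng, cv=cv)
        # untouched parameters (e.g. the whole draw at CV = 0) keep their
        # base behaviour, including the verbatim printed utility cells
        changed = {p: v for p, v in draws.items()
                   if v != _current_value(params, p)}
        results = {}
        if method == "direct":
            p = _apply_draw(params, changed)
            for a in arms:
                tr = run_cohort(p, a, lt)
                results[a.arm] = tr.totals
        else:
            costs_draw = dataclasses.replace(params.costs, **{
                path.split(".")[1]: v for path, v in changed.items()
                if path.startswith("costs.")})
            us_draw = dataclasses.replace(
                params.utilities,
                base_increment_bimodal=draws[_UTILITY_PATHS[0]],
                base_increment_bilateral_extra=draws[_UTILITY_PATHS[1]],
                derive_bimodal_cells=_UTILITY_PATHS[0] in changed,
                derive_bilateral_cells=_UTILITY_PATHS[1] in changed)
            for a in arms:
                loads = base_traces[id(a)].loadings
                results[a.arm] = ArmResult(
                    discounted_cost=loads.cost(costs_draw),
                    discounted_qaly=loads.qaly(us_draw),
                    arm=a)
        out.append(PsaDraw(i, draws, results))
    return out


def psa_frame(draws: list[PsaDraw]) -> pd.DataFrame:
    rows = []
    for d in draws:
        row = {"draw": d.draw_index}
        for arm, res in d.arm_results.items():
            row[f"cost_{arm.value}"] = res.discounted_cost
            row[f"qaly_{arm.value}"] = res.discounted_qaly
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cost-effectiveness acceptability curves

@dataclass
class CeacTable:
    wtp_grid: np.ndarray
    probabilities: pd.DataFrame  # one column per strategy, rows sum to 1

    def crossing(self, a: Arm, b: Arm) -> Optional[float]:
        """First willingness-to-pay at which strategy ``b`` overtakes ``a``,
        linearly interpolated between grid points; None if no crossing."""
        diff = (self.probabilities[a.value] - self.probabilities[b.value]).to_numpy()
        sign = np.sign(diff)
        for i in range(1, len(sign)):
            if sign[i - 1] > 0 and sign[i] <= 0:
                w0, w1 = self.wtp_grid[i - 1], self.wtp_grid[i]
                d0, d1 = diff[i - 1], diff[i]
                if d0 == d1:
                    return float(w0)
                return float(w0 + (w1 - w0) * d0 / (d0 - d1))
        return None


def ceac(draws: list[PsaDraw], wtp_grid: Sequence[float]) -> CeacTable:
    """Probability each strategy has the highest net monetary benefit at each
    willingness-to-pay; ties split equally so rows always sum to 1."""
    if not draws:
        raise ValueError("need at least one PSA draw")
    arms = list(draws[0].arm_results.keys())
    costs = np.array([[d.arm_results[a].discounted_cost for a in arms]
                      for d in draws])
    qalys = np.array([[d.arm_results[a].discounted_qaly for a in arms]
                      for d in draws])
    wtp = np.asarray(list(wtp_grid), dtype=float)
    probs = np.zeros((len(wtp), len(arms)))
    for i, w in enumerate(wtp):
        nmb = w * qalys - costs
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb >= best - 1e-9
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        probs[i] = weights.mean(axis=0)
    df = pd.DataFrame(probs, columns=[a.value for a in arms])
    df.insert(0, "wtp", wtp)
    return CeacTable(wtp_grid=wtp, probabilities=df.set_index("wtp"))


# --------------------------------------------------------------------------
# convenience

def base_case(params: ModelParameters, lt: LifeTable) -> dict:
    """Cohort-mode arm results and both pairwise comparisons."""
    arms = {a: run_cohort(params, strategy_for(a), lt).totals for a in Arm}
    return {
        "arms": arms,
        "simultaneous_vs_bimodal": compute_icer(arms[Arm.BIMODAL],
                                                arms[Arm.SIMULTANEOUS]),
        "sequential_vs_bimodal": compute_icer(arms[Arm.BIMODAL],
                                              arms[Arm.SEQUENTIAL]),
    }
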