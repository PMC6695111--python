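"""Four-state Markov engine: device chain x annual cycles, two run modes.

States are "use of 1st internal device", "use of 2nd internal device",
"use of 3rd internal device" and "death".  Each annual cycle resolves, in a
fixed order, (1) all-cause mortality from the life table, (2) a major
surgical complication -- wound revision (no state change) or explantation
with re-implantation (advance to the next device) -- and (3) internal device
failure (advance to the next device).  A maximum of two replacements is
enforced structurally: no failure/explantation transitions leave the third
device.  The failure and first-year-complication clocks reset on every
(re)implantation.

Cohort mode propagates exact state-occupancy expectations over the expanded
state space (device index, years of use of the current device), so the
time-dependent failure hazard is handled without approximation.
Microsimulation samples individual trajectories from the identical
per-cycle distributions; the two modes agree in expectation and the test
suite checks that convergence.

QALYs are accrued on the utility-gain-over-no-implantation scale, discounted
at mid-cycle (half-cycle correction on QALYs only); costs are discounted at
cycle start.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import costing
from .device_reliability import failure_probability_vector
from .life_table import LifeTable, annual_death_probability
from .parameters import (Arm, ModelParameters, StrategyDefinition,
                         UtilitySchedule, validate)


class HealthState(enum.Enum):
    DEV1 = 1
    DEV2 = 2
    DEV3 = 3
    DEATH = 0


@dataclass(frozen=True)
class CycleEvents:
    died: bool = False
    internal_failure: bool = False
    major_complication_wound: bool = False
    major_complication_explant: bool = False


NO_EVENTS = CycleEvents()


@dataclass
class CycleContext:
    age: int
    cycle_index: int
    years_since_current_device: int
    replacements_done: int
    arm: StrategyDefinition
    second_implant_active: bool = True
    warranty_years: int = 10


@dataclass
class CycleRecord:
    age: int
    alive: float
    occupancy: dict
    utility_accrued_discounted: float
    cost_accrued_discounted: float


@dataclass
class ArmResult:
    discounted_cost: float
    discounted_qaly: float
    arm: StrategyDefinition
    n_individuals: object = "cohort"
    standard_errors: Optional[tuple[float, float]] = None  # (cost, qaly)


@dataclass
class CohortLoadings:
    """Linear decomposition of the cohort result.

    ``resource_units``: discounted expected units of each unit-cost item
    (event probabilities and cost multipliers folded in), so that
    total cost = sum_r units[r] * unit_cost[r].
    ``qaly_bimodal`` / ``qaly_bilateral``: discounted alive-person-years per
    utility band, so that total QALYs = sum_b cell[b] * loading[b].
    Valid for reweighting unit costs and utility cells only; any change to
    transition probabilities requires a fresh cohort run.
    """

    resource_units: dict = field(default_factory=dict)
    qaly_bimodal: np.ndarray = None
    qaly_bilateral: np.ndarray = None

    def cost(self, costs) -> float:
        return sum(costing._unit_cost(costs, r) * u
                   for r, u in self.resource_units.items())

    def qaly(self, us: UtilitySchedule) -> float:
        total = 0.0
        for i, b in enumerate(us.bands):
            bim = (b.scaling * us.base_increment_bimodal
                   if us.derive_bimodal_cells else b.bimodal_cell)
            bil = (b.scaling * us.base_increment_bilateral_extra
                   if us.derive_bilateral_cells else b.bilateral_cell)
            total += bim * self.qaly_bimodal[i] + bil * self.qaly_bilateral[i]
        return total


@dataclass
class Trace:
    cycles: list[CycleRecord]
    totals: ArmResult
    loadings: Optional[CohortLoadings] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "age": r.age, "alive": r.alive,
            **{f"occ_{k}": v for k, v in r.occupancy.items()},
            "utility_discounted": r.utility_accrued_discounted,
            "cost_discounted": r.cost_accrued_discounted,
        } for r in self.cycles])


# --------------------------------------------------------------------------
# elementary operations

def discount_factor(rate: float, cycle_index: int, mid_cycle: bool) -> float:
    """Cycle-start factor for costs; mid-cycle factor for QALYs."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    exponent = cycle_index - 0.5 if mid_cycle else cycle_index - 1
    return float((1.0 + rate) ** -exponent)


def utility_increment(age: int, arm: StrategyDefinition,
                      us: UtilitySchedule) -> float:
    """Annual utility gain over no implantation for a live individual of
    ``age`` in ``arm``; the bilateral addend applies only once the second
    implant is in place."""
    u = us.bimodal_increment(age)  # raises outside the banded range
    if arm.is_bilateral and age >= arm.age_second_implant:
        u += us.bilateral_increment(age)
    return u


def _complication_probs(strategy: StrategyDefinition, clinical, age: int,
                        t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(wound, explant) probabilities per years-of-use vector ``t``.

    Sequential arms attribute no surgical complications to the first implant:
    complication risk starts with the second implantation, whose surgery year
    carries the first-year rates; afterwards the first-year rates re-apply in
    the year after each re-implantation (clock reset).
    """
    t = np.asarray(t)
    if (strategy.arm is Arm.SEQUENTIAL
            and not clinical.first_implant_complications_in_sequential):
        if age < strategy.age_second_implant:
            z = np.zeros_like(t, dtype=float)
            return z, z.copy()
        if age == strategy.age_second_implant:
            shape = np.ones_like(t, dtype=float)
            return (clinical.p_wound_first_year * shape,
                    clinical.p_explant_first_year * shape)
    first = t == 1
    pw = np.where(first, clinical.p_wound_first_year, clinical.p_wound_subsequent)
    pe = np.where(first, clinical.p_explant_first_year,
                  clinical.p_explant_subsequent)
    return pw.astype(float), pe.astype(float)


def transition_distribution(state: HealthState, ctx: CycleContext,
                            params: ModelParameters, lt: LifeTable) -> dict:
    """Distribution over (next state, events) for one cycle.

    Competing risks resolve in the order death -> major complication ->
    internal failure, mutually exclusively; the returned probabilities sum
    to 1.  In the third-device state further explantation/failure events are
    suppressed (replacement cap); wound revisions may still occur.
    """
    if state is HealthState.DEATH:
        return {(HealthState.DEATH, NO_EVENTS): 1.0}

    qx = annual_death_probability(lt, ctx.age)
    t = ctx.years_since_current_device
    pw, pe = (float(x[0]) for x in _complication_probs(
        ctx.arm, params.clinical, ctx.age, np.array([t])))
    capped = state is HealthState.DEV3
    if capped:
        pe = 0.0
        qf = 0.0
    else:
        qf = failure_probability_vector(params.reliability, t)[t]

    nxt = HealthState(state.value + 1) if not capped else state
    dist = {
        (HealthState.DEATH, CycleEvents(died=True)): qx,
        (state, CycleEvents(major_complication_wound=True)): (1 - qx) * pw,
        (nxt, CycleEvents(major_complication_explant=True)): (1 - qx) * pe,
        (nxt, CycleEvents(internal_failure=True)):
            (1 - qx) * (1 - pw - pe) * qf,
        (state, NO_EVENTS): (1 - qx) * (1 - pw - pe) * (1 - qf),
    }
    return {k: v for k, v in dist.items() if v > 0.0 or k[1] is NO_EVENTS}


# --------------------------------------------------------------------------
# cohort expectation mode

def run_cohort(params: ModelParameters, arm: StrategyDefinition,
               lt: LifeTable) -> Trace:
    """Deterministic expectation over the expanded (device, years-of-use)
    state space; returns a Trace whose totals are the exact expected
    discounted cost and QALYs."""
    violations = validate(params)
    if violations:
        raise ValueError("refusing to run with invalid parameters: "
                         + "; ".join(f"{v.field}: {v.rule}" for v in violations))

    eco, cli, us, costs = (params.economic, params.clinical, params.utilities,
                           params.costs)
    r = eco.discount_rate_annual
    T = eco.horizon_end_age - eco.start_age + 1
    qf_vec = failure_probability_vector(params.reliability, T + 1)
    warranty = cli.warranty_years
    mult = arm.replacement_cost_multiplier

    band_idx = np.zeros(eco.horizon_end_age + 1, dtype=int)
    for i, b in enumerate(us.bands):
        band_idx[b.age_low:b.age_high + 1] = i

    # occ[k, t]: probability of being alive on device k+1 in its t-th year
    occ = np.zeros((3, T + 2))
    occ[0, 1] = 1.0
    n_bands = len(us.bands)
    loads = CohortLoadings(resource_units={},
                           qaly_bimodal=np.zeros(n_bands),
                           qaly_bilateral=np.zeros(n_bands))
    records: list[CycleRecord] = []
    total_cost = 0.0
    total_qaly = 0.0

    def add_units(resource: str, units: float) -> None:
        loads.resource_units[resource] = (
            loads.resource_units.get(resource, 0.0) + units)

    tgrid = np.arange(T + 2)
    for y in range(1, T + 1):
        age = eco.start_age + y - 1
        qx = annual_death_probability(lt, age)
        occ *= (1.0 - qx)
        alive = occ.sum()
        dfc = discount_factor(r, y, mid_cycle=False)
        dfq = discount_factor(r, y, mid_cycle=True)

        # QALY accrual (mid-cycle discounting)
        u = utility_increment(age, arm, us)
        cyc_qaly = u * alive * dfq
        total_qaly += cyc_qaly
        bi = band_idx[age]
        loads.qaly_bimodal[bi] += alive * dfq
        if arm.is_bilateral and age >= arm.age_second_implant:
            loads.qaly_bilateral[bi] += alive * dfq

        # scheduled + periodic costs (cycle-start discounting)
        sched_units = costing.scheduled_units(params.schedule, costs, arm, y)
        cyc_cost = 0.0
        for res, un in sched_units.items():
            cyc_cost += costing._unit_cost(costs, res) * un * alive * dfc
            add_units(res, un * alive * dfc)

        # event-driven costs and device transitions
        pw_vec, pe_vec = _complication_probs(arm, cli, age, tgrid)
        new_occ = np.zeros_like(occ)
        for k in range(3):
            row = occ[k]
            if not row.any():
                continue
            pw, pe = pw_vec.copy(), pe_vec.copy()
            if k == 2:  # replacement cap: no explant/failure out of DEV3
                pe = np.zeros_like(pe)
                qf = np.zeros_like(qf_vec[:T + 2])
            else:
                qf = qf_vec[:T + 2]
            p_fail = (1.0 - pw - pe) * qf
            p_repl = pe + p_fail
            e_wound = float(np.sum(row * pw))
            e_repl = float(np.sum(row * p_repl))
            e_repl_post = float(np.sum((row * p_repl)[warranty + 1:]))
            cyc_cost += ((costs.surgery_wound_revision + costs.ward_day)
                         * e_wound * mult * dfc)
            cyc_cost += ((costs.surgery_explant_reimplant + costs.ward_day)
                         * e_repl * mult * dfc)
            cyc_cost += costs.ci_device * e_repl_post * mult * dfc
            add_units("surgery_wound_revision", e_wound * mult * dfc)
            add_units("surgery_explant_reimplant", e_repl * mult * dfc)
            add_units("ward_day", (e_wound + e_repl) * mult * dfc)
            add_units("ci_device", e_repl_post * mult * dfc)

            stay = row * (1.0 - p_repl)
            new_occ[k, 1:] += stay[:-1]  # device ages one year
            if k < 2:
                new_occ[k + 1, 1] += e_repl  # fresh clock next cycle

        total_cost += cyc_cost
        records.append(CycleRecord(
            age=age, alive=alive,
            occupancy={"dev1": occ[0].sum(), "dev2": occ[1].sum(),
                       "dev3": occ[2].sum(), "death": 1.0 - alive},
            utility_accrued_discounted=cyc_qaly,
            cost_accrued_discounted=cyc_cost))
        occ = new_occ

    totals = ArmResult(discounted_cost=total_cost, discounted_qaly=total_qaly,
                       arm=arm)
    return Trace(cycles=records, totals=totals, loadings=loads)


# --------------------------------------------------------------------------
# microsimulation mode

def run_microsim(params: ModelParameters, arm: StrategyDefinition,
                 lt: LifeTable, n: int, seed: int) -> ArmResult:
    """First-order Monte Carlo: sample ``n`` independent trajectories from
    the same per-cycle distributions as cohort mode.  Identical
    (params, arm, n, seed) give bit-identical results."""
    if n < 1:
        raise ValueError("n must be >= 1")
    violations = validate(params)
    if violations:
        raise ValueError("refusing to run with invalid parameters: "
                         + "; ".join(f"{v.field}: {v.rule}" for v in violations))

    eco, cli, us, costs = (params.economic, params.clinical, params.utilities,
                           params.costs)
    r = eco.discount_rate_annual
    T = eco.horizon_end_age - eco.start_age + 1
    qf_vec = failure_probability_vector(params.reliability, T + 1)
    warranty = cli.warranty_years
    mult = arm.replacement_cost_multiplier
    rng = np.random.default_rng(seed)

    k = np.ones(n, dtype=np.int64)       # current device index 1..3
    t = np.ones(n, dtype=np.int64)       # years of use of current device
    alive = np.ones(n, dtype=bool)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    max_k = np.ones(n, dtype=np.int64)

    for y in range(1, T + 1):
        age = eco.start_age + y - 1
        qx = annual_death_probability(lt, age)
        dfc = discount_factor(r, y, mid_cycle=False)
        dfq = discount_factor(r, y, mid_cycle=True)

        u_death = rng.random(n)
        died = alive & (u_death < qx)
        alive &= ~died

        u = utility_increment(age, arm, us)
        qaly[alive] += u * dfq
        sched = costing.scheduled_cycle_cost(params.schedule, costs, arm, y)
        cost[alive] += sched * dfc

        pw, pe = _complication_probs(arm, cli, age, t)
        capped = k >= 3
        pe = np.where(capped, 0.0, pe)
        qf = np.where(capped, 0.0, qf_vec[np.minimum(t, T + 1)])

        u_comp = rng.random(n)
        wound = alive & (u_comp < pw)
        explant = alive & (u_comp >= pw) & (u_comp < pw + pe)
        u_fail = rng.random(n)
        fail = alive & ~wound & ~explant & (u_fail < qf)

        cost[wound] += (costs.surgery_wound_revision + costs.ward_day) * mult * dfc
        repl = explant | fail
        if repl.any():
            repl_cost = np.full(n, costs.surgery_explant_reimplant
                                + costs.ward_day)
            repl_cost[t > warranty] += costs.ci_device
            cost[repl] += repl_cost[repl] * mult * dfc
            k[repl] += 1
            t[repl] = 0
            max_k = np.maximum(max_k, k)
        t += 1

    se = (float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
          float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0)
    assert int(max_k.max(initial=1)) <= 1 + cli.max_internal_replacements
    return ArmResult(discounted_cost=float(cost.mean()),
                     discounted_qaly=float(qaly.mean()),
                     arm=arm, n_individuals=n, standard_errors=se)
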