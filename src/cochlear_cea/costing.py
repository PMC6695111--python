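"""Per-cycle cost accrual: scheduled pathway costs, periodic device
replacements, and event-driven surgical costs with warranty logic.

All computation is in 2017 USD from the healthcare payer perspective.  The
published schedule is *incremental* (second implant versus bimodal hearing);
arm-level totals additionally carry a reconstructed first-implant backbone
that is identical across arms and cancels from every pairwise comparison.
Replacement-related costs in bilateral arms are doubled (two independent
ears with identical risks), via the strategy's replacement_cost_multiplier.

Warranty rule: a replacement internal device is free within ``warranty_years``
of that device's implantation; the explantation/re-implantation surgery and
one ward day are always charged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import (Arm, ModelParameters, ResourceSchedule,
                         StrategyDefinition, UnitCosts)

# resources whose units the bilateral-acquisition DSA lever scales
_ACQUISITION_RESOURCES = ("ci_device", "surgery_implantation")


class CostConfigError(KeyError):
    pass


@dataclass
class EventCostRule:
    """Cost composition of the three surgical events."""

    multiplier: float = 1.0

    def wound_revision(self, costs: UnitCosts) -> float:
        return (costs.surgery_wound_revision + costs.ward_day) * self.multiplier

    def replacement(self, costs: UnitCosts, years_since_current_device: int,
                    warranty_years: int) -> float:
        base = costs.surgery_explant_reimplant + costs.ward_day
        if years_since_current_device > warranty_years:
            base += costs.ci_device
        return base * self.multiplier


def _unit_cost(costs: UnitCosts, resource: str) -> float:
    try:
        value = getattr(costs, resource)
    except AttributeError:
        raise CostConfigError(f"unknown resource '{resource}' in schedule") from None
    if value is None:
        raise CostConfigError(f"cost for resource '{resource}' is unset")
    return float(value)


def scheduled_units(schedule: ResourceSchedule, costs: UnitCosts,
                    arm: StrategyDefinition, model_year: int,
                    include_backbone: bool = True) -> dict[str, float]:
    """Units of each resource due in ``model_year``: scheduled items for the
    arm, the shared backbone, and periodic replacements.

    Periodic items fire strictly after their anchor year (the initial device
    of each kind is part of the acquisition, not a replacement): external
    processors every 7 years from each implant's implantation year, and, for
    the bimodal comparator only, a hearing-aid replacement every 5 years from
    model start.
    """
    units: dict[str, float] = {}

    def add(resource: str, u: float) -> None:
        units[resource] = units.get(resource, 0.0) + u

    acq_mult = costs.bilateral_acquisition_multiplier if arm.is_bilateral else 1.0
    for item in schedule.incremental:
        if item.arm is arm.arm and item.model_year == model_year:
            u = item.units
            if item.resource in _ACQUISITION_RESOURCES:
                u *= acq_mult
            add(item.resource, u)
    if include_backbone:
        for item in schedule.backbone:
            if item.model_year == model_year:
                u = item.units
                if item.resource in _ACQUISITION_RESOURCES:
                    u *= acq_mult
                add(item.resource, u)

    # periodic replacements
    cyc_p = costs.external_processor_cycle_years
    anchors = [1]  # first implant's processor (backbone, all arms)
    if arm.is_bilateral:
        anchors.append(arm.age_second_implant - arm.age_first_implant + 1)
    for anchor in anchors:
        if include_backbone or anchor != 1:
            if model_year > anchor and (model_year - anchor) % cyc_p == 0:
                add("external_processor_replacement", 1.0)
    if arm.arm is Arm.BIMODAL and include_backbone:
        cyc_h = costs.hearing_aid_cycle_years
        if model_year > 1 and (model_year - 1) % cyc_h == 0:
            add("hearing_aid", 1.0)
    return units


def scheduled_cycle_cost(schedule: ResourceSchedule, costs: UnitCosts,
                         arm: StrategyDefinition, model_year: int,
                         include_backbone: bool = True) -> float:
    """USD due in ``model_year`` from scheduled and periodic items."""
    if model_year < 1:
        raise ValueError("model_year starts at 1")
    return sum(_unit_cost(costs, res) * u
               for res, u in scheduled_units(schedule, costs, arm, model_year,
                                             include_backbone).items())


def event_cost(events, ctx, costs: UnitCosts, rule: EventCostRule) -> float:
    """USD incurred by the cycle's resolved events (0 when nothing happened).

    ``events`` carries the wound/explant/failure flags and ``ctx`` the years
    of use of the failed device (warranty clock).
    """
    if getattr(events, "died", False):
        return 0.0
    total = 0.0
    if events.major_complication_wound:
        total += rule.wound_revision(costs)
    if events.major_complication_explant or events.internal_failure:
        total += rule.replacement(costs, ctx.years_since_current_device,
                                  ctx.warranty_years)
    return total


def arm_total_cost(trace) -> float:
    """Discounted lifetime cost of a completed trace (equals its totals)."""
    return float(sum(rec.cost_accrued_discounted for rec in trace.cycles))


# --------------------------------------------------------------------------
# processor-price calibration

def calibrate_processor_cost(params: ModelParameters, lt,
                             target_delta_cost: float = 53451.0,
                             bracket: tuple[float, float] = (0.0, 100000.0),
                             ) -> float:
    """Back out the unpublished external-processor price.

    The processor replacement price is absent from the published cost table.
    It is reconstructed so that the cohort-mode incremental cost of
    simultaneous implantation over bimodal hearing equals ``target_delta_cost``
    (the published base-case increment).  The incremental cost is affine and
    strictly increasing in the price (bilateral arms carry one extra
    processor-replacement stream), so Brent root finding converges quickly.
    """
    from scipy.optimize import brentq

    from .markov_engine import run_cohort
    from .parameters import apply_override, strategy_for

    def delta(price: float) -> float:
        p = apply_override(params, "costs.external_processor_replacement", price)
        bim = run_cohort(p, strategy_for(Arm.BIMODAL), lt)
        sim = run_cohort(p, strategy_for(Arm.SIMULTANEOUS), lt)
        return sim.totals.discounted_cost - bim.totals.discounted_cost

    lo, hi = bracket
    f_lo, f_hi = delta(lo) - target_delta_cost, delta(hi) - target_delta_cost
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"target incremental cost {target_delta_cost} not bracketed by "
            f"processor prices {bracket}")
    return float(brentq(lambda x: delta(x) - target_delta_cost, lo, hi,
                        xtol=1e-6))
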