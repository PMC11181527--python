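"""Cost-utility accounting: life years, QALYs, costs, increments, ICERs.

Accumulation walks a cohort trace cycle by cycle, adding living occupancy
(life years), occupancy-weighted utilities (QALYs) and occupancy-weighted
state costs plus per-arm programme costs, once undiscounted and once
discounted.  Discounting follows the annuity-due convention: cycle 0
(model entry) is undiscounted and cycle t carries (1 + r)^(-t).

Programme costs per cohort member alive and per year: the mass-media cost
per drinker in both arms, plus checkpoint unit cost x annual testing
coverage in the intervention arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov import STATE_INDEX, STATE_ORDER, CohortTrace, StrategyArm
from .params import (
    DEAD_STATES,
    EconomicSettings,
    HealthState,
    InterventionCosts,
    ModelOptions,
    PopulationParams,
    StateValue,
    ValidationError,
)

__all__ = [
    "ArmResult",
    "IncrementalResult",
    "DerivedPopulationQuantities",
    "PopulationTotals",
    "discount_factor",
    "arm_annual_cost",
    "accumulate",
    "incremental",
    "derived_population_quantities",
    "scale_to_population",
]

DOMINANT = "DOMINANT"
DOMINATED = "DOMINATED"


def discount_factor(year_index, rate: float):
    """(1 + rate)^(-year_index); year 0 maps to 1 (annuity-due)."""
    if rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {rate}")
    idx = np.asarray(year_index)
    if np.any(idx < 0):
        raise ValidationError("year_index must be >= 0")
    out = (1.0 + rate) ** (-idx.astype(float))
    return float(out) if np.isscalar(year_index) else out


@dataclass
class ArmResult:
    """Per-cohort-member lifetime outcomes for one strategy arm."""

    label: str
    life_years: float
    disc_life_years: float
    disc_qalys: float
    lifetime_cost: float
    disc_lifetime_cost: float

    def __post_init__(self) -> None:
        if self.disc_life_years > self.life_years + 1e-9:
            raise ValidationError("discounted life years exceed undiscounted")
        if self.disc_qalys > self.disc_life_years + 1e-9:
            raise ValidationError("discounted QALYs exceed discounted life years")
        if self.lifetime_cost < 0 or self.disc_lifetime_cost < 0:
            raise ValidationError("costs must be nonnegative")


@dataclass
class IncrementalResult:
    """Incremental cost, effect and ICER of the intervention arm versus the
    comparator.  ``icer`` is None when a dominance label applies."""

    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: str | None = None
    delta_life_years: float | None = None
    delta_disc_life_years: float | None = None
    delta_undisc_cost: float | None = None


def arm_annual_cost(costs: InterventionCosts, arm: StrategyArm) -> float:
    """Programme cost per cohort member alive, per year, for one arm.

    Both strategies carry the mass-media cost per drinker (the
    intervention is breath testing *added to* the campaigns); the
    intervention arm additionally pays checkpoint unit cost times the
    annual testing coverage.
    """
    cost = costs.media_cost_per_case
    if arm.apply_effect:
        cost += costs.checkpoint_unit_cost * costs.checkpoint_coverage
    return cost


def accumulate(trace: CohortTrace,
               state_values: dict[HealthState, StateValue],
               arm_cost_per_year: float,
               settings: EconomicSettings,
               options: ModelOptions | None = None) -> ArmResult:
    """Accumulate lifetime outcomes over a cohort trace.

    Life years count occupancy of living states at cycle start; QALYs
    weight each state's occupancy by its utility; costs add each state's
    annual cost plus the arm's programme cost per living member.  With the
    half-cycle switch on, per-cycle occupancy is the mean of the cycle's
    start and end distributions.
    """
    options = options or ModelOptions()
    missing = set(trace.states) - set(state_values)
    if missing:
        raise ValidationError(
            f"state values missing for {sorted(s.value for s in missing)}")

    occ = trace.occupancy[:-1]
    if options.half_cycle_correction:
        occ = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])
    n_cycles = occ.shape[0]

    util = np.array([state_values[s].utility for s in trace.states])
    cost = np.array([state_values[s].cost for s in trace.states])
    living_cols = [i for i, s in enumerate(trace.states) if s not in DEAD_STATES]

    living = occ[:, living_cols].sum(axis=1)
    qaly_t = occ @ util
    if options.cost_recurrence == "annual":
        programme = arm_cost_per_year * living
    else:  # once, at entry
        programme = np.zeros(n_cycles)
        programme[0] = arm_cost_per_year
    cost_t = occ @ cost + programme

    d = discount_factor(np.arange(n_cycles), settings.discount_rate)
    return ArmResult(
        label=trace.arm_label,
        life_years=float(living.sum()),
        disc_life_years=float(living @ d),
        disc_qalys=float(qaly_t @ d),
        lifetime_cost=float(cost_t.sum()),
        disc_lifetime_cost=float(cost_t @ d),
    )


def incremental(base: ArmResult, comp: ArmResult) -> IncrementalResult:
    """Incremental result of ``comp`` (intervention) versus ``base``.

    ICER = delta discounted cost / delta discounted QALYs when the trade-off
    is genuine; DOMINANT when the intervention is no more costly and more
    effective, DOMINATED when costlier and no more effective.
    """
    delta_cost = comp.disc_lifetime_cost - base.disc_lifetime_cost
    delta_effect = comp.disc_qalys - base.disc_qalys
    dominance = None
    icer: float | None = None
    if delta_cost <= 0 and delta_effect > 0:
        dominance = DOMINANT
    elif delta_cost > 0 and delta_effect <= 0:
        dominance = DOMINATED
    elif delta_effect != 0:
        icer = delta_cost / delta_effect
    return IncrementalResult(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        dominance=dominance,
        delta_life_years=comp.life_years - base.life_years,
        delta_disc_life_years=comp.disc_life_years - base.disc_life_years,
        delta_undisc_cost=comp.lifetime_cost - base.lifetime_cost,
    )


@dataclass
class DerivedPopulationQuantities:
    """Quantities derived from the population inputs: binge-drinker counts,
    mass-media beneficiaries (licence holders x drunk-driving proportion)
    and the media cost per beneficiary."""

    male_binge_count: int
    female_binge_count: int
    media_beneficiaries: int
    media_cost_per_case: float


def derived_population_quantities(pop: PopulationParams,
                                  media_total_cost: float
                                  ) -> DerivedPopulationQuantities:
    """Person counts use floor rounding; per-case cost is reported to two
    decimals."""
    beneficiaries = math.floor(pop.licenses * pop.drunk_driving_proportion)
    if beneficiaries == 0:
        raise ZeroDivisionError("no media-campaign beneficiaries")
    return DerivedPopulationQuantities(
        male_binge_count=math.floor(pop.male_population * pop.male_binge_pct),
        female_binge_count=math.floor(pop.female_population * pop.female_binge_pct),
        media_beneficiaries=beneficiaries,
        media_cost_per_case=round(media_total_cost / beneficiaries, 2),
    )


@dataclass
class PopulationTotals:
    n: int
    total_life_years_gained: float
    total_qalys_gained: float
    total_cost: float


def scale_to_population(inc: IncrementalResult, n: int) -> PopulationTotals:
    """Scale per-capita incremental gains to a population of ``n`` drinkers.

    Reproducing published population totals requires the unrounded
    per-capita increments; totals computed from rounded per-capita values
    differ in the last digits.
    """
    if n < 0:
        raise ValidationError(f"population size must be >= 0, got {n}")
    return PopulationTotals(
        n=n,
        total_life_years_gained=(inc.delta_life_years or 0.0) * n,
        total_qalys_gained=inc.delta_effect * n,
        total_cost=inc.delta_cost * n,
    )
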