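"""Shared fixtures: the default bundle, synthetic scenarios, and minimal
bundles with hand-set hazards for closed-form checks."""

from __future__ import annotations

import math

import pytest

from rbtcea import (
    EconomicSettings,
    EventType,
    HazardSpec,
    HealthState,
    InterventionCosts,
    InterventionEffect,
    ModelBundle,
    PopulationParams,
    StateValue,
    default_bundle,
    make_scenario,
)

#: intercept whose exp underflows to exactly 0.0 — a structurally "off" cause
NULL_INTERCEPT = -1e3


def constant_hazard_bundle(base_hazards: dict[EventType, float],
                           discount_rate: float = 0.0,
                           media_cost: float = 0.0,
                           checkpoint_cost: float = 0.0,
                           state_cost: float = 0.0,
                           utility: float = 1.0) -> ModelBundle:
    """Bundle with time-constant, covariate-free hazards (gamma = 0, no
    coefficients); unspecified events get hazard exactly 0."""
    hazards = {}
    for ev in EventType:
        h = base_hazards.get(ev, 0.0)
        hazards[ev] = HazardSpec(
            event=ev, intercept=math.log(h) if h > 0 else NULL_INTERCEPT,
            gamma=0.0, cf=1.0, coefficients={})
    states = {}
    for st in HealthState:
        dead = st in (HealthState.DEAD_ALC, HealthState.DEAD_NONALC)
        states[st] = StateValue(cost=0.0 if dead else state_cost,
                                utility=0.0 if dead else utility)
    return ModelBundle(
        population=PopulationParams(),
        economics=EconomicSettings(discount_rate=discount_rate),
        intervention_effect=InterventionEffect(),
        intervention_costs=InterventionCosts(
            checkpoint_unit_cost=checkpoint_cost,
            media_cost_per_case=media_cost),
        states=states,
        hazards=hazards,
    )


@pytest.fixture(scope="session")
def bundle() -> ModelBundle:
    return default_bundle()


@pytest.fixture(scope="session")
def scenario():
    return make_scenario(3, "realistic")


@pytest.fixture(scope="session")
def easy_scenario():
    return make_scenario(5, "easy")


@pytest.fixture()
def null_bundle() -> ModelBundle:
    return constant_hazard_bundle({})
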