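"""Synthetic model scenarios with known ground truth.

The source transition parameters of the original analysis (Scottish
hazard-ratio coefficients recalibrated to Thai survey, cohort and
life-table data) were never published.  This module generates complete,
validated parameter bundles with known ground truth so every pipeline
stage — hazards, calibration, cohort runs, economics, PSA — is testable
end to end without any external data.

Scenario construction anchors the age-20 all-cause first-event probability
to an epidemiologically plausible band (young-adult annual event risk of a
few per mille to a few percent), gives death causes Gompertz-like time
slopes (mortality doubling roughly every 7–14 years), and forces the
binge-drinking and AUDIT coefficients of the alcohol-attributable causes
positive.  Population, economic and intervention parameters keep the
published Thai values: those *are* the study conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import hazards as hz
from .params import (
    DEAD_STATES,
    EconomicSettings,
    EventType,
    HazardSpec,
    HealthState,
    InterventionCosts,
    InterventionEffect,
    ModelBundle,
    PopulationParams,
    StateValue,
    base_case_profile,
)
from .psa import DistributionSpec

__all__ = ["SyntheticScenario", "make_scenario", "make_calibration_targets",
           "make_psa_specs"]

_ALC_EVENTS = (EventType.WHOLLY_ALC_HOSP, EventType.PARTLY_ALC_HOSP,
               EventType.ALC_DEATH)
_CVD_EVENTS = (EventType.NONALC_HOSP_NONEM_CVD, EventType.NONALC_HOSP_EM_CVD)

#: relative first-event weights (Dirichlet concentration): non-alcohol
#: hospitalisations dominate first events in a young cohort, deaths are rare
_EVENT_WEIGHT_ALPHA = {
    EventType.WHOLLY_ALC_HOSP: 1.0,
    EventType.PARTLY_ALC_HOSP: 1.5,
    EventType.ALC_DEATH: 0.4,
    EventType.NONALC_DEATH: 0.5,
    EventType.NONALC_HOSP_NONEM_NONCVD: 4.0,
    EventType.NONALC_HOSP_NONEM_CVD: 1.0,
    EventType.NONALC_HOSP_EM_NONCVD: 3.0,
    EventType.NONALC_HOSP_EM_CVD: 0.8,
}

#: annual all-cause first-event probability band at age 20
_P0_BAND = {"realistic": (0.005, 0.05), "easy": (0.05, 0.2)}


@dataclass
class SyntheticScenario:
    """A reproducible ground-truth scenario.

    ``cf_true`` holds the calibration-factor multipliers used to generate
    calibration targets (all 1 in the bundle itself); ``orderings`` records
    qualitative relations the generated parameters guarantee, for use as
    test oracles.
    """

    seed: int
    difficulty: str
    bundle: ModelBundle
    cf_true: dict[EventType, float]
    calibration_age: int
    orderings: dict[str, bool] = field(default_factory=dict)


def make_scenario(seed: int, difficulty: str = "realistic") -> SyntheticScenario:
    """Generate a validated scenario; same seed, same scenario, bit for bit.

    ``easy`` scenarios use higher event probabilities (faster absorption,
    cheaper tests); ``realistic`` ones sit in the plausible epidemiological
    band and give life expectancies in the 70s.
    """
    if difficulty not in _P0_BAND:
        raise ValueError(f"difficulty must be one of {sorted(_P0_BAND)}")
    rng = np.random.default_rng(np.random.SeedSequence([1_234_567, seed]))
    lo, hi = _P0_BAND[difficulty]
    p0 = rng.uniform(lo, hi)
    total_hazard = -math.log1p(-p0)
    weights = rng.dirichlet([_EVENT_WEIGHT_ALPHA[ev] for ev in EventType])
    # floor each cause at 1% of the total so no hazard degenerates to ~0
    weights = 0.99 * weights + 0.01 / len(weights)

    anchor = base_case_profile("male")
    x = anchor.as_dict()
    specs: dict[EventType, HazardSpec] = {}
    for w, ev in zip(weights, EventType):
        alc = ev in _ALC_EVENTS
        cvd = ev in _CVD_EVENTS
        death = ev in (EventType.ALC_DEATH, EventType.NONALC_DEATH)
        coeffs = {
            "age": rng.uniform(0.005, 0.02),
            "audit_score": rng.uniform(0.02, 0.06) if alc else rng.uniform(0, 0.01),
            "binge": rng.uniform(0.4, 1.0) if alc else rng.uniform(0, 0.15),
            "bmi_class": rng.uniform(0.1, 0.25) if cvd else rng.uniform(0, 0.1),
            "cvd": rng.uniform(0.5, 1.2) if cvd else rng.uniform(0.1, 0.4),
            "diabetes": rng.uniform(0.1, 0.4),
            "cigs_per_day": rng.uniform(0.01, 0.03) if (cvd or death)
                            else rng.uniform(0, 0.01),
            "phys_act": -rng.uniform(0.05, 0.15),
            "ses": -rng.uniform(0.02, 0.1),
            "prior_hosp": rng.uniform(0.2, 0.6),
            "ghq": rng.uniform(0.05, 0.2),
        }
        gamma = rng.uniform(0.05, 0.12) if death else rng.uniform(0.01, 0.05)
        xb = sum(c * x[k] for k, c in coeffs.items())
        specs[ev] = HazardSpec(event=ev, intercept=math.log(w * total_hazard) - xb,
                               gamma=gamma, cf=1.0, coefficients=coeffs)

    states: dict[HealthState, StateValue] = {}
    healthy_u = rng.uniform(0.85, 0.95)
    for st in HealthState:
        if st in DEAD_STATES:
            states[st] = StateValue(cost=0.0, utility=0.0)
        elif st is HealthState.HEALTHY:
            states[st] = StateValue(cost=0.0, utility=healthy_u)
        else:
            states[st] = StateValue(cost=float(rng.uniform(5_000, 30_000)),
                                    utility=float(rng.uniform(0.6,
                                                              healthy_u - 0.02)))

    bundle = ModelBundle(
        population=PopulationParams(),
        economics=EconomicSettings(),
        intervention_effect=InterventionEffect(),
        intervention_costs=InterventionCosts(),
        states=states,
        hazards=specs,
    )

    male, female = base_case_profile("male"), base_case_profile("female")
    orderings = {
        "male_alc_hosp_hazard_gt_female": all(
            hz.cause_specific_hazard(specs[ev], male, 0.0)
            > hz.cause_specific_hazard(specs[ev], female, 0.0)
            for ev in _ALC_EVENTS),
        "death_hazard_increasing_in_time": all(
            specs[ev].gamma > 0 for ev in
            (EventType.ALC_DEATH, EventType.NONALC_DEATH)),
    }
    return SyntheticScenario(seed=seed, difficulty=difficulty, bundle=bundle,
                             cf_true={ev: 1.0 for ev in EventType},
                             calibration_age=70, orderings=orderings)


def make_calibration_targets(scenario: SyntheticScenario,
                             cf_true: dict[EventType, float],
                             by_age: int | None = None,
                             sex: str = "male") -> dict[EventType, float]:
    """Cumulative first-event incidences from the ground-truth model with
    the given calibration factors applied — the inputs the calibration
    machinery must invert."""
    for ev, cf in cf_true.items():
        if cf <= 0:
            raise ValueError(f"cf_true[{ev.value}] must be > 0, got {cf}")
    by_age = by_age or scenario.calibration_age
    profile = scenario.bundle.profiles[sex]
    hazards = {}
    for ev, spec in scenario.bundle.hazards.items():
        cf = cf_true.get(ev, 1.0)
        hazards[ev] = HazardSpec(event=ev, intercept=spec.intercept,
                                 gamma=spec.gamma, cf=spec.cf * cf,
                                 coefficients=dict(spec.coefficients))
    return {ev: hz.cumulative_incidence(hazards, ev, profile,
                                        profile.age, by_age)
            for ev in cf_true}


def _beta_moment_params(mean: float, sd: float) -> dict[str, float]:
    if mean <= 0.0 or mean >= 1.0 or sd <= 0.0:
        return {"alpha": 0.0, "beta": 0.0, "loc": mean}  # point mass
    var = min(sd * sd, 0.5 * mean * (1.0 - mean))
    nu = mean * (1.0 - mean) / var - 1.0
    return {"alpha": mean * nu, "beta": (1.0 - mean) * nu}


def make_psa_specs(scenario: SyntheticScenario,
                   relative_se: float = 0.1) -> list[DistributionSpec]:
    """Moment-matched distribution specs centred on the scenario's true
    values: beta for [0,1] parameters, gamma for costs, lognormal for the
    calibration factors (log-SD = ``relative_se``)."""
    if relative_se <= 0:
        raise ValueError(f"relative_se must be > 0, got {relative_se}")
    b = scenario.bundle
    specs: list[DistributionSpec] = []

    for st, sv in b.states.items():
        if st in DEAD_STATES:
            continue
        specs.append(DistributionSpec(
            path=f"states.{st.value}.utility", family="beta",
            params=_beta_moment_params(sv.utility, relative_se * sv.utility)))
        if sv.cost > 0:
            specs.append(DistributionSpec(
                path=f"states.{st.value}.cost", family="gamma",
                params={"shape": 1.0 / relative_se ** 2,
                        "scale": sv.cost * relative_se ** 2}))

    for leaf in ("rti_reduction", "fatality_reduction"):
        mean = getattr(b.intervention_effect, leaf)
        specs.append(DistributionSpec(
            path=f"intervention_effect.{leaf}", family="beta",
            params=_beta_moment_params(mean, relative_se * mean)))
    specs.append(DistributionSpec(
        path="intervention_costs.checkpoint_coverage", family="beta",
        params=_beta_moment_params(b.intervention_costs.checkpoint_coverage,
                                   relative_se
                                   * b.intervention_costs.checkpoint_coverage)))
    for leaf in ("checkpoint_unit_cost", "media_cost_per_case"):
        mean = getattr(b.intervention_costs, leaf)
        specs.append(DistributionSpec(
            path=f"intervention_costs.{leaf}", family="gamma",
            params={"shape": 1.0 / relative_se ** 2,
                    "scale": mean * relative_se ** 2}))

    for ev, spec in b.hazards.items():
        specs.append(DistributionSpec(
            path=f"hazards.{ev.value}.cf", family="lognormal",
            params={"mu": math.log(spec.cf), "sigma": relative_se}))
    return specs
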