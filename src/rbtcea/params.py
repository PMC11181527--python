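"""Parameter registry: domain types, validation, and config I/O.

Every quantity the model consumes lives here: the cohort risk profile
(covariate vector of the cause-specific hazard equations), per-event hazard
specifications, economic settings, per-state costs and utilities,
intervention efficacy and costs, and population denominators.  Bundles are
serialized as a YAML config referencing a CSV hazard-coefficient table so
that parameter sets stay diffable and fixtures are ordinary inputs.

Covariate encoding convention (used by the hazard linear predictor):
indicators are 0/1, ordered categories enter as their integer score, AUDIT
and cigarettes/day enter as raw counts.
"""

from __future__ import annotations

import copy
import enum
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "EventType",
    "HealthState",
    "RiskProfile",
    "HazardSpec",
    "EconomicSettings",
    "StateValue",
    "InterventionEffect",
    "InterventionCosts",
    "PopulationParams",
    "ModelOptions",
    "ModelBundle",
    "base_case_profile",
    "default_bundle",
    "load_model_config",
    "save_model_config",
    "HOSPITALISATION_EVENTS",
    "DEATH_EVENTS",
    "EVENT_DESTINATION",
    "LIVING_STATES",
    "DEAD_STATES",
]


class ValidationError(ValueError):
    """A parameter violated one of its declared invariants."""


class EventType(enum.Enum):
    """The eight competing first-event causes.

    Five cause groups, with non-alcohol hospitalisation partitioned into
    four admission types (emergency vs non-emergency, CVD vs non-CVD).
    """

    WHOLLY_ALC_HOSP = "WHOLLY_ALC_HOSP"
    PARTLY_ALC_HOSP = "PARTLY_ALC_HOSP"
    ALC_DEATH = "ALC_DEATH"
    NONALC_DEATH = "NONALC_DEATH"
    NONALC_HOSP_NONEM_NONCVD = "NONALC_HOSP_NONEM_NONCVD"
    NONALC_HOSP_NONEM_CVD = "NONALC_HOSP_NONEM_CVD"
    NONALC_HOSP_EM_NONCVD = "NONALC_HOSP_EM_NONCVD"
    NONALC_HOSP_EM_CVD = "NONALC_HOSP_EM_CVD"


HOSPITALISATION_EVENTS = (
    EventType.WHOLLY_ALC_HOSP,
    EventType.PARTLY_ALC_HOSP,
    EventType.NONALC_HOSP_NONEM_NONCVD,
    EventType.NONALC_HOSP_NONEM_CVD,
    EventType.NONALC_HOSP_EM_NONCVD,
    EventType.NONALC_HOSP_EM_CVD,
)
DEATH_EVENTS = (EventType.ALC_DEATH, EventType.NONALC_DEATH)


class HealthState(enum.Enum):
    """Markov states: event-free entry cohort, post-first-event states per
    hospitalisation cause, and two absorbing death states."""

    HEALTHY = "HEALTHY"
    POST_WHOLLY_ALC = "POST_WHOLLY_ALC"
    POST_PARTLY_ALC = "POST_PARTLY_ALC"
    POST_NONALC_NONEM_NONCVD = "POST_NONALC_NONEM_NONCVD"
    POST_NONALC_NONEM_CVD = "POST_NONALC_NONEM_CVD"
    POST_NONALC_EM_NONCVD = "POST_NONALC_EM_NONCVD"
    POST_NONALC_EM_CVD = "POST_NONALC_EM_CVD"
    DEAD_ALC = "DEAD_ALC"
    DEAD_NONALC = "DEAD_NONALC"


LIVING_STATES = tuple(
    s for s in HealthState if s not in (HealthState.DEAD_ALC, HealthState.DEAD_NONALC)
)
DEAD_STATES = (HealthState.DEAD_ALC, HealthState.DEAD_NONALC)

#: destination state for each first event (death events go straight to the
#: absorbing states; hospitalisations to the matching post-event state).
EVENT_DESTINATION: dict[EventType, HealthState] = {
    EventType.WHOLLY_ALC_HOSP: HealthState.POST_WHOLLY_ALC,
    EventType.PARTLY_ALC_HOSP: HealthState.POST_PARTLY_ALC,
    EventType.ALC_DEATH: HealthState.DEAD_ALC,
    EventType.NONALC_DEATH: HealthState.DEAD_NONALC,
    EventType.NONALC_HOSP_NONEM_NONCVD: HealthState.POST_NONALC_NONEM_NONCVD,
    EventType.NONALC_HOSP_NONEM_CVD: HealthState.POST_NONALC_NONEM_CVD,
    EventType.NONALC_HOSP_EM_NONCVD: HealthState.POST_NONALC_EM_NONCVD,
    EventType.NONALC_HOSP_EM_CVD: HealthState.POST_NONALC_EM_CVD,
}

#: death state that a 28-day case-fatality split on a hospitalisation
#: transition routes to.
EVENT_CASE_FATALITY_DESTINATION: dict[EventType, HealthState] = {
    EventType.WHOLLY_ALC_HOSP: HealthState.DEAD_ALC,
    EventType.PARTLY_ALC_HOSP: HealthState.DEAD_ALC,
    EventType.NONALC_HOSP_NONEM_NONCVD: HealthState.DEAD_NONALC,
    EventType.NONALC_HOSP_NONEM_CVD: HealthState.DEAD_NONALC,
    EventType.NONALC_HOSP_EM_NONCVD: HealthState.DEAD_NONALC,
    EventType.NONALC_HOSP_EM_CVD: HealthState.DEAD_NONALC,
}


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class RiskProfile:
    """One cohort's covariate vector x.

    Fields follow the base-scenario risk-factor table: AUDIT score 0-40,
    binge-drinking indicator, BMI class (0 normal / 1 overweight /
    2 obesity), CVD and diabetes indicators, cigarettes per day, physical
    activity 0-3 (none..high), socioeconomic status 1-5 (most..least
    deprived), prior hospitalisation 0-2 (none / last year / over a year),
    GHQ class 1-3 (best..worst).
    """

    age: int = 20
    audit_score: int = 7
    binge: int = 0
    bmi_class: int = 0
    cvd: int = 0
    diabetes: int = 0
    cigs_per_day: int = 0
    phys_act: int = 2
    ses: int = 3
    prior_hosp: int = 0
    ghq: int = 1

    def __post_init__(self) -> None:
        _check(self.age >= 0, f"age must be >= 0, got {self.age}")
        _check(0 <= self.audit_score <= 40,
               f"audit_score must be in [0, 40], got {self.audit_score}")
        _check(self.binge in (0, 1), f"binge must be 0/1, got {self.binge}")
        _check(self.bmi_class in (0, 1, 2),
               f"bmi_class must be in {{0,1,2}}, got {self.bmi_class}")
        _check(self.cvd in (0, 1), f"cvd must be 0/1, got {self.cvd}")
        _check(self.diabetes in (0, 1), f"diabetes must be 0/1, got {self.diabetes}")
        _check(self.cigs_per_day >= 0,
               f"cigs_per_day must be >= 0, got {self.cigs_per_day}")
        _check(self.phys_act in (0, 1, 2, 3),
               f"phys_act must be in {{0..3}}, got {self.phys_act}")
        _check(self.ses in (1, 2, 3, 4, 5), f"ses must be in {{1..5}}, got {self.ses}")
        _check(self.prior_hosp in (0, 1, 2),
               f"prior_hosp must be in {{0,1,2}}, got {self.prior_hosp}")
        _check(self.ghq in (1, 2, 3), f"ghq must be in {{1,2,3}}, got {self.ghq}")

    def replace(self, **kwargs: Any) -> "RiskProfile":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


PROFILE_FIELDS = tuple(f.name for f in fields(RiskProfile))


def base_case_profile(sex: str) -> RiskProfile:
    """Base-scenario risk profile for 20-year-old drinkers.

    Both sexes: AUDIT 7 (low-risk consumption), normal BMI, no CVD or
    diabetes, 4 cigarettes/day, medium physical activity, middle SES, no
    prior hospitalisation, best GHQ class.  Males are binge drinkers in the
    base case; females are not.
    """
    if sex not in ("male", "female"):
        raise ValidationError(f"sex must be 'male' or 'female', got {sex!r}")
    return RiskProfile(
        age=20, audit_score=7, binge=1 if sex == "male" else 0, bmi_class=0,
        cvd=0, diabetes=0, cigs_per_day=4, phys_act=2, ses=3, prior_hosp=0, ghq=1,
    )


@dataclass
class HazardSpec:
    """Cause-specific hazard parameters for one event type.

    The hazard at time t since cohort entry is
    ``exp(intercept + x.b) * cf * exp(gamma * t)`` where x is the risk
    profile, b the per-covariate log hazard ratios, gamma the log-linear
    time slope and cf a calibration factor fitted against external
    incidence targets.
    """

    event: EventType
    intercept: float
    gamma: float = 0.0
    cf: float = 1.0
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check(self.cf > 0, f"{self.event.value}: calibration_factor must be > 0, "
                            f"got {self.cf}")
        _check(math.isfinite(self.intercept) and math.isfinite(self.gamma),
               f"{self.event.value}: intercept/gamma must be finite")
        unknown = set(self.coefficients) - set(PROFILE_FIELDS)
        _check(not unknown,
               f"{self.event.value}: coefficients reference unknown risk-profile "
               f"fields {sorted(unknown)}")


@dataclass
class EconomicSettings:
    """Discounting and decision-rule settings (Thai reference case)."""

    discount_rate: float = 0.03
    wtp_threshold: float = 160_000.0
    horizon_age: int = 100
    currency: str = "THB"

    def __post_init__(self) -> None:
        _check(0.0 <= self.discount_rate < 1.0,
               f"discount_rate must be in [0, 1), got {self.discount_rate}")
        _check(self.wtp_threshold >= 0,
               f"wtp_threshold must be >= 0, got {self.wtp_threshold}")
        _check(self.horizon_age > 0, "horizon_age must be positive")


@dataclass
class StateValue:
    """Annual cost (THB/cycle) and utility weight for one health state."""

    cost: float = 0.0
    utility: float = 1.0

    def __post_init__(self) -> None:
        _check(self.cost >= 0, f"state cost must be >= 0, got {self.cost}")
        _check(0.0 <= self.utility <= 1.0,
               f"state utility must be in [0, 1], got {self.utility}")


@dataclass
class InterventionEffect:
    """Efficacy of random breath testing added to mass media campaigns:
    fractional reductions in alcohol-related road-traffic injuries and
    fatalities at current checkpoint coverage."""

    rti_reduction: float = 0.106
    fatality_reduction: float = 0.171

    def __post_init__(self) -> None:
        for name in ("rti_reduction", "fatality_reduction"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v}")


@dataclass
class InterventionCosts:
    """Programme costs (2021 THB): sobriety-checkpoint unit cost per tested
    case, annual checkpoint coverage, and mass-media cost per drinker."""

    checkpoint_unit_cost: float = 1_322.0
    checkpoint_coverage: float = 0.046
    media_cost_per_case: float = 10.48
    media_total_cost: float = 194_821_538.0

    def __post_init__(self) -> None:
        for name in ("checkpoint_unit_cost", "checkpoint_coverage",
                     "media_cost_per_case", "media_total_cost"):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")
        _check(self.checkpoint_coverage <= 1.0,
               f"checkpoint_coverage must be in [0, 1], "
               f"got {self.checkpoint_coverage}")


@dataclass
class PopulationParams:
    """Population denominators (Thailand, 2021) used to scale per-capita
    results and derive media-campaign beneficiaries."""

    male_population: int = 32_339_118
    female_population: int = 33_960_884
    male_binge_pct: float = 0.0281
    female_binge_pct: float = 0.0092
    licenses: int = 37_338_139
    drunk_driving_proportion: float = 0.498

    def __post_init__(self) -> None:
        for name in ("male_population", "female_population", "licenses"):
            v = getattr(self, name)
            _check(isinstance(v, int) and v >= 0,
                   f"{name} must be a nonnegative integer, got {v}")
        for name in ("male_binge_pct", "female_binge_pct",
                     "drunk_driving_proportion"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v}")

    def population(self, sex: str) -> int:
        return self.male_population if sex == "male" else self.female_population

    def binge_pct(self, sex: str) -> float:
        return self.male_binge_pct if sex == "male" else self.female_binge_pct


@dataclass
class ModelOptions:
    """Structural switches of the cohort engine.

    cycle_length is fixed at one year in the base configuration.  The
    28-day case-fatality fractions split each hospitalisation transition
    towards the matching death state; they default to 0 because short-term
    deaths are already competing first events.  rti_share is the fraction
    of the partly-alcohol hospitalisation and alcohol-death hazards
    attributable to road-traffic injury (the share the intervention acts
    on).  cost_recurrence: 'annual' accrues programme costs every cycle
    alive, 'once' only at entry.
    """

    cycle_length: float = 1.0
    half_cycle_correction: bool = False
    rti_share: float = 1.0
    case_fatality: dict[EventType, float] = field(default_factory=dict)
    cost_recurrence: str = "annual"
    min_alive: float = 1e-9

    def __post_init__(self) -> None:
        _check(self.cycle_length > 0, "cycle_length must be > 0")
        _check(0.0 <= self.rti_share <= 1.0,
               f"rti_share must be in [0, 1], got {self.rti_share}")
        _check(self.cost_recurrence in ("annual", "once"),
               f"cost_recurrence must be 'annual' or 'once', "
               f"got {self.cost_recurrence!r}")
        for ev, f_ in self.case_fatality.items():
            _check(ev in HOSPITALISATION_EVENTS,
                   f"case_fatality only applies to hospitalisation events, "
                   f"got {ev}")
            _check(0.0 <= f_ <= 1.0,
                   f"case_fatality[{ev.value}] must be in [0, 1], got {f_}")

    def case_fatality_for(self, event: EventType) -> float:
        return self.case_fatality.get(event, 0.0)


@dataclass
class ModelBundle:
    """A complete, validated parameter set for one model run."""

    population: PopulationParams
    economics: EconomicSettings
    intervention_effect: InterventionEffect
    intervention_costs: InterventionCosts
    states: dict[HealthState, StateValue]
    hazards: dict[EventType, HazardSpec]
    options: ModelOptions = field(default_factory=ModelOptions)
    profiles: dict[str, RiskProfile] = field(
        default_factory=lambda: {"male": base_case_profile("male"),
                                 "female": base_case_profile("female")})

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing_states = set(HealthState) - set(self.states)
        _check(not missing_states,
               f"states missing entries for {sorted(s.value for s in missing_states)}")
        missing_events = set(EventType) - set(self.hazards)
        _check(not missing_events,
               f"hazards missing entries for {sorted(e.value for e in missing_events)}")
        for st in DEAD_STATES:
            sv = self.states[st]
            _check(sv.utility == 0.0, f"{st.value}: death-state utility must be 0")
            _check(sv.cost == 0.0, f"{st.value}: death-state cost must be 0")
        for ev, spec in self.hazards.items():
            _check(spec.event == ev, f"hazard map key {ev} != spec.event {spec.event}")
        for prof in self.profiles.values():
            _check(self.economics.horizon_age > prof.age,
                   f"horizon_age {self.economics.horizon_age} must exceed entry "
                   f"age {prof.age}")

    def copy(self) -> "ModelBundle":
        return copy.deepcopy(self)

    # --- dotted-path access (used by the PSA sampler) -------------------

    def _resolve(self, path: str) -> tuple[Any, str]:
        parts = path.split(".")
        obj: Any = self
        for p in parts[:-1]:
            if isinstance(obj, dict):
                key: Any = p
                sample = next(iter(obj))
                if isinstance(sample, EventType):
                    key = EventType(p)
                elif isinstance(sample, HealthState):
                    key = HealthState(p)
                obj = obj[key]
            else:
                if not hasattr(obj, p):
                    raise ValidationError(f"unknown parameter path {path!r}")
                obj = getattr(obj, p)
        return obj, parts[-1]

    def get_path(self, path: str) -> float:
        obj, leaf = self._resolve(path)
        if isinstance(obj, dict):
            raise ValidationError(f"path {path!r} does not end at a scalar")
        if not hasattr(obj, leaf):
            raise ValidationError(f"unknown parameter path {path!r}")
        return getattr(obj, leaf)

    def set_path(self, path: str, value: float) -> None:
        obj, leaf = self._resolve(path)
        if not hasattr(obj, leaf):
            raise ValidationError(f"unknown parameter path {path!r}")
        setattr(obj, leaf, value)
        # re-run the leaf object's own invariant checks
        if hasattr(obj, "__post_init__"):
            obj.__post_init__()


# ---------------------------------------------------------------------------
# Default parameter set
# ---------------------------------------------------------------------------

# Printed population/economic/intervention inputs are built into the type
# defaults above.  Hazard coefficients, per-state utilities and costs were
# never published; the constants below are the package's documented
# synthetic defaults, anchored so the age-20 cohort's all-cause first-event
# probability and lifetime trace are epidemiologically plausible (young-adult
# all-cause mortality of order 1e-3/year, life expectancy in the 70s).

# per-event: (annual hazard for the base-case male profile at entry, gamma)
_DEFAULT_BASE_HAZARD = {
    EventType.WHOLLY_ALC_HOSP: (0.0015, 0.010),
    EventType.PARTLY_ALC_HOSP: (0.0035, 0.012),
    EventType.ALC_DEATH: (0.00030, 0.052),
    EventType.NONALC_DEATH: (0.00040, 0.090),
    EventType.NONALC_HOSP_NONEM_NONCVD: (0.0080, 0.020),
    EventType.NONALC_HOSP_NONEM_CVD: (0.0012, 0.045),
    EventType.NONALC_HOSP_EM_NONCVD: (0.0055, 0.025),
    EventType.NONALC_HOSP_EM_CVD: (0.0010, 0.050),
}

_ALC_EVENTS = (EventType.WHOLLY_ALC_HOSP, EventType.PARTLY_ALC_HOSP,
               EventType.ALC_DEATH)
_CVD_EVENTS = (EventType.NONALC_HOSP_NONEM_CVD, EventType.NONALC_HOSP_EM_CVD)


def _default_coefficients(event: EventType) -> dict[str, float]:
    alc = event in _ALC_EVENTS
    cvd = event in _CVD_EVENTS
    return {
        "age": 0.010,
        "audit_score": 0.045 if alc else 0.005,
        "binge": 0.70 if alc else 0.05,
        "bmi_class": 0.18 if cvd else 0.05,
        "cvd": 0.90 if cvd else 0.25,
        "diabetes": 0.25,
        "cigs_per_day": 0.020 if (cvd or event in DEATH_EVENTS) else 0.008,
        "phys_act": -0.10,
        "ses": -0.06,
        "prior_hosp": 0.20,
        "ghq": 0.12,
    }


def _specs_from_base_hazards(
    base_hazards: Mapping[EventType, tuple[float, float]],
    coefficients: Mapping[EventType, dict[str, float]],
    anchor: RiskProfile,
) -> dict[EventType, HazardSpec]:
    """Build HazardSpecs whose hazard at t=0 for ``anchor`` equals the
    stated base hazard (intercept solved from the linear predictor)."""
    specs = {}
    x = anchor.as_dict()
    for ev, (h0, gamma) in base_hazards.items():
        b = coefficients[ev]
        xb = sum(c * x[k] for k, c in b.items())
        specs[ev] = HazardSpec(event=ev, intercept=math.log(h0) - xb,
                               gamma=gamma, cf=1.0, coefficients=dict(b))
    return specs


_DEFAULT_STATE_VALUES = {
    HealthState.HEALTHY: (0.0, 0.92),
    HealthState.POST_WHOLLY_ALC: (15_000.0, 0.72),
    HealthState.POST_PARTLY_ALC: (12_000.0, 0.76),
    HealthState.POST_NONALC_NONEM_NONCVD: (6_000.0, 0.85),
    HealthState.POST_NONALC_NONEM_CVD: (12_000.0, 0.78),
    HealthState.POST_NONALC_EM_NONCVD: (9_000.0, 0.82),
    HealthState.POST_NONALC_EM_CVD: (18_000.0, 0.74),
    HealthState.DEAD_ALC: (0.0, 0.0),
    HealthState.DEAD_NONALC: (0.0, 0.0),
}


def default_bundle() -> ModelBundle:
    """The default parameter bundle: printed population, economic and
    intervention inputs plus the package's synthetic hazard/state defaults.
    Runs the base case with zero external input."""
    coeffs = {ev: _default_coefficients(ev) for ev in EventType}
    hazards = _specs_from_base_hazards(_DEFAULT_BASE_HAZARD, coeffs,
                                       base_case_profile("male"))
    states = {st: StateValue(cost=c, utility=u)
              for st, (c, u) in _DEFAULT_STATE_VALUES.items()}
    return ModelBundle(
        population=PopulationParams(),
        economics=EconomicSettings(),
        intervention_effect=InterventionEffect(),
        intervention_costs=InterventionCosts(),
        states=states,
        hazards=hazards,
    )


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS = ("population", "economics", "intervention", "states",
                    "hazards", "model", "profiles")


def _build(cls: type, section: Mapping[str, Any], name: str) -> Any:
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValidationError(f"[{name}] unknown keys {sorted(unknown)}")
    return cls(**section)


def load_model_config(path: str | Path) -> ModelBundle:
    """Load a full parameter bundle from a YAML config.

    The config has sections population, economics, intervention (efficacy
    and cost fields together), states (per-state cost/utility), model
    (engine options), profiles, and a ``hazards`` entry naming a CSV with
    columns event, term, value (terms: intercept, gamma, cf, or a
    risk-profile field name).  Relative table paths resolve against the
    config file's directory.  Unknown keys are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"config root must be a mapping, got {type(raw)}")
    unknown = set(raw) - set(_CONFIG_SECTIONS)
    if unknown:
        raise ValidationError(f"unknown config sections {sorted(unknown)}")

    population = _build(PopulationParams, raw.get("population", {}), "population")
    economics = _build(EconomicSettings, raw.get("economics", {}), "economics")

    interv = dict(raw.get("intervention", {}))
    eff_keys = {f.name for f in fields(InterventionEffect)}
    cost_keys = {f.name for f in fields(InterventionCosts)}
    unknown = set(interv) - eff_keys - cost_keys
    if unknown:
        raise ValidationError(f"[intervention] unknown keys {sorted(unknown)}")
    effect = InterventionEffect(**{k: v for k, v in interv.items() if k in eff_keys})
    icosts = InterventionCosts(**{k: v for k, v in interv.items() if k in cost_keys})

    states_raw = raw.get("states", {})
    states = {}
    for name, sv in states_raw.items():
        try:
            st = HealthState(name)
        except ValueError:
            raise ValidationError(f"[states] unknown health state {name!r}") from None
        states[st] = _build(StateValue, sv, f"states.{name}")

    model_raw = dict(raw.get("model", {}))
    if "case_fatality" in model_raw:
        model_raw["case_fatality"] = {
            EventType(k): v for k, v in model_raw["case_fatality"].items()}
    options = _build(ModelOptions, model_raw, "model")

    profiles_raw = raw.get("profiles")
    if profiles_raw is None:
        profiles = {"male": base_case_profile("male"),
                    "female": base_case_profile("female")}
    else:
        profiles = {sex: _build(RiskProfile, p, f"profiles.{sex}")
                    for sex, p in profiles_raw.items()}

    hazards_entry = raw.get("hazards")
    if hazards_entry is None:
        raise ValidationError("config must name a hazards CSV under 'hazards'")
    hz_path = Path(hazards_entry)
    if not hz_path.is_absolute():
        hz_path = path.parent / hz_path
    hazards = read_hazard_table(hz_path)

    return ModelBundle(population=population, economics=economics,
                       intervention_effect=effect, intervention_costs=icosts,
                       states=states, hazards=hazards, options=options,
                       profiles=profiles)


def read_hazard_table(path: str | Path) -> dict[EventType, HazardSpec]:
    """Read the per-event hazard coefficient table (CSV: event, term, value)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"hazard table not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    expected = {"event", "term", "value"}
    if set(df.columns) != expected:
        raise ValidationError(
            f"hazard table must have columns {sorted(expected)}, "
            f"got {sorted(df.columns)}")
    specs: dict[EventType, HazardSpec] = {}
    for ev_name, grp in df.groupby("event", sort=False):
        try:
            ev = EventType(ev_name)
        except ValueError:
            raise ValidationError(f"unknown event type {ev_name!r}") from None
        terms = dict(zip(grp["term"], grp["value"].astype(float)))
        intercept = terms.pop("intercept", 0.0)
        gamma = terms.pop("gamma", 0.0)
        cf = terms.pop("cf", 1.0)
        specs[ev] = HazardSpec(event=ev, intercept=intercept, gamma=gamma,
                               cf=cf, coefficients=terms)
    return specs


def write_hazard_table(hazards: Mapping[EventType, HazardSpec],
                       path: str | Path) -> None:
    rows = []
    for ev, spec in hazards.items():
        rows.append({"event": ev.value, "term": "intercept", "value": spec.intercept})
        rows.append({"event": ev.value, "term": "gamma", "value": spec.gamma})
        rows.append({"event": ev.value, "term": "cf", "value": spec.cf})
        for k, v in spec.coefficients.items():
            rows.append({"event": ev.value, "term": k, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def save_model_config(bundle: ModelBundle, out_dir: str | Path,
                      name: str = "config") -> Path:
    """Serialize a bundle to ``<out_dir>/<name>.yaml`` + hazards CSV.

    Round-trips through :func:`load_model_config` field-by-field.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hz_name = f"{name}_hazards.csv"
    write_hazard_table(bundle.hazards, out_dir / hz_name)

    def _asdict(obj: Any) -> dict[str, Any]:
        return {f.name: getattr(obj, f.name) for f in fields(obj)}

    cfg = {
        "population": _asdict(bundle.population),
        "economics": _asdict(bundle.economics),
        "intervention": {**_asdict(bundle.intervention_effect),
                         **_asdict(bundle.intervention_costs)},
        "states": {st.value: _asdict(sv) for st, sv in bundle.states.items()},
        "model": {**_asdict(bundle.options),
                  "case_fatality": {ev.value: v for ev, v in
                                    bundle.options.case_fatality.items()}},
        "profiles": {sex: p.as_dict() for sex, p in bundle.profiles.items()},
        "hazards": hz_name,
    }
    cfg_path = out_dir / f"{name}.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return cfg_path
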