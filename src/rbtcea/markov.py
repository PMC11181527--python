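"""Cohort Markov engine for the alcohol-intervention state space.

States: an event-free entry cohort (no prior alcohol-related
hospitalisation), one post-event state per hospitalisation cause, and two
absorbing death states (alcohol- and non-alcohol-related).  Cycles are
annual.  Post-event cohorts keep their entry covariates but their prior-
hospitalisation covariate advances 0 -> 1 (first cycle after admission)
-> 2 (thereafter); this is implemented with a one-cycle internal tunnel
per post-event state, aggregated away in the public trace.  A new
hospitalisation from a post-event state re-enters the corresponding
post-event tunnel (prior hospitalisation resets to "last year").

The intervention (random breath testing added to mass media) scales the
road-traffic-attributable share of the partly-alcohol hospitalisation
hazard by (1 - rti_reduction) and of the alcohol-death hazard by
(1 - fatality_reduction); all other hazards are untouched.

`microsim_oracle` replays the exact same per-cycle transition
probabilities on sampled individuals and is the engine's independent
stochastic check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hazards as hz
from .params import (
    DEAD_STATES,
    EVENT_CASE_FATALITY_DESTINATION,
    EVENT_DESTINATION,
    EventType,
    HazardSpec,
    HealthState,
    HOSPITALISATION_EVENTS,
    InterventionEffect,
    ModelBundle,
    RiskProfile,
    ValidationError,
)

__all__ = [
    "HealthState",
    "StrategyArm",
    "MEDIA_ONLY",
    "RBT_PLUS_MEDIA",
    "CohortTrace",
    "MicrosimResult",
    "apply_intervention",
    "run_cohort",
    "microsim_oracle",
]

STATE_ORDER = tuple(HealthState)
STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}
POST_STATES = tuple(s for s in HealthState if s.value.startswith("POST_"))
N_STATES = len(STATE_ORDER)

# internal layout: 0 = HEALTHY, 1..6 = post (recent), 7..12 = post (later),
# 13 = DEAD_ALC, 14 = DEAD_NONALC
_N_POST = len(POST_STATES)
_RECENT0 = 1
_LATER0 = _RECENT0 + _N_POST
_I_DEAD_ALC = _LATER0 + _N_POST
_I_DEAD_NONALC = _I_DEAD_ALC + 1
_N_INTERNAL = _I_DEAD_NONALC + 1

_EVENTS = hz.EVENT_ORDER
_N_EVENTS = len(_EVENTS)

#: intervention-modified events and which effect fraction applies
_RTI_EVENTS = {EventType.PARTLY_ALC_HOSP: "rti_reduction",
               EventType.ALC_DEATH: "fatality_reduction"}


@dataclass(frozen=True)
class StrategyArm:
    """One strategy: comparator (mass media alone) or the intervention
    (random breath testing with mass media).  Only the intervention arm
    applies the hazard reductions; programme costs are resolved per arm by
    the economics layer."""

    label: str
    apply_effect: bool


MEDIA_ONLY = StrategyArm("MEDIA_ONLY", apply_effect=False)
RBT_PLUS_MEDIA = StrategyArm("RBT_PLUS_MEDIA", apply_effect=True)


@dataclass
class CohortTrace:
    """State-occupancy proportions by annual cycle.

    ``occupancy`` has shape (n_cycles + 1, n_states): row t is the start of
    cycle t, row 0 the entry distribution (all mass event-free), the last
    row the distribution at the horizon.
    """

    occupancy: np.ndarray
    entry_age: int
    arm_label: str
    states: tuple[HealthState, ...] = STATE_ORDER

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_column(self, state: HealthState) -> np.ndarray:
        return self.occupancy[:, STATE_INDEX[state]]

    def living(self) -> np.ndarray:
        dead = [STATE_INDEX[s] for s in DEAD_STATES]
        alive = [i for i in range(N_STATES) if i not in dead]
        return self.occupancy[:, alive].sum(axis=1)

    def to_frame(self):
        import pandas as pd

        ages = self.entry_age + np.arange(self.occupancy.shape[0])
        df = pd.DataFrame(self.occupancy, columns=[s.value for s in self.states])
        df.insert(0, "age", ages)
        df.insert(0, "strategy", self.arm_label)
        return df


def apply_intervention(hazard_vector: hz.HazardVector,
                       effect: InterventionEffect,
                       rti_share: float = 1.0) -> hz.HazardVector:
    """Scale the road-traffic-attributable share of the affected hazards.

    h' = h * (1 - share * reduction) for partly-alcohol hospitalisation
    (injury reduction) and alcohol death (fatality reduction).
    """
    if not (0.0 <= rti_share <= 1.0):
        raise ValidationError(f"rti_share must be in [0, 1], got {rti_share}")
    values = dict(hazard_vector.values)
    for ev, attr in _RTI_EVENTS.items():
        if ev in values:
            values[ev] = values[ev] * (1.0 - rti_share * getattr(effect, attr))
    return hz.HazardVector(values=values, cycle_time=hazard_vector.cycle_time)


def _hazard_array(bundle: ModelBundle, profile: RiskProfile,
                  arm: StrategyArm, n_cycles: int) -> np.ndarray:
    """Hazards for every (cycle, prior-hosp variant, event): shape
    (n_cycles, 3, n_events)."""
    base = np.empty((3, _N_EVENTS))
    for ph in range(3):
        prof = profile.replace(prior_hosp=ph)
        for j, ev in enumerate(_EVENTS):
            spec: HazardSpec = bundle.hazards[ev]
            base[ph, j] = np.exp(hz.linear_predictor(prof, spec)) * spec.cf
    t = np.arange(n_cycles, dtype=float)
    gammas = np.array([bundle.hazards[ev].gamma for ev in _EVENTS])
    time_factor = np.exp(np.outer(t, gammas))  # (n_cycles, n_events)
    out = time_factor[:, None, :] * base[None, :, :]
    if arm.apply_effect:
        eff = bundle.intervention_effect
        share = bundle.options.rti_share
        for ev, attr in _RTI_EVENTS.items():
            out[:, :, hz.EVENT_INDEX[ev]] *= 1.0 - share * getattr(eff, attr)
    if not np.all(np.isfinite(out)):
        bad = int(np.argwhere(~np.isfinite(out).all(axis=(1, 2)))[0, 0])
        raise ArithmeticError(f"non-finite hazards at cycle {bad}")
    return out


def _destination_matrix(bundle: ModelBundle) -> np.ndarray:
    """(n_events, n_internal) mapping each first event to internal states,
    including the 28-day case-fatality split on hospitalisations."""
    D = np.zeros((_N_EVENTS, _N_INTERNAL))
    dead_idx = {HealthState.DEAD_ALC: _I_DEAD_ALC,
                HealthState.DEAD_NONALC: _I_DEAD_NONALC}
    for j, ev in enumerate(_EVENTS):
        dest = EVENT_DESTINATION[ev]
        if dest in dead_idx:
            D[j, dead_idx[dest]] = 1.0
        else:
            f = bundle.options.case_fatality_for(ev)
            post = POST_STATES.index(dest)
            D[j, _RECENT0 + post] = 1.0 - f
            D[j, dead_idx[EVENT_CASE_FATALITY_DESTINATION[ev]]] = f
    return D


def _aggregate(internal: np.ndarray) -> np.ndarray:
    """Collapse the recent/later tunnels into the public state order."""
    out = np.zeros(internal.shape[:-1] + (N_STATES,))
    out[..., STATE_INDEX[HealthState.HEALTHY]] = internal[..., 0]
    for j, st in enumerate(POST_STATES):
        out[..., STATE_INDEX[st]] = (internal[..., _RECENT0 + j]
                                     + internal[..., _LATER0 + j])
    out[..., STATE_INDEX[HealthState.DEAD_ALC]] = internal[..., _I_DEAD_ALC]
    out[..., STATE_INDEX[HealthState.DEAD_NONALC]] = internal[..., _I_DEAD_NONALC]
    return out


def run_cohort(bundle: ModelBundle, profile: RiskProfile,
               arm: StrategyArm) -> CohortTrace:
    """Run the annual-cycle cohort simulation for one strategy arm.

    Deterministic given the bundle.  Cycles run from the entry age to the
    horizon age; the loop short-circuits once living occupancy falls below
    ``options.min_alive`` (the remaining rows repeat the final
    distribution).
    """
    entry_age = profile.age
    horizon = bundle.economics.horizon_age
    if entry_age >= horizon:
        raise ValidationError(
            f"entry age {entry_age} must be below horizon {horizon}")
    n_cycles = horizon - entry_age

    haz = _hazard_array(bundle, profile, arm, n_cycles)
    probs, stay = hz._transition_probs_array(haz, bundle.options.cycle_length)
    D = _destination_matrix(bundle)
    exits = probs @ D  # (n_cycles, 3, n_internal)

    occ = np.zeros((n_cycles + 1, _N_INTERNAL))
    occ[0, 0] = 1.0
    living_slice = slice(0, _LATER0 + _N_POST)
    for t in range(n_cycles):
        cur = occ[t]
        m0 = cur[0]
        recent = cur[_RECENT0:_RECENT0 + _N_POST]
        later = cur[_LATER0:_LATER0 + _N_POST]
        nxt = np.zeros(_N_INTERNAL)
        nxt += m0 * exits[t, 0] + recent.sum() * exits[t, 1] + later.sum() * exits[t, 2]
        nxt[0] += m0 * stay[t, 0]
        nxt[_LATER0:_LATER0 + _N_POST] += recent * stay[t, 1] + later * stay[t, 2]
        nxt[_I_DEAD_ALC] += cur[_I_DEAD_ALC]
        nxt[_I_DEAD_NONALC] += cur[_I_DEAD_NONALC]
        occ[t + 1] = nxt
        if nxt[living_slice].sum() < bundle.options.min_alive:
            occ[t + 2:] = nxt
            break

    return CohortTrace(occupancy=_aggregate(occ), entry_age=entry_age,
                       arm_label=arm.label)


@dataclass
class MicrosimResult:
    """Individual-level replay of the cohort transition probabilities."""

    n_individuals: int
    seed: int
    mean_life_years: float
    se_life_years: float
    occupancy: np.ndarray       # mean trace, (n_cycles + 1, n_states)
    occupancy_se: np.ndarray
    states: tuple[HealthState, ...] = STATE_ORDER

    @property
    def final_occupancy(self) -> np.ndarray:
        return self.occupancy[-1]


def microsim_oracle(bundle: ModelBundle, profile: RiskProfile,
                    arm: StrategyArm, n_individuals: int,
                    seed: int) -> MicrosimResult:
    """Monte Carlo microsimulation with the same per-cycle transition rows
    as :func:`run_cohort`; the cohort trace should match its means within
    Monte Carlo error."""
    if n_individuals <= 0:
        raise ValidationError("n_individuals must be positive")
    rng = np.random.default_rng(seed)
    entry_age = profile.age
    n_cycles = bundle.economics.horizon_age - entry_age

    haz = _hazard_array(bundle, profile, arm, n_cycles)
    probs, stay = hz._transition_probs_array(haz, bundle.options.cycle_length)
    D = _destination_matrix(bundle)
    # per (cycle, variant): cumulative thresholds over [stay, dest_1..dest_K]
    # where destinations are internal states reached by some event
    exits = probs @ D  # (n_cycles, 3, n_internal)

    state = np.zeros(n_individuals, dtype=np.int64)
    life_years = np.zeros(n_individuals)
    counts = np.zeros((n_cycles + 1, _N_INTERNAL))
    counts[0] = np.bincount(state, minlength=_N_INTERNAL)

    for t in range(n_cycles):
        alive = state < _I_DEAD_ALC
        life_years += alive
        if not alive.any():
            counts[t + 1:] = counts[t]
            break
        u = rng.random(n_individuals)
        new_state = state.copy()
        variant = np.full(n_individuals, -1, dtype=np.int64)
        variant[state == 0] = 0
        variant[(state >= _RECENT0) & (state < _LATER0)] = 1
        variant[(state >= _LATER0) & (state < _I_DEAD_ALC)] = 2
        for v in range(3):
            mask = variant == v
            if not mask.any():
                continue
            cum = np.concatenate(([stay[t, v]], stay[t, v] + np.cumsum(exits[t, v])))
            dest = np.searchsorted(cum, u[mask], side="right")
            dest = np.minimum(dest, len(cum) - 1)  # fp guard at u ~ 1
            # dest 0 = stay, dest 1+i = internal state i
            stayed = dest == 0
            moved_to = dest - 1
            idx = np.flatnonzero(mask)
            if v == 0:
                new_state[idx[stayed]] = 0
            elif v == 1:
                new_state[idx[stayed]] = state[idx[stayed]] + _N_POST
            else:
                new_state[idx[stayed]] = state[idx[stayed]]
            new_state[idx[~stayed]] = moved_to[~stayed]
        state = new_state
        counts[t + 1] = np.bincount(state, minlength=_N_INTERNAL)

    occ_internal = counts / n_individuals
    occupancy = _aggregate(occ_internal)
    occ_se = np.sqrt(occupancy * (1.0 - occupancy) / n_individuals)
    return MicrosimResult(
        n_individuals=n_individuals, seed=seed,
        mean_life_years=float(life_years.mean()),
        se_life_years=float(life_years.std(ddof=1) / np.sqrt(n_individuals)),
        occupancy=occupancy, occupancy_se=occ_se)
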