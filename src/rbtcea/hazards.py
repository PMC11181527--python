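"""Cause-specific hazards and their conversion to transition probabilities.

The hazard for event k at time t since cohort entry is

    h_k(t) = exp(x.b_k) * CF_k * exp(gamma_k * t)

with x the risk profile (covariates fixed at entry, except prior
hospitalisation which the cohort engine updates), b_k per-covariate log
hazard ratios, gamma_k a log-linear time slope and CF_k a calibration
factor.  Competing hazards are converted to annual transition
probabilities with the standard constant-within-cycle exponential formula:
with H = sum_k h_k,

    P(stay)    = exp(-H * dt)
    P(event k) = (h_k / H) * (1 - exp(-H * dt))

which is exact when each h_k is constant over the cycle.  Calibration
fits CF so the modelled cumulative first-event incidence by a stated age
matches an external target, by bracketed root search (the incidence is
strictly increasing in CF, so the root is unique).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .params import (
    EventType,
    HazardSpec,
    RiskProfile,
    ValidationError,
    PROFILE_FIELDS,
)

__all__ = [
    "HazardVector",
    "TransitionRow",
    "CalibrationError",
    "CalibrationReport",
    "linear_predictor",
    "cause_specific_hazard",
    "competing_transition_row",
    "cumulative_incidence",
    "calibrate_cf",
]

EVENT_ORDER = tuple(EventType)
EVENT_INDEX = {ev: i for i, ev in enumerate(EVENT_ORDER)}


class CalibrationError(RuntimeError):
    """The calibration target is unreachable within the CF bracket."""


@dataclass
class HazardVector:
    """Per-event hazards (events/person-year) at one cycle time."""

    values: dict[EventType, float]
    cycle_time: float = 0.0

    def __post_init__(self) -> None:
        for ev, h in self.values.items():
            if not (math.isfinite(h) and h >= 0):
                raise ValidationError(
                    f"hazard for {ev.value} must be finite and >= 0, got {h}")

    def total(self) -> float:
        return sum(self.values.values())


@dataclass
class TransitionRow:
    """One cycle's transition probabilities: per-event plus stay."""

    probs: dict[EventType, float]
    stay: float

    def __post_init__(self) -> None:
        total = self.stay + sum(self.probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"transition row sums to {total!r}, not 1")
        for ev, p in self.probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"P({ev.value}) = {p} outside [0, 1]")
        if not (0.0 <= self.stay <= 1.0):
            raise ValidationError(f"stay probability {self.stay} outside [0, 1]")


def linear_predictor(profile: RiskProfile, spec: HazardSpec) -> float:
    """x.b for one event: intercept plus coefficient-weighted covariates.

    Indicators enter as 0/1, ordered categories as integer scores, AUDIT
    and cigarettes/day as raw counts.
    """
    unknown = set(spec.coefficients) - set(PROFILE_FIELDS)
    if unknown:
        raise ValidationError(
            f"coefficients reference unknown fields {sorted(unknown)}")
    return spec.intercept + sum(
        c * getattr(profile, name) for name, c in spec.coefficients.items())


def cause_specific_hazard(spec: HazardSpec, profile: RiskProfile,
                          t: float) -> float:
    """h_k(t) = exp(x.b) * CF * exp(gamma t); t in years since entry."""
    if t < 0:
        raise ValidationError(f"t must be >= 0, got {t}")
    return math.exp(linear_predictor(profile, spec)) * spec.cf * math.exp(
        spec.gamma * t)


def competing_transition_row(hazards: HazardVector,
                             cycle_length: float = 1.0) -> TransitionRow:
    """Convert competing cause-specific hazards to one cycle's probabilities.

    Exact for hazards constant within the cycle: each cause's probability
    is its share h_k/H of the total exit probability 1 - exp(-H dt).
    """
    if cycle_length <= 0:
        raise ValidationError(f"cycle_length must be > 0, got {cycle_length}")
    total = hazards.total()
    if total == 0.0:
        return TransitionRow(probs={ev: 0.0 for ev in hazards.values}, stay=1.0)
    exit_p = -math.expm1(-total * cycle_length)
    probs = {ev: (h / total) * exit_p for ev, h in hazards.values.items()}
    stay = math.exp(-total * cycle_length)
    # absorb fp residue of the share normalisation into the stay term
    stay += 1.0 - (stay + sum(probs.values()))
    return TransitionRow(probs=probs, stay=max(stay, 0.0))


def _transition_probs_array(hazard_values: np.ndarray,
                            cycle_length: float = 1.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized competing-risk conversion.

    hazard_values: (..., n_events) nonnegative.  Returns (probs, stay)
    with probs shaped like the input.
    """
    h = np.asarray(hazard_values, dtype=float)
    if np.any(h < 0) or not np.all(np.isfinite(h)):
        raise ValidationError("hazards must be finite and nonnegative")
    total = h.sum(axis=-1, keepdims=True)
    exit_p = -np.expm1(-total * cycle_length)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, h / np.where(total > 0, total, 1.0), 0.0)
    probs = share * exit_p
    stay = 1.0 - probs.sum(axis=-1)
    return probs, stay


def cumulative_incidence(hazards: Mapping[EventType, HazardSpec],
                         event: EventType,
                         profile: RiskProfile,
                         entry_age: int,
                         by_age: int,
                         cycle_length: float = 1.0) -> float:
    """Cumulative incidence of ``event`` as the *first* event by ``by_age``.

    Discrete-cycle competing-risk sum: CI_k = sum_t S(t) p_k(t) with
    S(t) the probability of remaining event-free through cycle t.
    """
    if by_age <= entry_age:
        raise ValidationError("by_age must exceed entry_age")
    n_cycles = by_age - entry_age
    surv = 1.0
    ci = 0.0
    base = {ev: math.exp(linear_predictor(profile, spec)) * spec.cf
            for ev, spec in hazards.items()}
    for t in range(n_cycles):
        hv = HazardVector(
            values={ev: base[ev] * math.exp(hazards[ev].gamma * t)
                    for ev in hazards},
            cycle_time=float(t))
        row = competing_transition_row(hv, cycle_length)
        ci += surv * row.probs[event]
        surv *= row.stay
    return ci


@dataclass
class CalibrationReport:
    event: EventType
    cf: float
    target: float
    achieved: float
    iterations: int


def calibrate_cf(hazards: Mapping[EventType, HazardSpec],
                 event: EventType,
                 profile: RiskProfile,
                 target: float,
                 entry_age: int,
                 by_age: int,
                 tolerance: float = 1e-6,
                 bracket: tuple[float, float] = (1e-6, 1e6),
                 ) -> tuple[HazardSpec, CalibrationReport]:
    """Fit the calibration factor of one event's hazard.

    Finds CF in ``bracket`` such that the modelled cumulative first-event
    incidence of ``event`` by ``by_age`` matches ``target`` within relative
    ``tolerance``.  The incidence is strictly increasing in CF, so a
    bracketed root search (Brent) converges to the unique solution.

    Returns the calibrated spec (other events untouched) and a report.
    Raises :class:`CalibrationError` if the target lies outside the
    incidence range achievable over the bracket.
    """
    if not (0.0 < target < 1.0):
        raise ValidationError(f"target must be in (0, 1), got {target}")
    evaluations = 0

    def modelled(cf: float) -> float:
        nonlocal evaluations
        evaluations += 1
        hz = dict(hazards)
        hz[event] = replace(hazards[event], cf=cf)
        return cumulative_incidence(hz, event, profile, entry_age, by_age)

    lo, hi = bracket
    f_lo = modelled(lo) - target
    f_hi = modelled(hi) - target
    if f_lo > 0 or f_hi < 0:
        raise CalibrationError(
            f"target {target} for {event.value} unreachable: achievable "
            f"incidence range [{f_lo + target:.6g}, {f_hi + target:.6g}] "
            f"over CF bracket [{lo:g}, {hi:g}]")
    cf_star = brentq(lambda cf: modelled(cf) - target, lo, hi,
                     xtol=1e-12, rtol=1e-12)
    achieved = modelled(cf_star)
    if target != 0 and abs(achieved - target) / target > tolerance:
        raise CalibrationError(
            f"calibration for {event.value} stalled: achieved {achieved:.6g} "
            f"vs target {target:.6g}")
    spec = replace(hazards[event], cf=float(cf_star))
    report = CalibrationReport(event=event, cf=float(cf_star), target=target,
                               achieved=achieved, iterations=evaluations)
    return spec, report
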