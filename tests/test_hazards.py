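"""Hazard equation, competing-risk conversion, and CF calibration."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbtcea import EventType, HazardSpec, base_case_profile
from rbtcea.hazards import (
    CalibrationError,
    HazardVector,
    calibrate_cf,
    cause_specific_hazard,
    competing_transition_row,
    cumulative_incidence,
    linear_predictor,
)
from rbtcea.params import ValidationError
from rbtcea.synthetic import make_calibration_targets

EV = EventType.ALC_DEATH


def spec(intercept=0.0, gamma=0.0, cf=1.0, **coeffs):
    return HazardSpec(event=EV, intercept=intercept, gamma=gamma, cf=cf,
                      coefficients=coeffs)


class TestLinearPredictor:
    def test_empty_predictor_is_zero(self):
        assert linear_predictor(base_case_profile("male"), spec()) == 0.0

    def test_single_term_sum(self):
        s = spec(intercept=-5.0, binge=0.7)
        assert linear_predictor(base_case_profile("male"), s) == pytest.approx(-4.3)

    def test_linearity_in_coefficients(self):
        p = base_case_profile("male")
        lo = spec(audit_score=0.03)
        hi = spec(audit_score=0.06)
        assert linear_predictor(p, hi) == pytest.approx(
            2 * linear_predictor(p, lo))

    def test_unknown_coefficient_field_rejected(self):
        with pytest.raises(ValidationError, match="not_a_field"):
            HazardSpec(event=EV, intercept=0.0,
                       coefficients={"not_a_field": 1.0})


class TestCauseSpecificHazard:
    def test_identity_case(self):
        assert cause_specific_hazard(spec(), base_case_profile("female"),
                                     t=3.0) == 1.0

    def test_cf_scales_linearly(self):
        p = base_case_profile("male")
        s1 = spec(intercept=-2.0, gamma=0.05)
        s2 = spec(intercept=-2.0, gamma=0.05, cf=2.0)
        assert cause_specific_hazard(s2, p, 4.0) == pytest.approx(
            2.0 * cause_specific_hazard(s1, p, 4.0))

    def test_closed_form_value(self):
        # exp(-5) * exp(0.09 * 10) = exp(-4.1)
        s = spec(intercept=-5.0, gamma=0.09)
        got = cause_specific_hazard(s, base_case_profile("female"), t=10.0)
        assert got == pytest.approx(math.exp(-4.1))
        assert got == pytest.approx(0.016573, abs=5e-7)

    def test_monotone_in_time_when_gamma_positive(self):
        s = spec(intercept=-3.0, gamma=0.08)
        p = base_case_profile("male")
        hs = [cause_specific_hazard(s, p, t) for t in range(10)]
        assert np.all(np.diff(hs) > 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            cause_specific_hazard(spec(), base_case_profile("male"), -1.0)


def hv(**hazards):
    values = {ev: 0.0 for ev in EventType}
    for name, h in hazards.items():
        values[EventType[name]] = h
    return HazardVector(values=values)


class TestCompetingTransitionRow:
    def test_null_hazards_stay_one(self):
        row = competing_transition_row(hv())
        assert row.stay == 1.0
        assert all(p == 0.0 for p in row.probs.values())

    def test_single_cause_closed_form(self):
        row = competing_transition_row(hv(ALC_DEATH=0.1))
        assert row.probs[EventType.ALC_DEATH] == pytest.approx(
            -math.expm1(-0.1))
        assert row.probs[EventType.ALC_DEATH] == pytest.approx(0.095163,
                                                               abs=5e-7)

    def test_two_cause_closed_form(self):
        row = competing_transition_row(hv(ALC_DEATH=0.1, NONALC_DEATH=0.3))
        exit_p = -math.expm1(-0.4)
        assert row.probs[EventType.ALC_DEATH] == pytest.approx(
            0.25 * exit_p) == pytest.approx(0.082420, abs=5e-7)
        assert row.probs[EventType.NONALC_DEATH] == pytest.approx(
            0.75 * exit_p) == pytest.approx(0.247260, abs=5e-7)
        assert row.stay == pytest.approx(0.670320, abs=5e-7)

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValidationError):
            HazardVector(values={EventType.ALC_DEATH: -0.1})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=50.0,
                              allow_nan=False), min_size=8, max_size=8),
           st.floats(min_value=0.01, max_value=5.0))
    def test_row_sums_to_one_for_arbitrary_hazards(self, hazards, dt):
        values = dict(zip(EventType, hazards))
        row = competing_transition_row(HazardVector(values=values), dt)
        total = row.stay + sum(row.probs.values())
        assert abs(total - 1.0) <= 1e-12

    def test_agrees_with_continuous_time_simulation(self):
        """Two competing exponential clocks, 1e5 draws: empirical one-cycle
        outcome frequencies match the closed form within 3 MC SE."""
        h1, h2, dt = 0.15, 0.45, 1.0
        rng = np.random.default_rng(42)
        n = 100_000
        t1 = rng.exponential(1.0 / h1, size=n)
        t2 = rng.exponential(1.0 / h2, size=n)
        first = np.minimum(t1, t2)
        event1 = (first < dt) & (t1 < t2)
        event2 = (first < dt) & (t2 <= t1)
        row = competing_transition_row(hv(ALC_DEATH=h1, NONALC_DEATH=h2), dt)
        for p_hat, p in [(event1.mean(), row.probs[EventType.ALC_DEATH]),
                         (event2.mean(), row.probs[EventType.NONALC_DEATH])]:
            se = math.sqrt(p * (1 - p) / n)
            assert abs(p_hat - p) < 3 * se


class TestCalibration:
    def test_fixed_point_recovers_unit_cf(self, scenario):
        hazards = scenario.bundle.hazards
        profile = scenario.bundle.profiles["male"]
        target = cumulative_incidence(hazards, EV, profile, 20, 70)
        calibrated, report = calibrate_cf(hazards, EV, profile, target,
                                          entry_age=20, by_age=70)
        assert calibrated.cf == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("cf_true", [1.5, 0.5])
    def test_recovers_ground_truth_cf(self, scenario, cf_true):
        targets = make_calibration_targets(scenario, {EV: cf_true})
        profile = scenario.bundle.profiles["male"]
        calibrated, report = calibrate_cf(
            scenario.bundle.hazards, EV, profile, targets[EV],
            entry_age=20, by_age=scenario.calibration_age)
        assert calibrated.cf == pytest.approx(cf_true, rel=1e-3)
        assert report.achieved == pytest.approx(report.target, rel=1e-6)

    def test_unreachable_target_reports_bounds(self, scenario):
        profile = scenario.bundle.profiles["male"]
        with pytest.raises(CalibrationError, match="unreachable"):
            calibrate_cf(scenario.bundle.hazards, EV, profile, 0.999999,
                         entry_age=20, by_age=22)

    def test_incidence_strictly_increasing_in_cf(self, scenario):
        """Monotonicity over a CF grid — the uniqueness guarantee behind
        the bracketed root search."""
        from dataclasses import replace

        profile = scenario.bundle.profiles["male"]
        incidences = []
        for cf in (0.2, 0.5, 1.0, 2.0, 5.0, 20.0):
            hz = dict(scenario.bundle.hazards)
            hz[EV] = replace(hz[EV], cf=cf)
            incidences.append(cumulative_incidence(hz, EV, profile, 20, 70))
        assert np.all(np.diff(incidences) > 0)
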