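"""PSA sampling, CEAC identities, and the cost-effectiveness plane."""

from __future__ import annotations

import numpy as np
import pytest

from rbtcea import (
    DistributionSpec,
    ceac,
    ce_plane_export,
    default_wtp_grid,
    make_psa_specs,
    run_psa,
    sample_bundle,
)
from rbtcea.cli import run_base_case
from rbtcea.params import ValidationError
from rbtcea.psa import PSAResult, PSASample, _iteration_rng


def result_from(points):
    return PSAResult(samples=[PSASample(i, dc, de)
                              for i, (dc, de) in enumerate(points)],
                     n_failures=0, seed=0)


class TestDistributionSpec:
    def test_family_assignment_enforced(self):
        with pytest.raises(ValidationError):
            DistributionSpec(path="states.HEALTHY.utility", family="gamma",
                             params={"shape": 1.0, "scale": 1.0})
        with pytest.raises(ValidationError):
            DistributionSpec(path="states.HEALTHY.cost", family="beta",
                             params={"alpha": 2.0, "beta": 2.0})
        with pytest.raises(ValidationError):
            DistributionSpec(path="hazards.ALC_DEATH.cf", family="beta",
                             params={"alpha": 2.0, "beta": 2.0})

    def test_beta_moments(self):
        spec = DistributionSpec(path="intervention_effect.rti_reduction",
                                family="beta",
                                params={"alpha": 2.0, "beta": 2.0})
        rng = _iteration_rng(0, 0)
        draws = np.array([spec.draw(rng) for _ in range(5_000)])
        se = np.sqrt(1 / 8 / 5_000)  # var of beta(2,2) = 0.05
        assert abs(draws.mean() - 0.5) < 3 * np.sqrt(0.05 / 5_000)
        assert np.all((draws >= 0) & (draws <= 1))


class TestSampleBundle:
    def test_zero_variance_specs_reproduce_base(self, scenario):
        b = scenario.bundle
        specs = [DistributionSpec.point_mass("states.HEALTHY.utility",
                                             b.states[next(iter(b.states))].utility)]
        specs = [DistributionSpec.point_mass(
            "intervention_effect.rti_reduction",
            b.intervention_effect.rti_reduction)]
        sampled = sample_bundle(specs, b, seed=1, iteration=0)
        assert sampled.intervention_effect == b.intervention_effect

    def test_reproducible_from_seed_and_iteration(self, scenario):
        specs = make_psa_specs(scenario)
        b1 = sample_bundle(specs, scenario.bundle, seed=9, iteration=4)
        b2 = sample_bundle(specs, scenario.bundle, seed=9, iteration=4)
        assert b1.intervention_effect == b2.intervention_effect
        assert all(b1.hazards[ev].cf == b2.hazards[ev].cf
                   for ev in b1.hazards)

    def test_iterations_differ(self, scenario):
        specs = make_psa_specs(scenario)
        b1 = sample_bundle(specs, scenario.bundle, seed=9, iteration=0)
        b2 = sample_bundle(specs, scenario.bundle, seed=9, iteration=1)
        assert b1.intervention_effect != b2.intervention_effect

    def test_unknown_path_rejected(self, scenario):
        specs = [DistributionSpec.point_mass("economics.nope", 1.0)]
        with pytest.raises(ValidationError):
            sample_bundle(specs, scenario.bundle, seed=0, iteration=0)


class TestRunPSA:
    def test_zero_variance_equals_deterministic_increment(self, scenario):
        b = scenario.bundle
        specs = [DistributionSpec.point_mass(
            "intervention_effect.rti_reduction",
            b.intervention_effect.rti_reduction)]
        res = run_psa(b, specs, b.profiles["male"], n_iter=10, seed=0,
                      log_every=0)
        assert len(res.samples) == 10
        _, _, inc = run_base_case(b, "male")
        for s in res.samples:
            assert s.delta_cost == pytest.approx(inc.delta_cost)
            assert s.delta_effect == pytest.approx(inc.delta_effect)

    def test_same_seed_identical_sample_sets(self, scenario):
        specs = make_psa_specs(scenario)
        profile = scenario.bundle.profiles["male"]
        r1 = run_psa(scenario.bundle, specs, profile, n_iter=20, seed=5,
                     log_every=0)
        r2 = run_psa(scenario.bundle, specs, profile, n_iter=20, seed=5,
                     log_every=0)
        assert r1.to_frame().equals(r2.to_frame())

    def test_requested_iteration_count_returned(self, scenario):
        specs = make_psa_specs(scenario)
        res = run_psa(scenario.bundle, specs,
                      scenario.bundle.profiles["female"], n_iter=50, seed=2,
                      log_every=0)
        assert len(res.samples) + res.n_failures == 50
        dc, de = res.as_arrays()
        assert np.all(np.isfinite(dc)) and np.all(np.isfinite(de))


class TestCEAC:
    def test_enumerated_example_with_tie_rule(self):
        res = result_from([(10, 1), (20, 1), (30, 1)])
        curve = ceac(res, np.array([0.0, 20.0]))
        assert curve.at(20.0) == pytest.approx(2 / 3)

    def test_dominant_samples_probability_one_at_zero_wtp(self):
        res = result_from([(-5, 0.5), (-1, 0.1)])
        curve = ceac(res, np.array([0.0, 10.0]))
        assert curve.at(0.0) == 1.0

    def test_value_at_zero_wtp_is_cost_saving_fraction(self, scenario):
        specs = make_psa_specs(scenario)
        res = run_psa(scenario.bundle, specs,
                      scenario.bundle.profiles["male"], n_iter=100, seed=3,
                      log_every=0)
        curve = ceac(res, default_wtp_grid())
        dc, _ = res.as_arrays()
        assert curve.at(0.0) == pytest.approx((dc <= 0).mean())

    def test_monotone_when_all_effects_positive(self, scenario):
        specs = make_psa_specs(scenario)
        res = run_psa(scenario.bundle, specs,
                      scenario.bundle.profiles["male"], n_iter=100, seed=3,
                      log_every=0)
        _, de = res.as_arrays()
        assert np.all(de > 0)  # intervention reduces death hazards
        curve = ceac(res)
        assert np.all(np.diff(curve.probability) >= 0)

    def test_limit_at_large_wtp_counts_positive_effects(self):
        res = result_from([(100, 0.2), (100, -0.1), (-5, 0.0)])
        curve = ceac(res, np.array([0.0, 1e9]))
        #  lambda -> inf: dE > 0 wins; dE = 0 decided by cost sign (tie rule)
        assert curve.at(1e9) == pytest.approx(2 / 3)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValidationError):
            ceac(PSAResult(samples=[], n_failures=0, seed=0))

    def test_default_grid_contains_threshold(self):
        assert 160_000.0 in default_wtp_grid()


class TestCEPlane:
    def test_tie_counts_below_diagonal(self, tmp_path):
        res = result_from([(200.0, 0.00125)])  # exactly on a 160k diagonal
        frac = ce_plane_export(res, 160_000.0, tmp_path)
        assert frac == 1.0

    def test_dominant_quadrant_fraction_one(self, tmp_path):
        res = result_from([(-10, 0.5), (-2, 0.1)])
        assert ce_plane_export(res, 0.0, tmp_path) == 1.0

    def test_below_diagonal_equals_ceac_at_threshold(self, scenario, tmp_path):
        specs = make_psa_specs(scenario)
        res = run_psa(scenario.bundle, specs,
                      scenario.bundle.profiles["male"], n_iter=100, seed=7,
                      log_every=0)
        frac = ce_plane_export(res, 160_000.0, tmp_path)
        curve = ceac(res)
        assert frac == curve.at(160_000.0)
        assert (tmp_path / "ce_plane_samples.csv").exists()
        assert (tmp_path / "ce_plane.png").exists()
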