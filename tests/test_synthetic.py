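"""Synthetic cohort generator: soundness, determinism, noise response."""

import math

import pytest

from eppheno import (
    AlgorithmVariantConfig,
    CohortConfig,
    classify_enhanced,
    classify_with_variant,
    default_registry,
    evaluate_case_finding,
    expected_sensitivity,
    generate_boundary_suite,
    generate_cohort,
    patient_level_predictions,
    run_case_finding,
    write_cohort,
)
from eppheno.records import read_encounters, read_medications
from eppheno.synthetic import CohortConfigError


def _pipeline_metrics(cohort, registry):
    _, decisions = run_case_finding(cohort.encounters, cohort.medications, registry)
    pred = patient_level_predictions(decisions, cohort.gold["patient_id"])
    return evaluate_case_finding(pred, cohort.gold)


class TestConfig:
    def test_probability_vector_validation(self):
        with pytest.raises(CohortConfigError):
            CohortConfig(branch_mix=(0.5, 0.5, 0.5, 0, 0))
        with pytest.raises(CohortConfigError):
            CohortConfig(prevalence=1.2)

    def test_infeasible_unclassified_mix(self):
        with pytest.raises(CohortConfigError):
            CohortConfig(branch_mix=(0, 0.5, 0, 0.5, 0), management_mix=(0.5, 0.4, 0.1))


class TestGeneration:
    def test_zero_prevalence_no_ep_codes(self, registry):
        cohort = generate_cohort(CohortConfig(n_patients=100, prevalence=0.0, seed=2))
        episodes, _ = run_case_finding(cohort.encounters, cohort.medications, registry)
        assert episodes == []
        assert not cohort.gold["ep_true"].any()

    def test_empty_cohort(self):
        cohort = generate_cohort(CohortConfig(n_patients=0, seed=1))
        assert cohort.encounters == [] and len(cohort.gold) == 0

    def test_zero_noise_all_true_cases_classified(self, registry):
        cohort = generate_cohort(CohortConfig(n_patients=500, seed=1))
        report = _pipeline_metrics(cohort, registry)
        assert report.sensitivity == 100.0
        assert report.specificity == 100.0

    def test_near_miss_patterns_stay_negative(self, registry):
        cohort = generate_cohort(
            CohortConfig(n_patients=400, prevalence=0.0, p_false_dx=1.0, seed=3)
        )
        episodes, decisions = run_case_finding(cohort.encounters, cohort.medications, registry)
        assert episodes  # near-miss patterns do create candidate episodes
        assert not any(d.is_ep for d in decisions)

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_patients=120, p_drop_dx=0.1, p_false_dx=0.2, seed=7)
        p1 = write_cohort(generate_cohort(cfg), tmp_path / "a")
        p2 = write_cohort(generate_cohort(cfg), tmp_path / "b")
        for key in ("encounters", "medications", "patients", "enrollment", "gold"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_written_cohort_round_trips_through_readers(self, tmp_path, registry):
        cohort = generate_cohort(CohortConfig(n_patients=50, seed=9))
        paths = write_cohort(cohort, tmp_path)
        assert read_encounters(paths["encounters"], registry) == cohort.encounters
        assert read_medications(paths["medications"]) == cohort.medications


class TestNoiseModel:
    def test_expected_sensitivity_zero_noise_is_one(self):
        assert expected_sensitivity(CohortConfig()) == pytest.approx(1.0)

    def test_expected_sensitivity_closed_form_spot_check(self):
        # uniform branches, management mix 0.604/0.387/0.009, p_drop = 0.1:
        # hand computation gives 0.913662 (see docs on the survival terms)
        e = expected_sensitivity(CohortConfig(p_drop_dx=0.1))
        assert e == pytest.approx(0.913662, abs=1e-9)

    def test_drop_noise_strictly_decreases_expectation(self):
        es = [expected_sensitivity(CohortConfig(p_drop_dx=p)) for p in (0.0, 0.05, 0.1, 0.3)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_label_shift_on_simulation(self, registry):
        low = generate_cohort(CohortConfig(n_patients=3000, p_drop_dx=0.05, seed=17))
        high = generate_cohort(CohortConfig(n_patients=3000, p_drop_dx=0.3, seed=17))
        assert (
            _pipeline_metrics(low, registry).sensitivity
            > _pipeline_metrics(high, registry).sensitivity
        )

    def test_mtx_displacement_reduces_sensitivity(self, registry):
        cfg = CohortConfig(n_patients=2000, p_mtx_outside_window=1.0, seed=19)
        report = _pipeline_metrics(generate_cohort(cfg), registry)
        expected = expected_sensitivity(cfg)
        assert expected < 1.0
        n_true = 2000 * 0.668
        se = math.sqrt(expected * (1 - expected) / n_true)
        assert report.sensitivity / 100 == pytest.approx(expected, abs=4 * se)


class TestBoundarySuite:
    def test_suite_size_and_determinism(self):
        suite = generate_boundary_suite()
        assert len(suite) >= 20
        assert suite == generate_boundary_suite()
        assert len({fx.name for fx in suite}) == len(suite)

    def test_expected_decisions_both_variants(self, registry):
        enhanced = AlgorithmVariantConfig.enhanced()
        comparison = AlgorithmVariantConfig.comparison()
        for fx in generate_boundary_suite():
            for cfg, expected in (
                (enhanced, fx.expected_enhanced),
                (comparison, fx.expected_comparison),
            ):
                _, decisions = run_case_finding(
                    list(fx.encounters), list(fx.medications), registry, cfg
                )
                got = tuple((d.is_ep, d.branch) for d in decisions)
                assert got == expected, f"{fx.name} ({cfg.variant.value})"

    def test_enhanced_straight_line_agrees_on_suite(self, registry):
        for fx in generate_boundary_suite():
            episodes, _ = run_case_finding(list(fx.encounters), list(fx.medications), registry)
            got = tuple(
                (d.is_ep, d.branch)
                for d in (classify_enhanced(ep, registry) for ep in episodes)
            )
            assert got == fx.expected_enhanced, fx.name
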