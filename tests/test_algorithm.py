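"""Case-finding branches: spec'd examples, brute-force oracle, properties."""

import dataclasses
import datetime as dt

import numpy as np
import pytest

from eppheno import (
    AlgorithmVariantConfig,
    Branch,
    Encounter,
    MedicationAdministration,
    PregnancyEpisode,
    Setting,
    classify_cohort,
    classify_enhanced,
    classify_with_variant,
)
from eppheno.codes import DxCategory, classify_diagnosis

from conftest import BASE, random_episode

D0 = dt.date(2016, 2, 1)
OP, IP, OC, TAV = Setting.OUTPATIENT, Setting.INPATIENT, Setting.OUTSIDE_CLAIM, Setting.TELEPHONE


def episode(encs, meds=()):
    encounters = tuple(
        Encounter("P1", D0 + dt.timedelta(days=o), s, tuple(dx), tuple(px))
        for o, s, dx, px in encs
    )
    records = tuple(
        MedicationAdministration("P1", D0 + dt.timedelta(days=o), "MTX-INJ", "ADMIN-GIVEN")
        for o in meds
    )
    return PregnancyEpisode("P1", min(e.date for e in encounters), encounters, records)


def oracle(ep, registry):
    """Brute-force evaluation of the five enhanced branch predicates written
    as direct set/count expressions, independent of the implementation."""
    cats = [
        ({classify_diagnosis(c, registry) for c in e.diagnosis_codes}, e)
        for e in ep.encounters
    ]
    non_abd = [
        e
        for cset, e in cats
        if cset & {DxCategory.SPECIFIC_TUBAL, DxCategory.NONSPECIFIC_EP}
    ]
    mtx = len(ep.methotrexate_records) > 0
    b1 = len(non_abd) >= 2 and any(e.setting != TAV for e in non_abd)
    b2 = sum(1 for e in non_abd if e.setting == TAV) >= 2 and mtx
    b3 = any(
        DxCategory.SPECIFIC_TUBAL in cset and e.setting in {OP, IP, OC} for cset, e in cats
    )
    b4 = mtx and any(DxCategory.NONSPECIFIC_EP in cset for cset, e in cats)
    b5 = any(
        e.setting != TAV
        and cset & {DxCategory.SPECIFIC_TUBAL, DxCategory.NONSPECIFIC_EP, DxCategory.ABDOMINAL}
        and any(registry.is_ep_procedure(c) for c in e.procedure_codes)
        for cset, e in cats
    )
    for fired, br in zip(
        (b1, b2, b3, b4, b5),
        (
            Branch.B1_MULTI_ENCOUNTER,
            Branch.B2_TAV_MTX,
            Branch.B3_SPECIFIC_CODE,
            Branch.B4_NONSPECIFIC_PLUS_MTX,
            Branch.B5_SINGLE_DX_PLUS_PX,
        ),
    ):
        if fired:
            return True, br
    return False, Branch.NONE


class TestEnhancedExamples:
    def test_single_inpatient_specific_fires_b3(self, registry):
        d = classify_enhanced(episode([(0, IP, ["O00.10"], [])]), registry)
        assert (d.is_ep, d.branch) == (True, Branch.B3_SPECIFIC_CODE)

    def test_two_tavs_without_mtx_not_case(self, registry):
        d = classify_enhanced(
            episode([(0, TAV, ["EP10-NOS"], []), (2, TAV, ["EP10-NOS"], [])]), registry
        )
        assert not d.is_ep

    def test_abdominal_only_with_mtx_not_case(self, registry):
        d = classify_enhanced(
            episode([(0, OP, ["O00.00"], []), (2, TAV, ["O00.00"], [])], meds=[1]), registry
        )
        assert not d.is_ep

    def test_dx_plus_px_same_encounter_fires_b5(self, registry):
        d = classify_enhanced(episode([(0, OP, ["EP10-NOS"], ["EP-PX-OTHER"])]), registry)
        assert (d.is_ep, d.branch) == (True, Branch.B5_SINGLE_DX_PLUS_PX)

    def test_empty_episode_is_contract_violation(self, registry):
        with pytest.raises(ValueError):
            PregnancyEpisode("P1", D0, ())


class TestVariantToggles:
    def test_comparison_drops_tav_channel(self, registry):
        ep = episode([(0, TAV, ["EP10-NOS"], []), (2, TAV, ["EP10-NOS"], [])], meds=[1])
        assert classify_enhanced(ep, registry).branch is Branch.B2_TAV_MTX
        d = classify_with_variant(ep, registry, AlgorithmVariantConfig.comparison())
        assert not d.is_ep

    def test_comparison_7_day_mtx_pre_window(self, registry):
        ep = episode([(0, OP, ["EP10-NOS"], [])], meds=[-10])
        assert classify_enhanced(ep, registry).is_ep  # within 30-day lookback
        assert not classify_with_variant(ep, registry, AlgorithmVariantConfig.comparison()).is_ep

    def test_comparison_counts_abdominal_as_nonspecific(self, registry):
        ep = episode([(0, OP, ["O00.00"], []), (3, OP, ["O00.01"], [])])
        assert not classify_enhanced(ep, registry).is_ep
        d = classify_with_variant(ep, registry, AlgorithmVariantConfig.comparison())
        assert (d.is_ep, d.branch) == (True, Branch.B1_MULTI_ENCOUNTER)

    def test_comparison_has_no_dx_plus_px_branch(self, registry):
        ep = episode([(0, OP, ["EP10-NOS"], ["EP-PX-OTHER"])])
        assert not classify_with_variant(ep, registry, AlgorithmVariantConfig.comparison()).is_ep


class TestProperties:
    def test_oracle_equivalence_randomized(self, registry):
        """classify_enhanced agrees with brute-force predicate evaluation."""
        rng = np.random.default_rng(42)
        for _ in range(2000):
            ep = random_episode(rng)
            d = classify_enhanced(ep, registry)
            assert (d.is_ep, d.branch) == oracle(ep, registry)

    def test_variant_machinery_equals_enhanced_randomized(self, registry):
        cfg = AlgorithmVariantConfig.enhanced()
        rng = np.random.default_rng(43)
        for _ in range(2000):
            ep = random_episode(rng)
            a = classify_enhanced(ep, registry)
            b = classify_with_variant(ep, registry, cfg)
            assert (a.is_ep, a.branch) == (b.is_ep, b.branch)

    def test_monotone_in_evidence(self, registry):
        """Adding an encounter or a methotrexate record never un-makes a case."""
        rng = np.random.default_rng(44)
        extra_enc = Encounter("R", BASE + dt.timedelta(days=5), OP, ("EP10-NOS",), ())
        extra_mtx = MedicationAdministration("R", BASE + dt.timedelta(days=2), "MTX-INJ", "ADMIN-GIVEN")
        for _ in range(500):
            ep = random_episode(rng)
            if not classify_enhanced(ep, registry).is_ep:
                continue
            grown = dataclasses.replace(
                ep,
                encounters=ep.encounters + (extra_enc,),
                methotrexate_records=ep.methotrexate_records + (extra_mtx,),
            )
            assert classify_enhanced(grown, registry).is_ep

    def test_cohort_statelessness_and_order(self, registry):
        rng = np.random.default_rng(45)
        eps = [random_episode(rng, pid=f"P{i}") for i in range(50)]
        dec = classify_cohort(eps, registry)
        assert len(dec) == len(eps)
        perm = list(reversed(eps))
        dec_perm = classify_cohort(perm, registry)
        assert dec_perm == list(reversed(dec))
        assert classify_cohort([], registry) == []
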