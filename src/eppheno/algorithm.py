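"""Five-branch case-finding rules for ectopic pregnancy episodes.

The enhanced algorithm labels an episode a case when any of five branches
fires (evaluated in fixed order B1..B5 for attribution; the case/non-case
outcome is order-independent):

B1  >=2 encounters carrying a non-abdominal EP diagnosis code, at least one
    of them in person;
B2  >=2 telephone appointment visits (TAVs) carrying a non-abdominal EP
    diagnosis code, plus methotrexate evidence;
B3  >=1 in-person (outpatient/inpatient/outside-claim) encounter with a
    *specific tubal* code (633.10, 633.11, O00.10, O00.11);
B4  >=1 encounter in any setting (TAV included) with a nonspecific EP
    diagnosis code, plus methotrexate evidence;
B5  a single non-TAV encounter carrying both an EP diagnosis code and an EP
    procedure code.

Episodes whose only EP diagnosis codes are abdominal (O00.00/O00.01) fire no
branch under the enhanced rules: B1–B4 ignore abdominal codes, which realizes
the exclusion of abdominal-only cases.

A configurable *comparison* variant models the previously published algorithm
through the differences that are documented: no TAV channel, no abdominal
exclusion, no diagnosis+procedure branch, and a 7-day (not 30-day)
methotrexate pre-window.  It is deliberately named "comparison" — the
original algorithm's full decision tree is not modeled.
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .codes import CodeRegistry, DxCategory, classify_diagnosis
from .episodes import PregnancyEpisode
from .records import Encounter, Setting

logger = logging.getLogger(__name__)

__all__ = [
    "Branch",
    "Variant",
    "CaseDecision",
    "AlgorithmVariantConfig",
    "classify_enhanced",
    "classify_with_variant",
    "classify_cohort",
]


class Branch(str, enum.Enum):
    B1_MULTI_ENCOUNTER = "B1_multi_encounter"
    B2_TAV_MTX = "B2_tav_mtx"
    B3_SPECIFIC_CODE = "B3_specific_code"
    B4_NONSPECIFIC_PLUS_MTX = "B4_nonspecific_plus_mtx"
    B5_SINGLE_DX_PLUS_PX = "B5_single_dx_plus_px"
    NONE = "none"


class Variant(str, enum.Enum):
    ENHANCED = "enhanced"
    COMPARISON = "comparison"


@dataclass(frozen=True)
class CaseDecision:
    """Per-episode outcome: case yes/no, first branch that fired, variant used."""

    patient_id: str
    index_date: dt.date
    is_ep: bool
    branch: Branch
    variant: Variant

    def __post_init__(self) -> None:
        if self.is_ep != (self.branch is not Branch.NONE):
            raise ValueError("is_ep must be true exactly when a branch fired")


@dataclass(frozen=True)
class AlgorithmVariantConfig:
    """Toggles and windows distinguishing the algorithm variants.

    ``use_tav=False`` removes B2 and makes telephone encounters count
    nowhere; ``exclude_abdominal_only=False`` lets abdominal codes count as
    nonspecific EP codes in B1/B4; ``allow_single_dx_plus_px=False`` removes
    B5.  The methotrexate windows are re-applied to the episode's attached
    records before classification, so episodes should be built with windows
    at least as wide as the variant's.
    """

    use_tav: bool = True
    exclude_abdominal_only: bool = True
    allow_single_dx_plus_px: bool = True
    mtx_pre_window_days: int = 30
    mtx_post_window_days: int = 180
    variant: Variant = Variant.ENHANCED

    def __post_init__(self) -> None:
        if self.mtx_pre_window_days < 0 or self.mtx_post_window_days < 0:
            raise ValueError("methotrexate window days must be >= 0")

    @classmethod
    def enhanced(cls) -> "AlgorithmVariantConfig":
        return cls()

    @classmethod
    def comparison(cls) -> "AlgorithmVariantConfig":
        return cls(
            use_tav=False,
            exclude_abdominal_only=False,
            allow_single_dx_plus_px=False,
            mtx_pre_window_days=7,
            mtx_post_window_days=180,
            variant=Variant.COMPARISON,
        )


# ---------------------------------------------------------------------------
# Enhanced algorithm: straight-line implementation with fixed constants.
# ---------------------------------------------------------------------------


def classify_enhanced(episode: PregnancyEpisode, registry: CodeRegistry) -> CaseDecision:
    """Classify one episode under the enhanced algorithm (fixed rules).

    The episode must have been built and had methotrexate attached with the
    enhanced windows (−30/+180 days).  Deterministic; monotone in evidence
    (adding an encounter or methotrexate record never turns a case into a
    non-case).
    """
    if not episode.encounters:
        raise ValueError("episode has no encounters")

    has_mtx = bool(episode.methotrexate_records)

    non_abd_dx_encounters = 0  # encounters with >=1 specific-tubal or nonspecific dx
    non_abd_inperson = False
    tav_non_abd_dx = 0
    b3 = b4 = b5 = False
    for enc in episode.encounters:
        cats = {classify_diagnosis(c, registry) for c in enc.diagnosis_codes}
        has_specific = DxCategory.SPECIFIC_TUBAL in cats
        has_nonspecific = DxCategory.NONSPECIFIC_EP in cats
        has_any_ep_dx = has_specific or has_nonspecific or DxCategory.ABDOMINAL in cats
        non_abd = has_specific or has_nonspecific
        if non_abd:
            non_abd_dx_encounters += 1
            if enc.setting is not Setting.TELEPHONE:
                non_abd_inperson = True
            if enc.setting is Setting.TELEPHONE:
                tav_non_abd_dx += 1
        if has_specific and enc.setting in (
            Setting.OUTPATIENT,
            Setting.INPATIENT,
            Setting.OUTSIDE_CLAIM,
        ):
            b3 = True
        if has_nonspecific and has_mtx:
            b4 = True
        if (
            enc.setting is not Setting.TELEPHONE
            and has_any_ep_dx
            and any(registry.is_ep_procedure(c) for c in enc.procedure_codes)
        ):
            b5 = True

    b1 = non_abd_dx_encounters >= 2 and non_abd_inperson
    b2 = tav_non_abd_dx >= 2 and has_mtx

    for fired, branch in (
        (b1, Branch.B1_MULTI_ENCOUNTER),
        (b2, Branch.B2_TAV_MTX),
        (b3, Branch.B3_SPECIFIC_CODE),
        (b4, Branch.B4_NONSPECIFIC_PLUS_MTX),
        (b5, Branch.B5_SINGLE_DX_PLUS_PX),
    ):
        if fired:
            return CaseDecision(
                episode.patient_id, episode.index_date, True, branch, Variant.ENHANCED
            )
    return CaseDecision(
        episode.patient_id, episode.index_date, False, Branch.NONE, Variant.ENHANCED
    )


# ---------------------------------------------------------------------------
# Configurable variant machinery (independent code path).
# ---------------------------------------------------------------------------


def _mtx_in_window(episode: PregnancyEpisode, cfg: AlgorithmVariantConfig) -> bool:
    lo = episode.index_date - dt.timedelta(days=cfg.mtx_pre_window_days)
    hi = episode.index_date + dt.timedelta(days=cfg.mtx_post_window_days)
    return any(lo <= m.date <= hi for m in episode.methotrexate_records)


def classify_with_variant(
    episode: PregnancyEpisode, registry: CodeRegistry, cfg: AlgorithmVariantConfig
) -> CaseDecision:
    """Classify one episode under a configured variant of the branch machinery.

    With the enhanced configuration this is equivalent to
    :func:`classify_enhanced` (an equivalence the test suite checks across
    randomized episodes; the two are separate implementations on purpose).
    """
    if not episode.encounters:
        raise ValueError("episode has no encounters")

    has_mtx = _mtx_in_window(episode, cfg)

    def counted(enc: Encounter) -> bool:
        # telephone encounters count nowhere when the TAV channel is off
        return cfg.use_tav or enc.setting is not Setting.TELEPHONE

    def enc_cats(enc: Encounter) -> set[DxCategory]:
        return {classify_diagnosis(c, registry) for c in enc.diagnosis_codes}

    def countable_dx(cats: set[DxCategory]) -> bool:
        # "EP code other than abdominal" under the abdominal exclusion;
        # otherwise any EP diagnosis code counts.
        if DxCategory.SPECIFIC_TUBAL in cats or DxCategory.NONSPECIFIC_EP in cats:
            return True
        return (not cfg.exclude_abdominal_only) and DxCategory.ABDOMINAL in cats

    def nonspecific_dx(cats: set[DxCategory]) -> bool:
        if DxCategory.NONSPECIFIC_EP in cats:
            return True
        return (not cfg.exclude_abdominal_only) and DxCategory.ABDOMINAL in cats

    encs = [(e, enc_cats(e)) for e in episode.encounters]

    b1_count = sum(1 for e, cats in encs if counted(e) and countable_dx(cats))
    b1_inperson = any(
        e.in_person for e, cats in encs if counted(e) and countable_dx(cats)
    )
    b1 = b1_count >= 2 and b1_inperson

    b2 = (
        cfg.use_tav
        and has_mtx
        and sum(
            1
            for e, cats in encs
            if e.setting is Setting.TELEPHONE and countable_dx(cats)
        )
        >= 2
    )

    b3 = any(
        e.in_person and DxCategory.SPECIFIC_TUBAL in cats for e, cats in encs
    )

    b4 = has_mtx and any(
        counted(e) and nonspecific_dx(cats) for e, cats in encs
    )

    b5 = cfg.allow_single_dx_plus_px and any(
        e.in_person
        and (cats & {DxCategory.SPECIFIC_TUBAL, DxCategory.NONSPECIFIC_EP, DxCategory.ABDOMINAL})
        and any(registry.is_ep_procedure(c) for c in e.procedure_codes)
        for e, cats in encs
    )

    for fired, branch in (
        (b1, Branch.B1_MULTI_ENCOUNTER),
        (b2, Branch.B2_TAV_MTX),
        (b3, Branch.B3_SPECIFIC_CODE),
        (b4, Branch.B4_NONSPECIFIC_PLUS_MTX),
        (b5, Branch.B5_SINGLE_DX_PLUS_PX),
    ):
        if fired:
            return CaseDecision(
                episode.patient_id, episode.index_date, True, branch, cfg.variant
            )
    return CaseDecision(episode.patient_id, episode.index_date, False, Branch.NONE, cfg.variant)


def classify_cohort(
    episodes: Sequence[PregnancyEpisode],
    registry: CodeRegistry,
    cfg: AlgorithmVariantConfig | None = None,
) -> list[CaseDecision]:
    """Classify every episode; order preserved; logs per-branch firing counts."""
    cfg = cfg or AlgorithmVariantConfig.enhanced()
    decisions = [classify_with_variant(ep, registry, cfg) for ep in episodes]
    counts = Counter(d.branch.value for d in decisions)
    logger.info(
        "classified %d episodes (%s): %s",
        len(decisions),
        cfg.variant.value,
        dict(sorted(counts.items())),
    )
    return decisions


def decisions_table(decisions: Sequence[CaseDecision]):
    """Serialize decisions to a DataFrame (patient_id, index_date, variant, is_ep, branch)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "index_date": d.index_date.isoformat(),
                "variant": d.variant.value,
                "is_ep": d.is_ep,
                "branch": d.branch.value,
            }
            for d in decisions
        ],
        columns=["patient_id", "index_date", "variant", "is_ep", "branch"],
    )
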