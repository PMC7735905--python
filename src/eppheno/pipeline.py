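"""End-to-end wiring: records -> episodes -> decisions -> validation.

Convenience layer used by the CLI, the examples, and the test suite; each
step delegates to the corresponding module.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .algorithm import AlgorithmVariantConfig, CaseDecision, classify_cohort
from .codes import CodeRegistry, default_registry
from .episodes import PregnancyEpisode, attach_methotrexate, build_episodes, select_ep_coded_encounters
from .management import ManagementDecision, management_cohort
from .metrics import BinaryMetricsReport, binary_metrics, confusion
from .records import Encounter, MedicationAdministration

__all__ = [
    "run_case_finding",
    "patient_level_predictions",
    "evaluate_case_finding",
    "run_management",
]


def run_case_finding(
    encounters: Sequence[Encounter],
    medications: Sequence[MedicationAdministration],
    registry: CodeRegistry | None = None,
    cfg: AlgorithmVariantConfig | None = None,
) -> tuple[list[PregnancyEpisode], list[CaseDecision]]:
    """Select EP-coded encounters, build episodes, attach methotrexate, classify."""
    registry = registry or default_registry()
    cfg = cfg or AlgorithmVariantConfig.enhanced()
    ep_encounters = select_ep_coded_encounters(encounters, registry)
    episodes = build_episodes(ep_encounters)
    meds_by_patient: dict[str, list[MedicationAdministration]] = {}
    for m in medications:
        meds_by_patient.setdefault(m.patient_id, []).append(m)
    episodes = [
        attach_methotrexate(
            ep,
            meds_by_patient.get(ep.patient_id, ()),
            registry,
            pre_days=cfg.mtx_pre_window_days,
            post_days=cfg.mtx_post_window_days,
        )
        for ep in episodes
    ]
    decisions = classify_cohort(episodes, registry, cfg)
    return episodes, decisions


def patient_level_predictions(
    decisions: Iterable[CaseDecision], patient_ids: Iterable[str]
) -> dict[str, bool]:
    """A patient is predicted EP iff any of their episodes is a case."""
    pred = {pid: False for pid in patient_ids}
    for d in decisions:
        if d.is_ep:
            pred[d.patient_id] = True
    return pred


def evaluate_case_finding(
    pred: Mapping[str, bool], gold: pd.DataFrame
) -> BinaryMetricsReport:
    """Score patient-level predictions against gold labels (``ep_true`` column)."""
    gold_map = dict(zip(gold["patient_id"], gold["ep_true"].astype(bool)))
    return binary_metrics(confusion(pred, gold_map))


def run_management(
    episodes: Sequence[PregnancyEpisode],
    decisions: Sequence[CaseDecision],
    registry: CodeRegistry | None = None,
) -> list[ManagementDecision]:
    """Management classification for the EP-positive episodes."""
    return management_cohort(episodes, decisions, registry or default_registry())
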