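"""Pregnancy-episode construction.

A candidate pregnancy episode groups every EP-coded encounter occurring
within a 180-day period (inclusive) of the first EP-coded encounter, whose
date is the episode's *index date* (the EP diagnosis date).  Methotrexate
evidence is attached from 30 days before to 180 days after the index date,
both ends inclusive; both windows are configurable.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .codes import CodeRegistry
from .records import Encounter, MedicationAdministration

logger = logging.getLogger(__name__)

__all__ = [
    "PregnancyEpisode",
    "select_ep_coded_encounters",
    "build_episodes",
    "attach_methotrexate",
    "EPISODE_WINDOW_DAYS",
    "MTX_PRE_DAYS",
    "MTX_POST_DAYS",
]

EPISODE_WINDOW_DAYS = 180
MTX_PRE_DAYS = 30
MTX_POST_DAYS = 180


@dataclass(frozen=True)
class PregnancyEpisode:
    """One candidate pregnancy: EP-coded encounters anchored at the index date.

    Invariants: ``encounters`` is non-empty and chronologically sorted, the
    earliest encounter date equals ``index_date``, every encounter falls in
    [index_date, index_date + 180 d], and every attached methotrexate record
    falls in [index_date − 30 d, index_date + 180 d] (inclusive bounds).
    """

    patient_id: str
    index_date: dt.date
    encounters: tuple[Encounter, ...]
    methotrexate_records: tuple[MedicationAdministration, ...] = ()

    def __post_init__(self) -> None:
        if not self.encounters:
            raise ValueError("episode must contain at least one encounter")
        if min(e.date for e in self.encounters) != self.index_date:
            raise ValueError("index_date must equal the earliest encounter date")


def select_ep_coded_encounters(
    encounters: Iterable[Encounter], registry: CodeRegistry
) -> list[Encounter]:
    """Keep exactly the encounters carrying >=1 EP diagnosis OR EP procedure code.

    Abdominal-coded encounters are retained here — the abdominal exclusion is
    applied by the case-finding branches, not at the potential-case stage.
    Order is preserved.
    """
    out = []
    for e in encounters:
        if any(registry.is_ep_diagnosis(c) for c in e.diagnosis_codes) or any(
            registry.is_ep_procedure(c) for c in e.procedure_codes
        ):
            if not any(registry.is_ep_diagnosis(c) for c in e.diagnosis_codes):
                logger.debug(
                    "patient %s %s: procedure-only EP encounter retained",
                    e.patient_id,
                    e.date,
                )
            out.append(e)
    return out


def build_episodes(
    ep_encounters: Sequence[Encounter],
    *,
    window_days: int = EPISODE_WINDOW_DAYS,
    inclusive: bool = True,
) -> list[PregnancyEpisode]:
    """Greedy left-to-right grouping of EP-coded encounters into episodes.

    Per patient, the earliest unassigned encounter opens an episode and fixes
    its index date; every subsequent encounter dated <= index + window joins
    it (``inclusive=True`` keeps day ``window_days`` itself); the next
    encounter beyond the window opens a new episode.  Deterministic, and a
    partition: every input encounter lands in exactly one episode.
    """
    by_patient: dict[str, list[Encounter]] = {}
    for e in ep_encounters:
        by_patient.setdefault(e.patient_id, []).append(e)

    limit = dt.timedelta(days=window_days)
    episodes: list[PregnancyEpisode] = []
    for pid in sorted(by_patient):
        encs = sorted(by_patient[pid], key=lambda e: e.date)
        current: list[Encounter] = []
        index: dt.date | None = None
        for e in encs:
            delta = None if index is None else e.date - index
            in_window = delta is not None and (
                delta <= limit if inclusive else delta < limit
            )
            if index is None or in_window:
                if index is None:
                    index = e.date
                current.append(e)
            else:
                episodes.append(
                    PregnancyEpisode(patient_id=pid, index_date=index, encounters=tuple(current))
                )
                index = e.date
                current = [e]
        if current:
            episodes.append(
                PregnancyEpisode(patient_id=pid, index_date=index, encounters=tuple(current))
            )
    return episodes


def attach_methotrexate(
    episode: PregnancyEpisode,
    meds: Iterable[MedicationAdministration],
    registry: CodeRegistry,
    *,
    pre_days: int = MTX_PRE_DAYS,
    post_days: int = MTX_POST_DAYS,
) -> PregnancyEpisode:
    """Attach admissible methotrexate records within [−pre_days, +post_days].

    A record qualifies iff it belongs to the episode's patient, its drug code
    is a registered methotrexate code with an admissible administration
    subcode, and −pre_days <= (date − index_date) <= post_days (inclusive at
    both ends).  All other episode fields are unchanged.
    """
    lo = episode.index_date - dt.timedelta(days=pre_days)
    hi = episode.index_date + dt.timedelta(days=post_days)
    keep = tuple(
        sorted(
            (
                m
                for m in meds
                if m.patient_id == episode.patient_id
                and lo <= m.date <= hi
                and registry.is_methotrexate(m.drug_code, m.admin_subcode)
            ),
            key=lambda m: m.date,
        )
    )
    return replace(episode, methotrexate_records=keep)


def episode_table(episodes: Sequence[PregnancyEpisode]):
    """Summarize episodes as a DataFrame (patient_id, index_date, counts)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "patient_id": ep.patient_id,
                "index_date": ep.index_date.isoformat(),
                "n_encounters": len(ep.encounters),
                "n_mtx_records": len(ep.methotrexate_records),
            }
            for ep in episodes
        ],
        columns=["patient_id", "index_date", "n_encounters", "n_mtx_records"],
    )
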