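"""Treatment-modality classification for confirmed EP episodes.

A case is *surgically* managed if any EP removal surgery code appears on an
encounter within 30 days after the index date — regardless of methotrexate
receipt (surgical precedence is absolute).  Remaining cases with episode
methotrexate evidence are *medically* managed; the rest are *unclassified*.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from typing import Sequence

from .algorithm import CaseDecision
from .codes import CodeRegistry
from .episodes import PregnancyEpisode

__all__ = ["Management", "ManagementDecision", "classify_management", "management_cohort"]

SURGERY_WINDOW_DAYS = 30


class Management(str, enum.Enum):
    SURGICAL = "surgical"
    MEDICAL = "medical"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ManagementDecision:
    patient_id: str
    index_date: dt.date
    management: Management
    evidence_date: dt.date | None  # earliest qualifying surgery or methotrexate date


def classify_management(
    episode: PregnancyEpisode,
    registry: CodeRegistry,
    *,
    surgery_window_days: int = SURGERY_WINDOW_DAYS,
    allow_pre_index_surgery: bool = False,
) -> ManagementDecision:
    """Assign surgical / medical / unclassified to one episode.

    Surgery counts only in [index_date, index_date + window] by default
    (``allow_pre_index_surgery=True`` widens to a symmetric window for sites
    with coding lag).  Evidence reported is the earliest qualifying date.
    """
    lo = (
        episode.index_date - dt.timedelta(days=surgery_window_days)
        if allow_pre_index_surgery
        else episode.index_date
    )
    hi = episode.index_date + dt.timedelta(days=surgery_window_days)

    surgery_dates = sorted(
        e.date
        for e in episode.encounters
        if lo <= e.date <= hi and any(registry.is_ep_surgery(c) for c in e.procedure_codes)
    )
    if surgery_dates:
        return ManagementDecision(
            episode.patient_id, episode.index_date, Management.SURGICAL, surgery_dates[0]
        )
    if episode.methotrexate_records:
        first = min(m.date for m in episode.methotrexate_records)
        return ManagementDecision(
            episode.patient_id, episode.index_date, Management.MEDICAL, first
        )
    return ManagementDecision(
        episode.patient_id, episode.index_date, Management.UNCLASSIFIED, None
    )


def management_cohort(
    episodes: Sequence[PregnancyEpisode],
    decisions: Sequence[CaseDecision],
    registry: CodeRegistry,
    **kwargs,
) -> list[ManagementDecision]:
    """Classify management for every EP-positive episode (others skipped).

    ``decisions`` must be aligned 1:1 with ``episodes``.
    """
    if len(episodes) != len(decisions):
        raise ValueError(
            f"episodes ({len(episodes)}) and decisions ({len(decisions)}) are misaligned"
        )
    out = []
    for ep, dec in zip(episodes, decisions):
        if (ep.patient_id, ep.index_date) != (dec.patient_id, dec.index_date):
            raise ValueError(
                f"decision for {dec.patient_id}/{dec.index_date} does not match "
                f"episode {ep.patient_id}/{ep.index_date}"
            )
        if dec.is_ep:
            out.append(classify_management(ep, registry, **kwargs))
    return out


def management_table(decisions: Sequence[ManagementDecision]):
    """Serialize to a DataFrame (patient_id, index_date, management, evidence_date)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "index_date": d.index_date.isoformat(),
                "management": d.management.value,
                "evidence_date": d.evidence_date.isoformat() if d.evidence_date else "",
            }
            for d in decisions
        ],
        columns=["patient_id", "index_date", "management", "evidence_date"],
    )
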