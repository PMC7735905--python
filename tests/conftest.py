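"""Shared fixtures and the randomized-episode generator used across tests."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from eppheno import (
    Encounter,
    MedicationAdministration,
    PregnancyEpisode,
    Setting,
    default_registry,
)

BASE = dt.date(2016, 3, 1)

DX_POOL = ["633.10", "O00.10", "EP9-NOS", "EP10-NOS", "O00.00", "O00.01", "NONEP-DX"]
PX_POOL = ["EP-PX-REMOVAL", "EP-PX-OTHER", "NONEP-PX"]
SETTINGS = list(Setting)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def random_episode(rng: np.random.Generator, pid: str = "R") -> PregnancyEpisode:
    """A random episode respecting the construction invariants.

    First encounter at day 0 (the index date), later ones within 180 days;
    methotrexate records within [-30, +180] with an admissible subcode (the
    variant machinery re-filters to its own window).
    """
    n_enc = int(rng.integers(1, 5))
    offsets = [0] + sorted(int(rng.integers(0, 181)) for _ in range(n_enc - 1))
    encounters = []
    for off in offsets:
        dx = tuple(
            DX_POOL[i] for i in rng.choice(len(DX_POOL), size=int(rng.integers(0, 3)), replace=False)
        )
        px = tuple(
            PX_POOL[i] for i in rng.choice(len(PX_POOL), size=int(rng.integers(0, 2)), replace=False)
        )
        encounters.append(
            Encounter(pid, BASE + dt.timedelta(days=off), SETTINGS[int(rng.integers(4))], dx, px)
        )
    meds = tuple(
        MedicationAdministration(
            pid, BASE + dt.timedelta(days=int(rng.integers(-30, 181))), "MTX-INJ", "ADMIN-GIVEN"
        )
        for _ in range(int(rng.integers(0, 3)))
    )
    return PregnancyEpisode(
        patient_id=pid, index_date=BASE, encounters=tuple(encounters), methotrexate_records=meds
    )
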