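"""EHR record schema, delimited-text IO, and the study eligibility filter.

Inputs are flat longitudinal extracts in delimited text (comma by default),
one row per encounter / medication administration / patient / enrollment span,
ISO-8601 dates, multiple codes per cell separated by ``|``.  Column layouts:

* encounters: ``patient_id, date, setting, dx_codes, px_codes``
* medications: ``patient_id, date, drug_code, admin_subcode``
* patients: ``patient_id, birth_date``
* enrollment: ``patient_id, start, end``  (half-open spans, [start, end))
* gold labels: ``patient_id, ep_true, management_true``

Rows that fail to parse (bad date, unknown setting) are rejected with
row-level diagnostics rather than aborting the load.
"""

from __future__ import annotations

import datetime as dt
import enum
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import pandas as pd

from .codes import CodeRegistry, InvalidCodeError, normalize_code

logger = logging.getLogger(__name__)

__all__ = [
    "Setting",
    "Encounter",
    "MedicationAdministration",
    "PatientInfo",
    "EnrollmentSpan",
    "EligibilityCriteria",
    "SchemaError",
    "read_encounters",
    "read_medications",
    "read_patients",
    "read_enrollment",
    "read_gold_labels",
    "write_encounters",
    "write_medications",
    "filter_eligible",
]

Source = Union[str, Path, IO[str]]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class Setting(str, enum.Enum):
    """Care setting of an encounter.

    ``telephone`` corresponds to telephone appointment visits (TAVs); the
    other three settings are "in-person" for the purposes of the rules
    (outside claims count as in-person).
    """

    OUTPATIENT = "outpatient"
    INPATIENT = "inpatient"
    OUTSIDE_CLAIM = "outside_claim"
    TELEPHONE = "telephone"

    @property
    def in_person(self) -> bool:
        return self is not Setting.TELEPHONE


# Alias table for the setting column of flat extracts.
SETTING_ALIASES: dict[str, Setting] = {
    "outpatient": Setting.OUTPATIENT,
    "op": Setting.OUTPATIENT,
    "ambulatory": Setting.OUTPATIENT,
    "inpatient": Setting.INPATIENT,
    "ip": Setting.INPATIENT,
    "hospital": Setting.INPATIENT,
    "outside_claim": Setting.OUTSIDE_CLAIM,
    "outside-claim": Setting.OUTSIDE_CLAIM,
    "claim": Setting.OUTSIDE_CLAIM,
    "oc": Setting.OUTSIDE_CLAIM,
    "telephone": Setting.TELEPHONE,
    "tav": Setting.TELEPHONE,
    "phone": Setting.TELEPHONE,
}


def parse_setting(raw: str) -> Setting:
    try:
        return SETTING_ALIASES[str(raw).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown care setting: {raw!r}") from None


@dataclass(frozen=True)
class Encounter:
    """One dated clinical contact with attached diagnosis/procedure codes."""

    patient_id: str
    date: dt.date
    setting: Setting
    diagnosis_codes: tuple[str, ...] = ()
    procedure_codes: tuple[str, ...] = ()

    @property
    def in_person(self) -> bool:
        return self.setting.in_person


@dataclass(frozen=True)
class MedicationAdministration:
    """One dated drug administration with drug code and optional subcode."""

    patient_id: str
    date: dt.date
    drug_code: str
    admin_subcode: str | None = None


@dataclass(frozen=True)
class PatientInfo:
    patient_id: str
    birth_date: dt.date | None


@dataclass(frozen=True)
class EnrollmentSpan:
    """Half-open health-plan enrollment span [start, end); days = end − start."""

    patient_id: str
    start: dt.date
    end: dt.date


@dataclass(frozen=True)
class EligibilityCriteria:
    """Study inclusion criteria: reproductive-age women, enrolled, in-window.

    Defaults follow the validation-study design: ages 15–44 inclusive at the
    index date, index date within 2009-01-01..2018-12-31, and at least 30
    days of enrollment overlapping the study period (a stand-in for "at
    least 1 month").
    """

    min_age_years: int = 15
    max_age_years: int = 44
    min_enrollment_days: int = 30
    study_start: dt.date = dt.date(2009, 1, 1)
    study_end: dt.date = dt.date(2018, 12, 31)

    def __post_init__(self) -> None:
        if self.min_age_years > self.max_age_years:
            raise ValueError("min_age_years must be <= max_age_years")
        if self.study_start > self.study_end:
            raise ValueError("study_start must be <= study_end")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _read_table(source: Source, required: Sequence[str], delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    return df


def _parse_date(raw: str) -> dt.date:
    return dt.date.fromisoformat(str(raw).strip())


def _split_codes(cell: str, code_sep: str) -> tuple[str, ...]:
    cell = (cell or "").strip()
    if not cell:
        return ()
    return tuple(normalize_code(c) for c in cell.split(code_sep) if c.strip())


def read_encounters(
    source: Source,
    registry: CodeRegistry | None = None,
    *,
    delimiter: str = ",",
    code_sep: str = "|",
) -> list[Encounter]:
    """Parse an encounter table; codes normalized, output sorted by (patient, date).

    Rows with unparseable dates or unknown settings are rejected and logged;
    a file with zero parseable rows yields an empty list with a warning.
    ``registry`` is accepted for interface symmetry (codes are normalized the
    same way regardless of registry content).
    """
    df = _read_table(source, ["patient_id", "date", "setting", "dx_codes", "px_codes"], delimiter)
    out: list[Encounter] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                Encounter(
                    patient_id=str(row.patient_id).strip(),
                    date=_parse_date(row.date),
                    setting=parse_setting(row.setting),
                    diagnosis_codes=_split_codes(row.dx_codes, code_sep),
                    procedure_codes=_split_codes(row.px_codes, code_sep),
                )
            )
        except (ValueError, InvalidCodeError) as exc:
            logger.warning("encounters row %d rejected: %s", i + 2, exc)
    if not out and len(df):
        logger.warning("no parseable encounter rows in input")
    out.sort(key=lambda e: (e.patient_id, e.date))
    return out


def read_medications(
    source: Source, *, delimiter: str = ",", code_sep: str = "|"
) -> list[MedicationAdministration]:
    """Parse a medication-administration table; see :func:`read_encounters`."""
    df = _read_table(source, ["patient_id", "date", "drug_code"], delimiter)
    has_sub = "admin_subcode" in df.columns
    out: list[MedicationAdministration] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            sub_raw = (getattr(row, "admin_subcode", "") if has_sub else "").strip()
            out.append(
                MedicationAdministration(
                    patient_id=str(row.patient_id).strip(),
                    date=_parse_date(row.date),
                    drug_code=normalize_code(row.drug_code),
                    admin_subcode=normalize_code(sub_raw) if sub_raw else None,
                )
            )
        except (ValueError, InvalidCodeError) as exc:
            logger.warning("medications row %d rejected: %s", i + 2, exc)
    if not out and len(df):
        logger.warning("no parseable medication rows in input")
    out.sort(key=lambda m: (m.patient_id, m.date))
    return out


def read_patients(source: Source, *, delimiter: str = ",") -> list[PatientInfo]:
    df = _read_table(source, ["patient_id", "birth_date"], delimiter)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = str(row.birth_date).strip()
        birth: dt.date | None
        try:
            birth = _parse_date(raw) if raw else None
        except ValueError as exc:
            logger.warning("patients row %d: bad birth date (%s); kept as missing", i + 2, exc)
            birth = None
        out.append(PatientInfo(patient_id=str(row.patient_id).strip(), birth_date=birth))
    return out


def read_enrollment(source: Source, *, delimiter: str = ",") -> list[EnrollmentSpan]:
    df = _read_table(source, ["patient_id", "start", "end"], delimiter)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                EnrollmentSpan(
                    patient_id=str(row.patient_id).strip(),
                    start=_parse_date(row.start),
                    end=_parse_date(row.end),
                )
            )
        except ValueError as exc:
            logger.warning("enrollment row %d rejected: %s", i + 2, exc)
    return out


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


def read_gold_labels(source: Source, *, delimiter: str = ",") -> pd.DataFrame:
    """Read chart-review gold labels: patient_id, ep_true, management_true."""
    df = _read_table(source, ["patient_id", "ep_true"], delimiter)

    def to_bool(v: str) -> bool:
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        raise ValueError(f"unparseable boolean label: {v!r}")

    df["patient_id"] = df["patient_id"].str.strip()
    df["ep_true"] = df["ep_true"].map(to_bool)
    if "management_true" in df.columns:
        df["management_true"] = df["management_true"].str.strip().str.lower()
    return df


# ---------------------------------------------------------------------------
# Writing (round-trips with the readers)
# ---------------------------------------------------------------------------


def write_encounters(
    encounters: Iterable[Encounter], dest: Source, *, delimiter: str = ",", code_sep: str = "|"
) -> None:
    rows = [
        {
            "patient_id": e.patient_id,
            "date": e.date.isoformat(),
            "setting": e.setting.value,
            "dx_codes": code_sep.join(e.diagnosis_codes),
            "px_codes": code_sep.join(e.procedure_codes),
        }
        for e in encounters
    ]
    pd.DataFrame(rows, columns=["patient_id", "date", "setting", "dx_codes", "px_codes"]).to_csv(
        dest, sep=delimiter, index=False
    )


def write_medications(
    meds: Iterable[MedicationAdministration], dest: Source, *, delimiter: str = ","
) -> None:
    rows = [
        {
            "patient_id": m.patient_id,
            "date": m.date.isoformat(),
            "drug_code": m.drug_code,
            "admin_subcode": m.admin_subcode or "",
        }
        for m in meds
    ]
    pd.DataFrame(rows, columns=["patient_id", "date", "drug_code", "admin_subcode"]).to_csv(
        dest, sep=delimiter, index=False
    )


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------


def _age_in_completed_years(birth: dt.date, on: dt.date) -> int:
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


def filter_eligible(
    patients: Iterable[PatientInfo],
    enrollment: Iterable[EnrollmentSpan],
    criteria: EligibilityCriteria,
    index_dates: Mapping[str, dt.date],
) -> set[str]:
    """Apply the study inclusion criteria; returns the eligible patient-id set.

    A patient is eligible iff: age at index date within [min, max] inclusive
    (completed years); index date inside the study period; and total
    enrollment days overlapping the study period >= ``min_enrollment_days``.
    Patients with a missing birth date are excluded with a diagnostic.
    Invariant to input ordering.
    """
    spans_by_patient: dict[str, list[EnrollmentSpan]] = {}
    for s in enrollment:
        spans_by_patient.setdefault(s.patient_id, []).append(s)

    # Half-open overlap with the inclusive study period [start, end].
    study_lo = criteria.study_start
    study_hi = criteria.study_end + dt.timedelta(days=1)

    eligible: set[str] = set()
    for p in patients:
        idx = index_dates.get(p.patient_id)
        if idx is None:
            continue
        if p.birth_date is None:
            logger.warning("patient %s excluded: missing birth date", p.patient_id)
            continue
        if not (criteria.study_start <= idx <= criteria.study_end):
            continue
        age = _age_in_completed_years(p.birth_date, idx)
        if not (criteria.min_age_years <= age <= criteria.max_age_years):
            continue
        days = 0
        for s in spans_by_patient.get(p.patient_id, ()):
            lo = max(s.start, study_lo)
            hi = min(s.end, study_hi)
            days += max(0, (hi - lo).days)
        if days >= criteria.min_enrollment_days:
            eligible.add(p.patient_id)
    return eligible
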