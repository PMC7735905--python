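"""Synthetic EHR cohort generator with gold labels.

Builds reproducible encounter/medication histories that exercise every
case-finding branch, every temporal window boundary, and every management
category, so the whole pipeline can be validated without access to protected
health data.  Defaults mirror the validation study's conditions: a true-EP
prevalence of 0.668 (334/500), a surgical/medical/unclassified management mix
of 0.604/0.387/0.009, the 2009-01-01..2018-12-31 study window with the
ICD-9 -> ICD-10 cutover at 2015-10-01, and an age distribution following the
sample's published bands.  Branch frequencies are not published; the default
branch mix is uniform and explicitly an invention of this generator.

Under zero noise the generator and the enhanced classifier are exact inverses
by construction: every true case satisfies its drawn branch, every non-case
(including the explicit near-miss patterns) fails all five branches, so
pipeline sensitivity and specificity are exactly 100%.  Noise channels then
perturb records: per-instance EP-diagnosis-code drops, false EP codes on
non-cases (near-miss patterns), abdominal-only recoding of true cases, and
methotrexate displaced outside its window.  The expected sensitivity under
these channels has a closed form (:func:`expected_sensitivity`).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .algorithm import Branch
from .records import (
    Encounter,
    EnrollmentSpan,
    MedicationAdministration,
    PatientInfo,
    Setting,
)

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "BoundaryFixture",
    "generate_cohort",
    "generate_boundary_suite",
    "expected_sensitivity",
    "write_cohort",
]

STUDY_START = dt.date(2009, 1, 1)
STUDY_END = dt.date(2018, 12, 31)
ICD10_CUTOVER = dt.date(2015, 10, 1)  # US national ICD-10-CM transition date

# Era-specific code choices (placeholders for the categories whose real code
# lists are site-specific; see eppheno.codes).
_SPECIFIC_ICD9 = ("633.10", "633.11")
_SPECIFIC_ICD10 = ("O00.10", "O00.11")
_NONSPECIFIC_ICD9 = "EP9-NOS"
_NONSPECIFIC_ICD10 = "EP10-NOS"
_ABDOMINAL = ("O00.00", "O00.01")  # ICD-10 only
_PX_CODE = "EP-PX-OTHER"  # EP procedure that is not a removal surgery
_SURGERY_CODE = "EP-PX-REMOVAL"
_MTX_CODE = "MTX-INJ"
_MTX_SUBCODE = "ADMIN-GIVEN"
_BENIGN_DX = "NONEP-DX"

_BRANCHES = (
    Branch.B1_MULTI_ENCOUNTER,
    Branch.B2_TAV_MTX,
    Branch.B3_SPECIFIC_CODE,
    Branch.B4_NONSPECIFIC_PLUS_MTX,
    Branch.B5_SINGLE_DX_PLUS_PX,
)
_MTX_BRANCHES = {Branch.B2_TAV_MTX, Branch.B4_NONSPECIFIC_PLUS_MTX}
_NO_MTX_BRANCHES = (
    Branch.B1_MULTI_ENCOUNTER,
    Branch.B3_SPECIFIC_CODE,
    Branch.B5_SINGLE_DX_PLUS_PX,
)

# Published age-band shares of the validation sample: <20, 20-29, 30-34, >=35.
_AGE_BANDS = ((15, 19, 0.044), (20, 29, 0.338), (30, 34, 0.314), (35, 44, 0.304))


class CohortConfigError(ValueError):
    """Invalid or infeasible generator configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults are the study conditions.

    ``branch_mix`` orders probabilities over B1..B5 for true cases;
    ``management_mix`` over surgical/medical/unclassified. Noise channels:
    ``p_drop_dx`` drops each EP diagnosis-code instance of a true case,
    ``p_false_dx`` gives a non-case a near-miss EP pattern that fails every
    branch, ``p_abdominal_only`` recodes a true case's diagnoses as abdominal
    only, ``p_mtx_outside_window`` displaces a methotrexate record beyond the
    attachment window.
    """

    n_patients: int = 500
    prevalence: float = 0.668
    branch_mix: tuple[float, float, float, float, float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    management_mix: tuple[float, float, float] = (0.604, 0.387, 0.009)
    p_drop_dx: float = 0.0
    p_false_dx: float = 0.0
    p_abdominal_only: float = 0.0
    p_mtx_outside_window: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise CohortConfigError("n_patients must be >= 0")
        for name in ("prevalence", "p_drop_dx", "p_false_dx", "p_abdominal_only",
                     "p_mtx_outside_window"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(f"{name} must be in [0, 1], got {v}")
        for name, vec, k in (("branch_mix", self.branch_mix, 5),
                             ("management_mix", self.management_mix, 3)):
            if len(vec) != k or any(p < 0 for p in vec):
                raise CohortConfigError(f"{name} must be {k} non-negative probabilities")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise CohortConfigError(f"{name} must sum to 1 (got {sum(vec)})")
        # An unclassified management (no surgery, no methotrexate) is
        # incompatible with the methotrexate-requiring branches B2/B4.
        if self.management_mix[2] > 0:
            no_mtx_mass = self.branch_mix[0] + self.branch_mix[2] + self.branch_mix[4]
            if no_mtx_mass <= 0:
                raise CohortConfigError(
                    "management_mix assigns mass to 'unclassified' but branch_mix "
                    "puts all mass on the methotrexate-requiring branches B2/B4; "
                    "unclassified cases can only be drawn from B1/B3/B5"
                )


@dataclass
class SyntheticCohort:
    """Generated cohort: record lists, gold labels, and a config/seed manifest."""

    encounters: list[Encounter]
    medications: list[MedicationAdministration]
    patients: list[PatientInfo]
    enrollment: list[EnrollmentSpan]
    gold: pd.DataFrame  # patient_id, ep_true, management_true, branch_true
    manifest: dict


def _era_nonspecific(era9: bool) -> str:
    return _NONSPECIFIC_ICD9 if era9 else _NONSPECIFIC_ICD10


def _era_specific(era9: bool, rng: np.random.Generator) -> str:
    pool = _SPECIFIC_ICD9 if era9 else _SPECIFIC_ICD10
    return pool[int(rng.integers(len(pool)))]


def generate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Generate a gold-labeled cohort; byte-identical given the same config."""
    rng = np.random.default_rng(cfg.seed)
    total_days = (STUDY_END - STUDY_START).days

    encounters: list[Encounter] = []
    medications: list[MedicationAdministration] = []
    patients: list[PatientInfo] = []
    enrollment: list[EnrollmentSpan] = []
    gold_rows: list[dict] = []

    mgmt_levels = ("surgical", "medical", "unclassified")

    for i in range(cfg.n_patients):
        pid = f"P{i:06d}"
        # Index date leaves room for the -30 d methotrexate lookback and the
        # +180 d (+ displaced-methotrexate) follow-up inside the study window.
        offset = int(rng.integers(40, total_days - 220))
        index = STUDY_START + dt.timedelta(days=offset)
        era9 = index < ICD10_CUTOVER

        lo, hi, _ = _AGE_BANDS[int(rng.choice(len(_AGE_BANDS), p=[b[2] for b in _AGE_BANDS]))]
        age = int(rng.integers(lo, hi + 1))
        birth = index - dt.timedelta(days=age * 365 + int(rng.integers(0, 360)))
        patients.append(PatientInfo(patient_id=pid, birth_date=birth))
        enrollment.append(EnrollmentSpan(patient_id=pid, start=STUDY_START, end=STUDY_END))

        is_case = bool(rng.random() < cfg.prevalence)
        if not is_case:
            gold_rows.append({"patient_id": pid, "ep_true": False,
                              "management_true": "", "branch_true": ""})
            if rng.random() < cfg.p_false_dx:
                choices = ["single_tav", "single_ns"] + ([] if era9 else ["abdominal_only"])
                kind = choices[int(rng.integers(len(choices)))]
                if kind == "abdominal_only":
                    encounters.append(Encounter(pid, index, Setting.OUTPATIENT,
                                                (_ABDOMINAL[int(rng.integers(2))],)))
                elif kind == "single_tav":
                    encounters.append(Encounter(pid, index, Setting.TELEPHONE,
                                                (_era_nonspecific(era9),)))
                else:
                    encounters.append(Encounter(pid, index, Setting.OUTPATIENT,
                                                (_era_nonspecific(era9),)))
            else:
                encounters.append(Encounter(pid, index, Setting.OUTPATIENT, (_BENIGN_DX,)))
            continue

        # --- true case -----------------------------------------------------
        mgmt = mgmt_levels[int(rng.choice(3, p=cfg.management_mix))]
        if mgmt == "unclassified":
            weights = np.array([cfg.branch_mix[0], cfg.branch_mix[2], cfg.branch_mix[4]])
            branch = _NO_MTX_BRANCHES[int(rng.choice(3, p=weights / weights.sum()))]
        else:
            branch = _BRANCHES[int(rng.choice(5, p=cfg.branch_mix))]

        ns = _era_nonspecific(era9)
        spec = _era_specific(era9, rng)
        # pattern: (day offset, setting, dx codes, px codes)
        if branch is Branch.B1_MULTI_ENCOUNTER:
            pattern = [(0, Setting.OUTPATIENT, [ns], []), (3, Setting.OUTPATIENT, [ns], [])]
        elif branch is Branch.B2_TAV_MTX:
            pattern = [(0, Setting.TELEPHONE, [ns], []), (2, Setting.TELEPHONE, [ns], [])]
        elif branch is Branch.B3_SPECIFIC_CODE:
            pattern = [(0, Setting.OUTPATIENT, [spec], [])]
        elif branch is Branch.B4_NONSPECIFIC_PLUS_MTX:
            pattern = [(0, Setting.OUTPATIENT, [ns], [])]
        else:  # B5
            pattern = [(0, Setting.OUTPATIENT, [ns], [_PX_CODE])]

        # Noise: abdominal-only recoding replaces every EP diagnosis code.
        if rng.random() < cfg.p_abdominal_only:
            pattern = [
                (day, setting, [_ABDOMINAL[0] for _ in dx], px)
                for day, setting, dx, px in pattern
            ]
        # Noise: each diagnosis-code instance independently omitted.
        if cfg.p_drop_dx > 0:
            pattern = [
                (day, setting, [c for c in dx if rng.random() >= cfg.p_drop_dx], px)
                for day, setting, dx, px in pattern
            ]

        for day, setting, dx, px in pattern:
            encounters.append(
                Encounter(pid, index + dt.timedelta(days=day), setting, tuple(dx), tuple(px))
            )

        needs_mtx = mgmt == "medical" or branch in _MTX_BRANCHES
        if needs_mtx:
            mtx_day = 1
            if rng.random() < cfg.p_mtx_outside_window:
                mtx_day = 201  # beyond the +180 d attachment window
            medications.append(
                MedicationAdministration(pid, index + dt.timedelta(days=mtx_day),
                                         _MTX_CODE, _MTX_SUBCODE)
            )
        if mgmt == "surgical":
            encounters.append(
                Encounter(pid, index + dt.timedelta(days=5), Setting.INPATIENT,
                          (), (_SURGERY_CODE,))
            )
        gold_rows.append({"patient_id": pid, "ep_true": True,
                          "management_true": mgmt, "branch_true": branch.value})

    encounters.sort(key=lambda e: (e.patient_id, e.date))
    medications.sort(key=lambda m: (m.patient_id, m.date))
    gold = pd.DataFrame(gold_rows,
                        columns=["patient_id", "ep_true", "management_true", "branch_true"])
    manifest = {
        "generator": "eppheno.synthetic.generate_cohort",
        "config": dataclasses.asdict(cfg),
        "n_patients": cfg.n_patients,
        "n_true_cases": int(gold["ep_true"].sum()) if len(gold) else 0,
        "n_encounters": len(encounters),
        "n_medications": len(medications),
    }
    return SyntheticCohort(encounters, medications, patients, enrollment, gold, manifest)


def expected_sensitivity(cfg: CohortConfig) -> float:
    """Closed-form expected pipeline sensitivity under the noise channels.

    Derived per branch from the canonical generated patterns.  With q = 1 −
    p_drop_dx, p = p_drop_dx, and methotrexate present with probability
    1 − p_mtx_outside_window when the pattern nominally includes it:

    * B1 survives when both diagnosis instances are kept (q²) or exactly one
      is kept and methotrexate rescues it through B4 (2qp, methotrexate
      patterns only);
    * B2 requires methotrexate; given it, both TAV codes kept fires B2 (q²)
      and a single surviving TAV code fires B4 (2qp);
    * B3 and B5 survive iff their single diagnosis instance is kept (q);
    * B4 requires methotrexate and its diagnosis instance (q);
    * an abdominal-only recoded case survives only as a B5 pattern whose
      diagnosis instance is kept (the diagnosis+procedure branch admits
      abdominal codes; every other branch ignores them).

    Independent of the classifier implementation; used as the analytic
    reference that simulated sensitivity is tested against.
    """
    p = cfg.p_drop_dx
    q = 1.0 - p
    p_mtx_kept = 1.0 - cfg.p_mtx_outside_window
    pa = cfg.p_abdominal_only

    def survival(branch: Branch, mtx: bool, abdominal: bool) -> float:
        if abdominal:
            return q if branch is Branch.B5_SINGLE_DX_PLUS_PX else 0.0
        if branch is Branch.B1_MULTI_ENCOUNTER:
            return q * q + (2.0 * q * p if mtx else 0.0)
        if branch is Branch.B2_TAV_MTX:
            return (q * q + 2.0 * q * p) if mtx else 0.0
        if branch is Branch.B3_SPECIFIC_CODE:
            return q
        if branch is Branch.B4_NONSPECIFIC_PLUS_MTX:
            return q if mtx else 0.0
        return q  # B5

    mgmt_probs = dict(zip(("surgical", "medical", "unclassified"), cfg.management_mix))
    total = 0.0
    for mgmt, w in mgmt_probs.items():
        if w == 0.0:
            continue
        if mgmt == "unclassified":
            weights = {b: cfg.branch_mix[_BRANCHES.index(b)] for b in _NO_MTX_BRANCHES}
            z = sum(weights.values())
            branch_probs = {b: v / z for b, v in weights.items()}
        else:
            branch_probs = dict(zip(_BRANCHES, cfg.branch_mix))
        for branch, bp in branch_probs.items():
            if bp == 0.0:
                continue
            nominal_mtx = mgmt == "medical" or branch in _MTX_BRANCHES
            for mtx, pm in ((True, p_mtx_kept if nominal_mtx else 0.0),
                            (False, 1.0 - (p_mtx_kept if nominal_mtx else 0.0))):
                if pm == 0.0:
                    continue
                for abd, pab in ((True, pa), (False, 1.0 - pa)):
                    if pab == 0.0:
                        continue
                    total += w * bp * pm * pab * survival(branch, mtx, abd)
    return total


# ---------------------------------------------------------------------------
# Boundary suite: hand-built fixtures with frozen expected decisions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundaryFixture:
    """One hand-built patient history with expected per-episode decisions.

    ``expected_enhanced`` / ``expected_comparison`` list (is_ep, branch) per
    chronological episode under each variant.
    """

    name: str
    encounters: tuple[Encounter, ...]
    medications: tuple[MedicationAdministration, ...]
    expected_enhanced: tuple[tuple[bool, Branch], ...]
    expected_comparison: tuple[tuple[bool, Branch], ...]


def generate_boundary_suite() -> list[BoundaryFixture]:
    """Deterministic fixtures covering window boundaries and rule differences."""
    d0 = dt.date(2016, 2, 1)
    NS = "EP10-NOS"
    fixtures: list[BoundaryFixture] = []
    counter = 0

    def day(n: int) -> dt.date:
        return d0 + dt.timedelta(days=n)

    def enc(pid: str, offset: int, setting: Setting, dx=(), px=()) -> Encounter:
        return Encounter(pid, day(offset), setting, tuple(dx), tuple(px))

    def mtx(pid: str, offset: int, subcode: str = _MTX_SUBCODE) -> MedicationAdministration:
        return MedicationAdministration(pid, day(offset), _MTX_CODE, subcode)

    POS = True
    NEG = False
    none = Branch.NONE

    def add(name, encounters, medications, enhanced, comparison):
        nonlocal counter
        counter += 1
        pid = f"BF{counter:02d}"
        fixtures.append(
            BoundaryFixture(
                name=name,
                encounters=tuple(e if e.patient_id == pid else dataclasses.replace(e, patient_id=pid)
                                 for e in encounters),
                medications=tuple(m if m.patient_id == pid else dataclasses.replace(m, patient_id=pid)
                                  for m in medications),
                expected_enhanced=tuple(enhanced),
                expected_comparison=tuple(comparison),
            )
        )

    OP, IP, OC, TAV = Setting.OUTPATIENT, Setting.INPATIENT, Setting.OUTSIDE_CLAIM, Setting.TELEPHONE
    B1, B2, B3, B4, B5 = (
        Branch.B1_MULTI_ENCOUNTER,
        Branch.B2_TAV_MTX,
        Branch.B3_SPECIFIC_CODE,
        Branch.B4_NONSPECIFIC_PLUS_MTX,
        Branch.B5_SINGLE_DX_PLUS_PX,
    )
    p = "x"  # placeholder pid, rewritten by add()

    add("two_outpatient_nonspecific",
        [enc(p, 0, OP, [NS]), enc(p, 3, OP, [NS])], [],
        [(POS, B1)], [(POS, B1)])
    add("episode_window_day180_inclusive",
        [enc(p, 0, OP, [NS]), enc(p, 180, OP, [NS])], [],
        [(POS, B1)], [(POS, B1)])
    add("episode_split_day181",
        [enc(p, 0, OP, [NS]), enc(p, 181, OP, [NS])], [],
        [(NEG, none), (NEG, none)], [(NEG, none), (NEG, none)])
    add("single_tav_nonspecific",
        [enc(p, 0, TAV, [NS])], [],
        [(NEG, none)], [(NEG, none)])
    add("two_tav_nonspecific_with_mtx",
        [enc(p, 0, TAV, [NS]), enc(p, 2, TAV, [NS])], [mtx(p, 1)],
        [(POS, B2)], [(NEG, none)])
    add("two_tav_nonspecific_no_mtx",
        [enc(p, 0, TAV, [NS]), enc(p, 2, TAV, [NS])], [],
        [(NEG, none)], [(NEG, none)])
    add("single_inpatient_specific_tubal",
        [enc(p, 0, IP, ["O00.10"])], [],
        [(POS, B3)], [(POS, B3)])
    add("single_tav_specific_tubal",
        [enc(p, 0, TAV, ["O00.10"])], [],
        [(NEG, none)], [(NEG, none)])
    add("outside_claim_specific_tubal",
        [enc(p, 0, OC, ["633.10"])], [],
        [(POS, B3)], [(POS, B3)])
    add("nonspecific_with_mtx_minus30",
        [enc(p, 0, OP, [NS])], [mtx(p, -30)],
        [(POS, B4)], [(NEG, none)])
    add("nonspecific_with_mtx_minus31",
        [enc(p, 0, OP, [NS])], [mtx(p, -31)],
        [(NEG, none)], [(NEG, none)])
    add("nonspecific_with_mtx_minus7",
        [enc(p, 0, OP, [NS])], [mtx(p, -7)],
        [(POS, B4)], [(POS, B4)])
    add("nonspecific_with_mtx_minus8",
        [enc(p, 0, OP, [NS])], [mtx(p, -8)],
        [(POS, B4)], [(NEG, none)])
    add("nonspecific_with_mtx_plus180",
        [enc(p, 0, OP, [NS])], [mtx(p, 180)],
        [(POS, B4)], [(POS, B4)])
    add("nonspecific_with_mtx_plus181",
        [enc(p, 0, OP, [NS])], [mtx(p, 181)],
        [(NEG, none)], [(NEG, none)])
    add("mtx_with_inadmissible_subcode",
        [enc(p, 0, OP, [NS])], [mtx(p, 1, subcode="ADMIN-WASTED")],
        [(NEG, none)], [(NEG, none)])
    add("dx_and_px_same_encounter",
        [enc(p, 0, OP, [NS], [_PX_CODE])], [],
        [(POS, B5)], [(NEG, none)])
    add("dx_and_px_different_encounters",
        [enc(p, 0, OP, [NS]), enc(p, 1, OP, [], [_PX_CODE])], [],
        [(NEG, none)], [(NEG, none)])
    add("dx_px_second_encounter_also_dx",
        [enc(p, 0, OP, [NS]), enc(p, 1, OP, [NS], [_PX_CODE])], [],
        [(POS, B1)], [(POS, B1)])
    add("abdominal_only_two_inperson",
        [enc(p, 0, OP, ["O00.00"]), enc(p, 3, OP, ["O00.01"])], [],
        [(NEG, none)], [(POS, B1)])
    add("abdominal_single_with_mtx",
        [enc(p, 0, OP, ["O00.00"])], [mtx(p, 1)],
        [(NEG, none)], [(POS, B4)])
    add("abdominal_op_plus_tav_with_mtx",
        [enc(p, 0, OP, ["O00.00"]), enc(p, 2, TAV, ["O00.00"])], [mtx(p, 1)],
        [(NEG, none)], [(POS, B4)])
    add("abdominal_dx_and_px_same_encounter",
        [enc(p, 0, OP, ["O00.00"], [_PX_CODE])], [],
        [(POS, B5)], [(NEG, none)])
    add("tav_plus_outpatient_nonspecific",
        [enc(p, 0, TAV, [NS]), enc(p, 2, OP, [NS])], [],
        [(POS, B1)], [(NEG, none)])
    add("two_tav_specific_with_mtx",
        [enc(p, 0, TAV, ["O00.10"]), enc(p, 1, TAV, ["O00.11"])], [mtx(p, 0)],
        [(POS, B2)], [(NEG, none)])
    add("same_day_two_encounters_count_separately",
        [enc(p, 0, OP, [NS]), enc(p, 0, OP, [NS])], [],
        [(POS, B1)], [(POS, B1)])
    return fixtures


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort in the delimited formats consumed by eppheno.records."""
    import json

    from .records import write_encounters, write_medications

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "encounters": out / "encounters.csv",
        "medications": out / "medications.csv",
        "patients": out / "patients.csv",
        "enrollment": out / "enrollment.csv",
        "gold": out / "gold.csv",
        "manifest": out / "manifest.json",
    }
    write_encounters(cohort.encounters, paths["encounters"])
    write_medications(cohort.medications, paths["medications"])
    pd.DataFrame(
        [{"patient_id": pt.patient_id,
          "birth_date": pt.birth_date.isoformat() if pt.birth_date else ""}
         for pt in cohort.patients],
        columns=["patient_id", "birth_date"],
    ).to_csv(paths["patients"], index=False)
    pd.DataFrame(
        [{"patient_id": s.patient_id, "start": s.start.isoformat(), "end": s.end.isoformat()}
         for s in cohort.enrollment],
        columns=["patient_id", "start", "end"],
    ).to_csv(paths["enrollment"], index=False)
    cohort.gold.to_csv(paths["gold"], index=False)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)
    return paths
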