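"""Diagnosis, procedure, and medication code sets used by the case-finding rules.

Every downstream rule (episode construction, the five case-finding branches,
management classification) consults a single :class:`CodeRegistry`.  Codes are
matched as normalized strings *with* their decimal point (``"633.10"``, not
``"63310"``); an optional prefix-matching mode supports sites whose extracts
truncate trailing digits.

The packaged defaults carry only the handful of diagnosis codes that are safe
to hard-code — the specific tubal codes (ICD-9 633.10/633.11, ICD-10
O00.10/O00.11) and the abdominal codes (O00.00/O00.01).  Every other category
ships obviously synthetic placeholder tokens (``EP9-NOS``, ``EP-PX-REMOVAL``,
``MTX-INJ``, ...): real deployments must supply their site's full code lists
via :func:`load_registry`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

__all__ = [
    "CodeRegistry",
    "DxCategory",
    "InvalidCodeError",
    "RegistryConsistencyError",
    "classify_diagnosis",
    "default_registry",
    "load_registry",
    "normalize_code",
    "save_registry",
]


class InvalidCodeError(ValueError):
    """Raised when a raw code string is empty or blank."""


class RegistryConsistencyError(ValueError):
    """Raised when a code-list configuration violates registry invariants."""


def normalize_code(raw: str) -> str:
    """Normalize a raw code string: strip whitespace, uppercase letters.

    The decimal point is preserved — ICD codes are matched with their decimal.
    Idempotent: ``normalize_code(normalize_code(x)) == normalize_code(x)``.

    Raises
    ------
    InvalidCodeError
        If the input is empty after stripping.
    """
    if raw is None:
        raise InvalidCodeError("code is None")
    code = str(raw).strip().upper()
    if not code:
        raise InvalidCodeError(f"blank code string: {raw!r}")
    return code


def _normset(codes: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_code(c) for c in codes)


class DxCategory(str, enum.Enum):
    """Partition of diagnosis-code space as seen by the case-finding branches."""

    SPECIFIC_TUBAL = "specific_tubal"
    ABDOMINAL = "abdominal"
    NONSPECIFIC_EP = "nonspecific_ep"
    NOT_EP = "not_ep"


# The six diagnosis codes that are safe to hard-code.
SPECIFIC_TUBAL_DEFAULT = frozenset({"633.10", "633.11", "O00.10", "O00.11"})
ABDOMINAL_DEFAULT = frozenset({"O00.00", "O00.01"})

# Placeholder tokens (synthetic, clearly non-clinical). EP9-/EP10- prefixes mark
# the code era they stand in for so the synthetic cohort can respect the
# ICD-9 -> ICD-10 cutover.
PLACEHOLDER_NONSPECIFIC = frozenset({"EP9-NOS", "EP10-NOS"})
PLACEHOLDER_PROCEDURE = frozenset({"EP-PX-REMOVAL", "EP-PX-OTHER"})
PLACEHOLDER_SURGERY = frozenset({"EP-PX-REMOVAL"})
PLACEHOLDER_MTX = frozenset({"MTX-INJ"})
PLACEHOLDER_SUBCODES = frozenset({"ADMIN-GIVEN"})


@dataclass(frozen=True)
class CodeRegistry:
    """Normalized code sets for every category the rules consult.

    Invariants (enforced at construction):

    * ``specific_tubal_codes`` and ``abdominal_codes`` are disjoint subsets of
      ``ep_diagnosis_codes``;
    * all stored codes are in normalized form.

    ``prefix_match=True`` lets a stored code match any queried code it is a
    prefix of (e.g. stored ``O00.1`` matches queried ``O00.10``); default OFF —
    exact matching is auditable.
    """

    ep_diagnosis_codes: frozenset[str]
    ep_procedure_codes: frozenset[str]
    ep_surgery_codes: frozenset[str]
    specific_tubal_codes: frozenset[str]
    abdominal_codes: frozenset[str]
    methotrexate_drug_codes: frozenset[str]
    valid_admin_subcodes: frozenset[str]
    prefix_match: bool = False

    def __post_init__(self) -> None:
        for name in (
            "ep_diagnosis_codes",
            "ep_procedure_codes",
            "ep_surgery_codes",
            "specific_tubal_codes",
            "abdominal_codes",
            "methotrexate_drug_codes",
            "valid_admin_subcodes",
        ):
            object.__setattr__(self, name, _normset(getattr(self, name)))
        if not self.specific_tubal_codes <= self.ep_diagnosis_codes:
            raise RegistryConsistencyError(
                "specific tubal codes must be a subset of EP diagnosis codes: "
                f"{sorted(self.specific_tubal_codes - self.ep_diagnosis_codes)}"
            )
        if not self.abdominal_codes <= self.ep_diagnosis_codes:
            raise RegistryConsistencyError(
                "abdominal codes must be a subset of EP diagnosis codes: "
                f"{sorted(self.abdominal_codes - self.ep_diagnosis_codes)}"
            )
        if self.specific_tubal_codes & self.abdominal_codes:
            raise RegistryConsistencyError(
                "specific tubal and abdominal code sets must be disjoint"
            )

    # -- membership helpers -------------------------------------------------

    def _member(self, code: str, codeset: frozenset[str]) -> bool:
        if code in codeset:
            return True
        if self.prefix_match:
            return any(code.startswith(c) for c in codeset)
        return False

    def is_ep_diagnosis(self, code: str) -> bool:
        return self._member(code, self.ep_diagnosis_codes)

    def is_ep_procedure(self, code: str) -> bool:
        return self._member(code, self.ep_procedure_codes)

    def is_ep_surgery(self, code: str) -> bool:
        return self._member(code, self.ep_surgery_codes)

    def is_methotrexate(self, drug_code: str, admin_subcode: str | None) -> bool:
        """Methotrexate evidence: drug code matches AND the administration
        subcode is admissible (the allow-list is empty, or the record's
        subcode is in it)."""
        if not self._member(drug_code, self.methotrexate_drug_codes):
            return False
        if not self.valid_admin_subcodes:
            return True
        return admin_subcode is not None and self._member(
            admin_subcode, self.valid_admin_subcodes
        )

    def to_config(self) -> dict:
        """Serialize to the code-list configuration mapping (round-trips)."""
        return {
            "ep_diagnosis": sorted(self.ep_diagnosis_codes),
            "ep_procedure": sorted(self.ep_procedure_codes),
            "ep_surgery": sorted(self.ep_surgery_codes),
            "specific_tubal": sorted(self.specific_tubal_codes),
            "abdominal": sorted(self.abdominal_codes),
            "methotrexate": sorted(self.methotrexate_drug_codes),
            "admin_subcodes": sorted(self.valid_admin_subcodes),
            "prefix_match": self.prefix_match,
        }


def classify_diagnosis(code: str, registry: CodeRegistry) -> DxCategory:
    """Assign a normalized diagnosis code to its category.

    Specific tubal and abdominal take precedence over nonspecific; any other
    registered EP diagnosis code is nonspecific; everything else is not-EP.
    Total over normalized strings; the four categories partition the space.
    """
    if registry._member(code, registry.specific_tubal_codes):
        return DxCategory.SPECIFIC_TUBAL
    if registry._member(code, registry.abdominal_codes):
        return DxCategory.ABDOMINAL
    if registry.is_ep_diagnosis(code):
        return DxCategory.NONSPECIFIC_EP
    return DxCategory.NOT_EP


def default_registry() -> CodeRegistry:
    """Packaged default registry: printed diagnosis codes + labeled placeholders."""
    return CodeRegistry(
        ep_diagnosis_codes=SPECIFIC_TUBAL_DEFAULT
        | ABDOMINAL_DEFAULT
        | PLACEHOLDER_NONSPECIFIC,
        ep_procedure_codes=PLACEHOLDER_PROCEDURE,
        ep_surgery_codes=PLACEHOLDER_SURGERY,
        specific_tubal_codes=SPECIFIC_TUBAL_DEFAULT,
        abdominal_codes=ABDOMINAL_DEFAULT,
        methotrexate_drug_codes=PLACEHOLDER_MTX,
        valid_admin_subcodes=PLACEHOLDER_SUBCODES,
    )


_CATEGORY_KEYS = {
    "ep_diagnosis": "ep_diagnosis_codes",
    "ep_procedure": "ep_procedure_codes",
    "ep_surgery": "ep_surgery_codes",
    "specific_tubal": "specific_tubal_codes",
    "abdominal": "abdominal_codes",
    "methotrexate": "methotrexate_drug_codes",
    "admin_subcodes": "valid_admin_subcodes",
}


def load_registry(
    config: Union[Mapping, str, Path, None] = None,
) -> CodeRegistry:
    """Build a :class:`CodeRegistry` from a configuration mapping or YAML file.

    ``config`` may be a mapping (possibly under a top-level ``codes:`` key),
    a path to a YAML document, or None.  Categories absent from the config
    fall back to the packaged defaults; registry invariants are re-checked,
    so e.g. an abdominal code missing from ``ep_diagnosis`` raises
    :class:`RegistryConsistencyError`.
    """
    if config is None:
        return default_registry()
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if doc is None:
            return default_registry()
        if not isinstance(doc, Mapping):
            raise RegistryConsistencyError(
                f"malformed code-list document: expected a mapping, got {type(doc).__name__}"
            )
        config = doc
    if "codes" in config and isinstance(config["codes"], Mapping):
        body = dict(config["codes"])
    else:
        body = dict(config)
    prefix = bool(body.pop("prefix_match", config.get("prefix_match", False)))

    unknown = set(body) - set(_CATEGORY_KEYS) - {"prefix_match"}
    if unknown:
        raise RegistryConsistencyError(f"unknown code categories: {sorted(unknown)}")

    base = default_registry()
    kwargs: dict = {"prefix_match": prefix}
    for key, attr in _CATEGORY_KEYS.items():
        if key in body and body[key] is not None:
            vals = body[key]
            if isinstance(vals, str):
                vals = [vals]
            kwargs[attr] = _normset(vals)
        else:
            kwargs[attr] = getattr(base, attr)
    # If the user supplied diagnosis codes but not the special subsets, keep
    # only the default special codes that are actually present.
    if "ep_diagnosis" in body:
        dx = kwargs["ep_diagnosis_codes"]
        if "specific_tubal" not in body:
            kwargs["specific_tubal_codes"] = kwargs["specific_tubal_codes"] & dx
        if "abdominal" not in body:
            kwargs["abdominal_codes"] = kwargs["abdominal_codes"] & dx
    return CodeRegistry(**kwargs)


def save_registry(registry: CodeRegistry, path: Union[str, Path]) -> None:
    """Write a registry to a YAML code-list document (round-trips with load)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"codes": registry.to_config()}, fh, sort_keys=True)
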