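"""Declarative diagnostic criteria sets and symptom-to-item mapping.

Four proposed rule sets for persistent impairing grief share a common
skeleton: one or more *core* symptoms (yearning/longing, preoccupation
with the deceased), a *k-of-m* count of associated symptoms, grief-related
functional impairment, and a minimum time since the death. They differ
mainly in restrictiveness:

===========  =================================
criteria     associated symptoms required
===========  =================================
PCBD         6 of 12  (DSM-5 Section III)
PGD_PLOS     5 of 9   (Prigerson et al.)
CG           2 of 8   (complicated grief)
ICD11_PGD    1 of 7   (WHO ICD-11 guideline)
===========  =================================

A symptom is *present* when at least one of its mapped CGQ items is
endorsed "often" or "very often" (code >= 3 on the 0-4 scale).

The shipped symptom-to-item mapping is a **reconstruction**: the published
item-matching tables are not reproduced here, so the default mapping is
built to be consistent with the k-of-m structure and with the observed
nesting of the four sets — coarser criteria define broader symptom
categories whose item sets union the items of the finer-grained symptoms
they subsume. Every mapping is fully configurable through the JSON config
(see :func:`load_criteria`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .instruments import CGQ_BANK, RespondentRecord

__all__ = [
    "SymptomSpec",
    "CriteriaSet",
    "EndorsementRule",
    "CriteriaValidationError",
    "load_criteria",
    "loads_criteria",
    "dump_criteria",
    "default_criteria",
    "symptom_present",
    "with_min_associated",
    "DEFAULT_CRITERIA_PATH",
]

DEFAULT_CRITERIA_PATH = Path(__file__).parent / "data" / "default_criteria.json"


class CriteriaValidationError(ValueError):
    """Raised when a criteria config violates the schema; message names the path."""


@dataclass(frozen=True)
class EndorsementRule:
    """Ordinal cutoff above which a CGQ item endorses its symptom (default 3 = 'often')."""

    endorsement_cutoff: int = 3

    def __post_init__(self):
        if not CGQ_BANK.in_range(self.endorsement_cutoff):
            raise CriteriaValidationError(
                f"endorsement_cutoff {self.endorsement_cutoff} outside CGQ code "
                f"range [{CGQ_BANK.min_code}, {CGQ_BANK.max_code}]"
            )


@dataclass(frozen=True)
class SymptomSpec:
    """An abstract symptom and the CGQ items that may endorse it."""

    symptom_id: str
    role: str  # "core" | "associated"
    mapped_items: frozenset[str]

    def __post_init__(self):
        if self.role not in ("core", "associated"):
            raise CriteriaValidationError(
                f"symptom {self.symptom_id}: role must be 'core' or 'associated', "
                f"got {self.role!r}"
            )
        if not self.mapped_items:
            raise CriteriaValidationError(
                f"symptom {self.symptom_id}: mapped_items must be non-empty"
            )
        unknown = set(self.mapped_items) - set(CGQ_BANK.item_ids)
        if unknown:
            raise CriteriaValidationError(
                f"symptom {self.symptom_id}: unknown CGQ items {sorted(unknown)}"
            )


@dataclass(frozen=True)
class CriteriaSet:
    """One rule-based diagnostic criteria set.

    Diagnosis requires, conjointly: at least ``min_core`` core symptoms,
    at least ``min_associated`` of the ``m`` associated symptoms,
    grief-related impairment (when ``require_impairment``), and strictly
    more than ``min_months_since_death`` months since the death.
    """

    name: str
    core_symptoms: tuple[SymptomSpec, ...]
    associated_symptoms: tuple[SymptomSpec, ...]
    min_associated: int
    min_core: int = 1
    require_impairment: bool = True
    min_months_since_death: float = 12.0

    def __post_init__(self):
        if not self.core_symptoms:
            raise CriteriaValidationError(f"{self.name}: core_symptoms empty")
        if not 1 <= self.min_core <= len(self.core_symptoms):
            raise CriteriaValidationError(
                f"{self.name}: min_core {self.min_core} outside "
                f"[1, {len(self.core_symptoms)}]"
            )
        if not 0 <= self.min_associated <= len(self.associated_symptoms):
            raise CriteriaValidationError(
                f"{self.name}: min_associated {self.min_associated} outside "
                f"[0, {len(self.associated_symptoms)}]"
            )
        for spec in self.core_symptoms:
            if spec.role != "core":
                raise CriteriaValidationError(
                    f"{self.name}: {spec.symptom_id} listed as core but role={spec.role}"
                )
        for spec in self.associated_symptoms:
            if spec.role != "associated":
                raise CriteriaValidationError(
                    f"{self.name}: {spec.symptom_id} listed as associated "
                    f"but role={spec.role}"
                )

    @property
    def m(self) -> int:
        """Size of the associated-symptom pool."""
        return len(self.associated_symptoms)


def with_min_associated(cs: CriteriaSet, k: int) -> CriteriaSet:
    """Copy of ``cs`` requiring ``k`` associated symptoms (restrictiveness override)."""
    if not 0 <= k <= cs.m:
        raise CriteriaValidationError(
            f"{cs.name}: min_associated override {k} outside [0, {cs.m}]"
        )
    return replace(cs, min_associated=k)


def symptom_present(
    record: RespondentRecord,
    spec: SymptomSpec,
    rule: EndorsementRule = EndorsementRule(),
) -> Optional[bool]:
    """True if any mapped item is endorsed at/above cutoff; None if unknowable.

    Endorsement dominates missingness: one endorsed item makes the symptom
    present regardless of other missing items. The symptom is *absent*
    (False) when at least one mapped item is answered below cutoff and
    none is endorsed; it is *missing* (None) only when every mapped item
    is unanswered.
    """
    any_observed = False
    for item in spec.mapped_items:
        code = record.cgq.get(item)
        if code is None:
            continue
        any_observed = True
        if code >= rule.endorsement_cutoff:
            return True
    return False if any_observed else None


# ---------------------------------------------------------------------------
# JSON config


def _symptom_from_dict(obj, role: str, path: str) -> SymptomSpec:
    if not isinstance(obj, Mapping):
        raise CriteriaValidationError(f"{path}: expected object, got {type(obj).__name__}")
    try:
        symptom_id = obj["symptom_id"]
        items = obj["mapped_items"]
    except KeyError as exc:
        raise CriteriaValidationError(f"{path}: missing key {exc.args[0]!r}") from None
    if not isinstance(items, (list, tuple)) or not all(isinstance(i, str) for i in items):
        raise CriteriaValidationError(f"{path}.mapped_items: expected list of item ids")
    try:
        return SymptomSpec(str(symptom_id), role, frozenset(items))
    except CriteriaValidationError as exc:
        raise CriteriaValidationError(f"{path}: {exc}") from None


def _criteria_from_dict(obj, path: str) -> CriteriaSet:
    if not isinstance(obj, Mapping):
        raise CriteriaValidationError(f"{path}: expected object")
    for key in ("name", "core_symptoms", "associated_symptoms", "min_associated"):
        if key not in obj:
            raise CriteriaValidationError(f"{path}: missing key {key!r}")
    name = str(obj["name"])
    core = tuple(
        _symptom_from_dict(s, "core", f"{path}.core_symptoms[{i}]")
        for i, s in enumerate(obj["core_symptoms"])
    )
    assoc = tuple(
        _symptom_from_dict(s, "associated", f"{path}.associated_symptoms[{i}]")
        for i, s in enumerate(obj["associated_symptoms"])
    )
    try:
        return CriteriaSet(
            name=name,
            core_symptoms=core,
            associated_symptoms=assoc,
            min_associated=int(obj["min_associated"]),
            min_core=int(obj.get("min_core", 1)),
            require_impairment=bool(obj.get("require_impairment", True)),
            min_months_since_death=float(obj.get("min_months_since_death", 12.0)),
        )
    except CriteriaValidationError as exc:
        raise CriteriaValidationError(f"{path}: {exc}") from None


def loads_criteria(document: Mapping | str) -> list[CriteriaSet]:
    """Parse a criteria config (JSON string or already-parsed mapping)."""
    if isinstance(document, str):
        document = json.loads(document)
    if not isinstance(document, Mapping) or "criteria_sets" not in document:
        raise CriteriaValidationError("document: missing key 'criteria_sets'")
    sets = [
        _criteria_from_dict(cs, f"criteria_sets[{i}]")
        for i, cs in enumerate(document["criteria_sets"])
    ]
    if not sets:
        raise CriteriaValidationError("criteria_sets: must be non-empty")
    names = [cs.name for cs in sets]
    if len(set(names)) != len(names):
        raise CriteriaValidationError(f"criteria_sets: duplicate names in {names}")
    return sets


def load_criteria(path=DEFAULT_CRITERIA_PATH) -> list[CriteriaSet]:
    """Load criteria sets from a JSON config file (defaults to the shipped sets)."""
    with open(path) as handle:
        return loads_criteria(json.load(handle))


def _symptom_to_dict(spec: SymptomSpec) -> dict:
    return {"symptom_id": spec.symptom_id, "mapped_items": sorted(spec.mapped_items)}


def dump_criteria(sets: Sequence[CriteriaSet]) -> dict:
    """Serialize criteria sets to the JSON-config structure (round-trips)."""
    return {
        "criteria_sets": [
            {
                "name": cs.name,
                "min_core": cs.min_core,
                "min_associated": cs.min_associated,
                "require_impairment": cs.require_impairment,
                "min_months_since_death": cs.min_months_since_death,
                "core_symptoms": [_symptom_to_dict(s) for s in cs.core_symptoms],
                "associated_symptoms": [_symptom_to_dict(s) for s in cs.associated_symptoms],
            }
            for cs in sets
        ]
    }


def default_criteria() -> list[CriteriaSet]:
    """The four shipped criteria sets (reconstructed default mapping)."""
    return load_criteria(DEFAULT_CRITERIA_PATH)
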