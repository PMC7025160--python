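"""Apply criteria sets to respondents and cohorts.

A diagnosis is the conjunction of four clauses — core symptoms, k-of-m
associated symptoms, impairment at least weekly, duration strictly more
than the minimum months since death. Missing item responses never raise:
a symptom whose mapped items are all unanswered is *unknown*, and a
respondent is flagged ``data_sufficient=False`` when (and only when) the
observed responses leave the diagnosis undecidable — i.e. the observed
data fail some clause, but a completion of the missing responses could
satisfy all clauses. A respondent whose observed endorsements already meet
every clause is diagnosed regardless of other missing items.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .criteria import CriteriaSet, EndorsementRule, symptom_present
from .instruments import IMPAIRMENT_WEEKLY, RespondentRecord

__all__ = ["DiagnosisResult", "diagnose", "diagnose_cohort"]


@dataclass(frozen=True)
class DiagnosisResult:
    """Per-respondent, per-criteria outcome with component breakdown."""

    respondent_id: str
    criteria_name: str
    diagnosed: bool
    core_met: bool
    n_associated_endorsed: int
    impairment_met: bool
    duration_met: bool
    data_sufficient: bool


def diagnose(
    record: RespondentRecord,
    cs: CriteriaSet,
    rule: EndorsementRule = EndorsementRule(),
    impairment_cutoff: int = IMPAIRMENT_WEEKLY,
) -> DiagnosisResult:
    """Evaluate one criteria set on one respondent.

    Missing responses count as not endorsed for the reported components;
    ``data_sufficient`` is False only when filling in the missing
    responses could flip the (negative) diagnosis to positive.
    """
    core_states = [symptom_present(record, s, rule) for s in cs.core_symptoms]
    assoc_states = [symptom_present(record, s, rule) for s in cs.associated_symptoms]

    n_core = sum(1 for s in core_states if s is True)
    n_core_unknown = sum(1 for s in core_states if s is None)
    n_assoc = sum(1 for s in assoc_states if s is True)
    n_assoc_unknown = sum(1 for s in assoc_states if s is None)

    core_met = n_core >= cs.min_core
    impairment_known = record.impairment_frequency is not None
    impairment_met = impairment_known and record.impairment_frequency >= impairment_cutoff
    duration_met = record.months_since_death > cs.min_months_since_death

    impairment_clause = impairment_met or not cs.require_impairment
    diagnosed = core_met and n_assoc >= cs.min_associated and impairment_clause and duration_met

    if diagnosed:
        sufficient = True
    else:
        # could some completion of the unknowns produce a diagnosis?
        could_core = n_core + n_core_unknown >= cs.min_core
        could_assoc = n_assoc + n_assoc_unknown >= cs.min_associated
        could_impair = impairment_clause or (cs.require_impairment and not impairment_known)
        undecidable = could_core and could_assoc and could_impair and duration_met
        sufficient = not undecidable

    return DiagnosisResult(
        respondent_id=record.respondent_id,
        criteria_name=cs.name,
        diagnosed=diagnosed,
        core_met=core_met,
        n_associated_endorsed=n_assoc,
        impairment_met=impairment_met,
        duration_met=duration_met,
        data_sufficient=sufficient,
    )


def diagnose_cohort(
    records: Iterable[RespondentRecord],
    criteria_sets: Sequence[CriteriaSet],
    rule: EndorsementRule = EndorsementRule(),
    impairment_cutoff: int = IMPAIRMENT_WEEKLY,
) -> pd.DataFrame:
    """Long-format diagnosis table: one row per (respondent, criteria set).

    Columns mirror :class:`DiagnosisResult`. Content is order-independent:
    permuting the input records permutes rows but not their values.
    """
    if not criteria_sets:
        raise ValueError("criteria_sets must be non-empty")
    rows = [
        diagnose(record, cs, rule, impairment_cutoff).__dict__
        for record in records
        for cs in criteria_sets
    ]
    columns = [
        "respondent_id",
        "criteria_name",
        "diagnosed",
        "core_met",
        "n_associated_endorsed",
        "impairment_met",
        "duration_met",
        "data_sufficient",
    ]
    return pd.DataFrame(rows, columns=columns)
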