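"""Shared test utilities: record builders, random cohorts, brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np

from griefcriteria import CriteriaSet, EndorsementRule, RespondentRecord, SymptomSpec
from griefcriteria.instruments import BANKS, CGQ_BANK, ICG_BANK, WSAS_BANK


def _responses(bank, value):
    """Expand an int / sequence / dict-of-overrides into a full response map."""
    if value is None:
        value = 0
    if isinstance(value, int):
        return {item: value for item in bank.item_ids}
    if isinstance(value, dict):
        base = {item: 0 for item in bank.item_ids}
        base.update(value)
        return base
    return dict(zip(bank.item_ids, value))


def make_record(cgq=None, icg=None, wsas=None, impairment=4, months=24.0, rid="r1"):
    return RespondentRecord(
        respondent_id=rid,
        cgq=_responses(CGQ_BANK, cgq),
        icg=_responses(ICG_BANK, icg),
        wsas=_responses(WSAS_BANK, wsas),
        impairment_frequency=impairment,
        months_since_death=months,
    )


def record_with_totals(icg_total, wsas_total, **kwargs):
    """Record whose ICG/WSAS totals equal the requested values (greedy fill)."""

    def fill(bank, total):
        remaining = total
        out = {}
        for item in bank.item_ids:
            code = min(remaining, bank.max_code)
            out[item] = code
            remaining -= code
        assert remaining == 0
        return out

    return make_record(icg=fill(ICG_BANK, icg_total), wsas=fill(WSAS_BANK, wsas_total), **kwargs)


def random_cohort(rng, n, missing_prob=0.15, n_items=6):
    """Small random cohort over the first ``n_items`` CGQ items (rest zero)."""
    records = []
    items = CGQ_BANK.item_ids[:n_items]
    for i in range(n):
        cgq = {}
        for item in items:
            cgq[item] = None if rng.random() < missing_prob else int(rng.integers(0, 5))
        impairment = None if rng.random() < missing_prob else int(rng.integers(0, 5))
        months = float(rng.uniform(0, 40))
        records.append(
            make_record(cgq=cgq, impairment=impairment, months=months, rid=f"r{i}")
        )
    return records


def random_small_criteria(rng, n_items=6, name="RAND"):
    """Random criteria set over the first ``n_items`` CGQ items."""
    items = CGQ_BANK.item_ids[:n_items]

    def symptom(role, j):
        size = int(rng.integers(1, 3))
        mapped = rng.choice(items, size=size, replace=False)
        return SymptomSpec(f"{role}_{j}", role, frozenset(str(i) for i in mapped))

    n_core = int(rng.integers(1, 3))
    m = int(rng.integers(2, 5))
    core = tuple(symptom("core", j) for j in range(n_core))
    assoc = tuple(symptom("associated", j) for j in range(m))
    return CriteriaSet(
        name=name,
        core_symptoms=core,
        associated_symptoms=assoc,
        min_associated=int(rng.integers(0, m + 1)),
        min_core=int(rng.integers(1, n_core + 1)),
        require_impairment=bool(rng.integers(0, 2)),
        min_months_since_death=12.0,
    )


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_symptom_state(record, spec, cutoff):
    observed = [
        record.cgq[item] for item in spec.mapped_items if record.cgq[item] is not None
    ]
    if any(code >= cutoff for code in observed):
        return True
    return False if observed else None


def oracle_diagnose(record, cs, rule=EndorsementRule(), impairment_cutoff=3):
    """Truth-table evaluation of the criteria logic.

    Computes the diagnosis with unknown symptoms treated as absent, then
    enumerates every truth assignment of the unknown symptoms (and every
    possible impairment code if unanswered) to decide whether the negative
    outcome is decidable from the observed data.
    """
    core_states = [oracle_symptom_state(record, s, rule.endorsement_cutoff) for s in cs.core_symptoms]
    assoc_states = [oracle_symptom_state(record, s, rule.endorsement_cutoff) for s in cs.associated_symptoms]

    def decide(core, assoc, imp_code):
        core_ok = sum(core) >= cs.min_core
        assoc_ok = sum(assoc) >= cs.min_associated
        imp_ok = (imp_code is not None and imp_code >= impairment_cutoff) or not cs.require_impairment
        return core_ok and assoc_ok and imp_ok and record.months_since_death > cs.min_months_since_death

    observed_core = [bool(s) for s in core_states]
    observed_assoc = [bool(s) for s in assoc_states]
    diagnosed = decide(observed_core, observed_assoc, record.impairment_frequency)

    if diagnosed:
        sufficient = True
    else:
        core_unknown = [i for i, s in enumerate(core_states) if s is None]
        assoc_unknown = [i for i, s in enumerate(assoc_states) if s is None]
        imp_options = (
            range(5) if record.impairment_frequency is None else [record.impairment_frequency]
        )
        possible = False
        for core_fill in itertools.product([False, True], repeat=len(core_unknown)):
            for assoc_fill in itertools.product([False, True], repeat=len(assoc_unknown)):
                core = list(observed_core)
                for i, v in zip(core_unknown, core_fill):
                    core[i] = v
                assoc = list(observed_assoc)
                for i, v in zip(assoc_unknown, assoc_fill):
                    assoc[i] = v
                if any(decide(core, assoc, imp) for imp in imp_options):
                    possible = True
                    break
            if possible:
                break
        sufficient = not possible
    n_assoc = sum(observed_assoc)
    return diagnosed, sufficient, n_assoc
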