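"""Questionnaire definitions, scoring, and caseness thresholds.

Three self-report instruments drive the analysis:

* **CGQ** — Complicated Grief Questionnaire, 26 items rated on a 0-4
  frequency Likert scale (never / rarely / sometimes / often / very often).
  Symptom endorsements for the diagnostic criteria sets are read from it.
* **ICG** — Inventory of Complicated Grief, 19 items (0-4), total 0-76.
  A total of >= 30 is the conventional threshold for clinically
  significant grief severity.
* **WSAS** — Work and Social Adjustment Scale, 5 items (0-8), total 0-40.
  A total of >= 20 indicates moderate-to-severe functional impairment.

Clinical *caseness* is the multidimensional rule ICG >= 30 AND WSAS >= 20;
respondents below it are *subthreshold*. Scoring is complete-case: a
respondent missing any item on an instrument contributes no total for that
instrument and is *indeterminate* for any rule needing that total.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemBank",
    "CGQ_BANK",
    "ICG_BANK",
    "WSAS_BANK",
    "BANKS",
    "IMPAIRMENT_ANCHORS",
    "RespondentRecord",
    "CasenessRule",
    "RecordValidationError",
    "ConfigurationError",
    "score_total",
    "classify_caseness",
    "caseness_grid",
    "validate_record",
    "read_cohort",
    "write_cohort",
    "score_cohort",
]


class ConfigurationError(ValueError):
    """Raised for invalid instrument/rule configuration (unknown labels, bad cutoffs)."""


class RecordValidationError(ValueError):
    """Raised when a raw row cannot become a :class:`RespondentRecord`.

    Attributes
    ----------
    errors : list of str
        One message per offending field, each naming the field.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class ItemBank:
    """An instrument's item roster and admissible response codes."""

    instrument_name: str
    item_ids: tuple[str, ...]
    min_code: int
    max_code: int
    anchors: tuple[str, ...] = ()

    def __post_init__(self):
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ConfigurationError(f"{self.instrument_name}: duplicate item ids")
        if self.anchors and len(self.anchors) != self.max_code - self.min_code + 1:
            raise ConfigurationError(
                f"{self.instrument_name}: {len(self.anchors)} anchors for "
                f"codes {self.min_code}..{self.max_code}"
            )

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def max_total(self) -> int:
        return self.n_items * self.max_code

    def in_range(self, code: int) -> bool:
        return self.min_code <= code <= self.max_code


LIKERT_ANCHORS = ("never", "rarely", "sometimes", "often", "very often")

CGQ_BANK = ItemBank(
    "CGQ", tuple(f"cgq_{i:02d}" for i in range(1, 27)), 0, 4, LIKERT_ANCHORS
)
ICG_BANK = ItemBank("ICG", tuple(f"icg_{i:02d}" for i in range(1, 20)), 0, 4)
WSAS_BANK = ItemBank("WSAS", tuple(f"wsas_{i:02d}" for i in range(1, 6)), 0, 8)

BANKS: dict[str, ItemBank] = {"CGQ": CGQ_BANK, "ICG": ICG_BANK, "WSAS": WSAS_BANK}

#: Frequency anchors for the impairment probe ("how often have you had grief
#: reactions at a level that interfere with your life?"). "weekly" = code 3.
IMPAIRMENT_ANCHORS = ("never", "less than monthly", "monthly", "weekly", "daily")
IMPAIRMENT_WEEKLY = 3

MONTHS_COLUMN = "months_since_death"
IMPAIRMENT_COLUMN = "impairment_frequency"
ID_COLUMN = "respondent_id"


@dataclass(frozen=True)
class RespondentRecord:
    """One bereaved respondent's item responses.

    Response mappings are keyed by item identifier; a value of ``None``
    means the item was not answered. ``impairment_frequency`` is the
    separate frequency-worded probe (0=never .. 4=daily), distinct from
    the CGQ intensity items.
    """

    respondent_id: str
    cgq: Mapping[str, Optional[int]]
    icg: Mapping[str, Optional[int]]
    wsas: Mapping[str, Optional[int]]
    impairment_frequency: Optional[int]
    months_since_death: float

    def responses(self, instrument: str) -> Mapping[str, Optional[int]]:
        try:
            return {"CGQ": self.cgq, "ICG": self.icg, "WSAS": self.wsas}[instrument]
        except KeyError:
            raise ConfigurationError(f"unknown instrument {instrument!r}") from None


@dataclass(frozen=True)
class CasenessRule:
    """Multidimensional clinical threshold: ICG total and WSAS total cutoffs."""

    icg_cutoff: int = 30
    wsas_cutoff: int = 20

    def __post_init__(self):
        if not 0 <= self.icg_cutoff <= ICG_BANK.max_total:
            raise ConfigurationError(
                f"icg_cutoff {self.icg_cutoff} outside [0, {ICG_BANK.max_total}]"
            )
        if not 0 <= self.wsas_cutoff <= WSAS_BANK.max_total:
            raise ConfigurationError(
                f"wsas_cutoff {self.wsas_cutoff} outside [0, {WSAS_BANK.max_total}]"
            )


# ---------------------------------------------------------------------------
# scoring


def score_total(record: RespondentRecord, instrument: str) -> Optional[int]:
    """Summed total score, or ``None`` if any item is missing (complete-case)."""
    if instrument not in ("ICG", "WSAS"):
        raise ConfigurationError(
            f"score_total expects 'ICG' or 'WSAS', got {instrument!r}"
        )
    bank = BANKS[instrument]
    responses = record.responses(instrument)
    total = 0
    for item in bank.item_ids:
        code = responses.get(item)
        if code is None:
            return None
        total += code
    return total


def classify_caseness(
    record: RespondentRecord, rule: CasenessRule = CasenessRule()
) -> str:
    """``"case"``, ``"subthreshold"``, or ``"indeterminate"`` (missing total)."""
    icg = score_total(record, "ICG")
    wsas = score_total(record, "WSAS")
    if icg is None or wsas is None:
        return "indeterminate"
    if icg >= rule.icg_cutoff and wsas >= rule.wsas_cutoff:
        return "case"
    return "subthreshold"


def caseness_grid(
    records: Iterable[RespondentRecord],
    icg_cutoffs: Sequence[int] = (20, 25, 30),
    wsas_cutoffs: Sequence[int] = (15, 20),
) -> pd.DataFrame:
    """Case counts over a grid of (ICG cutoff, WSAS cutoff) combinations.

    Returns one row per grid cell with columns ``icg_cutoff``,
    ``wsas_cutoff``, ``n_cases``, ``n_subthreshold``, ``n_indeterminate``.
    Counts are monotonically non-increasing in each cutoff.
    """
    if not icg_cutoffs or not wsas_cutoffs:
        raise ConfigurationError("cutoff lists must be non-empty")
    records = list(records)
    totals = [(score_total(r, "ICG"), score_total(r, "WSAS")) for r in records]
    rows = []
    for ic in icg_cutoffs:
        for wc in wsas_cutoffs:
            rule = CasenessRule(ic, wc)
            n_case = n_sub = n_ind = 0
            for icg, wsas in totals:
                if icg is None or wsas is None:
                    n_ind += 1
                elif icg >= rule.icg_cutoff and wsas >= rule.wsas_cutoff:
                    n_case += 1
                else:
                    n_sub += 1
            rows.append(
                {
                    "icg_cutoff": ic,
                    "wsas_cutoff": wc,
                    "n_cases": n_case,
                    "n_subthreshold": n_sub,
                    "n_indeterminate": n_ind,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation and I/O


def _parse_code(raw, bank: ItemBank, item: str, errors: list[str]) -> Optional[int]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    try:
        code = int(raw)
    except (TypeError, ValueError):
        errors.append(f"{item}: non-integer response {raw!r}")
        return None
    if not bank.in_range(code):
        errors.append(
            f"{item}: code {code} outside [{bank.min_code}, {bank.max_code}]"
        )
        return None
    return code


def validate_record(row: Mapping[str, object]) -> RespondentRecord:
    """Build a validated :class:`RespondentRecord` from a raw mapping.

    Empty/NaN cells become missing responses. Out-of-range or non-numeric
    codes raise :class:`RecordValidationError` naming every offending field.
    """
    errors: list[str] = []
    responses: dict[str, dict[str, Optional[int]]] = {}
    for name, bank in BANKS.items():
        responses[name] = {
            item: _parse_code(row.get(item), bank, item, errors)
            for item in bank.item_ids
        }

    imp_raw = row.get(IMPAIRMENT_COLUMN)
    impairment: Optional[int]
    if imp_raw is None or (isinstance(imp_raw, float) and np.isnan(imp_raw)) or imp_raw == "":
        impairment = None
    else:
        try:
            impairment = int(imp_raw)
        except (TypeError, ValueError):
            errors.append(f"{IMPAIRMENT_COLUMN}: non-integer response {imp_raw!r}")
            impairment = None
        else:
            if not 0 <= impairment <= 4:
                errors.append(f"{IMPAIRMENT_COLUMN}: code {impairment} outside [0, 4]")
                impairment = None

    months_raw = row.get(MONTHS_COLUMN)
    months = np.nan
    if months_raw is None or months_raw == "":
        errors.append(f"{MONTHS_COLUMN}: missing")
    else:
        try:
            months = float(months_raw)
        except (TypeError, ValueError):
            errors.append(f"{MONTHS_COLUMN}: non-numeric {months_raw!r}")
        else:
            if not np.isfinite(months) or months < 0:
                errors.append(f"{MONTHS_COLUMN}: must be finite and >= 0, got {months}")

    if errors:
        raise RecordValidationError(errors)

    return RespondentRecord(
        respondent_id=str(row.get(ID_COLUMN, "")),
        cgq=responses["CGQ"],
        icg=responses["ICG"],
        wsas=responses["WSAS"],
        impairment_frequency=impairment,
        months_since_death=months,
    )


def _record_row(record: RespondentRecord) -> dict:
    row: dict = {ID_COLUMN: record.respondent_id}
    for name, bank in BANKS.items():
        responses = record.responses(name)
        for item in bank.item_ids:
            row[item] = responses.get(item)
    row[IMPAIRMENT_COLUMN] = record.impairment_frequency
    row[MONTHS_COLUMN] = record.months_since_death
    return row


def write_cohort(records: Iterable[RespondentRecord], path) -> None:
    """Write a cohort to CSV, one row per respondent, empty cell = missing."""
    frame = pd.DataFrame([_record_row(r) for r in records])
    frame.to_csv(path, index=False)


def read_cohort(path) -> tuple[list[RespondentRecord], pd.DataFrame]:
    """Read a cohort CSV; returns ``(records, rejects)``.

    ``rejects`` is a DataFrame with columns ``respondent_id`` and
    ``reason`` for rows that failed validation.
    """
    frame = pd.read_csv(path, dtype={ID_COLUMN: str})
    records: list[RespondentRecord] = []
    rejects: list[dict] = []
    for _, row in frame.iterrows():
        try:
            records.append(validate_record(row.to_dict()))
        except RecordValidationError as exc:
            rejects.append(
                {ID_COLUMN: row.get(ID_COLUMN, ""), "reason": str(exc)}
            )
    return records, pd.DataFrame(rejects, columns=[ID_COLUMN, "reason"])


def score_cohort(
    records: Iterable[RespondentRecord], rule: CasenessRule = CasenessRule()
) -> pd.DataFrame:
    """Scored-cohort table: totals plus the caseness label per respondent."""
    rows = []
    for r in records:
        rows.append(
            {
                ID_COLUMN: r.respondent_id,
                "icg_total": score_total(r, "ICG"),
                "wsas_total": score_total(r, "WSAS"),
                "caseness": classify_caseness(r, rule),
                MONTHS_COLUMN: r.months_since_death,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[ID_COLUMN, "icg_total", "wsas_total", "caseness", MONTHS_COLUMN],
    )
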