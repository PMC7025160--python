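"""Criteria-performance statistics: conditional probabilities, agreement, nesting, sweep.

Because no population gold standard exists for persistent impairing grief,
performance is framed as conditional probabilities against the
multidimensional clinical threshold (ICG >= 30 and WSAS >= 20), not as
sensitivity/specificity against a true disorder state:

* inclusion% = 100 * P(diagnosed | case)
* exclusion% = 100 * P(not diagnosed | subthreshold)

with Wilson score 95% confidence intervals. Agreement between pairs of
criteria sets is Cohen's kappa on the full sample, banded qualitatively
(poor < 0.20 <= fair < 0.40 <= moderate < 0.60 <= good < 0.80 <= very good).
The 16-cell membership partition over the four sets exposes the nesting
("Russian doll") structure, and the restrictiveness sweep traces
inclusion/exclusion as the required number of associated symptoms k runs
from 0 upward, with the operating point chosen by the Youden index
J = inclusion% + exclusion% - 100 (ties broken toward smaller k).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .classify import diagnose_cohort
from .criteria import CriteriaSet, EndorsementRule, with_min_associated
from .instruments import RespondentRecord

__all__ = [
    "PerformanceRow",
    "AgreementResult",
    "VennPartition",
    "SweepPoint",
    "kappa_band",
    "performance",
    "cohens_kappa",
    "pairwise_agreement_matrix",
    "venn_partition",
    "restrictiveness_sweep",
    "select_optimum",
    "plot_sweep",
]

logger = logging.getLogger(__name__)

KAPPA_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (math.inf, "very good"),
)


def kappa_band(kappa: float) -> str:
    """Qualitative agreement band for a kappa value.

    Boundaries: poor < 0.20; fair [0.20, 0.40); moderate [0.40, 0.60);
    good [0.60, 0.80); very good [0.80, 1.00].
    """
    for upper, name in KAPPA_BANDS:
        if kappa < upper:
            return name
    return "very good"


@dataclass(frozen=True)
class PerformanceRow:
    """Inclusion/exclusion percentages with Wilson 95% CIs for one criteria set."""

    criteria_name: str
    n_cases: int
    n_subthreshold: int
    pct_cases_included: float
    inclusion_ci_low: float
    inclusion_ci_high: float
    pct_subthreshold_excluded: float
    exclusion_ci_low: float
    exclusion_ci_high: float
    defined: bool = True


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa between two criteria sets' diagnoses."""

    pair: tuple[str, str]
    kappa: float
    band: str
    n: int
    defined: bool = True


@dataclass(frozen=True)
class VennPartition:
    """Counts over the 16 membership patterns of four criteria sets.

    ``cell_counts`` maps a tuple of booleans (ordered as ``names``) to the
    number of respondents with exactly that diagnosis pattern; respondents
    lacking a decidable diagnosis under any of the four sets are excluded
    and tallied in ``n_excluded``.
    """

    names: tuple[str, str, str, str]
    cell_counts: Mapping[tuple[bool, bool, bool, bool], int]
    n_total: int
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {**{name: member for name, member in zip(self.names, pattern)}, "count": count}
            for pattern, count in sorted(self.cell_counts.items())
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepPoint:
    """Performance of one criteria set at one required-associated-symptom count k."""

    criteria_name: str
    k: int
    pct_cases_included: float
    pct_subthreshold_excluded: float


# ---------------------------------------------------------------------------
# conditional performance


def _wilson(count: int, nobs: int) -> tuple[float, float, float]:
    pct = 100.0 * count / nobs
    low, high = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return pct, 100.0 * low, 100.0 * high


def performance(
    diagnoses: pd.DataFrame, caseness: Mapping[str, str]
) -> list[PerformanceRow]:
    """Inclusion/exclusion probabilities per criteria set.

    Parameters
    ----------
    diagnoses
        Long-format table from :func:`griefcriteria.classify.diagnose_cohort`.
    caseness
        Map respondent_id -> "case" | "subthreshold" | "indeterminate".
        Indeterminate respondents are excluded; respondents with
        insufficient data for a criteria set are excluded from that set's
        row. Each row records its analyzed denominators.
    """
    rows: list[PerformanceRow] = []
    for name, sub in diagnoses.groupby("criteria_name", sort=False):
        usable = sub[sub["data_sufficient"]]
        labels = usable["respondent_id"].map(lambda rid: caseness.get(rid, "indeterminate"))
        case_mask = labels == "case"
        sub_mask = labels == "subthreshold"
        n_cases = int(case_mask.sum())
        n_sub = int(sub_mask.sum())
        if n_cases == 0 or n_sub == 0:
            rows.append(
                PerformanceRow(name, n_cases, n_sub, math.nan, math.nan, math.nan,
                               math.nan, math.nan, math.nan, defined=False)
            )
            continue
        n_included = int(usable.loc[case_mask, "diagnosed"].sum())
        n_excluded = int((~usable.loc[sub_mask, "diagnosed"]).sum())
        inc, inc_lo, inc_hi = _wilson(n_included, n_cases)
        exc, exc_lo, exc_hi = _wilson(n_excluded, n_sub)
        rows.append(
            PerformanceRow(name, n_cases, n_sub, inc, inc_lo, inc_hi, exc, exc_lo, exc_hi)
        )
    return rows


# ---------------------------------------------------------------------------
# agreement


def cohens_kappa(labels_a: Sequence[bool], labels_b: Sequence[bool]) -> AgreementResult:
    """Cohen's kappa between two paired binary classifications.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    product of the marginals. When both raters agree perfectly on a
    constant vector (p_o = p_e = 1) the limit kappa = 1 is returned; an
    empty input yields an undefined result (``defined=False``).
    """
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"paired labels differ in length: {a.shape} vs {b.shape}")
    n = a.size
    if n == 0:
        return AgreementResult(("a", "b"), math.nan, "undefined", 0, defined=False)
    p_o = float(np.mean(a == b))
    pa, pb = float(a.mean()), float(b.mean())
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        kappa = 1.0 if p_o == 1.0 else -1.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return AgreementResult(("a", "b"), kappa, kappa_band(kappa), n)


def _diagnosis_pivot(diagnoses: pd.DataFrame) -> pd.DataFrame:
    """Wide respondent x criteria table of diagnoses, restricted to rows decidable everywhere."""
    usable = diagnoses[diagnoses["data_sufficient"]]
    wide = usable.pivot(index="respondent_id", columns="criteria_name", values="diagnosed")
    return wide.dropna().astype(bool)


def pairwise_agreement_matrix(diagnoses: pd.DataFrame) -> list[AgreementResult]:
    """Kappa for every unordered pair of criteria sets, on the full decidable sample."""
    wide = _diagnosis_pivot(diagnoses)
    names = list(wide.columns)
    if len(names) < 2:
        raise ValueError("need at least two criteria sets for pairwise agreement")
    results = []
    for a, b in itertools.combinations(names, 2):
        res = cohens_kappa(wide[a].to_numpy(), wide[b].to_numpy())
        results.append(AgreementResult((a, b), res.kappa, res.band, res.n, res.defined))
    return results


def venn_partition(diagnoses: pd.DataFrame, names: Optional[Sequence[str]] = None) -> VennPartition:
    """Partition respondents into the 16 membership cells of four criteria sets."""
    wide = _diagnosis_pivot(diagnoses)
    if names is None:
        names = list(dict.fromkeys(diagnoses["criteria_name"]))
    if len(names) != 4:
        raise ValueError(f"venn_partition expects exactly 4 criteria sets, got {list(names)}")
    wide = wide[list(names)]
    n_all_ids = diagnoses["respondent_id"].nunique()
    counts = {pattern: 0 for pattern in itertools.product([False, True], repeat=4)}
    for pattern, group in wide.groupby(list(names), sort=False):
        counts[tuple(bool(x) for x in pattern)] = len(group)
    n_total = len(wide)
    return VennPartition(tuple(names), counts, n_total, n_all_ids - n_total)


# ---------------------------------------------------------------------------
# restrictiveness sweep


def restrictiveness_sweep(
    records: Iterable[RespondentRecord],
    criteria_sets: Sequence[CriteriaSet],
    caseness: Mapping[str, str],
    k_range: Sequence[int] = range(0, 7),
    rule: EndorsementRule = EndorsementRule(),
) -> list[SweepPoint]:
    """Inclusion/exclusion per criteria set as required associated symptoms vary.

    Points where k exceeds a set's pool size m are omitted (logged).
    """
    records = list(records)
    points: list[SweepPoint] = []
    for cs in criteria_sets:
        for k in k_range:
            if k > cs.m:
                logger.info("sweep: skipping %s at k=%d (pool m=%d)", cs.name, k, cs.m)
                continue
            variant = with_min_associated(cs, k)
            diag = diagnose_cohort(records, [variant], rule)
            rows = performance(diag, caseness)
            row = rows[0]
            if not row.defined:
                logger.info("sweep: %s at k=%d undefined (no cases or no subthreshold)", cs.name, k)
                points.append(SweepPoint(cs.name, k, math.nan, math.nan))
                continue
            points.append(
                SweepPoint(cs.name, k, row.pct_cases_included, row.pct_subthreshold_excluded)
            )
    return points


def select_optimum(points: Sequence[SweepPoint]) -> tuple[str, int]:
    """Operating point maximizing Youden J = inclusion% + exclusion% - 100.

    Exact ties are broken toward smaller k (less restrictive criteria
    preferred at equal accuracy); NaN points are ignored.
    """
    if not points:
        raise ValueError("select_optimum requires at least one sweep point")
    best: Optional[SweepPoint] = None
    best_j = -math.inf
    for p in sorted(points, key=lambda p: (p.k, p.criteria_name)):
        if math.isnan(p.pct_cases_included) or math.isnan(p.pct_subthreshold_excluded):
            continue
        j = p.pct_cases_included + p.pct_subthreshold_excluded - 100.0
        if j > best_j:
            best, best_j = p, j
    if best is None:
        raise ValueError("all sweep points undefined")
    return best.criteria_name, best.k


def plot_sweep(points: Sequence[SweepPoint], path) -> None:
    """Summary ROC-style plot: one curve per criteria set over k, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    frame = pd.DataFrame([p.__dict__ for p in points])
    for name, sub in frame.groupby("criteria_name", sort=False):
        sub = sub.sort_values("k")
        ax.plot(
            100.0 - sub["pct_subthreshold_excluded"],
            sub["pct_cases_included"],
            marker="o",
            label=name,
        )
        for _, row in sub.iterrows():
            ax.annotate(
                str(int(row["k"])),
                (100.0 - row["pct_subthreshold_excluded"], row["pct_cases_included"]),
                textcoords="offset points",
                xytext=(4, 4),
                fontsize=8,
            )
    ax.set_xlabel("100 − subthreshold excluded (%)")
    ax.set_ylabel("cases included (%)")
    ax.set_xlim(-2, 102)
    ax.set_ylim(-2, 102)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
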