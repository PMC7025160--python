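import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import cohen_kappa_score

from griefcriteria import (
    cohens_kappa,
    diagnose_cohort,
    kappa_band,
    pairwise_agreement_matrix,
    performance,
    restrictiveness_sweep,
    score_cohort,
    select_optimum,
    venn_partition,
    with_min_associated,
)
from griefcriteria.compare import SweepPoint

from helpers import make_record, random_cohort


def diagnoses_frame(diagnosed_by_name, sufficient=True):
    """Long-format diagnosis table from {criteria: {rid: bool}}."""
    rows = []
    for name, by_rid in diagnosed_by_name.items():
        for rid, diag in by_rid.items():
            rows.append(
                {
                    "respondent_id": rid,
                    "criteria_name": name,
                    "diagnosed": diag,
                    "data_sufficient": sufficient,
                }
            )
    return pd.DataFrame(rows)


class TestPerformance:
    def test_diagnose_everyone(self):
        labels = {f"r{i}": "case" if i < 4 else "subthreshold" for i in range(10)}
        diag = diagnoses_frame({"ALL": {rid: True for rid in labels}})
        row = performance(diag, labels)[0]
        assert row.pct_cases_included == 100.0
        assert row.pct_subthreshold_excluded == 0.0

    def test_oracle_criteria(self):
        labels = {f"r{i}": "case" if i % 3 == 0 else "subthreshold" for i in range(30)}
        diag = diagnoses_frame({"ORACLE": {rid: lab == "case" for rid, lab in labels.items()}})
        row = performance(diag, labels)[0]
        assert (row.pct_cases_included, row.pct_subthreshold_excluded) == (100.0, 100.0)

    def test_wilson_interval_closed_form(self):
        # 8 of 10 cases included: check against the Wilson formula directly
        labels = {f"c{i}": "case" for i in range(10)}
        labels.update({f"s{i}": "subthreshold" for i in range(5)})
        diagnosed = {f"c{i}": i < 8 for i in range(10)}
        diagnosed.update({f"s{i}": False for i in range(5)})
        row = performance(diagnoses_frame({"X": diagnosed}), labels)[0]
        assert row.pct_cases_included == pytest.approx(80.0)
        z = 1.959963984540054
        p, n = 0.8, 10
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (z / (1 + z**2 / n)) * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
        assert row.inclusion_ci_low == pytest.approx(100 * (centre - half), abs=1e-9)
        assert row.inclusion_ci_high == pytest.approx(100 * (centre + half), abs=1e-9)
        assert row.inclusion_ci_low <= row.pct_cases_included <= row.inclusion_ci_high

    def test_no_cases_flagged_undefined(self):
        labels = {"a": "subthreshold", "b": "subthreshold"}
        row = performance(diagnoses_frame({"X": {"a": False, "b": True}}), labels)[0]
        assert not row.defined and math.isnan(row.pct_cases_included)

    def test_interval_shrinks_with_n(self):
        def width(n):
            labels = {f"c{i}": "case" for i in range(n)}
            labels["s0"] = "subthreshold"
            diagnosed = {rid: i < int(0.8 * n) for i, rid in enumerate(labels)}
            row = performance(diagnoses_frame({"X": diagnosed}), labels)[0]
            return row.inclusion_ci_high - row.inclusion_ci_low

        assert width(400) < width(100) < width(25)

    def test_insufficient_rows_excluded_from_denominator(self):
        labels = {"a": "case", "b": "case"}
        diag = pd.concat(
            [
                diagnoses_frame({"X": {"a": True}}),
                diagnoses_frame({"X": {"b": False}}, sufficient=False),
            ]
        )
        labels["s"] = "subthreshold"
        diag = pd.concat([diag, diagnoses_frame({"X": {"s": False}})])
        row = performance(diag, labels)[0]
        assert row.n_cases == 1 and row.pct_cases_included == 100.0


class TestCohensKappa:
    def test_identical_labels(self):
        labels = [True, False, True, True]
        res = cohens_kappa(labels, labels)
        assert res.kappa == 1.0 and res.band == "very good"

    def test_contingency_table_example(self):
        # table: both+ 45, a+b- 15, a-b+ 25, both- 15 (n=100)
        a = [True] * 60 + [False] * 40
        b = [True] * 45 + [False] * 15 + [True] * 25 + [False] * 15
        expected = (0.60 - 0.54) / (1 - 0.54)  # (p_o - p_e)/(1 - p_e)
        res = cohens_kappa(a, b)
        assert res.kappa == pytest.approx(expected)
        assert res.band == "poor"
        assert res.n == 100

    def test_perfect_disagreement(self):
        a = [True] * 5 + [False] * 5
        assert cohens_kappa(a, [not x for x in a]).kappa == pytest.approx(-1.0)

    def test_empty_undefined(self):
        res = cohens_kappa([], [])
        assert not res.defined

    def test_constant_agreement_limit(self):
        res = cohens_kappa([True, True], [True, True])
        assert res.kappa == 1.0  # p_o = p_e = 1 limit

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=40))
    def test_label_swap_invariance(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        k1 = cohens_kappa(a, b).kappa
        k2 = cohens_kappa([not x for x in a], [not x for x in b]).kappa
        assert k1 == pytest.approx(k2, nan_ok=True)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(50) < 0.4
        b = (rng.random(50) < 0.7) & a | (rng.random(50) < 0.2)
        if a.all() or (~a).all() or b.all() or (~b).all():
            return
        assert cohens_kappa(a, b).kappa == pytest.approx(cohen_kappa_score(a, b))


class TestKappaBands:
    @pytest.mark.parametrize(
        "value,band",
        [
            (-0.3, "poor"),
            (0.19, "poor"),
            (0.20, "fair"),
            (0.39, "fair"),
            (0.40, "moderate"),
            (0.59, "moderate"),
            (0.60, "good"),
            (0.79, "good"),
            (0.80, "very good"),
            (1.00, "very good"),
        ],
    )
    def test_boundaries(self, value, band):
        assert kappa_band(value) == band


class TestVennPartition:
    names = ("A", "B", "C", "D")

    def test_nobody_diagnosed(self):
        diag = diagnoses_frame({n: {f"r{i}": False for i in range(7)} for n in self.names})
        venn = venn_partition(diag, self.names)
        assert venn.cell_counts[(False,) * 4] == 7
        assert sum(venn.cell_counts.values()) == venn.n_total == 7

    def test_nested_criteria_use_only_chain_cells(self):
        # A subset of B subset of C subset of D: only the 5 chain patterns occur
        sizes = {"A": 1, "B": 2, "C": 3, "D": 4}
        diag = diagnoses_frame(
            {n: {f"r{i}": i < sizes[n] for i in range(10)} for n in self.names}
        )
        venn = venn_partition(diag, self.names)
        chain = {
            (False, False, False, False): 6,
            (False, False, False, True): 1,
            (False, False, True, True): 1,
            (False, True, True, True): 1,
            (True, True, True, True): 1,
        }
        assert {p: c for p, c in venn.cell_counts.items() if c} == chain

    def test_insufficient_respondents_tallied(self):
        diag = diagnoses_frame({n: {"r0": True, "r1": False} for n in self.names})
        diag.loc[(diag.respondent_id == "r1") & (diag.criteria_name == "B"), "data_sufficient"] = False
        venn = venn_partition(diag, self.names)
        assert venn.n_total == 1 and venn.n_excluded == 1

    def test_requires_four_sets(self):
        diag = diagnoses_frame({"A": {"r0": True}, "B": {"r0": False}})
        with pytest.raises(ValueError):
            venn_partition(diag, ("A", "B"))


@pytest.fixture(scope="module")
def small_setup(default_sets):
    from griefcriteria import default_config, generate_cohort

    cohort = generate_cohort(default_config(n=150, seed=5))
    scored = score_cohort(cohort)
    caseness = dict(zip(scored.respondent_id, scored.caseness))
    return cohort, default_sets, caseness


class TestSweep:
    def test_monotone_in_k(self, small_setup):
        cohort, sets, caseness = small_setup
        points = restrictiveness_sweep(cohort, sets, caseness)
        frame = pd.DataFrame([p.__dict__ for p in points])
        for _, sub in frame.groupby("criteria_name"):
            sub = sub.sort_values("k")
            assert (sub.pct_cases_included.diff().dropna() <= 1e-9).all()
            assert (sub.pct_subthreshold_excluded.diff().dropna() >= -1e-9).all()

    def test_k0_dominates_inclusion(self, small_setup):
        cohort, sets, caseness = small_setup
        points = restrictiveness_sweep(cohort, sets, caseness)
        frame = pd.DataFrame([p.__dict__ for p in points])
        for _, sub in frame.groupby("criteria_name"):
            k0 = sub.loc[sub.k == 0, "pct_cases_included"].iloc[0]
            assert (sub.pct_cases_included <= k0 + 1e-9).all()

    def test_identical_pools_identical_points(self, small_setup, default_sets):
        cohort, _, caseness = small_setup
        pgd = next(cs for cs in default_sets if cs.name == "PGD_PLOS")
        import dataclasses

        twin = dataclasses.replace(pgd, name="TWIN")
        points = restrictiveness_sweep(cohort, [pgd, twin], caseness)
        by_name = {
            name: sorted((p.k, p.pct_cases_included, p.pct_subthreshold_excluded)
                         for p in points if p.criteria_name == name)
            for name in ("PGD_PLOS", "TWIN")
        }
        assert by_name["PGD_PLOS"] == by_name["TWIN"]

    def test_k_beyond_pool_omitted(self, small_setup):
        cohort, sets, caseness = small_setup
        points = restrictiveness_sweep(cohort, sets, caseness, k_range=range(0, 9))
        by_name = {
            cs.name: [p.k for p in points if p.criteria_name == cs.name] for cs in sets
        }
        assert max(by_name["ICD11_PGD"]) == 7  # pool m = 7
        assert max(by_name["PCBD"]) == 8


class TestSelectOptimum:
    def test_single_point(self):
        assert select_optimum([SweepPoint("A", 3, 70.0, 90.0)]) == ("A", 3)

    def test_youden_comparison(self):
        points = [SweepPoint("A", 1, 90.0, 90.0), SweepPoint("A", 5, 50.0, 96.0)]
        assert select_optimum(points) == ("A", 1)  # J: 80 vs 46

    def test_tie_breaks_toward_smaller_k(self):
        points = [SweepPoint("A", 2, 80.0, 90.0), SweepPoint("A", 1, 90.0, 80.0)]
        assert select_optimum(points) == ("A", 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_optimum([])


class TestPairwiseAgreement:
    def test_six_pairs_for_four_sets(self, default_sets, default_cohort):
        diag = diagnose_cohort(default_cohort[:300], default_sets)
        results = pairwise_agreement_matrix(diag)
        assert len(results) == 6
        assert {frozenset(r.pair) for r in results} == {
            frozenset(p)
            for p in [("PCBD", "PGD_PLOS"), ("PCBD", "CG"), ("PCBD", "ICD11_PGD"),
                      ("PGD_PLOS", "CG"), ("PGD_PLOS", "ICD11_PGD"), ("CG", "ICD11_PGD")]
        }

    def test_set_against_itself(self):
        diag = diagnoses_frame({"A": {"r0": True, "r1": False}, "A2": {"r0": True, "r1": False}})
        (res,) = pairwise_agreement_matrix(diag)
        assert res.kappa == 1.0

    def test_invariant_under_reordering(self, default_sets, default_cohort):
        cohort = default_cohort[:200]
        a = pairwise_agreement_matrix(diagnose_cohort(cohort, default_sets))
        b = pairwise_agreement_matrix(diagnose_cohort(cohort, default_sets[::-1]))
        as_map = {frozenset(r.pair): r.kappa for r in a}
        bs_map = {frozenset(r.pair): r.kappa for r in b}
        assert as_map == pytest.approx(bs_map)
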