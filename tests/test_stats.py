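import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from amlreclass import (
    build_matrix,
    burden_strata,
    fisher_pair,
    group_compare,
    kaplan_meier,
    km_logrank,
    pairwise_screen,
)
from amlreclass.stats import Direction
from amlreclass.types import VariantCall


def olo(pid, gene, onc="ONCOGENIC", vclass="SNV"):
    return VariantCall(patient_id=pid, gene=gene, variant_class=vclass,
                       impact="HIGH", alt_reads=30, vaf=0.4,
                       oncogenicity=onc, paired_normal=True)


def matrix_from_bool(cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"P{i}" for i in range(n)]).astype(bool)


# ----------------------------------------------------------------- matrix

class TestBuildMatrix:
    def test_empty(self):
        assert build_matrix([], min_mutated=1).empty

    def test_min_mutated_drops_rare_genes(self):
        vs = [olo(f"P{i}", "X") for i in range(3)] + [olo(f"P{i}", "Y") for i in range(4)]
        m = build_matrix(vs, min_mutated=4)
        assert list(m.columns) == ["Y"]

    def test_vus_excluded_and_multihit_counts_once(self):
        vs = [olo("P1", "X"), olo("P1", "X"), olo("P2", "X", onc="VUS")]
        m = build_matrix(vs, min_mutated=1, patients=["P1", "P2"])
        assert int(m["X"].sum()) == 1

    def test_flt3_collapses_by_default(self):
        vs = [olo("P1", "FLT3", vclass="FLT3_ITD"), olo("P2", "FLT3", vclass="FLT3_TKD")]
        m = build_matrix(vs, min_mutated=1)
        assert list(m.columns) == ["FLT3"] and int(m["FLT3"].sum()) == 2
        m2 = build_matrix(vs, min_mutated=1, collapse_flt3=False)
        assert set(m2.columns) == {"FLT3_ITD", "FLT3_TKD"}

    def test_fixture_matrix_respects_min_mutated(self, patients, variants):
        m = build_matrix(variants, min_mutated=4, patients=[p.patient_id for p in patients])
        assert (m.sum(axis=0) >= 4).all()
        assert len(m) == 69


# ----------------------------------------------------------------- fisher

def fisher_two_sided_oracle(n11, n10, n01, n00):
    """Exhaustive two-sided Fisher p: sum of hypergeometric point masses
    not exceeding the observed table's mass, over all tables with the
    observed margins."""
    n = n11 + n10 + n01 + n00
    row1, col1 = n11 + n10, n11 + n01
    p_obs = hypergeom.pmf(n11, n, row1, col1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = hypergeom.pmf(k, n, row1, col1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


class TestFisherPair:
    def test_constructed_table_arithmetic(self):
        cols = {"a": [i < 5 for i in range(10)],
                "b": [3 <= i < 8 for i in range(10)]}
        r = fisher_pair(matrix_from_bool(cols), "a", "b")
        assert (r.n11, r.n10, r.n01, r.n00) == (2, 3, 3, 2)
        assert r.odds_ratio == pytest.approx(4 / 9)
        assert r.p_two_sided == pytest.approx(fisher_two_sided_oracle(2, 3, 3, 2))

    def test_identical_columns_infinite_or(self):
        cols = {"a": [True] * 4 + [False] * 8}
        m = matrix_from_bool({"a": cols["a"], "b": cols["a"]})
        r = fisher_pair(m, "a", "b")
        assert math.isinf(r.odds_ratio)
        if r.p_two_sided <= 0.05:
            assert r.direction is Direction.CO_OCCURRENCE

    def test_degenerate_margin_gives_p1_none(self):
        m = matrix_from_bool({"a": [False] * 6, "b": [True, False] * 3})
        r = fisher_pair(m, "a", "b")
        assert r.p_two_sided == 1.0 and r.direction is Direction.NONE

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        m = matrix_from_bool({"a": rng.random(20) < 0.4, "b": rng.random(20) < 0.4})
        ra, rb = fisher_pair(m, "a", "b"), fisher_pair(m, "b", "a")
        assert ra.p_two_sided == rb.p_two_sided
        assert ra.odds_ratio == pytest.approx(rb.odds_ratio)

    def test_matches_enumeration_oracle_on_random_small_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 31))
            a = rng.random(n) < rng.uniform(0.1, 0.9)
            b = rng.random(n) < rng.uniform(0.1, 0.9)
            m = matrix_from_bool({"a": a.tolist(), "b": b.tolist()})
            r = fisher_pair(m, "a", "b")
            oracle = fisher_two_sided_oracle(r.n11, r.n10, r.n01, r.n00)
            if (r.n11 + r.n10) in (0, n) or (r.n11 + r.n01) in (0, n):
                assert r.p_two_sided == 1.0
            else:
                assert r.p_two_sided == pytest.approx(oracle, rel=1e-8)


class TestPairwiseScreen:
    def test_pair_count(self):
        rng = np.random.default_rng(0)
        for k in (2, 5, 8):
            m = matrix_from_bool({f"G{i}": (rng.random(15) < 0.5).tolist() for i in range(k)})
            assert len(pairwise_screen(m)) == k * (k - 1) // 2

    def test_planted_pair_ranks_first(self):
        rng = np.random.default_rng(42)
        n = 60
        carriers = rng.random(n) < 0.4
        cols = {"A": carriers.tolist(), "B": carriers.tolist()}
        for i in range(6):
            cols[f"N{i}"] = (rng.random(n) < 0.3).tolist()
        results = pairwise_screen(matrix_from_bool(cols))
        top = results[0]
        assert {top.gene_a, top.gene_b} == {"A", "B"}
        assert top.direction is Direction.CO_OCCURRENCE


# ---------------------------------------------------------- group compare

class TestGroupCompare:
    def test_identical_groups_p1(self):
        vals = [1.0, 2.0, 3.0] * 2
        groups = ["x"] * 3 + ["y"] * 3
        assert group_compare(vals, groups).p == pytest.approx(1.0)

    def test_three_groups_uses_kruskal(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=30).tolist()
        groups = (["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        assert group_compare(vals, groups).test == "kruskal"

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], ["a", "a"])

    def test_categorical_uses_fisher(self):
        vals = ["yes"] * 5 + ["no"] * 5
        groups = ["g1"] * 5 + ["g2"] * 5
        r = group_compare(vals, groups, categorical=True)
        assert r.test == "fisher" and 0 <= r.p <= 1

    def test_type_i_error_calibrated(self):
        """Null rejection rate of the rank-sum over 1000 seeded replicates."""
        rng = np.random.default_rng(2024)
        groups = ["a"] * 30 + ["b"] * 30
        rejections = sum(
            group_compare(rng.normal(size=60).tolist(), groups).p <= 0.05
            for _ in range(1000)
        )
        rate = rejections / 1000
        # three Monte-Carlo SDs around the nominal level
        assert abs(rate - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / 1000)

    def test_power_under_two_sd_shift(self):
        rng = np.random.default_rng(99)
        groups = ["a"] * 20 + ["b"] * 20
        hits = sum(
            group_compare(
                np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)]).tolist(),
                groups,
            ).p <= 0.05
            for _ in range(200)
        )
        assert hits / 200 > 0.9


# -------------------------------------------------------------- survival

class TestKaplanMeier:
    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(10, size=40)
        km = kaplan_meier(times, [True] * 40)
        for _, row in km.iterrows():
            t = row["time"]
            assert row["survival"] == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_monotone_from_one(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(10, size=30)
        events = rng.random(30) < 0.7
        km = kaplan_meier(times, events)
        s = km["survival"].to_numpy()
        assert s[0] == pytest.approx(1.0)
        assert (np.diff(s) <= 1e-12).all()

    def test_identical_groups_logrank_zero(self, patients, variants):
        from lifelines.statistics import logrank_test

        t = [5.0, 10.0, 15.0, 20.0]
        res = logrank_test(t, t, event_observed_A=[1] * 4, event_observed_B=[1] * 4)
        assert res.test_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_strata_partition_cohort(self, patients, variants):
        for rule in ("olo_gt3", "all_gt4", "mr_runx1_gt1"):
            strata = burden_strata(patients, variants, rule)
            assert set(strata) == {p.patient_id for p in patients}
            assert set(strata.values()) <= {"high", "low"}

    def test_unknown_rule_names_allowed(self, patients, variants):
        with pytest.raises(ValueError, match="olo_gt3"):
            burden_strata(patients, variants, "bogus")

    def test_fixture_km_runs(self, patients, variants):
        res = km_logrank(patients, variants, "olo_gt3")
        assert 0 <= res.p <= 1
        assert sum(res.strata_sizes.values()) == 69

    def test_logrank_detects_hazard_ratio_two(self):
        """Exponential groups with HR 2, n=100/100: significant in >80% of
        seeded replicates."""
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            t1 = rng.exponential(10, 100)
            t2 = rng.exponential(5, 100)
            res = logrank_test(t1, t2, event_observed_A=np.ones(100),
                               event_observed_B=np.ones(100))
            hits += res.p_value < 0.05
        assert hits / n_rep > 0.8
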