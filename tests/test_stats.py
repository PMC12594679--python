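"""Group statistics: summaries, pooled t, exact Mann–Whitney."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nvumorph import (
    GroupSample,
    compare_groups,
    compare_metric_table,
    exact_mann_whitney_p,
    mann_whitney_u,
    students_t_unpaired,
    summarize,
)
from nvumorph.stats import choose_test, stars


class TestSummarize:
    def test_constant_sample(self):
        assert summarize([5, 5, 5]) == (5.0, 0.0, 3)

    def test_sem_closed_form(self):
        mean, sem, n = summarize([1, 2, 3])
        assert mean == 2.0 and n == 3
        assert sem == pytest.approx(1 / np.sqrt(3), abs=1e-12)

    def test_single_value_has_no_sem(self):
        assert summarize([7]) == (7.0, None, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestStudentsT:
    def test_closed_form_example(self):
        a = GroupSample("a", [1, 2, 3])
        b = GroupSample("b", [4, 5, 6])
        res = students_t_unpaired(a, b)
        # pooled sd = 1, se = sqrt(2/3): t = -3/0.8165
        assert res.statistic == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-12)
        assert res.p_two_tailed == pytest.approx(0.021312, abs=1e-5)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            xa = rng.normal(size=rng.integers(2, 12))
            xb = rng.normal(1.0, 2.0, size=rng.integers(2, 12))
            res = students_t_unpaired(GroupSample("a", xa), GroupSample("b", xb))
            ref = sps.ttest_ind(xa, xb, equal_var=True)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-12)

    def test_identical_groups_give_p_one(self):
        a = GroupSample("a", [1, 2, 3])
        res = students_t_unpaired(a, GroupSample("b", [1, 2, 3]))
        assert res.statistic == 0.0 and res.p_two_tailed == 1.0

    def test_swapping_groups_flips_sign_keeps_p(self):
        a = GroupSample("a", [1.0, 2.0, 5.0])
        b = GroupSample("b", [2.5, 3.5, 9.0])
        r1 = students_t_unpaired(a, b)
        r2 = students_t_unpaired(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed, abs=1e-12)

    def test_degenerate_zero_variance(self):
        same = students_t_unpaired(GroupSample("a", [2, 2]), GroupSample("b", [2, 2]))
        assert same.p_two_tailed == 1.0
        diff = students_t_unpaired(GroupSample("a", [2, 2]), GroupSample("b", [3, 3]))
        assert diff.p_two_tailed == 0.0

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            students_t_unpaired(GroupSample("a", [1]), GroupSample("b", [1, 2]))


class TestMannWhitney:
    def test_extreme_separation_example(self):
        res = mann_whitney_u(GroupSample("a", [1, 2, 3]), GroupSample("b", [4, 5, 6]))
        assert res.method == "exact_enumeration"
        assert res.statistic == 0.0
        assert res.p_two_tailed == pytest.approx(2 / 20)  # 0.1 by enumeration

    def test_exact_matches_independent_enumeration_small_n(self):
        """Every tie-free rank pattern with n_a + n_b <= 10 agrees with a
        direct tail count over all C(N, n_a) assignments."""
        for n_a, n_b in [(2, 2), (3, 3), (3, 4), (4, 4), (5, 5), (2, 8)]:
            N = n_a + n_b
            for subset in combinations(range(N), n_a):
                xa = np.array(subset, dtype=float)
                xb = np.array(sorted(set(range(N)) - set(subset)), dtype=float)
                p = exact_mann_whitney_p(xa, xb)
                # independent tail count
                mu = n_a * n_b / 2
                u_obs = sum(
                    (a > b) + 0.5 * (a == b) for a in xa for b in xb
                )
                hits = 0
                for alt in combinations(range(1, N + 1), n_a):
                    u = sum(alt) - n_a * (n_a + 1) / 2
                    if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                        hits += 1
                assert p == pytest.approx(hits / comb(N, n_a), abs=1e-12)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            xa = rng.permutation(50)[: rng.integers(2, 7)].astype(float)
            xb = np.setdiff1d(rng.permutation(50), xa)[: rng.integers(2, 7)].astype(float)
            res = mann_whitney_u(GroupSample("a", xa), GroupSample("b", xb))
            ref = sps.mannwhitneyu(xa, xb, alternative="two-sided", method="exact")
            assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-12)

    def test_identical_multisets_sit_at_null_centre(self):
        a = GroupSample("a", [1, 2, 3, 4])
        res = mann_whitney_u(a, GroupSample("b", [1, 2, 3, 4]))
        assert res.statistic == 4 * 4 / 2
        assert res.p_two_tailed == 1.0

    def test_ties_fall_back_to_normal_approximation(self):
        res = mann_whitney_u(GroupSample("a", [1, 1, 2]), GroupSample("b", [2, 3, 4]))
        assert res.method == "normal_approx"
        assert 0 < res.p_two_tailed <= 1

    def test_exact_and_approx_agree_at_7v7(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            pool = rng.permutation(1000)[:14].astype(float)
            xa, xb = pool[:7], pool[7:]
            exact = mann_whitney_u(GroupSample("a", xa), GroupSample("b", xb), method="exact")
            approx = mann_whitney_u(GroupSample("a", xa), GroupSample("b", xb), method="normal")
            assert abs(exact.p_two_tailed - approx.p_two_tailed) < 0.02

    @given(st.permutations(list(range(8))))
    @settings(max_examples=25, deadline=None)
    def test_order_invariance(self, perm):
        values = np.array([3.0, 1.5, 9.0, 4.0, 0.5, 7.0, 2.0, 8.0])[list(perm)]
        a = GroupSample("a", values[:4])
        ref = mann_whitney_u(GroupSample("a", np.sort(values[:4])), GroupSample("b", values[4:]))
        res = mann_whitney_u(a, GroupSample("b", values[4:]))
        assert res.p_two_tailed == ref.p_two_tailed


class TestSelectionAndTables:
    def test_small_n_routes_to_mann_whitney(self):
        a = GroupSample("a", [1.0, 2.0, 3.0])
        b = GroupSample("b", [4.0, 5.0, 6.0])
        assert choose_test(a, b) == "mann_whitney"

    def test_normal_samples_route_to_t(self):
        rng = np.random.default_rng(0)
        a = GroupSample("a", rng.normal(size=9))
        b = GroupSample("b", rng.normal(size=9))
        assert choose_test(a, b) == "student_t"

    def test_constant_group_routes_to_mann_whitney(self):
        a = GroupSample("a", [2.0] * 9)
        b = GroupSample("b", np.linspace(0, 1, 9))
        assert choose_test(a, b) == "mann_whitney"

    def test_compare_metric_table_roundtrip(self):
        table = pd.DataFrame(
            {
                "group": ["nd"] * 3 + ["d"] * 3,
                "freq_peg_socket": [3.0, 3.2, 2.9, 1.1, 1.3, 1.0],
            }
        )
        res = compare_metric_table(table, "freq_peg_socket")
        assert res.test_name == "mann_whitney_u"  # n=3 < 5
        assert res.p_two_tailed == pytest.approx(0.1)
        assert res.metric == "freq_peg_socket"

    def test_missing_group_errors(self):
        table = pd.DataFrame({"group": ["nd"] * 3, "m": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing group"):
            compare_metric_table(table, "m")

    def test_missing_metric_errors(self):
        table = pd.DataFrame({"group": ["a", "b"], "m": [1.0, 2.0]})
        with pytest.raises(KeyError):
            compare_metric_table(table, "absent")

    def test_significance_flags_and_stars(self):
        res = compare_groups(
            GroupSample("a", [1, 2, 3]), GroupSample("b", [4, 5, 6]), test="mann_whitney"
        )
        assert res.significant_at == {0.05: False, 0.01: False, 0.001: False}
        assert res.stars == "ns"
        assert stars(0.04) == "*" and stars(0.009) == "**" and stars(5e-4) == "***"
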