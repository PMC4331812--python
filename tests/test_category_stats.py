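"""MRPP, Fisher over-representation and class-by-cluster contingency tests."""

from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedfill.category_stats import (
    _group_assignments,
    class_by_cluster_tests,
    category_fdr,
    fisher_exact_2xk,
    fisher_overrep,
    mrpp_test,
)
from seedfill.io import CategoryCatalog

from conftest import make_matrix


class TestMrpp:
    def test_identical_samples_give_p_one(self, design_2x3):
        m = make_matrix(np.ones((3, 6)), design_2x3, scale="ln_centered")
        cat = CategoryCatalog.build("c", ["f0", "f1", "f2"])
        res = mrpp_test(m, cat, B=200, seed=0)
        assert res.delta_obs == 0.0
        assert res.p == 1.0

    def test_monte_carlo_matches_exhaustive_enumeration(self, design_2x3, rng):
        m = make_matrix(rng.normal(size=(3, 6)), design_2x3, scale="ln_centered")
        cat = CategoryCatalog.build("c", ["f0", "f1", "f2"])
        ex = mrpp_test(m, cat, exhaustive=True)
        assert ex.B == comb(6, 3)  # all 20 assignments into two groups of 3
        mc = mrpp_test(m, cat, B=20_000, seed=3)
        # MC estimate concentrates on the exhaustive value
        se = np.sqrt(ex.p * (1 - ex.p) / 20_000)
        assert abs(mc.p - ex.p) < max(4 * se, 2 / 20_001)

    def test_group_assignment_enumeration_count(self):
        sizes = np.array([2, 2, 2])
        assignments = list(_group_assignments(6, sizes))
        assert len(assignments) == 90  # 6!/(2!2!2!)

    def test_separated_groups_give_smallest_possible_p(self, design_2x3):
        vals = np.vstack([
            np.array([0.0, 0.1, -0.1, 5.0, 5.1, 4.9]),
            np.array([1.0, 1.1, 0.9, -4.0, -4.1, -3.9]),
        ])
        m = make_matrix(vals, design_2x3, scale="ln_centered")
        cat = CategoryCatalog.build("c", ["f0", "f1"])
        res = mrpp_test(m, cat, exhaustive=True)
        # only the identity and the mirrored assignment reach delta_obs
        assert res.p == pytest.approx(2 / 20)

    def test_non_testable_category_rejected(self, design_2x3):
        m = make_matrix(np.ones((2, 6)), design_2x3, scale="ln_centered")
        cat = CategoryCatalog.build("c", ["f0", "not_measured"])
        with pytest.raises(ValueError, match="not testable"):
            mrpp_test(m, cat)

    def test_category_fdr_attaches_q(self, design_2x3, rng):
        m = make_matrix(rng.normal(size=(6, 6)), design_2x3, scale="ln_centered")
        results = [
            mrpp_test(m, CategoryCatalog.build(f"c{i}", [f"f{i}", f"f{i+1}"]),
                      B=99, seed=i)
            for i in range(5)
        ]
        category_fdr(results)
        assert all(r.q is not None and r.q <= 1.0 for r in results)


class TestFisherOverrep:
    def test_selected_equals_background_gives_p_one(self):
        bg = {f"f{i}" for i in range(20)}
        cat = CategoryCatalog.build("c", [f"f{i}" for i in range(5)], bg)
        res = fisher_overrep(bg, cat, bg)
        assert res.p == pytest.approx(1.0)

    def test_tail_matches_direct_summation(self):
        # background 100, selected 10, category 10, overlap 5
        bg = {f"f{i}" for i in range(100)}
        cat_members = [f"f{i}" for i in range(10)]
        selected = set(cat_members[:5]) | {f"f{i}" for i in range(50, 55)}
        cat = CategoryCatalog.build("c", cat_members, bg)
        res = fisher_overrep(selected, cat, bg)
        direct = sum(
            comb(10, k) * comb(90, 10 - k) for k in range(5, 11)
        ) / comb(100, 10)
        assert res.p == pytest.approx(direct, rel=1e-12)
        assert (res.a, res.b, res.c, res.d) == (5, 5, 5, 85)

    def test_feature_relabeling_invariance(self, rng):
        bg = [f"f{i}" for i in range(40)]
        cat_members = bg[:8]
        selected = set(bg[:4]) | set(bg[20:26])
        cat = CategoryCatalog.build("c", cat_members, bg)
        p1 = fisher_overrep(selected, cat, set(bg)).p
        mapping = dict(zip(bg, rng.permutation(bg)))
        cat2 = CategoryCatalog.build("c", [mapping[f] for f in cat_members], list(mapping.values()))
        p2 = fisher_overrep({mapping[f] for f in selected}, cat2, set(mapping.values())).p
        assert p1 == pytest.approx(p2)

    def test_selected_outside_background_rejected(self):
        cat = CategoryCatalog.build("c", ["a", "b"])
        with pytest.raises(ValueError, match="subset"):
            fisher_overrep({"zzz"}, cat, {"a", "b"})


def _brute_force_2xk(row, other):
    """Enumerate all margin-preserving 2xK tables; prob-ordering p-value."""
    row = np.asarray(row)
    other = np.asarray(other)
    cols = row + other
    r = row.sum()
    N = cols.sum()

    def prob(ks):
        num = 1.0
        for c, k in zip(cols, ks):
            num *= comb(int(c), int(k))
        return num / comb(int(N), int(r))

    p_obs = prob(row)
    total = 0.0
    for ks in product(*[range(int(c) + 1) for c in cols]):
        if sum(ks) != r:
            continue
        pk = prob(ks)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return total


class TestFisherExact2xk:
    @pytest.mark.parametrize(
        "row,other",
        [
            ([3, 1, 4], [2, 5, 0]),
            ([5, 0, 2, 1], [1, 4, 3, 6]),
            ([8, 2], [3, 9]),
            ([0, 0, 6], [4, 4, 0]),
            ([2, 2, 2, 2, 2], [3, 1, 4, 2, 5]),
        ],
    )
    def test_matches_brute_force_enumeration(self, row, other):
        assert fisher_exact_2xk(row, other) == pytest.approx(
            _brute_force_2xk(row, other), rel=1e-9
        )

    def test_2x2_matches_scipy_fisher(self):
        table = np.array([[7, 3], [2, 8]])
        p = fisher_exact_2xk(table[0], table[1])
        assert p == pytest.approx(stats.fisher_exact(table).pvalue, rel=1e-9)

    def test_degenerate_row_gives_p_one(self):
        assert fisher_exact_2xk([0, 0, 0], [3, 4, 5]) == 1.0


def _table_to_series(T, class_names, cluster_names):
    feats, cls, clu = [], [], []
    k = 0
    for i, cname in enumerate(class_names):
        for j, gname in enumerate(cluster_names):
            for _ in range(T[i][j]):
                feats.append(f"x{k}")
                cls.append(cname)
                clu.append(gname)
                k += 1
    return (
        pd.Series(clu, index=feats, name="cluster"),
        pd.Series(cls, index=feats, name="class"),
    )


class TestClassByCluster:
    def test_proportional_table_gives_p_one_everywhere(self):
        # class counts exactly proportional to (equal) cluster sizes
        T = [[4, 4, 4, 4], [6, 6, 6, 6]]
        assign, classes = _table_to_series(T, ["A", "B"], list("wxyz"))
        res = class_by_cluster_tests(assign, classes, B=2000, seed=0)
        for r in res["per_class"]:
            assert r.p == pytest.approx(1.0)
        for r in res["per_cluster"]:
            assert r.p == pytest.approx(1.0)
        assert res["overall"].p == pytest.approx(1.0)

    def test_per_class_uniformity_known_chi2(self):
        # one class: counts (23, 0, 4, 2, 1); chi-square gof against uniform
        T = [[23, 0, 4, 2, 1], [57, 61, 32, 33, 60]]
        assign, classes = _table_to_series(T, ["ST", "rest"], list("abcde"))
        res = class_by_cluster_tests(assign, classes, B=500, seed=0)
        st = next(r for r in res["per_class"] if r.label == "ST")
        obs = np.array([23, 0, 4, 2, 1])
        expected = np.full(5, obs.sum() / 5)
        stat = ((obs - expected) ** 2 / expected).sum()
        assert st.p == pytest.approx(float(stats.chi2.sf(stat, 4)), rel=1e-12)

    def test_fisher_variant_matches_exact_2xk(self):
        T = [[5, 1, 3], [2, 6, 4]]
        assign, classes = _table_to_series(T, ["A", "B"], list("pqr"))
        res = class_by_cluster_tests(
            assign, classes, B=200, seed=0, per_class_method="fisher_exact"
        )
        a = next(r for r in res["per_class"] if r.label == "A")
        assert a.p == pytest.approx(fisher_exact_2xk([5, 1, 3], [2, 6, 4]), rel=1e-12)

    def test_monte_carlo_agrees_with_exact_on_small_2xj(self):
        row = np.array([6, 0, 1])
        other = np.array([2, 5, 4])
        from seedfill.category_stats import _mc_chi2_2xj

        stat, p_mc = _mc_chi2_2xj(row, other, B=100_000, seed=1)
        # exact reference: enumerate tables, chi-square extremeness
        cols = row + other
        r = int(row.sum())
        N = int(cols.sum())
        exp_r = r * cols / N
        exp_o = (N - r) * cols / N
        stat_obs = (((row - exp_r) ** 2) / exp_r).sum() + (((other - exp_o) ** 2) / exp_o).sum()
        total = 0.0
        for ks in product(*[range(int(c) + 1) for c in cols]):
            if sum(ks) != r:
                continue
            ks = np.array(ks)
            pk = np.prod([comb(int(c), int(k)) for c, k in zip(cols, ks)]) / comb(N, r)
            s = (((ks - exp_r) ** 2) / exp_r).sum() + (((cols - ks - exp_o) ** 2) / exp_o).sum()
            if s >= stat_obs - 1e-12:
                total += pk
        se = np.sqrt(total * (1 - total) / 100_000)
        assert abs(p_mc - total) < 4 * se + 2e-5

    def test_empty_class_rejected(self):
        assign = pd.Series(["c1", "c1"], index=["a", "b"])
        classes = pd.Series(["A", "A"], index=["a", "c"])
        with pytest.raises(ValueError):
            class_by_cluster_tests(assign, classes)
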