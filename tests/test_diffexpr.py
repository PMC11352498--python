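import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import oracles
from mirforge.diffexpr import (
    CountMatrix,
    anova_p,
    call_de,
    cluster_de,
    concordance_classes,
    ddct,
    normalize,
    pearson_matrix,
    venn_partition,
)
from mirforge.synthetic_data import simulate_count_matrix


class TestNormalize:
    def test_cpm_arithmetic(self):
        m = pd.DataFrame({"s1": [10, 90]}, index=["a", "b"])
        out = normalize(m)
        assert out["s1"].tolist() == [1e5, 9e5]

    def test_all_zero_column_rejected(self):
        m = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            normalize(m)

    def test_row_permutation_invariance(self):
        m = pd.DataFrame({"s1": [1, 2, 3], "s2": [4, 5, 6]}, index=["a", "b", "c"])
        out1 = normalize(m)
        out2 = normalize(m.iloc[[2, 0, 1]])
        assert np.allclose(out1.loc[["a", "b", "c"]].values, out2.loc[["a", "b", "c"]].values)


def permutation_p(values, labels, n_perm=20000, seed=0):
    """Permutation oracle for the one-way F-test."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)

    def f_stat(v):
        groups = [v[labels == g] for g in np.unique(labels)]
        k = len(groups)
        n = len(v)
        grand = v.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        return (ssb / (k - 1)) / (ssw / (n - k))

    obs = f_stat(values)
    hits = 0
    for _ in range(n_perm):
        hits += f_stat(rng.permutation(values)) >= obs - 1e-12
    return hits / n_perm


class TestAnova:
    def test_no_variance_gives_p_one(self):
        assert anova_p([5.0, 5.0, 5.0, 5.0, 5.0, 5.0], ["a"] * 3 + ["b"] * 3) == 1.0

    def test_textbook_two_group_case(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = ["a"] * 3 + ["b"] * 3
        p = anova_p(values, labels)
        # closed form: SSB = 13.5, SSW = 4, F = 13.5 -> p ~ 0.0213
        f_ref, p_ref = stats.f_oneway(values[:3], values[3:])
        assert f_ref == pytest.approx(13.5)
        assert p == pytest.approx(p_ref, abs=1e-12)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_agrees_with_permutation_oracle_at_larger_n(self):
        # permutation granularity is too coarse at n=3/group (20 splits),
        # so the permutation cross-check uses 10 per group
        rng = np.random.default_rng(12)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(1.0, 1, 10)])
        labels = ["a"] * 10 + ["b"] * 10
        p = anova_p(values, labels)
        assert p == pytest.approx(permutation_p(values, labels), abs=0.02)

    def test_matches_scipy_on_three_groups(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.normal(size=9)
            p = anova_p(v, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
            p_ref = stats.f_oneway(v[:3], v[3:6], v[6:]).pvalue
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_two_group_anova_equals_pooled_t_test(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            v = rng.normal(size=6)
            p = anova_p(v, ["a"] * 3 + ["b"] * 3)
            t = stats.ttest_ind(v[:3], v[3:], equal_var=True)
            assert abs(p - t.pvalue) < 1e-10

    def test_requires_two_replicates_per_group(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_p([1.0, 2.0, 3.0], ["a", "a", "b"])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=6, max_size=6))
    def test_p_always_in_unit_interval(self, values):
        p = anova_p(values, ["a"] * 3 + ["b"] * 3)
        assert 0.0 <= p <= 1.0


class TestCallDe:
    def matrix(self, a, b):
        counts = pd.DataFrame(
            {f"t_{i}": col for i, col in enumerate(np.asarray(a).T)}
            | {f"c_{i}": col for i, col in enumerate(np.asarray(b).T)},
            index=[f"m{j}" for j in range(len(a))],
        )
        groups = {f"t_{i}": "T" for i in range(np.asarray(a).shape[1])}
        groups |= {f"c_{i}": "C" for i in range(np.asarray(b).shape[1])}
        return CountMatrix(counts, groups)

    def test_identical_means_not_significant(self):
        cm = self.matrix([[100, 100, 100]], [[100, 100, 100]])
        (r,) = call_de(cm, ("T", "C"))
        assert not r.significant
        assert r.p_value == 1.0

    def test_fold_gate_blocks_small_changes(self):
        # strong p-value but fold < 2 after normalisation must not be called
        base = np.array([[1000, 1010, 990], [1000, 990, 1010]])
        treat = np.array([[1900, 1910, 1890], [1000, 1010, 990]])
        cm = self.matrix(treat, base)
        r0 = call_de(cm, ("T", "C"))[0]
        assert r0.p_value < 0.05
        assert 2 ** abs(r0.log2_fc) < 2
        assert not r0.significant

    def test_spiked_fold_four_called_up(self):
        cm, truth = simulate_count_matrix(
            n_mirnas=50, n_spiked=1, fold=4.0, cv=0.1, frac_up=1.0, seed=5
        )
        results = {r.mirna: r for r in call_de(cm, ("NaCl", "H2O"))}
        spiked = results["mir-0001"]
        assert spiked.significant
        assert spiked.direction == "up"

    def test_dual_thresholds_reported(self):
        cm, _ = simulate_count_matrix(n_mirnas=30, n_spiked=5, fold=4.0, cv=0.1, seed=6)
        for r in call_de(cm, ("NaCl", "H2O")):
            if r.significant_01:
                assert r.significant  # 0.01 calls are a subset of 0.05 calls


sets_strategy = st.tuples(
    st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20))
)


class TestSetLogic:
    def test_enumerable_example(self):
        parts = venn_partition({"a", "b", "c"}, {"b", "c", "d"}, {"c"})
        assert parts["A&B only"] == {"b"}
        assert parts["A&C only"] == set()
        assert parts["B&C only"] == set()
        assert parts["A&B&C"] == {"c"}
        assert parts["A only"] == {"a"}
        assert parts["B only"] == {"d"}
        assert parts["C only"] == set()

    def test_empty_sets(self):
        parts = venn_partition(set(), set(), set())
        assert all(v == set() for v in parts.values())

    @settings(max_examples=200, deadline=None)
    @given(sets_strategy)
    def test_partition_is_disjoint_and_exhaustive(self, sets):
        a, b, c = sets
        parts = venn_partition(a, b, c)
        union = a | b | c
        combined = set()
        total = 0
        for region in parts.values():
            assert region.isdisjoint(combined)
            combined |= region
            total += len(region)
        assert combined == union
        assert total == len(union)

    def test_concordance_example(self):
        a = {"x": "up", "y": "up", "z": "down"}
        b = {"x": "up", "y": "down", "z": "down", "w": "up"}
        classes = concordance_classes(a, b)
        assert classes["consistent_up"] == {"x"}
        assert classes["consistent_down"] == {"z"}
        assert classes["a_up_b_down"] == {"y"}
        assert classes["a_down_b_up"] == set()

    @settings(max_examples=100, deadline=None)
    @given(
        st.dictionaries(st.integers(0, 10), st.sampled_from(["up", "down"])),
        st.dictionaries(st.integers(0, 10), st.sampled_from(["up", "down"])),
    )
    def test_concordance_partitions_shared_set(self, a, b):
        classes = concordance_classes(a, b)
        shared = set(a) & set(b)
        combined = set()
        for region in classes.values():
            assert region.isdisjoint(combined)
            combined |= region
        assert combined == shared


class TestPearson:
    def test_duplicated_columns_correlate_perfectly(self):
        m = pd.DataFrame({"s1": [1.0, 5.0, 2.0, 8.0], "s2": [1.0, 5.0, 2.0, 8.0]})
        r = pearson_matrix(m)
        assert r.loc["s1", "s2"] == pytest.approx(1.0)

    def test_matches_hand_computed_toy(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 5.0, 3.0])
        m = pd.DataFrame({"s1": x, "s2": y})
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert pearson_matrix(m).loc["s1", "s2"] == pytest.approx(expected)

    def test_centered_negation_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = pd.DataFrame({"s1": x, "s2": x.mean() - (x - x.mean())})
        assert pearson_matrix(m).loc["s1", "s2"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.uniform(1, 100, size=(20, 5)), columns=list("abcde"))
        r = pearson_matrix(m)
        assert np.allclose(r.values, r.values.T)
        assert np.allclose(np.diag(r.values), 1.0)
        assert (r.values <= 1 + 1e-12).all() and (r.values >= -1 - 1e-12).all()


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame(
            {
                "s1": [10.0, 10.0, 50.0],
                "s2": [20.0, 20.0, 10.0],
                "s3": [40.0, 40.0, 5.0],
            },
            index=["a", "b", "c"],
        )
        out = cluster_de(m)
        link = out["row_linkage"]
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)
        merged = {int(link[0, 0]), int(link[0, 1])}
        assert merged == {0, 1}  # rows a and b

    def test_leaf_order_invariant_to_row_permutation(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(
            rng.uniform(1, 500, size=(8, 6)),
            index=[f"m{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(6)],
        )
        o1 = cluster_de(m)
        o2 = cluster_de(m.iloc[rng.permutation(8)])
        assert o1["row_order"] == o2["row_order"]
        assert o1["col_order"] == o2["col_order"]

    def test_linkage_matches_naive_average_linkage_oracle(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(
            rng.uniform(1, 500, size=(6, 5)),
            index=list("abcdef"),
            columns=[f"s{i}" for i in range(5)],
        )
        out = cluster_de(m)
        # rebuild the same distance the implementation defines
        logm = np.log2(m.sort_index().values + 1.0)
        z = logm - logm.mean(axis=1, keepdims=True)
        z = z / z.std(axis=1, keepdims=True)
        r = np.corrcoef(z)
        labels = sorted(m.index)
        dist = {
            frozenset((labels[i], labels[j])): 1.0 - r[i, j]
            for i in range(6)
            for j in range(i + 1, 6)
        }
        merges = oracles.average_linkage_oracle(dist)
        heights = sorted(h for _, _, h in merges)
        assert np.allclose(sorted(out["row_linkage"][:, 2]), heights, atol=1e-9)


class TestDdct:
    def ct_table(self, target_cts, u6=20.0):
        rows = []
        for (sample, group), ct in target_cts.items():
            rows.append({"sample": sample, "group": group, "target": "mirX", "ct": ct})
            rows.append({"sample": sample, "group": group, "target": "U6", "ct": u6})
        return pd.DataFrame(rows)

    def test_equal_dct_gives_fold_one(self):
        ct = self.ct_table({("a", "H2O"): 25.0, ("b", "NaCl"): 25.0})
        folds = ddct(ct)
        assert folds.loc["mirX", "NaCl"] == pytest.approx(1.0)
        assert folds.loc["mirX", "H2O"] == pytest.approx(1.0)

    def test_closed_form_identities(self):
        ct = self.ct_table({("a", "H2O"): 25.0, ("b", "NaCl"): 26.0, ("c", "Na2CO3"): 23.0})
        folds = ddct(ct)
        assert folds.loc["mirX", "NaCl"] == pytest.approx(0.5)  # ddCt +1
        assert folds.loc["mirX", "Na2CO3"] == pytest.approx(4.0)  # ddCt -2

    def test_missing_reference_is_error(self):
        ct = pd.DataFrame(
            [{"sample": "a", "group": "H2O", "target": "mirX", "ct": 25.0}]
        )
        with pytest.raises(ValueError, match="U6"):
            ddct(ct)

    def test_nonpositive_ct_rejected(self):
        ct = self.ct_table({("a", "H2O"): -1.0})
        with pytest.raises(ValueError, match="positive"):
            ddct(ct)
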