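"""Normalization, correlation, differential sites, classification, de-novo."""

import numpy as np
import pandas as pd
import pytest

from tfpair import (
    TagCountTable,
    classify_shared_specific,
    correlation_matrix,
    detect_de_novo,
    differential_sites,
    normalize_tags,
    rank_matrix,
)


def table_from(columns, ids=None, **kwargs):
    df = pd.DataFrame(columns)
    df.index = pd.Index(ids or [f"p{i}" for i in range(len(df))], name="peak_id")
    return TagCountTable(df, **kwargs)


def normalized_two_factor(tf1_values, tf2_values, target=None):
    """A normalized table with one tf1 and one tf2 column (padded to equal sums)."""
    tf1 = np.asarray(tf1_values, dtype=float)
    tf2 = np.asarray(tf2_values, dtype=float)
    total = max(tf1.sum(), tf2.sum()) + 10
    tf1 = np.append(tf1, total - tf1.sum())
    tf2 = np.append(tf2, total - tf2.sum())
    table = table_from({"tf1": tf1, "tf2": tf2})
    return normalize_tags(table, norm_target=target or total)


class TestNormalizeTags:
    def test_column_sums_hit_target(self, rng):
        table = table_from({f"s{j}": rng.integers(0, 100, 10) + 1 for j in range(3)})
        norm = normalize_tags(table, norm_target=1e6)
        assert np.allclose(norm.data.sum(axis=0), 1e6)
        assert norm.normalized and norm.norm_target == 1e6

    def test_already_normalized_column_is_unchanged(self):
        table = table_from({"s": [2.0, 3.0, 5.0]})
        norm = normalize_tags(table, norm_target=10.0)
        assert np.allclose(norm.data["s"], [2, 3, 5])

    def test_scale_invariance(self, rng):
        counts = rng.integers(1, 50, 20).astype(float)
        a = normalize_tags(table_from({"s": counts}), 1e4)
        b = normalize_tags(table_from({"s": counts * 7}), 1e4)
        assert np.allclose(a.data["s"], b.data["s"])

    def test_all_zero_column_names_the_sample(self):
        table = table_from({"good": [1.0, 2.0], "bad": [0.0, 0.0]})
        with pytest.raises(ValueError, match="bad"):
            normalize_tags(table)

    def test_input_table_not_modified(self):
        table = table_from({"s": [1.0, 3.0]})
        before = table.data.copy()
        normalize_tags(table)
        pd.testing.assert_frame_equal(table.data, before)


class TestCorrelationMatrix:
    def test_duplicated_sample_has_unit_correlation(self, rng):
        counts = rng.integers(1, 200, 30).astype(float)
        table = table_from({"a": counts, "b": counts})
        corr = correlation_matrix(table)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_scaled_copy_has_unit_correlation(self, rng):
        counts = rng.integers(1, 200, 30).astype(float)
        corr = correlation_matrix(table_from({"a": counts, "b": 3 * counts}))
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_textbook_pearson(self, rng):
        table = normalize_tags(table_from({f"s{j}": rng.integers(1, 99, 5) for j in range(3)}))
        corr = correlation_matrix(table)
        logged = np.log2(table.data.to_numpy() + 1.0)
        for i in range(3):
            for j in range(3):
                x, y = logged[:, i], logged[:, j]
                expected = (
                    ((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                )
                assert corr.iloc[i, j] == pytest.approx(expected)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_zero_variance_sample_is_named(self):
        table = table_from({"flat": [5.0, 5.0, 5.0], "ok": [1.0, 2.0, 9.0]})
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(normalize_tags(table, 15.0))


class TestDifferentialSites:
    def test_identical_columns_give_empty_sets(self, rng):
        col = pd.Series(rng.integers(0, 50, 20).astype(float))
        gained, lost = differential_sites(col, col)
        assert gained == [] and lost == []

    def test_exact_twofold_is_inclusive(self):
        a = pd.Series({"p": 4.0})
        b = pd.Series({"p": 8.0})
        gained, lost = differential_sites(a, b, fold_threshold=2.0, pseudocount=0.0)
        assert gained == ["p"] and lost == []
        gained, lost = differential_sites(b, a, fold_threshold=2.0, pseudocount=0.0)
        assert gained == [] and lost == ["p"]

    def test_recovers_planted_gained_and_lost_sites(self):
        rng = np.random.default_rng(7)
        n, fold, depth = 400, 4.0, 50.0
        status = np.array(["same"] * (n - 100) + ["gained"] * 50 + ["lost"] * 50)
        mean_a = np.where(status == "gained", depth / fold, depth)
        mean_b = np.where(status == "lost", depth / fold, depth)
        reps = 2
        a = pd.Series(sum(rng.poisson(mean_a) for _ in range(reps)) / reps, dtype=float)
        b = pd.Series(sum(rng.poisson(mean_b) for _ in range(reps)) / reps, dtype=float)
        gained, lost = differential_sites(a, b)
        got_g, got_l = set(gained), set(lost)
        true_g = set(np.nonzero(status == "gained")[0])
        true_l = set(np.nonzero(status == "lost")[0])
        for got, true in ((got_g, true_g), (got_l, true_l)):
            sens = len(got & true) / len(true)
            spec = 1 - len(got - true) / (n - len(true))
            assert sens >= 0.95 and spec >= 0.95

    def test_misaligned_universes_rejected(self):
        a = pd.Series({"p1": 1.0})
        b = pd.Series({"p2": 1.0})
        with pytest.raises(ValueError, match="aligned"):
            differential_sites(a, b)


class TestClassifySharedSpecific:
    def test_equal_columns_are_all_shared(self, rng):
        counts = rng.integers(1, 100, 20).astype(float)
        table = normalize_tags(table_from({"tf1": counts, "tf2": counts}))
        cls = classify_shared_specific(table, "tf1", "tf2")
        assert set(cls.table["label"]) == {"shared"}

    def test_exact_twofold_boundary_is_specific(self):
        table = normalized_two_factor([9.0], [4.0])
        cls = classify_shared_specific(table, "tf1", "tf2", pseudocount=1.0)
        # (9 + 1) / (4 + 1) == 2.0 exactly: inclusive rule labels it specific
        assert cls.table.loc["p0", "label"] == "tf1_specific"
        assert cls.table.loc["p0", "fold"] == pytest.approx(2.0)

    def test_factor_swap_swaps_specific_labels(self, rng):
        counts = table_from(
            {"tf1": rng.integers(0, 100, 50).astype(float) + 1,
             "tf2": rng.integers(0, 100, 50).astype(float) + 1})
        total = counts.data["tf1"].sum()
        counts.data["tf2"] *= total / counts.data["tf2"].sum()
        table = normalize_tags(counts)
        fwd = classify_shared_specific(table, "tf1", "tf2")
        rev = classify_shared_specific(table, "tf2", "tf1")
        assert fwd.ids_with_label("tf1_specific") == rev.ids_with_label("tf2_specific")
        assert fwd.ids_with_label("tf2_specific") == rev.ids_with_label("tf1_specific")
        assert fwd.ids_with_label("shared") == rev.ids_with_label("shared")

    def test_labels_partition_the_universe(self, rng):
        counts = table_from({"tf1": rng.integers(0, 60, 100).astype(float),
                             "tf2": rng.integers(0, 60, 100).astype(float)})
        counts.data.iloc[0] = [30.0, 30.0]  # guard against zero columns
        table = normalize_tags(counts)
        cls = classify_shared_specific(table, "tf1", "tf2")
        sizes = cls.counts
        assert sum(sizes.values()) == 100
        all_ids = sorted(
            cls.ids_with_label("shared")
            + cls.ids_with_label("tf1_specific")
            + cls.ids_with_label("tf2_specific"))
        assert all_ids == sorted(table.peak_ids)

    def test_unnormalized_input_rejected(self):
        table = table_from({"tf1": [1.0], "tf2": [2.0]})
        with pytest.raises(ValueError, match="normalized"):
            classify_shared_specific(table, "tf1", "tf2")


class TestDetectDeNovo:
    def test_identical_columns_are_all_unchanged(self, rng):
        counts = rng.integers(0, 80, 30).astype(float)
        table = normalize_tags(table_from({"wt": counts + 1, "mut": counts + 1}), 100.0)
        res = detect_de_novo(table, table.peak_ids, "wt", "mut")
        assert set(res.table["label"]) == {"unchanged"}

    def test_arithmetic_example(self):
        # (10 + 1) / (2 + 1) = 11/3 > 2 -> acquired
        table = normalized_two_factor([2.0], [10.0]).data
        table.columns = ["wt", "mut"]
        tab = TagCountTable(table, normalized=True, norm_target=table["wt"].sum())
        res = detect_de_novo(tab, ["p0"], "wt", "mut", pseudocount=1.0)
        assert res.table.loc["p0", "label"] == "acquired"
        assert res.table.loc["p0", "fold"] == pytest.approx(11 / 3)

    def test_labels_are_mutually_exclusive(self, rng):
        wt = rng.integers(0, 100, 60).astype(float) + 1
        mut = rng.integers(0, 100, 60).astype(float) + 1
        mut *= wt.sum() / mut.sum()
        table = TagCountTable(
            pd.DataFrame({"wt": wt, "mut": mut},
                         index=[f"p{i}" for i in range(60)]),
            normalized=True, norm_target=wt.sum())
        res = detect_de_novo(table, table.peak_ids, "wt", "mut")
        assert res.counts["acquired"] + res.counts["lost"] + res.counts["unchanged"] == 60

    def test_unknown_id_rejected(self):
        table = normalize_tags(table_from({"wt": [1.0, 2.0], "mut": [2.0, 1.0]}), 3.0)
        with pytest.raises(KeyError, match="universe"):
            detect_de_novo(table, ["nope"], "wt", "mut")


class TestRankMatrix:
    def test_sorted_column_is_fixed_point(self):
        table = table_from({"s": [9.0, 5.0, 1.0], "other": [1.0, 2.0, 3.0]})
        ranked = rank_matrix(table, "s", descending=True)
        assert list(ranked.data.index) == list(table.data.index)

    def test_ties_break_lexicographically_by_id(self):
        table = table_from({"s": [5.0, 5.0, 7.0]}, ids=["b", "a", "c"])
        ranked = rank_matrix(table, "s", descending=True)
        assert list(ranked.data.index) == ["c", "a", "b"]

    def test_matches_sort_oracle(self, rng):
        values = rng.uniform(0, 10, 40)
        table = table_from({"s": values, "carry": rng.uniform(0, 1, 40)})
        ranked = rank_matrix(table, "s", descending=True)
        expected = sorted(table.data.index, key=lambda i: (-table.data.loc[i, "s"], i))
        assert list(ranked.data.index) == expected
        # other columns carried along unchanged
        pd.testing.assert_series_equal(
            ranked.data["carry"], table.data["carry"].loc[ranked.data.index])

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            rank_matrix(table_from({"s": [1.0]}), "nope")
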