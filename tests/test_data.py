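import numpy as np
import pytest

from mfge import (
    ExpressionDataset,
    LoadError,
    bss_wss_scores,
    build_cv_plan,
    normalize_genes,
    prefilter_top_k,
    read_expression_table,
    standardize_genes,
    stratified_kfold,
    write_expression_table,
)

from oracles import brute_bss_wss


class TestIO:
    def test_round_trip_identity(self, tiny_ds, tmp_path):
        path = tmp_path / "tiny.tsv"
        write_expression_table(tiny_ds, path)
        back = read_expression_table(path)
        assert back == tiny_ds

    def test_label_row_parsed(self, tiny_ds, tmp_path):
        path = tmp_path / "t.tsv"
        write_expression_table(tiny_ds, path)
        ds = read_expression_table(path)
        assert ds.values.shape == (3, 4)
        assert len(ds.classes) == 2

    def test_missing_label_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "gene_id\ts1\ts2\ts3\ts4\n"
            "class\tA\tA\tB\t\n"
            "g1\t1\t2\t3\t4\n"
        )
        with pytest.raises(LoadError):
            read_expression_table(path)

    def test_non_numeric_cell_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "gene_id\ts1\ts2\ts3\ts4\n"
            "class\tA\tA\tB\tB\n"
            "g1\t1\toops\t3\t4\n"
            "g2\t1\t2\t3\t4\n"
        )
        with pytest.raises(LoadError, match="g1"):
            read_expression_table(path)

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(LoadError, match="duplicate"):
            ExpressionDataset(
                ["g1", "g1"], np.ones((2, 4)), list("abcd"),
                np.array(["A", "A", "B", "B"]),
            )

    def test_separate_labels_file(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "gene_id\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\ng2\t4\t3\t2\t1\n"
        )
        (tmp_path / "lab.tsv").write_text("s1\tA\ns2\tA\ns3\tB\ns4\tB\n")
        ds = read_expression_table(tmp_path / "m.tsv", labels_path=tmp_path / "lab.tsv")
        assert list(ds.labels) == ["A", "A", "B", "B"]


class TestStandardizeNormalize:
    def test_row_123(self):
        # row (1,2,3) twice keeps the per-value expectations of the
        # 3-point case: (x - mean) / population sd with sd = sqrt(2/3)
        ds = ExpressionDataset(["g"], [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]],
                               list("abcdef"),
                               np.array(["A", "A", "A", "B", "B", "B"]))
        out = standardize_genes(ds)
        expected = np.array([-1.22474487, 0.0, 1.22474487] * 2)
        np.testing.assert_allclose(out.values[0], expected, atol=1e-8)
        assert abs(out.values[0].mean()) < 1e-9
        assert abs(out.values[0].var() - 1) < 1e-9

    def test_idempotent_on_standardized(self, tiny_ds):
        once = standardize_genes(tiny_ds)
        twice = standardize_genes(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_row_zeroed(self, tiny_ds):
        out = standardize_genes(tiny_ds)
        np.testing.assert_array_equal(out.values[2], np.zeros(4))

    def test_normalize_range(self, tiny_ds):
        out = normalize_genes(standardize_genes(tiny_ds))
        assert out.values[0].min() == 0.0 and out.values[0].max() == 1.0
        np.testing.assert_allclose(
            normalize_genes(ExpressionDataset(
                ["g"], [[-1.0, 0.0, 1.0, -1.0]], list("abcd"),
                np.array(["A", "A", "B", "B"]))).values[0],
            [0.0, 0.5, 1.0, 0.0],
        )

    def test_normalize_constant_row_half(self, tiny_ds):
        out = normalize_genes(tiny_ds)
        np.testing.assert_array_equal(out.values[2], np.full(4, 0.5))


class TestStratifiedKFold:
    def test_exact_divisibility(self):
        labels = np.array(["A"] * 6 + ["B"] * 6)
        folds = stratified_kfold(labels, 3, seed=0)
        for _tr, te in folds:
            assert sum(labels[te] == "A") == 2
            assert sum(labels[te] == "B") == 2

    def test_uneven_classes_within_one(self):
        labels = np.array(["A"] * 4 + ["B"] * 3)
        folds = stratified_kfold(labels, 3, seed=1)
        covered = np.sort(np.concatenate([te for _tr, te in folds]))
        np.testing.assert_array_equal(covered, np.arange(7))
        for _tr, te in folds:
            assert 1 <= len(te) <= 3
            for c in "AB":
                assert sum(labels[te] == c) in (0, 1, 2)

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            labels = rng.choice(["A", "B", "C"], size=30)
            while np.unique(labels, return_counts=True)[1].min() < 3:
                labels = rng.choice(["A", "B", "C"], size=30)
            folds = stratified_kfold(labels, 3, seed=5)
            covered = np.sort(np.concatenate([te for _tr, te in folds]))
            np.testing.assert_array_equal(covered, np.arange(30))
            for tr, te in folds:
                assert not set(tr) & set(te)
                assert len(tr) + len(te) == 30

    def test_same_seed_same_folds(self):
        labels = np.array(["A", "B"] * 10)
        f1 = stratified_kfold(labels, 3, seed=42)
        f2 = stratified_kfold(labels, 3, seed=42)
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array(["A", "B"] * 5), 1, seed=0)


class TestBssWss:
    def test_hand_example(self):
        # class means 0.5, 2.5; grand 1.5 -> BSS 4, WSS 1
        ds = ExpressionDataset(["g"], [[0.0, 1.0, 2.0, 3.0]], list("abcd"),
                               np.array(["A", "A", "B", "B"]))
        assert bss_wss_scores(ds)[0] == pytest.approx(4.0)

    def test_perfect_separator_infinite(self):
        ds = ExpressionDataset(["g"], [[0.0, 0.0, 2.0, 2.0]], list("abcd"),
                               np.array(["A", "A", "B", "B"]))
        assert np.isinf(bss_wss_scores(ds)[0])

    def test_constant_gene_zero(self, tiny_ds):
        assert bss_wss_scores(tiny_ds)[2] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            X = rng.normal(size=(20, 12))
            y = np.array(["A"] * 5 + ["B"] * 4 + ["C"] * 3)
            ds = ExpressionDataset([f"g{i}" for i in range(20)], X,
                                   [f"s{i}" for i in range(12)], y)
            np.testing.assert_allclose(
                bss_wss_scores(ds), brute_bss_wss(X, y), atol=1e-10
            )


class TestPrefilter:
    def test_exact_count(self):
        rng = np.random.default_rng(1)
        ds = ExpressionDataset(
            [f"g{i}" for i in range(50)], rng.normal(size=(50, 8)),
            [f"s{i}" for i in range(8)], np.array(["A", "B"] * 4),
        )
        out = prefilter_top_k(ds, bss_wss_scores(ds), 20)
        assert out.n_genes == 20

    def test_identity_when_k_equals_gene_count(self, tiny_ds):
        out = prefilter_top_k(tiny_ds, np.array([3.0, 1.0, 2.0]), 3)
        assert out == tiny_ds

    def test_order_preserved(self, tiny_ds):
        out = prefilter_top_k(tiny_ds, np.array([3.0, 1.0, 2.0]), 2)
        assert out.gene_ids == ["g1", "g3"]

    def test_k_nonpositive_rejected(self, tiny_ds):
        with pytest.raises(ValueError):
            prefilter_top_k(tiny_ds, np.zeros(3), 0)


class TestCVPlan:
    def _ds18(self):
        rng = np.random.default_rng(0)
        return ExpressionDataset(
            [f"g{i}" for i in range(4)], rng.normal(size=(4, 18)),
            [f"s{i}" for i in range(18)], np.array(["A", "B"] * 9),
        )

    def test_structure(self):
        plan = build_cv_plan(self._ds18(), 3, 3, seed=0)
        assert len(plan.external_folds) == 3
        for (tr, _te), inner in zip(plan.external_folds, plan.internal_folds):
            assert len(inner) == 3
            assert len(tr) == 12

    def test_no_leakage(self):
        plan = build_cv_plan(self._ds18(), 3, 3, seed=1)
        for (tr, te), inner in zip(plan.external_folds, plan.internal_folds):
            for itr, ite in inner:
                assert not set(te) & set(itr)
                assert not set(te) & set(ite)
                assert set(itr) | set(ite) == set(tr)

    def test_deterministic(self):
        p1 = build_cv_plan(self._ds18(), 3, 3, seed=5)
        p2 = build_cv_plan(self._ds18(), 3, 3, seed=5)
        for (a, b), (c, d) in zip(p1.external_folds, p2.external_folds):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)
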