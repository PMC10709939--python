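import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lmsdiag import (
    Label,
    MssRecord,
    PipelineConfig,
    Scale,
    apply_gene_selection,
    filter_by_mean_expression,
    fit_gene_selection,
    gap_select,
    mean_test_p,
    mss,
    mss_ratio_table,
    select_ndeg,
    variance_test_p,
    zero_sum_transform,
)
from lmsdiag.gene_selection import GeneSelectionModel

from conftest import make_matrix


class TestMeanExpressionFilter:
    def test_keeps_highest_mean_genes(self):
        values = np.arange(1.0, 11.0)[:, None] * np.ones((1, 3))
        m = make_matrix(values, gene_ids=[f"g{i}" for i in range(10)])
        kept = filter_by_mean_expression(m, 0.3)
        assert kept == ["g9", "g8", "g7"]

    def test_ties_break_lexicographically(self):
        m = make_matrix(np.ones((4, 2)), gene_ids=["d", "b", "a", "c"])
        assert filter_by_mean_expression(m, 0.5) == ["a", "b"]

    def test_fraction_one_keeps_everything(self):
        m = make_matrix(np.random.default_rng(0).random((7, 2)))
        assert len(filter_by_mean_expression(m, 1.0)) == 7

    def test_empty_result_rejected(self):
        m = make_matrix(np.ones((2, 2)))
        with pytest.raises(ValueError):
            filter_by_mean_expression(m, 0.2)


class TestVarianceTest:
    def test_identical_vectors_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert variance_test_p(x, x) == 1.0

    def test_matches_f_distribution_oracle(self):
        # frozen against R: var.test(c(1,2,3,4,5), c(10,20,30,40,50))
        p = variance_test_p([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert p == pytest.approx(0.000584295269052441, rel=1e-12)
        # second fixture, unequal spreads
        a = [2.1, 1.9, 2.0, 2.4, 1.8, 2.2]
        b = [1.2, 3.1, 0.4, 2.9, 4.0, 1.6]
        assert variance_test_p(a, b) == pytest.approx(0.00103407708952177, rel=1e-12)

    def test_two_sided_symmetry(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        assert variance_test_p(x, y) == pytest.approx(variance_test_p(y, x), rel=1e-12)

    def test_degenerate_variances(self):
        const = np.array([2.0, 2.0, 2.0])
        varying = np.array([1.0, 2.0, 3.0])
        assert variance_test_p(const, const) == 1.0
        assert variance_test_p(const, varying) == 0.0
        assert variance_test_p(varying, const) == 0.0


class TestMeanTest:
    def test_identical_vectors_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert mean_test_p(x, x) == 1.0

    def test_matches_welch_oracle(self):
        # frozen against R: t.test(c(1,2,3,4,5), c(10,20,30,40,50))
        p = mean_test_p([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert p == pytest.approx(0.018430858997467, rel=1e-10)
        a = [2.1, 1.9, 2.0, 2.4, 1.8, 2.2]
        b = [1.2, 3.1, 0.4, 2.9, 4.0, 1.6]
        assert mean_test_p(a, b) == pytest.approx(0.820490614088879, rel=1e-10)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 1.0, 10)
        y = rng.normal(10.0, 1.0, 10)  # 10-SD shift
        assert mean_test_p(x, y) < 1e-6

    def test_sign_flip_invariance(self):
        x = np.array([0.5, 1.0, 1.5, 0.2])
        y = np.array([2.0, 2.5, 1.8, 2.2])
        assert mean_test_p(x, y) == pytest.approx(mean_test_p(-x, -y), rel=1e-12)

    def test_constant_groups(self):
        same = np.array([1.0, 1.0, 1.0])
        other = np.array([2.0, 2.0, 2.0])
        assert mean_test_p(same, same) == 1.0
        assert mean_test_p(same, other) == 0.0


class TestSelectNdeg:
    @staticmethod
    def _matrices(normal_rows, benign_rows, genes):
        normal = make_matrix(np.array(normal_rows), gene_ids=genes,
                             scale=Scale.STANDARDIZED,
                             sample_ids=[f"n{i}" for i in range(len(normal_rows[0]))])
        benign = make_matrix(np.array(benign_rows), gene_ids=genes,
                             scale=Scale.STANDARDIZED,
                             sample_ids=[f"b{i}" for i in range(len(benign_rows[0]))])
        return normal, benign

    def test_identical_gene_retained_shifted_gene_excluded(self):
        rng = np.random.default_rng(3)
        stable_n = rng.normal(0, 1, 20)
        stable_b = rng.normal(0, 1, 8)
        shifted_b = rng.normal(5.0, 1, 8)  # 5-SD mean shift
        normal, benign = self._matrices(
            [stable_n, stable_n], [stable_b, shifted_b], ["keep", "shifted"]
        )
        kept = select_ndeg(normal, benign, ["keep", "shifted"], alpha=0.05)
        assert kept == ["keep"]
        assert mean_test_p(stable_n, shifted_b) < 0.05

    def test_alpha_zero_is_identity(self):
        rng = np.random.default_rng(4)
        normal, benign = self._matrices(
            rng.normal(0, 1, (5, 10)), rng.normal(3, 5, (5, 6)),
            [f"g{i}" for i in range(5)],
        )
        genes = [f"g{i}" for i in range(5)]
        assert select_ndeg(normal, benign, genes, alpha=0.0) == genes

    def test_empty_result_reports_rejection_counts(self):
        rng = np.random.default_rng(5)
        normal, benign = self._matrices(
            rng.normal(0, 0.1, (2, 20)), rng.normal(50, 10, (2, 20)), ["a", "b"]
        )
        with pytest.raises(ValueError, match="rejections"):
            select_ndeg(normal, benign, ["a", "b"], alpha=0.05)


class TestZeroSum:
    def test_three_gene_example(self):
        m = make_matrix(np.array([[1.0], [2.0], [3.0]]), scale=Scale.STANDARDIZED)
        z = zero_sum_transform(m, ["g0", "g1", "g2"])
        assert z.scale is Scale.ZEROSUM
        np.testing.assert_allclose(z.values[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_sample_becomes_zero(self):
        m = make_matrix(np.full((4, 2), 7.0), scale=Scale.STANDARDIZED)
        z = zero_sum_transform(m, [f"g{i}" for i in range(4)])
        np.testing.assert_array_equal(z.values, np.zeros((4, 2)))

    def test_restricts_to_ndeg_subset(self):
        m = make_matrix(np.array([[1.0], [5.0], [9.0]]), scale=Scale.STANDARDIZED)
        z = zero_sum_transform(m, ["g0", "g2"])
        assert z.gene_ids == ["g0", "g2"]
        np.testing.assert_allclose(z.values[:, 0], [-4.0, 4.0])

    def test_missing_gene_rejected(self):
        m = make_matrix(np.ones((2, 2)), scale=Scale.STANDARDIZED)
        with pytest.raises(KeyError, match="nope"):
            zero_sum_transform(m, ["g0", "nope"])

    @given(st.integers(0, 2**32 - 1))
    def test_sample_means_vanish(self, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.normal(3, 10, (100, 10)), scale=Scale.STANDARDIZED)
        z = zero_sum_transform(m, list(m.gene_ids))
        assert np.all(np.abs(z.values.mean(axis=0)) < 1e-9)


class TestMss:
    def test_reference_values(self):
        assert mss([0.0, 0.0, 0.0]) == 0.0
        assert mss([1.0, -1.0]) == 1.0
        assert mss([2.0, 0.0, -2.0]) == pytest.approx(8.0 / 3.0, rel=1e-15)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            mss([])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_matches_brute_force_sum_of_squares(self, xs):
        brute = sum(v * v for v in xs) / len(xs)
        assert mss(xs) == pytest.approx(brute, rel=1e-12, abs=1e-12)


class TestMssRatioTable:
    @staticmethod
    def _table(values, labels, genes=None):
        m = make_matrix(np.array(values), scale=Scale.ZEROSUM, gene_ids=genes)
        label_map = {f"s{j}": lab for j, lab in enumerate(labels)}
        return mss_ratio_table(m, label_map)

    def test_identical_groups_give_ratio_one(self):
        labels = [Label.LEIOMYOSARCOMA] * 2 + [Label.NORMAL] * 2
        records = self._table([[1.0, -1.0, 1.0, -1.0]], labels)
        assert records[0].mss_ratio == pytest.approx(1.0)

    def test_ratio_is_division_of_group_mss(self):
        labels = [Label.LEIOMYOSARCOMA] * 2 + [Label.NORMAL] * 2
        records = self._table([[1.0, -1.0, 0.2, -0.2]], labels)
        r = records[0]
        assert r.mss_lms == pytest.approx(1.0)
        assert r.mss_normal == pytest.approx(0.04)
        assert r.mss_ratio == pytest.approx(25.0)

    def test_near_zero_normal_mss_dropped_with_warning(self, caplog):
        labels = [Label.LEIOMYOSARCOMA] * 2 + [Label.NORMAL] * 2
        with caplog.at_level("WARNING", logger="lmsdiag.gene_selection"):
            records = self._table(
                [[1.0, -1.0, 0.0, 0.0], [1.0, -1.0, 0.5, -0.5]], labels,
                genes=["degenerate", "fine"],
            )
        assert [r.gene_id for r in records] == ["fine"]
        assert "degenerate" in caplog.text

    def test_group_missing_rejected(self):
        with pytest.raises(ValueError, match="normal"):
            self._table([[1.0, -1.0]], [Label.LEIOMYOSARCOMA] * 2)


def _records(ratios):
    return [MssRecord(f"g{i:02d}", 1.0, r, r) for i, r in enumerate(ratios)]


class TestGapSelect:
    def test_dominant_gap_cuts_curve(self):
        selected = gap_select(_records([10.0, 9.0, 8.0, 2.0, 1.0]), inspect_n=5)
        assert selected == ["g00", "g01", "g02"]

    def test_relative_gap_ignores_large_absolute_top_spread(self):
        # 100 -> 60 is the biggest absolute drop but only 1.7-fold; the
        # marker/background boundary 30 -> 3 is a 10-fold drop
        selected = gap_select(_records([100.0, 60.0, 30.0, 3.0, 2.0]), inspect_n=5)
        assert selected == ["g00", "g01", "g02"]

    def test_all_equal_falls_back_to_top_k(self):
        selected = gap_select(_records([2.0] * 30), inspect_n=20, fallback_k=17)
        assert len(selected) == 17
        assert selected == [f"g{i:02d}" for i in range(17)]

    def test_gap_after_rank_17_selects_17(self):
        ratios = list(np.linspace(40.0, 25.0, 17)) + [2.5, 2.0, 1.8, 1.5, 1.2]
        selected = gap_select(_records(ratios), inspect_n=20, fallback_k=17)
        assert len(selected) == 17

    def test_selection_shrinks_as_gap_moves_earlier(self):
        sizes = []
        for cut in (2, 5, 8):
            ratios = [30.0 - 0.1 * i for i in range(cut)] + [
                1.0 - 0.01 * i for i in range(12 - cut)
            ]
            sizes.append(len(gap_select(_records(ratios), inspect_n=12)))
        assert sizes == [2, 5, 8]

    def test_ties_sorted_lexicographically(self):
        records = [
            MssRecord("b", 1.0, 5.0, 5.0),
            MssRecord("a", 1.0, 5.0, 5.0),
            MssRecord("c", 1.0, 0.5, 0.5),
        ]
        assert gap_select(records, inspect_n=3) == ["a", "b"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gap_select([], inspect_n=5)


class TestFitApply:
    def test_recovers_planted_genes_in_small_cohort(self, small_study):
        parts = small_study["parts"]
        model = fit_gene_selection(parts["train"], parts["benign_ref"],
                                   PipelineConfig(fallback_k=8, seed=7))
        planted = set(small_study["truth"].planted_gene_ids)
        recovered = planted & set(model.selected_genes)
        assert len(recovered) >= len(planted) - 2
        # pipeline containments
        assert set(model.selected_genes) <= set(model.ndeg_genes)
        assert set(model.ndeg_genes) <= set(model.retained_genes)

    def test_apply_reproduces_training_features(self, small_study):
        parts = small_study["parts"]
        model = fit_gene_selection(parts["train"], parts["benign_ref"],
                                   PipelineConfig(seed=7))
        feats1 = apply_gene_selection(model, parts["train"])
        feats2 = apply_gene_selection(model, parts["train"])
        np.testing.assert_allclose(feats1.values, feats2.values, atol=1e-12)
        assert feats1.gene_ids == model.selected_genes
        # per-sample NDEG means vanish on held-out cohorts too
        from lmsdiag import log_transform, reference_standardize, zero_sum_transform
        std = reference_standardize(
            log_transform(parts["validation"].matrix, model.pseudo_count),
            model.reference_gene,
        )
        z = zero_sum_transform(std, model.ndeg_genes)
        assert np.all(np.abs(z.values.mean(axis=0)) < 1e-9)

    def test_missing_selected_gene_named(self, small_study):
        parts = small_study["parts"]
        model = fit_gene_selection(parts["train"], parts["benign_ref"],
                                   PipelineConfig(seed=7))
        victim = model.selected_genes[0]
        keep = [g for g in parts["test1"].matrix.gene_ids if g != victim]
        pruned = parts["test1"].subset_samples(parts["test1"].matrix.sample_ids)
        pruned = type(pruned)(pruned.matrix.subset_genes(keep), pruned.labels)
        with pytest.raises(KeyError, match=victim):
            apply_gene_selection(model, pruned)

    def test_fit_is_deterministic(self, small_study):
        parts = small_study["parts"]
        m1 = fit_gene_selection(parts["train"], parts["benign_ref"], PipelineConfig(seed=7))
        m2 = fit_gene_selection(parts["train"], parts["benign_ref"], PipelineConfig(seed=7))
        assert m1.selected_genes == m2.selected_genes
        assert m1.ndeg_genes == m2.ndeg_genes

    def test_benign_cohort_must_be_leiomyoma_only(self, small_study):
        parts = small_study["parts"]
        with pytest.raises(ValueError, match="non-leiomyoma"):
            fit_gene_selection(parts["train"], parts["train"], PipelineConfig())

    def test_model_bundle_round_trip(self, small_study, tmp_path):
        parts = small_study["parts"]
        model = fit_gene_selection(parts["train"], parts["benign_ref"],
                                   PipelineConfig(seed=7))
        model.save(tmp_path / "bundle")
        back = GeneSelectionModel.load(tmp_path / "bundle")
        assert back.selected_genes == model.selected_genes
        assert back.ndeg_genes == model.ndeg_genes
        assert back.reference_gene == model.reference_gene
        assert back.config == model.config
        feats1 = apply_gene_selection(model, parts["test1"])
        feats2 = apply_gene_selection(back, parts["test1"])
        np.testing.assert_allclose(feats1.values, feats2.values, atol=1e-12)
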