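import numpy as np
import pytest
from scipy import stats

from landmarker import evaluation as ev

from conftest import make_matrix


class TestMaePerGene:
    def test_identical_matrices_give_zero(self, small_matrix):
        np.testing.assert_array_equal(
            ev.mae_per_gene(small_matrix, small_matrix), np.zeros(20)
        )

    def test_hand_computed(self):
        G = make_matrix([[1.0, 2.0, 3.0]])
        G_hat = make_matrix([[2.0, 2.0, 5.0]])
        np.testing.assert_allclose(ev.mae_per_gene(G, G_hat), [1.0])

    def test_matches_element_loop(self, rng):
        G = make_matrix(rng.random((10, 8)))
        G_hat = make_matrix(rng.random((10, 8)))
        result = ev.mae_per_gene(G, G_hat)
        for j in range(10):
            brute = sum(abs(a - b) for a, b in zip(G.values[j], G_hat.values[j])) / 8
            assert abs(result[j] - brute) < 1e-12

    def test_misaligned_ids_refused(self, rng):
        G = make_matrix(rng.random((3, 4)))
        other = make_matrix(rng.random((3, 4)), prefix_g="x")
        with pytest.raises(ValueError, match="gene ids"):
            ev.mae_per_gene(G, other)


class TestPccPerGene:
    def test_affine_prediction_gives_one(self, rng):
        G = make_matrix(rng.random((5, 10)))
        G_hat = G.with_values(2.0 * G.values + 1.0)
        np.testing.assert_allclose(ev.pcc_per_gene(G, G_hat), np.ones(5), atol=1e-12)

    def test_negated_prediction_gives_minus_one(self, rng):
        G = make_matrix(rng.random((5, 10)))
        np.testing.assert_allclose(
            ev.pcc_per_gene(G, G.with_values(-G.values)), -np.ones(5), atol=1e-12
        )

    def test_matches_scipy_pearson(self, rng):
        G = make_matrix(rng.random((12, 10)))
        G_hat = make_matrix(rng.random((12, 10)))
        result = ev.pcc_per_gene(G, G_hat)
        for j in range(12):
            expected = stats.pearsonr(G.values[j], G_hat.values[j]).statistic
            assert abs(result[j] - expected) < 1e-12

    def test_constant_gene_reported_zero_with_flag(self, rng):
        v = rng.random((4, 6))
        v[1, :] = 0.7
        G = make_matrix(v)
        G_hat = make_matrix(rng.random((4, 6)))
        r, undefined = ev.pcc_per_gene(G, G_hat, with_flags=True)
        assert r[1] == 0.0
        assert undefined[1] and not undefined[0]

    def test_requires_three_samples(self, rng):
        G = make_matrix(rng.random((4, 2)))
        with pytest.raises(ValueError, match="3 samples"):
            ev.pcc_per_gene(G, G)


class TestPermutationTest:
    def test_self_prediction_is_maximally_significant(self, rng):
        G = make_matrix(rng.normal(size=(1000, 50)))
        p, significant = ev.permutation_test(G, G, "g0", alpha=0.01)
        assert p == 0.0 and significant
        p_all, sig_all = ev.permutation_test_all(G, G)
        assert np.all(p_all == 0.0) and np.all(sig_all)

    def test_pvalues_within_unit_interval(self, rng):
        G = make_matrix(rng.normal(size=(40, 12)))
        G_hat = make_matrix(rng.normal(size=(40, 12)))
        p, _ = ev.permutation_test_all(G, G_hat)
        assert np.all((p >= 0) & (p <= 1))

    def test_alpha_boundary_is_strict(self, rng):
        # gene g0 predicted exactly; one decoy duplicates it so exactly 1 of
        # 100 reference correlations ties the self-correlation -> p = 0.01
        v = rng.normal(size=(101, 30))
        v[1, :] = v[0, :]
        G = make_matrix(v)
        G_hat = G.copy()
        p, significant = ev.permutation_test(G, G_hat, "g0", alpha=0.01)
        assert p == pytest.approx(0.01)
        assert not significant  # requires p < alpha strictly

    def test_constant_gene_never_significant(self, rng):
        v = rng.normal(size=(10, 8))
        v[3, :] = 1.0
        G = make_matrix(v)
        _, sig = ev.permutation_test_all(G, G)
        assert not sig[3]

    def test_single_gene_matrix_refused(self, rng):
        G = make_matrix(rng.normal(size=(1, 8)))
        with pytest.raises(ValueError, match="2 genes"):
            ev.permutation_test_all(G, G)

    def test_matches_brute_force_reference_scan(self, rng):
        G = make_matrix(rng.normal(size=(25, 15)))
        G_hat = make_matrix(rng.normal(size=(25, 15)))
        p_all, _ = ev.permutation_test_all(G, G_hat)
        for j in (0, 7, 24):
            r_self = stats.pearsonr(G.values[j], G_hat.values[j]).statistic
            refs = [
                stats.pearsonr(G.values[i], G_hat.values[j]).statistic
                for i in range(25)
                if i != j
            ]
            brute = np.mean([r >= r_self for r in refs])
            assert abs(p_all[j] - brute) < 1e-12


class TestCompare:
    def _report(self, rng, n=30):
        G = make_matrix(rng.normal(size=(n, 20)))
        G_hat = make_matrix(G.values + rng.normal(scale=0.5, size=(n, 20)))
        return ev.evaluate(G, G_hat)

    def test_self_comparison_is_null(self, rng):
        report = self._report(rng)
        cmp = ev.compare_landmark_sets(report, report)
        assert cmp.mae_t == 0.0 and cmp.mae_p == 1.0
        assert np.all(cmp.per_gene["mae_delta"] == 0.0)

    def test_constant_nonzero_deltas_flagged(self, rng):
        report_a = self._report(rng)
        b_genes = report_a.per_gene.copy()
        b_genes["mae"] = b_genes["mae"] + 0.5
        report_b = ev.EvaluationReport(per_gene=b_genes)
        cmp = ev.compare_landmark_sets(report_a, report_b)
        assert cmp.mae_zero_variance
        assert cmp.mae_p == 0.0

    def test_matches_scipy_paired_t(self, rng):
        a = self._report(rng)
        b = self._report(rng)
        cmp = ev.compare_landmark_sets(a, b)
        expected = stats.ttest_rel(a.per_gene["mae"], b.per_gene["mae"])
        assert abs(cmp.mae_t - expected.statistic) < 1e-10
        assert abs(cmp.mae_p - expected.pvalue) < 1e-10

    def test_antisymmetry(self, rng):
        a = self._report(rng)
        b = self._report(rng)
        ab = ev.compare_landmark_sets(a, b)
        ba = ev.compare_landmark_sets(b, a)
        assert ab.mae_t == -ba.mae_t
        assert ab.pcc_t == -ba.pcc_t
        np.testing.assert_allclose(
            ab.per_gene["pcc_delta"], -ba.per_gene["pcc_delta"].to_numpy()
        )
        assert ab.mae_wins_a == ba.mae_wins_b

    def test_comparison_restricted_to_common_genes(self, rng):
        a = self._report(rng, n=30)
        b = self._report(rng, n=30)
        b.per_gene["gene_id"] = ["g%d" % (i + 20) for i in range(30)]  # overlap g20-g29
        cmp = ev.compare_landmark_sets(a, b)
        assert len(cmp.per_gene) == 10

    def test_fewer_than_two_common_genes_refused(self, rng):
        a = self._report(rng)
        b_genes = a.per_gene.copy()
        b_genes["gene_id"] = ["x%d" % i for i in range(len(b_genes))]
        with pytest.raises(ValueError, match="common"):
            ev.compare_landmark_sets(a, ev.EvaluationReport(per_gene=b_genes))


class TestEmbeddingClustering:
    def test_perfectly_separated_classes_give_ari_one(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        labels = np.repeat([0, 1, 2], 20)
        E = centers[labels] + 0.01 * rng.normal(size=(60, 2))
        ari, sil = ev.embedding_cluster_quality(E, labels, seed=0)
        assert ari == 1.0
        assert sil > 0.9

    def test_shuffled_labels_score_near_zero(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        labels = np.repeat([0, 1, 2], 20)
        E = centers[labels] + 0.01 * rng.normal(size=(60, 2))
        shuffled = rng.permutation(labels)
        ari, _ = ev.embedding_cluster_quality(E, shuffled, seed=0)
        assert abs(ari) < 0.2

    def test_single_class_refused(self, rng):
        with pytest.raises(ValueError, match="2 label classes"):
            ev.embedding_cluster_quality(rng.normal(size=(10, 3)), np.zeros(10))


class TestReportIO:
    def test_report_round_trip(self, tmp_path, rng):
        G = make_matrix(rng.normal(size=(8, 12)))
        G_hat = make_matrix(G.values + rng.normal(scale=0.3, size=(8, 12)))
        report = ev.evaluate(G, G_hat, alpha=0.05)
        path = str(tmp_path / "report.tsv")
        report.write(path)
        back = ev.read_report(path)
        assert back.alpha == 0.05
        np.testing.assert_allclose(back.per_gene["mae"], report.per_gene["mae"])
        assert list(back.per_gene["significant"]) == list(
            report.per_gene["significant"]
        )
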