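import numpy as np
import pytest
from scipy.special import expit

from landmarker import attribution as at
from landmarker import autoencoder as ae
from landmarker import nn

from conftest import make_matrix


def random_encoder(rng, n_in, widths, activation="sigmoid"):
    layers = []
    fan_in = n_in
    for w in widths:
        layers.append(
            nn.Layer(W=rng.normal(scale=0.5, size=(w, fan_in)),
                     b=rng.normal(scale=0.2, size=w), activation=activation)
        )
        fan_in = w
    return nn.NetworkParams(layers=layers, bottleneck_index=len(widths) - 1)


class TestRescaleMultiplier:
    def test_sigmoid_finite_difference(self):
        expected = expit(1.0) - expit(0.0)
        assert abs(at.rescale_multiplier(1.0, 0.0, "sigmoid") - expected) < 1e-12

    def test_linear_slope_is_one(self):
        assert at.rescale_multiplier(3.7, -1.2, "linear") == 1.0

    def test_gradient_fallback_at_coincident_inputs(self):
        assert abs(at.rescale_multiplier(0.0, 0.0, "sigmoid") - 0.25) < 1e-12

    def test_unknown_activation_refused(self):
        with pytest.raises(ValueError):
            at.rescale_multiplier(1.0, 0.0, "relu")

    def test_vectorized_matches_scalar(self, rng):
        x = rng.normal(size=7)
        x0 = rng.normal(size=7)
        vec = at.rescale_multiplier(x, x0, "sigmoid")
        for i in range(7):
            assert vec[i] == at.rescale_multiplier(x[i], x0[i], "sigmoid")


class TestPropagate:
    def test_input_equal_to_reference_gives_zero(self, rng):
        params = random_encoder(rng, 6, [4, 2])
        x = rng.random(6)
        ref = at.ReferenceInput(values=x.copy())
        np.testing.assert_array_equal(
            at.propagate_contributions(params, x, ref), np.zeros((6, 2))
        )

    def test_single_unit_summation_forces_hand_value(self):
        w = 1.3
        params = nn.NetworkParams(
            layers=[nn.Layer(W=[[w]], b=[0.0], activation="sigmoid")]
        )
        ref = at.ReferenceInput(values=np.zeros(1), source="zeros")
        c = at.propagate_contributions(params, np.array([0.8]), ref)
        np.testing.assert_allclose(c, [[expit(w * 0.8) - expit(0.0)]], rtol=1e-12)

    def test_linear_encoder_equals_gradient_times_input(self, rng):
        params = random_encoder(rng, 8, [5, 3], activation="linear")
        x = rng.random(8)
        ref = at.ReferenceInput(values=np.zeros(8), source="zeros")
        C = at.propagate_contributions(params, x, ref)
        W_path = params.layers[1].W @ params.layers[0].W  # (3, 8)
        np.testing.assert_allclose(C, W_path.T * x[:, None], atol=1e-10)

    def test_summation_to_delta_random_networks(self, rng):
        for _ in range(20):
            widths = [int(rng.integers(2, 12)), int(rng.integers(2, 8))]
            params = random_encoder(rng, 10, widths)
            x = rng.random(10)
            ref = at.ReferenceInput(values=rng.random(10))
            C = at.propagate_contributions(params, x, ref)
            delta = ae.encode(params, x) - ae.encode(params, ref.values)
            np.testing.assert_allclose(C.sum(axis=0), delta, rtol=1e-6, atol=1e-12)

    def test_attribution_reads_encoder_only(self, rng):
        params = nn.init_network(
            6, [nn.LayerSpec(4), nn.LayerSpec(2), nn.LayerSpec(4), nn.LayerSpec(6)],
            seed=0, bottleneck_index=1,
        )
        X = make_matrix(rng.random((6, 5)))
        ref = at.reference_from_training(X)
        before = at.compute_contribution_tensor(params, X, ref)
        params.layers[2].W += 10.0  # decoder perturbation
        params.layers[3].b -= 3.0
        after = at.compute_contribution_tensor(params, X, ref)
        np.testing.assert_array_equal(before.scores, after.scores)

    def test_determinism_bit_identical(self, rng):
        params = random_encoder(rng, 7, [5, 3])
        X = make_matrix(rng.random((7, 9)))
        ref = at.reference_from_training(X)
        a = at.compute_contribution_tensor(params, X, ref)
        b = at.compute_contribution_tensor(params, X, ref)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_out_of_unit_range_refused(self, rng):
        params = random_encoder(rng, 4, [2])
        ref = at.ReferenceInput(values=np.full(4, 0.5))
        with pytest.raises(ValueError, match="unit scale"):
            at.propagate_contributions(params, np.array([0.1, 2.0, 0.3, 0.4]), ref)

    def test_seeded_subsample(self, rng):
        params = random_encoder(rng, 5, [3, 2])
        X = make_matrix(rng.random((5, 20)))
        ref = at.reference_from_training(X)
        sub = at.compute_contribution_tensor(params, X, ref, n_samples=6, seed=1)
        assert sub.scores.shape[0] == 6
        sub2 = at.compute_contribution_tensor(params, X, ref, n_samples=6, seed=1)
        np.testing.assert_array_equal(sub.scores, sub2.scores)


class TestReference:
    def test_constant_matrix_gives_constant_reference(self):
        X = make_matrix(np.full((4, 6), 0.3))
        ref = at.reference_from_training(X)
        np.testing.assert_array_equal(ref.values, np.full(4, 0.3))
        assert ref.source == "train_mean"

    def test_mean_of_zero_and_one_is_half(self):
        X = make_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_array_equal(
            at.reference_from_training(X).values, [0.5, 0.5]
        )

    def test_matches_column_mean_loop(self, rng):
        X = make_matrix(rng.random((9, 7)))
        ref = at.reference_from_training(X)
        brute = np.array([X.values[i, :].sum() / 7 for i in range(9)])
        np.testing.assert_allclose(ref.values, brute, atol=1e-12)


class TestAggregateAndSelect:
    def test_gene_at_reference_scores_zero_and_ranks_last(self, rng):
        params = random_encoder(rng, 5, [3, 2])
        v = rng.random((5, 8))
        v[2, :] = 0.4  # constant gene
        X = make_matrix(v)
        ref = at.reference_from_training(X)  # mean of constant gene = its value
        C = at.compute_contribution_tensor(params, X, ref)
        ranking = at.aggregate_importance(C)
        idx = ranking.gene_ids.index("g2")
        assert ranking.scores[idx] == 0.0
        assert idx == len(ranking) - 1

    def test_uniform_doubling_ranks_higher(self, rng):
        scores = np.abs(rng.normal(size=(6, 4, 3)))
        scores[:, 1, :] = 2.0 * scores[:, 0, :]
        C = at.ContributionTensor(
            scores=scores,
            sample_ids=[f"s{i}" for i in range(6)],
            gene_ids=[f"g{i}" for i in range(4)],
        )
        ranking = at.aggregate_importance(C)
        assert ranking.gene_ids.index("g1") < ranking.gene_ids.index("g0")

    def test_matches_brute_force_triple_loop(self, rng):
        scores = rng.normal(size=(5, 6, 4))
        C = at.ContributionTensor(
            scores=scores,
            sample_ids=[f"s{i}" for i in range(5)],
            gene_ids=[f"g{i}" for i in range(6)],
        )
        ranking = at.aggregate_importance(C)
        for gi in range(6):
            total = 0.0
            for s in range(5):
                for t in range(4):
                    total += abs(scores[s, gi, t])
            brute = total / (5 * 4)
            idx = ranking.gene_ids.index(f"g{gi}")
            assert abs(ranking.scores[idx] - brute) < 1e-12

    def test_ties_break_by_ascending_gene_id(self):
        scores = np.ones((2, 3, 2))
        C = at.ContributionTensor(
            scores=scores, sample_ids=["s0", "s1"], gene_ids=["gc", "ga", "gb"]
        )
        ranking = at.aggregate_importance(C)
        assert ranking.gene_ids == ["ga", "gb", "gc"]

    def test_select_top_k(self):
        ranking = at.ImportanceRanking(
            gene_ids=["a", "b", "c"], scores=np.array([3.0, 2.0, 1.0])
        )
        assert at.select_landmarks(ranking, 3).gene_ids == ["a", "b", "c"]
        assert at.select_landmarks(ranking, 1).gene_ids == ["a"]
        with pytest.raises(ValueError):
            at.select_landmarks(ranking, 0)
        with pytest.raises(ValueError):
            at.select_landmarks(ranking, 4)

    def test_default_k_is_l1000_panel_size(self):
        assert at.DEFAULT_K == 943

    def test_empty_tensor_refused(self):
        C = at.ContributionTensor(
            scores=np.zeros((0, 3, 2)), sample_ids=[], gene_ids=["a", "b", "c"]
        )
        with pytest.raises(ValueError):
            at.aggregate_importance(C)
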