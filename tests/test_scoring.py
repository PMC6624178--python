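import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from clearf import (
    ClearF,
    EmbeddingSpec,
    LabeledDataset,
    ScoreConfig,
    ValidationError,
    clearf_scores,
    feature_errors,
    generate_informative,
    generate_two_class_2d,
    rank_features,
    total_squared_error,
)
from clearf.scoring import reconstruction_result
from conftest import brute_force_clearf


class TestFeatureErrors:
    def test_arithmetic_example(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        Xhat = np.array([[1.0, 0.0], [3.0, 3.0]])
        np.testing.assert_allclose(feature_errors(X, Xhat, "sum"), [0.0, 5.0])
        np.testing.assert_allclose(feature_errors(X, Xhat, "mean"), [0.0, 2.5])

    def test_unit_residual_column_counts_samples(self):
        X = np.zeros((500, 3))
        Xhat = X.copy()
        Xhat[:, 1] = 1.0
        assert feature_errors(X, Xhat, "sum")[1] == pytest.approx(500.0)

    @given(
        arrays(np.float64, (6, 4), elements=st.floats(-50, 50)),
        arrays(np.float64, (6, 4), elements=st.floats(-50, 50)),
    )
    def test_sum_aggregation_matches_total_error(self, X, Xhat):
        np.testing.assert_allclose(
            feature_errors(X, Xhat, "sum").sum(),
            total_squared_error(X, Xhat),
            rtol=1e-10, atol=1e-8,
        )

    def test_shape_mismatch_coded(self):
        with pytest.raises(ValidationError) as exc:
            feature_errors(np.ones((2, 2)), np.ones((2, 3)))
        assert exc.value.code == "shape-mismatch"

    def test_reconstruction_result_total_is_sum_of_features(self, rng):
        X = rng.normal(size=(8, 3))
        Xhat = X + rng.normal(scale=0.1, size=X.shape)
        res = reconstruction_result(X, Xhat, "mean")
        assert res.total_error == pytest.approx(res.per_feature_error.sum())
        assert (res.per_feature_error >= 0).all()
        assert res.n_samples_used == 8


class TestRanking:
    def test_ties_break_by_feature_index(self):
        ranks = rank_features([0.4, 0.1, 0.4])
        np.testing.assert_array_equal(ranks, [1, 3, 2])

    def test_all_equal_scores_rank_in_index_order(self):
        np.testing.assert_array_equal(rank_features(np.zeros(4)), [1, 2, 3, 4])

    @given(arrays(np.float64, 12, elements=st.floats(-1e6, 1e6)))
    def test_agrees_with_reference_sort(self, scores):
        ranks = rank_features(scores)
        assert sorted(ranks) == list(range(1, 13))
        order = np.argsort(ranks)
        sorted_scores = scores[order]
        assert all(a >= b for a, b in zip(sorted_scores, sorted_scores[1:]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError) as exc:
            rank_features([1.0, np.nan])
        assert exc.value.code == "non-finite-score"


class TestClearFScores:
    def test_single_class_scores_are_zero(self, rng):
        X = rng.normal(size=(20, 6))
        d = LabeledDataset(X=X, y=np.array(["a"] * 20))
        for agg in ("mean", "sum"):
            t = clearf_scores(d, ScoreConfig(aggregation=agg))
            np.testing.assert_allclose(t.scores, 0.0, atol=1e-10)

    def test_worked_example_matches_brute_force_oracle(self):
        # 6 samples, 2 features, 2 classes, k=1, summed errors, raw scale
        X = np.array(
            [[0.0, 0.2], [1.0, 1.1], [2.0, 1.9], [5.0, -4.8], [6.0, -6.2], [7.0, -7.1]]
        )
        y = np.array(["a", "a", "a", "b", "b", "b"])
        cfg = ScoreConfig(
            embedding=EmbeddingSpec(n_components=1),
            aggregation="sum",
            standardize=False,
        )
        t = clearf_scores(LabeledDataset(X=X, y=y), cfg)
        np.testing.assert_allclose(t.scores, brute_force_clearf(X, y, 1), atol=1e-8)

    @pytest.mark.parametrize("agg", ["mean", "sum"])
    def test_oracle_agreement_on_random_multiclass(self, agg, rng):
        X = rng.normal(size=(30, 5))
        y = rng.choice(["a", "b", "c"], size=30)
        cfg = ScoreConfig(
            embedding=EmbeddingSpec(n_components=2), aggregation=agg, standardize=False
        )
        t = clearf_scores(LabeledDataset(X=X, y=y), cfg)
        np.testing.assert_allclose(
            t.scores, brute_force_clearf(X, y, 2, agg), atol=1e-8
        )

    @pytest.mark.parametrize("agg", ["mean", "sum"])
    def test_decomposition_sums_to_dataset_level_score(self, agg, small_dataset):
        d = small_dataset
        cfg = ScoreConfig(aggregation=agg, standardize=False)
        t = clearf_scores(d, cfg)
        sel = ClearF(aggregation=agg, standardize=False).fit(d.X, d.y)
        dataset_score = sel.pooled_errors_.sum() - sel.classwise_errors_.sum()
        assert t.scores.sum() == pytest.approx(dataset_score, rel=1e-8)

    def test_feature_permutation_equivariance(self, small_dataset, rng):
        d = small_dataset
        perm = rng.permutation(d.n_features)
        t = clearf_scores(d)
        d_p = LabeledDataset(
            X=d.X[:, perm],
            y=d.y,
            feature_names=[d.feature_names[j] for j in perm],
        )
        t_p = clearf_scores(d_p)
        np.testing.assert_allclose(t_p.scores, t.scores[perm], atol=1e-8)

    def test_sample_order_invariance(self, small_dataset, rng):
        d = small_dataset
        shuf = rng.permutation(d.n_samples)
        t = clearf_scores(d)
        t_s = clearf_scores(
            LabeledDataset(X=d.X[shuf], y=d.y[shuf], feature_names=d.feature_names)
        )
        np.testing.assert_allclose(t_s.scores, t.scores, atol=1e-8)

    def test_separated_dwarfs_overlapping(self):
        cfg = ScoreConfig(aggregation="sum", standardize=False)
        sep = clearf_scores(generate_two_class_2d("separated", 500, 11), cfg)
        ovl = clearf_scores(generate_two_class_2d("overlapping", 500, 11), cfg)
        assert sep.scores.min() >= 50 * max(ovl.scores.max(), 1e-9)

    @pytest.mark.parametrize("method", ["kernel-rbf", "kernel-poly"])
    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_kernel_backends_rank_informative_near_top(self, method, seed):
        # kernel reconstructions are noisier scorers than linear PCA, but
        # strongly shifted features must still dominate the ranking
        d = generate_informative(80, 3, 12, shift=6.0, seed=seed)
        cfg = ScoreConfig(embedding=EmbeddingSpec(method=method, n_components=2))
        t = clearf_scores(d, cfg)
        assert (t.ranks[:3] <= 5).all()


class TestClearFEstimator:
    def test_selector_mask_and_transform(self):
        d = generate_informative(80, 2, 8, shift=4.0, seed=3)
        sel = ClearF(n_features_to_select=2).fit(d.X, d.y)
        assert sel.get_support().sum() == 2
        assert sel.transform(d.X).shape == (80, 2)
        assert set(np.flatnonzero(sel.get_support())) == {0, 1}

    def test_works_in_sklearn_pipeline(self):
        from sklearn.pipeline import Pipeline
        from sklearn.svm import SVC

        d = generate_informative(60, 2, 6, shift=4.0, seed=9)
        pipe = Pipeline(
            [("select", ClearF(n_features_to_select=2)), ("clf", SVC())]
        )
        pipe.fit(d.X, d.y)
        assert pipe.score(d.X, d.y) > 0.9

    def test_too_many_features_requested(self):
        d = generate_informative(20, 1, 3, shift=3.0, seed=0)
        sel = ClearF(n_features_to_select=10).fit(d.X, d.y)
        with pytest.raises(ValidationError) as exc:
            sel.get_support()
        assert exc.value.code == "too-many-features"

    def test_get_set_params_roundtrip(self):
        params = ClearF(method="kernel-rbf", n_components=5).get_params()
        assert ClearF().set_params(**params).get_params() == params
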