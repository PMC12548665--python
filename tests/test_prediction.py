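"""Rank splitting, nested CV, statistical comparisons and latent PCA."""

import numpy as np
import pandas as pd
import pytest

from tggan.data_model import ConnectomeDataset, ScoredSample
from tggan.prediction import (
    CVConfig,
    CVResult,
    RIDGE_ALPHAS,
    compare_accuracy,
    evaluate_test,
    inner_tune,
    latent_pca,
    rank_interleaved_split,
    repeated_nested_cv,
    split_dataset,
    weight_reliability,
)
from tggan.synthetic import SyntheticConfig, generate_dataset


class TestRankInterleavedSplit:
    def test_nine_samples_hold_out_first_fourth_seventh_rank(self, tiny_dataset):
        dataset, _ = tiny_dataset
        d = ConnectomeDataset(
            tuple(
                ScoredSample(s.matrix, float(i + 1), f"r{i + 1}")
                for i, s in enumerate(dataset.samples[:9])
            )
        )
        plan = rank_interleaved_split(d)
        assert plan.holdout_ids == ("r1", "r4", "r7")
        assert plan.retained_ids == ("r2", "r3", "r5", "r6", "r8", "r9")

    def test_counts_for_108_subjects(self):
        d, _ = generate_dataset(
            SyntheticConfig(n_subjects=108, n_nodes=12, n_signal_edges=8, seed=0)
        )
        plan = rank_interleaved_split(d)
        assert (len(plan.retained_ids), len(plan.holdout_ids)) == (72, 36)

    def test_score_distributions_match_between_parts(self):
        d, _ = generate_dataset(
            SyntheticConfig(n_subjects=60, n_nodes=12, n_signal_edges=8, seed=1)
        )
        retained, holdout = split_dataset(d, rank_interleaved_split(d))
        gap = abs(retained.scores.mean() - holdout.scores.mean())
        assert gap < 0.5 * d.scores.std(ddof=1)

    def test_too_small_dataset_rejected(self, tiny_dataset):
        dataset, _ = tiny_dataset
        with pytest.raises(ValueError):
            rank_interleaved_split(dataset.subset([0, 1]), holdout_stride=3)


def linear_dataset(n=40, n_nodes=8, seed=0, noise=0.0):
    """Edge features with an exactly linear score read-out."""
    cfg = SyntheticConfig(
        n_subjects=n, n_nodes=n_nodes, n_signal_edges=6, noise_sd=noise,
        signal_strength=0.3, seed=seed,
    )
    d, truth = generate_dataset(cfg)
    return d, truth


class TestInnerTune:
    def test_single_grid_point_returned(self):
        d, _ = linear_dataset()
        cfg = CVConfig(ridge_alphas=(2.0,), seed=0)
        assert inner_tune(d.edge_matrix(), d.scores, cfg, seed=0) == {"alpha": 2.0}

    def test_dominating_point_selected_on_clean_linear_problem(self):
        # with a noiseless linear signal, weak regularisation dominates both
        # the correlation and the MAE, so the z-sum argmax must pick it
        d, _ = linear_dataset(n=60, noise=0.0, seed=3)
        cfg = CVConfig(ridge_alphas=(2.0**-10, 2.0**10), seed=0)
        best = inner_tune(d.edge_matrix(), d.scores, cfg, seed=1)
        assert best == {"alpha": 2.0**-10}

    def test_needs_ten_samples(self):
        d, _ = linear_dataset(n=40)
        small = d.subset(range(8))
        with pytest.raises(ValueError):
            inner_tune(small.edge_matrix(), small.scores, CVConfig(), seed=0)


@pytest.fixture(scope="module")
def cv_setup():
    d, _ = generate_dataset(
        SyntheticConfig(n_subjects=60, n_nodes=12, n_signal_edges=10, seed=5)
    )
    cfg = CVConfig(n_repeats=3, ridge_alphas=(0.01, 1.0, 100.0), seed=2)
    return d, cfg, repeated_nested_cv(d, cfg)


class TestRepeatedNestedCV:
    def test_record_count_is_repeats_times_folds(self, cv_setup):
        d, cfg, result = cv_setup
        assert result.n_models == cfg.n_repeats * cfg.n_outer_folds == 15
        assert result.weights.shape == (15, d.n_nodes * (d.n_nodes - 1) // 2)

    def test_reproducible_given_seed(self, cv_setup):
        d, cfg, result = cv_setup
        again = repeated_nested_cv(d, cfg)
        pd.testing.assert_frame_equal(result.records, again.records)
        np.testing.assert_array_equal(result.weights, again.weights)

    def test_planted_signal_yields_high_validation_r(self):
        d, _ = generate_dataset(
            SyntheticConfig(n_subjects=200, n_nodes=30, seed=9)
        )
        cfg = CVConfig(n_repeats=2, seed=3)
        result = repeated_nested_cv(d, cfg)
        assert result.records["val_r"].mean() >= 0.5

    def test_synthetic_samples_never_in_validation(self, cv_setup, tiny_model):
        from tggan.augmentation import augment

        d, cfg, _ = cv_setup
        augmented = augment(d, tiny_model, per_pair_count=1)
        result = repeated_nested_cv(augmented, cfg)
        # every training fold contains all 59 synthetic samples on top of
        # its 48 original ones; validation folds stay original-only
        assert (result.records["n_train"] == 48 + 59).all()

    def test_summary_mentions_model_count(self, cv_setup):
        _, _, result = cv_setup
        assert "15 models" in result.summary()


def manual_cv_result(weights, mu=None, sd=None):
    """A CVResult with externally chosen linear models (1 repeat, k folds)."""
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    n_models, n_edges = w.shape
    cfg = CVConfig(n_repeats=1, n_outer_folds=n_models, seed=0)
    records = pd.DataFrame(
        {
            "repeat": [0] * n_models,
            "fold": list(range(n_models)),
            "val_r": [0.0] * n_models,
            "val_mae": [0.0] * n_models,
        }
    )
    return CVResult(
        config=cfg,
        records=records,
        weights=w,
        intercepts=np.zeros(n_models),
        feature_means=np.zeros((n_models, n_edges)) if mu is None else mu,
        feature_sds=np.ones((n_models, n_edges)) if sd is None else sd,
    )


class TestEvaluateTest:
    def test_perfect_and_constant_models(self):
        d, truth = linear_dataset(n=20, noise=0.0, seed=7)
        X = d.edge_matrix()
        # solve for exact linear weights on the signal edges
        w = np.zeros(X.shape[1])
        beta, *_ = np.linalg.lstsq(
            np.c_[X[:, truth.signal_edges], np.ones(len(d))], d.scores, rcond=None
        )
        w[truth.signal_edges] = beta[:-1]
        perfect = manual_cv_result([w])
        perfect.intercepts = np.array([beta[-1]])
        table = evaluate_test(perfect, d)
        assert table["test_r"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert table["test_rmse"].iloc[0] == pytest.approx(0.0, abs=1e-6)

        constant = manual_cv_result([np.zeros(X.shape[1])])
        t2 = evaluate_test(constant, d)
        assert t2["test_r"].iloc[0] == 0.0
        assert bool(t2["test_r_degenerate"].iloc[0])

    def test_hand_computed_four_point_example(self):
        # one edge feature (3 nodes), model y = 2x
        samples = []
        from tggan.data_model import matricize

        xs = [1.0, 2.0, 3.0, 4.0]
        ys = [2.5, 3.5, 6.5, 7.5]
        for i, (x, y) in enumerate(zip(xs, ys)):
            samples.append(
                ScoredSample(matricize(np.array([x, 0.0, 0.0])), y, f"p{i}")
            )
        d = ConnectomeDataset(tuple(samples))
        model = manual_cv_result([[2.0, 0.0, 0.0]])
        table = evaluate_test(model, d)
        pred = 2 * np.array(xs)
        r_hand = np.corrcoef(ys, pred)[0, 1]
        rmse_hand = np.sqrt(np.mean((np.array(ys) - pred) ** 2))
        assert table["test_r"].iloc[0] == pytest.approx(r_hand)
        assert table["test_rmse"].iloc[0] == pytest.approx(rmse_hand)

    def test_synthetic_samples_in_test_refused(self, tiny_dataset, tiny_model):
        from tggan.augmentation import augment

        dataset, _ = tiny_dataset
        augmented = augment(dataset, tiny_model, per_pair_count=1)
        model = manual_cv_result([np.zeros(66)])
        with pytest.raises(ValueError, match="synthetic"):
            evaluate_test(model, augmented)


class TestCompareAccuracy:
    def test_identical_groups(self):
        v = np.random.default_rng(0).normal(size=50)
        out = compare_accuracy(v, v.copy())
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_separated_groups_significant_after_bonferroni(self):
        rng = np.random.default_rng(1)
        out = compare_accuracy(
            rng.normal(0, 1, 100), rng.normal(1, 1, 100), n_comparisons=4
        )
        assert out["p_adjusted"] < 0.01
        assert out["t"] > 0  # group b has the larger mean

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 30), rng.normal(0.1, 1, 30)
        one = compare_accuracy(a, b, n_comparisons=1)
        four = compare_accuracy(a, b, n_comparisons=4)
        assert four["p_adjusted"] == pytest.approx(min(1.0, one["p"] * 4))

    def test_ten_sd_outlier_removed(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 99)
        a = np.append(a, a.mean() + 10 * a.std(ddof=1))
        out = compare_accuracy(a, rng.normal(0, 1, 100))
        assert out["removed_a"] == 1
        assert out["n_a"] == 99

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_accuracy([1.0, 2.0], [1.0, 2.0, 3.0])


class TestWeightReliability:
    def test_identical_models_zero_width(self):
        result = manual_cv_result(np.tile(np.arange(5.0), (4, 1)))
        rel = weight_reliability(result)
        np.testing.assert_allclose(rel["ci_width"], 0.0)
        np.testing.assert_allclose(rel["mean"], np.arange(5.0))

    def test_ci_width_matches_normal_theory(self):
        rng = np.random.default_rng(4)
        sigma = 0.7
        w = rng.normal(1.0, sigma, size=(100, 400))
        rel = weight_reliability(manual_cv_result(w))
        expected = 2 * 1.96 * sigma
        assert abs(rel["ci_width"].mean() - expected) / expected < 0.15

    def test_mean_equals_columnwise_mean(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=(10, 6))
        rel = weight_reliability(manual_cv_result(w))
        np.testing.assert_allclose(rel["mean"], w.mean(axis=0))

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            weight_reliability(manual_cv_result(np.ones((1, 3))))


class FakeEncoder:
    """Stands in for a trained GAN: returns preset latent codes."""

    def __init__(self, latents):
        self.latents = np.asarray(latents, dtype=float)

    def encode(self, weights):
        return self.latents


class TestLatentPCA:
    def test_planted_one_dimensional_structure_recovered(self, tiny_dataset):
        dataset, _ = tiny_dataset
        rng = np.random.default_rng(6)
        v = rng.normal(size=8)
        y = dataset.scores
        z = np.outer((y - y.mean()) / y.std(), v) + 1e-6 * rng.normal(
            size=(len(dataset), 8)
        )
        out = latent_pca(FakeEncoder(z), dataset)
        assert abs(out["pc1_score_r"]) > 0.99
        assert out["p_value"] < 1e-6

    def test_random_latents_uncorrelated(self):
        d, _ = generate_dataset(
            SyntheticConfig(n_subjects=100, n_nodes=12, n_signal_edges=8, seed=8)
        )
        z = np.random.default_rng(7).normal(size=(100, 16))
        out = latent_pca(FakeEncoder(z), d)
        assert abs(out["pc1_score_r"]) < 0.3

    def test_sign_canonicalization_is_deterministic(self, tiny_dataset):
        dataset, _ = tiny_dataset
        rng = np.random.default_rng(9)
        z = rng.normal(size=(len(dataset), 5))
        r1 = latent_pca(FakeEncoder(z), dataset)["pc1_score_r"]
        r2 = latent_pca(FakeEncoder(z), dataset)["pc1_score_r"]
        assert r1 == r2

    def test_zero_variance_latents_rejected(self, tiny_dataset):
        dataset, _ = tiny_dataset
        with pytest.raises(ValueError):
            latent_pca(FakeEncoder(np.ones((len(dataset), 4))), dataset)


def test_ridge_grid_has_sixteen_powers_of_two():
    assert len(RIDGE_ALPHAS) == 16
    assert RIDGE_ALPHAS[0] == 2.0**-10 and RIDGE_ALPHAS[-1] == 2.0**5


def test_elastic_net_near_lasso_limit_matches_ols():
    # l1_ratio=1 with a vanishing alpha approaches the least-squares fit
    from sklearn.linear_model import ElasticNet, LinearRegression

    rng = np.random.default_rng(10)
    X = rng.normal(size=(200, 5))
    w_true = np.array([1.0, -2.0, 0.5, 3.0, 0.0])
    y = X @ w_true + 0.01 * rng.normal(size=200)
    enet = ElasticNet(alpha=1e-6, l1_ratio=1.0, max_iter=50000).fit(X, y)
    ols = LinearRegression().fit(X, y)
    assert np.linalg.norm(enet.coef_ - ols.coef_) / np.linalg.norm(ols.coef_) < 0.05
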