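"""WGAN-GP losses, gradient penalty, training loop and grid search."""

import numpy as np
import pandas as pd
import pytest

from tggan._tensor import Tensor, grad
from tggan.brainnet import NetworkSpec, build_critic
from tggan.data_model import ConnectomeDataset
from tggan.gan import (
    GridSearchSpace,
    TrainConfig,
    TrainedGAN,
    critic_loss,
    generator_adv_loss,
    gradient_penalty,
    grid_search,
    matrices_to_batch,
    regressor_loss,
    train,
)
from tggan.prediction import rank_interleaved_split, split_dataset
from tggan.synthetic import SyntheticConfig, generate_dataset


class LinearCritic:
    """C(x) = <w, x> with controllable weight norm."""

    def __init__(self, n, norm):
        w = np.ones((1, 1, n, n))
        self.w = Tensor(w * norm / np.linalg.norm(w))

    def __call__(self, x):
        return (x * self.w).sum(axis=(1, 2, 3)).reshape(x.shape[0], 1)

    def parameters(self):
        return [self.w]


def random_batches(n, b=4, seed=0):
    rng = np.random.default_rng(seed)
    return (
        matrices_to_batch(rng.random((b, n, n))),
        matrices_to_batch(rng.random((b, n, n))),
        rng,
    )


class TestGradientPenalty:
    def test_unit_norm_linear_critic_has_zero_penalty(self):
        xr, xf, rng = random_batches(6)
        gp = gradient_penalty(LinearCritic(6, 1.0), xr, xf, rng)
        assert float(gp.data) == pytest.approx(0.0, abs=1e-6)

    def test_norm_three_linear_critic_penalty_is_four(self):
        xr, xf, rng = random_batches(6, seed=1)
        gp = gradient_penalty(LinearCritic(6, 3.0), xr, xf, rng)
        assert float(gp.data) == pytest.approx(4.0, abs=1e-6)

    def test_penalty_nonnegative_for_random_critics(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            critic = build_critic(NetworkSpec.small(6), rng).eval()
            xr, xf, rng2 = random_batches(6, seed=seed + 100)
            assert float(gradient_penalty(critic, xr, xf, rng2).data) >= 0.0

    def test_matches_finite_differences_on_small_critic(self):
        rng = np.random.default_rng(5)
        critic = build_critic(NetworkSpec.small(6), rng).eval()
        xr, xf, _ = random_batches(6, b=2, seed=6)

        def gp():
            return gradient_penalty(critic, xr, xf, np.random.default_rng(7))

        params = critic.parameters()
        analytic = grad(gp(), params)
        rng2 = np.random.default_rng(8)
        for pi in rng2.choice(len(params), 4, replace=False):
            flat = params[pi].data.ravel()
            idx = int(rng2.integers(flat.size))
            orig = flat[idx]
            eps = 1e-6
            flat[idx] = orig + eps
            up = float(gp().data)
            flat[idx] = orig - eps
            dn = float(gp().data)
            flat[idx] = orig
            fd = (up - dn) / (2 * eps)
            assert analytic[pi].data.ravel()[idx] == pytest.approx(fd, abs=1e-3)

    def test_shape_mismatch_rejected(self):
        xr, _, rng = random_batches(6)
        xf = matrices_to_batch(np.random.default_rng(0).random((2, 6, 6)))
        with pytest.raises(ValueError):
            gradient_penalty(LinearCritic(6, 1.0), xr, xf, rng)


class TestLosses:
    def test_constant_critic_loss_reduces_to_penalty_term(self):
        class Const:
            def __call__(self, x):
                return Tensor(np.full((x.shape[0], 1), 3.0))

        xr, xf, rng = random_batches(5)
        lam = 7.0
        # constant critic: zero Wasserstein gap, zero gradient -> penalty 1
        loss = critic_loss(Const(), xr, xf, lam, rng)
        assert float(loss.data) == pytest.approx(lam * 1.0)

    def test_sum_critic_matches_hand_computation_without_penalty(self):
        xr, xf, rng = random_batches(4, b=3, seed=2)
        loss = critic_loss(LinearCritic(4, 4.0), xr, xf, gp_lambda=0.0, rng=rng)
        w = LinearCritic(4, 4.0).w.data
        hand = -(np.mean((xr.data * w).sum(axis=(1, 2, 3)))
                 - np.mean((xf.data * w).sum(axis=(1, 2, 3))))
        assert float(loss.data) == pytest.approx(hand, rel=1e-12)

    def test_generator_loss_decreases_as_critic_scores_fakes_higher(self):
        xf = matrices_to_batch(np.random.default_rng(3).random((4, 5, 5)))
        low = generator_adv_loss(LinearCritic(5, 1.0), xf)
        high = generator_adv_loss(LinearCritic(5, 2.0), xf)
        assert float(high.data) < float(low.data)


class TestRegressorLoss:
    def test_exact_values(self):
        assert regressor_loss([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert regressor_loss([0.0, 0.0], [3.0, 4.0]) == pytest.approx(
            np.sqrt(12.5)
        )
        assert regressor_loss([0.0, 0.0], [3.0, 4.0], sum_squares=True) == 25.0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=6), rng.normal(size=6)
        for c in (-2.0, 0.5):
            assert regressor_loss(c * a, c * b) == pytest.approx(
                abs(c) * regressor_loss(a, b)
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            regressor_loss([], [])

    def test_tensor_path_matches_numpy(self):
        y, p = np.array([1.0, 4.0, 2.0]), np.array([0.5, 3.0, 2.5])
        t = regressor_loss(Tensor(y), Tensor(p))
        assert float(t.data) == pytest.approx(regressor_loss(y, p), abs=1e-7)


@pytest.fixture(scope="module")
def splits(tiny_dataset):
    dataset, _ = tiny_dataset
    return split_dataset(dataset, rank_interleaved_split(dataset))


class TestTraining:
    def test_plain_wgan_gp_builds_no_regressor(self, splits):
        tr, va = splits
        model = train(
            tr, va, NetworkSpec.small(12),
            TrainConfig(batch_size=4, max_epochs=2, critic_steps_per_gen=1,
                        task_alpha=0.0, seed=0),
        )
        assert model.regressor is None
        assert not model.task_guided
        assert "val_reg_loss" not in model.training_log.columns

    def test_training_is_bit_reproducible(self, splits):
        tr, va = splits
        cfg = TrainConfig(batch_size=4, max_epochs=3, critic_steps_per_gen=1,
                          task_alpha=0.5, seed=11)
        m1 = train(tr, va, NetworkSpec.small(12), cfg)
        m2 = train(tr, va, NetworkSpec.small(12), cfg)
        for p1, p2 in zip(m1.encoder.parameters(), m2.encoder.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)
        pd.testing.assert_frame_equal(m1.training_log, m2.training_log)

    def test_early_stopping_triggers_after_warmup_with_flat_loss(self, splits):
        # zero learning rate freezes every loss; the patience counter fills
        # long before the warm-up gate opens, so training halts exactly there
        tr, va = splits
        cfg = TrainConfig(learning_rate=1e-30, batch_size=4, max_epochs=50,
                          critic_steps_per_gen=1, warmup_epochs=7, patience=3,
                          task_alpha=0.5, seed=1)
        model = train(tr, va, NetworkSpec.small(12), cfg)
        assert len(model.training_log) == 7
        assert model.best_epoch == 1

    def test_reconstruction_error_drops_during_training(self):
        cfg_data = SyntheticConfig(n_subjects=40, n_nodes=30, seed=21)
        dataset, _ = generate_dataset(cfg_data)
        tr, va = split_dataset(dataset, rank_interleaved_split(dataset))
        model = train(
            tr, va, NetworkSpec.small(30),
            TrainConfig(learning_rate=5e-4, batch_size=2, max_epochs=100,
                        critic_steps_per_gen=1, warmup_epochs=100, patience=50,
                        task_alpha=0.5, seed=2),
        )
        log = model.training_log
        assert log["recon_error"].iloc[-1] <= 0.8 * log["recon_error"].iloc[0]

    def test_reconstruct_contract(self, tiny_model, tiny_dataset):
        dataset, _ = tiny_dataset
        for s in dataset.samples[:5]:
            rec = tiny_model.reconstruct(s.matrix)
            assert np.all(np.diag(rec.weights) == 0)
            assert rec.weights.min() >= 0
            rec2 = tiny_model.reconstruct(s.matrix)
            np.testing.assert_array_equal(rec.weights, rec2.weights)

    def test_node_count_mismatch_rejected(self, tiny_model):
        from tggan.data_model import ConnectivityMatrix

        bad = ConnectivityMatrix(weights=np.zeros((5, 5)))
        with pytest.raises(ValueError, match="nodes"):
            tiny_model.reconstruct(bad)

    def test_save_load_roundtrip(self, tiny_model, tiny_dataset, tmp_path):
        dataset, _ = tiny_dataset
        path = tiny_model.save(tmp_path / "model.npz")
        back = TrainedGAN.load(path)
        np.testing.assert_array_equal(
            tiny_model.encode(dataset.matrices()), back.encode(dataset.matrices())
        )
        assert back.task_guided == tiny_model.task_guided
        assert back.y_mean == tiny_model.y_mean


class TestGridSearch:
    def test_single_cell_grid_returns_that_cell(self, splits):
        tr, va = splits
        space = GridSearchSpace(dropout_values=(0.2,), alpha_values=(0.3,))
        res = grid_search(
            space, tr, va, NetworkSpec.small(12),
            TrainConfig(batch_size=4, max_epochs=2, critic_steps_per_gen=1, seed=0),
        )
        assert (res.dropout_p, res.task_alpha) == (0.2, 0.3)
        assert len(res.cells) == 1

    def test_default_grid_has_fifty_cells(self):
        space = GridSearchSpace()
        assert len(space.dropout_values) * len(space.alpha_values) == 50

    def test_injected_unique_minimum_is_selected(self, splits):
        tr, va = splits

        def fake_train(ds_tr, ds_va, spec, cfg):
            # loss landscape with a unique minimum at (0.2, 0.4)
            loss = abs(spec.dropout_p - 0.2) + abs(cfg.task_alpha - 0.4)
            log = pd.DataFrame(
                {"train_reg_loss": [loss / 2], "val_reg_loss": [loss / 2]}
            )
            return type("M", (), {"training_log": log, "best_epoch": 1})()

        space = GridSearchSpace(
            dropout_values=(0.1, 0.2, 0.3), alpha_values=(0.2, 0.4, 0.6)
        )
        res = grid_search(
            space, tr, va, NetworkSpec.small(12), TrainConfig(), train_fn=fake_train
        )
        assert (res.dropout_p, res.task_alpha) == (0.2, 0.4)
        assert len(res.cells) == 9

    def test_ties_break_toward_smaller_dropout_then_alpha(self, splits):
        tr, va = splits

        def flat_train(ds_tr, ds_va, spec, cfg):
            log = pd.DataFrame({"train_reg_loss": [1.0], "val_reg_loss": [1.0]})
            return type("M", (), {"training_log": log, "best_epoch": 1})()

        space = GridSearchSpace(dropout_values=(0.3, 0.1), alpha_values=(0.5, 0.2))
        res = grid_search(
            space, tr, va, NetworkSpec.small(12), TrainConfig(), train_fn=flat_train
        )
        assert (res.dropout_p, res.task_alpha) == (0.1, 0.2)
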