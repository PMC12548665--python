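"""Wasserstein-GAN training with gradient penalty and a task-guided branch.

The generator is an autoencoder pair: an encoder D mapping a connectivity
matrix to a latent code and a decoder G mapping the code back to an edge
vector.  A critic C scores matrices; training maximises over C and minimises
over G the Wasserstein objective

    L_{G,C} = E[C(x)] − E[C(x̃)] − λ·E[(‖∇_x̂ C(x̂)‖₂ − 1)²],

with x̃ = G(D(x)) and x̂ a random convex combination of real and generated
samples.  In task-guided mode an auxiliary regressor R predicts the
cognitive score from the synthesized matrix and its RMSE loss L_R is added
with weight α (min over G and R of L_{G,C} + α·L_R), which pushes the
latent space to encode score-relevant variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional

import json

import numpy as np
import pandas as pd

from ._tensor import Tensor, grad
from .brainnet import NetworkSpec, build_critic, build_decoder, build_encoder, build_regressor
from .data_model import (
    ConnectivityMatrix,
    ConnectomeDataset,
    ScoredSample,
    matricize,
)
from .nn import Adam, Sequential

__all__ = [
    "TrainConfig",
    "GridSearchSpace",
    "TrainedGAN",
    "TaskGuidedGAN",
    "TrainingDiverged",
    "gradient_penalty",
    "critic_loss",
    "generator_adv_loss",
    "regressor_loss",
    "train",
    "grid_search",
    "reconstruct",
]


class TrainingDiverged(RuntimeError):
    """Raised when a forward pass produces NaN; carries the last checkpoint."""

    def __init__(self, message, checkpoint=None):
        super().__init__(message)
        self.checkpoint = checkpoint


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.

    Defaults follow common practice for this model family: Adam with
    β1=0.9, β2=0.999, learning rate 1e-4, batch size 2, up to 2000 epochs,
    early stopping on the validation regressor loss with patience 50 after
    a 500-epoch warm-up; gradient-penalty coefficient 10 and 5 critic
    updates per generator update (canonical WGAN-GP settings).
    """

    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 2
    max_epochs: int = 2000
    gp_lambda: float = 10.0
    task_alpha: float = 0.5
    critic_steps_per_gen: int = 5
    patience: int = 50
    warmup_epochs: int = 500
    seed: int = 0
    sum_squares: bool = False  # use Σ(y−ŷ)² instead of RMSE for the regressor

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs must be > 0")
        if self.task_alpha < 0 or self.gp_lambda < 0:
            raise ValueError("task_alpha and gp_lambda must be >= 0")
        if self.critic_steps_per_gen < 1:
            raise ValueError("critic_steps_per_gen must be >= 1")


@dataclass(frozen=True)
class GridSearchSpace:
    """Hyperparameter grid: dropout rates × task-loss weights α.

    Defaults are the canonical grid: p ∈ {0.1..0.5}, α ∈ {0.1..1.0}.
    """

    dropout_values: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    alpha_values: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 11))

    def __post_init__(self):
        if not self.dropout_values or not self.alpha_values:
            raise ValueError("grid must be non-empty")
        for v in tuple(self.dropout_values) + tuple(self.alpha_values):
            if not (0 < v <= 1):
                raise ValueError(f"grid value {v} outside (0, 1]")


def _edge_embedding(n_nodes: int) -> np.ndarray:
    """Constant matrix mapping an edge vector to a flattened symmetric matrix."""
    n_edges = n_nodes * (n_nodes - 1) // 2
    M = np.zeros((n_edges, n_nodes * n_nodes))
    rows, cols = np.tril_indices(n_nodes, k=-1)
    for e, (i, j) in enumerate(zip(rows, cols)):
        M[e, i * n_nodes + j] = 1.0
        M[e, j * n_nodes + i] = 1.0
    return M


def edges_to_matrix_batch(edges: Tensor, n_nodes: int, embedding=None) -> Tensor:
    """Differentiable matricization: (B, n_edges) -> (B, 1, n, n)."""
    M = Tensor(embedding if embedding is not None else _edge_embedding(n_nodes))
    b = edges.shape[0]
    return (edges @ M).reshape(b, 1, n_nodes, n_nodes)


def matrices_to_batch(weights: np.ndarray) -> Tensor:
    """(N, n, n) numpy -> (N, 1, n, n) graph input."""
    w = np.asarray(weights, dtype=np.float64)
    return Tensor(w[:, None, :, :])


def gradient_penalty(critic, x_real: Tensor, x_fake: Tensor, rng) -> Tensor:
    """Mean over the batch of (‖∇_x̂ C(x̂)‖₂ − 1)².

    x̂ interpolates real and generated samples with a per-sample
    u ~ Uniform(0,1).  Returned as a graph node so it can be differentiated
    with respect to the critic parameters.
    """
    if x_real.shape != x_fake.shape:
        raise ValueError("real and fake batches must share a shape")
    b = x_real.shape[0]
    u = rng.random((b, 1, 1, 1))
    x_hat = Tensor(u) * x_real + Tensor(1.0 - u) * x_fake
    out = critic(x_hat)
    (gx,) = grad(out.sum(), [x_hat])
    sq_norm = (gx ** 2.0).sum(axis=(1, 2, 3))
    norm = (sq_norm + 1e-16) ** 0.5
    return ((norm - 1.0) ** 2.0).mean()


def critic_loss(critic, x_real: Tensor, x_fake: Tensor, gp_lambda: float, rng) -> Tensor:
    """Negated Wasserstein objective plus the gradient penalty (minimised)."""
    wasserstein = critic(x_real).mean() - critic(x_fake).mean()
    loss = -wasserstein
    if gp_lambda > 0:
        loss = loss + gp_lambda * gradient_penalty(critic, x_real, x_fake, rng)
    if not np.all(np.isfinite(loss.data)):
        raise TrainingDiverged("NaN in critic loss")
    return loss


def generator_adv_loss(critic, x_fake: Tensor) -> Tensor:
    """−E[C(x̃)]: decreases as the critic scores fakes higher."""
    loss = -critic(x_fake).mean()
    if not np.all(np.isfinite(loss.data)):
        raise TrainingDiverged("NaN in generator loss")
    return loss


def regressor_loss(y_obs, y_pred, sum_squares: bool = False):
    """Root-mean-squared error between observed and predicted scores.

    With ``sum_squares=True`` returns the plain sum of squared errors
    instead.  Accepts numpy arrays (returns a float) or graph tensors
    (returns a differentiable node).
    """
    if isinstance(y_obs, Tensor) or isinstance(y_pred, Tensor):
        y_obs = y_obs if isinstance(y_obs, Tensor) else Tensor(y_obs)
        y_pred = y_pred if isinstance(y_pred, Tensor) else Tensor(y_pred)
        sq = (y_obs - y_pred) ** 2.0
        if sum_squares:
            return sq.sum()
        return (sq.mean() + 1e-16) ** 0.5
    y_obs = np.asarray(y_obs, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_obs.size == 0 or y_obs.size != y_pred.size:
        raise ValueError("score vectors must be non-empty and equal length")
    if sum_squares:
        return float(np.sum((y_obs - y_pred) ** 2))
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


@dataclass
class TrainedGAN:
    """Fitted encoder/decoder/critic(/regressor) bundle with training log."""

    spec: NetworkSpec
    config: TrainConfig
    encoder: Sequential
    decoder: Sequential
    critic: Sequential
    regressor: Optional[Sequential]
    training_log: pd.DataFrame
    y_mean: float
    y_sd: float
    best_epoch: int
    diverged: bool = False
    _embedding: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self._embedding is None:
            self._embedding = _edge_embedding(self.spec.n_nodes)

    @property
    def task_guided(self) -> bool:
        return self.regressor is not None

    def encode(self, weights: np.ndarray) -> np.ndarray:
        """Latent codes for a stack of matrices (dropout off)."""
        w = np.asarray(weights, dtype=np.float64)
        if w.ndim == 2:
            w = w[None]
        self.encoder.eval()
        return self.encoder(matrices_to_batch(w)).data

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Edge vectors decoded from latent codes, shape (N, n_edges)."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        self.decoder.eval()
        return self.decoder(Tensor(z)).data

    def reconstruct(self, m: ConnectivityMatrix) -> ConnectivityMatrix:
        """G(D(x)) for a single matrix."""
        if m.n_nodes != self.spec.n_nodes:
            raise ValueError(
                f"model built for {self.spec.n_nodes} nodes, got {m.n_nodes}"
            )
        edges = self.decode(self.encode(m.weights))[0]
        return matricize(edges, node_labels=m.node_labels)

    def reconstruct_dataset(self, d: ConnectomeDataset) -> ConnectomeDataset:
        """Synthesize G(D(x)) for every subject, keeping scores and order."""
        edges = self.decode(self.encode(d.matrices()))
        samples = tuple(
            ScoredSample(
                matrix=matricize(edges[i], node_labels=s.matrix.node_labels),
                score=s.score,
                subject_id=f"{s.subject_id}_syn",
                synthetic=True,
            )
            for i, s in enumerate(d.samples)
        )
        return ConnectomeDataset(samples, atlas_name=d.atlas_name)

    def summary(self) -> str:
        mode = "task-guided (TG GAN II)" if self.task_guided else "WGAN-GP"
        log = self.training_log
        lines = [
            f"{mode}: {self.spec.n_nodes} nodes, latent dim {self.spec.latent_dim}",
            f"epochs run: {len(log)}, checkpoint epoch: {self.best_epoch}",
        ]
        if len(log):
            last = log.iloc[-1]
            lines.append(
                f"final critic loss {last['critic_loss']:.4f}, "
                f"generator adv loss {last['gen_adv_loss']:.4f}"
            )
            if self.task_guided:
                lines.append(
                    f"validation regressor loss at checkpoint: "
                    f"{log['val_reg_loss'].iloc[self.best_epoch - 1]:.4f}"
                )
            lines.append(
                f"reconstruction error: {log['recon_error'].iloc[0]:.4f} -> "
                f"{last['recon_error']:.4f}"
            )
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "spec": _spec_to_dict(self.spec),
            "config": self.config.__dict__,
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "best_epoch": self.best_epoch,
            "task_guided": self.task_guided,
            "diverged": self.diverged,
        }
        arrays = {}
        for name, mod in self._named_modules():
            for i, a in enumerate(mod.state_arrays()):
                arrays[f"{name}_{i}"] = a
        np.savez(path, meta=json.dumps(meta), **arrays)
        self.training_log.to_csv(path.with_suffix(".log.csv"), index=False)
        return path

    def _named_modules(self):
        mods = [("encoder", self.encoder), ("decoder", self.decoder), ("critic", self.critic)]
        if self.regressor is not None:
            mods.append(("regressor", self.regressor))
        return mods

    @classmethod
    def load(cls, path: str | Path) -> "TrainedGAN":
        path = Path(path)
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            spec = NetworkSpec(**meta["spec"])
            cfg = TrainConfig(**meta["config"])
            rng = np.random.default_rng(0)
            encoder = build_encoder(spec, rng)
            decoder = build_decoder(spec, rng)
            critic = build_critic(spec, rng)
            regressor = build_regressor(spec, rng) if meta["task_guided"] else None
            for name, mod in [
                ("encoder", encoder),
                ("decoder", decoder),
                ("critic", critic),
            ] + ([("regressor", regressor)] if regressor else []):
                n = len(mod.parameters())
                mod.load_state_arrays([data[f"{name}_{i}"] for i in range(n)])
        log_path = path.with_suffix(".log.csv")
        log = pd.read_csv(log_path) if log_path.exists() else pd.DataFrame()
        return cls(
            spec=spec,
            config=cfg,
            encoder=encoder,
            decoder=decoder,
            critic=critic,
            regressor=regressor,
            training_log=log,
            y_mean=meta["y_mean"],
            y_sd=meta["y_sd"],
            best_epoch=meta["best_epoch"],
            diverged=meta["diverged"],
        )


def _spec_to_dict(spec: NetworkSpec) -> dict:
    d = dict(spec.__dict__)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def reconstruct(model: TrainedGAN, x: ConnectivityMatrix) -> ConnectivityMatrix:
    """Functional alias for :meth:`TrainedGAN.reconstruct`."""
    return model.reconstruct(x)


def _batched_forward(module, X: Tensor, batch: int = 64) -> np.ndarray:
    outs = []
    for start in range(0, X.shape[0], batch):
        outs.append(module(Tensor(X.data[start : start + batch])).data)
    return np.concatenate(outs, axis=0)


def train(
    dataset_train: ConnectomeDataset,
    dataset_val: ConnectomeDataset,
    spec: NetworkSpec,
    cfg: TrainConfig,
    progress: Callable[[int, dict], None] | None = None,
) -> TrainedGAN:
    """Alternating WGAN-GP / task-guided optimisation.

    Per generator step the critic is updated ``critic_steps_per_gen`` times.
    In task-guided mode (``task_alpha > 0``) training early-stops when the
    validation regressor loss has not improved for ``patience`` consecutive
    epochs once ``warmup_epochs`` epochs have been reached, and the returned
    model is the checkpoint with the best validation regressor loss; in
    plain WGAN-GP mode it runs ``max_epochs`` and returns the final model.
    Scores are z-scored internally (training-set statistics) so the RMSE
    term is on a comparable scale to the adversarial term.
    """
    if dataset_train.n_nodes != spec.n_nodes or dataset_val.n_nodes != spec.n_nodes:
        raise ValueError("dataset node count does not match spec.n_nodes")
    task = cfg.task_alpha > 0
    root = np.random.SeedSequence(cfg.seed)
    init_ss, drop_ss, shuffle_ss, gp_ss = root.spawn(4)
    init_rng = np.random.default_rng(init_ss)
    drop_rng = np.random.default_rng(drop_ss)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    gp_rng = np.random.default_rng(gp_ss)

    encoder = build_encoder(spec, init_rng)
    decoder = build_decoder(spec, init_rng)
    critic = build_critic(spec, init_rng)
    regressor = build_regressor(spec, init_rng) if task else None
    # a single dropout RNG drives all stochastic masks
    for mod in [encoder, decoder, critic] + ([regressor] if regressor else []):
        for sub in mod.modules():
            if hasattr(sub, "rng") and hasattr(sub, "p"):
                sub.rng = drop_rng

    emb = _edge_embedding(spec.n_nodes)
    X = matrices_to_batch(dataset_train.matrices())
    Xv = matrices_to_batch(dataset_val.matrices())
    y_mean = float(dataset_train.scores.mean())
    y_sd = float(dataset_train.scores.std()) or 1.0
    y = Tensor(((dataset_train.scores - y_mean) / y_sd)[:, None])
    yv = ((dataset_val.scores - y_mean) / y_sd)[:, None]

    n = len(dataset_train)
    critic_opt = Adam(critic.parameters(), cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)
    gen_params = encoder.parameters() + decoder.parameters()
    if regressor is not None:
        gen_params = gen_params + regressor.parameters()
    gen_opt = Adam(gen_params, cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)

    records = []
    best_val = np.inf
    best_epoch = 0
    best_state = None
    bad_epochs = 0
    diverged = False

    def snapshot():
        return [
            m.state_arrays()
            for m in [encoder, decoder, critic] + ([regressor] if regressor else [])
        ]

    def restore(state):
        mods = [encoder, decoder, critic] + ([regressor] if regressor else [])
        for m, s in zip(mods, state):
            m.load_state_arrays(s)

    for epoch in range(1, cfg.max_epochs + 1):
        order = shuffle_rng.permutation(n)
        c_losses, g_losses, r_losses = [], [], []
        try:
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = Tensor(X.data[idx])
                yb = Tensor(y.data[idx])
                # --- critic updates (generator frozen: fake batch detached)
                with_fake = decoder(encoder(xb))
                x_fake_const = Tensor(
                    edges_to_matrix_batch(with_fake, spec.n_nodes, emb).data
                )
                for _ in range(cfg.critic_steps_per_gen):
                    c_loss = critic_loss(critic, xb, x_fake_const, cfg.gp_lambda, gp_rng)
                    critic_opt.step(grad(c_loss, critic.parameters()))
                c_losses.append(float(c_loss.data))
                # --- generator (+ regressor) update
                z = encoder(xb)
                x_fake = edges_to_matrix_batch(decoder(z), spec.n_nodes, emb)
                g_loss = generator_adv_loss(critic, x_fake)
                if task:
                    y_pred = regressor(x_fake)
                    r_loss = regressor_loss(yb, y_pred, cfg.sum_squares)
                    total = g_loss + cfg.task_alpha * r_loss
                    r_losses.append(float(r_loss.data))
                else:
                    total = g_loss
                gen_opt.step(grad(total, gen_params))
                g_losses.append(float(g_loss.data))
        except TrainingDiverged:
            diverged = True

        # --- end-of-epoch evaluation (dropout off)
        for m in [encoder, decoder, critic] + ([regressor] if regressor else []):
            m.eval()
        recon_edges = _batched_forward(Sequential(encoder, decoder), X)
        recon = recon_edges @ emb  # (N, n*n)
        flat_x = X.data.reshape(n, -1)
        recon_error = float(np.mean(np.linalg.norm(flat_x - recon, axis=1)))
        record = {
            "epoch": epoch,
            "critic_loss": float(np.mean(c_losses)) if c_losses else np.nan,
            "gen_adv_loss": float(np.mean(g_losses)) if g_losses else np.nan,
            "recon_error": recon_error,
        }
        if task:
            pred_tr = regressor(
                edges_to_matrix_batch(Tensor(recon_edges), spec.n_nodes, emb)
            ).data
            train_reg = regressor_loss(y.data.ravel(), pred_tr.ravel(), cfg.sum_squares)
            rec_val = _batched_forward(Sequential(encoder, decoder), Xv)
            pred_val = regressor(
                edges_to_matrix_batch(Tensor(rec_val), spec.n_nodes, emb)
            ).data
            val_reg = regressor_loss(yv.ravel(), pred_val.ravel(), cfg.sum_squares)
            record["train_reg_loss"] = train_reg
            record["val_reg_loss"] = val_reg
        for m in [encoder, decoder, critic] + ([regressor] if regressor else []):
            m.train()
        records.append(record)
        if progress is not None:
            progress(epoch, record)

        if diverged:
            break
        if task:
            if record["val_reg_loss"] < best_val - 1e-12:
                best_val = record["val_reg_loss"]
                best_epoch = epoch
                best_state = snapshot()
                bad_epochs = 0
            else:
                bad_epochs += 1
            if epoch >= cfg.warmup_epochs and bad_epochs >= cfg.patience:
                break
        else:
            best_epoch = epoch

    if task and best_state is not None:
        restore(best_state)
    for m in [encoder, decoder, critic] + ([regressor] if regressor else []):
        m.eval()
    return TrainedGAN(
        spec=spec,
        config=cfg,
        encoder=encoder,
        decoder=decoder,
        critic=critic,
        regressor=regressor,
        training_log=pd.DataFrame(records),
        y_mean=y_mean,
        y_sd=y_sd,
        best_epoch=best_epoch or len(records),
        diverged=diverged,
        _embedding=emb,
    )


@dataclass(frozen=True)
class GridSearchResult:
    dropout_p: float
    task_alpha: float
    cells: pd.DataFrame

    def best_key(self) -> float:
        mask = (self.cells["dropout_p"] == self.dropout_p) & (
            self.cells["task_alpha"] == self.task_alpha
        )
        return float(self.cells.loc[mask, "selection_loss"].iloc[0])


def grid_search(
    space: GridSearchSpace,
    dataset_train: ConnectomeDataset,
    dataset_val: ConnectomeDataset,
    spec: NetworkSpec,
    cfg: TrainConfig,
    train_fn: Callable = train,
) -> GridSearchResult:
    """Exhaustive dropout × α search.

    Selection key: training + validation regressor loss at the stopping
    checkpoint; ties broken by smaller dropout, then smaller α.  The plain
    WGAN-GP baseline is meant to inherit the selected dropout rate.
    """
    rows = []
    for p in space.dropout_values:
        for a in space.alpha_values:
            model = train_fn(
                dataset_train,
                dataset_val,
                replace(spec, dropout_p=p),
                replace(cfg, task_alpha=a),
            )
            log = model.training_log
            at = model.best_epoch - 1
            sel = float(log["train_reg_loss"].iloc[at] + log["val_reg_loss"].iloc[at])
            rows.append({"dropout_p": p, "task_alpha": a, "selection_loss": sel})
    cells = pd.DataFrame(rows)
    ordered = cells.sort_values(
        ["selection_loss", "dropout_p", "task_alpha"], kind="stable"
    )
    best = ordered.iloc[0]
    return GridSearchResult(
        dropout_p=float(best["dropout_p"]),
        task_alpha=float(best["task_alpha"]),
        cells=cells,
    )


class TaskGuidedGAN:
    """Model object: a task-guided (or plain) WGAN-GP for a scored dataset.

    ``fit()`` returns a :class:`TrainedGAN` results object.  When no
    validation set is given, every third rank of the score-sorted training
    data is held out, which keeps the score distributions of the two parts
    aligned.
    """

    def __init__(
        self,
        dataset_train: ConnectomeDataset,
        dataset_val: ConnectomeDataset | None = None,
        spec: NetworkSpec | None = None,
        config: TrainConfig | None = None,
    ):
        if dataset_val is None:
            from .prediction import rank_interleaved_split

            plan = rank_interleaved_split(dataset_train)
            ids = dataset_train.subject_ids
            dataset_val = dataset_train.subset(
                [ids.index(i) for i in plan.holdout_ids]
            )
            dataset_train = dataset_train.subset(
                [ids.index(i) for i in plan.retained_ids]
            )
        self.dataset_train = dataset_train
        self.dataset_val = dataset_val
        self.spec = spec or NetworkSpec.small(dataset_train.n_nodes)
        self.config = config or TrainConfig()

    def fit(self, progress=None) -> TrainedGAN:
        return train(
            self.dataset_train, self.dataset_val, self.spec, self.config, progress
        )
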