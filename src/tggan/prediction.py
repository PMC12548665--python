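"""Connectome-based prediction benchmark with repeated nested CV.

The protocol: sort subjects by score and hold out every third rank so the
score distributions of the retained and held-out sets match; on the
retained (discovery) set run 20 repeats of an outer 5-fold CV whose inner
5-fold CV tunes the regularisation of a Ridge (or Elastic-Net) model on
vectorized edge features; validate all 100 resulting models on the fixed
test set (Pearson r and RMSE); compare augmented against baseline model
populations with Welch's t test after 3-SD outlier removal and Bonferroni
correction; and summarise edge-weight reliability as the per-edge mean and
95% percentile confidence interval across the 100 models.

Synthetic (interpolated) samples are only ever added to training folds —
never to validation folds or the test set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import ElasticNet, Ridge
from sklearn.model_selection import KFold

from .data_model import ConnectomeDataset

__all__ = [
    "SplitPlan",
    "CVConfig",
    "CVResult",
    "rank_interleaved_split",
    "inner_tune",
    "repeated_nested_cv",
    "evaluate_test",
    "compare_accuracy",
    "weight_reliability",
    "latent_pca",
    "ConnectomePredictor",
    "RIDGE_ALPHAS",
    "ENET_ALPHAS",
    "ENET_L1_RATIOS",
]

RIDGE_ALPHAS = tuple(2.0 ** n for n in range(-10, 6))  # 16 values
ENET_ALPHAS = tuple(2.0 ** (2 * n) for n in range(-5, 5))  # 10 values
ENET_L1_RATIOS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class SplitPlan:
    """Rank-interleaved partition of subject ids."""

    retained_ids: tuple[str, ...]
    holdout_ids: tuple[str, ...]
    rule: str

    def __post_init__(self):
        if set(self.retained_ids) & set(self.holdout_ids):
            raise ValueError("retained and holdout sets overlap")


def rank_interleaved_split(
    d: ConnectomeDataset, holdout_stride: int = 3, offset: int = 0
) -> SplitPlan:
    """Hold out every ``holdout_stride``-th rank of the score-sorted samples.

    With the default stride 3 and offset 0, ranks 1, 4, 7, ... (1-based)
    go to the held-out set and the rest are retained, which keeps the score
    distributions of the two parts similar.
    """
    if len(d) < holdout_stride:
        raise ValueError("dataset smaller than the holdout stride")
    order = sorted(range(len(d)), key=lambda i: (d[i].score, d[i].subject_id))
    holdout, retained = [], []
    for rank0, idx in enumerate(order):
        if rank0 % holdout_stride == offset % holdout_stride:
            holdout.append(d[idx].subject_id)
        else:
            retained.append(d[idx].subject_id)
    return SplitPlan(
        retained_ids=tuple(retained),
        holdout_ids=tuple(holdout),
        rule=f"every {holdout_stride}-th rank (offset {offset}) held out",
    )


def split_dataset(d: ConnectomeDataset, plan: SplitPlan):
    ids = list(d.subject_ids)
    retained = d.subset([ids.index(i) for i in plan.retained_ids])
    holdout = d.subset([ids.index(i) for i in plan.holdout_ids])
    return retained, holdout


@dataclass(frozen=True)
class CVConfig:
    """Nested-CV settings: 20 repeats × outer 5-fold, inner 5-fold tuning."""

    n_outer_folds: int = 5
    n_repeats: int = 20
    n_inner_folds: int = 5
    regressor: str = "ridge"  # "ridge" | "elastic_net"
    ridge_alphas: tuple[float, ...] = RIDGE_ALPHAS
    enet_alphas: tuple[float, ...] = ENET_ALPHAS
    enet_l1_ratios: tuple[float, ...] = ENET_L1_RATIOS
    seed: int = 0

    def __post_init__(self):
        if self.regressor not in ("ridge", "elastic_net"):
            raise ValueError("regressor must be 'ridge' or 'elastic_net'")
        if not self.ridge_alphas or not self.enet_alphas or not self.enet_l1_ratios:
            raise ValueError("hyperparameter grids must be non-empty")

    def grid(self) -> list[dict]:
        if self.regressor == "ridge":
            return [{"alpha": a} for a in sorted(self.ridge_alphas)]
        return [
            {"alpha": a, "l1_ratio": r}
            for a in sorted(self.enet_alphas)
            for r in sorted(self.enet_l1_ratios)
        ]

    def make_model(self, params: dict):
        if self.regressor == "ridge":
            return Ridge(alpha=params["alpha"])
        return ElasticNet(
            alpha=params["alpha"], l1_ratio=params["l1_ratio"], max_iter=5000
        )


@dataclass
class CVResult:
    """100 (= repeats × outer folds) fitted models and their metrics."""

    config: CVConfig
    records: pd.DataFrame  # repeat, fold, params, val_r, val_mae, n_train
    weights: np.ndarray  # (n_models, n_edges)
    intercepts: np.ndarray
    feature_means: np.ndarray  # per-model standardisation statistics
    feature_sds: np.ndarray

    def __post_init__(self):
        expected = self.config.n_repeats * self.config.n_outer_folds
        if len(self.records) != expected:
            raise ValueError(
                f"expected {expected} model records, got {len(self.records)}"
            )

    @property
    def n_models(self) -> int:
        return len(self.records)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predictions of every model on raw edge features, (n_models, N)."""
        Xs = (X[None, :, :] - self.feature_means[:, None, :]) / self.feature_sds[
            :, None, :
        ]
        return np.einsum("mne,me->mn", Xs, self.weights) + self.intercepts[:, None]

    def summary(self) -> str:
        r = self.records
        lines = [
            f"{self.config.regressor} nested CV: "
            f"{self.config.n_repeats} repeats x {self.config.n_outer_folds} folds "
            f"= {self.n_models} models",
            f"validation r: {r['val_r'].mean():.3f} ± {r['val_r'].std(ddof=1):.3f}",
            f"validation MAE: {r['val_mae'].mean():.3f} ± {r['val_mae'].std(ddof=1):.3f}",
        ]
        return "\n".join(lines)


def _safe_pearson(y_true, y_pred) -> tuple[float, bool]:
    """Pearson r with degenerate (constant) predictions reported as 0."""
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        return 0.0, True
    return float(np.corrcoef(y_true, y_pred)[0, 1]), False


def inner_tune(X: np.ndarray, y: np.ndarray, cfg: CVConfig, seed: int) -> dict:
    """Inner 5-fold grid search.

    For each grid point the fold-mean Pearson r and fold-mean MAE are
    computed; r and 1/MAE are z-scored across grid points and summed, and
    the argmax wins (ties go to the smaller regularisation, i.e. earlier
    grid order).
    """
    if len(y) < 10:
        raise ValueError("need at least 10 samples for inner tuning")
    grid = cfg.grid()
    kf = KFold(n_splits=cfg.n_inner_folds, shuffle=True, random_state=seed % 2**31)
    splits = list(kf.split(X))
    mean_r = np.zeros(len(grid))
    mean_mae = np.zeros(len(grid))
    for gi, params in enumerate(grid):
        rs, maes = [], []
        for tr, va in splits:
            model = cfg.make_model(params)
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            model.fit((X[tr] - mu) / sd, y[tr])
            pred = model.predict((X[va] - mu) / sd)
            r, _ = _safe_pearson(y[va], pred)
            rs.append(r)
            maes.append(float(np.mean(np.abs(y[va] - pred))))
        mean_r[gi] = np.mean(rs)
        mean_mae[gi] = np.mean(maes)
    inv_mae = 1.0 / mean_mae
    score = _zscore(mean_r) + _zscore(inv_mae)
    return grid[int(np.argmax(score))]


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def repeated_nested_cv(
    train_data: ConnectomeDataset,
    cfg: CVConfig,
    augmenter: Optional[Callable[[ConnectomeDataset], ConnectomeDataset]] = None,
) -> CVResult:
    """20 × 5 outer CV with inner tuning; synthetic samples train-only.

    Outer folds are formed over the original (non-synthetic) samples.  If
    the dataset already contains synthetic samples, they are appended to
    every training fold; an ``augmenter`` callable may instead synthesize
    them per run.  Edge features are standardized with training-fold
    statistics.
    """
    originals = train_data.originals()
    data = augmenter(originals) if augmenter is not None else train_data
    synth_idx = [i for i, s in enumerate(data.samples) if s.synthetic]
    orig_idx = [i for i, s in enumerate(data.samples) if not s.synthetic]
    X_all = data.edge_matrix()
    y_all = data.scores
    flags = np.array([s.synthetic for s in data.samples])

    ss = np.random.SeedSequence(cfg.seed)
    repeat_seeds = ss.generate_state(cfg.n_repeats * 2)
    records = []
    weights, intercepts, mus, sds = [], [], [], []
    for rep in range(cfg.n_repeats):
        kf = KFold(
            n_splits=cfg.n_outer_folds,
            shuffle=True,
            random_state=int(repeat_seeds[2 * rep] % 2**31),
        )
        for fold, (tr0, va0) in enumerate(kf.split(orig_idx)):
            tr_idx = [orig_idx[i] for i in tr0] + synth_idx
            va_idx = [orig_idx[i] for i in va0]
            if len(va_idx) < 2:
                raise ValueError("validation fold too small")
            assert not flags[va_idx].any(), "synthetic sample leaked into validation"
            X_tr, y_tr = X_all[tr_idx], y_all[tr_idx]
            X_va, y_va = X_all[va_idx], y_all[va_idx]
            params = inner_tune(
                X_tr, y_tr, cfg, seed=int(repeat_seeds[2 * rep + 1] % 2**31) + fold
            )
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0)
            sd[sd == 0] = 1.0
            model = cfg.make_model(params)
            model.fit((X_tr - mu) / sd, y_tr)
            pred = model.predict((X_va - mu) / sd)
            r, degenerate = _safe_pearson(y_va, pred)
            records.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    **{f"param_{k}": v for k, v in params.items()},
                    "val_r": r,
                    "val_r_degenerate": degenerate,
                    "val_mae": float(np.mean(np.abs(y_va - pred))),
                    "n_train": len(tr_idx),
                }
            )
            weights.append(model.coef_.copy())
            intercepts.append(float(model.intercept_))
            mus.append(mu)
            sds.append(sd)
    return CVResult(
        config=cfg,
        records=pd.DataFrame(records),
        weights=np.stack(weights),
        intercepts=np.array(intercepts),
        feature_means=np.stack(mus),
        feature_sds=np.stack(sds),
    )


def evaluate_test(models: CVResult, test_data: ConnectomeDataset) -> pd.DataFrame:
    """Per-model Pearson r and RMSE on the fixed held-out test set."""
    if any(s.synthetic for s in test_data.samples):
        raise ValueError("test set must not contain synthetic samples")
    X = test_data.edge_matrix()
    y = test_data.scores
    preds = models.predict(X)
    rows = []
    for m in range(preds.shape[0]):
        r, degenerate = _safe_pearson(y, preds[m])
        rows.append(
            {
                "model": m,
                "test_r": r,
                "test_r_degenerate": degenerate,
                "test_rmse": float(np.sqrt(np.mean((y - preds[m]) ** 2))),
            }
        )
    return pd.DataFrame(rows)


def summarize_test(table: pd.DataFrame) -> dict:
    return {
        "r_mean": float(table["test_r"].mean()),
        "r_sd": float(table["test_r"].std(ddof=1)),
        "rmse_mean": float(table["test_rmse"].mean()),
        "rmse_sd": float(table["test_rmse"].std(ddof=1)),
        "n_models": int(len(table)),
    }


def _drop_outliers(v: np.ndarray) -> np.ndarray:
    mu, sd = v.mean(), v.std(ddof=1)
    if sd == 0:
        return v
    return v[np.abs(v - mu) <= 3 * sd]


def compare_accuracy(
    group_a, group_b, n_comparisons: int = 1
) -> dict:
    """Welch's t test with single-pass 3-SD outlier removal and Bonferroni.

    Group a is the reference (e.g. baseline), group b the comparison
    (e.g. augmented); the sign of t follows ``b − a``.
    """
    a = np.asarray(group_a, dtype=np.float64).ravel()
    b = np.asarray(group_b, dtype=np.float64).ravel()
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    a_kept = _drop_outliers(a)
    b_kept = _drop_outliers(b)
    if a_kept.size == 0 or b_kept.size == 0:
        raise ValueError("outlier removal emptied a group")
    t, p = stats.ttest_ind(b_kept, a_kept, equal_var=False)
    t, p = float(t), float(p)
    if np.isnan(t):
        # both groups constant: equal means -> no effect, else infinite t
        if np.isclose(a_kept.mean(), b_kept.mean()):
            t, p = 0.0, 1.0
        else:
            t = np.sign(b_kept.mean() - a_kept.mean()) * np.inf
            p = 0.0
    return {
        "t": t,
        "p": p,
        "p_adjusted": min(1.0, p * n_comparisons),
        "n_a": int(a_kept.size),
        "n_b": int(b_kept.size),
        "removed_a": int(a.size - a_kept.size),
        "removed_b": int(b.size - b_kept.size),
        "mean_a": float(a_kept.mean()),
        "mean_b": float(b_kept.mean()),
        "n_comparisons": int(n_comparisons),
    }


def weight_reliability(models: CVResult) -> pd.DataFrame:
    """Per-edge mean and 95% percentile CI across the fitted models."""
    if models.weights.shape[0] < 2:
        raise ValueError("need at least 2 models")
    w = models.weights
    lo = np.percentile(w, 2.5, axis=0)
    hi = np.percentile(w, 97.5, axis=0)
    return pd.DataFrame(
        {
            "edge": np.arange(w.shape[1]),
            "mean": w.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
            "ci_width": hi - lo,
        }
    )


def latent_pca(model, d: ConnectomeDataset) -> dict:
    """PCA of the encoder's latent codes and the PC1–score correlation.

    The PCA is fitted on this subset's latents only.  PC1's sign is
    canonicalized (the largest-magnitude loading is made positive) so the
    reported correlation is deterministic.
    """
    if len(d) < 3:
        raise ValueError("need at least 3 samples")
    z = model.encode(d.matrices())
    if np.allclose(z.std(axis=0), 0):
        raise ValueError("zero-variance latent codes")
    pca = PCA(n_components=2)
    proj = pca.fit_transform(z)
    for k in range(2):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            proj[:, k] = -proj[:, k]
    r, p = stats.pearsonr(proj[:, 0], d.scores)
    return {
        "projections": proj,
        "pc1_score_r": float(r),
        "p_value": float(p),
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
    }


class ConnectomePredictor:
    """Model object: nested-CV edge-based prediction of a cognitive score.

    ``fit()`` runs the repeated nested CV on the (optionally augmented)
    dataset and returns a :class:`CVResult`.
    """

    def __init__(self, dataset: ConnectomeDataset, config: CVConfig | None = None):
        self.dataset = dataset
        self.config = config or CVConfig()

    def fit(self, augmenter=None) -> CVResult:
        return repeated_nested_cv(self.dataset, self.config, augmenter)
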