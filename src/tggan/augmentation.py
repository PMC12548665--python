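"""Data augmentation by latent-space interpolation between score neighbours.

New samples are synthesized from pairs of real samples that are adjacent
when sorted by cognitive score: the pair's latent codes are combined
convexly, z_s = ε·D(X_i) + (1−ε)·D(X_j), decoded to a matrix X_s = G(z_s),
and the score is interpolated with the same coefficient,
y_s = ε·y_i + (1−ε)·y_j.  Doubling a 75-sample set this way yields
75 + 74 = 149 samples (one midpoint per adjacent pair), quintupling
75 + 4·74 = 371.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ConnectomeDataset, ScoredSample, matricize
from .gan import TrainedGAN

__all__ = ["AugmentationPlan", "neighbor_pairs", "interpolate_pair", "augment"]


@dataclass(frozen=True)
class AugmentationPlan:
    """Which pairs to interpolate and at which ε values."""

    pairs: tuple[tuple[int, int], ...]
    epsilons_per_pair: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        for (i, j), eps in zip(self.pairs, self.epsilons_per_pair):
            if i == j:
                raise ValueError("pair must reference distinct samples")
            for e in eps:
                if not (0 < e < 1):
                    raise ValueError(f"epsilon {e} must be strictly inside (0, 1)")

    @property
    def total_synthesized(self) -> int:
        return sum(len(e) for e in self.epsilons_per_pair)


def _score_order(d: ConnectomeDataset) -> list[int]:
    # stable sort on (score, subject_id) so ties are deterministic
    return sorted(range(len(d)), key=lambda i: (d[i].score, d[i].subject_id))


def neighbor_pairs(d: ConnectomeDataset) -> tuple[tuple[int, int], ...]:
    """The N−1 consecutive pairs of the score-sorted samples.

    Returned as pairs of original indices, lower-score sample first.
    """
    if len(d) < 2:
        raise ValueError("need at least two samples to form pairs")
    order = _score_order(d)
    return tuple((order[k], order[k + 1]) for k in range(len(order) - 1))


def interpolate_pair(
    model: TrainedGAN, a: ScoredSample, b: ScoredSample, eps: float
) -> ScoredSample:
    """One synthesized sample on the latent segment between ``a`` and ``b``.

    ε = 1 reproduces ``a``'s latent code and score, ε = 0 reproduces ``b``'s.
    """
    if not (0 <= eps <= 1):
        raise ValueError("eps must lie in [0, 1]")
    if a.matrix.n_nodes != model.spec.n_nodes:
        raise ValueError("node count does not match the model")
    za = model.encode(a.matrix.weights)[0]
    zb = model.encode(b.matrix.weights)[0]
    z = eps * za + (1.0 - eps) * zb
    edges = model.decode(z)[0]
    matrix = matricize(edges, node_labels=a.matrix.node_labels)
    score = eps * a.score + (1.0 - eps) * b.score
    return ScoredSample(
        matrix=matrix,
        score=float(score),
        subject_id=f"syn_{a.subject_id}_{b.subject_id}_{eps:.4f}",
        synthetic=True,
    )


def build_plan(
    d: ConnectomeDataset,
    per_pair_count: int | None = None,
    target_total: int | None = None,
) -> AugmentationPlan:
    """ε assignment for the two augmentation modes.

    per-pair mode: each pair contributes k samples at ε = t/(k+1); the
    endpoints are excluded because they would duplicate real samples.
    target-total mode: the m−N synthesized samples are distributed
    round-robin across pairs in sorted order, with ε equally spaced within
    each pair.
    """
    pairs = neighbor_pairs(d)
    if (per_pair_count is None) == (target_total is None):
        raise ValueError("give exactly one of per_pair_count / target_total")
    counts = np.zeros(len(pairs), dtype=int)
    if per_pair_count is not None:
        if per_pair_count < 1:
            raise ValueError("per_pair_count must be >= 1")
        counts[:] = per_pair_count
    else:
        extra = target_total - len(d)
        if extra <= 0:
            raise ValueError("target_total must exceed the dataset size")
        counts += extra // len(pairs)
        counts[: extra % len(pairs)] += 1
    epsilons = tuple(
        tuple((t + 1) / (k + 1) for t in range(k)) for k in counts
    )
    return AugmentationPlan(pairs=pairs, epsilons_per_pair=epsilons)


def augment(
    d: ConnectomeDataset,
    model: TrainedGAN,
    per_pair_count: int | None = None,
    target_total: int | None = None,
) -> ConnectomeDataset:
    """Append interpolated samples to the dataset.

    The original samples are retained bit-identically; synthesized samples
    carry ``synthetic=True`` so later cross-validation can keep them out of
    validation and test folds.
    """
    plan = build_plan(d, per_pair_count=per_pair_count, target_total=target_total)
    # encode every subject once
    latents = model.encode(d.matrices())
    new_samples = []
    for (i, j), eps_list in zip(plan.pairs, plan.epsilons_per_pair):
        if not eps_list:
            continue
        zi, zj = latents[i], latents[j]
        zs = np.stack([e * zi + (1 - e) * zj for e in eps_list])
        edge_batch = model.decode(zs)
        for e, edges in zip(eps_list, edge_batch):
            sid_a, sid_b = d[i].subject_id, d[j].subject_id
            new_samples.append(
                ScoredSample(
                    matrix=matricize(
                        edges, node_labels=d[i].matrix.node_labels
                    ),
                    score=float(e * d[i].score + (1 - e) * d[j].score),
                    subject_id=f"syn_{sid_a}_{sid_b}_{e:.4f}",
                    synthetic=True,
                )
            )
    return ConnectomeDataset(
        d.samples + tuple(new_samples), atlas_name=d.atlas_name
    )
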