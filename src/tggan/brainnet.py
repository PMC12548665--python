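"""BrainNetCNN operators and the four network roles of the task-guided GAN.

The three graph convolutions act directly on adjacency matrices:

* edge-to-edge (E2E): a cross-shaped filter combining an element's entire
  row and column, ``out(i,j) = Σ_k r_k x(i,k) + Σ_k c_k x(k,j) + b``;
* edge-to-node (E2N): a weighted sum of each region's incident edges,
  ``out(i) = Σ_j r_j x(i,j) + Σ_j c_j x(j,i) + b``;
* node-to-graph (N2G): weighted integration of node values to a scalar.

The functional forms here are single-filter reference implementations on
plain numpy arrays; the trainable multi-channel layers live in
:mod:`tggan.nn`.  Four builders assemble the roles used by the GAN:

* encoder — E2E, E2E, E2N, N2G (four convolutions) + two fully connected
  layers down to the latent dimension;
* decoder — a five-layer MLP from the latent space to the lower-triangle
  edge vector, with a final softplus so edge weights are non-negative;
* critic — the four-convolution stack + a linear scalar head with no output
  activation (a Wasserstein critic must be unbounded);
* regressor — four convolutions + four fully connected layers to a scalar
  cognitive-score prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Dropout,
    E2EConv,
    E2NConv,
    Linear,
    Module,
    N2GPool,
    Sequential,
    leaky_relu_layer,
    softplus_layer,
)

__all__ = [
    "E2EFilter",
    "NetworkSpec",
    "e2e_apply",
    "e2n_apply",
    "n2g_apply",
    "build_encoder",
    "build_decoder",
    "build_critic",
    "build_regressor",
]


@dataclass(frozen=True)
class E2EFilter:
    row_weights: np.ndarray
    col_weights: np.ndarray
    bias: float = 0.0

    def __post_init__(self):
        r = np.asarray(self.row_weights, dtype=np.float64)
        c = np.asarray(self.col_weights, dtype=np.float64)
        if r.shape != c.shape or r.ndim != 1:
            raise ValueError("row/col weights must be equal-length vectors")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(c)) and np.isfinite(self.bias)):
            raise ValueError("filter weights must be finite")
        object.__setattr__(self, "row_weights", r)
        object.__setattr__(self, "col_weights", c)


def _check_square(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {x.shape}")
    return x


def e2e_apply(x, f: E2EFilter) -> np.ndarray:
    """out(i,j) = Σ_k row_k·x(i,k) + Σ_k col_k·x(k,j) + bias."""
    x = _check_square(x)
    if f.row_weights.size != x.shape[0]:
        raise ValueError("filter length must match matrix size")
    row_term = x @ f.row_weights  # (n,) indexed by i
    col_term = f.col_weights @ x  # (n,) indexed by j
    return row_term[:, None] + col_term[None, :] + f.bias


def e2n_apply(x, row_weights, col_weights, bias=0.0) -> np.ndarray:
    """out(i) = Σ_j row_j·x(i,j) + Σ_j col_j·x(j,i) + bias."""
    x = _check_square(x)
    r = np.asarray(row_weights, dtype=np.float64)
    c = np.asarray(col_weights, dtype=np.float64)
    if r.size != x.shape[0] or c.size != x.shape[0]:
        raise ValueError("weight length must match matrix size")
    return x @ r + x.T @ c + bias


def n2g_apply(v, weights, bias=0.0) -> float:
    """Weighted sum of node values plus bias."""
    v = np.asarray(v, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if v.shape != w.shape:
        raise ValueError(f"length mismatch: {v.shape} vs {w.shape}")
    return float(v @ w + bias)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters shared by the four network roles.

    ``fc_widths_encoder`` are the two fully connected widths after the
    convolution stack (the last must equal ``latent_dim``);
    ``fc_widths_decoder`` are the five decoder widths (the last must equal
    the edge-vector length n(n-1)/2); ``fc_widths_regressor`` are the four
    regressor widths (the last must be 1).
    """

    n_nodes: int
    latent_dim: int = 64
    e2e_channels: tuple[int, int] = (32, 64)
    e2n_channels: int = 128
    n2g_units: int = 256
    fc_widths_encoder: tuple[int, ...] = ()
    fc_widths_decoder: tuple[int, ...] = ()
    fc_widths_regressor: tuple[int, ...] = ()
    dropout_p: float = 0.1

    def __post_init__(self):
        n_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if not self.fc_widths_encoder:
            object.__setattr__(
                self, "fc_widths_encoder", (2 * self.latent_dim, self.latent_dim)
            )
        if not self.fc_widths_decoder:
            object.__setattr__(
                self,
                "fc_widths_decoder",
                (128, 256, 256, 512, n_edges),
            )
        if not self.fc_widths_regressor:
            object.__setattr__(self, "fc_widths_regressor", (128, 64, 32, 1))
        if len(self.fc_widths_encoder) != 2:
            raise ValueError("encoder needs exactly two fully connected widths")
        if self.fc_widths_encoder[-1] != self.latent_dim:
            raise ValueError("last encoder fc width must equal latent_dim")
        if len(self.fc_widths_decoder) != 5:
            raise ValueError("decoder needs exactly five fully connected widths")
        if self.fc_widths_decoder[-1] != n_edges:
            raise ValueError(
                f"last decoder width must be n(n-1)/2 = {n_edges}"
            )
        if len(self.fc_widths_regressor) != 4 or self.fc_widths_regressor[-1] != 1:
            raise ValueError("regressor needs four fc widths ending in 1")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must be in [0, 1)")
        if min(self.e2e_channels) < 1 or self.e2n_channels < 1 or self.n2g_units < 1:
            raise ValueError("channel widths must be positive")

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @classmethod
    def small(cls, n_nodes: int, latent_dim: int = 16) -> "NetworkSpec":
        """A light desk-scale spec for CPU experiments and tests."""
        n_edges = n_nodes * (n_nodes - 1) // 2
        return cls(
            n_nodes=n_nodes,
            latent_dim=latent_dim,
            e2e_channels=(4, 8),
            e2n_channels=16,
            n2g_units=32,
            fc_widths_encoder=(32, latent_dim),
            fc_widths_decoder=(32, 64, 64, 128, n_edges),
            fc_widths_regressor=(32, 16, 8, 1),
        )


def _conv_stack(spec: NetworkSpec, rng, dropout: bool):
    """The shared four-convolution stack: E2E -> E2E -> E2N -> N2G."""
    c1, c2 = spec.e2e_channels
    layers = [
        E2EConv(1, c1, spec.n_nodes, rng),
        leaky_relu_layer(),
    ]
    if dropout:
        layers.append(Dropout(spec.dropout_p, rng))
    layers += [E2EConv(c1, c2, spec.n_nodes, rng), leaky_relu_layer()]
    if dropout:
        layers.append(Dropout(spec.dropout_p, rng))
    layers += [E2NConv(c2, spec.e2n_channels, spec.n_nodes, rng), leaky_relu_layer()]
    if dropout:
        layers.append(Dropout(spec.dropout_p, rng))
    layers += [
        N2GPool(spec.e2n_channels, spec.n2g_units, spec.n_nodes, rng),
        leaky_relu_layer(),
    ]
    return layers


def build_encoder(spec: NetworkSpec, rng) -> Sequential:
    """Matrix (B,1,n,n) -> latent (B, latent_dim)."""
    w1, w2 = spec.fc_widths_encoder
    layers = _conv_stack(spec, rng, dropout=True)
    layers += [
        Dropout(spec.dropout_p, rng),
        Linear(spec.n2g_units, w1, rng),
        leaky_relu_layer(),
        Linear(w1, w2, rng),  # no activation on the latent code
    ]
    return Sequential(*layers)


def build_decoder(spec: NetworkSpec, rng) -> Sequential:
    """Latent (B, latent_dim) -> edge vector (B, n_edges), non-negative."""
    widths = spec.fc_widths_decoder
    layers = []
    prev = spec.latent_dim
    for w in widths[:-1]:
        layers += [Linear(prev, w, rng), leaky_relu_layer()]
        prev = w
    layers += [Linear(prev, widths[-1], rng), softplus_layer()]
    return Sequential(*layers)


def build_critic(spec: NetworkSpec, rng) -> Sequential:
    """Matrix (B,1,n,n) -> unbounded scalar score (B, 1)."""
    layers = _conv_stack(spec, rng, dropout=True)
    layers += [Dropout(spec.dropout_p, rng), Linear(spec.n2g_units, 1, rng)]
    return Sequential(*layers)


def build_regressor(spec: NetworkSpec, rng) -> Sequential:
    """Matrix (B,1,n,n) -> predicted score (B, 1)."""
    layers = _conv_stack(spec, rng, dropout=True)
    prev = spec.n2g_units
    widths = spec.fc_widths_regressor
    layers.append(Dropout(spec.dropout_p, rng))
    for w in widths[:-1]:
        layers += [Linear(prev, w, rng), leaky_relu_layer()]
        prev = w
    layers.append(Linear(prev, widths[-1], rng))
    return Sequential(*layers)
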