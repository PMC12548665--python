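"""Neural-network building blocks for adjacency-matrix networks.

Layers are thin parameter containers whose ``__call__`` composes
:class:`~tggan._tensor.Tensor` operations; the BrainNetCNN operators
(edge-to-edge, edge-to-node, node-to-graph) act on batches of adjacency
matrices shaped ``(batch, channels, n, n)``.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, einsum2

__all__ = [
    "Module",
    "Linear",
    "E2EConv",
    "E2NConv",
    "N2GPool",
    "Dropout",
    "Sequential",
    "Adam",
]


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode=True):
        for m in self.modules():
            if isinstance(m, Dropout):
                m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = np.array(a, dtype=np.float64)


def _init(rng, shape, fan_in):
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape))


class Linear(Module):
    def __init__(self, n_in, n_out, rng):
        self.weight = _init(rng, (n_in, n_out), n_in)
        self.bias = Tensor(np.zeros(n_out))

    def __call__(self, x):
        return x @ self.weight + self.bias


class E2EConv(Module):
    """Cross-shaped edge-to-edge filter bank.

    out[b,o,i,j] = sum_{c,k} row[o,c,k] x[b,c,i,k] + col[o,c,k] x[b,c,k,j] + bias[o]
    """

    def __init__(self, c_in, c_out, n_nodes, rng):
        fan = 2 * c_in * n_nodes
        self.row = _init(rng, (c_out, c_in, n_nodes), fan)
        self.col = _init(rng, (c_out, c_in, n_nodes), fan)
        self.bias = Tensor(np.zeros(c_out))
        self.c_out = c_out

    def __call__(self, x):
        b, c, n, _ = x.shape
        r = einsum2("ock,bcik->boi", self.row, x).reshape(b, self.c_out, n, 1)
        s = einsum2("ock,bckj->boj", self.col, x).reshape(b, self.c_out, 1, n)
        return r + s + self.bias.reshape(1, self.c_out, 1, 1)


class E2NConv(Module):
    """Edge-to-node reduction: a weighted sum over each node's row and column.

    out[b,o,i] = sum_{c,j} row[o,c,j] x[b,c,i,j] + col[o,c,j] x[b,c,j,i] + bias[o]
    """

    def __init__(self, c_in, c_out, n_nodes, rng):
        fan = 2 * c_in * n_nodes
        self.row = _init(rng, (c_out, c_in, n_nodes), fan)
        self.col = _init(rng, (c_out, c_in, n_nodes), fan)
        self.bias = Tensor(np.zeros(c_out))
        self.c_out = c_out

    def __call__(self, x):
        r = einsum2("ocj,bcij->boi", self.row, x)
        s = einsum2("ocj,bcji->boi", self.col, x)
        return r + s + self.bias.reshape(1, self.c_out, 1)


class N2GPool(Module):
    """Node-to-graph pooling: weighted integration of node values to units.

    out[b,u] = sum_{c,i} w[u,c,i] v[b,c,i] + bias[u]
    """

    def __init__(self, c_in, units, n_nodes, rng):
        self.weight = _init(rng, (units, c_in, n_nodes), c_in * n_nodes)
        self.bias = Tensor(np.zeros(units))

    def __call__(self, v):
        return einsum2("uci,bci->bu", self.weight, v) + self.bias


class Dropout(Module):
    """Inverted dropout; the mask is resampled per call in training mode."""

    def __init__(self, p, rng):
        self.p = float(p)
        self.rng = rng
        self.training = True

    def __call__(self, x):
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class _Lambda(Module):
    def __init__(self, fn):
        self.fn = fn

    def __call__(self, x):
        return self.fn(x)


def leaky_relu_layer(slope=0.2):
    return _Lambda(lambda t: t.leaky_relu(slope))


def softplus_layer():
    return _Lambda(lambda t: t.softplus())


class Adam:
    """Adam optimizer acting in place on parameter tensors."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= self.b1
            m += (1.0 - self.b1) * gd
            v *= self.b2
            v += (1.0 - self.b2) * gd * gd
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

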