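"""Reverse-mode automatic differentiation on numpy arrays.

A minimal graph-building autodiff core: every operation records, for each
parent, a vector-Jacobian product (VJP) closure that is itself expressed in
terms of :class:`Tensor` operations.  Because the backward pass builds a new
graph, gradients are themselves differentiable — which is what the
Wasserstein-GAN gradient penalty needs (the penalty is a function of the
gradient norm of the critic with respect to its input, and must be
differentiated again with respect to the critic parameters).

Only the operations required by the BrainNetCNN-style networks are provided:
broadcast arithmetic, constant powers, exp/log/sigmoid, leaky-ReLU and
softplus, reductions, reshape/transpose, matmul and a two-operand einsum.
Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "grad", "einsum2"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "parents", "vjps")

    def __init__(self, data, parents=(), vjps=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self.vjps = vjps

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape})"

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            parents=(self, other),
            vjps=(
                lambda g, s=self.shape: _unbroadcast(g, s),
                lambda g, s=other.shape: _unbroadcast(g, s),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), vjps=(lambda g: -g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            vjps=(
                lambda g, o=other, s=self.shape: _unbroadcast(g * o, s),
                lambda g, o=self, s=other.shape: _unbroadcast(g * o, s),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only constant exponents are supported")
        out = Tensor(
            self.data ** p,
            parents=(self,),
            vjps=(lambda g, x=self, p=p: g * (p * x ** (p - 1.0)),),
        )
        return out

    def sqrt(self):
        return self ** 0.5

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,), vjps=())
        out.vjps = (lambda g, o=out: g * o,)
        return out

    def log(self):
        return Tensor(
            np.log(self.data), parents=(self,), vjps=(lambda g, x=self: g / x,)
        )

    def sigmoid(self):
        out = Tensor(
            1.0 / (1.0 + np.exp(-self.data)), parents=(self,), vjps=()
        )
        out.vjps = (lambda g, o=out: g * o * (1.0 - o),)
        return out

    def leaky_relu(self, slope=0.2):
        # piecewise-linear: the mask is constant, so second derivatives
        # through this op are zero almost everywhere (exact off the kink)
        mask = np.where(self.data > 0, 1.0, slope)
        return Tensor(
            self.data * mask,
            parents=(self,),
            vjps=(lambda g, m=mask: g * Tensor(m),),
        )

    def softplus(self):
        # numerically stable forward; backward is sigmoid (differentiable)
        out = Tensor(np.logaddexp(0.0, self.data), parents=(self,), vjps=())
        out.vjps = (lambda g, x=self: g * x.sigmoid(),)
        return out

    # -- reductions & shape --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))

        def vjp(g, shape=self.shape, axis=axis, keepdims=keepdims):
            gd = g
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(a % len(shape) for a in ax)
                ns = tuple(
                    1 if i in ax else s for i, s in enumerate(shape)
                )
                gd = gd.reshape(ns)
            return gd * Tensor(np.ones(shape))

        out.parents = (self,)
        out.vjps = (vjp,)
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(
            self.data.reshape(shape),
            parents=(self,),
            vjps=(lambda g, s=self.shape: g.reshape(s),),
        )

    def transpose(self, axes):
        inv = tuple(np.argsort(axes))
        return Tensor(
            self.data.transpose(axes),
            parents=(self,),
            vjps=(lambda g, inv=inv: g.transpose(inv),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data)

        def vjp_a(g, a=self, b=other):
            return _unbroadcast(g @ _swap_last(b), a.shape)

        def vjp_b(g, a=self, b=other):
            return _unbroadcast(_swap_last(a) @ g, b.shape)

        out.parents = (self, other)
        out.vjps = (vjp_a, vjp_b)
        return out


def _swap_last(t: Tensor) -> Tensor:
    axes = tuple(range(t.ndim - 2)) + (t.ndim - 1, t.ndim - 2)
    return t.transpose(axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a broadcast gradient back to ``shape`` by summation."""
    if g.shape == tuple(shape):
        return g
    ndiff = g.ndim - len(shape)
    if ndiff > 0:
        g = g.sum(axis=tuple(range(ndiff)))
    axes = tuple(
        i for i, (a, b) in enumerate(zip(g.shape, shape)) if b == 1 and a != 1
    )
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = g.reshape(shape)
    return g


def einsum2(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with differentiable VJPs.

    Restricted to contractions where each operand's indices appear in the
    union of the output's and the other operand's indices (no diagonals),
    which makes the gradient another einsum with permuted subscripts.
    """
    a, b = as_tensor(a), as_tensor(b)
    lhs, out_spec = subscripts.split("->")
    sa, sb = lhs.split(",")
    if len(set(sa)) != len(sa) or len(set(sb)) != len(sb):
        raise ValueError(f"repeated operand index in {subscripts!r}")
    if not (set(sa) <= set(out_spec) | set(sb)) or not (
        set(sb) <= set(out_spec) | set(sa)
    ):
        raise ValueError(f"unsupported einsum spec {subscripts!r}")
    out = Tensor(np.einsum(subscripts, a.data, b.data))

    def vjp_a(g, b=b):
        return einsum2(f"{out_spec},{sb}->{sa}", g, b)

    def vjp_b(g, a=a):
        return einsum2(f"{out_spec},{sa}->{sb}", g, a)

    out.parents = (a, b)
    out.vjps = (vjp_a, vjp_b)
    return out


def grad(output: Tensor, inputs, grad_output=None):
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    The returned gradients are Tensors attached to a new graph, so they may
    be differentiated again (double backprop).
    """
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))

    grads: dict[int, Tensor] = {
        id(output): grad_output
        if grad_output is not None
        else Tensor(np.ones_like(output.data))
    }
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None:
            continue
        for p, vjp in zip(node.parents, node.vjps):
            contrib = vjp(g)
            prev = grads.get(id(p))
            grads[id(p)] = contrib if prev is None else prev + contrib
    return [
        grads.get(id(t), Tensor(np.zeros(t.shape))) for t in inputs
    ]
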