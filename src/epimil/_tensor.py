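"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the presentation model needs: broadcasted
arithmetic, (batched, broadcasting) matmul, gather/embedding lookups, masked
softmax, layer normalisation, ReLU, dropout, masked max-pooling and a fused
weighted binary-cross-entropy-with-logits loss.  All tensors are float32; the
graph is a flat tape resolved by topological sort in :meth:`Tensor.backward`.

Gradients of every fused op are verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

from . import _kernels

__all__ = ["Tensor", "Parameter"]

_NEG_INF = np.float32(-1e9)


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = _as_array(data)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # ---- graph machinery -------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        # Safe to take ownership: every backward fn hands each parent its own
        # fresh buffer (the one shared-buffer case, __add__ with equal shapes,
        # copies explicitly).  Read-only arrays (broadcasts) still get copied.
        if self.grad is None:
            if grad.flags.writeable:
                self.grad = grad
            else:
                self.grad = np.array(grad, dtype=np.float32)
        else:
            self.grad += grad

    # ---- elementwise -----------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                gb = _unbroadcast(g, other.shape)
                if gb is g and self.requires_grad:
                    gb = g.copy()   # same array handed to both parents
                other._accum(gb)

        out._backward = bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (other * Tensor(np.float32(-1.0)))

    def __matmul__(self, other):
        """Batched matmul with NumPy broadcasting on leading dims."""
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(np.matmul(self.data, other.data), (self, other))

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # ---- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        out._backward = bw
        return out

    def expand_dims(self, axis):
        out = Tensor(np.expand_dims(self.data, axis), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(np.squeeze(g, axis=axis))

        out._backward = bw
        return out

    def squeeze(self, axis):
        out = Tensor(np.squeeze(self.data, axis=axis), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(np.expand_dims(g, axis))

        out._backward = bw
        return out

    def linear(self, w: "Tensor", b: "Tensor") -> "Tensor":
        """Affine map on the last axis via a single 2-D GEMM.

        Equivalent to ``self @ w + b`` but collapses all leading axes first,
        which is far faster than a batched matmul of many tiny matrices.
        """
        *lead, din = self.shape
        x2 = self.data.reshape(-1, din)
        y = x2 @ w.data
        y += b.data
        out = Tensor(y.reshape(*lead, w.shape[1]), (self, w, b))

        def bw(g):
            g2 = np.ascontiguousarray(g.reshape(-1, w.shape[1]))
            if self.requires_grad:
                gx = np.empty(self.shape, np.float32)
                np.matmul(g2, w.data.T, out=gx.reshape(-1, din))
                self._accum(gx)
            if w.requires_grad:
                w._accum(x2.T @ g2)
            if b.requires_grad:
                b._accum(g2.sum(axis=0))

        out._backward = bw
        return out

    # ---- gathers -----------------------------------------------------------

    def take_rows(self, idx: np.ndarray):
        """out[...] = self[idx], indexing axis 0 (embedding / registry gather)."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            if self.requires_grad:
                gw = np.zeros_like(self.data)
                np.add.at(gw, idx, g)
                self._accum(gw)

        out._backward = bw
        return out

    def take_axis1(self, idx: np.ndarray):
        """Gather along axis 1 with a shared index array: out = self[:, idx]."""
        idx = np.asarray(idx)
        out = Tensor(self.data[:, idx], (self,))

        def bw(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                # scatter-add over the gathered axis, batched over axis 0
                np.add.at(gx, (slice(None), idx), g)
                self._accum(gx)

        out._backward = bw
        return out

    # ---- nonlinearities / norms -------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = bw
        return out

    def masked_softmax(self, mask: np.ndarray | None = None):
        """Softmax over the last axis; positions where mask is False get ~0."""
        x = self.data
        if mask is None and _kernels.HAS_NUMBA:
            L = x.shape[-1]
            p = _kernels.softmax_forward(
                np.ascontiguousarray(x).reshape(-1, L)).reshape(x.shape)
            out = Tensor(p, (self,))

            def bw_fast(g):
                if self.requires_grad:
                    gx = _kernels.softmax_backward(
                        np.ascontiguousarray(g).reshape(-1, L),
                        p.reshape(-1, L))
                    self._accum(gx.reshape(self.shape))

            out._backward = bw_fast
            return out
        if mask is not None:
            x = np.where(mask, x, _NEG_INF)
        x = x - x.max(axis=-1, keepdims=True)
        e = np.exp(x)
        p = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(p, (self,))

        def bw(g):
            if self.requires_grad:
                gi = p * (g - (g * p).sum(axis=-1, keepdims=True))
                self._accum(gi.astype(np.float32, copy=False))

        out._backward = bw
        return out

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        if _kernels.HAS_NUMBA:
            d = self.shape[-1]
            x2 = np.ascontiguousarray(self.data).reshape(-1, d)
            o2, mu, inv = _kernels.ln_forward(x2, gamma.data, beta.data,
                                              np.float32(eps))
            out = Tensor(o2.reshape(self.shape), (self, gamma, beta))

            def bw_fast(g):
                gx, gg, gb = _kernels.ln_backward(
                    np.ascontiguousarray(g).reshape(-1, d), x2,
                    gamma.data, mu, inv)
                if gamma.requires_grad:
                    gamma._accum(gg)
                if beta.requires_grad:
                    beta._accum(gb)
                if self.requires_grad:
                    self._accum(gx.reshape(self.shape))

            out._backward = bw_fast
            return out
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = Tensor(xhat * gamma.data + beta.data, (self, gamma, beta))
        d = x.shape[-1]

        def bw(g):
            if gamma.requires_grad:
                axes = tuple(range(g.ndim - 1))
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                axes = tuple(range(g.ndim - 1))
                beta._accum(g.sum(axis=axes))
            if self.requires_grad:
                gh = g * gamma.data
                gx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                            - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
                self._accum(gx.astype(np.float32, copy=False))

        out._backward = bw
        return out

    def dropout(self, rate: float, rng: np.random.Generator | None):
        """Inverted dropout; identity when rng is None (evaluation mode)."""
        if rng is None or rate <= 0.0:
            return self
        keep = (rng.random(self.shape, dtype=np.float32) >= rate
                ).astype(np.float32) / np.float32(1.0 - rate)
        out = Tensor(self.data * keep, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * keep)

        out._backward = bw
        return out

    # ---- reductions ----------------------------------------------------------

    def sum(self):
        out = Tensor(self.data.sum(), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.shape).astype(np.float32))

        out._backward = bw
        return out

    def masked_max(self, mask: np.ndarray):
        """Max over all axes but the first, restricted to mask==True.

        Returns (values, flat argmax indices).  Gradient is routed to the
        argmax element of each row — the multiple-instance 'max over pairs'.
        """
        B = self.shape[0]
        flat = self.data.reshape(B, -1)
        fmask = np.asarray(mask).reshape(B, -1)
        if not fmask.any(axis=1).all():
            raise ValueError("each row needs at least one unmasked element")
        masked = np.where(fmask, flat, _NEG_INF)
        arg = masked.argmax(axis=1)
        vals = masked[np.arange(B), arg]
        out = Tensor(vals, (self,))

        def bw(g):
            if self.requires_grad:
                gx = np.zeros_like(flat)
                gx[np.arange(B), arg] = g
                self._accum(gx.reshape(self.shape))

        out._backward = bw
        return out, arg

    def weighted_bce_with_logits(self, labels: np.ndarray, weights: np.ndarray):
        """loss = sum_i w_i * [softplus(l_i) - y_i * l_i] / sum_i w_i  (scalar)."""
        l = self.data.astype(np.float64)
        y = np.asarray(labels, dtype=np.float64)
        w = np.asarray(weights, dtype=np.float64)
        sp = np.logaddexp(0.0, l)  # stable softplus
        wsum = w.sum()
        loss = float((w * (sp - y * l)).sum() / wsum)
        out = Tensor(np.float32(loss), (self,))
        sig = 1.0 / (1.0 + np.exp(-l))

        def bw(g):
            if self.requires_grad:
                gi = (w * (sig - y) / wsum) * g
                self._accum(gi.astype(np.float32))

        out._backward = bw
        return out


class Parameter(Tensor):
    """A leaf tensor updated by the optimiser."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self):
        self.grad = None
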