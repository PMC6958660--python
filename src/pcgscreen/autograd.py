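"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the classifiers need: broadcast add/mul,
matmul, elementwise sigmoid/tanh/ReLU, power, reductions, reshape, slicing,
row-stacking, 1-D convolution (via im2col) and a fused softmax
cross-entropy.  Gradients for broadcast operations are reduced back to the
parent shape; gradient buffers are allocated lazily so long unrolled
recurrences stay cheap.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

#: computation dtype; float32 halves memory traffic through long unrolls
DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    n_extra = grad.ndim - len(shape)
    if n_extra > 0:
        grad = grad.sum(axis=tuple(range(n_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        if isinstance(data, np.ndarray) and data.dtype == DTYPE:
            self.data = data
        else:
            self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        if not requires_grad:
            for p in parents:
                if p.requires_grad:
                    requires_grad = True
                    break
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __pow__(self, k: float):
        out = Tensor(self.data**k, parents=(self,))
        out._backward = lambda g: (g * k * self.data ** (k - 1),)
        return out

    def __truediv__(self, other):
        return self * (self._coerce(other) ** -1.0)

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        out._backward = backward
        return out

    def sigmoid(self):
        y = expit(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * y * (1.0 - y),)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * (1.0 - y * y),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def narrow(self, start: int, size: int) -> "Tensor":
        """Contiguous slice [start, start+size) along the last axis.

        The gradient is accumulated into the parent buffer in place (the
        backward closure returns None), so repeated slicing of one large
        tensor does not allocate a full-size gradient per slice.
        """
        parent = self
        out = Tensor(self.data[..., start:start + size], parents=(self,))

        def backward(g):
            if parent.requires_grad:
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad[..., start:start + size] += g
            return None

        out._backward = backward
        return out

    def rows(self, start: int, size: int) -> "Tensor":
        """Contiguous slice [start, start+size) along the first axis (in-place grad)."""
        parent = self
        out = Tensor(self.data[start:start + size], parents=(self,))

        def backward(g):
            if parent.requires_grad:
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad[start:start + size] += g
            return None

        out._backward = backward
        return out

    # -- backward pass --------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            if grads is None:  # op accumulated into its parents itself
                continue
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad:
                    if parent.grad is None:
                        parent.grad = np.array(g)  # own the buffer
                    else:
                        parent.grad += g


def blend(z: Tensor, a: Tensor, b: Tensor) -> Tensor:
    """Convex-combination gate: z * a + (1 - z) * b, as one fused op."""
    out = Tensor(z.data * a.data + (1.0 - z.data) * b.data, parents=(z, a, b))

    def backward(g):
        return g * (a.data - b.data), g * z.data, g * (1.0 - z.data)

    out._backward = backward
    return out


def fma2(a: Tensor, b: Tensor, c: Tensor, d: Tensor) -> Tensor:
    """Fused a * b + c * d (elementwise, equal shapes)."""
    out = Tensor(a.data * b.data + c.data * d.data, parents=(a, b, c, d))

    def backward(g):
        return g * b.data, g * a.data, g * d.data, g * c.data

    out._backward = backward
    return out


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Concatenate equally shaped 2-D tensors along axis 0."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=0),
                 parents=tuple(tensors))
    sizes = [t.data.shape[0] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(g[offsets[i]:offsets[i + 1]] for i in range(len(sizes)))

    out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Computed from logits with the log-sum-exp shift for stability; the
    gradient is the usual (softmax - onehot) / n.
    """
    z = logits.data
    n = z.shape[0]
    shift = z - z.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shift).sum(axis=1, keepdims=True))
    logp = shift - logsumexp
    loss_val = -logp[np.arange(n), labels].mean()
    out = Tensor(loss_val, parents=(logits,))
    probs = np.exp(logp)

    def backward(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        return (g * grad / n,)

    out._backward = backward
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D convolution, stride 1, "same" zero padding.

    x: (N, L, C_in); w: (K, C_in, C_out); b: (C_out,). Returns (N, L, C_out).
    """
    N, L, Cin = x.data.shape
    K, _, Cout = w.data.shape
    pad_l = (K - 1) // 2
    pad_r = K - 1 - pad_l
    xp = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
    win = win.transpose(0, 1, 3, 2)  # (N, L, K, Cin)
    cols = win.reshape(N * L, K * Cin)
    wmat = w.data.reshape(K * Cin, Cout)
    out_data = (cols @ wmat + b.data).reshape(N, L, Cout)
    out = Tensor(out_data, parents=(x, w, b))

    def backward(g):
        gflat = g.reshape(N * L, Cout)
        gw = (cols.T @ gflat).reshape(K, Cin, Cout)
        gb = gflat.sum(axis=0)
        gcols = (gflat @ wmat.T).reshape(N, L, K, Cin)
        gxp = np.zeros_like(xp)
        for k in range(K):
            gxp[:, k : k + L, :] += gcols[:, :, k, :]
        gx = gxp[:, pad_l : pad_l + L, :]
        return gx, gw, gb

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
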