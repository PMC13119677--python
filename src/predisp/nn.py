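"""Minimal reverse-mode autodiff core and neural-network building blocks.

The predictor networks in this package are small (well under a quarter of a
million parameters) and run on CPU, so they are built on a compact tape-based
autodiff engine over numpy arrays rather than a full deep-learning framework.
Every op implemented here is gradient-checked against central differences in
the test suite.

Conventions: image tensors are ``(B, C, H, W)``, feature vectors ``(B, F)``.
All computation is float64 for run-to-run determinism.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "Module",
    "Conv2d",
    "Linear",
    "GRUCell",
    "Adam",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- elementwise arithmetic -------------------------------------------

    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
        """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for ax, n in enumerate(shape):
            if n == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g

    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            a._accum(Tensor._unbroadcast(g, a.data.shape))
            b._accum(Tensor._unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            a._accum(Tensor._unbroadcast(g * b.data, a.data.shape))
            b._accum(Tensor._unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    # -- linear algebra ----------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), bw)

    def __matmul__(self, other):
        return self.matmul(other)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        a = self
        old = a.data.shape
        return Tensor._make(
            a.data.reshape(*shape), (a,), lambda g: a._accum(g.reshape(old))
        )

    def sum(self) -> "Tensor":
        a = self
        return Tensor._make(
            a.data.sum(), (a,), lambda g: a._accum(np.broadcast_to(g, a.data.shape).copy())
        )

    def mean(self) -> "Tensor":
        a = self
        n = a.data.size
        return Tensor._make(
            a.data.mean(),
            (a,),
            lambda g: a._accum(np.broadcast_to(g / n, a.data.shape).copy()),
        )

    def mean_axis(self, axis: int, keepdims: bool = True) -> "Tensor":
        a = self
        n = a.data.shape[axis]

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g / n, a.data.shape).copy())

        return Tensor._make(a.data.mean(axis=axis, keepdims=keepdims), (a,), bw)

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        a = self
        m = a.data > 0
        return Tensor._make(a.data * m, (a,), lambda g: a._accum(g * m))

    def tanh(self) -> "Tensor":
        a = self
        y = np.tanh(a.data)
        return Tensor._make(y, (a,), lambda g: a._accum(g * (1.0 - y * y)))

    def sigmoid(self) -> "Tensor":
        a = self
        y = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(y, (a,), lambda g: a._accum(g * y * (1.0 - y)))

    # -- spatial ops -------------------------------------------------------

    def avg_pool(self, out_hw: tuple[int, int]) -> "Tensor":
        """Adaptive average pooling; input H, W must be divisible by out H, W."""
        a = self
        B, C, H, W = a.data.shape
        oh, ow = out_hw
        if H % oh or W % ow:
            raise ValueError(f"pool {H}x{W} -> {oh}x{ow} not divisible")
        fh, fw = H // oh, W // ow
        y = a.data.reshape(B, C, oh, fh, ow, fw).mean(axis=(3, 5))

        def bw(g):
            gexp = np.broadcast_to(
                g[:, :, :, None, :, None] / (fh * fw), (B, C, oh, fh, ow, fw)
            )
            a._accum(gexp.reshape(B, C, H, W).copy())

        return Tensor._make(y, (a,), bw)

    def upsample_nearest(self, factor_hw: tuple[int, int]) -> "Tensor":
        a = self
        B, C, H, W = a.data.shape
        fh, fw = factor_hw
        y = np.repeat(np.repeat(a.data, fh, axis=2), fw, axis=3)

        def bw(g):
            a._accum(g.reshape(B, C, H, fh, W, fw).sum(axis=(3, 5)))

        return Tensor._make(y, (a,), bw)

    def shift_left(self, k: int) -> "Tensor":
        """Shift along the x (last) axis: out[..., x] = in[..., x + k], zero-padded."""
        a = self
        if k == 0:
            return a * 1.0
        y = np.zeros_like(a.data)
        y[..., :-k] = a.data[..., k:]

        def bw(g):
            ga = np.zeros_like(a.data)
            ga[..., k:] = g[..., :-k]
            a._accum(ga)

        return Tensor._make(y, (a,), bw)

    # -- convolution -------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1, pad: int = 0) -> "Tensor":
        """2-D convolution (cross-correlation) via im2col."""
        a, w, b = self, weight, bias
        B, C, H, W = a.data.shape
        O, C2, kh, kw = w.data.shape
        if C != C2:
            raise ValueError("channel mismatch in conv2d")
        xp = np.pad(a.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        Hp, Wp = H + 2 * pad, W + 2 * pad
        oh = (Hp - kh) // stride + 1
        ow = (Wp - kw) // stride + 1
        # im2col: (B, C, kh, kw, oh, ow)
        s0, s1, s2, s3 = xp.strides
        col = np.lib.stride_tricks.as_strided(
            xp,
            shape=(B, C, kh, kw, oh, ow),
            strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
            writeable=False,
        )
        colm = col.reshape(B, C * kh * kw, oh * ow)
        wm = w.data.reshape(O, C * kh * kw)
        y = np.einsum("of,bfp->bop", wm, colm, optimize=True).reshape(B, O, oh, ow)
        y = y + b.data[None, :, None, None]

        def bw(g):
            gm = g.reshape(B, O, oh * ow)
            b._accum(g.sum(axis=(0, 2, 3)))
            gw = np.einsum("bop,bfp->of", gm, colm, optimize=True)
            w._accum(gw.reshape(O, C, kh, kw))
            if a.requires_grad:
                gcol = np.einsum("of,bop->bfp", wm, gm, optimize=True)
                gcol = gcol.reshape(B, C, kh, kw, oh, ow)
                gx = np.zeros((B, C, Hp, Wp))
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += gcol[
                            :, :, i, j
                        ]
                a._accum(gx[:, :, pad : pad + H, pad : pad + W] if pad else gx)

        return Tensor._make(y, (a, w, b), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bw)


# ---------------------------------------------------------------------------
# Modules


class Module:
    """Base class: parameter discovery, zero_grad, state (de)serialisation."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.weight = Tensor(rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in), True)
        self.bias = Tensor(np.zeros(c_out), True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.pad)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in), True)
        self.bias = Tensor(np.zeros(n_out), True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class GRUCell(Module):
    """Single-step gated recurrent unit: input (B, n_in), hidden (B, n_hidden)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        s_x = np.sqrt(1.0 / n_in)
        s_h = np.sqrt(1.0 / n_hidden)
        self.w_x = Tensor(rng.standard_normal((n_in, 3 * n_hidden)) * s_x, True)
        self.w_h = Tensor(rng.standard_normal((n_hidden, 3 * n_hidden)) * s_h, True)
        self.b = Tensor(np.zeros(3 * n_hidden), True)
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        K = self.n_hidden
        gx = x @ self.w_x + self.b
        gh = h @ self.w_h

        def sl(t, i):
            return _slice_cols(t, i * K, (i + 1) * K)

        r = (sl(gx, 0) + sl(gh, 0)).sigmoid()
        z = (sl(gx, 1) + sl(gh, 1)).sigmoid()
        n = (sl(gx, 2) + r * sl(gh, 2)).tanh()
        return (1.0 - z) * n + z * h


def _slice_cols(t: Tensor, lo: int, hi: int) -> Tensor:
    def bw(g):
        ga = np.zeros_like(t.data)
        ga[:, lo:hi] = g
        t._accum(ga)

    return Tensor._make(t.data[:, lo:hi], (t,), bw)


class Adam:
    """Adaptive-moment optimiser (beta1=0.9, beta2=0.999 defaults)."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
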