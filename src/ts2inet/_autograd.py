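"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-free define-by-run graph: every operation returns a :class:`Tensor`
holding its forward value and a closure that scatters the incoming gradient
to its parents. Only the operations the classifiers need are implemented
(broadcast add/mul, batched matmul, reshape/transpose, relu, softmax,
layer norm, dropout, 2-D convolution via im2col, 2x2 max pooling, and a
fused softmax cross-entropy). Gradients accumulate in ``Tensor.grad`` after
``backward()`` on a scalar loss.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ---- arithmetic ----

    def __add__(self, other: "Tensor") -> "Tensor":
        out_data = self.data + other.data

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        if not isinstance(other, Tensor):
            c = float(other)
            out = Tensor(self.data * c, parents=(self,))
            out._backward = lambda g: self.requires_grad and self._accumulate(g * c)
            return out
        out_data = self.data * other.data

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (other * -1.0)

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __matmul__ = matmul

    # ---- shape ----

    def reshape(self, *shape: int) -> "Tensor":
        old = self.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.reshape(old))
        return out

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.transpose(inv))
        return out

    # ---- nonlinearities ----

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def softmax(self) -> "Tensor":
        """Softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                dot = (g * y).sum(axis=-1, keepdims=True)
                self._accumulate(y * (g - dot))

        return Tensor(y, parents=(self,), backward=bwd)

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalize the last axis to zero mean / unit variance, then affine."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out_data = xhat * gain.data + bias.data
        d = self.data.shape[-1]

        def bwd(g: np.ndarray) -> None:
            if gain.requires_grad:
                gain._accumulate(_unbroadcast(g * xhat, gain.shape))
            if bias.requires_grad:
                bias._accumulate(_unbroadcast(g, bias.shape))
            if self.requires_grad:
                gx = g * gain.data
                self._accumulate(
                    inv / d * (d * gx - gx.sum(axis=-1, keepdims=True) - xhat * (gx * xhat).sum(axis=-1, keepdims=True))
                )

        return Tensor(out_data, parents=(self, gain, bias), backward=bwd)

    def dropout(self, p: float, rng: np.random.Generator, train: bool) -> "Tensor":
        """Inverted dropout; identity when not training or p == 0."""
        if not train or p <= 0.0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    # ---- convolution ----

    def conv2d(self, weight: "Tensor", bias: "Tensor", pad: int = 1) -> "Tensor":
        """Stride-1 2-D convolution, NCHW input, OIHW weight, via im2col."""
        x = self.data
        B, C, H, W = x.shape
        O, _, kh, kw = weight.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        Ho, Wo = H + 2 * pad - kh + 1, W + 2 * pad - kw + 1
        # (B, C, kh, kw, Ho, Wo) patch view without copying
        s = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, (B, C, kh, kw, Ho, Wo), (s[0], s[1], s[2], s[3], s[2], s[3])
        ).reshape(B, C * kh * kw, Ho * Wo)
        wmat = weight.data.reshape(O, C * kh * kw)
        out_data = (wmat @ cols).reshape(B, O, Ho, Wo) + bias.data.reshape(1, O, 1, 1)

        def bwd(g: np.ndarray) -> None:
            gmat = g.reshape(B, O, Ho * Wo)
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                gw = np.einsum("bop,bcp->oc", gmat, cols)
                weight._accumulate(gw.reshape(weight.shape))
            if self.requires_grad:
                gcols = np.einsum("oc,bop->bcp", wmat, gmat).reshape(B, C, kh, kw, Ho, Wo)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + Ho, j : j + Wo] += gcols[:, :, i, j]
                self._accumulate(gxp[:, :, pad : pad + H, pad : pad + W])

        return Tensor(out_data, parents=(self, weight, bias), backward=bwd)

    def maxpool2d(self, k: int = 2) -> "Tensor":
        x = self.data
        B, C, H, W = x.shape
        Ho, Wo = H // k, W // k
        xr = x[:, :, : Ho * k, : Wo * k].reshape(B, C, Ho, k, Wo, k)
        out_data = xr.max(axis=(3, 5))
        argmask = xr == out_data[:, :, :, None, :, None]
        # break ties toward a single winner to conserve gradient mass
        flat = argmask.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, k * k)
        first = np.zeros(flat.shape, dtype=bool)
        np.put_along_axis(first, flat.argmax(axis=-1, keepdims=True), True, axis=-1)
        mask = first.reshape(B, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                gx = (mask * g[:, :, :, None, :, None]).reshape(B, C, Ho * k, Wo * k)
                full = np.zeros_like(x)
                full[:, :, : Ho * k, : Wo * k] = gx
                self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bwd)

    # ---- losses ----

    def cross_entropy(self, labels: np.ndarray) -> "Tensor":
        """Mean softmax cross-entropy of logits ``(B, C)`` against int labels."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        B = self.data.shape[0]
        loss = -np.log(np.clip(p[np.arange(B), labels], 1e-300, None)).mean()

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                gp = p.copy()
                gp[np.arange(B), labels] -= 1.0
                self._accumulate(g * gp / B)

        return Tensor(loss, parents=(self,), backward=bwd)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
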