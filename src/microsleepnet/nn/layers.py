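"""Minimal 1-D neural-network layers with explicit forward/backward passes.

Every layer is a :class:`Module` holding :class:`Parameter` objects.  A
forward call caches whatever the matching ``backward`` needs; ``backward``
consumes the upstream gradient and returns the gradient with respect to the
layer input while accumulating parameter gradients in ``Parameter.grad``.

The framework is deliberately small: it covers exactly the operations the
sleep-staging network needs (grouped/dilated 1-D convolution, batch norm,
leaky ReLU, max pooling, dropout, linear, global average pooling) and is
dtype-agnostic so unit tests can run gradient checks in float64 while
training runs in float32.
"""

from __future__ import annotations

import math

import numpy as np

DEFAULT_DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient.

    ``decay`` marks parameters that participate in L2 weight decay
    (convolution/linear weights); batch-norm scales/shifts and biases are
    excluded by convention.
    """

    __slots__ = ("data", "grad", "decay", "name")

    def __init__(self, data: np.ndarray, decay: bool = False, name: str = ""):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.decay = decay
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter({self.name or 'unnamed'}, shape={self.data.shape})"


class Module:
    """Base class: tracks sub-modules/parameters through instance attributes."""

    def __init__(self):
        self.training = True

    # -- introspection -------------------------------------------------
    def children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item
                    elif (isinstance(item, tuple) and len(item) == 2
                          and isinstance(item[1], Module)):
                        yield item[1]

    def parameters(self) -> list[Parameter]:
        params = [v for v in self.__dict__.values() if isinstance(v, Parameter)]
        for child in self.children():
            params.extend(child.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state ----------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        """Parameter data plus persistent buffers (BN running stats)."""
        arrays = [p.data for p in self.parameters()]
        for m in self.iter_modules():
            if isinstance(m, BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError(
                f"state has {len(state)} arrays, model expects {len(arrays)}"
            )
        for dst, src in zip(arrays, state):
            if dst.shape != np.shape(src):
                raise ValueError(f"shape mismatch {dst.shape} vs {np.shape(src)}")
            dst[...] = src

    def iter_modules(self):
        yield self
        for child in self.children():
            yield from child.iter_modules()

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _uniform_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv1d(Module):
    """Grouped, dilated 1-D cross-correlation, ``bias`` optional.

    Weight shape is ``(out_channels, in_channels // groups, kernel_size)``.
    The forward pass builds a column view with three strided slices (one per
    kernel tap), so no scatter/gather indexing is needed anywhere.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 groups: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None,
                 dtype=DEFAULT_DTYPE, name: str = "conv"):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}"
            )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kernel_size
        self.weight = Parameter(
            _uniform_init(rng, (out_channels, in_channels // groups, kernel_size),
                          fan_in, dtype),
            decay=True, name=f"{name}.weight")
        self.bias = (Parameter(_uniform_init(rng, (out_channels,), fan_in, dtype),
                               name=f"{name}.bias") if bias else None)
        self._cache = None

    def out_length(self, length: int) -> int:
        k, s, p, d = self.kernel_size, self.stride, self.padding, self.dilation
        return (length + 2 * p - d * (k - 1) - 1) // s + 1

    def _im2col(self, xp: np.ndarray, l_out: int) -> np.ndarray:
        b, c, _ = xp.shape
        k, s, d = self.kernel_size, self.stride, self.dilation
        cols = np.empty((b, c, k, l_out), dtype=xp.dtype)
        for j in range(k):
            start = j * d
            cols[:, :, j, :] = xp[:, :, start:start + s * (l_out - 1) + 1:s]
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        p, g = self.padding, self.groups
        l_out = self.out_length(length)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        cols = self._im2col(xp, l_out)
        cg = self.in_channels // g
        cols_g = cols.reshape(b, g, cg * self.kernel_size, l_out)
        w_g = self.weight.data.reshape(g, self.out_channels // g,
                                       cg * self.kernel_size)
        out = np.matmul(w_g, cols_g).reshape(b, self.out_channels, l_out)
        if self.bias is not None:
            out += self.bias.data[None, :, None]
        self._cache = ((x.shape, cols_g, l_out) if self.training
                       else (x.shape, None, l_out))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (b, c, length), cols_g, l_out = self._cache
        if cols_g is None:
            raise RuntimeError("backward called without a training-mode forward")
        k, s, p, d, g = (self.kernel_size, self.stride, self.padding,
                         self.dilation, self.groups)
        cg = c // g
        g_g = grad.reshape(b, g, self.out_channels // g, l_out)
        dw = np.matmul(g_g, cols_g.transpose(0, 1, 3, 2)).sum(axis=0)
        self.weight.accumulate(dw.reshape(self.weight.data.shape))
        if self.bias is not None:
            self.bias.accumulate(grad.sum(axis=(0, 2)))
        w_g = self.weight.data.reshape(g, self.out_channels // g, cg * k)
        dcols = np.matmul(w_g.transpose(0, 2, 1), g_g).reshape(b, c, k, l_out)
        dxp = np.zeros((b, c, length + 2 * p), dtype=grad.dtype)
        for j in range(k):
            start = j * d
            dxp[:, :, start:start + s * (l_out - 1) + 1:s] += dcols[:, :, j, :]
        return dxp[:, :, p:p + length] if p else dxp


class BatchNorm1d(Module):
    """Batch normalisation over (batch, time) per channel; eps 1e-5."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=DEFAULT_DTYPE, name: str = "bn"):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.batches_seen = 0
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        if self.training:
            n = x.shape[0] * x.shape[2]
            s = np.einsum("bcl->c", x, dtype=np.float64)
            ss = np.einsum("bcl,bcl->c", x, x, dtype=np.float64)
            mean = s / n
            var = np.maximum(ss / n - mean * mean, 0.0)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = x - mean[None, :, None].astype(x.dtype)
            xhat *= inv_std[None, :, None].astype(x.dtype)
            # cumulative average for the first batches (so eval-mode
            # statistics are usable immediately), EMA afterwards
            m = max(self.momentum, 1.0 / (self.batches_seen + 1))
            self.batches_seen += 1
            self.running_mean += m * (mean - self.running_mean)
            unbiased = var * n / max(n - 1, 1)
            self.running_var += m * (unbiased - self.running_var)
            self._cache = (xhat, inv_std.astype(x.dtype))
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = x - self.running_mean[None, :, None].astype(x.dtype)
            xhat *= inv_std[None, :, None].astype(x.dtype)
            self._cache = None
        out = xhat * self.gamma.data[None, :, None]
        out += self.beta.data[None, :, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward requires a training-mode forward")
        xhat, inv_std = self._cache
        n = grad.shape[0] * grad.shape[2]
        self.gamma.accumulate(np.einsum("bcl,bcl->c", grad, xhat))
        self.beta.accumulate(np.einsum("bcl->c", grad))
        g = self.gamma.data
        s1 = np.einsum("bcl,c->c", grad, g)
        s2 = np.einsum("bcl,bcl,c->c", grad, xhat, g)
        dx = grad * g[None, :, None]
        dx -= (s1 / n)[None, :, None].astype(grad.dtype)
        dx -= xhat * (s2 / n)[None, :, None].astype(grad.dtype)
        dx *= inv_std[None, :, None]
        return dx


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope
        self._factor = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        factor = np.where(x >= 0, x.dtype.type(1), x.dtype.type(self.slope))
        self._factor = factor
        return x * factor

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._factor


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        self._y = y
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        y = self._y
        return grad * y * (1.0 - y)


class MaxPool1d(Module):
    """Max pooling without padding; trailing samples beyond the last full
    window are dropped (floor arithmetic)."""

    def __init__(self, kernel_size: int = 3, stride: int | None = None):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride if stride is not None else kernel_size
        self._cache = None

    def out_length(self, length: int) -> int:
        return (length - self.kernel_size) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.kernel_size, self.stride
        l_out = self.out_length(x.shape[2])
        if s == k and x.flags.c_contiguous:
            # non-overlapping windows are a contiguous reshape
            windows = x[:, :, :l_out * k].reshape(x.shape[0], x.shape[1],
                                                  l_out, k)
            arg = windows.argmax(axis=3)
            out = np.take_along_axis(windows, arg[..., None], axis=3)[..., 0]
            self._cache = (x.shape, arg.astype(np.int8), True)
            return out
        windows = np.empty(x.shape[:2] + (k, l_out), dtype=x.dtype)
        for j in range(k):
            windows[:, :, j, :] = x[:, :, j:j + s * (l_out - 1) + 1:s]
        arg = windows.argmax(axis=2).astype(np.int8)
        self._cache = (x.shape, arg, False)
        return windows.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        shape, arg, contiguous = self._cache
        k, s = self.kernel_size, self.stride
        l_out = grad.shape[2]
        dx = np.zeros(shape, dtype=grad.dtype)
        if contiguous:
            view = dx[:, :, :l_out * k].reshape(shape[0], shape[1], l_out, k)
            np.put_along_axis(view, arg[..., None].astype(np.intp),
                              grad[..., None], axis=3)
            return dx
        for j in range(k):
            dx[:, :, j:j + s * (l_out - 1) + 1:s] += grad * (arg == j)
        return dx


class Dropout(Module):
    def __init__(self, rate: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
        self._mask = mask
        return x * mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=DEFAULT_DTYPE,
                 name: str = "linear"):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(
            _uniform_init(rng, (out_features, in_features), in_features, dtype),
            decay=True, name=f"{name}.weight")
        self.bias = (Parameter(_uniform_init(rng, (out_features,), in_features, dtype),
                               name=f"{name}.bias") if bias else None)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.weight.data.T
        if self.bias is not None:
            y += self.bias.data[None, :]
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.accumulate(grad.T @ self._x)
        if self.bias is not None:
            self.bias.accumulate(grad.sum(axis=0))
        return grad @ self.weight.data


class GlobalAvgPool(Module):
    """Mean over the temporal axis: (B, C, L) -> (B, C)."""

    def __init__(self):
        super().__init__()
        self._length = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        length = self._length
        return np.repeat(grad[:, :, None] / grad.dtype.type(length), length, axis=2)


class Flatten(Module):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class ChannelShuffle(Module):
    """Reshape-transpose-flatten permutation of channels.

    With ``C`` channels and ``g`` groups the channel at index ``i`` moves to
    position ``(i % g) * (C // g) + i // g``; values are untouched.
    """

    def __init__(self, groups: int):
        super().__init__()
        if groups < 1:
            raise ValueError("groups must be >= 1")
        self.groups = groups
        self._perm = None
        self._inv = None

    def _permutation(self, channels: int) -> np.ndarray:
        if channels % self.groups:
            raise ValueError(
                f"channels={channels} not divisible by groups={self.groups}")
        return (np.arange(channels)
                .reshape(self.groups, channels // self.groups).T.ravel())

    def forward(self, x: np.ndarray) -> np.ndarray:
        perm = self._permutation(x.shape[1])
        self._perm = perm
        self._inv = np.argsort(perm)
        return x[:, perm, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad[:, self._inv, :]


class Sequential(Module):
    def __init__(self, modules: list[tuple[str, Module]]):
        super().__init__()
        self.steps = list(modules)

    def children(self):
        for _, m in self.steps:
            yield m

    def forward(self, x: np.ndarray) -> np.ndarray:
        for _, m in self.steps:
            x = m(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for _, m in reversed(self.steps):
            grad = m.backward(grad)
        return grad

    def __getitem__(self, name: str) -> Module:
        for n, m in self.steps:
            if n == name:
                return m
        raise KeyError(name)
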