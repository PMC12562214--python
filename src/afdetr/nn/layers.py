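"""Neural-network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import math
from typing import Iterator, Sequence

import numpy as np

from .tensor import Tensor, conv1d, maxpool1d


class Module:
    """Tiny module base: tracks named parameters and submodules."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        return t

    def buffer(self, name: str, array: np.ndarray) -> np.ndarray:
        arr = np.asarray(array, dtype=np.float64)
        self._buffers[name] = arr
        return arr

    def add(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        return module

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=np.float64)
        for name, b in self.named_buffers():
            b[...] = state["buffer:" + name]


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            bound = math.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.w = self.param("w", w)
        self.b = self.param("b", np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        if self.b is not None:
            out = out + self.b
        return out


class MLP(Module):
    """Stack of linear layers with ReLU between (none after the last)."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator,
                 zero_init_last: bool = False):
        super().__init__()
        self.layers = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            last = i == len(dims) - 2
            lin = Linear(a, b, rng, zero_init=zero_init_last and last)
            self.add(f"lin{i}", lin)
            self.layers.append(lin)

    def __call__(self, x: Tensor) -> Tensor:
        for i, lin in enumerate(self.layers):
            x = lin(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 padding: int = 0, bias: bool = True):
        super().__init__()
        self.padding = padding
        bound = math.sqrt(2.0 / (c_in * kernel))
        self.w = self.param("w", rng.normal(0.0, bound, size=(c_out, c_in, kernel)))
        self.b = self.param("b", np.zeros(c_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, stride=1, padding=self.padding)


class BatchNorm1d(Module):
    """Batch normalization over (batch, length) for (B, C, L) inputs."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.param("gamma", np.ones(channels))
        self.beta = self.param("beta", np.zeros(channels))
        self.running_mean = self.buffer("running_mean", np.zeros(channels))
        self.running_var = self.buffer("running_var", np.ones(channels))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2), keepdims=True)
            self.running_mean += self.momentum * (mean.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
            xn = (x - mean) / ((var + self.eps) ** 0.5)
        else:
            mean = self.running_mean.reshape(1, -1, 1)
            var = self.running_var.reshape(1, -1, 1)
            xn = (x - mean) / np.sqrt(var + self.eps)
        return xn * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = self.param("gamma", np.ones(dim))
        self.beta = self.param("beta", np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        return (x - mean) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, num: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.param("w", rng.normal(0.0, 0.02, size=(num, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.w[np.asarray(idx, dtype=np.intp)]


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``H`` heads and output projection."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 identity_qk: bool = False):
        super().__init__()
        if dim % heads != 0:
            raise ValueError("feature width must be divisible by head count")
        self.dim = dim
        self.heads = heads
        self.dk = dim // heads
        self.wq = self.add("wq", Linear(dim, dim, rng))
        self.wk = self.add("wk", Linear(dim, dim, rng))
        self.wv = self.add("wv", Linear(dim, dim, rng))
        self.wo = self.add("wo", Linear(dim, dim, rng))
        if identity_qk:
            # start Q/K as the identity so sinusoidal positional embeddings
            # carry their similarity kernel into the attention logits from
            # the first step (they remain fully learnable)
            self.wq.w.data = np.eye(dim, dtype=self.wq.w.data.dtype)
            self.wk.w.data = np.eye(dim, dtype=self.wk.w.data.dtype)

    def _split(self, t: Tensor, B: int, L: int) -> Tensor:
        return t.reshape(B, L, self.heads, self.dk).transpose(0, 2, 1, 3)

    def __call__(self, q: Tensor, k: Tensor, v: Tensor,
                 mask: np.ndarray | None = None) -> Tensor:
        B, Lq, _ = q.shape
        Lk = k.shape[1]
        qh = self._split(self.wq(q), B, Lq)
        kh = self._split(self.wk(k), B, Lk)
        vh = self._split(self.wv(v), B, Lk)
        logits = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dk))
        if mask is not None:
            # mask: additive, broadcastable to (B, H, Lq, Lk); -inf style blocks
            logits = logits + mask
        attn = logits.softmax(axis=-1)
        out = attn @ vh
        out = out.transpose(0, 2, 1, 3).reshape(B, Lq, self.dim)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.lin1 = self.add("lin1", Linear(dim, hidden, rng))
        self.lin2 = self.add("lin2", Linear(hidden, dim, rng))

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())
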