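"""Neural-network building blocks and optimization on :mod:`aetrans.autograd`.

Layers follow the original Transformer conventions: scaled dot-product
multi-head attention, position-wise two-layer ReLU feed-forward nets, and
post-norm residual blocks (sublayer -> add -> LayerNorm).  Weights are plain
:class:`~aetrans.autograd.Tensor` leaves collected by name, so checkpoints
are dictionaries of named arrays.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .autograd import Tensor, concatenate


class Module:
    """Minimal parameter container with named-parameter traversal."""

    def __init__(self) -> None:
        self._params: Dict[str, Tensor] = {}
        self._children: Dict[str, "Module"] = {}
        self.training = True

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for cname, child in self._children.items():
            out.update(child.named_parameters(prefix + cname + "."))
        return out

    def parameters(self) -> List[Tensor]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    """Affine map y = x W + b with Glorot-uniform initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / (in_dim + out_dim))
        self.W = self.add_param("W", rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.b = self.add_param("b", np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(dim))
        self.beta = self.add_param("beta", np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / ((var + self.eps) ** 0.5) * self.gamma + self.beta


def split_heads(x: Tensor, n_heads: int) -> Tensor:
    """(B, T, D) -> (B, H, T, D/H)."""
    b, t, d = x.shape
    return x.reshape(b, t, n_heads, d // n_heads).swapaxes(1, 2)


def merge_heads(x: Tensor) -> Tensor:
    """(B, H, T, Dh) -> (B, T, H*Dh)."""
    b, h, t, dh = x.shape
    return x.swapaxes(1, 2).reshape(b, t, h * dh)


class MultiHeadAttention(Module):
    """softmax(Q K^T / sqrt(d_k)) V per head, concatenated and projected."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.last_attention: Optional[np.ndarray] = None

    def __call__(self, query: Tensor, key: Tensor, value: Tensor) -> Tensor:
        q = split_heads(self.wq(query), self.n_heads)
        k = split_heads(self.wk(key), self.n_heads)
        v = split_heads(self.wv(value), self.n_heads)
        scores = (q @ k.T) * (1.0 / math.sqrt(self.d_k))
        attn = scores.softmax(axis=-1)
        self.last_attention = attn.data
        return self.wo(merge_heads(attn @ v))


class FeedForward(Module):
    """Position-wise max(0, x W1 + b1) W2 + b2."""

    def __init__(self, d_model: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.lin1 = Linear(d_model, hidden_dim, rng)
        self.lin2 = Linear(hidden_dim, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class EncoderLayer(Module):
    """Post-norm block: x <- LN(x + MHA(x)); x <- LN(x + FFN(x))."""

    def __init__(self, d_model: int, n_heads: int, ffn_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.mha = MultiHeadAttention(d_model, n_heads, rng)
        self.ffn = FeedForward(d_model, ffn_hidden, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.mha(x, x, x))
        return self.norm2(x + self.ffn(x))


class DecoderLayer(Module):
    """Post-norm decoder block: self-attention, cross-attention over memory, FFN."""

    def __init__(self, d_model: int, n_heads: int, ffn_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ffn = FeedForward(d_model, ffn_hidden, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.norm3 = LayerNorm(d_model)

    def __call__(self, x: Tensor, memory: Tensor) -> Tensor:
        x = self.norm1(x + self.self_attn(x, x, x))
        x = self.norm2(x + self.cross_attn(x, memory, memory))
        return self.norm3(x + self.ffn(x))


class Sequential(Module):
    def __init__(self, layers: Sequence[Module]):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(self.layers):
            self._children[str(i)] = layer

    def __call__(self, x: Tensor, *extra) -> Tensor:
        for layer in self.layers:
            x = layer(x, *extra)
        return x


class MLP(Module):
    """ReLU-hidden multilayer perceptron with a linear final layer."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        super().__init__()
        self.lins = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        for i, lin in enumerate(self.lins):
            self._children[str(i)] = lin

    def __call__(self, x: Tensor) -> Tensor:
        for lin in self.lins[:-1]:
            x = lin(x).relu()
        return self.lins[-1](x)


class Adam:
    """Adam with decoupled-from-nothing classic L2 via weight_decay added to grads."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Halve (by `factor`) the optimizer lr after `patience` non-improving epochs."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-6, threshold: float = 1e-8):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = math.inf
        self.bad_epochs = 0
        self.n_reductions = 0

    def step(self, metric: float) -> None:
        if metric < self.best - self.threshold:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                new_lr = max(self.optimizer.lr * self.factor, self.min_lr)
                if new_lr < self.optimizer.lr:
                    self.optimizer.lr = new_lr
                    self.n_reductions += 1
                self.bad_epochs = 0
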