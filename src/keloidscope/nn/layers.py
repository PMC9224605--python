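"""Neural building blocks: modules, linear/attention/transformer layers, SGD.

All parameters are float64 numpy arrays initialized from an explicit
``numpy.random.Generator`` so every training run is a pure function of
its seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadAttention",
    "Mlp",
    "TransformerBlock",
    "SGD",
    "clip_grad_norm",
]


class Module:
    """Lightweight parameter container with recursive discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Parameter], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, params, seen)

    def _collect_value(self, value, params, seen) -> None:
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                self._collect_value(v, params, seen)
        elif isinstance(value, dict):
            for v in value.values():
                self._collect_value(v, params, seen)

    # -- (de)serialization ------------------------------------------------
    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        out.update(v.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(v, Parameter):
                        out[f"{key}.{i}"] = v
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]} ...")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, scale: float | None = None):
        std = scale if scale is not None else np.sqrt(2.0 / (d_in + d_out))
        self.weight = Parameter(rng.normal(0.0, std, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)


class MultiHeadAttention(Module):
    """Standard scaled dot-product self-attention over (B, N, D) tokens."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError("dim must be divisible by n_heads")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x)  # (B, N, 3D)
        qkv = qkv.reshape(B, N, 3, h, hd).transpose(2, 0, 3, 1, 4)  # (3, B, h, N, hd)
        q = qkv.gather_rows(np.array([0]), axis=0).reshape(B, h, N, hd)
        k = qkv.gather_rows(np.array([1]), axis=0).reshape(B, h, N, hd)
        v = qkv.gather_rows(np.array([2]), axis=0).reshape(B, h, N, hd)
        attn = q.matmul(k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = attn.softmax(axis=-1)
        out = attn.matmul(v)  # (B, h, N, hd)
        out = out.transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj(out)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class TransformerBlock(Module):
    """Pre-norm transformer block: LN → MHSA → residual, LN → MLP → residual."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: float, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.mlp(self.norm2(x))
        return x


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is ≤ ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad * p.grad).sum())
    norm = np.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class SGD:
    """SGD with classical momentum and a pluggable per-epoch LR schedule."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
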