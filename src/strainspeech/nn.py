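"""Neural-network layers for the word decoder, built on the autodiff engine.

Provides the building blocks of the hybrid CNN-Transformer classifier:
strided 1-D convolutions (im2col), layer normalization, multi-head
self-attention with optional low-rank adaptation (LoRA) factors on the
query/value projections, position-wise feed-forward blocks, learned
positional embeddings, dropout, and the Adam optimizer.

All parameters are float64 numpy arrays; initialization is driven by an
explicit ``numpy.random.Generator`` so training runs are reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, unfold1d

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv1d",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "FeedForward",
    "TransformerEncoderLayer",
    "Dropout",
    "Adam",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module base: parameter traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, attr in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                out.append((full, attr))
            elif isinstance(attr, Module):
                out.extend(attr.named_parameters(prefix=full + "."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> None:
        self.training = True
        for attr in vars(self).values():
            if isinstance(attr, Module):
                attr.train()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.train()

    def eval(self) -> None:
        self.training = False
        for attr in vars(self).values():
            if isinstance(attr, Module):
                attr.eval()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.eval()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.array(state[name], dtype=np.float64, copy=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = Parameter(_glorot(rng, d_in, d_out, (d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))
        self.d_in, self.d_out = d_in, d_out

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv1d(Module):
    """Strided 1-D convolution over (B, T, C) sequences, via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel
        self.W = Parameter(_glorot(rng, fan_in, c_out, (fan_in, c_out)))
        self.b = Parameter(np.zeros(c_out))
        self.kernel, self.stride = kernel, stride
        self.c_in, self.c_out = c_in, c_out

    def __call__(self, x: Tensor) -> Tensor:
        cols = unfold1d(x, self.kernel, self.stride)  # (B, T', k*C)
        return cols @ self.W + self.b

    def out_len(self, T: int) -> int:
        return (T - self.kernel) // self.stride + 1


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return self.gamma * (xc / (var + self.eps).sqrt()) + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask


class _LoRAFactors(Module):
    """Additive low-rank factors W + (alpha/r) A B for a frozen projection.

    ``A`` is Gaussian-initialized and ``B`` zero-initialized, so the adapted
    projection equals the base projection exactly at attachment time.
    """

    def __init__(self, d_in: int, d_out: int, rank: int, alpha: float, rng: np.random.Generator):
        super().__init__()
        self.A = Parameter(rng.normal(0.0, 0.02, size=(d_in, rank)))
        self.B = Parameter(np.zeros((rank, d_out)))
        self.scale = alpha / rank

    def __call__(self, x: Tensor) -> Tensor:
        return ((x @ self.A) @ self.B) * self.scale


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_head = d_model // n_heads
        self.Wq = Linear(d_model, d_model, rng)
        self.Wk = Linear(d_model, d_model, rng)
        self.Wv = Linear(d_model, d_model, rng)
        self.Wo = Linear(d_model, d_model, rng)
        self.drop = Dropout(dropout, rng)
        self.lora_q: _LoRAFactors | None = None
        self.lora_v: _LoRAFactors | None = None

    def attach_lora(self, rank: int, alpha: float, rng: np.random.Generator, targets=("q", "v")) -> None:
        for t in targets:
            if t == "q":
                self.lora_q = _LoRAFactors(self.d_model, self.d_model, rank, alpha, rng)
            elif t == "v":
                self.lora_v = _LoRAFactors(self.d_model, self.d_model, rank, alpha, rng)
            else:
                raise ValueError(f"no such attention projection to adapt: {t!r}")

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        # (B, T, d) -> (B, h, T, dh)
        return x.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        q = self.Wq(x)
        if self.lora_q is not None:
            q = q + self.lora_q(x)
        k = self.Wk(x)
        v = self.Wv(x)
        if self.lora_v is not None:
            v = v + self.lora_v(x)
        qh = self._split(q, B, T)
        kh = self._split(k, B, T)
        vh = self._split(v, B, T)
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        attn = self.drop(attn)
        ctx = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, T, self.d_model)
        return self.Wo(ctx)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        self.fc1 = Linear(d_model, d_ff, rng)
        self.fc2 = Linear(d_ff, d_model, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(x).relu()))


class TransformerEncoderLayer(Module):
    """Post-norm transformer encoder block."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng, dropout)
        self.ff = FeedForward(d_model, d_ff, rng, dropout)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.attn(x))
        x = self.ln2(x + self.ff(x))
        return x


class Adam:
    """Adam optimizer over an explicit parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
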