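"""Neural-network building blocks (layers, init, Adam) on top of `minigrad`.

Initialization follows the usual fan-in scaling; every constructor takes an
explicit ``numpy.random.Generator`` so that model construction is fully seeded.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .minigrad import Parameter, Tensor

__all__ = ["Module", "Linear", "Embedding", "LayerNorm", "Adam"]


class Module:
    """Base class with recursive parameter discovery (attribute order)."""

    def parameters(self) -> Iterator[Parameter]:
        seen = set()
        for value in vars(self).values():
            yield from _params_of(value, seen)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            yield from _named_params_of(value, f"{prefix}{name}", set())

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, param in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != param.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {param.data.shape}"
                )
            param.data = arr.copy()


def _params_of(value, seen) -> Iterator[Parameter]:
    if isinstance(value, Parameter):
        if id(value) not in seen:
            seen.add(id(value))
            yield value
    elif isinstance(value, Module):
        for p in value.parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _params_of(item, seen)


def _named_params_of(value, name, seen) -> Iterator[tuple[str, Parameter]]:
    if isinstance(value, Parameter):
        yield name, value
    elif isinstance(value, Module):
        yield from value.named_parameters(prefix=name + ".")
    elif isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            yield from _named_params_of(item, f"{name}.{i}", seen)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = 1.0 / np.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_vocab: int, width: int, rng: np.random.Generator, scale: float = 0.02):
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_vocab, width)))

    def __call__(self, ids) -> Tensor:
        return self.weight.take_rows(np.asarray(ids, dtype=np.intp))


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(width))
        self.beta = Parameter(np.zeros(width))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Adam:
    """Adam with optional global-norm gradient clipping and linear LR decay."""

    def __init__(
        self,
        params,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        grad_clip: float | None = None,
        total_steps: int | None = None,
        min_lr_frac: float = 0.1,
    ):
        self.params = list(params)
        self.lr0 = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.total_steps = total_steps
        self.min_lr_frac = min_lr_frac
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self) -> float:
        if not self.total_steps:
            return self.lr0
        frac = min(self.t / self.total_steps, 1.0)
        return self.lr0 * (1.0 - (1.0 - self.min_lr_frac) * frac)

    def step(self) -> None:
        self.t += 1
        lr = self.current_lr()
        grads = [np.zeros_like(p.data) if p.grad is None else p.grad for p in self.params]
        if self.grad_clip is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.grad_clip:
                grads = [g * (self.grad_clip / (total + 1e-12)) for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
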