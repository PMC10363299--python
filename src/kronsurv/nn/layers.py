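"""Parameterised layers and the Adam optimiser used by every model here."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Linear", "SparseLinear", "MLP", "Adam", "ACTIVATIONS"]

ACTIVATIONS = {
    "identity": lambda t: t,
    "tanh": Tensor.tanh,
    "relu": Tensor.relu,
    "sigmoid": Tensor.sigmoid,
}


class Module:
    """Base class: tracks parameters through attribute discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = a.copy()


def _collect(value):
    if isinstance(value, Tensor):
        if value.requires_grad:
            yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out


class SparseLinear(Module):
    """Linear layer whose connectivity is clamped by a binary mask.

    The effective weight is ``W * M`` with ``M`` constant, so a feature with
    ``M[f, c] == 0`` can never influence capsule ``c`` — the locality contract
    of the sparsely coded omics layers.
    """

    def __init__(self, mask: np.ndarray, rng: np.random.Generator, bias: bool = True):
        mask = np.asarray(mask, dtype=np.float64)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D (n_features x n_capsules)")
        self.mask = Tensor(mask)  # constant, no grad
        self.W = Tensor(glorot(rng, *mask.shape) * mask.data, requires_grad=True)
        self.b = Tensor(np.zeros(mask.shape[1]), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ (self.W * self.mask)
        return out + self.b if self.b is not None else out


class MLP(Module):
    """Feed-forward stack; hidden activations ReLU, output linear by default."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 hidden_activation: str = "relu", out_activation: str = "identity"):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.hidden_activation = hidden_activation
        self.out_activation = out_activation

    def __call__(self, x: Tensor) -> Tensor:
        act = ACTIVATIONS[self.hidden_activation]
        for layer in self.layers[:-1]:
            x = act(layer(x))
        return ACTIVATIONS[self.out_activation](self.layers[-1](x))


class Adam:
    """Adam with decoupled L2 weight decay (decay added to the gradient)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, frozen: set[int] | None = None) -> None:
        """Apply one update; parameters whose id is in ``frozen`` are skipped."""
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None or (frozen and id(p) in frozen):
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
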