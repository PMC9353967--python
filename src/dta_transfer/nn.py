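"""Minimal dense neural-network primitives on NumPy.

The models in this package are small (a few dense layers around a graph or
sequence encoder), so forward and backward passes are written explicitly
rather than through an autodiff framework.  Every layer keeps its parameters
in a flat ``dict[str, ndarray]`` so that whole models can be checkpointed,
fingerprinted and transferred between training phases by name.

All arrays are float64; gradients are accumulated into a ``grads`` dict that
mirrors the parameter dict and is zeroed once per optimisation step, which
makes siamese (shared-weight) use — two forward passes through one encoder —
work without any special casing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ParamModule", "Dense", "relu", "sigmoid", "Adam", "glorot"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialisation for a (fan_in, fan_out) matrix."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # Split by sign for numerical stability at large |x|.
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class ParamModule:
    """Base class: a named bag of parameters with mirrored gradients."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        value = np.asarray(value, dtype=float)
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)
        return value

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def load_params(self, params: dict[str, np.ndarray]) -> None:
        """Replace parameter values in place; keys must match exactly."""
        missing = set(self.params) ^ set(params)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in params.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.params[k].shape:
                raise ValueError(
                    f"shape mismatch for {k!r}: have {self.params[k].shape}, "
                    f"got {v.shape}"
                )
            self.params[k][...] = v

    def export_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


class Dense:
    """Affine map y = x @ W + b operating on the last axis.

    Owned by a parent ParamModule: the parent registers ``<prefix>.W`` and
    ``<prefix>.b`` and this object reads/writes them through the parent, so
    checkpointing stays a flat dict operation.  The layer is stateless:
    ``backward`` takes the input the caller cached, which lets a siamese
    encoder run two forward passes before any backward pass.
    """

    def __init__(
        self,
        parent: ParamModule,
        prefix: str,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
    ) -> None:
        self.parent = parent
        self.prefix = prefix
        parent.add_param(f"{prefix}.W", glorot(rng, n_in, n_out))
        parent.add_param(f"{prefix}.b", np.zeros(n_out))

    @property
    def W(self) -> np.ndarray:
        return self.parent.params[f"{self.prefix}.W"]

    @property
    def b(self) -> np.ndarray:
        return self.parent.params[f"{self.prefix}.b"]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.W.shape[0]:
            raise ValueError(
                f"{self.prefix}: input width {x.shape[-1]} does not match "
                f"layer fan-in {self.W.shape[0]}"
            )
        return x @ self.W + self.b

    def backward(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients and return the input gradient."""
        x2 = x.reshape(-1, x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.parent.grads[f"{self.prefix}.W"] += x2.T @ g2
        self.parent.grads[f"{self.prefix}.b"] += g2.sum(axis=0)
        return g @ self.W.T


class Adam:
    """Adam optimiser over a ParamModule's flat parameter dict."""

    def __init__(
        self,
        module: ParamModule,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.module = module
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in module.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in module.params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, p in self.module.params.items():
            g = self.module.grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bias1
            vhat = self.v[k] / bias2
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
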