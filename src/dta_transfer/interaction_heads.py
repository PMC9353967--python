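"""Pairwise joining and the three task heads (CCI, PPI, DTA).

Two encodings are joined by plain ordered concatenation; a classifier head
maps the joint vector to an interaction probability and a regression head to
an unbounded affinity.  The printed one-layer classifier form
``sigmoid(ReLU(Wx + b))`` can only emit probabilities >= 0.5, so the default
head is the two-layer reading (affine, ReLU, affine, sigmoid); the literal
single-layer form remains available behind ``literal_head=True`` for anyone
who wants the printed formula verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Dense, ParamModule, relu, sigmoid

__all__ = [
    "PairHeadConfig",
    "join_pair",
    "InteractionClassifier",
    "AffinityHead",
    "task_loss",
    "bce_loss",
    "mse_loss",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PairHeadConfig:
    """Head over a concatenated pair of branch encodings.

    ``input_dim`` is the per-branch width d' (joint input is 2 d');
    ``hidden_dim`` defaults to 2 d' when left as None.  ``task`` selects the
    output contract: probability for cci/ppi, unbounded scalar for dta.
    ``inner_activation`` applies to the regression head's two affine layers
    (disabling it collapses them to one affine map); ``literal_head``
    switches the classifier to the printed one-layer form.
    """

    input_dim: int
    task: str = "dta"
    hidden_dim: int | None = None
    inner_activation: bool = True
    literal_head: bool = False
    threshold: float = 0.5  # decision threshold for accuracy-style reporting

    def __post_init__(self) -> None:
        if self.task not in {"cci", "ppi", "dta"}:
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def joint_dim(self) -> int:
        return 2 * self.input_dim

    @property
    def hidden(self) -> int:
        return self.hidden_dim if self.hidden_dim is not None else self.joint_dim


def join_pair(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Ordered concatenation [left; right] along the last axis.

    Order is part of the contract: drug1;drug2 for CCI, protein1;protein2
    for PPI, protein;drug for DTA.
    """
    left = np.asarray(left)
    right = np.asarray(right)
    if left.shape != right.shape:
        raise ValueError(
            f"branch shapes differ: {left.shape} vs {right.shape}"
        )
    return np.concatenate([left, right], axis=-1)


class InteractionClassifier(ParamModule):
    """Binary interaction head: joint vector -> P(interaction) in (0, 1)."""

    def __init__(self, config: PairHeadConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.config = config
        if config.literal_head:
            self.lin = Dense(self, "head", config.joint_dim, 1, rng)
        else:
            self.fc1 = Dense(self, "head1", config.joint_dim, config.hidden, rng)
            self.fc2 = Dense(self, "head2", config.hidden, 1, rng)

    def forward(self, joint: np.ndarray):
        """Returns (probabilities (B,), cache). Logits are kept in the cache
        so the BCE gradient can be taken in the numerically stable form."""
        if self.config.literal_head:
            z = self.lin.forward(joint)
            a = relu(z)
            p = sigmoid(a)
            cache = {"joint": joint, "z": z, "logit": a}
        else:
            z1 = self.fc1.forward(joint)
            h1 = relu(z1)
            logit = self.fc2.forward(h1)
            p = sigmoid(logit)
            cache = {"joint": joint, "z1": z1, "h1": h1, "logit": logit}
        return p[:, 0], cache

    def backward_bce(self, cache: dict, labels: np.ndarray) -> np.ndarray:
        """Accumulate gradients of mean BCE; returns d loss / d joint."""
        p = sigmoid(cache["logit"])
        g_logit = (p - labels[:, None]) / labels.shape[0]
        if self.config.literal_head:
            g_logit = g_logit * (cache["z"] > 0)
            return self.lin.backward(cache["joint"], g_logit)
        g_h1 = self.fc2.backward(cache["h1"], g_logit)
        g_z1 = g_h1 * (cache["z1"] > 0)
        return self.fc1.backward(cache["joint"], g_z1)


class AffinityHead(ParamModule):
    """Regression head: joint vector -> unbounded affinity scalar.

    Two affine layers; with ``inner_activation`` off the map is affine in
    the joint vector (the literal stacked form).
    """

    def __init__(self, config: PairHeadConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.config = config
        self.fc1 = Dense(self, "reg1", config.joint_dim, config.hidden, rng)
        self.fc2 = Dense(self, "reg2", config.hidden, 1, rng)

    def forward(self, joint: np.ndarray):
        z1 = self.fc1.forward(joint)
        h1 = relu(z1) if self.config.inner_activation else z1
        y = self.fc2.forward(h1)
        return y[:, 0], {"joint": joint, "z1": z1, "h1": h1}

    def backward(self, cache: dict, g_y: np.ndarray) -> np.ndarray:
        """Backprop an arbitrary output gradient; returns d/d joint."""
        g_h1 = self.fc2.backward(cache["h1"], g_y[:, None])
        if self.config.inner_activation:
            g_h1 = g_h1 * (cache["z1"] > 0)
        return self.fc1.backward(cache["joint"], g_h1)


def mse_loss(predictions: np.ndarray, labels: np.ndarray) -> float:
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    return float(np.mean((predictions - labels) ** 2))


def bce_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(np.asarray(probabilities, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(labels, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def task_loss(predictions: np.ndarray, labels: np.ndarray, task: str) -> float:
    """Training loss: MSE for dta, binary cross-entropy for cci/ppi."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have identical shape")
    if predictions.size == 0:
        raise ValueError("empty batch")
    if task == "dta":
        return mse_loss(predictions, labels)
    if task in {"cci", "ppi"}:
        if not np.all(np.isin(labels, (0.0, 1.0))):
            raise ValueError("classification labels must be 0/1")
        return bce_loss(predictions, labels)
    raise ValueError(f"unknown task {task!r}")
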