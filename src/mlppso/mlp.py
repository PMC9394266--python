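"""Feed-forward network core: one ReLU hidden layer, one sigmoid output,
and the bijection between layer weights/biases and a flat parameter vector.

The flat encoding is what a swarm optimizer searches over: one particle
position <-> one complete set of network parameters.  Layout (fixed and
stable across save/load):

    [W1 row-major (n_hidden x n_input) | b1 | W2 row-major (n_output x n_hidden) | b2]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Topology:
    """Network shape: input width is derived from the encoded design matrix;
    the classifier default is 30 hidden ReLU units and 1 sigmoid output."""

    n_input: int
    n_hidden: int = 30
    n_output: int = 1
    hidden_activation: str = "relu"
    output_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("all layer sizes must be >= 1")
        if self.hidden_activation != "relu" or self.output_activation != "sigmoid":
            raise ValueError("supported activations: relu hidden, sigmoid output")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_hidden": self.n_hidden,
            "n_output": self.n_output,
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        return cls(**d)


def param_count(t: Topology) -> int:
    """Number of free parameters: every connection weight plus one bias per
    non-input neuron, i.e. I*H + H + H*O + O."""
    return t.n_input * t.n_hidden + t.n_hidden + t.n_hidden * t.n_output + t.n_output


def decode(v: np.ndarray, t: Topology) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unflatten a parameter vector into (W1, b1, W2, b2)."""
    v = np.asarray(v, dtype=float)
    expected = param_count(t)
    if v.shape != (expected,):
        raise ValueError(f"expected parameter vector of length {expected}, got {v.shape}")
    i = t.n_input * t.n_hidden
    W1 = v[:i].reshape(t.n_hidden, t.n_input)
    b1 = v[i : i + t.n_hidden]
    j = i + t.n_hidden
    W2 = v[j : j + t.n_hidden * t.n_output].reshape(t.n_output, t.n_hidden)
    b2 = v[j + t.n_hidden * t.n_output :]
    return W1, b1, W2, b2


def encode(
    W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2: np.ndarray, t: Topology
) -> np.ndarray:
    """Flatten layer parameters; exact inverse of :func:`decode`."""
    W1 = np.asarray(W1, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    W2 = np.asarray(W2, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    if W1.shape != (t.n_hidden, t.n_input) or b1.shape != (t.n_hidden,):
        raise ValueError("hidden-layer shapes do not match topology")
    if W2.shape != (t.n_output, t.n_hidden) or b2.shape != (t.n_output,):
        raise ValueError("output-layer shapes do not match topology")
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def sigmoid(z):
    """Numerically stable logistic function, elementwise.

    Monotone, sigmoid(0) = 0.5, sigmoid(-z) = 1 - sigmoid(z); safe for
    |z| up to at least 1e3 (extreme inputs underflow to exactly 0 or 1).
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def relu(z):
    """max(0, z) elementwise."""
    z = np.asarray(z, dtype=float)
    out = np.maximum(z, 0.0)
    return out if out.ndim else float(out)


def forward(t: Topology, v: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Forward pass: sigmoid(W2 @ relu(W1 x + b1) + b2) per row of X.

    Returns one probability per row (the single output unit squeezed out).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != t.n_input:
        raise ValueError(f"input width {X.shape[1]} != topology n_input {t.n_input}")
    W1, b1, W2, b2 = decode(v, t)
    hidden = np.maximum(X @ W1.T + b1, 0.0)
    out = sigmoid(hidden @ W2.T + b2)
    return out[:, 0] if t.n_output == 1 else out


def predict(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary decision: label 1 iff probability >= threshold (ties positive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(probabilities, dtype=float) >= threshold).astype(int)
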