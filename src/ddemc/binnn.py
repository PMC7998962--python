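"""Binary neural network objective for high-dimensional bit-space sampling.

A one-hidden-layer network whose weights are constrained to {-1, +1} is
encoded as a bit vector ``x`` of length ``D = n_in * n_hidden + n_hidden``
via ``w = 2 b - 1``: first-layer weights stored row-major (one hidden unit's
input weights at a time), then the hidden-to-output weights.  Hidden units
use tanh followed by sign binarization (zero maps to +1) so activations are
polar like the inputs; the output unit is a sigmoid thresholded at 0.5.

The training signal for ABC is the classification error on a labeled polar
dataset — a non-differentiable black-box distance.  The prior over weights is
a Boltzmann law ``p(x) ∝ exp(-(1/D) Σ x_d)`` that favors fewer active bits;
its partition function cancels in the Metropolis ratio, which is exactly
``exp`` of :func:`boltzmann_log_ratio`.

A synthetic two-prototype generator stands in for a real binary-image task:
two opposite polar prototypes, labels balanced, coordinates flipped
independently with a noise probability, linearly separable at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .abc_core import TargetModel

__all__ = [
    "BinaryNet",
    "LabeledBinaryDataset",
    "decode_weights",
    "predict",
    "classification_error",
    "boltzmann_log_ratio",
    "boltzmann_log_prior",
    "generate_synthetic_dataset",
    "majority_vote_error",
    "make_target_model",
]


@dataclass
class BinaryNet:
    """Architecture plus flattened weight bits (weights are 2b - 1)."""

    n_in: int
    n_hidden: int
    weight_bits: np.ndarray
    binarize_hidden: bool = True  # sign-binarize tanh activations (default)

    def __post_init__(self) -> None:
        self.weight_bits = np.asarray(self.weight_bits, dtype=np.uint8)
        if self.weight_bits.size != self.n_weights(self.n_in, self.n_hidden):
            raise ValueError(
                f"weight_bits has length {self.weight_bits.size}, expected "
                f"{self.n_weights(self.n_in, self.n_hidden)}"
            )

    @staticmethod
    def n_weights(n_in: int, n_hidden: int) -> int:
        return n_in * n_hidden + n_hidden

    @property
    def w1(self) -> np.ndarray:
        """First-layer polar weights, shape (n_hidden, n_in)."""
        bits = self.weight_bits[: self.n_in * self.n_hidden]
        return (2.0 * bits - 1.0).reshape(self.n_hidden, self.n_in)

    @property
    def w2(self) -> np.ndarray:
        """Hidden-to-output polar weights, shape (n_hidden,)."""
        return 2.0 * self.weight_bits[self.n_in * self.n_hidden :] - 1.0


def decode_weights(x: np.ndarray, n_in: int, n_hidden: int) -> BinaryNet:
    """Interpret a bit vector as a network with the given architecture."""
    return BinaryNet(n_in=n_in, n_hidden=n_hidden, weight_bits=x)


def predict(net: BinaryNet, inputs: np.ndarray) -> np.ndarray:
    """Predicted labels in {0, 1} for one polar input vector or a batch."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != net.n_in:
        raise ValueError(f"input length {X.shape[1]} != n_in={net.n_in}")
    pre = X @ net.w1.T
    h = np.tanh(pre)
    if net.binarize_hidden:
        h = np.where(h >= 0.0, 1.0, -1.0)  # sign with 0 -> +1
    z = h @ net.w2
    # sigmoid(z) >= 0.5  iff  z >= 0
    labels = (z >= 0.0).astype(np.uint8)
    return labels if np.asarray(inputs).ndim == 2 else labels[0]


@dataclass
class LabeledBinaryDataset:
    """Polar inputs in {-1,+1}^n_in with binary labels."""

    inputs: np.ndarray  # (N, n_in)
    labels: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.inputs.ndim != 2 or self.inputs.shape[0] != self.labels.size:
            raise ValueError("inputs must be (N, n_in) with one label per row")
        if not np.isin(self.inputs, (-1.0, 1.0)).all():
            raise ValueError("inputs must be polar (-1 or +1)")

    @property
    def n_in(self) -> int:
        return self.inputs.shape[1]

    def __len__(self) -> int:
        return self.labels.size

    # -- plain-text round trip: polar entries then the label per row -----
    def to_text(self) -> str:
        rows = np.column_stack([self.inputs.astype(int), self.labels.astype(int)])
        header = f"# binnn dataset n_in={self.n_in} N={len(self)}"
        body = "\n".join(" ".join(str(v) for v in row) for row in rows)
        return header + "\n" + body + "\n"

    @classmethod
    def from_text(cls, text: str) -> "LabeledBinaryDataset":
        rows = np.loadtxt(
            [ln for ln in text.splitlines() if not ln.startswith("#")], ndmin=2
        )
        return cls(inputs=rows[:, :-1], labels=rows[:, -1].astype(np.uint8))


def classification_error(
    x: np.ndarray, data: LabeledBinaryDataset, n_in: int, n_hidden: int
) -> float:
    """Fraction of examples misclassified by the network encoded in ``x``."""
    if len(data) == 0:
        raise ValueError("dataset is empty")
    net = decode_weights(x, n_in, n_hidden)
    pred = predict(net, data.inputs)
    return float(np.mean(pred != data.labels))


def boltzmann_log_prior(x: np.ndarray) -> float:
    """Unnormalized Boltzmann log prior -(1/D) Σ x_d (fewer active bits win)."""
    x = np.asarray(x)
    return -float(np.sum(x)) / x.size


def boltzmann_log_ratio(x_new: np.ndarray, x_old: np.ndarray) -> float:
    """log p(x_new) - log p(x_old); the partition function cancels."""
    x_new, x_old = np.asarray(x_new), np.asarray(x_old)
    if x_new.shape != x_old.shape:
        raise ValueError("vectors must have equal length")
    return -(float(np.sum(x_new)) - float(np.sum(x_old))) / x_new.size


def generate_synthetic_dataset(
    n_in: int,
    N: int,
    noise: float,
    rng: np.random.Generator,
    separation: int | None = None,
) -> LabeledBinaryDataset:
    """Two-prototype polar dataset with independent coordinate noise.

    Class 0 and class 1 prototypes differ in ``separation`` coordinates
    (default: all of them).  Each example copies its class prototype and
    flips every coordinate independently with probability ``noise``; labels
    are balanced Bernoulli(0.5).  At ``noise = 0`` the task is linearly
    separable.
    """
    if not 0.0 <= noise < 0.5:
        raise ValueError(f"noise must lie in [0, 0.5), got {noise}")
    if separation is None:
        separation = n_in
    if not 1 <= separation <= n_in:
        raise ValueError("separation must lie in [1, n_in]")
    proto0 = (2.0 * (rng.random(n_in) < 0.5) - 1.0).astype(float)
    proto1 = proto0.copy()
    flip_at = rng.choice(n_in, size=separation, replace=False)
    proto1[flip_at] *= -1.0
    labels = (rng.random(N) < 0.5).astype(np.uint8)
    X = np.where(labels[:, None] == 1, proto1, proto0)
    noise_flips = rng.random((N, n_in)) < noise
    X = np.where(noise_flips, -X, X)
    return LabeledBinaryDataset(inputs=X, labels=labels)


def majority_vote_error(
    models: list[np.ndarray],
    data: LabeledBinaryDataset,
    n_in: int,
    n_hidden: int,
) -> float:
    """Classification error of the ensemble's majority-vote labels.

    Ties (even ensembles split half/half) are broken toward label 1.
    """
    if len(models) == 0:
        raise ValueError("ensemble must contain at least one model")
    votes = np.zeros(len(data))
    for x in models:
        net = decode_weights(x, n_in, n_hidden)
        votes += predict(net, data.inputs)
    voted = (votes >= len(models) / 2.0).astype(np.uint8)
    return float(np.mean(voted != data.labels))


def make_target_model(
    data: LabeledBinaryDataset, n_hidden: int
) -> TargetModel:
    """ABC target: deterministic label simulator + classification-error distance.

    The "simulated data" for a weight vector is its vector of predicted
    labels; the distance to the observed labels is the misclassification
    fraction, so the epsilon-ball acceptance gates directly on training
    error.  The prior is the Boltzmann sparsity law.
    """
    n_in = data.n_in

    def simulator(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return predict(decode_weights(x, n_in, n_hidden), data.inputs)

    def distance(y: np.ndarray, ydata: np.ndarray) -> float:
        return float(np.mean(y != ydata))

    return TargetModel(
        log_prior=boltzmann_log_prior,
        simulator=simulator,
        distance=distance,
        ydata=data.labels,
    )
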