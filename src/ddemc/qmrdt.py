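"""Synthetic QMR-DT two-level noisy-OR disease networks.

A QMR-DT-style network is a bipartite graphical model with ``m`` binary
disease nodes on top and ``n`` binary finding nodes below.  A finding fires
unless the leak cause and every active disease independently fail to trigger
it:

    P(y_i = 1 | x) = 1 - (1 - q_i0) * prod_l (1 - q_il)^{x_l}

with leak probabilities ``q_i0``, association probabilities ``q_il`` and an
independent Bernoulli prior ``p_l`` over diseases.  Inference targets the
disease vector ``x``; the network parameters are known.

Two presets mirror the study conditions used throughout the package:

* likelihood-based: ``m=20, n=80``, parameters uniform on (0,1) with sparse
  disease priors uniform on (0.01, 0.5);
* likelihood-free: ``m=10, n=20``, all probabilities drawn from
  Beta(0.15, 0.15), which concentrates them near 0 and 1 and makes the
  simulator close to deterministic.

For small ``m`` the exact posterior over all ``2^m`` disease vectors is
available by enumeration and serves as the test oracle for the samplers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from . import bitspace
from .abc_core import TargetModel, mean_hamming_distance

__all__ = [
    "QMRNetwork",
    "ProblemInstance",
    "finding_probability",
    "simulate_findings",
    "log_likelihood",
    "log_prior",
    "generate_instance",
    "enumerate_posterior",
    "make_target_model",
    "LIKELIHOOD_PRESET",
    "ABC_PRESET",
]

#: probabilities are clipped into this open interval when drawn
_P_EPS = 1e-6

#: likelihood-based study conditions: 20 diseases, 80 findings, one case vector.
#: Sparse-graph networks (small leaks, few strong parents per finding) keep the
#: diseases identifiable from the findings; dense uniform parameters saturate
#: the noisy-OR and leave the posterior nearly flat.
LIKELIHOOD_PRESET = dict(m=20, n=80, N=1, param_mode="sparse")

#: likelihood-free study conditions: reduced dimension, peaked Beta parameters
ABC_PRESET = dict(m=10, n=20, N=10, param_mode="beta", beta_a=0.15, beta_b=0.15)


@dataclass
class QMRNetwork:
    """Noisy-OR network parameters (all strictly inside (0, 1))."""

    leak: np.ndarray          # (n,)  q_i0
    assoc: np.ndarray         # (n, m)  q_il
    disease_prior: np.ndarray  # (m,)  p_l

    def __post_init__(self) -> None:
        self.leak = np.asarray(self.leak, dtype=float)
        self.assoc = np.asarray(self.assoc, dtype=float)
        self.disease_prior = np.asarray(self.disease_prior, dtype=float)
        n, m = self.assoc.shape
        if self.leak.shape != (n,) or self.disease_prior.shape != (m,):
            raise ValueError(
                "inconsistent dimensions: leak must match assoc rows, "
                "disease_prior must match assoc columns"
            )
        for name, arr in (
            ("leak", self.leak),
            ("assoc", self.assoc),
            ("disease_prior", self.disease_prior),
        ):
            if np.any((arr <= 0.0) | (arr >= 1.0)):
                raise ValueError(f"{name} entries must lie strictly inside (0, 1)")
        # cached terms for the noisy-OR product and the Bernoulli prior
        self._one_minus_leak = 1.0 - self.leak
        self._log1m_assoc = np.log1p(-self.assoc)
        self._logit_prior = np.log(self.disease_prior) - np.log1p(-self.disease_prior)
        self._log1m_prior_sum = float(np.sum(np.log1p(-self.disease_prior)))

    @property
    def n(self) -> int:
        return self.assoc.shape[0]

    @property
    def m(self) -> int:
        return self.assoc.shape[1]


@dataclass
class ProblemInstance:
    """A network, its ground-truth disease vector, and simulated findings."""

    network: QMRNetwork
    x_true: np.ndarray
    ydata: np.ndarray  # (N, n)

    def __post_init__(self) -> None:
        self.x_true = bitspace.as_bits(self.x_true)
        self.ydata = np.atleast_2d(np.asarray(self.ydata, dtype=np.uint8))
        if self.x_true.size != self.network.m:
            raise ValueError("x_true length must equal the number of diseases")
        if self.ydata.shape[1] != self.network.n or self.ydata.shape[0] < 1:
            raise ValueError("ydata must be an (N >= 1, n) bit array")

    def hamming_error(self, x: np.ndarray) -> float:
        """Hamming distance of a candidate disease vector from the truth."""
        return float(np.count_nonzero(x != self.x_true))

    # -- plain-text round trip -------------------------------------------
    def to_text(self) -> str:
        buf = io.StringIO()
        net = self.network
        buf.write(f"# qmrdt instance m={net.m} n={net.n} N={self.ydata.shape[0]}\n")
        np.savetxt(buf, net.leak[None, :], header="leak", comments="# ")
        np.savetxt(buf, net.assoc, header="assoc", comments="# ")
        np.savetxt(buf, net.disease_prior[None, :], header="disease_prior", comments="# ")
        np.savetxt(buf, self.x_true[None, :], fmt="%d", header="x_true", comments="# ")
        np.savetxt(buf, self.ydata, fmt="%d", header="ydata", comments="# ")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "ProblemInstance":
        sections: dict[str, list[list[float]]] = {}
        current: list[list[float]] | None = None
        for line in text.splitlines():
            if line.startswith("#"):
                name = line[1:].strip().split()[0]
                if name in ("leak", "assoc", "disease_prior", "x_true", "ydata"):
                    current = sections.setdefault(name, [])
            elif line.strip() and current is not None:
                current.append([float(v) for v in line.split()])
        leak = np.asarray(sections["leak"]).ravel()
        assoc = np.asarray(sections["assoc"])
        prior = np.asarray(sections["disease_prior"]).ravel()
        x_true = np.asarray(sections["x_true"]).ravel().astype(np.uint8)
        ydata = np.asarray(sections["ydata"]).astype(np.uint8)
        return cls(QMRNetwork(leak, assoc, prior), x_true, ydata)


def finding_probability(network: QMRNetwork, x: np.ndarray) -> np.ndarray:
    """P(y_i = 1 | x) for every finding under the noisy-OR model."""
    x = np.asarray(x)
    if x.shape[-1] != network.m:
        raise ValueError(f"x has length {x.shape[-1]}, expected m={network.m}")
    log_fail = network._log1m_assoc @ x.astype(float)
    return 1.0 - network._one_minus_leak * np.exp(log_fail)


def simulate_findings(
    network: QMRNetwork, x: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one findings vector from the noisy-OR conditional."""
    p = finding_probability(network, x)
    return (rng.random(network.n) < p).astype(np.uint8)


def log_likelihood(network: QMRNetwork, x: np.ndarray, ydata: np.ndarray) -> float:
    """Exact log likelihood of the observed findings given diseases ``x``."""
    ydata = np.atleast_2d(np.asarray(ydata, dtype=float))
    if ydata.shape[1] != network.n:
        raise ValueError("ydata row length must equal the number of findings")
    p = finding_probability(network, x)
    p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    return float(np.sum(ydata * np.log(p) + (1.0 - ydata) * np.log1p(-p)))


def log_prior(disease_prior: np.ndarray, x: np.ndarray) -> float:
    """Independent Bernoulli log prior over the disease vector."""
    disease_prior = np.asarray(disease_prior, dtype=float)
    x = np.asarray(x, dtype=float)
    if disease_prior.shape != x.shape:
        raise ValueError("disease_prior and x must have equal length")
    return float(
        np.sum(x * np.log(disease_prior) + (1.0 - x) * np.log1p(-disease_prior))
    )


def _draw_probs(shape, param_mode, beta_a, beta_b, rng) -> np.ndarray:
    if param_mode == "beta":
        p = rng.beta(beta_a, beta_b, size=shape)
    elif param_mode == "uniform":
        p = rng.random(shape)
    else:
        raise ValueError(f"unknown param_mode {param_mode!r}")
    return np.clip(p, _P_EPS, 1.0 - _P_EPS)


def _draw_sparse_network(n, m, rng, mean_parents=3.0) -> tuple[np.ndarray, np.ndarray]:
    """Diagnostic-style network: small leaks, few strong parents per finding.

    Edges appear with probability ``mean_parents / m`` (at least one parent
    per finding); association strengths on edges are uniform on (0.2, 0.9),
    absent edges carry a negligible probability so all entries stay inside
    (0, 1).  Leaks are uniform on (0.005, 0.05).
    """
    leak = rng.uniform(0.005, 0.05, n)
    edges = rng.random((n, m)) < min(1.0, mean_parents / m)
    for i in np.flatnonzero(~edges.any(axis=1)):
        edges[i, rng.integers(m)] = True
    strength = rng.uniform(0.2, 0.9, (n, m))
    assoc = np.where(edges, strength, _P_EPS)
    return leak, assoc


def generate_instance(
    m: int,
    n: int,
    N: int,
    rng: np.random.Generator,
    param_mode: str = "beta",
    beta_a: float = 0.15,
    beta_b: float = 0.15,
    prior_mode: str | None = None,
) -> ProblemInstance:
    """Draw a random problem instance: network, true diseases, findings.

    ``param_mode="beta"`` draws every network probability — leaks,
    associations and disease priors — from Beta(beta_a, beta_b);
    ``param_mode="uniform"`` draws leaks/associations uniformly on (0, 1);
    ``param_mode="sparse"`` draws a diagnostic-style network (small leaks,
    a sparse strong-edge association graph).  Outside beta mode the default
    disease priors are sparse, uniform on (0.01, 0.5), so the true disease
    vector stays sparse; ``prior_mode`` ∈ {"match", "sparse"} overrides the
    pairing.
    """
    if min(m, n, N) < 1:
        raise ValueError("m, n and N must all be >= 1")
    if beta_a <= 0 or beta_b <= 0:
        raise ValueError("beta shape parameters must be positive")
    if param_mode == "sparse":
        leak, assoc = _draw_sparse_network(n, m, rng)
    else:
        leak = _draw_probs(n, param_mode, beta_a, beta_b, rng)
        assoc = _draw_probs((n, m), param_mode, beta_a, beta_b, rng)
    if prior_mode is None:
        prior_mode = "match" if param_mode == "beta" else "sparse"
    if prior_mode == "match":
        prior = _draw_probs(m, param_mode, beta_a, beta_b, rng)
    elif prior_mode == "sparse":
        prior = rng.uniform(0.01, 0.5, size=m)
    else:
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    network = QMRNetwork(leak, assoc, prior)
    x_true = (rng.random(m) < prior).astype(np.uint8)
    ydata = np.stack([simulate_findings(network, x_true, rng) for _ in range(N)])
    return ProblemInstance(network, x_true, ydata)


def enumerate_posterior(network: QMRNetwork, ydata: np.ndarray) -> np.ndarray:
    """Exact posterior over all 2^m disease vectors (indexed as in bitspace).

    Normalized table proportional to exp(log likelihood + log prior);
    refused for m > 12.
    """
    states = bitspace.all_states(network.m)
    logp = np.array(
        [
            log_likelihood(network, x, ydata) + log_prior(network.disease_prior, x)
            for x in states
        ]
    )
    logp -= logp.max()
    w = np.exp(logp)
    return w / w.sum()


def make_target_model(instance: ProblemInstance) -> TargetModel:
    """Bundle an instance into the sampler-facing target model.

    The same model serves both run modes: the exact noisy-OR likelihood for
    likelihood-based Metropolis, and the forward simulator with the mean
    Hamming distance for ABC.
    """
    net = instance.network
    # hot path: closures over precomputed terms, one matvec per evaluation
    logit, log1m_sum = net._logit_prior, net._log1m_prior_sum
    one_minus_leak, log1m_assoc, n = net._one_minus_leak, net._log1m_assoc, net.n
    N = instance.ydata.shape[0]
    ydata = instance.ydata

    def fast_log_prior(x: np.ndarray) -> float:
        return float(x @ logit) + log1m_sum

    def fast_simulator(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        p = 1.0 - one_minus_leak * np.exp(log1m_assoc @ x)
        return rng.random(n) < p

    def fast_distance(y: np.ndarray, ydata_rows: np.ndarray) -> float:
        return np.count_nonzero(ydata_rows != y) / N

    return TargetModel(
        log_prior=fast_log_prior,
        log_likelihood=lambda x: log_likelihood(net, x, ydata),
        simulator=fast_simulator,
        distance=fast_distance,
        ydata=ydata,
    )
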