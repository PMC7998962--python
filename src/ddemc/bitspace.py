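"""Binary parameter vectors and population-based proposal kernels.

The state space is ``{0,1}^D``.  A *population* of ``C`` chains is stored as a
``(C, D)`` uint8 array; proposals for chain ``i`` may use the rest of the
population.  The differential kernels translate the classic differential
evolution move ``x + gamma (x_j - x_k)`` to bit space by replacing the
subtraction with xor and the Gaussian noise with independent bit flips:

* ``dde-mc``  : ``x_new = x_i  xor  mut(x_j xor x_k)`` — flip noise is applied
  to the *difference*, which makes every state reachable (irreducibility)
  while keeping the proposal symmetric.
* ``mut+xor`` : mixture ``pi * mut(x_i) + (1 - pi) * (x_i xor (x_j xor x_k))``.
* ``mut``     : independent bit flips of the current state.
* ``mut+crx`` : mixture of ``mut`` with a single-offspring uniform crossover
  against a random partner (a reconstruction of an earlier evolutionary MCMC
  move; not exactly symmetric, see docs/methods.md).
* ``ind-samp``: product-Bernoulli independent sampler, ignores the population.
* ``xor``     : the bare difference move without noise; it is *not* ergodic
  (a constant population can never leave the current state) and is kept only
  as a diagnostic.

``enumerate_proposal_distribution`` computes the exact transition law of each
kernel by exhaustive enumeration over partner pairs; it is the oracle used by
the test suite to certify symmetry and irreducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KERNELS",
    "ProposalConfig",
    "as_bits",
    "hamming",
    "xor_diff",
    "sample_partner_pair",
    "sample_difference",
    "mutate",
    "propose_dde_mc",
    "propose_mut",
    "propose_mut_xor",
    "propose_mut_crx",
    "propose_ind_samp",
    "propose",
    "all_states",
    "state_index",
    "enumerate_proposal_distribution",
]

#: kernels selectable by name ("xor" is diagnostic only — not ergodic)
KERNELS = ("dde-mc", "mut", "mut+xor", "mut+crx", "ind-samp", "xor")

#: largest D for which exhaustive 2^D enumeration is allowed
MAX_ENUM_D = 12


def as_bits(x) -> np.ndarray:
    """Validate and convert ``x`` to a 1-D uint8 bit vector."""
    arr = np.asarray(x)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("bit vector must be one-dimensional and non-empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("bit vector entries must be 0 or 1")
    return arr.astype(np.uint8)


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of disagreeing positions between two equal-length bit vectors."""
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def xor_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Bitwise difference: 1 exactly where ``a`` and ``b`` disagree."""
    if a.shape != b.shape:
        raise ValueError(f"incompatible vectors: length {a.shape} vs {b.shape}")
    return np.bitwise_xor(a, b)


@dataclass
class ProposalConfig:
    """Settings for a proposal kernel.

    Parameters
    ----------
    kernel_name
        One of :data:`KERNELS`.
    p_flip
        Per-bit flip probability of the mutation operator, in (0, 1).
    pi_mix
        Mixture weight of the mutation branch in ``mut+xor`` / ``mut+crx``.
    p_cross
        Per-bit probability of inheriting the partner's bit in ``mut+crx``.
    theta
        Per-bit Bernoulli parameters of ``ind-samp``; ``None`` means 0.5
        everywhere (the uniform, hence symmetric, independent sampler).
    include_current
        Whether chain ``i`` itself may be drawn as a difference partner
        (sensitivity flag; the default mirrors the DE-1 convention j != k != i).
    """

    kernel_name: str = "dde-mc"
    p_flip: float = 0.01
    pi_mix: float = 0.5
    p_cross: float = 0.5
    theta: np.ndarray | None = None
    include_current: bool = False

    def __post_init__(self) -> None:
        if self.kernel_name not in KERNELS:
            raise ValueError(
                f"unknown kernel {self.kernel_name!r}; choose from {KERNELS}"
            )
        for name in ("p_flip", "pi_mix", "p_cross"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly inside (0, 1), got {v}")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
            if np.any((self.theta <= 0) | (self.theta >= 1)):
                raise ValueError("theta entries must lie strictly inside (0, 1)")

    def theta_for(self, D: int) -> np.ndarray:
        if self.theta is None:
            return np.full(D, 0.5)
        if self.theta.size != D:
            raise ValueError(
                f"theta has length {self.theta.size}, expected D={D}"
            )
        return self.theta


def _check_population(pop: np.ndarray, i: int) -> None:
    if pop.ndim != 2:
        raise ValueError("population must be a (C, D) array")
    C = pop.shape[0]
    if not 0 <= i < C:
        raise IndexError(f"chain index {i} out of range for C={C}")
    if C < 3:
        raise ValueError(
            "differential proposals need a population of at least 3 chains "
            f"(got C={C}): two distinct partners plus the updated chain"
        )


def sample_partner_pair(
    C: int, i: int, rng: np.random.Generator, include_current: bool = False
) -> tuple[int, int]:
    """Uniform ordered pair (j, k), j != k, both != i unless ``include_current``."""
    if include_current:
        j = int(rng.integers(C))
        k = int(rng.integers(C - 1))
        if k >= j:
            k += 1
        return j, k
    j = int(rng.integers(C - 1))
    if j >= i:
        j += 1
    k = int(rng.integers(C - 2))
    lo, hi = (i, j) if i < j else (j, i)
    if k >= lo:
        k += 1
    if k >= hi:
        k += 1
    return j, k


def sample_difference(
    pop: np.ndarray,
    i: int,
    rng: np.random.Generator,
    include_current: bool = False,
) -> np.ndarray:
    """Draw the xor difference of a uniform ordered pair of distinct chains."""
    _check_population(pop, i)
    j, k = sample_partner_pair(pop.shape[0], i, rng, include_current)
    return np.bitwise_xor(pop[j], pop[k])


def mutate(x: np.ndarray, p_flip: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``p_flip``."""
    if not 0.0 < p_flip < 1.0:
        raise ValueError(f"p_flip must lie strictly inside (0, 1), got {p_flip}")
    flips = rng.random(x.shape[0]) < p_flip
    return np.bitwise_xor(x, flips.astype(np.uint8))


def propose_dde_mc(
    pop: np.ndarray,
    i: int,
    p_flip: float,
    rng: np.random.Generator,
    include_current: bool = False,
) -> np.ndarray:
    """Discrete differential evolution move: xor a mutated chain difference."""
    delta = sample_difference(pop, i, rng, include_current)
    return np.bitwise_xor(pop[i], mutate(delta, p_flip, rng))


def propose_mut(
    pop: np.ndarray, i: int, p_flip: float, rng: np.random.Generator
) -> np.ndarray:
    return mutate(pop[i], p_flip, rng)


def propose_mut_xor(
    pop: np.ndarray, i: int, cfg: ProposalConfig, rng: np.random.Generator
) -> np.ndarray:
    """Mixture of mutation and the bare xor-difference move."""
    _check_population(pop, i)
    if rng.random() < cfg.pi_mix:
        return mutate(pop[i], cfg.p_flip, rng)
    delta = sample_difference(pop, i, rng, cfg.include_current)
    return np.bitwise_xor(pop[i], delta)


def propose_mut_crx(
    pop: np.ndarray, i: int, cfg: ProposalConfig, rng: np.random.Generator
) -> np.ndarray:
    """Mixture of mutation and single-offspring uniform crossover.

    Reconstruction of an evolutionary-MCMC crossover move: a partner ``x_j``
    (j != i) is chosen uniformly and each bit of the offspring is taken from
    the partner with probability ``p_cross``, otherwise kept from ``x_i``.
    """
    _check_population(pop, i)
    if rng.random() < cfg.pi_mix:
        return mutate(pop[i], cfg.p_flip, rng)
    j = int(rng.integers(pop.shape[0] - 1))
    if j >= i:
        j += 1
    take = rng.random(pop.shape[1]) < cfg.p_cross
    return np.where(take, pop[j], pop[i]).astype(np.uint8)


def propose_ind_samp(
    D: int, theta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independent product-Bernoulli draw; ignores the current state."""
    theta = np.asarray(theta, dtype=float)
    if theta.size != D:
        raise ValueError(f"theta has length {theta.size}, expected D={D}")
    return (rng.random(D) < theta).astype(np.uint8)


def propose_xor(
    pop: np.ndarray,
    i: int,
    rng: np.random.Generator,
    include_current: bool = False,
) -> np.ndarray:
    """Bare difference move (diagnostic; not irreducible on its own)."""
    delta = sample_difference(pop, i, rng, include_current)
    return np.bitwise_xor(pop[i], delta)


def propose(
    pop: np.ndarray, i: int, cfg: ProposalConfig, rng: np.random.Generator
) -> np.ndarray:
    """Dispatch a proposal for chain ``i`` according to ``cfg.kernel_name``."""
    name = cfg.kernel_name
    if name == "dde-mc":
        return propose_dde_mc(pop, i, cfg.p_flip, rng, cfg.include_current)
    if name == "mut":
        return propose_mut(pop, i, cfg.p_flip, rng)
    if name == "mut+xor":
        return propose_mut_xor(pop, i, cfg, rng)
    if name == "mut+crx":
        return propose_mut_crx(pop, i, cfg, rng)
    if name == "ind-samp":
        return propose_ind_samp(pop.shape[1], cfg.theta_for(pop.shape[1]), rng)
    if name == "xor":
        return propose_xor(pop, i, rng, cfg.include_current)
    raise ValueError(f"unknown kernel {name!r}")  # pragma: no cover


def crossover_mixture_log_prob(
    pop: np.ndarray,
    i: int,
    x_target: np.ndarray,
    cfg: ProposalConfig,
    x_from: np.ndarray | None = None,
) -> float:
    """Exact log q(x_target | x_i, rest) for the ``mut+crx`` kernel.

    Unlike the other kernels, single-offspring uniform crossover is not
    symmetric (a partner can force bits), so its Metropolis step needs the
    proposal ratio q(x|x') / q(x'|x).  Closed form in O(C * D): the mutation
    branch is a product of per-bit flip probabilities and the crossover
    branch averages the per-partner inheritance law.
    """
    C, D = pop.shape
    x_i = pop[i] if x_from is None else x_from
    h = int(np.count_nonzero(x_target != x_i))
    q_mut = cfg.p_flip**h * (1.0 - cfg.p_flip) ** (D - h)
    partners = np.delete(pop, i, axis=0)  # (C-1, D)
    same = partners == x_i
    forced_ok = ~np.any(same & (x_target != x_i), axis=1)
    take = np.count_nonzero(~same & (x_target == partners), axis=1)
    keep = np.count_nonzero(~same, axis=1) - take
    per_partner = forced_ok * cfg.p_cross**take * (1.0 - cfg.p_cross) ** keep
    q_crx = float(per_partner.sum()) / (C - 1)
    q = cfg.pi_mix * q_mut + (1.0 - cfg.pi_mix) * q_crx
    return float(np.log(q)) if q > 0.0 else -np.inf


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def all_states(D: int) -> np.ndarray:
    """All 2^D bit vectors as a (2^D, D) array, index = binary encoding."""
    if D > MAX_ENUM_D:
        raise ValueError(
            f"enumeration over 2^{D} states refused (limit D <= {MAX_ENUM_D})"
        )
    grid = np.indices((2,) * D).reshape(D, -1).T
    return grid.astype(np.uint8)


def state_index(x: np.ndarray) -> int:
    """Binary encoding of a bit vector (first bit most significant)."""
    return int(np.dot(x.astype(np.int64), 1 << np.arange(x.size - 1, -1, -1)))


def _partner_pairs(C: int, i: int, include_current: bool) -> list[tuple[int, int]]:
    idx = [c for c in range(C)] if include_current else [c for c in range(C) if c != i]
    return [(j, k) for j in idx for k in idx if j != k]


def _mut_law(x_from: np.ndarray, states: np.ndarray, p: float) -> np.ndarray:
    """Exact law of independent bit flips: p^h (1-p)^(D-h) per target state."""
    D = x_from.size
    h = np.count_nonzero(states != x_from, axis=1)
    return p**h * (1.0 - p) ** (D - h)


def enumerate_proposal_distribution(
    pop: np.ndarray, i: int, cfg: ProposalConfig
) -> np.ndarray:
    """Exact proposal law ``q(x' | x_i, rest)`` over all 2^D states.

    Returns a vector of length ``2^D`` indexed by :func:`state_index`.
    Partner pairs are enumerated exhaustively, and the mutation layer is
    folded in analytically, so the table is exact to floating point.
    """
    pop = np.asarray(pop, dtype=np.uint8)
    C, D = pop.shape
    states = all_states(D)
    x_i = pop[i]
    name = cfg.kernel_name

    if name == "ind-samp":
        theta = cfg.theta_for(D)
        return np.prod(np.where(states == 1, theta, 1.0 - theta), axis=1)
    if name == "mut":
        return _mut_law(x_i, states, cfg.p_flip)

    _check_population(pop, i)
    pairs = _partner_pairs(C, i, cfg.include_current)

    if name in ("dde-mc", "xor"):
        q = np.zeros(states.shape[0])
        for j, k in pairs:
            target = np.bitwise_xor(x_i, np.bitwise_xor(pop[j], pop[k]))
            if name == "xor":
                q[state_index(target)] += 1.0
            else:
                # x' = x_i ^ delta ^ flips  =>  flip pattern is fixed per x'
                q += _mut_law(target, states, cfg.p_flip)
        return q / len(pairs)

    if name == "mut+xor":
        q_xor = np.zeros(states.shape[0])
        for j, k in pairs:
            target = np.bitwise_xor(x_i, np.bitwise_xor(pop[j], pop[k]))
            q_xor[state_index(target)] += 1.0
        q_xor /= len(pairs)
        q_mut = _mut_law(x_i, states, cfg.p_flip)
        return cfg.pi_mix * q_mut + (1.0 - cfg.pi_mix) * q_xor

    if name == "mut+crx":
        partners = [c for c in range(C) if c != i]
        q_crx = np.zeros(states.shape[0])
        for j in partners:
            same = pop[j] == x_i
            # bit-wise inheritance law given partner j
            per_bit = np.where(
                same,
                (states == x_i).astype(float),  # forced bit
                np.where(states == pop[j], cfg.p_cross, 1.0 - cfg.p_cross),
            )
            q_crx += np.prod(per_bit, axis=1)
        q_crx /= len(partners)
        q_mut = _mut_law(x_i, states, cfg.p_flip)
        return cfg.pi_mix * q_mut + (1.0 - cfg.pi_mix) * q_crx

    raise ValueError(f"unknown kernel {name!r}")  # pragma: no cover
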