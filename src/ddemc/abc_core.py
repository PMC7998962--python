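"""Population MCMC in bit space: likelihood-based and likelihood-free steps.

The sampler runs ``C`` parallel chains over a product target in which every
chain has the same stationary law (the posterior over the bit vector).  One
iteration sweeps the chains in index order; each chain proposes a move with a
population-aware kernel from :mod:`ddemc.bitspace`, so later chains in the
sweep see the partially updated population (a standard single-sweep scheme; a
``frozen_sweep`` flag reverts to proposals drawn from the population as it
stood at the start of the iteration).

Two update rules are available:

* :func:`likelihood_step` — plain Metropolis with the exact log posterior,
  used when the likelihood is tractable.
* :func:`abc_step` — the likelihood-free rule: simulate data from the
  proposed state, reject outright if the simulated data falls outside an
  ``epsilon``-ball of the observed data under the chosen distance, and
  otherwise apply Metropolis with the *prior* ratio only (the likelihood is
  replaced by the ball indicator).  All kernels used here are symmetric, so
  no proposal correction appears in the ratio.

The tolerance ``epsilon`` is either fixed or redrawn from an exponential law
(mean ``tau``) at every proposal evaluation, per chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import bitspace
from .bitspace import ProposalConfig

__all__ = [
    "ToleranceSchedule",
    "TargetModel",
    "ChainState",
    "RunTrace",
    "mean_hamming_distance",
    "sample_epsilon",
    "abc_step",
    "likelihood_step",
    "run_population",
]

logger = logging.getLogger("ddemc")


def _hastings_correction(
    pop: np.ndarray, i: int, x_new: np.ndarray, cfg: ProposalConfig
) -> float:
    """log q(x_i | x_new, rest) - log q(x_new | x_i, rest).

    Zero for the symmetric kernels; the single-offspring crossover mixture
    is the one asymmetric proposal and gets the exact closed-form ratio so
    its Metropolis step still targets the intended law.
    """
    if cfg.kernel_name != "mut+crx":
        return 0.0
    fwd = bitspace.crossover_mixture_log_prob(pop, i, x_new, cfg)
    rev = bitspace.crossover_mixture_log_prob(pop, i, pop[i], cfg, x_from=x_new)
    return rev - fwd

#: kernels that require at least 3 chains (two partners besides the current one)
_DIFFERENTIAL_KERNELS = ("dde-mc", "mut+xor", "mut+crx", "xor")


@dataclass
class ToleranceSchedule:
    """Fixed tolerance or per-proposal exponential tolerance.

    ``mode="fixed"`` returns ``epsilon`` verbatim; ``mode="exponential"``
    draws a fresh value from an exponential distribution with **mean**
    ``tau`` at every proposal evaluation.  The mean parameterization keeps
    ``tau`` on the same scale as the fixed-epsilon sweep (0.5 ... 2.0).
    """

    mode: str = "fixed"
    epsilon: float | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "exponential"):
            raise ValueError(f"unknown tolerance mode {self.mode!r}")
        if self.mode == "fixed":
            if self.epsilon is None or self.epsilon <= 0:
                raise ValueError("fixed mode requires epsilon > 0")
        else:
            if self.tau is None or self.tau <= 0:
                raise ValueError("exponential mode requires tau > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.mode == "fixed":
            return float(self.epsilon)
        return float(rng.standard_exponential() * self.tau)


def sample_epsilon(schedule: ToleranceSchedule, rng: np.random.Generator) -> float:
    """Draw the tolerance for one proposal evaluation."""
    return schedule.sample(rng)


def mean_hamming_distance(y: np.ndarray, ydata: np.ndarray) -> float:
    """Average Hamming distance between ``y`` and each row of ``ydata``.

    Fractional values arise from averaging over the observed vectors, which
    is what makes sub-integer tolerances meaningful.
    """
    ydata = np.atleast_2d(np.asarray(ydata))
    if ydata.shape[0] == 0:
        raise ValueError("ydata must contain at least one observed vector")
    if ydata.shape[1] != np.asarray(y).shape[0]:
        raise ValueError(
            f"length mismatch: y has {np.asarray(y).shape[0]} bits, "
            f"ydata rows have {ydata.shape[1]}"
        )
    return float(np.count_nonzero(ydata != y) / ydata.shape[0])


@dataclass
class TargetModel:
    """Inference target: prior plus either an exact likelihood or a simulator.

    Exactly one of the two acceptance drivers is used per run: the
    likelihood-based step needs ``log_likelihood``; the ABC step needs
    ``simulator`` (a stochastic map ``x, rng -> y``) together with
    ``distance`` (a map ``y, ydata -> nonnegative float``) and ``ydata``.
    """

    log_prior: Callable[[np.ndarray], float]
    log_likelihood: Callable[[np.ndarray], float] | None = None
    simulator: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None
    distance: Callable[[np.ndarray, np.ndarray], float] | None = None
    ydata: np.ndarray | None = None

    def require_abc(self) -> None:
        if self.simulator is None or self.distance is None or self.ydata is None:
            raise ValueError(
                "ABC mode requires simulator, distance and ydata on the model"
            )

    def require_likelihood(self) -> None:
        if self.log_likelihood is None:
            raise ValueError("likelihood mode requires log_likelihood on the model")


@dataclass
class ChainState:
    """Per-chain bookkeeping: current state, best score seen, counters."""

    x: np.ndarray
    best_x: np.ndarray | None = None
    best_score: float = np.inf
    n_accepted: int = 0
    n_proposed: int = 0
    # cached log prior (and log posterior in likelihood mode) of ``x``
    log_prior: float = np.nan
    log_post: float = np.nan

    def record_accept(self, x_new: np.ndarray, score: float, better) -> None:
        self.x = x_new
        self.n_accepted += 1
        if self.best_x is None or better(score, self.best_score):
            self.best_score = score
            self.best_x = x_new.copy()


def abc_step(
    state: ChainState,
    pop: np.ndarray,
    i: int,
    model: TargetModel,
    schedule: ToleranceSchedule,
    cfg: ProposalConfig,
    rng: np.random.Generator,
) -> ChainState:
    """One likelihood-free update of chain ``i`` (mutates ``state`` and ``pop``).

    Propose, simulate once, gate on the epsilon-ball, then Metropolis with
    the prior ratio.  A completed assignment counts as an acceptance even
    when the proposed vector happens to equal the current one — the
    acceptance-rate bookkeeping mirrors the algorithm's accept branch.
    """
    state.n_proposed += 1
    x_new = bitspace.propose(pop, i, cfg, rng)
    try:
        y = model.simulator(x_new, rng)
    except Exception as exc:  # annotate failures with the chain index
        raise RuntimeError(f"simulator failed for chain {i}: {exc}") from exc
    dist = model.distance(y, model.ydata)
    eps = schedule.sample(rng)
    if dist > eps:
        return state
    lp_new = model.log_prior(x_new)
    if np.isnan(state.log_prior):
        state.log_prior = model.log_prior(state.x)
    log_alpha = lp_new - state.log_prior + _hastings_correction(pop, i, x_new, cfg)
    if log_alpha >= 0.0 or rng.random() < np.exp(log_alpha):
        state.record_accept(x_new, dist, better=lambda a, b: a < b)
        state.log_prior = lp_new
        pop[i] = x_new
    return state


def likelihood_step(
    state: ChainState,
    pop: np.ndarray,
    i: int,
    model: TargetModel,
    cfg: ProposalConfig,
    rng: np.random.Generator,
) -> ChainState:
    """One Metropolis update of chain ``i`` with the exact log posterior."""
    state.n_proposed += 1
    x_new = bitspace.propose(pop, i, cfg, rng)
    lp_new = model.log_prior(x_new)
    ll_new = model.log_likelihood(x_new)
    post_new = lp_new + ll_new
    if not np.isfinite(post_new):
        logger.warning("non-finite log posterior at chain %d; auto-rejecting", i)
        post_new = -np.inf
    if np.isnan(state.log_post):
        state.log_post = model.log_prior(state.x) + model.log_likelihood(state.x)
    log_alpha = post_new - state.log_post + _hastings_correction(pop, i, x_new, cfg)
    if log_alpha >= 0.0 or rng.random() < np.exp(log_alpha):
        state.record_accept(x_new, post_new, better=lambda a, b: a > b)
        state.log_post = post_new
        pop[i] = x_new
    return state


@dataclass
class RunTrace:
    """Per-iteration record of a population run.

    ``records`` holds one row per recording interval with the iteration
    number, population-average and population-minimum error (under the
    caller-supplied ``error_fn``) and the cumulative acceptance fraction.
    ``samples`` optionally stores every visited population (for occupancy
    statistics); ``population`` is the final population.
    """

    records: pd.DataFrame
    population: np.ndarray
    chains: list[ChainState]
    samples: np.ndarray | None = None
    seed_info: dict = field(default_factory=dict)

    @property
    def acceptance_fraction(self) -> float:
        prop = sum(c.n_proposed for c in self.chains)
        acc = sum(c.n_accepted for c in self.chains)
        return acc / prop if prop else 0.0

    @property
    def best_chain(self) -> ChainState:
        return min(self.chains, key=lambda c: c.best_score)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def run_population(
    model: TargetModel,
    schedule: ToleranceSchedule | None,
    cfg: ProposalConfig,
    C: int,
    D: int,
    n_iterations: int,
    rng: np.random.Generator,
    *,
    mode: str = "abc",
    error_fn: Callable[[np.ndarray], float] | None = None,
    record_every: int = 50,
    collect_samples: bool = False,
    burn_in: int = 0,
    frozen_sweep: bool = False,
    init: np.ndarray | None = None,
) -> RunTrace:
    """Run ``C`` chains for ``n_iterations`` sweeps and record a trace.

    Parameters
    ----------
    mode
        ``"abc"`` (simulator + distance + tolerance) or ``"likelihood"``.
    error_fn
        Optional per-state error (e.g. Hamming distance to a known truth);
        recorded as population average and minimum at every interval.
    collect_samples
        Store every post-burn-in population (``(n_kept, C, D)`` array) for
        occupancy/posterior checks.
    burn_in
        Iterations discarded from ``samples`` (the trace records them).
    frozen_sweep
        Propose from the population as it stood at the start of each
        iteration instead of the partially updated one.
    init
        Optional initial ``(C, D)`` population; default independent uniform
        bits.
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    if mode not in ("abc", "likelihood"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "abc":
        if schedule is None:
            raise ValueError("abc mode requires a tolerance schedule")
        model.require_abc()
    else:
        model.require_likelihood()
    if cfg.kernel_name in _DIFFERENTIAL_KERNELS and C < 3:
        raise ValueError(
            f"kernel {cfg.kernel_name!r} needs C >= 3 chains, got C={C}"
        )

    if init is not None:
        pop = np.array(init, dtype=np.uint8, copy=True)
        if pop.shape != (C, D):
            raise ValueError(f"init has shape {pop.shape}, expected {(C, D)}")
    else:
        pop = (rng.random((C, D)) < 0.5).astype(np.uint8)

    chains = [ChainState(x=pop[c].copy()) for c in range(C)]
    rows: list[tuple] = []
    kept: list[np.ndarray] = []

    def record(it: int) -> None:
        if error_fn is not None:
            errs = [error_fn(pop[c]) for c in range(C)]
            avg, mn = float(np.mean(errs)), float(np.min(errs))
        else:
            avg = mn = np.nan
        prop = sum(c.n_proposed for c in chains)
        acc = sum(c.n_accepted for c in chains)
        rows.append((it, avg, mn, acc / prop if prop else np.nan))

    record(0)
    for it in range(1, n_iterations + 1):
        context = pop.copy() if frozen_sweep else pop
        for c in range(C):
            if mode == "abc":
                abc_step(chains[c], context, c, model, schedule, cfg, rng)
            else:
                likelihood_step(chains[c], context, c, model, cfg, rng)
            if frozen_sweep:
                context[c] = pop[c]  # keep the proposal context frozen
        if frozen_sweep:
            for c in range(C):
                pop[c] = chains[c].x
        if collect_samples and it > burn_in:
            kept.append(pop.copy())
        if it % record_every == 0 or it == n_iterations:
            record(it)

    records = pd.DataFrame(
        rows,
        columns=["iteration", "avg_error", "min_error", "acceptance_fraction"],
    ).drop_duplicates(subset="iteration", keep="last")
    samples = np.stack(kept) if kept else None
    return RunTrace(records=records, population=pop, chains=chains, samples=samples)
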