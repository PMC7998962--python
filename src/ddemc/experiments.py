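"""Configuration-driven experiment runner over the three test-beds.

An :class:`ExperimentConfig` names a test-bed (likelihood-based QMR-DT,
likelihood-free QMR-DT, or the synthetic binary-network task), a proposal
kernel and its parameters, a tolerance schedule, and a cross-evaluation
count.  :func:`run_experiment` draws that many independent problem
instances from the run seed (one spawned substream per instance, so runs
are reproducible bit-for-bit and instances could be dispatched
concurrently without changing the results), runs the population sampler on
each, and aggregates the final error metrics and acceptance percentages
with their standard errors across instances.

The error metric on the QMR-DT test-beds is the Hamming distance between a
chain's current disease vector and the ground truth, reported as the
population average and the population minimum; on the network task it is
the training classification error.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import binnn, qmrdt
from .abc_core import RunTrace, ToleranceSchedule, run_population
from .bitspace import ProposalConfig

__all__ = [
    "TESTBEDS",
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "run_single_instance",
    "posterior_comparison_report",
    "load_config",
    "acceptance_rate_protocol",
]

TESTBEDS = ("qmr_likelihood", "qmr_abc", "binnn_synthetic")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    testbed: str = "qmr_abc"
    kernel_name: str = "dde-mc"
    C: int = 24
    p_flip: float = 0.01
    pi_mix: float = 0.5
    p_cross: float = 0.5
    tolerance_mode: str = "exponential"  # "fixed" | "exponential"
    epsilon: float | None = None
    tau: float | None = 2.0
    n_iterations: int = 10_000
    n_instances: int = 20
    seed: int = 0
    record_every: int = 50
    collect_samples: bool = False
    burn_in: int = 0
    frozen_sweep: bool = False
    # test-bed parameters (filled from the preset when None)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.testbed not in TESTBEDS:
            raise ValueError(
                f"unknown testbed {self.testbed!r}; choose from {TESTBEDS}"
            )
        if self.n_iterations < 0 or self.n_instances < 1:
            raise ValueError("n_iterations must be >= 0 and n_instances >= 1")
        # build early so invalid kernel settings fail before any run starts
        self.proposal_config()
        if self.kernel_name in ("dde-mc", "mut+xor", "mut+crx", "xor") and self.C < 3:
            raise ValueError(
                f"kernel {self.kernel_name!r} needs a population of C >= 3 "
                f"chains (got C={self.C}): it proposes with two partner chains"
            )
        if self.testbed != "qmr_likelihood":
            self.tolerance_schedule()
        defaults = {
            "qmr_likelihood": dict(qmrdt.LIKELIHOOD_PRESET),
            "qmr_abc": dict(qmrdt.ABC_PRESET),
            "binnn_synthetic": dict(
                n_in=16, n_hidden=4, N=200, noise=0.05, theta_active=0.5
            ),
        }[self.testbed]
        self.params = {**defaults, **self.params}

    def proposal_config(self) -> ProposalConfig:
        return ProposalConfig(
            kernel_name=self.kernel_name,
            p_flip=self.p_flip,
            pi_mix=self.pi_mix,
            p_cross=self.p_cross,
        )

    def tolerance_schedule(self) -> ToleranceSchedule:
        return ToleranceSchedule(
            mode=self.tolerance_mode, epsilon=self.epsilon, tau=self.tau
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExperimentResult:
    """Per-instance metrics plus cross-instance mean and standard error."""

    config: ExperimentConfig
    per_instance: pd.DataFrame  # one row per instance
    traces: list[RunTrace]

    def summary(self) -> pd.DataFrame:
        """Mean and standard error of each metric across instances."""
        num = self.per_instance.drop(columns=["instance"])
        k = len(num)
        out = pd.DataFrame({"mean": num.mean()})
        # SE undefined for a single instance — flagged as NaN
        out["se"] = num.std(ddof=1) / np.sqrt(k) if k > 1 else np.nan
        out["n_instances"] = k
        return out


def _spawn_rngs(seed: int, k: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(k)]


def run_single_instance(
    config: ExperimentConfig, rng: np.random.Generator
) -> tuple[RunTrace, dict]:
    """Generate one problem instance from ``rng`` and run the sampler on it."""
    p = config.params
    cfg = config.proposal_config()
    if config.testbed in ("qmr_likelihood", "qmr_abc"):
        instance = qmrdt.generate_instance(
            m=p["m"],
            n=p["n"],
            N=p["N"],
            rng=rng,
            param_mode=p.get("param_mode", "beta"),
            beta_a=p.get("beta_a", 0.15),
            beta_b=p.get("beta_b", 0.15),
            prior_mode=p.get("prior_mode"),
        )
        model = qmrdt.make_target_model(instance)
        mode = "likelihood" if config.testbed == "qmr_likelihood" else "abc"
        schedule = None if mode == "likelihood" else config.tolerance_schedule()
        trace = run_population(
            model,
            schedule,
            cfg,
            C=config.C,
            D=instance.network.m,
            n_iterations=config.n_iterations,
            rng=rng,
            mode=mode,
            error_fn=instance.hamming_error,
            record_every=config.record_every,
            collect_samples=config.collect_samples,
            burn_in=config.burn_in,
            frozen_sweep=config.frozen_sweep,
        )
        context = {"instance": instance}
    else:
        data = binnn.generate_synthetic_dataset(
            n_in=p["n_in"], N=p["N"], noise=p["noise"], rng=rng
        )
        model = binnn.make_target_model(data, n_hidden=p["n_hidden"])
        D = binnn.BinaryNet.n_weights(p["n_in"], p["n_hidden"])

        def error_fn(x: np.ndarray) -> float:
            return binnn.classification_error(x, data, p["n_in"], p["n_hidden"])

        trace = run_population(
            model,
            config.tolerance_schedule(),
            cfg,
            C=config.C,
            D=D,
            n_iterations=config.n_iterations,
            rng=rng,
            mode="abc",
            error_fn=error_fn,
            record_every=config.record_every,
            collect_samples=config.collect_samples,
            burn_in=config.burn_in,
            frozen_sweep=config.frozen_sweep,
        )
        context = {"dataset": data}
    return trace, context


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run ``n_instances`` independent instances and aggregate the metrics."""
    rngs = _spawn_rngs(config.seed, config.n_instances)
    rows = []
    traces: list[RunTrace] = []
    for idx, rng in enumerate(rngs):
        trace, _ = run_single_instance(config, rng)
        last = trace.records.iloc[-1]
        rows.append(
            {
                "instance": idx,
                "final_avg_error": last["avg_error"],
                "final_min_error": last["min_error"],
                "acceptance_pct": 100.0 * trace.acceptance_fraction,
            }
        )
        traces.append(trace)
    return ExperimentResult(
        config=config, per_instance=pd.DataFrame(rows), traces=traces
    )


def posterior_comparison_report(
    instance: qmrdt.ProblemInstance, trace: RunTrace, last_k: int
) -> pd.DataFrame:
    """Negative log posterior of the last ``last_k`` populations vs the truth.

    One row per visited state of the last ``last_k`` recorded populations
    (``source="chains"``, unit weight) and one row per state of the exact
    enumerated posterior (``source="exact"``, weight = posterior mass), so
    weighted histograms of the two sources are directly comparable.
    """
    cols = ["source", "neg_log_posterior", "weight"]
    if last_k == 0:
        return pd.DataFrame(columns=cols)
    if trace.samples is None:
        raise ValueError("trace has no stored samples; run with collect_samples")
    posterior = qmrdt.enumerate_posterior(instance.network, instance.ydata)
    from .bitspace import all_states, state_index

    states = all_states(instance.network.m)
    neg_log = -np.log(np.clip(posterior, 1e-300, None))
    rows = []
    for pop in trace.samples[-last_k:]:
        for x in pop:
            rows.append(("chains", neg_log[state_index(x)], 1.0))
    for s, p in zip(states, posterior):
        rows.append(("exact", neg_log[state_index(s)], float(p)))
    return pd.DataFrame(rows, columns=cols)


def load_config(path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return ExperimentConfig(**raw)


def acceptance_rate_protocol(
    kernel_name: str, seed: int, n_instances: int = 20, n_iterations: int = 10_000
) -> ExperimentConfig:
    """The likelihood-free QMR-DT acceptance-rate protocol.

    m=10 diseases, n=20 findings, Beta(0.15, 0.15) network parameters,
    C=24 chains, p_flip=0.01, tolerance drawn per proposal from an
    exponential law with mean 2, acceptance percentage measured over the
    first 10,000 iterations and averaged across instances.
    """
    return ExperimentConfig(
        testbed="qmr_abc",
        kernel_name=kernel_name,
        C=24,
        p_flip=0.01,
        tolerance_mode="exponential",
        tau=2.0,
        n_iterations=n_iterations,
        n_instances=n_instances,
        seed=seed,
    )
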