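"""Sampler-level tests: distances, tolerance schedules, Metropolis steps,
and the population runner's contracts (determinism, counters, invariances)."""

import numpy as np
import pytest

from ddemc.abc_core import (
    ChainState,
    TargetModel,
    ToleranceSchedule,
    abc_step,
    likelihood_step,
    mean_hamming_distance,
    run_population,
    sample_epsilon,
)
from ddemc.bitspace import ProposalConfig


def bits(*vals):
    return np.array(vals, dtype=np.uint8)


class TestMeanHamming:
    @pytest.mark.parametrize(
        "y, ydata, expected",
        [
            (bits(0, 0), [bits(0, 0)], 0.0),
            (bits(0, 0), [bits(1, 1)], 2.0),
            (bits(0, 0), [bits(0, 0), bits(0, 1)], 0.5),
        ],
    )
    def test_examples(self, y, ydata, expected):
        assert mean_hamming_distance(y, np.stack(ydata)) == expected

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            mean_hamming_distance(bits(0, 1), np.empty((0, 2)))

    def test_invariant_to_dataset_order(self, rng):
        y = (rng.random(12) < 0.5).astype(np.uint8)
        ydata = (rng.random((9, 12)) < 0.5).astype(np.uint8)
        perm = rng.permutation(9)
        assert mean_hamming_distance(y, ydata) == mean_hamming_distance(
            y, ydata[perm]
        )


class TestToleranceSchedule:
    def test_fixed_returns_epsilon_verbatim(self, rng):
        sched = ToleranceSchedule(mode="fixed", epsilon=2.0)
        assert all(sample_epsilon(sched, rng) == 2.0 for _ in range(10))

    def test_exponential_mean_parameterization(self, rng):
        sched = ToleranceSchedule(mode="exponential", tau=2.0)
        n = 100_000
        draws = np.array([sample_epsilon(sched, rng) for _ in range(n)])
        assert np.all(draws > 0)
        # exponential with mean tau: SD equals the mean
        assert abs(draws.mean() - 2.0) <= 3 * 2.0 / np.sqrt(n)

    @pytest.mark.parametrize(
        "kwargs", [dict(mode="fixed"), dict(mode="exponential", tau=-1.0),
                   dict(mode="weird", epsilon=1.0)]
    )
    def test_invalid_configurations(self, kwargs):
        with pytest.raises(ValueError):
            ToleranceSchedule(**kwargs)


def _flat_prior_model(simulator, ydata, distance=mean_hamming_distance):
    return TargetModel(
        log_prior=lambda x: 0.0,
        simulator=simulator,
        distance=distance,
        ydata=np.atleast_2d(ydata),
    )


class TestAbcStep:
    def test_ball_rejection_leaves_state_unchanged(self, rng):
        """A proposal whose simulation lands outside the ball never moves."""
        ydata = bits(0, 0, 0)
        model = _flat_prior_model(lambda x, r: 1 - ydata, ydata)  # distance 3 always
        sched = ToleranceSchedule(mode="fixed", epsilon=1.0)
        pop = np.zeros((3, 3), dtype=np.uint8)
        state = ChainState(x=pop[0].copy())
        for _ in range(30):
            abc_step(state, pop, 0, model, sched, ProposalConfig(), rng)
        assert state.n_proposed == 30 and state.n_accepted == 0
        assert np.array_equal(state.x, bits(0, 0, 0))

    def test_flat_prior_exact_simulator_always_accepts(self, rng):
        """Degenerate simulator reproducing ydata exactly: 100% acceptance."""
        ydata = bits(1, 0, 1)
        model = _flat_prior_model(lambda x, r: ydata, ydata)
        sched = ToleranceSchedule(mode="fixed", epsilon=0.5)
        pop = (rng.random((4, 3)) < 0.5).astype(np.uint8)
        state = ChainState(x=pop[1].copy())
        for _ in range(50):
            abc_step(state, pop, 1, model, sched, ProposalConfig(p_flip=0.3), rng)
        assert state.n_accepted == state.n_proposed == 50

    def test_zero_prior_state_never_entered(self, rng):
        """Proposals into a prior-null state are rejected by the Metropolis gate."""
        ydata = bits(0, 0)
        forbidden = bits(1, 1)

        def log_prior(x):
            return -np.inf if np.array_equal(x, forbidden) else 0.0

        model = TargetModel(
            log_prior=log_prior,
            simulator=lambda x, r: ydata,
            distance=mean_hamming_distance,
            ydata=np.atleast_2d(ydata),
        )
        sched = ToleranceSchedule(mode="fixed", epsilon=1.0)
        pop = np.zeros((3, 2), dtype=np.uint8)
        state = ChainState(x=pop[0].copy())
        cfg = ProposalConfig(kernel_name="mut", p_flip=0.4)
        for _ in range(300):
            abc_step(state, pop, 0, model, sched, cfg, rng)
            assert not np.array_equal(state.x, forbidden)

    def test_simulator_failure_reports_chain_index(self, rng):
        def broken(x, r):
            raise RuntimeError("boom")

        model = _flat_prior_model(broken, bits(0, 0))
        sched = ToleranceSchedule(mode="fixed", epsilon=1.0)
        pop = np.zeros((3, 2), dtype=np.uint8)
        with pytest.raises(RuntimeError, match="chain 2"):
            abc_step(ChainState(x=pop[2].copy()), pop, 2, model, sched,
                     ProposalConfig(), rng)


class TestLikelihoodStep:
    def test_identity_proposal_always_accepted(self, rng):
        model = TargetModel(log_prior=lambda x: 0.0, log_likelihood=lambda x: -1.0)
        pop = np.ones((3, 2), dtype=np.uint8)  # constant population
        cfg = ProposalConfig(kernel_name="xor")  # delta always zero => x' = x
        state = ChainState(x=pop[0].copy())
        for _ in range(20):
            likelihood_step(state, pop, 0, model, cfg, rng)
        assert state.n_accepted == 20

    def test_two_state_occupancy_ratio(self, rng):
        """D=1 target with p(1)/p(0) = 2: long-run occupancy approaches 2:1."""
        log_p = {0: np.log(1 / 3), 1: np.log(2 / 3)}
        model = TargetModel(
            log_prior=lambda x: log_p[int(x[0])], log_likelihood=lambda x: 0.0
        )
        cfg = ProposalConfig(kernel_name="mut", p_flip=0.5)
        pop = np.zeros((1, 1), dtype=np.uint8)
        state = ChainState(x=pop[0].copy())
        n = 100_000
        ones = 0
        for _ in range(n):
            likelihood_step(state, pop, 0, model, cfg, rng)
            ones += int(state.x[0])
        p_hat = ones / n
        # near-independent proposals at p_flip = 0.5; allow 3 binomial SE x2
        assert abs(p_hat - 2 / 3) <= 6 * np.sqrt((2 / 3) * (1 / 3) / n)

    def test_non_finite_log_likelihood_auto_rejects(self, rng, caplog):
        model = TargetModel(
            log_prior=lambda x: 0.0,
            log_likelihood=lambda x: np.nan if x.any() else 0.0,
        )
        cfg = ProposalConfig(kernel_name="mut", p_flip=0.45)
        pop = np.zeros((1, 3), dtype=np.uint8)
        state = ChainState(x=pop[0].copy())
        with caplog.at_level("WARNING", logger="ddemc"):
            for _ in range(50):
                likelihood_step(state, pop, 0, model, cfg, rng)
        assert not state.x.any()
        assert any("non-finite" in r.message for r in caplog.records)


class TestAsymmetricCrossoverCorrection:
    def test_flat_target_occupancy_stays_uniform(self, rng_factory):
        """The crossover mixture is asymmetric; with the exact Hastings
        correction a flat target must yield uniform occupancy (without it the
        kernel collapses chains toward the population consensus)."""
        model = TargetModel(log_prior=lambda x: 0.0, log_likelihood=lambda x: 0.0)
        cfg = ProposalConfig(kernel_name="mut+crx", p_flip=0.2, pi_mix=0.3)
        trace = run_population(
            model, None, cfg, C=4, D=2, n_iterations=15_000,
            rng=rng_factory(17), mode="likelihood",
            collect_samples=True, burn_in=1_000,
        )
        flat = trace.samples.reshape(-1, 2)
        idx = flat @ np.array([2, 1])
        freq = np.bincount(idx, minlength=4) / len(idx)
        # generous band: correlated samples, 56k draws
        assert np.all(np.abs(freq - 0.25) < 0.03), freq


class TestRunPopulation:
    def _toy_model(self):
        ydata = np.array([[1, 0, 1, 0]], dtype=np.uint8)
        return TargetModel(
            log_prior=lambda x: 0.0,
            simulator=lambda x, r: x,  # identity simulator
            distance=mean_hamming_distance,
            ydata=ydata,
        )

    def test_zero_iterations_keeps_initial_population(self, rng):
        trace = run_population(
            self._toy_model(),
            ToleranceSchedule(mode="fixed", epsilon=1.0),
            ProposalConfig(),
            C=4, D=4, n_iterations=0, rng=rng,
        )
        assert len(trace.records) == 1
        assert trace.records.iloc[0]["iteration"] == 0

    def test_acceptance_fraction_counter_arithmetic(self, rng):
        trace = run_population(
            self._toy_model(),
            ToleranceSchedule(mode="exponential", tau=1.0),
            ProposalConfig(p_flip=0.2),
            C=4, D=4, n_iterations=200, rng=rng,
        )
        total_prop = sum(c.n_proposed for c in trace.chains)
        total_acc = sum(c.n_accepted for c in trace.chains)
        assert total_prop == 4 * 200
        assert all(c.n_accepted <= c.n_proposed for c in trace.chains)
        assert trace.acceptance_fraction == pytest.approx(total_acc / total_prop)
        assert 0.0 <= trace.acceptance_fraction <= 1.0

    def test_differential_kernel_rejected_below_three_chains(self, rng):
        with pytest.raises(ValueError, match="C >= 3"):
            run_population(
                self._toy_model(),
                ToleranceSchedule(mode="fixed", epsilon=1.0),
                ProposalConfig(kernel_name="dde-mc"),
                C=2, D=4, n_iterations=5, rng=rng,
            )

    def test_fixed_seed_bitwise_reproducible(self, rng_factory):
        def go(seed):
            return run_population(
                self._toy_model(),
                ToleranceSchedule(mode="exponential", tau=1.0),
                ProposalConfig(p_flip=0.1),
                C=5, D=4, n_iterations=300, rng=rng_factory(seed),
                error_fn=lambda x: float(x.sum()), record_every=25,
            )

        a, b = go(42), go(42)
        assert np.array_equal(a.population, b.population)
        assert a.records.equals(b.records)
        c = go(43)
        assert not (np.array_equal(c.population, a.population)
                    and c.records.equals(a.records))

    def test_dataset_order_invariance(self, rng_factory):
        """Permuting the observed data rows changes nothing: the distance
        averages over rows."""
        ydata = (rng_factory(7).random((6, 5)) < 0.5).astype(np.uint8)

        def go(rows):
            model = TargetModel(
                log_prior=lambda x: 0.0,
                simulator=lambda x, r: x[:5],
                distance=mean_hamming_distance,
                ydata=rows,
            )
            return run_population(
                model,
                ToleranceSchedule(mode="exponential", tau=1.0),
                ProposalConfig(p_flip=0.2),
                C=4, D=5, n_iterations=200, rng=rng_factory(11),
            )

        a = go(ydata)
        b = go(ydata[::-1].copy())
        assert a.acceptance_fraction == b.acceptance_fraction
        assert np.array_equal(a.population, b.population)

    def test_chain_relabeling_leaves_acceptance_statistics_unchanged(
        self, rng_factory
    ):
        """Relabeling chains only permutes the initial states; long-run
        acceptance is statistically identical."""
        ydata = np.array([[1, 1, 0, 0, 1]], dtype=np.uint8)
        model = TargetModel(
            log_prior=lambda x: 0.0,
            simulator=lambda x, r: x,
            distance=mean_hamming_distance,
            ydata=ydata,
        )
        init = (rng_factory(3).random((6, 5)) < 0.5).astype(np.uint8)

        def go(init_pop, seed):
            return run_population(
                model,
                ToleranceSchedule(mode="exponential", tau=1.0),
                ProposalConfig(p_flip=0.2),
                C=6, D=5, n_iterations=2000, rng=rng_factory(seed), init=init_pop,
            ).acceptance_fraction

        base = np.mean([go(init, s) for s in (1, 2, 3)])
        perm = np.mean([go(init[::-1].copy(), s) for s in (4, 5, 6)])
        assert abs(base - perm) < 0.05

    def test_samples_collection_and_burn_in(self, rng):
        trace = run_population(
            self._toy_model(),
            ToleranceSchedule(mode="fixed", epsilon=2.0),
            ProposalConfig(p_flip=0.2),
            C=3, D=4, n_iterations=50, rng=rng,
            collect_samples=True, burn_in=10,
        )
        assert trace.samples.shape == (40, 3, 4)

    def test_best_score_tracks_running_minimum_distance(self, rng):
        trace = run_population(
            self._toy_model(),
            ToleranceSchedule(mode="exponential", tau=2.0),
            ProposalConfig(p_flip=0.2),
            C=4, D=4, n_iterations=300, rng=rng,
        )
        best = trace.best_chain
        assert best.best_score >= 0.0
        # the best accepted state achieves the recorded best distance
        assert mean_hamming_distance(
            best.best_x, np.array([[1, 0, 1, 0]])
        ) == pytest.approx(best.best_score)
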