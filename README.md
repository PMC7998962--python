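# ddemc — population MCMC-ABC for binary parameter spaces

Many inference problems over binary decision vectors — which diseases
explain a patient's findings, which ±1 weight setting makes a binarized
network classify well — come with a simulator but no tractable likelihood.
For continuous parameters such likelihood-free problems are routinely
solved with Approximate Bayesian Computation (ABC); for discrete spaces
there is no natural notion of proposal direction or scale, and most
practice falls back on blind independent resampling.

`ddemc` implements a population MCMC-ABC sampler for `x ∈ {0,1}^D` whose
centerpiece is a discrete differential-evolution Markov kernel, **dde-mc**:
with a population of `C` chains, chain `i` proposes

    x_new = x_i ⊕ mut(x_j ⊕ x_k),        (j, k) ≠ i distinct, uniform,

where `⊕` is bitwise xor and `mut` flips each bit independently with
probability `p_flip`.  The xor difference of two other chains plays the
role of the DE direction `γ(x_j − x_k)`; applying the flip noise to the
difference makes the kernel irreducible, aperiodic and symmetric — a valid
ergodic Metropolis proposal with no mixture weight to tune.  The companion
kernels `mut`, `mut+xor`, `mut+crx` and the independent Bernoulli sampler
`ind-samp` are included for comparison, together with *exact* enumeration
oracles that certify symmetry and irreducibility for small `D`.

The ABC step simulates `y ~ p̃(y|x')` once per proposal and accepts through
an ε-ball gate (`‖y − y_data‖ ≤ ε`, fixed or ε ~ Exp(τ) redrawn per
proposal) followed by a Metropolis test on the prior ratio.  Two synthetic
test-beds exercise the machinery end to end:

* a **QMR-DT noisy-OR disease network** (`m` diseases, `n` findings,
  `P(y_i=1|x) = 1 − (1−q_i0)∏_l(1−q_il)^{x_l}`), with exact likelihood,
  forward simulator, and an enumerated-posterior oracle for `m ≤ 12`;
* a **binary neural network** (±1 weights and activations) trained through
  its classification error as the ABC distance, with a Boltzmann sparsity
  prior and majority-vote ensemble evaluation.

## Worked example

Infer the active diseases of a small noisy-OR network from a single
findings vector, treating the network as a black-box simulator:

```python
import numpy as np
from ddemc import qmrdt
from ddemc.abc_core import ToleranceSchedule, run_population
from ddemc.bitspace import ProposalConfig, all_states

rng = np.random.default_rng(7)
inst = qmrdt.generate_instance(m=4, n=8, N=1, rng=rng)
model = qmrdt.make_target_model(inst)

trace = run_population(
    model, ToleranceSchedule(mode="exponential", tau=0.5),
    ProposalConfig(kernel_name="dde-mc", p_flip=0.1),
    C=8, D=4, n_iterations=5_000, rng=rng,
    mode="abc", error_fn=inst.hamming_error,
    collect_samples=True, burn_in=500,
)

posterior = qmrdt.enumerate_posterior(inst.network, inst.ydata)
occ = np.bincount(
    trace.samples.reshape(-1, 4) @ (1 << np.arange(3, -1, -1)), minlength=16
)
occ = occ / occ.sum()
tv = 0.5 * np.abs(occ - posterior).sum()

print(f"true diseases        : {inst.x_true}")
print(f"posterior mode       : {all_states(4)[posterior.argmax()]}")
print(f"acceptance rate      : {100 * trace.acceptance_fraction:.1f}%")
print(f"final population avg Hamming error: {trace.records['avg_error'].iloc[-1]:.2f}")
print(f"total variation to exact posterior: {tv:.3f}")
```

Output:

```
true diseases        : [1 1 1 0]
posterior mode       : [1 1 1 0]
acceptance rate      : 21.7%
final population avg Hamming error: 0.12
total variation to exact posterior: 0.012
```

The likelihood-free chain recovers the true disease pattern: its occupancy
over all 16 disease vectors is within total-variation 0.012 of the exact
enumerated posterior, and the population ends essentially on the truth
(0.12 bits average error), having accepted about a fifth of its proposals.

## Command line

Experiments are configuration-driven (`YAML` + `key=value` overrides):

```bash
ddemc run   --override testbed=qmr_abc --override kernel_name=dde-mc \
            --seed 1 --out results/run1
ddemc report --override "params={m: 6, n: 12, N: 1}" --last-k 5 \
            --out results/posterior.csv
ddemc sweep --override testbed=qmr_abc --param tau --values 0.5,1.0,2.0 \
            --out results/tau_sweep.csv
```

`run` writes per-instance trace CSVs, a per-instance metric table, a
mean/standard-error summary, and a config echo for provenance.

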