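# Methods

## The sampling problem

`ddemc` performs Bayesian inference over binary parameter vectors
`x ∈ {0,1}^D` in two regimes:

* **likelihood-based** — the log likelihood `ℓ(x) = log p(y_data | x)` is
  computable and a population Metropolis sampler targets
  `p(x | y_data) ∝ exp(ℓ(x) + log p(x))`;
* **likelihood-free (ABC)** — only a stochastic simulator `y ~ p̃(y | x)` is
  available.  The likelihood is replaced by an ε-ball indicator: a proposed
  state is considered only if its simulated data lands within distance ε of
  the observed data, and is then accepted or rejected by a Metropolis test
  on the prior ratio alone.

Both regimes run `C` parallel chains over the product target
`p(x_1, …, x_C) = ∏_c p(x_c)`: each chain has the same stationary law, and
the population exists so that proposals can use the joint state.

## Markov kernels

There is no natural notion of direction or scale in `{0,1}^D`, so the
package adapts the differential-evolution move `x_i + γ(x_j − x_k) + noise`
to bit space.  Subtraction becomes xor and Gaussian noise becomes
independent bit flips (`mut`, flip probability `p_flip`):

| kernel     | move |
|------------|------|
| `dde-mc`   | `x_i ⊕ mut(x_j ⊕ x_k)` with `(j, k)` a uniform ordered pair of distinct chains, both `≠ i` |
| `mut+xor`  | with prob `π`: `mut(x_i)`; else `x_i ⊕ (x_j ⊕ x_k)` |
| `mut`      | `mut(x_i)` |
| `mut+crx`  | with prob `π`: `mut(x_i)`; else uniform crossover with a random partner (each bit inherited with prob `p_cross`) |
| `ind-samp` | independent product-Bernoulli draw, parameters `θ_d` (0.5 by default) |
| `xor`      | `x_i ⊕ (x_j ⊕ x_k)` — diagnostic only |

Validity: the bare `xor` move is reversible and aperiodic but *not*
irreducible — on a population that has collapsed to one state it can never
leave it.  Mixing in mutation (`mut+xor`) restores irreducibility; applying
the mutation *to the difference* (`dde-mc`) does the same with a single
operator and no mixture weight.  These are not merely asymptotic claims
here: `enumerate_proposal_distribution` computes every kernel's exact
transition law for `D ≤ 12` by exhausting partner pairs (the flip layer is
folded in analytically), and the test suite certifies, for `D ≤ 4`,
`C = 3`, that

* every kernel above except `mut+crx` is exactly symmetric,
  `q(x'|x_i, rest) = q(x_i|x', rest)` — the property that lets the
  Metropolis ratio omit the proposal term;
* `dde-mc` and `mut+xor` (π > 0) put strictly positive mass on every state;
* the bare `xor` kernel concentrates all mass on the current state when the
  population is constant.

**The crossover exception.**  Single-offspring uniform crossover is *not*
symmetric: where the current state and the partner agree, the offspring bit
is forced, so a partner can make a move possible whose reversal is
impossible (e.g. `D = 1`, both partners at 1: `q(1|0) = p_cross` but
`q(0|1) = 0`).  `mut+crx` here is a reconstruction — the historical variant
it imitates exchanges bits between *two* chains with joint acceptance, and
its exact mechanics are not available — so the package makes the
reconstruction a proper kernel by applying the exact Hastings correction
`q(x|x') / q(x'|x)` in the Metropolis step, computed in closed form in
`crossover_mixture_log_prob` (O(C·D) per evaluation).  Without the
correction the kernel drifts toward population consensus, which looks like
spectacularly fast convergence but samples the wrong law.  A side effect
worth knowing: the corrected recombination move is genuinely strong on the
20-disease test problem (it propagates good blocks through the population),
so it does not reproduce the slow-crossover ordering reported for the
reference variant.

## Tolerance schedules

`ToleranceSchedule` is either a fixed ε or a fresh exponential draw per
proposal evaluation, per chain.  **τ is the mean** of the exponential law
(`Exp(τ=2)` has mean 2), keeping τ on the same scale as the fixed-ε sweep
0.5–2.0.  The acceptance probability of a state at distance `d` under the
exponential schedule is `exp(−d/τ)` — a soft gate instead of the hard
cutoff.  On the Beta(0.15, 0.15) networks the measured effect of the soft
gate at τ = 2 versus fixed ε = 2 is nil (the distance landscape near its
floor is too flat for the gate shape to matter), so the package does not
claim a convergence advantage for it at this scale.

## Accounting

Every chain update of every iteration counts as one proposal.  An
acceptance is a completed Metropolis assignment (ε-ball pass and coin
pass), whether or not the proposed vector happens to equal the current one
— with small `p_flip` many differential proposals are the identity, and
excluding them would make the reported rate a different quantity.
Acceptance percentages are `100 × accepted / proposed`, accumulated over
the whole run.

## QMR-DT test-bed

The two-level noisy-OR network has `m` binary diseases and `n` binary
findings.  Finding `i` fires unless the leak and every active disease
independently fail:

    P(y_i = 1 | x) = 1 − (1 − q_i0) ∏_l (1 − q_il)^{x_l}

with an independent Bernoulli prior `p_l` over diseases.  Presets:

* **likelihood-free** (`qmr_abc`): `m = 10`, `n = 20`, *all* network
  probabilities — leaks, associations, and disease priors — drawn from
  Beta(0.15, 0.15), which is strongly bimodal (≈ 65 % of draws outside
  (0.25, 0.75)), so the simulator is near-deterministic.  `x_true` is drawn
  from the prior, and `N = 10` findings vectors are simulated as observed
  data.  The distance is the Hamming distance averaged over the `N`
  observed vectors (hence fractional tolerances are meaningful); one
  simulation per proposal.
* **likelihood-based** (`qmr_likelihood`): `m = 20`, `n = 80`, `N = 1`,
  diagnostic-style **sparse-graph** networks: leaks uniform on
  (0.005, 0.05), each finding linked to ~3 diseases with association
  strengths uniform on (0.2, 0.9) (absent edges carry negligible
  probability), disease priors uniform on (0.01, 0.5).  This choice is
  deliberate: with dense uniform parameters the noisy-OR saturates — almost
  every disease vector produces near-identical findings, the posterior is
  nearly flat, and no sampler can be distinguished from any other.  Small
  leaks and a sparse strong-edge graph keep the diseases identifiable from
  the findings, which is also what real diagnostic networks look like.
  Dense modes remain available (`param_mode="uniform"` / `"beta"`).

For `m ≤ 12` the exact posterior over all `2^m` disease vectors is
enumerated and serves as the oracle: the likelihood-based sampler matches
it to total-variation distance < 0.05 at 2×10^5 kept samples, and the ABC
occupancy approaches it monotonically as ε shrinks through
{2, 1, 0.5, 0.1} on an `m = 4`, `n = 8`, `N = 1` instance (with `N = 1`
distances are integers, so ε < 1 is exact-match ABC, whose target *is* the
posterior up to simulator noise).

The error metric on these test-beds is the raw Hamming distance between a
chain's current state and `x_true`, reported as the population average and
the population minimum per recording interval (every 50 iterations by
default).

## Binary neural network test-bed

A one-hidden-layer network with weights in {−1, +1} encoded by
`w = 2b − 1`; bits are stored first-layer row-major (per hidden unit), then
the hidden→output weights, `D = n_in·n_hidden + n_hidden`.  Hidden units
apply tanh followed by sign binarization (0 → +1), so activations are polar
as well as weights — a flag keeps raw tanh for comparison; the output is a
sigmoid thresholded at 0.5.  The ABC distance is the training
classification error (a deterministic "simulator" returning predicted
labels), and the prior is the Boltzmann law
`p(x) ∝ exp(−(1/D) Σ_d x_d)`, whose partition function cancels in the
Metropolis ratio — it penalizes each active bit by `1/D` in log space.

The synthetic data generator emulates a binarized two-class image task:
two opposite polar prototypes, balanced labels, each coordinate flipped
independently with probability `noise` (linearly separable at zero noise).
What it deliberately does not model: correlated pixels, class imbalance,
within-class structure, or realistic image statistics — so passing tests
show the optimizer can drive a separable high-dimensional objective down,
not that it rivals gradient training on real images (it is not meant to).
Study conditions: `n_in = 16`, `n_hidden = 4` (D = 68), 200 training
examples at noise 0.05, ε ~ Exp(mean 0.05), `C = 24`, `p_flip = 0.01`;
both differential kernels drive the population-minimum training error
below 0.1 within 50,000 proposal evaluations, and majority voting over the
final population does at least as well on held-out data as the best single
model on average.  Vote ties break toward label 1 (fixed, seed-free).

## Numerical and procedural choices

* Chains initialize at independent uniform random bits; the sweep updates
  chains in index order and proposals see the partially updated population
  (a `frozen_sweep` flag reverts to start-of-iteration context).
* Probability draws for network parameters are clipped to
  [1e−6, 1 − 1e−6]; finding probabilities are clipped the same way inside
  the likelihood so logs stay finite.
* Non-finite log posteriors auto-reject with a logged warning; zero-prior
  states are never entered.
* One seedable generator per experiment run; per-instance substreams are
  spawned from the run seed (`numpy` `SeedSequence`), so cross-evaluations
  are reproducible bit-for-bit and order-independent.
* Pair selection for the difference draw excludes the updated chain
  (`j ≠ k ≠ i`, the DE-1 convention); an `include_current` flag exists for
  sensitivity checks.  Identical partners (zero difference) are kept —
  mutation restores irreducibility.
* `π = 0.5` for the mixtures by default; `p_cross = 0.5`; `θ_d = 0.5`.
* Enumeration oracles refuse `D > 12` (tables of 2^D entries).

## Problem sizes used by the shipped checks

The acceptance-rate protocol runs 20 instances of 10,000 iterations with
`C = 24` (the reference study used 80 instances); kernel-ordering runs use
20 instances at a reduced 250-iteration budget — the transient is where
convergence-speed differences are visible, because all valid kernels share
one stationary law and their errors tie once converged (measured: every
kernel ends near 0.8 bits by 10,000 iterations on the sparse preset).
Posterior-recovery runs keep 2×10^5 samples after burn-in.  These sizes are
the package's own trade-off between statistical resolution and a test
suite that runs in minutes.

## Known limitations

* The likelihood-free acceptance percentages depend strongly on details
  the reconstruction had to fix (disease-prior law, `N`, tolerance
  parameterization, the prior used in the Metropolis ratio); different
  choices move the per-kernel rates by tens of percentage points.  The
  shipped protocol is the documented default, not a claim that it matches
  any particular historical run.
* `mut+crx` is a reconstruction with a Hastings correction; conclusions
  about "crossover" kernels elsewhere do not transfer to it.
* Distances act on raw data space; summary statistics are out of scope, as
  are non-binary alphabets and SMC/neural ABC variants.
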