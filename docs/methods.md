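# Methods

## Model

`synaptogen` simulates the structural development of afferent connectivity
on a population of independent McCulloch–Pitts neurons. Each neuron j sees
binary input vectors x(t) on n input lines and carries a sparse set of
excitatory synapses with weights w_ij > 0. Three coupled processes act on
three timescales:

1. **Excitation and firing** (per pattern). Internal excitation is
   y_j(t) = Σ_i x_i(t)·w_ij(t); the output is z_j(t) = 1 iff y_j(t) > θ
   (strict), with θ = 1.0.
2. **Associative (Hebbian/anti-Hebbian) modification** (per pattern).
   Every *existing* synapse is updated as

       w_ij(t+1) = w_ij(t) + ε·[x_i(t) − E[x_i] − w_ij(t)]·y_j(t)

   The postsynaptic factor is the *excitation* y, not the binary output:
   subthreshold activity also moves weights, in proportion to its
   magnitude. Weights are floored at zero between block boundaries
   (no negative weights ever exist); synapse membership does not change
   here.
3. **Synaptogenesis and shedding** (per block). A block is one complete
   presentation of the environment's pattern set. After block k the
   moving-average firing rate updates as
   z̄_j(k) = z̄_j(k−1)·α + (1−α)·(block mean of z_j), α = 0.25, initialized
   at 0 (maximally receptive). While z̄_j < ρ (= 0.1, strict) the neuron is
   *receptive*: every input line without a synapse independently forms one
   with probability γ, at initial weight 0.1. Any synapse whose weight has
   fallen strictly below 0.01 is removed. The initial weight sits an order
   of magnitude above the shed threshold so a de novo synapse is not
   immediately eliminated.

Event order per block: present all patterns (excitation → fire → weight
update each) → update z̄ → shed → evaluate receptivity → synaptogenesis.
Shedding precedes synaptogenesis so a de novo synapse is never evaluated
before experiencing any input. Neurons never interact, so populations are
embarrassingly parallel and per-neuron means are unbiased at any
population size.

**Stability.** A neuron is quasi-stable when its synapse *identity set* —
not merely the count — is unchanged for 200 consecutive blocks
(`stability_window`). Time-to-stability is the index of the last block at
which the set changed; the confirmation window is observation, not
development, and is not counted. Weight convergence is treated as implied
by the quiet window. Non-convergence within `max_blocks` (default 20,000)
is flagged on the trace, never raised.

## Input environments

Patterns are noisy perturbations of category prototypes; every pattern has
exactly `lines_per_prototype − off_noise + on_noise` active lines. Kept
prototype lines and on-noise lines (drawn uniformly without replacement
from the complement of the generating prototype) are redrawn freshly for
every pattern — the environment is a distribution, not a fixed pattern
set. The built-in registry holds:

| name | lines | categories | prototype | noise on/off | probabilities |
|------|-------|------------|-----------|--------------|---------------|
| A1 | 1,000 | 5 disjoint | 200 adjacent | 100/100 | .1, .15, .2, .25, .3 |
| A2 | 1,000 | 5 disjoint | 200 adjacent | 100/100 (variable) | uniform |
| C1–C4 | 180 | 18, circular 10-line overlap | 20 | 5/5 | per-variant orientation biases |

The C family models orientation tuning (one line per degree, axial);
C3 is an unbiased prenatal (retinal-wave) environment, C4 a mildly
cardinal-biased postnatal one, C1/C2 stripe-tilt rearing at 45°/135°.
The printed C probabilities do not sum to one (0.93–0.99); they are
normalized, then converted to exact per-block counts by largest-remainder
rounding (ties to the lower category index). Blocks therefore have a
deterministic category composition — matching the definition of category
probability as the per-block fraction — with a uniformly shuffled
presentation order. The noise-to-signal ratio of an environment is
on-noise / (prototype lines − off-noise).

`E[x_i]` in the weight update is supplied analytically from the generative
process (using the realized per-block frequencies), not estimated online:
a line of category c's prototype has
E[x] = p_c·(keep/L) + Σ_{c'∌i} p_{c'}·on/(n−L), summed over all categories
containing the line for the overlapping C family. A test verifies the
closed form against 10⁵ Monte-Carlo patterns.

## Parameters

| symbol | meaning | default |
|--------|---------|---------|
| ε | Hebbian rate constant | manipulated (typ. 0.001–0.004) |
| γ | per-line, per-block synapse formation probability | manipulated (typ. 0.0003–0.004) |
| α | z̄ rate constant | 0.25 |
| ρ | receptivity shutoff threshold | 0.1 |
| θ | firing threshold | 1.0 |
| — | shed threshold | 0.01 |
| — | de novo weight | 0.1 |
| SSN | starting synapse number (uniform random lines) | 1 |
| — | stability window | 200 blocks |

ε must be matched to γ for fastest development: mean time-to-stability is
empirically convex in ε at fixed γ. `optimize_epsilon` performs that grid
search; `matched_epsilon` encodes the resulting map (ε ≈ 5γ below
γ = 0.001, a plateau near 0.004 above; 0.0038 at γ = 0.001). Boundary
comparisons are strict exactly as the update rules state (y > θ, z̄ < ρ,
w < 0.01); equalities stay on the inactive side.

## Measurement

All dependent variables are measured on a *frozen* network: a novel test
set (100 blocks by default) is presented with ε forced to 0 and
synaptogenesis/shedding disabled. Firing rate is the fraction of test
patterns fired to; the neuron allocation index is the per-category share
of the population's total firings; the error rate is the share of a
neuron's firings evoked outside its preferred (argmax, ties to lowest
index, silent neurons excluded and flagged) category; overproduction is
peak minus stable synapse count of a converged trace. The energy account
has four nonnegative terms — synaptic maintenance c_leak,syn·Σw, synaptic
use c_exc·E[Σwx], axonal leak c_leak,axo·(1−E[Z]) and action potentials
c_ap·E[Z] — reported together with the raw moments, since absolute
constants are unknown; a labeled preset sets c_ap = 100·c_leak,axo
(biologically the ratio is ~40–120).

## Numerics and implementation

The elementary rules live in `dynamics.py` as plain, dictionary-based
reference operations. The simulation loop uses two numba kernels (partial
Fisher–Yates sampling of active lines; the sequential per-pattern
presentation loop) that consume pre-drawn uniforms from numpy Generators,
so results are bit-reproducible for a given master seed and independent of
the compiled code path; a test holds kernel and reference routes equal to
1e-12 on identical streams. Neuron i always receives substream i of the
master `SeedSequence`, making results independent of population size.

## Scale of the shipped experiments

Population statistics in the test suite and the acceptance script use
40–200 neurons rather than 1,000. Because neurons are independent, the
estimated per-neuron means are identical in expectation; only the sampling
error widens (reported as ±3 SE bands). The ε-optimization and
noise-sweep registry entries default to reduced grids for the same reason.

## Known limitations

* The synthetic environments are block-ergodic and stationary by
  construction; the stability criterion relies on that well-mixing.
  Non-ergodic input streams, interacting neurons, inhibition, and
  threshold adaptation are out of scope.
* Quasi-stability is not absolute: with the moving average hovering near
  ρ, a rare late excursion can re-open receptivity. Mean time-to-stability
  is therefore right-skewed, and its absolute scale is sensitive to this
  churn in a way the structural statistics (stable count, peak count,
  overproduction, error rate) are not. In this implementation the
  structural statistics and the slope of time-to-stability versus 1/γ
  reproduce the published operating points closely, while absolute mean
  times-to-stability run longer at the same rate constants, and the
  SSN = 150 endpoint stabilizes at a lower firing rate (~0.31 vs ~0.5);
  both are reported as measured.
* Energy terms are relative; no conversion to joules or ATP is attempted.
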