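# synaptogen

A simulator of **adaptive synaptogenesis** — the developmental paradigm in
which feedforward threshold neurons grow, modify, and shed their afferent
synapses under purely activity-dependent rules — together with the metric
suite needed to study synapse **overproduction**: why developing neurons
transiently build more synapses than they keep, and what the speed of that
development costs the adult network in energy, response specificity, and
proportional neuron allocation.

It is intended for computational neuroscientists studying structural
plasticity and neural circuit development, and for anyone who wants a
small, fully reproducible testbed coupling Hebbian weight dynamics to
stochastic structural change.

## The model

Independent McCulloch–Pitts neurons receive binary patterns x(t) on n
input lines. For the synapses that exist,

    y_j(t) = Σ_i x_i(t) · w_ij(t)          (excitation)
    z_j(t) = 1  iff  y_j(t) > θ            (firing, θ = 1)

Three adaptive processes shape connectivity:

* **Hebbian/anti-Hebbian modification**, after every pattern:
  `Δw_ij = ε · (x_i − E[x_i] − w_ij) · y_j`, weights floored at 0;
* **stochastic synaptogenesis**, after every block of patterns: while the
  moving-average firing rate z̄_j (rate constant α = 0.25) is below the
  receptivity threshold ρ = 0.1, each unconnected line forms a synapse
  with probability γ at weight 0.1;
* **shedding**: any synapse whose weight falls below 0.01 is removed.

A neuron is (quasi-)stable when its synapse set is unchanged for 200
blocks. Development speed is controlled by γ, by matching ε to γ, or by
the starting synapse number (SSN); all three routes produce synapse
overproduction, and faster development buys more of it — at the price of
higher firing rates, larger error rates, and distorted allocation.

Input environments are built in: five-category orthogonal pattern sets on
1,000 lines (A1/A2) and eighteen overlapping orientation categories on 180
lines (C1–C4, modelling prenatal retinal waves, normal rearing, and
stripe-tilt rearing). See `docs/methods.md` for the full specification.

## Worked example

Develop 50 neurons on dataset A1 at γ = 0.001 with its matched ε, then
measure the frozen network on a novel 100-block test set:

```python
import synaptogen as sg
from synaptogen import metrics

spec = sg.get_spec("A1")
params = sg.RunParams(epsilon=0.0038, gamma=0.001)
pop = sg.run_population(50, spec, params, master_seed=7)
print(pop.summary)
ev = metrics.evaluate_population(pop, spec, n_blocks=100, seed=8)
print(ev.allocation, ev.mean_error_rate)
```

prints (numbers from this exact invocation):

```
{'n_neurons': 50, 'n_converged': 50, 'mean_time_to_stability': 97.2,
 'sd_time_to_stability': 37.9, 'mean_stable_synapses': 17.2,
 'mean_max_synapses': 35.6, 'mean_overproduction': 18.4, ...}
allocation: [0.002 0.102 0.246 0.22  0.429]
mean error rate: 0.0139
```

Read: every neuron converged; on the way to a stable ~17 synapses the
average neuron peaked at ~36, i.e. it overproduced ~18 synapses. On the
frozen network, the most frequent category (relative frequency 0.3)
attracts ~0.43 of all firings while the rarest (0.1) gets almost none,
and a neuron fires outside its preferred category ~1.4% of the time.

The same experiments are scriptable from the shell:

```sh
synaptogen run --dataset A1 --gamma 0.001 --epsilon 0.0038 --neurons 50 --seed 7 --out results/
synaptogen sweep --variable ssn --values 1,50,100,150 --neurons 100 --out ssn.csv
synaptogen sequence --stages C3,C4,C1 --neurons 100
synaptogen optimize-eps --gamma 0.002 --neurons 50
synaptogen experiments            # list built-in figure/table configurations
```

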