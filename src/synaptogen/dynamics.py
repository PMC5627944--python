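"""Per-time-step and per-block update rules of adaptive synaptogenesis.

The model couples three processes on a McCulloch-Pitts neuron:

* **Hebbian/anti-Hebbian modification** of existing synapses after every
  pattern: ``w <- w + eps * (x_i - E[x_i] - w) * y``, gated multiplicatively
  by the postsynaptic excitation ``y`` (no change when the neuron receives
  no input) and floored at zero so weights never go negative.
* **Stochastic synaptogenesis** at block boundaries: while the neuron's
  moving-average firing rate is below the receptivity threshold ``rho``,
  each input line without a synapse independently forms one with
  probability ``gamma``, at a fixed initial weight.
* **Shedding** at block boundaries: any synapse whose weight has fallen
  strictly below the shed threshold is removed.

These functions are the plain, auditable implementations; the simulation
loop uses a compiled kernel performing identical arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RunParams",
    "SynapseTable",
    "NeuronState",
    "excitation",
    "fire",
    "hebbian_step",
    "update_zbar",
    "receptivity",
    "synaptogenesis_step",
    "shed_step",
]


@dataclass(frozen=True)
class RunParams:
    """Model constants.

    epsilon and gamma are the experiment's manipulated rate constants; the
    remainder default to the model's standard operating point: moving-average
    rate constant alpha = 0.25, receptivity shutoff rho = 0.1, firing
    threshold theta = 1.0, shed threshold 0.01, de novo weight 0.1 (an order
    of magnitude above the shed threshold, so a new synapse is not
    immediately shed), convergence confirmed by a 200-block quiet window.
    """

    epsilon: float
    gamma: float
    alpha: float = 0.25
    rho: float = 0.1
    theta: float = 1.0
    shed_threshold: float = 0.01
    init_weight: float = 0.1
    ssn: int = 1
    stability_window: int = 200
    max_blocks: int = 20_000
    zbar_init: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "rho"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("epsilon", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.shed_threshold >= self.init_weight:
            raise ValueError("shed_threshold must be below init_weight")
        if self.ssn < 1:
            raise ValueError("ssn must be at least 1")
        if self.stability_window < 1 or self.max_blocks < 1:
            raise ValueError("stability_window and max_blocks must be positive")


@dataclass
class SynapseTable:
    """A neuron's afferent synapses: input-line index -> positive weight."""

    weights: dict[int, float] = field(default_factory=dict)

    @property
    def m(self) -> int:
        """Synapse count."""
        return len(self.weights)

    def indices(self) -> list[int]:
        return sorted(self.weights)

    def copy(self) -> "SynapseTable":
        return SynapseTable(dict(self.weights))

    def total_weight(self) -> float:
        return float(sum(self.weights[i] for i in self.indices()))

    def to_dense(self, n_inputs: int) -> np.ndarray:
        w = np.zeros(n_inputs)
        for i, v in self.weights.items():
            w[i] = v
        return w

    @classmethod
    def from_dense(cls, w: np.ndarray, exists: np.ndarray) -> "SynapseTable":
        return cls({int(i): float(w[i]) for i in np.flatnonzero(exists)})


@dataclass
class NeuronState:
    """Synapses plus the slow variables carried across blocks."""

    synapses: SynapseTable
    zbar: float = 0.0
    history: list[int] = field(default_factory=list)
    block_index: int = 0


def excitation(pattern: np.ndarray, synapses: SynapseTable) -> float:
    """Internal excitation: sum of weights over active lines with synapses."""
    y = 0.0
    for i in synapses.indices():
        y += synapses.weights[i] * float(pattern[i])
    return y


def fire(y: float, theta: float) -> int:
    """Binary output: 1 iff excitation strictly exceeds the threshold."""
    return 1 if y > theta else 0


def hebbian_step(
    synapses: SynapseTable,
    pattern: np.ndarray,
    e_x: np.ndarray,
    epsilon: float,
    y: float,
) -> SynapseTable:
    """Associative modification of every existing synapse.

    ``y`` must be the excitation this pattern produced on this table.
    Updated weights are floored at zero; synapse membership is untouched
    (creation and removal happen only at block boundaries).
    """
    out = synapses.copy()
    if y <= 0.0:
        return out
    for i in out.indices():
        w = out.weights[i]
        nw = w + epsilon * (float(pattern[i]) - float(e_x[i]) - w) * y
        out.weights[i] = nw if nw > 0.0 else 0.0
    return out


def update_zbar(zbar: float, block_firings: np.ndarray, alpha: float) -> float:
    """Moving-average firing rate across blocks.

    New value = alpha * old + (1 - alpha) * block mean, a contraction of the
    old average toward the block's empirical rate.
    """
    return zbar * alpha + float(np.mean(block_firings)) * (1.0 - alpha)


def receptivity(zbar: float, gamma: float, rho: float) -> float:
    """gamma while the moving-average rate is strictly below rho, else 0."""
    return gamma if zbar < rho else 0.0


def synaptogenesis_step(
    synapses: SynapseTable,
    r: float,
    n_inputs: int,
    init_weight: float,
    rng: np.random.Generator,
) -> SynapseTable:
    """Bernoulli synapse formation on every line without a synapse.

    Consumes exactly ``n_inputs`` uniforms when r > 0 (none otherwise), so
    the random stream is independent of the current synapse set.
    """
    out = synapses.copy()
    if r <= 0.0:
        return out
    u = rng.random(n_inputs)
    for i in range(n_inputs):
        if u[i] < r and i not in out.weights:
            out.weights[i] = init_weight
    return out


def shed_step(synapses: SynapseTable, shed_threshold: float) -> SynapseTable:
    """Remove every synapse whose weight is strictly below the threshold."""
    return SynapseTable(
        {i: w for i, w in synapses.weights.items() if w >= shed_threshold}
    )
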