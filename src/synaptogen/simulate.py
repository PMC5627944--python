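"""Neuron development: block loop, stability detection, populations, sweeps.

Each postsynaptic neuron develops independently (there is no lateral or
feedback interaction), so a population run is an embarrassingly parallel
collection of single-neuron simulations on per-neuron random substreams
spawned from one master seed.  Development proceeds in blocks: all patterns
of a block are presented in randomized order with Hebbian modification
after each pattern, then the firing-rate moving average, shedding,
receptivity and synaptogenesis are updated at the block boundary.

A neuron is considered (quasi-)stable when its synapse *identity set* —
not merely the count — is unchanged for ``stability_window`` consecutive
blocks.  The reported time-to-stability is the index of the last block at
which the set changed; the confirmation window is observation, not
development, and is not counted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import datasets
from ._kernels import present_block, sample_active_indices
from .dynamics import NeuronState, RunParams, SynapseTable

__all__ = [
    "NeuronTrace",
    "PopulationResult",
    "init_neuron",
    "run_until_stable",
    "run_population",
    "run_environment_sequence",
    "optimize_epsilon",
    "sweep",
    "matched_epsilon",
    "BEST_EPSILON",
]

#: Empirically fastest epsilon for each gamma on the A datasets: a fixed
#: ratio of about 5 below gamma = 0.001, a plateau near 0.004 above it.
BEST_EPSILON: dict[float, float] = {
    0.0003: 0.0015,
    0.001: 0.0038,
    0.002: 0.004,
    0.003: 0.004,
    0.004: 0.004,
}


def matched_epsilon(gamma: float) -> float:
    """Fastest-development epsilon for a given gamma (A-type environments)."""
    if gamma in BEST_EPSILON:
        return BEST_EPSILON[gamma]
    return 5.0 * gamma if gamma <= 0.001 else 0.004


@dataclass
class NeuronTrace:
    """Development record of one neuron in one environment."""

    synapse_count_per_block: np.ndarray
    max_synapses: int
    stable_synapses: int
    time_to_stability: int
    converged: bool
    final_weights: SynapseTable
    final_zbar: float


@dataclass
class PopulationResult:
    """Per-neuron traces plus recomputable population summary."""

    traces: list[NeuronTrace]
    params: RunParams
    dataset: str
    seed: int

    @property
    def summary(self) -> dict[str, float]:
        tts = np.array([t.time_to_stability for t in self.traces], dtype=float)
        stable = np.array([t.stable_synapses for t in self.traces], dtype=float)
        mx = np.array([t.max_synapses for t in self.traces], dtype=float)
        conv = np.array([t.converged for t in self.traces])
        over = mx - stable
        return {
            "n_neurons": len(self.traces),
            "n_converged": int(conv.sum()),
            "mean_time_to_stability": float(tts[conv].mean()) if conv.any() else float("nan"),
            "sd_time_to_stability": float(tts[conv].std(ddof=1)) if conv.sum() > 1 else 0.0,
            "mean_stable_synapses": float(stable[conv].mean()) if conv.any() else float("nan"),
            "mean_max_synapses": float(mx[conv].mean()) if conv.any() else float("nan"),
            "mean_overproduction": float(over[conv].mean()) if conv.any() else float("nan"),
            "sd_overproduction": float(over[conv].std(ddof=1)) if conv.sum() > 1 else 0.0,
        }

    def per_neuron_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron": np.arange(len(self.traces)),
                "time_to_stability": [t.time_to_stability for t in self.traces],
                "stable_synapses": [t.stable_synapses for t in self.traces],
                "max_synapses": [t.max_synapses for t in self.traces],
                "overproduction": [t.max_synapses - t.stable_synapses for t in self.traces],
                "converged": [t.converged for t in self.traces],
                "final_zbar": [t.final_zbar for t in self.traces],
            }
        )


def init_neuron(
    params: RunParams, n_inputs: int, rng: np.random.Generator
) -> NeuronState:
    """Place ``ssn`` synapses on distinct uniformly chosen lines.

    A large starting synapse number models an early phase of very fast,
    activity-independent synapse formation.
    """
    if not 1 <= params.ssn <= n_inputs:
        raise ValueError(f"ssn={params.ssn} out of range [1, {n_inputs}]")
    lines = rng.choice(n_inputs, size=params.ssn, replace=False)
    table = SynapseTable({int(i): params.init_weight for i in sorted(lines)})
    return NeuronState(synapses=table, zbar=params.zbar_init)


def _develop_arrays(
    w: np.ndarray,
    exists: np.ndarray,
    zbar: float,
    proto: datasets.PrototypeSet,
    comp: np.ndarray,
    e_x: np.ndarray,
    spec: datasets.DatasetSpec,
    params: RunParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, bool, float]:
    """Run the block loop in place until quiet for the stability window.

    Returns (per-block synapse counts, last-change block index, converged,
    final zbar).  Block indices are 1-based; the initial configuration
    counts as block 0.
    """
    n_inputs = spec.n_inputs
    n_t = spec.block_size
    member = proto.membership
    counts_base = datasets.category_counts(spec)
    label_base = np.repeat(np.arange(spec.n_categories, dtype=np.int32), counts_base)
    keep = spec.lines_per_prototype - spec.off_noise
    x_scratch = np.zeros(n_inputs)
    history: list[int] = []
    last_change = 0
    k = 0
    while k < params.max_blocks:
        k += 1
        labels = rng.permutation(label_base)
        u_keep = rng.random((n_t, keep))
        u_on = rng.random((n_t, spec.on_noise))
        active = sample_active_indices(labels, member, comp, u_keep, u_on)
        syn_idx = np.flatnonzero(exists)
        n_fire = present_block(
            active, w, syn_idx, e_x, params.epsilon, params.theta, x_scratch
        )
        zbar = zbar * params.alpha + (n_fire / n_t) * (1.0 - params.alpha)
        changed = False
        shed = exists & (w < params.shed_threshold)
        if shed.any():
            exists[shed] = False
            w[shed] = 0.0
            changed = True
        if zbar < params.rho and params.gamma > 0.0:
            u = rng.random(n_inputs)
            new = (~exists) & (u < params.gamma)
            if new.any():
                exists[new] = True
                w[new] = params.init_weight
                changed = True
        history.append(int(exists.sum()))
        if changed:
            last_change = k
        if k - last_change >= params.stability_window:
            return np.asarray(history), last_change, True, zbar
    return np.asarray(history), last_change, False, zbar


def run_until_stable(
    state: NeuronState,
    proto: datasets.PrototypeSet,
    spec: datasets.DatasetSpec,
    params: RunParams,
    rng: np.random.Generator,
) -> NeuronTrace:
    """Develop one neuron until its synapse set is quiet, or max_blocks.

    Non-convergence is reported in the trace (``converged=False``), never
    raised.
    """
    w = state.synapses.to_dense(spec.n_inputs)
    exists = w > 0.0
    # a clamped-to-zero weight still denotes an existing synapse
    for i in state.synapses.weights:
        exists[i] = True
    comp = proto.complements()
    e_x = datasets.input_line_expectations(proto, spec).e_x
    history, last_change, converged, zbar = _develop_arrays(
        w, exists, state.zbar, proto, comp, e_x, spec, params, rng
    )
    initial = state.synapses.m
    final = SynapseTable.from_dense(w, exists)
    state.synapses = final
    state.zbar = zbar
    state.history.extend(history.tolist())
    state.block_index += len(history)
    return NeuronTrace(
        synapse_count_per_block=history,
        max_synapses=int(max(initial, history.max() if history.size else initial)),
        stable_synapses=final.m,
        time_to_stability=int(last_change),
        converged=converged,
        final_weights=final.copy(),
        final_zbar=zbar,
    )


def _neuron_rngs(master_seed: int, n_neurons: int) -> list[np.random.Generator]:
    return [
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(master_seed).spawn(n_neurons)
    ]


def run_population(
    n_neurons: int,
    spec: datasets.DatasetSpec,
    params: RunParams,
    master_seed: int,
) -> PopulationResult:
    """Develop ``n_neurons`` independent neurons on one environment.

    Neuron i always receives substream i of the master seed, so results are
    bit-reproducible and independent of population size.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be at least 1")
    proto = datasets.build_prototypes(spec)
    traces = []
    for rng in _neuron_rngs(master_seed, n_neurons):
        state = init_neuron(params, spec.n_inputs, rng)
        traces.append(run_until_stable(state, proto, spec, params, rng))
    return PopulationResult(traces=traces, params=params, dataset=spec.name, seed=master_seed)


def run_environment_sequence(
    specs: list[datasets.DatasetSpec],
    params: RunParams,
    n_neurons: int,
    master_seed: int,
) -> list[PopulationResult]:
    """Present environments in sequence with the adaptive rules running
    throughout: weights and the firing-rate average carry across stages,
    and each stage runs to its own stability before the switch."""
    if len({s.n_inputs for s in specs}) != 1:
        raise ValueError("all stages must share n_inputs")
    protos = [datasets.build_prototypes(s) for s in specs]
    stage_traces: list[list[NeuronTrace]] = [[] for _ in specs]
    for rng in _neuron_rngs(master_seed, n_neurons):
        state = init_neuron(params, specs[0].n_inputs, rng)
        for j, (spec, proto) in enumerate(zip(specs, protos)):
            stage_traces[j].append(run_until_stable(state, proto, spec, params, rng))
    return [
        PopulationResult(traces=tr, params=params, dataset=spec.name, seed=master_seed)
        for tr, spec in zip(stage_traces, specs)
    ]


def optimize_epsilon(
    gamma: float,
    epsilon_grid: list[float],
    spec: datasets.DatasetSpec,
    params: RunParams,
    n_neurons: int,
    seed: int,
) -> tuple[float, pd.DataFrame]:
    """Grid search for the epsilon giving fastest mean time-to-stability.

    Mean development time is empirically convex in epsilon at fixed gamma,
    so a coarse grid suffices to bracket the optimum.  Grid points where no
    neuron converged are reported with NaN means, never dropped.
    """
    if not epsilon_grid:
        raise ValueError("epsilon_grid must be non-empty")
    rows = []
    for eps in epsilon_grid:
        res = run_population(
            n_neurons, spec, replace(params, epsilon=eps, gamma=gamma), seed
        )
        s = res.summary
        rows.append(
            {
                "epsilon": eps,
                "mean_time_to_stability": s["mean_time_to_stability"],
                "sd_time_to_stability": s["sd_time_to_stability"],
                "n_converged": s["n_converged"],
                "n_neurons": s["n_neurons"],
            }
        )
    profile = pd.DataFrame(rows)
    ok = profile["n_converged"] > 0
    if not ok.any():
        raise RuntimeError("no epsilon on the grid produced converged neurons")
    best = profile.loc[ok, "mean_time_to_stability"].idxmin()
    return float(profile.loc[best, "epsilon"]), profile


def default_epsilon_grid(gamma: float) -> list[float]:
    """Geometric grid spanning [gamma, 20*gamma] merged with 0.001..0.01."""
    g = list(np.geomspace(gamma, 20 * gamma, 7))
    g += list(np.geomspace(0.001, 0.01, 5))
    return sorted(set(round(float(v), 10) for v in g))


def sweep(
    variable: str,
    values: list[float],
    base_params: RunParams,
    spec: datasets.DatasetSpec,
    n_neurons: int,
    seed: int,
    epsilon_map: dict[float, float] | None = None,
    test_blocks: int = 100,
) -> pd.DataFrame:
    """One population per value of gamma, ssn, or nsr (equal on/off noise).

    For gamma sweeps epsilon is taken from ``epsilon_map`` (defaulting to
    the matched-epsilon rule).  Each row carries development statistics and
    frozen-network test metrics.
    """
    from . import metrics

    if variable not in {"gamma", "ssn", "nsr"}:
        raise ValueError("variable must be one of gamma, ssn, nsr")
    rows = []
    for v in values:
        run_spec = spec
        if variable == "gamma":
            eps = (epsilon_map or {}).get(v, matched_epsilon(v))
            p = replace(base_params, gamma=v, epsilon=eps)
        elif variable == "ssn":
            p = replace(base_params, ssn=int(v))
        else:
            run_spec = datasets.a2_with_noise(int(v))
            p = base_params
        res = run_population(n_neurons, run_spec, p, seed)
        ev = metrics.evaluate_population(
            res, run_spec, n_blocks=test_blocks, seed=seed + 1
        )
        s = res.summary
        rows.append(
            {
                "variable": variable,
                "value": v,
                "gamma": p.gamma,
                "epsilon": p.epsilon,
                "ssn": p.ssn,
                "mean_time_to_stability": s["mean_time_to_stability"],
                "mean_stable_synapses": s["mean_stable_synapses"],
                "mean_max_synapses": s["mean_max_synapses"],
                "mean_overproduction": s["mean_overproduction"],
                "n_converged": s["n_converged"],
                "mean_firing_rate": ev.per_neuron["firing_rate"].mean(),
                "mean_error_rate": ev.mean_error_rate,
                "mean_excitation": ev.per_neuron["mean_excitation"].mean(),
                "mean_total_weight": ev.per_neuron["total_weight"].mean(),
            }
        )
    return pd.DataFrame(rows)
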