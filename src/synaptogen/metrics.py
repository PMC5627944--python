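"""Dependent variables measured on frozen, post-development networks.

All measurements present a novel test set (100 blocks by default) with
plasticity disabled — no weight modification, synaptogenesis or shedding —
and reduce the resulting firings:

* firing rate — fraction of test patterns a neuron fires to;
* neuron allocation index — per category, the fraction of the population's
  total firings evoked by that category's patterns;
* error rate — per neuron, the fraction of its firings evoked by patterns
  outside its preferred (most-responded-to) category;
* energy terms — synaptic maintenance (proportional to total weight),
  synaptic use (proportional to mean excitation), axonal leak and action
  potential terms, each behind a nonnegative scale constant;
* overproduction — peak minus stabilized synapse count of a development
  trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from .dynamics import SynapseTable

__all__ = [
    "TestSet",
    "EnergyConstants",
    "EnergyTerms",
    "make_test_set",
    "firing_rate",
    "allocation_index",
    "error_rate",
    "energy_terms",
    "overproduction",
    "linear_fit",
    "orientation_histogram",
    "evaluate_population",
    "EvaluationResult",
]


@dataclass
class TestSet:
    """Concatenated novel blocks with per-pattern generating labels."""

    patterns: np.ndarray  # (n_patterns, n_inputs) uint8
    labels: np.ndarray  # (n_patterns,) int32
    n_categories: int

    def __post_init__(self) -> None:
        if len(self.patterns) == 0:
            raise ValueError("empty test set")
        if len(self.labels) != len(self.patterns):
            raise ValueError("labels must cover every pattern")


@dataclass(frozen=True)
class EnergyConstants:
    """Scale factors of the four energy terms.

    Absolute energies are only comparable across terms once these constants
    are known; the raw moments are therefore always reported alongside.
    The action-potential to axonal-leak ratio is biologically around
    40-120, so a preset with c_ap = 100 * c_leak_axo is provided.
    """

    c_exc: float = 1.0
    c_leak_syn: float = 1.0
    c_leak_axo: float = 1.0
    c_ap: float = 1.0

    def __post_init__(self) -> None:
        if min(self.c_exc, self.c_leak_syn, self.c_leak_axo, self.c_ap) < 0:
            raise ValueError("energy constants must be nonnegative")

    def ap_leak_ratio_plausible(self, band: tuple[float, float] = (40.0, 120.0)) -> bool:
        if self.c_leak_axo == 0:
            return False
        r = self.c_ap / self.c_leak_axo
        return band[0] <= r <= band[1]

    @classmethod
    def biological(cls) -> "EnergyConstants":
        return cls(c_exc=1.0, c_leak_syn=1.0, c_leak_axo=1.0, c_ap=100.0)


@dataclass(frozen=True)
class EnergyTerms:
    """Scaled energy terms plus the raw, constant-free moments."""

    syn_leak: float
    syn_use: float
    axo_leak: float
    ap: float
    total_weight: float  # sum of weights, exact from the table
    mean_excitation: float  # E[sum w x] over the test set
    mean_firing: float  # E[Z] over the test set

    @property
    def total(self) -> float:
        return self.syn_leak + self.syn_use + self.axo_leak + self.ap


def make_test_set(
    spec: datasets.DatasetSpec, seed: int, n_blocks: int = 100
) -> TestSet:
    """Generate a novel test set of ``n_blocks`` blocks from a spec."""
    proto = datasets.build_prototypes(spec)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    pats, labs = [], []
    for _ in range(n_blocks):
        blk = datasets.build_block(proto, spec, rng)
        pats.append(blk.patterns)
        labs.append(blk.labels)
    return TestSet(
        patterns=np.concatenate(pats),
        labels=np.concatenate(labs),
        n_categories=spec.n_categories,
    )


def _excitations(synapses: SynapseTable, test: TestSet) -> np.ndarray:
    w = synapses.to_dense(test.patterns.shape[1])
    return test.patterns @ w


def firing_rate(synapses: SynapseTable, test: TestSet, theta: float = 1.0) -> float:
    """Fraction of test patterns with output 1, plasticity off."""
    return float(np.mean(_excitations(synapses, test) > theta))


def _category_counts(z: np.ndarray, test: TestSet) -> np.ndarray:
    return np.bincount(test.labels[z], minlength=test.n_categories)


def error_rate(
    synapses: SynapseTable, test: TestSet, theta: float = 1.0
) -> tuple[float, int | None]:
    """Fraction of firings to non-preferred categories, and the preferred
    category (argmax of per-category firing counts, ties toward the lowest
    index).  A neuron that never fires has no preferred category: returns
    (nan, None)."""
    z = _excitations(synapses, test) > theta
    total = int(z.sum())
    if total == 0:
        return float("nan"), None
    counts = _category_counts(z, test)
    preferred = int(np.argmax(counts))
    return float((total - counts[preferred]) / total), preferred


def allocation_index(
    population: list[SynapseTable], test: TestSet, theta: float = 1.0
) -> np.ndarray:
    """Per-category fraction of the population's total firings.

    Sums to one whenever any neuron fired; all-zero (with no firings to
    apportion) otherwise.
    """
    counts = np.zeros(test.n_categories, dtype=float)
    for syn in population:
        z = _excitations(syn, test) > theta
        counts += _category_counts(z, test)
    total = counts.sum()
    return counts / total if total > 0 else counts


def energy_terms(
    synapses: SynapseTable,
    test: TestSet,
    constants: EnergyConstants = EnergyConstants(),
    theta: float = 1.0,
) -> EnergyTerms:
    """Four-term energy cost of using the frozen neuron.

    E[Z] and the mean excitation E[sum w x] are estimated over the test
    set; the total weight is exact from the synapse table.
    """
    y = _excitations(synapses, test)
    e_z = float(np.mean(y > theta))
    e_y = float(np.mean(y))
    sw = synapses.total_weight()
    return EnergyTerms(
        syn_leak=constants.c_leak_syn * sw,
        syn_use=constants.c_exc * e_y,
        axo_leak=constants.c_leak_axo * (1.0 - e_z),
        ap=constants.c_ap * e_z,
        total_weight=sw,
        mean_excitation=e_y,
        mean_firing=e_z,
    )


def overproduction(trace) -> int:
    """Peak synapse count minus stabilized count; defined only at convergence."""
    if not trace.converged:
        raise ValueError("overproduction is defined only for converged traces")
    return int(trace.max_synapses - trace.stable_synapses)


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares: (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.all(x == x[0]):
        raise ValueError("need at least two distinct x values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def orientation_histogram(
    population: list[SynapseTable], test: TestSet, theta: float = 1.0
) -> np.ndarray:
    """Neurons preferring each category (one bin per orientation category).

    Neurons that never fire on the test set are not counted in any bin.
    """
    hist = np.zeros(test.n_categories, dtype=int)
    for syn in population:
        _, pref = error_rate(syn, test, theta)
        if pref is not None:
            hist[pref] += 1
    return hist


@dataclass
class EvaluationResult:
    """Frozen-network metrics for a whole population on one test set."""

    per_neuron: pd.DataFrame
    allocation: np.ndarray
    preferred_histogram: np.ndarray
    mean_error_rate: float  # over neurons with at least one test firing
    n_silent: int


def evaluate_population(
    result,
    spec: datasets.DatasetSpec,
    n_blocks: int = 100,
    seed: int = 0,
    constants: EnergyConstants = EnergyConstants(),
    test: TestSet | None = None,
) -> EvaluationResult:
    """Measure every neuron of a PopulationResult on one shared test set.

    Vectorized across neurons: one excitation matrix for the whole
    population.
    """
    if test is None:
        test = make_test_set(spec, seed=seed, n_blocks=n_blocks)
    theta = result.params.theta
    n_inputs = test.patterns.shape[1]
    W = np.column_stack([t.final_weights.to_dense(n_inputs) for t in result.traces])
    Y = test.patterns @ W  # (n_patterns, n_neurons)
    Z = Y > theta
    # per-category firing counts, (n_categories, n_neurons)
    counts = np.zeros((test.n_categories, Z.shape[1]))
    for c in range(test.n_categories):
        counts[c] = Z[test.labels == c].sum(axis=0)
    totals = counts.sum(axis=0)
    preferred = np.argmax(counts, axis=0)
    fired = totals > 0
    err = np.full(Z.shape[1], np.nan)
    err[fired] = 1.0 - counts[preferred[fired], np.flatnonzero(fired)] / totals[fired]
    e_z = Z.mean(axis=0)
    e_y = Y.mean(axis=0)
    sw = W.sum(axis=0)
    per_neuron = pd.DataFrame(
        {
            "neuron": np.arange(Z.shape[1]),
            "firing_rate": e_z,
            "preferred_category": np.where(fired, preferred, -1),
            "error_rate": err,
            "total_weight": sw,
            "mean_excitation": e_y,
            "energy_syn_leak": constants.c_leak_syn * sw,
            "energy_syn_use": constants.c_exc * e_y,
            "energy_axo_leak": constants.c_leak_axo * (1.0 - e_z),
            "energy_ap": constants.c_ap * e_z,
        }
    )
    total_fires = counts.sum(axis=1)
    alloc = total_fires / total_fires.sum() if total_fires.sum() > 0 else total_fires
    hist = np.bincount(preferred[fired], minlength=test.n_categories)
    return EvaluationResult(
        per_neuron=per_neuron,
        allocation=alloc,
        preferred_histogram=hist,
        mean_error_rate=float(np.nanmean(err)) if fired.any() else float("nan"),
        n_silent=int((~fired).sum()),
    )
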