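"""Frozen-network measurements: allocation, error, energy, regression."""

import numpy as np
import pytest

from synaptogen import datasets, metrics, simulate
from synaptogen.dynamics import RunParams, SynapseTable
from synaptogen.metrics import (
    EnergyConstants,
    TestSet,
    allocation_index,
    energy_terms,
    error_rate,
    firing_rate,
    linear_fit,
    make_test_set,
    orientation_histogram,
    overproduction,
)
from synaptogen.simulate import NeuronTrace


def one_hot_test_set() -> TestSet:
    """100 patterns over 3 categories (20/30/50); line c is on iff the
    pattern belongs to category c, so a neuron with a large weight on line c
    fires exactly to category c."""
    labels = np.repeat([0, 1, 2], [20, 30, 50]).astype(np.int32)
    patterns = np.zeros((100, 3), dtype=np.uint8)
    patterns[np.arange(100), labels] = 1
    return TestSet(patterns=patterns, labels=labels, n_categories=3)


def detector(category: int, weight: float = 5.0) -> SynapseTable:
    return SynapseTable({category: weight})


class TestFiringRate:
    def test_synapse_free_neuron_is_silent(self):
        assert firing_rate(SynapseTable(), one_hot_test_set()) == 0.0

    def test_category_detector_rate(self):
        assert firing_rate(detector(2), one_hot_test_set()) == 0.5

    def test_saturated_neuron(self):
        table = SynapseTable({0: 99.0, 1: 99.0, 2: 99.0})
        assert firing_rate(table, one_hot_test_set()) == 1.0


class TestAllocation:
    def test_worked_example_fractions(self):
        # one detector per category: firings split 20/30/50
        pop = [detector(0), detector(1), detector(2)]
        alloc = allocation_index(pop, one_hot_test_set())
        assert np.allclose(alloc, [0.2, 0.3, 0.5])
        assert np.isclose(alloc.sum(), 1.0)

    def test_single_neuron_single_category(self):
        alloc = allocation_index([detector(1)], one_hot_test_set())
        assert np.allclose(alloc, [0.0, 1.0, 0.0])

    def test_silent_population_all_zero(self):
        alloc = allocation_index([SynapseTable()], one_hot_test_set())
        assert (alloc == 0).all()


class TestErrorRate:
    def test_pure_detector_has_zero_error(self):
        err, pref = error_rate(detector(2), one_hot_test_set())
        assert err == 0.0 and pref == 2

    def test_split_preference(self):
        table = SynapseTable({0: 5.0, 1: 5.0})
        err, pref = error_rate(table, one_hot_test_set())
        assert pref == 1  # fires 30 times to cat 1, 20 to cat 0 -> argmax
        assert np.isclose(err, 20 / 50)

    def test_equal_split_tie_to_lowest_and_half_error(self):
        labels = np.repeat([0, 1], [25, 25]).astype(np.int32)
        patterns = np.zeros((50, 2), dtype=np.uint8)
        patterns[np.arange(50), labels] = 1
        test = TestSet(patterns=patterns, labels=labels, n_categories=2)
        err, pref = error_rate(SynapseTable({0: 5.0, 1: 5.0}), test)
        assert pref == 0 and err == 0.5

    def test_silent_neuron_undefined(self):
        err, pref = error_rate(SynapseTable(), one_hot_test_set())
        assert np.isnan(err) and pref is None

    def test_error_bounded_by_preferred_share(self):
        # preferred is the argmax, so error <= 1 - 1/n_categories cannot be
        # exceeded when firing is spread across categories
        table = SynapseTable({0: 5.0, 1: 5.0, 2: 5.0})
        err, _ = error_rate(table, one_hot_test_set())
        assert err <= 1 - 1 / 3 + 1e-12


class TestEnergy:
    def test_synapse_free_neuron(self):
        terms = energy_terms(SynapseTable(), one_hot_test_set())
        assert (terms.syn_leak, terms.syn_use, terms.axo_leak, terms.ap) == (
            0.0, 0.0, 1.0, 0.0,
        )

    def test_substitution(self):
        # detector on the 50%-category: E[Z]=0.5, E[sum wx]=0.5*w, sum w = w
        terms = energy_terms(detector(2, weight=2.0), one_hot_test_set())
        assert terms.total_weight == 2.0
        assert np.isclose(terms.mean_excitation, 1.0)
        assert np.isclose(terms.mean_firing, 0.5)
        assert np.isclose(terms.axo_leak, 0.5)
        assert np.isclose(terms.total, 2.0 + 1.0 + 0.5 + 0.5)

    def test_use_bounded_by_leak_at_equal_constants(self, rng):
        test = one_hot_test_set()
        for _ in range(20):
            idx = rng.choice(3, size=rng.integers(1, 4), replace=False)
            table = SynapseTable({int(i): float(rng.random() * 3) for i in idx})
            t = energy_terms(table, test)
            assert t.syn_use <= t.syn_leak + 1e-12
            assert 0.0 <= t.mean_firing <= 1.0

    def test_constants_validation_and_preset(self):
        with pytest.raises(ValueError):
            EnergyConstants(c_ap=-1.0)
        bio = EnergyConstants.biological()
        assert bio.ap_leak_ratio_plausible()
        assert not EnergyConstants().ap_leak_ratio_plausible()


class TestOverproduction:
    def _trace(self, mx, stable, converged=True):
        return NeuronTrace(
            synapse_count_per_block=np.array([mx, stable]),
            max_synapses=mx,
            stable_synapses=stable,
            time_to_stability=1,
            converged=converged,
            final_weights=SynapseTable(),
            final_zbar=0.0,
        )

    def test_peak_minus_stable(self):
        assert overproduction(self._trace(30, 14)) == 16

    def test_monotone_trace_zero(self):
        assert overproduction(self._trace(5, 5)) == 0

    def test_nonconverged_rejected(self):
        with pytest.raises(ValueError):
            overproduction(self._trace(30, 14, converged=False))


class TestLinearFit:
    def test_exact_line(self):
        slope, intercept, r2 = linear_fit([0, 1, 2, 3], [0, 2, 4, 6])
        assert np.isclose(slope, 2.0) and np.isclose(intercept, 0.0)
        assert np.isclose(r2, 1.0)

    def test_matches_normal_equations(self, rng):
        x = rng.random(30)
        y = 1.5 * x + rng.normal(0, 0.1, 30)
        slope, intercept, r2 = linear_fit(x, y)
        X = np.column_stack([x, np.ones(30)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.isclose(slope, beta[0]) and np.isclose(intercept, beta[1])
        resid = y - X @ beta
        r2_oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert np.isclose(r2, r2_oracle)

    def test_degenerate_x(self):
        with pytest.raises(ValueError):
            linear_fit([1.0, 1.0], [0.0, 1.0])


class TestHistogram:
    def test_single_neuron_one_hot(self):
        hist = orientation_histogram([detector(1)], one_hot_test_set())
        assert hist.tolist() == [0, 1, 0]

    def test_silent_neurons_uncounted(self):
        hist = orientation_histogram([SynapseTable()], one_hot_test_set())
        assert hist.sum() == 0


class TestEvaluatePopulation:
    def test_vectorized_matches_per_neuron_functions(self, tiny_spec):
        """The population-level matrix pass must agree with the single-neuron
        reference metrics, neuron by neuron."""
        params = RunParams(epsilon=0.05, gamma=0.1, rho=0.5, theta=0.3,
                           stability_window=30)
        res = simulate.run_population(5, tiny_spec, params, master_seed=42)
        test = make_test_set(tiny_spec, seed=7, n_blocks=20)
        ev = metrics.evaluate_population(res, tiny_spec, test=test)
        tables = [t.final_weights for t in res.traces]
        for i, table in enumerate(tables):
            fr = firing_rate(table, test, theta=params.theta)
            assert np.isclose(ev.per_neuron["firing_rate"].iloc[i], fr)
            err, pref = error_rate(table, test, theta=params.theta)
            row_err = ev.per_neuron["error_rate"].iloc[i]
            if pref is None:
                assert np.isnan(row_err)
            else:
                assert np.isclose(row_err, err)
                assert ev.per_neuron["preferred_category"].iloc[i] == pref
            terms = energy_terms(table, test, theta=params.theta)
            assert np.isclose(ev.per_neuron["total_weight"].iloc[i], terms.total_weight)
            assert np.isclose(
                ev.per_neuron["mean_excitation"].iloc[i], terms.mean_excitation
            )
        alloc_ref = allocation_index(tables, test, theta=params.theta)
        assert np.allclose(ev.allocation, alloc_ref)
        if ev.allocation.sum() > 0:
            assert np.isclose(ev.allocation.sum(), 1.0)

    def test_repeatable_on_same_seed(self, tiny_spec):
        params = RunParams(epsilon=0.05, gamma=0.1, rho=0.5, theta=0.3,
                           stability_window=30)
        res = simulate.run_population(3, tiny_spec, params, master_seed=4)
        ev1 = metrics.evaluate_population(res, tiny_spec, n_blocks=10, seed=3)
        ev2 = metrics.evaluate_population(res, tiny_spec, n_blocks=10, seed=3)
        assert ev1.per_neuron.equals(ev2.per_neuron)
        assert np.array_equal(ev1.allocation, ev2.allocation)
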