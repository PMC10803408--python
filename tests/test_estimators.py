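"""Entropy backends: copula transform, Gaussian closed form, discrete entropies."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtri

from oigrad import (CohortSpec, CopulaBackend, ExactBackend, GateSpec, Panel,
                    PluginBackend, copula_transform, entropy_from_covariance,
                    gate_samples, gate_table, gaussian_cohort, joint_entropy,
                    make_backend, mutual_information)
from oigrad.errors import ContractError, DegenerateInputError

from _oracles import ranks_bruteforce

LN2PIE = math.log(2 * math.pi * math.e)


class TestCopulaTransform:
    def test_sorted_tiefree_column_maps_to_quantiles(self):
        panel = Panel(np.array([[10.0], [20.0], [30.0]]), ["a"])
        z = copula_transform(panel).values[:, 0]
        assert np.allclose(z, ndtri([1 / 4, 2 / 4, 3 / 4]))

    def test_ties_get_average_rank(self, rng):
        col = np.array([3.0, 1.0, 3.0, 2.0, 0.5])
        panel = Panel(col[:, None], ["a"])
        z = copula_transform(panel).values[:, 0]
        expected = ndtri(np.array(ranks_bruteforce(col)) / (len(col) + 1))
        assert np.allclose(z, expected)

    def test_constant_column_rejected_by_name(self):
        panel = Panel(np.column_stack([np.ones(5), np.arange(5.0)]), ["flat", "ok"])
        with pytest.raises(DegenerateInputError, match="flat"):
            copula_transform(panel)

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=3, max_size=40, unique=True))
    def test_invariant_under_monotone_reparametrization(self, xs):
        xs = [float(x) for x in xs]
        base = Panel(np.array(xs)[:, None], ["a"])
        for f in (lambda x: 3 * x + 1, np.arctan, lambda x: x ** 3):
            warped = Panel(f(np.array(xs))[:, None], ["a"])
            assert np.allclose(copula_transform(base).values,
                               copula_transform(warped).values)


class TestGaussianEntropy:
    @pytest.mark.parametrize("cov, expected", [
        ([[1.0]], 0.5 * LN2PIE),
        (np.eye(2), LN2PIE),
        ([[1.0, 0.5], [0.5, 1.0]], 0.5 * (2 * LN2PIE + math.log(0.75))),
    ])
    def test_closed_form(self, cov, expected):
        assert entropy_from_covariance(cov) == pytest.approx(expected, abs=1e-12)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(DegenerateInputError):
            entropy_from_covariance([[1.0, 2.0], [2.0, 1.0]])


class TestDiscreteBackends:
    def test_xor3_joint_entropy_two_bits(self, xor3):
        assert joint_entropy(xor3) == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("size", [1, 2, 3, 4])
    def test_copy_gate_every_subset_one_bit(self, size):
        backend = ExactBackend(gate_table(GateSpec("copy", 4)), units="bits")
        for subset in itertools.combinations(range(1, 5), size):
            assert joint_entropy(backend, subset) == pytest.approx(1.0, abs=1e-12)

    def test_empty_subset_entropy_is_exactly_zero(self, xor3):
        assert joint_entropy(xor3, ()) == 0.0

    def test_plugin_converges_to_exact(self):
        spec = GateSpec("xor", 3)
        exact = ExactBackend(gate_table(spec), units="bits")
        errs = []
        for T in (50, 5000):
            plugin = PluginBackend(gate_samples(spec, T, seed=7), units="bits")
            errs.append(abs(joint_entropy(plugin) - joint_entropy(exact)))
        assert errs[1] < errs[0] and errs[1] < 0.01

    def test_plugin_exact_on_exhaustive_samples(self):
        spec = GateSpec("xor", 4)
        exact = ExactBackend(gate_table(spec))
        plugin = PluginBackend(gate_samples(spec, 16, exhaustive=True))
        for size in range(1, 5):
            for subset in itertools.combinations(range(1, 5), size):
                assert joint_entropy(plugin, subset) == pytest.approx(
                    joint_entropy(exact, subset), abs=1e-12)

    def test_monotone_in_subset_for_exact_backend(self, rng, xor3):
        for _ in range(20):
            size = rng.integers(1, 3)
            a = tuple(rng.choice(3, size=size, replace=False) + 1)
            extra = tuple(set(range(1, 4)) - set(a))
            assert joint_entropy(xor3, a + extra) >= joint_entropy(xor3, a) - 1e-12


class TestConditionalEntropyIdentity:
    @pytest.mark.parametrize("backend_kind", ["exact", "plugin", "copula"])
    def test_holds_on_random_pairs(self, backend_kind, rng):
        if backend_kind == "exact":
            backend = ExactBackend(gate_table(GateSpec("xor", 4)))
        elif backend_kind == "plugin":
            backend = PluginBackend(gate_samples(GateSpec("xor", 4), 64, seed=3))
        else:
            panel = gaussian_cohort(CohortSpec(1, 4, 300, "common_latent",
                                               loading=0.7, seed=5))[0]
            backend = CopulaBackend(panel)
        for _ in range(10):
            i, j = rng.choice(4, size=2, replace=False) + 1
            h_cond = joint_entropy(backend, (i, j)) - joint_entropy(backend, (j,))
            # conditioning cannot increase entropy, and for discrete sources
            # the conditional entropy is non-negative
            assert h_cond <= joint_entropy(backend, (i,)) + 1e-10
            if backend_kind != "copula":
                assert h_cond >= -1e-12


class TestCopulaOnGaussianData:
    def test_bias_below_five_centinats_at_large_T(self):
        rho = 0.5
        cov = np.full((3, 3), rho)
        np.fill_diagonal(cov, 1.0)
        rng = np.random.default_rng(99)
        x = rng.multivariate_normal(np.zeros(3), cov, size=10_000)
        backend = CopulaBackend(Panel(x, ["a", "b", "c"]))
        true_h = entropy_from_covariance(cov)
        assert abs(joint_entropy(backend) - true_h) < 0.05

    def test_deterministic_and_cached(self, independent_panel):
        backend = CopulaBackend(independent_panel)
        first = joint_entropy(backend, (1, 3, 5))
        assert joint_entropy(backend, (5, 1, 3)) == first


class TestMutualInformation:
    def test_independent_variables_zero(self):
        p = np.full((2, 2), 0.25)
        backend = ExactBackend(__import__("oigrad").JointTable(p), units="bits")
        assert mutual_information(backend, (1,), (2,)) == pytest.approx(0, abs=1e-12)

    def test_copy_gate_pairwise_one_bit(self):
        backend = ExactBackend(gate_table(GateSpec("copy", 4)), units="bits")
        for i, j in itertools.combinations(range(1, 5), 2):
            assert mutual_information(backend, (i,), (j,)) == pytest.approx(1.0)

    def test_xor_synergy_signature(self, xor3):
        assert mutual_information(xor3, (1,), (2, 3)) == pytest.approx(1.0, abs=1e-12)
        assert mutual_information(xor3, (1,), (2,)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_rejects_overlap(self, xor3):
        assert mutual_information(xor3, (1,), (2, 3)) == pytest.approx(
            mutual_information(xor3, (2, 3), (1,)), abs=1e-14)
        with pytest.raises(ContractError):
            mutual_information(xor3, (1, 2), (2, 3))


def test_make_backend_dispatch(independent_panel):
    assert make_backend(gate_table(GateSpec("xor", 3))).kind == "exact"
    assert make_backend(gate_samples(GateSpec("xor", 3), 8, seed=0)).kind == "plugin"
    assert make_backend(independent_panel).kind == "copula"
    with pytest.raises(ContractError):
        make_backend(independent_panel, estimator="exact")
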