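"""Gradients of O-information: gate attainment, bounds, chain rule, scans."""

import itertools
import math

import numpy as np
import pytest

from oigrad import (ExactBackend, GateSpec, JointTable, first_order_bounds,
                    gate_table, gradient_first, gradient_k, gradient_second,
                    scan_multiplets)
from oigrad.errors import ContractError, OrderUnsupportedError

from _oracles import nested_gradient_bruteforce, random_dirichlet_table


def _gate_backend(kind, n, units="bits"):
    return ExactBackend(gate_table(GateSpec(kind, n)), units=units)


class TestGateAnalytics:
    @pytest.mark.parametrize("n", range(3, 9))
    def test_copy_gate_attains_upper_bound(self, n):
        backend = _gate_backend("copy", n)
        _, upper = first_order_bounds(n, 2, units="bits")
        for i in range(1, n + 1):
            assert gradient_first(backend, i).value == pytest.approx(upper, abs=1e-12)
            assert upper == 1.0  # log2 |X| in bits

    @pytest.mark.parametrize("n", range(3, 9))
    def test_xor_gate_attains_lower_bound(self, n):
        backend = _gate_backend("xor", n)
        lower, _ = first_order_bounds(n, 2, units="bits")
        for i in range(1, n + 1):
            assert gradient_first(backend, i).value == pytest.approx(lower, abs=1e-12)
            assert lower == -(n - 2)  # synergy capacity grows linearly with n

    @pytest.mark.parametrize("n", range(4, 9))
    def test_copy_pairs_add_no_further_redundancy(self, n):
        backend = _gate_backend("copy", n)
        for i, j in itertools.combinations(range(1, n + 1), 2):
            assert gradient_second(backend, i, j).value == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize("n", range(4, 9))
    def test_xor_pairs_contribute_irreducible_synergy(self, n):
        backend = _gate_backend("xor", n)
        for i, j in itertools.combinations(range(1, n + 1), 2):
            assert gradient_second(backend, i, j).value == pytest.approx(
                2 - n, abs=1e-12)


class TestIndependentVariables:
    def test_gradient_of_detached_variable_is_zero(self):
        gate = gate_table(GateSpec("xor", 3))
        augmented = JointTable(np.multiply.outer(gate.probabilities, [0.5, 0.5]))
        backend = ExactBackend(augmented, units="bits")
        assert gradient_first(backend, 4).value == pytest.approx(0, abs=1e-12)
        # any multiplet containing the detached bit scores zero
        for gamma in [(4,), (1, 4), (2, 4)]:
            assert gradient_k(backend, gamma).value == pytest.approx(0, abs=1e-12)


class TestChainRule:
    def test_matches_nested_first_differences_on_random_tables(self, rng):
        for _ in range(20):
            p = random_dirichlet_table(rng, (2, 2, 2, 2, 2))
            backend = ExactBackend(JointTable(p))
            for gamma in [(1,), (2, 4), (1, 3, 5)]:
                got = gradient_k(backend, gamma).value
                want = nested_gradient_bruteforce(p, tuple(g - 1 for g in gamma))
                assert got == pytest.approx(want, abs=1e-10)

    def test_triplet_expansion_has_eight_signed_terms(self, rng):
        from oigrad.gradients import _omega_nats
        p = random_dirichlet_table(rng, (2, 2, 2, 2, 2))
        backend = ExactBackend(JointTable(p))
        i, j, k = 0, 2, 3
        full = tuple(range(5))

        def w(*drop):
            return _omega_nats(backend, tuple(x for x in full if x not in drop))

        explicit = (w() - w(i) - w(j) - w(k)
                    + w(i, j) + w(i, k) + w(j, k) - w(i, j, k))
        assert gradient_k(backend, (i + 1, j + 1, k + 1)).value == pytest.approx(
            explicit, abs=1e-12)

    def test_agrees_with_dedicated_low_order_routines(self, rng):
        p = random_dirichlet_table(rng, (2, 2, 2, 2, 2))
        backend = ExactBackend(JointTable(p))
        assert gradient_k(backend, (2,)).value == pytest.approx(
            gradient_first(backend, 2).value, abs=1e-12)
        assert gradient_k(backend, (2, 5)).value == pytest.approx(
            gradient_second(backend, 2, 5).value, abs=1e-12)

    def test_value_independent_of_member_ordering(self, rng):
        p = random_dirichlet_table(rng, (2, 2, 2, 2, 2))
        backend = ExactBackend(JointTable(p))
        vals = {gradient_k(backend, perm).value
                for perm in itertools.permutations((1, 3, 4))}
        assert max(vals) - min(vals) < 1e-14


class TestBounds:
    def test_hold_on_random_binary_systems(self, rng):
        lower, upper = first_order_bounds(4, 2, units="nats")
        for _ in range(200):
            p = random_dirichlet_table(rng, (2, 2, 2, 2))
            backend = ExactBackend(JointTable(p))
            for i in range(1, 5):
                v = gradient_first(backend, i).value
                assert lower - 1e-10 <= v <= upper + 1e-10


class TestSymmetryAndErrors:
    def test_second_order_symmetric_in_the_pair(self, rng):
        p = random_dirichlet_table(rng, (2, 3, 2, 2))
        backend = ExactBackend(JointTable(p))
        for i, j in itertools.combinations(range(1, 5), 2):
            assert gradient_second(backend, i, j).value == pytest.approx(
                gradient_second(backend, j, i).value, abs=1e-14)

    def test_contract_violations(self, xor3):
        big = ExactBackend(gate_table(GateSpec("xor", 5)))
        with pytest.raises(ContractError):
            gradient_second(big, 2, 2)
        with pytest.raises(OrderUnsupportedError):
            gradient_k(big, (1, 2, 3, 4))  # order > n - 2
        with pytest.raises(OrderUnsupportedError):
            gradient_first(xor3, 1, system=(1, 2))
        with pytest.raises(OrderUnsupportedError):
            gradient_second(xor3, 1, 2)  # needs n >= 4


class TestScan:
    @pytest.mark.parametrize("order, count", [(1, 7), (2, 21), (3, 35)])
    def test_seven_variable_multiplet_counts(self, order, count):
        backend = _gate_backend("copy", 7)
        results = scan_multiplets(backend, order)
        assert len(results) == count == math.comb(7, order)

    def test_five_variable_order_one(self):
        backend = _gate_backend("xor", 5)
        assert [r.multiplet for r in scan_multiplets(backend, 1)] == [
            (1,), (2,), (3,), (4,), (5,)]

    def test_lexicographic_multiplet_order(self):
        backend = _gate_backend("xor", 5)
        multiplets = [r.multiplet for r in scan_multiplets(backend, 2)]
        assert multiplets == sorted(multiplets)
        assert multiplets[0] == (1, 2) and multiplets[-1] == (4, 5)

    def test_order_out_of_range(self, xor3):
        with pytest.raises(OrderUnsupportedError):
            scan_multiplets(xor3, 2)
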