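"""Gradients of the O-information: localized redundancy/synergy descriptors.

The first-order gradient of variable i is the change in O-information when
X_i joins the rest of the system,

    d_i Omega(X^n) = Omega(X^n) - Omega(X^n minus X_i),

positive when X_i contributes mainly redundancy, negative when it fosters
synergy. Higher orders follow by repeated differencing and collapse to an
inclusion-exclusion chain rule over a multiplet gamma:

    d^|gamma|_gamma Omega(X^n) = sum over alpha subset of gamma of
                                 (-1)^|alpha| Omega(X^n minus alpha),

the irreducible contribution of gamma that cannot be ascribed to any of its
sub-multiplets. For exact discrete systems the first-order gradient is
bounded by -(n-2) log|X| <= d_i Omega <= log|X| where |X| is the largest
alphabet; the binary n-XOR gate attains the lower bound and the n-COPY gate
the upper one.

Each operation also evaluates the algebraically equivalent alternative form
(the mutual-information expansion at order one, the whole-minus-sum and
index-swapped expansions at order two) and asserts agreement, guarding the
entropy cache and index bookkeeping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, log

from .errors import ContractError, OrderUnsupportedError
from .estimators import EntropyBackend
from .measures import o_information

__all__ = ["GradientResult", "gradient_first", "gradient_second", "gradient_k",
           "scan_multiplets", "first_order_bounds"]


@dataclass(frozen=True)
class GradientResult:
    """Gradient of the O-information for one multiplet.

    ``multiplet`` uses 1-based variable positions (sorted); ``names`` the
    corresponding labels; ``order`` is the multiplet size; ``n`` the size of
    the system within which the gradient was taken.
    """

    multiplet: tuple
    names: tuple
    order: int
    value: float
    n: int
    units: str
    estimator: str

    def __float__(self) -> float:
        return self.value

    @property
    def character(self) -> str:
        """Sign label: redundant (>0), synergistic (<0), or neutral."""
        if self.value > 0:
            return "redundant"
        if self.value < 0:
            return "synergistic"
        return "neutral"


def _system_key(backend: EntropyBackend, system):
    return tuple(range(backend.n)) if system is None else backend.resolve(system)


def _omega_nats(backend: EntropyBackend, key: tuple) -> float:
    """O-information of the subset `key` (0-based, sorted), in nats."""
    m = len(key)
    h = backend.entropy_nats_key
    return (m - 2) * h(key) + sum(
        h((i,)) - h(tuple(j for j in key if j != i)) for i in key
    )


def _check_membership(gamma_key, system_key, what="multiplet"):
    missing = set(gamma_key) - set(system_key)
    if missing:
        raise ContractError(f"{what} members {sorted(missing)} not in the system")


def _result(backend, gamma_key, system_key, value_nats) -> GradientResult:
    return GradientResult(
        multiplet=tuple(i + 1 for i in gamma_key),
        names=tuple(backend.names[i] for i in gamma_key),
        order=len(gamma_key),
        value=backend._convert(value_nats),
        n=len(system_key),
        units=backend.units,
        estimator=backend.kind,
    )


def gradient_first(backend: EntropyBackend, i, system=None) -> GradientResult:
    """First-order gradient of variable ``i`` within ``system`` (default: all).

    Computed as Omega(S) - Omega(S minus i) and cross-checked against the
    mutual-information expansion
    (2 - m) I(X_i; S_-i) + sum_{k != i} I(X_i; S_-ik).
    """
    system_key = _system_key(backend, system)
    m = len(system_key)
    if m < 3:
        raise OrderUnsupportedError(
            f"first-order gradient needs a system of >= 3 variables, got {m}")
    (i_key,) = backend.resolve([i])
    _check_membership((i_key,), system_key, "variable")

    rest = tuple(k for k in system_key if k != i_key)
    value = _omega_nats(backend, system_key) - _omega_nats(backend, rest)

    # mutual-information form of the same quantity:
    # (2 - m) I(X_i; S_-i) + sum over k != i of I(X_i; S_-ik)
    h = backend.entropy_nats_key
    def mi(a_key, b_key):
        return h(a_key) + h(b_key) - h(tuple(sorted(a_key + b_key)))
    mi_form = (2 - m) * mi((i_key,), rest)
    for k in rest:
        others = tuple(x for x in system_key if x not in (i_key, k))
        mi_form += mi((i_key,), others)
    if abs(value - mi_form) > backend.dual_route_tol * max(1.0, abs(value)):
        raise AssertionError(
            f"gradient forms disagree: difference {value} vs MI expansion {mi_form}")
    return _result(backend, (i_key,), system_key, value)


def gradient_second(backend: EntropyBackend, i, j, system=None) -> GradientResult:
    """Second-order gradient of the pair (i, j): d_i Omega(S) - d_i Omega(S minus j).

    Asserted equal to the whole-minus-sum expansion and to the (i, j)-swapped
    computation; the result is symmetric in the pair.
    """
    system_key = _system_key(backend, system)
    m = len(system_key)
    if m < 4:
        raise OrderUnsupportedError(
            f"second-order gradient needs a system of >= 4 variables, got {m}")
    (i_key,) = backend.resolve([i])
    (j_key,) = backend.resolve([j])
    if i_key == j_key:
        raise ContractError("second-order gradient needs two distinct variables")
    _check_membership((i_key, j_key), system_key, "pair")

    def omega_minus(*drop):
        return _omega_nats(backend, tuple(k for k in system_key if k not in drop))

    w_full = _omega_nats(backend, system_key)
    w_i, w_j, w_ij = omega_minus(i_key), omega_minus(j_key), omega_minus(i_key, j_key)

    value = (w_full - w_i) - (w_j - w_ij)            # d_i Omega(S) - d_i Omega(S-j)
    swapped = (w_full - w_j) - (w_i - w_ij)          # d_j Omega(S) - d_j Omega(S-i)
    whole_minus_sum = (w_full - w_ij) - (w_i - w_ij) - (w_j - w_ij)
    tol = backend.dual_route_tol * max(1.0, abs(value))
    if abs(value - swapped) > tol or abs(value - whole_minus_sum) > tol:
        raise AssertionError("second-order gradient expansions disagree")
    return _result(backend, (i_key, j_key), system_key, value)


def gradient_k(backend: EntropyBackend, gamma, system=None) -> GradientResult:
    """Gradient of order |gamma| via the inclusion-exclusion chain rule.

    Sums (-1)^|alpha| Omega(S minus alpha) over all 2^|gamma| subsets alpha
    of the multiplet, including the empty set (+Omega(S)). Requires
    |S| - |gamma| >= 2 so no Omega term degenerates below two variables.
    """
    system_key = _system_key(backend, system)
    gamma_key = backend.resolve(gamma)
    if not gamma_key:
        raise ContractError("multiplet must be nonempty")
    _check_membership(gamma_key, system_key)
    if len(gamma_key) > len(system_key) - 2:
        raise OrderUnsupportedError(
            f"order {len(gamma_key)} unsupported for a system of "
            f"{len(system_key)} variables (need order <= n - 2)")
    value = 0.0
    for r in range(len(gamma_key) + 1):
        for alpha in itertools.combinations(gamma_key, r):
            reduced = tuple(k for k in system_key if k not in alpha)
            value += (-1) ** r * _omega_nats(backend, reduced)
    return _result(backend, gamma_key, system_key, value)


def scan_multiplets(backend: EntropyBackend, order: int, system=None) -> list:
    """All gradients of the given order, one per multiplet, lexicographic.

    For an n-variable system this emits C(n, order) results (n = 7 gives the
    familiar 7 / 21 / 35 counts at orders 1 / 2 / 3).
    """
    system_key = _system_key(backend, system)
    n = len(system_key)
    if not 1 <= order <= n - 2:
        raise OrderUnsupportedError(
            f"order {order} out of range [1, {n - 2}] for {n} variables")
    results = [
        gradient_k(backend, tuple(i + 1 for i in gamma), system=system)
        for gamma in itertools.combinations(system_key, order)
    ]
    assert len(results) == comb(n, order)
    return results


def first_order_bounds(n: int, alphabet: int, units: str = "bits") -> tuple:
    """Tight bounds (lower, upper) on a first-order gradient of an n-variable
    discrete system whose largest alphabet has `alphabet` symbols:
    -(n-2) log|X| <= d_i Omega <= log|X|."""
    logx = log(alphabet) / log(2) if units == "bits" else log(alphabet)
    return (-(n - 2) * logx, logx)
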