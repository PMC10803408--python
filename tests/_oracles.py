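"""Independent brute-force oracles used only by the tests.

Everything here enumerates probability tables directly with dict
accumulation over outcome tuples — no marginalization axes, no entropy
caching — so it cannot share a defect with the implementation it checks.
"""

import itertools
import math

import numpy as np


def marginal_entropy_bruteforce(p: np.ndarray, subset, base=math.e) -> float:
    """Entropy of the marginal over `subset` (0-based) by explicit summation."""
    acc = {}
    for outcome in itertools.product(*(range(s) for s in p.shape)):
        key = tuple(outcome[i] for i in subset)
        acc[key] = acc.get(key, 0.0) + float(p[outcome])
    return -sum(q * math.log(q, base) for q in acc.values() if q > 0)


def omega_bruteforce(p: np.ndarray, subset=None, base=math.e) -> float:
    """O-information of `subset` by direct enumeration of every marginal."""
    key = tuple(range(p.ndim)) if subset is None else tuple(sorted(subset))
    m = len(key)
    h = lambda s: marginal_entropy_bruteforce(p, s, base) if s else 0.0
    return (m - 2) * h(key) + sum(
        h((i,)) - h(tuple(j for j in key if j != i)) for i in key
    )


def nested_gradient_bruteforce(p: np.ndarray, gamma, system=None, base=math.e) -> float:
    """Gradient of order |gamma| by explicit repeated first differences."""
    system = tuple(range(p.ndim)) if system is None else tuple(sorted(system))
    gamma = tuple(gamma)

    def diff(members, sys_key):
        if not members:
            return omega_bruteforce(p, sys_key, base)
        head, tail = members[0], members[1:]
        without_head = tuple(k for k in sys_key if k != head)
        return diff(tail, sys_key) - diff(tail, without_head)

    return diff(gamma, system)


def random_dirichlet_table(rng, shape) -> np.ndarray:
    """A random joint probability table with Dirichlet(1,...,1) mass."""
    flat = rng.dirichlet(np.ones(int(np.prod(shape))))
    return flat.reshape(shape)


def ranks_bruteforce(column) -> list:
    """Average ranks (1-based) by pairwise comparison, ties averaged."""
    out = []
    for x in column:
        less = sum(1 for y in column if y < x)
        equal = sum(1 for y in column if y == x)
        out.append(less + (equal + 1) / 2.0)
    return out
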