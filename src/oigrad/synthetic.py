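"""Ground-truth generators: logic-gate distributions and Gaussian cohorts.

Two families of inputs with known higher-order structure:

* **Gates.** The n-XOR gate takes X_1..X_{n-1} as fair Bernoulli variables
  and X_n their sum modulo the alphabet size; it is the maximally
  synergistic distribution and attains the first-order gradient lower bound.
  The n-COPY gate sets X_1 = X_2 = ... = X_n for a uniform X_1; it is the
  maximally redundant distribution and attains the upper bound.

* **Gaussian cohorts.** Continuous panels mimicking multi-record study
  designs, with planted structure: a common latent factor (every variable
  loads on one shared source -> redundancy-dominated, population Omega > 0),
  a sum node (one variable is the noisy sum of otherwise independent
  sources -> synergy-dominated, population Omega < 0, the continuous
  analogue of XOR), a mixed design planting both motifs on disjoint variable
  groups, or pure independent noise. All have closed-form covariances, so
  the population O-information is available analytically for convergence
  checks.

`preprocess` mirrors typical physiological-series conditioning: a
moving-average high-pass to strip slow trends, then per-column
standardization to zero mean and unit variance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DegenerateInputError
from .estimators import entropy_from_covariance
from .panel import JointTable, Panel

__all__ = ["GateSpec", "CohortSpec", "gate_table", "gate_samples",
           "gaussian_cohort", "population_covariance",
           "population_o_information", "preprocess"]


@dataclass(frozen=True)
class GateSpec:
    """A parity (xor) or replication (copy) gate over ``n`` variables with a
    uniform ``alphabet``-ary source alphabet (2 = the binary gates)."""

    kind: str
    n: int
    alphabet: int = 2

    def __post_init__(self):
        if self.kind not in ("xor", "copy"):
            raise ContractError(f"unknown gate kind {self.kind!r}")
        if self.n < 3:
            raise ContractError("gates need n >= 3 variables")
        if self.alphabet < 2:
            raise ContractError("alphabet size must be >= 2")


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic multi-record study design.

    structure:
        "independent"    pure standard-normal noise;
        "common_latent"  X_i = loading * Z + sqrt(1 - loading^2) * eps_i;
        "sum_node"       X_n = sum_{i<n} X_i + noise_sd * eta, X_{i<n} iid;
        "mixed"          first three variables carry a common latent, the
                         next three a sum node, the rest are independent
                         (requires n_vars >= 6).
    """

    n_records: int
    n_vars: int
    T: int
    structure: str = "independent"
    loading: float = 0.9
    noise_sd: float = 0.1
    seed: int | None = None
    names: tuple = field(default=None)

    def __post_init__(self):
        if min(self.n_records, self.n_vars, self.T) < 1:
            raise ContractError("all cohort counts must be positive")
        if self.structure not in ("independent", "common_latent", "sum_node", "mixed"):
            raise ContractError(f"unknown structure {self.structure!r}")
        if not 0.0 < self.loading < 1.0:
            raise ContractError("loading must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ContractError("noise_sd must be positive")
        if self.structure in ("common_latent", "sum_node") and self.n_vars < 3:
            raise ContractError(f"{self.structure} needs at least 3 variables")
        if self.structure == "mixed" and self.n_vars < 6:
            raise ContractError("mixed structure needs at least 6 variables")
        names = self.names or tuple(f"X{i}" for i in range(1, self.n_vars + 1))
        if len(names) != self.n_vars:
            raise ContractError("one name per variable required")
        object.__setattr__(self, "names", tuple(names))


def gate_table(spec: GateSpec) -> JointTable:
    """Exact joint probability table of the gate, lexicographic tuple order.

    XOR: uniform mass |X|^-(n-1) on the tuples whose last symbol equals the
    sum of the others modulo |X|. COPY: mass 1/|X| on each constant tuple.
    """
    k, n = spec.alphabet, spec.n
    p = np.zeros((k,) * n)
    if spec.kind == "xor":
        mass = float(k) ** (-(n - 1))
        for tup in itertools.product(range(k), repeat=n - 1):
            p[tup + (sum(tup) % k,)] = mass
    else:
        for a in range(k):
            p[(a,) * n] = 1.0 / k
    return JointTable(p)


def gate_samples(spec: GateSpec, T: int, seed=None, exhaustive: bool = False) -> Panel:
    """Draw a discrete sample panel from the gate distribution.

    With ``exhaustive=True`` each support outcome appears exactly
    T / |support| times (T must be divisible by the support size), so
    plug-in entropies reproduce the exact table values.
    """
    if T < 1:
        raise ContractError("T must be >= 1")
    table = gate_table(spec)
    support = np.argwhere(table.probabilities > 0)
    if exhaustive:
        reps, rem = divmod(T, len(support))
        if rem:
            raise ContractError(
                f"exhaustive sampling needs T divisible by the support size "
                f"{len(support)}, got T={T}")
        values = np.repeat(support, reps, axis=0)
    else:
        rng = np.random.default_rng(seed)
        weights = table.probabilities[tuple(support.T)]
        values = support[rng.choice(len(support), size=T, p=weights)]
    return Panel(values.astype(float), table.names, kind="discrete")


def population_covariance(spec: CohortSpec) -> np.ndarray:
    """Closed-form covariance implied by the cohort structure."""
    n = spec.n_vars
    cov = np.eye(n)
    if spec.structure == "common_latent":
        _fill_latent(cov, range(n), spec.loading)
    elif spec.structure == "sum_node":
        _fill_sum_node(cov, range(n), spec.noise_sd)
    elif spec.structure == "mixed":
        _fill_latent(cov, range(3), spec.loading)
        _fill_sum_node(cov, range(3, 6), spec.noise_sd)
    return cov


def _fill_latent(cov, idx, loading):
    idx = list(idx)
    for a in idx:
        for b in idx:
            if a != b:
                cov[a, b] = loading ** 2


def _fill_sum_node(cov, idx, noise_sd):
    idx = list(idx)
    sources, target = idx[:-1], idx[-1]
    cov[target, target] = len(sources) + noise_sd ** 2
    for s in sources:
        cov[s, target] = cov[target, s] = 1.0


def population_o_information(spec: CohortSpec, subset=None) -> float:
    """Analytic O-information (nats) of the Gaussian population law.

    Evaluates the whole-minus-residual entropy combination directly on the
    closed-form covariance; ``subset`` is a 0-based index sequence
    (default: all variables).
    """
    cov = population_covariance(spec)
    key = tuple(range(spec.n_vars)) if subset is None else tuple(sorted(subset))
    m = len(key)

    def h(ix):
        if not ix:
            return 0.0
        return entropy_from_covariance(cov[np.ix_(ix, ix)])

    return (m - 2) * h(key) + sum(
        h((i,)) - h(tuple(j for j in key if j != i)) for i in key
    )


def gaussian_cohort(spec: CohortSpec) -> list:
    """Generate ``n_records`` independent continuous panels from the design."""
    rng = np.random.default_rng(spec.seed)
    cov = population_covariance(spec)
    chol = np.linalg.cholesky(cov)
    panels = []
    for _ in range(spec.n_records):
        z = rng.standard_normal((spec.T, spec.n_vars))
        panels.append(Panel(z @ chol.T, spec.names, kind="continuous"))
    return panels


def _moving_average_baseline(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with reflected edges, per column."""
    half = window // 2
    padded = np.pad(x, ((half, half), (0, 0)), mode="reflect")
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    return np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="valid"),
                               0, padded)


def preprocess(panel: Panel, highpass: bool = True, zscore: bool = True,
               window: int | None = None) -> Panel:
    """High-pass filter (moving-average detrend) and standardize a panel.

    The high-pass subtracts a centered moving-average baseline (default
    window T/10 samples, reflected edges), removing slow trends while
    leaving fast covariation intact; standardization then makes every
    column exactly zero-mean, unit-variance.
    """
    if panel.kind != "continuous":
        raise ContractError("preprocessing applies to continuous panels")
    x = panel.values.copy()
    if highpass:
        if panel.n_samples < 10:
            raise ContractError("high-pass filtering needs at least 10 samples")
        w = window or max(3, panel.n_samples // 10)
        x = x - _moving_average_baseline(x, w)
    if zscore:
        sd = x.std(axis=0, ddof=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise DegenerateInputError(
                f"column {panel.names[dead[0]]!r} is constant; cannot standardize")
        x = (x - x.mean(axis=0)) / sd
    return Panel(x, panel.names, kind="continuous")
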