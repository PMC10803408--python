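"""Interchangeable joint-entropy backends.

Every information measure in this package is a linear combination of joint
entropies H(S) of variable subsets S. Three backends supply H:

* :class:`ExactBackend` — analytic entropies from a :class:`~oigrad.panel.JointTable`;
* :class:`PluginBackend` — empirical plug-in entropies from a discrete sample panel;
* :class:`CopulaBackend` — Gaussian-copula entropies from a continuous panel:
  each margin is rank-transformed to standard-normal quantiles, after which
  the closed-form Gaussian entropy of the empirical covariance estimates the
  dependence-carrying part of the joint entropy.

Entropies are computed in nats internally and converted to the backend's
``units`` ("nats" or "bits") at a single point on return. Values are memoized
per sorted subset because gradient scans reuse overlapping subsets heavily.

Subsets are specified user-side with 1-based variable positions (matching the
X_1 ... X_n convention) or variable names; they are resolved to sorted 0-based
tuples internally.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, special, stats

from .errors import ContractError, DegenerateInputError
from .panel import JointTable, Panel

__all__ = [
    "copula_transform",
    "entropy_from_covariance",
    "joint_entropy",
    "mutual_information",
    "EntropyBackend",
    "ExactBackend",
    "PluginBackend",
    "CopulaBackend",
    "make_backend",
]

_LN2 = np.log(2.0)
_EIG_TOL = 1e-10  # reject correlation matrices with eigenvalues below this


def resolve_subset(subset, names) -> tuple:
    """Resolve 1-based positions and/or names to a sorted 0-based index tuple."""
    n = len(names)
    name_to_idx = {s: i for i, s in enumerate(names)}
    out = []
    for item in subset:
        if isinstance(item, str):
            if item not in name_to_idx:
                raise ContractError(f"unknown variable name {item!r}")
            out.append(name_to_idx[item])
        else:
            i = int(item)
            if not 1 <= i <= n:
                raise ContractError(f"variable index {i} outside 1..{n}")
            out.append(i - 1)
    if len(set(out)) != len(out):
        raise ContractError(f"subset {tuple(subset)} contains duplicate variables")
    return tuple(sorted(out))


def copula_transform(panel: Panel) -> Panel:
    """Map each column to standard-normal quantiles of its empirical ranks.

    Ranks use the r/(T+1) convention with average ranks on ties, so the
    inverse normal CDF never receives 0 or 1. The transform is invariant
    under strictly monotone reparametrization of each column.
    """
    if panel.n_samples < 3:
        raise ContractError("copula transform needs at least 3 samples")
    T = panel.n_samples
    out = np.empty_like(panel.values)
    for j, name in enumerate(panel.names):
        col = panel.values[:, j]
        if np.ptp(col) == 0:
            raise DegenerateInputError(f"column {name!r} is constant")
        ranks = stats.rankdata(col, method="average")
        out[:, j] = special.ndtri(ranks / (T + 1))
    return Panel(out, panel.names, kind="continuous")


def entropy_from_covariance(cov: np.ndarray) -> float:
    """Differential entropy (nats) of a Gaussian with the given covariance.

    Returns (1/2) ln((2 pi e)^k det cov) for a k x k symmetric
    positive-definite covariance matrix.
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    k = cov.shape[0]
    if cov.shape != (k, k):
        raise ContractError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ContractError("covariance must be symmetric")
    try:
        ch = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise DegenerateInputError(f"covariance is not positive-definite: {exc}") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(ch)))
    return 0.5 * (k * np.log(2.0 * np.pi * np.e) + logdet)


class EntropyBackend:
    """Contract: map any subset of variables to a joint-entropy value.

    Subclasses implement ``_entropy_nats(key)`` for a sorted 0-based tuple;
    this base class handles resolution, memoization, the H(empty set) = 0
    convention, and unit conversion.
    """

    #: tolerance for asserting algebraically equivalent dual-route formulas
    dual_route_tol = 1e-10
    kind = "abstract"

    def __init__(self, names, units: str = "nats"):
        if units not in ("nats", "bits"):
            raise ContractError(f"unknown units {units!r}")
        self.names = tuple(names)
        self.units = units
        self._cache: dict = {}

    @property
    def n(self) -> int:
        return len(self.names)

    def resolve(self, subset) -> tuple:
        return resolve_subset(subset, self.names)

    def full_set(self) -> tuple:
        """The complete system as a 1-based index tuple."""
        return tuple(range(1, self.n + 1))

    def entropy(self, subset=None) -> float:
        """Joint entropy of the subset (default: all variables) in ``self.units``."""
        key = tuple(range(self.n)) if subset is None else self.resolve(subset)
        return self._convert(self.entropy_nats_key(key))

    def entropy_nats_key(self, key: tuple) -> float:
        if not key:
            return 0.0
        h = self._cache.get(key)
        if h is None:
            h = self._cache[key] = self._entropy_nats(key)
        return h

    def _convert(self, value_nats: float) -> float:
        return value_nats / _LN2 if self.units == "bits" else value_nats

    def _entropy_nats(self, key: tuple) -> float:  # pragma: no cover - abstract
        raise NotImplementedError


class ExactBackend(EntropyBackend):
    """Analytic entropies by direct marginalization of a probability table."""

    kind = "exact"

    def __init__(self, table: JointTable, units: str = "nats"):
        super().__init__(table.names, units=units)
        self.table = table

    def _entropy_nats(self, key: tuple) -> float:
        p = self.table.marginal(key).ravel()
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))


class PluginBackend(EntropyBackend):
    """Plug-in (maximum-likelihood) entropies from empirical outcome frequencies.

    No small-sample correction is applied: on exhaustively enumerated gate
    samples the estimate is exact, while on short random samples it carries
    the usual downward plug-in bias.
    """

    kind = "plugin"

    def __init__(self, panel: Panel, units: str = "nats"):
        if panel.kind != "discrete":
            raise ContractError("plugin backend requires a discrete panel")
        super().__init__(panel.names, units=units)
        self._data = panel.values.astype(np.int64)
        self._T = panel.n_samples

    def _entropy_nats(self, key: tuple) -> float:
        _, counts = np.unique(self._data[:, key], axis=0, return_counts=True)
        p = counts / self._T
        return float(-np.sum(p * np.log(p)))


class CopulaBackend(EntropyBackend):
    """Gaussian-copula entropies from a continuous sample panel.

    The panel is copula-transformed once; a subset's entropy is the Gaussian
    closed form of the empirical covariance (unbiased, T-1 denominator) of the
    transformed columns, optionally minus the finite-sample bias of the
    log-determinant (digamma correction). Margins are standard normal by
    construction, so differences of these entropies estimate the mutual
    informations and O-information of the underlying copula.
    """

    kind = "copula"
    dual_route_tol = 1e-7

    def __init__(self, panel: Panel, bias_correction: bool = True,
                 units: str = "nats", pretransformed: bool = False):
        if panel.kind != "continuous":
            raise ContractError("copula backend requires a continuous panel")
        super().__init__(panel.names, units=units)
        z = panel.values if pretransformed else copula_transform(panel).values
        self._T = panel.n_samples
        self._cov = np.cov(z, rowvar=False, ddof=1).reshape(panel.n_vars, panel.n_vars)
        self.bias_correction = bool(bias_correction)

    def _entropy_nats(self, key: tuple) -> float:
        k = len(key)
        sub = self._cov[np.ix_(key, key)]
        d = np.sqrt(np.diag(sub))
        corr = sub / np.outer(d, d)
        if np.min(linalg.eigvalsh(corr)) < _EIG_TOL:
            raise DegenerateInputError(
                f"near-singular correlation matrix for subset {tuple(np.array(key) + 1)}")
        h = entropy_from_covariance(sub)
        if self.bias_correction:
            T = self._T
            psiterms = special.psi((T - np.arange(1, k + 1)) / 2.0) / 2.0
            h -= k * (_LN2 - np.log(T - 1.0)) / 2.0 + psiterms.sum()
        return float(h)


def make_backend(source, estimator: str | None = None, units: str = "nats",
                 bias_correction: bool = True) -> EntropyBackend:
    """Build the appropriate backend for a JointTable or Panel.

    ``estimator`` may force one of {"exact", "plugin", "copula"}; by default
    it is inferred from the source type and panel kind.
    """
    if isinstance(source, JointTable):
        if estimator not in (None, "exact"):
            raise ContractError(f"estimator {estimator!r} incompatible with a JointTable")
        return ExactBackend(source, units=units)
    if isinstance(source, Panel):
        if estimator is None:
            estimator = "plugin" if source.kind == "discrete" else "copula"
        if estimator == "plugin":
            return PluginBackend(source, units=units)
        if estimator == "copula":
            return CopulaBackend(source, bias_correction=bias_correction, units=units)
        raise ContractError(f"unknown estimator {estimator!r} for a Panel")
    raise ContractError(f"cannot build a backend from {type(source).__name__}")


def joint_entropy(backend: EntropyBackend, subset=None) -> float:
    """Joint entropy of a subset under the backend, in the backend's units."""
    return backend.entropy(subset)


def mutual_information(backend: EntropyBackend, a, b) -> float:
    """I(A; B) = H(A) + H(B) - H(A,B) for disjoint nonempty subsets."""
    ka, kb = backend.resolve(a), backend.resolve(b)
    if not ka or not kb:
        raise ContractError("mutual information needs two nonempty subsets")
    if set(ka) & set(kb):
        raise ContractError(f"subsets overlap: {set(ka) & set(kb)}")
    joint = tuple(sorted(ka + kb))
    h = backend.entropy_nats_key
    return backend._convert(h(ka) + h(kb) - h(joint))
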