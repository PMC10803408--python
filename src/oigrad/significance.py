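"""Statistical significance of gradients: cohort percentiles and bootstrap.

Two decision procedures, both built on one percentile sign rule — a gradient
is significantly redundant when the low percentile (default 5th) of its
sampling distribution lies above zero, significantly synergistic when the
high percentile (default 95th) lies below zero, and not significant
otherwise:

* **Cohort test** — the distribution is the empirical spread of the gradient
  across the records (subjects) of a study; deterministic given the values.
* **Bootstrap test** — the distribution is generated per record by
  resampling time indices with replacement (iid by default, or circular
  blocks of a given length for serially-correlated data) and recomputing the
  gradient on each resample with the Gaussian-copula estimator.

Percentiles use linear interpolation between closest ranks. No
multiple-comparison correction is applied by default; a Benjamini-Hochberg
gate over a family of cohort tests is available for users who want one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DegenerateInputError, InsufficientDataError
from .estimators import CopulaBackend, resolve_subset
from .gradients import gradient_k
from .panel import Panel

__all__ = ["SignificanceDecision", "cohort_test", "bootstrap_test",
           "cohort_fraction", "benjamini_hochberg"]

LABELS = ("redundant", "synergistic", "not_significant")


@dataclass(frozen=True)
class SignificanceDecision:
    """Outcome of a percentile sign test for one multiplet."""

    label: str
    low_percentile: float
    high_percentile: float
    percentiles: tuple
    n_resamples: int
    multiplet: tuple = None
    names: tuple = None

    def __post_init__(self):
        if self.label not in LABELS:
            raise ContractError(f"unknown label {self.label!r}")
        if self.low_percentile > self.high_percentile:
            raise ContractError("low percentile exceeds high percentile")


def _decide(values, percentiles, n, multiplet=None, names=None) -> SignificanceDecision:
    lo, hi = np.percentile(values, percentiles, method="linear")
    if lo > 0:
        label = "redundant"
    elif hi < 0:
        label = "synergistic"
    else:
        label = "not_significant"
    return SignificanceDecision(label=label, low_percentile=float(lo),
                                high_percentile=float(hi),
                                percentiles=tuple(percentiles), n_resamples=n,
                                multiplet=multiplet, names=names)


def cohort_test(values, percentiles=(5, 95), multiplet=None, names=None) -> SignificanceDecision:
    """Percentile sign test on a gradient's across-record distribution.

    ``values`` are one gradient value per record; at least 3 records are
    required. Deterministic given the values.
    """
    values = np.asarray([float(v) for v in values], dtype=float)
    if values.size < 3:
        raise InsufficientDataError(
            f"cohort test needs >= 3 records, got {values.size}")
    lo, hi = percentiles
    if not 0 <= lo < hi <= 100:
        raise ContractError("percentiles must satisfy 0 <= low < high <= 100")
    return _decide(values, percentiles, values.size, multiplet, names)


def bootstrap_test(panel: Panel, multiplet, n_boot: int = 1000, seed=None,
                   block_length: int | None = None, percentiles=(5, 95),
                   bias_correction: bool = True,
                   return_samples: bool = False):
    """Bootstrap percentile sign test of one multiplet's gradient for one record.

    Time indices are resampled with replacement (``block_length`` switches to
    a circular block bootstrap), the copula-estimated gradient of ``multiplet``
    is recomputed per resample, and the percentile sign rule is applied.
    Resamples with a degenerate (near-singular) covariance are redrawn, up to
    10 x ``n_boot`` attempts. Fully reproducible under a fixed seed.
    """
    if panel.n_samples < 50:
        raise InsufficientDataError("bootstrap needs at least 50 time samples")
    if n_boot < 100:
        raise ContractError("n_boot must be >= 100 for stable tail percentiles")
    if block_length is not None and not 1 <= block_length <= panel.n_samples:
        raise ContractError("block_length must lie in [1, T]")
    rng = np.random.default_rng(seed)
    T = panel.n_samples
    gamma_key = resolve_subset(multiplet, panel.names)
    values = np.empty(n_boot)
    attempts = 0
    done = 0
    while done < n_boot:
        if attempts >= 10 * n_boot:
            raise DegenerateInputError(
                "too many degenerate bootstrap resamples; data may be rank-deficient")
        attempts += 1
        idx = _resample_indices(rng, T, block_length)
        try:
            backend = CopulaBackend(
                Panel(panel.values[idx], panel.names, kind="continuous"),
                bias_correction=bias_correction)
            values[done] = gradient_k(
                backend, tuple(i + 1 for i in gamma_key)).value
        except DegenerateInputError:
            continue
        done += 1
    decision = _decide(values, percentiles, n_boot,
                       multiplet=tuple(i + 1 for i in gamma_key),
                       names=tuple(panel.names[i] for i in gamma_key))
    return (decision, values) if return_samples else decision


def _resample_indices(rng, T, block_length):
    if block_length is None:
        return rng.integers(0, T, size=T)
    n_blocks = -(-T // block_length)
    starts = rng.integers(0, T, size=n_blocks)
    idx = (starts[:, None] + np.arange(block_length)[None, :]) % T
    return idx.ravel()[:T]


def cohort_fraction(decisions) -> dict:
    """Proportion of records carrying each significance label.

    Supports "significant in more than 50% of subjects" summaries; a label is
    cohort-level notable when its fraction exceeds 0.5 strictly.
    """
    decisions = list(decisions)
    if not decisions:
        raise InsufficientDataError("need at least one decision")
    n = len(decisions)
    return {lab: sum(d.label == lab for d in decisions) / n for lab in LABELS}


def benjamini_hochberg(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Boolean rejection mask controlling the false discovery rate at alpha."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.flatnonzero(passed))
        reject[order[:kmax + 1]] = True
    return reject
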