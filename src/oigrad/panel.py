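"""Core data containers: multivariate sample panels and exact joint probability tables.

A :class:`Panel` holds one record's multivariate time series (T samples of n
named variables); a :class:`JointTable` holds an exact probability mass
function over an enumerated finite alphabet and serves as the ground-truth
backend for small discrete systems such as logic gates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Panel", "JointTable", "read_panel", "write_panel",
           "read_joint_table", "write_joint_table"]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class Panel:
    """A named multivariate sample matrix for one record/subject.

    Parameters
    ----------
    values : ndarray, shape (T, n)
        Rows are time samples, columns are variables.
    names : tuple of str
        Unique variable labels, one per column.
    kind : {"continuous", "discrete"}
        Discrete panels must contain integer-valued entries drawn from a
        finite alphabet.
    """

    values: np.ndarray
    names: tuple
    kind: str = "continuous"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("panel values must be a 2-D matrix (T samples x n variables)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(str(s) for s in self.names))
        T, n = values.shape
        if n < 1:
            raise ValueError("panel needs at least one variable")
        if T < 2:
            raise ValueError("panel needs at least two time samples")
        if len(self.names) != n:
            raise ValueError(f"{len(self.names)} names for {n} columns")
        if len(set(self.names)) != n:
            raise ValueError("variable names must be unique")
        if self.kind not in ("continuous", "discrete"):
            raise ValueError(f"unknown panel kind {self.kind!r}")
        if not np.all(np.isfinite(values)):
            raise ValueError("panel contains missing or non-finite values")
        if self.kind == "discrete" and not np.array_equal(values, np.round(values)):
            raise ValueError("discrete panel entries must be integers")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))


@dataclass(frozen=True)
class JointTable:
    """Exact probability mass over the product of finite alphabets.

    ``probabilities`` has one axis per variable with lengths
    ``alphabet_sizes``; entry ``[a1, ..., an]`` is P(X_1=a1, ..., X_n=an).
    """

    probabilities: np.ndarray
    names: tuple = field(default=None)

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim < 1:
            raise ValueError("probability table needs at least one variable axis")
        if np.any(p < -_PROB_TOL):
            raise ValueError("negative probability mass")
        total = float(p.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probability mass sums to {total}, not 1")
        names = self.names
        if names is None:
            names = tuple(f"X{i}" for i in range(1, p.ndim + 1))
        object.__setattr__(self, "names", tuple(str(s) for s in names))
        if len(self.names) != p.ndim:
            raise ValueError("one name per variable axis required")

    @property
    def n_vars(self) -> int:
        return self.probabilities.ndim

    @property
    def alphabet_sizes(self) -> tuple:
        return self.probabilities.shape

    @property
    def max_alphabet(self) -> int:
        """Cardinality of the largest single-variable alphabet, |X|."""
        return max(self.probabilities.shape)

    def marginal(self, axes_to_keep) -> np.ndarray:
        """Marginal mass over the given (0-based) variable axes."""
        keep = tuple(sorted(axes_to_keep))
        drop = tuple(i for i in range(self.n_vars) if i not in keep)
        return self.probabilities.sum(axis=drop) if drop else self.probabilities


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_panel(path, kind: str = "continuous", delimiter: str | None = None) -> Panel:
    """Load a delimited-text panel: header row of names, one row per sample."""
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad} of {path}")
    return Panel(df.to_numpy(dtype=float), tuple(df.columns), kind=kind)


def write_panel(panel: Panel, path, delimiter: str = "\t") -> None:
    panel.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def write_joint_table(table: JointTable, path, delimiter: str = "\t") -> None:
    """One outcome tuple per row plus a probability column, 17 significant digits."""
    rows = []
    for outcome in itertools.product(*(range(k) for k in table.alphabet_sizes)):
        rows.append((*outcome, table.probabilities[outcome]))
    df = pd.DataFrame(rows, columns=[*table.names, "probability"])
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_joint_table(path, delimiter: str | None = None) -> JointTable:
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "probability" not in df.columns:
        raise ValueError("joint-table file needs a 'probability' column")
    names = [c for c in df.columns if c != "probability"]
    outcomes = df[names].to_numpy(dtype=int)
    sizes = tuple(outcomes.max(axis=0) + 1)
    if len(df) != int(np.prod(sizes)):
        raise ValueError("joint-table file must enumerate every outcome tuple")
    p = np.zeros(sizes)
    p[tuple(outcomes.T)] = df["probability"].to_numpy()
    return JointTable(p, names=tuple(names))
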