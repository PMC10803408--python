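"""End-to-end workflows: configured multiplet scans and gate demos.

`run_scan` ties the modules together the way the two study designs use
them: load (or synthesize) a cohort of panels, precondition the series,
compute all requested gradient orders per record with the configured entropy
estimator, apply a significance procedure (per-record bootstrap or
across-record cohort percentiles), and write one tidy TSV plus a run-log
that suffices to reproduce the run.
"""

from __future__ import annotations

import itertools
import sys
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .errors import ContractError
from .estimators import make_backend
from .gradients import first_order_bounds, gradient_k, scan_multiplets
from .measures import o_information
from .panel import read_panel, write_panel
from .significance import bootstrap_test, cohort_fraction, cohort_test
from .synthetic import CohortSpec, GateSpec, gate_table, gaussian_cohort, preprocess

__all__ = ["RunConfig", "run_scan", "run_gate_demo", "read_results",
           "write_cohort"]

RESULT_COLUMNS = ["record_id", "multiplet", "order", "value", "units",
                  "estimator", "n", "label", "pct_low", "pct_high",
                  "n_boot", "seed"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a scan.

    Exactly one of ``inputs`` (panel file paths) or ``cohort`` (synthetic
    design) supplies the data. ``orders`` lists the gradient orders to scan;
    each must be <= n - 2 for the panel width n.
    """

    inputs: tuple = ()
    cohort: CohortSpec | None = None
    orders: tuple = (1,)
    estimator: str = "copula"
    units: str = "bits"
    significance: str = "none"
    n_boot: int = 1000
    percentiles: tuple = (5.0, 95.0)
    block_length: int | None = None
    highpass: bool = False
    zscore: bool = False
    bias_correction: bool = True
    seed: int | None = None
    output: str = "results.tsv"
    log: str | None = None

    def __post_init__(self):
        if bool(self.inputs) == (self.cohort is not None):
            raise ContractError("provide either input paths or a synthetic cohort spec")
        if self.significance not in ("none", "bootstrap", "cohort"):
            raise ContractError(f"unknown significance mode {self.significance!r}")
        if self.estimator not in ("plugin", "copula"):
            raise ContractError("scans run on sampled panels: estimator must be "
                                "'plugin' or 'copula'")
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "orders", tuple(int(o) for o in self.orders))
        object.__setattr__(self, "percentiles", tuple(float(p) for p in self.percentiles))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat ``key: value`` configuration file."""
        raw = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition(":")
                raw[key.strip()] = value.strip()
        kwargs = {}
        if "inputs" in raw:
            kwargs["inputs"] = tuple(p for p in raw.pop("inputs").split(",") if p)
        cohort_keys = {k: raw.pop(k) for k in list(raw)
                       if k.startswith("cohort.")}
        if cohort_keys:
            ck = {k.split(".", 1)[1]: v for k, v in cohort_keys.items()}
            kwargs["cohort"] = CohortSpec(
                n_records=int(ck["n_records"]), n_vars=int(ck["n_vars"]),
                T=int(ck["T"]), structure=ck.get("structure", "independent"),
                loading=float(ck.get("loading", 0.9)),
                noise_sd=float(ck.get("noise_sd", 0.1)),
                seed=int(ck["seed"]) if "seed" in ck else None)
        casts = {"orders": lambda v: tuple(int(x) for x in v.split(",")),
                 "percentiles": lambda v: tuple(float(x) for x in v.split(",")),
                 "n_boot": int, "seed": int, "block_length": int,
                 "highpass": _parse_bool, "zscore": _parse_bool,
                 "bias_correction": _parse_bool}
        for key, value in raw.items():
            kwargs[key] = casts.get(key, str)(value)
        return cls(**kwargs)

    def to_text(self) -> str:
        lines = []
        if self.inputs:
            lines.append("inputs: " + ",".join(str(p) for p in self.inputs))
        if self.cohort is not None:
            c = self.cohort
            lines += [f"cohort.n_records: {c.n_records}", f"cohort.n_vars: {c.n_vars}",
                      f"cohort.T: {c.T}", f"cohort.structure: {c.structure}",
                      f"cohort.loading: {c.loading}", f"cohort.noise_sd: {c.noise_sd}"]
            if c.seed is not None:
                lines.append(f"cohort.seed: {c.seed}")
        lines += [f"orders: {','.join(map(str, self.orders))}",
                  f"estimator: {self.estimator}", f"units: {self.units}",
                  f"significance: {self.significance}", f"n_boot: {self.n_boot}",
                  f"percentiles: {','.join(map(str, self.percentiles))}",
                  f"highpass: {self.highpass}", f"zscore: {self.zscore}",
                  f"bias_correction: {self.bias_correction}",
                  f"output: {self.output}"]
        if self.block_length is not None:
            lines.append(f"block_length: {self.block_length}")
        if self.seed is not None:
            lines.append(f"seed: {self.seed}")
        return "\n".join(lines) + "\n"


def _parse_bool(v: str) -> bool:
    if v.lower() in ("true", "1", "yes"):
        return True
    if v.lower() in ("false", "0", "no"):
        return False
    raise ContractError(f"cannot parse boolean {v!r}")


def _load_records(config: RunConfig):
    if config.cohort is not None:
        panels = gaussian_cohort(config.cohort)
        return [(f"record{i + 1}", p) for i, p in enumerate(panels)]
    kind = "discrete" if config.estimator == "plugin" else "continuous"
    return [(str(path), read_panel(path, kind=kind)) for path in config.inputs]


def run_scan(config: RunConfig) -> pd.DataFrame:
    """Execute the configured scan; write the tidy TSV (and run-log) and
    return the result table."""
    t0 = time.perf_counter()
    records = _load_records(config)
    n_vars = records[0][1].n_vars
    for order in config.orders:
        if not 1 <= order <= n_vars - 2:
            raise ContractError(
                f"order {order} out of range [1, {n_vars - 2}] for {n_vars} variables")

    root_seed = np.random.SeedSequence(config.seed)
    record_seeds = root_seed.spawn(len(records))
    rows = []
    per_multiplet_values: dict = {}

    for (record_id, panel), rec_seed in zip(records, record_seeds):
        if panel.kind == "continuous" and (config.highpass or config.zscore):
            panel = preprocess(panel, highpass=config.highpass, zscore=config.zscore)
        backend = make_backend(panel, estimator=config.estimator,
                               units=config.units,
                               bias_correction=config.bias_correction)
        boot_seeds = iter(rec_seed.spawn(
            sum(len(list(itertools.combinations(range(n_vars), o)))
                for o in config.orders)))
        for order in config.orders:
            for res in scan_multiplets(backend, order):
                row = {"record_id": record_id,
                       "multiplet": ";".join(res.names),
                       "order": res.order, "value": res.value,
                       "units": res.units, "estimator": res.estimator,
                       "n": res.n, "label": "", "pct_low": np.nan,
                       "pct_high": np.nan, "n_boot": 0,
                       "seed": -1 if config.seed is None else config.seed}
                if config.significance == "bootstrap":
                    decision = bootstrap_test(
                        panel, res.names, n_boot=config.n_boot,
                        seed=next(boot_seeds),
                        block_length=config.block_length,
                        percentiles=config.percentiles,
                        bias_correction=config.bias_correction)
                    scale = 1.0 if config.units == "nats" else 1.0 / np.log(2)
                    row.update(label=decision.label,
                               pct_low=decision.low_percentile * scale,
                               pct_high=decision.high_percentile * scale,
                               n_boot=config.n_boot)
                per_multiplet_values.setdefault(
                    (order, ";".join(res.names)), []).append(res.value)
                rows.append(row)

    if config.significance == "cohort":
        for (order, multiplet), values in per_multiplet_values.items():
            decision = cohort_test(values, percentiles=config.percentiles)
            rows.append({"record_id": "cohort", "multiplet": multiplet,
                         "order": order, "value": float(np.mean(values)),
                         "units": config.units, "estimator": config.estimator,
                         "n": n_vars, "label": decision.label,
                         "pct_low": decision.low_percentile,
                         "pct_high": decision.high_percentile,
                         "n_boot": len(values),
                         "seed": -1 if config.seed is None else config.seed})

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    table.to_csv(config.output, sep="\t", index=False, float_format="%.17g")
    if config.log:
        _write_log(config, t0, len(records))
    return table


def _write_log(config: RunConfig, t0: float, n_records: int) -> None:
    with open(config.log, "w") as fh:
        fh.write("# oigrad run log\n")
        fh.write(f"version: {__version__}\n")
        fh.write(f"numpy: {np.__version__}\npandas: {pd.__version__}\n")
        fh.write(f"python: {sys.version.split()[0]}\n")
        fh.write(f"records: {n_records}\n")
        fh.write(f"wall_seconds: {time.perf_counter() - t0:.3f}\n")
        fh.write("# configuration (reusable as a config file)\n")
        fh.write(config.to_text())


def read_results(path) -> pd.DataFrame:
    """Re-read a tidy result TSV with full numeric precision."""
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""],
                       float_precision="round_trip",
                       dtype={"multiplet": str, "label": str})


def run_gate_demo(kind: str, n: int, alphabet: int = 2, units: str = "bits",
                  file=None) -> dict:
    """Print exact O-information, all order-1 and order-2 gradients, and the
    first-order gradient bounds for an n-variable gate; return them too."""
    if not 3 <= n <= 12:
        raise ContractError("gate demo supports n in [3, 12]")
    file = file or sys.stdout
    table = gate_table(GateSpec(kind=kind, n=n, alphabet=alphabet))
    backend = make_backend(table, units=units)
    omega = o_information(backend)
    g1 = scan_multiplets(backend, 1)
    g2 = scan_multiplets(backend, 2) if n >= 4 else []
    lo, hi = first_order_bounds(n, alphabet, units=units)

    print(f"{kind.upper()} gate, n={n}, alphabet={alphabet} ({units})", file=file)
    print(f"  O-information Omega = {omega.value:+.6f}", file=file)
    print(f"  order-1 gradient bounds: [{lo:+.6f}, {hi:+.6f}]", file=file)
    for r in g1:
        print(f"  d Omega / d {r.names[0]:<4s} = {r.value:+.6f}  ({r.character})",
              file=file)
    for r in g2:
        pair = ",".join(r.names)
        print(f"  d2 Omega / d({pair}) = {r.value:+.6f}  ({r.character})", file=file)
    return {"omega": omega.value, "order1": g1, "order2": g2, "bounds": (lo, hi)}


def write_cohort(panels, directory, spec: CohortSpec | None = None,
                 prefix: str = "record") -> pd.DataFrame:
    """Write one delimited-text panel per record plus a manifest TSV."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, panel in enumerate(panels, start=1):
        path = directory / f"{prefix}{i:03d}.tsv"
        write_panel(panel, path)
        rows.append({"record_id": f"{prefix}{i:03d}", "path": str(path),
                     "structure": spec.structure if spec else "unspecified",
                     "loading": spec.loading if spec else np.nan,
                     "noise_sd": spec.noise_sd if spec else np.nan,
                     "seed": spec.seed if spec and spec.seed is not None else -1,
                     "T": panel.n_samples, "n_vars": panel.n_vars})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return manifest
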