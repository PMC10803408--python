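# oigrad — gradients of O-information for multivariate time series

`oigrad` quantifies **higher-order statistical dependencies** — interactions
involving three or more variables at once — in multivariate data such as
multi-channel physiological recordings (fMRI network time series,
beat-to-beat cardiovascular variability), and localizes them on individual
variables, pairs, and general multiplets. It is aimed at researchers in
network physiology, neuroimaging and complex-systems analysis who need to
ask not just *whether* a system is redundancy- or synergy-dominated, but
*which* variables and groups carry that character.

## The measures

For a system **X**ⁿ = {X₁, …, Xₙ} with Shannon entropy H:

- **Total correlation** TC(**X**ⁿ) = Σᵢ H(Xᵢ) − H(**X**ⁿ) — the collective
  constraints among the variables.
- **Dual total correlation** DTC(**X**ⁿ) = H(**X**ⁿ) − Σᵢ H(Xᵢ | **X**ⁿ₋ᵢ)
  — the shared randomness.
- **O-information** Ω(**X**ⁿ) = TC − DTC
  = (n−2) H(**X**ⁿ) + Σᵢ [H(Xᵢ) − H(**X**ⁿ₋ᵢ)].
  Ω > 0: redundancy-dominated; Ω < 0: synergy-dominated.
- **Gradients of O-information** localize this balance. First order:
  ∂ᵢΩ = Ω(**X**ⁿ) − Ω(**X**ⁿ₋ᵢ), the change when Xᵢ joins the rest; second
  order: ∂²ᵢⱼΩ = ∂ᵢΩ(**X**ⁿ) − ∂ᵢΩ(**X**ⁿ₋ⱼ), symmetric in (i, j); and in
  general, for a multiplet γ, the inclusion–exclusion chain rule
  ∂γΩ = Σ_{α⊆γ} (−1)^{|α|} Ω(**X**ⁿ₋α) — the irreducible contribution of γ.
  First-order gradients obey the tight bounds
  −(n−2) log|X| ≤ ∂ᵢΩ ≤ log|X|; the binary n-XOR gate attains the lower
  bound and the n-COPY gate the upper one.

Entropies come from interchangeable backends: **exact** (an enumerated
probability table), **plug-in** (empirical frequencies of discrete samples),
or **Gaussian copula** (continuous data rank-transformed to standard-normal
quantiles, then the Gaussian closed form on the empirical covariance, with
an optional finite-sample bias correction). Significance is assessed with
two percentile sign tests: a per-record **bootstrap** (resample time points,
recompute, check whether the 5th/95th percentile band excludes zero) and an
across-record **cohort test** on the distribution over subjects.

## Worked example

```python
from oigrad import run_gate_demo
run_gate_demo("xor", 5)
```

prints

```
XOR gate, n=5, alphabet=2 (bits)
  O-information Omega = -3.000000
  order-1 gradient bounds: [-3.000000, +1.000000]
  d Omega / d X1   = -3.000000  (synergistic)
  ...
  d2 Omega / d(X1,X2) = -3.000000  (synergistic)
  ...
```

The 5-XOR gate's Ω is 2−n = −3 bits (synergy-dominated); every variable's
first-order gradient sits exactly on the lower bound −(n−2) log 2 = −3 bits,
and every pair contributes an irreducible (2−n) log 2 = −3 bits of synergy —
whereas for the COPY gate the same demo prints first-order gradients of
+1 bit (the upper bound) and second-order gradients of exactly 0.

On continuous data (`examples/cohort_scan.py`): a 30-record cohort of
7-variable Gaussian panels with a planted common-latent triplet (X1–X3) and
a noisy sum-node triplet (X4–X6) yields

```
  X1: mean +0.425, 5-95 pct [+0.405, +0.461] -> redundant
  X4: mean -1.775, 5-95 pct [-1.829, -1.717] -> synergistic
  X7: mean -0.001, 5-95 pct [-0.004, +0.001] -> not_significant
  third-order gradient of (X4,X5,X6): mean -1.775 -> synergistic
```

recovering the planted redundant and synergistic motifs and leaving the
independent channel unlabelled.

More narrative walk-throughs live in `examples/` (gate analytics, copula
estimation against closed-form population values, single-record bootstrap
significance, cohort scans), and a thin CLI exposes the same workflows:
`oigrad gates xor 5`, `oigrad synth ...`, `oigrad scan ...`.

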