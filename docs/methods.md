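# Methods

## Measures and their computation

All quantities are linear combinations of joint entropies H(S) of variable
subsets S, supplied by a backend and memoized per sorted index tuple (a
k-th-order gradient touches 2^k O-information terms, each touching O(n)
entropies, with heavy overlap). Internally every entropy is held in nats;
conversion to bits happens once, on output, controlled by the backend's
`units` flag. Subsets are addressed with 1-based positions or variable
names, matching the X_1 … X_n convention of the field.

The O-information is computed by the direct formula
Ω(S) = (m−2) H(S) + Σ_{i∈S} [H(X_i) − H(S∖i)] and, on every call, checked
against the TC − DTC route (tolerance 1e-10 for exact/plug-in backends,
1e-8 for the copula backend); since both routes draw on the same entropy
cache the check costs nothing and guards the index bookkeeping. Subsets of
size one or two return Ω = 0 identically; they are allowed rather than
rejected because chain-rule expansions reach them.

First-order gradients are the difference ∂_iΩ = Ω(S) − Ω(S∖i) and are
cross-checked against the mutual-information expansion

    ∂_iΩ = (2−m) I(X_i; S₋ᵢ) + Σ_{k≠i} I(X_i; S₋ᵢₖ),

which follows by substituting H(X_i|·) identities into the definition. (A
common typesetting of this identity puts X_k as the first argument of the
summed mutual informations; the two readings coincide on permutation-
symmetric systems such as the XOR and COPY gates, but only the form above
is an identity in general — easily confirmed by brute force on a gate with
an extra independent bit.) Second-order gradients are evaluated as
∂_iΩ(S) − ∂_iΩ(S∖j) and asserted equal to both the (i↔j)-swapped
computation and the whole-minus-sum expansion
[Ω(S)−Ω(S∖ij)] − [Ω(S∖i)−Ω(S∖ij)] − [Ω(S∖j)−Ω(S∖ij)]. General orders use
the inclusion–exclusion chain rule over all subsets of the multiplet.

**Minimum system size.** An order-k gradient is only defined here for
systems with at least k+2 variables, so that no Ω term in the expansion is
evaluated on fewer than two variables. Ω on one or two variables is zero by
construction, and admitting such terms silently would make low-n gradients
look meaningful when they are vacuous.

Multiplet scans enumerate subsets in lexicographic order on sorted indices,
so outputs are reproducible byte for byte. Sign convention throughout:
positive = redundant, negative = synergistic.

## Entropy backends

**Exact.** Marginalize an enumerated probability table and sum −p log p.
Used for the gate benchmarks and for property tests against brute-force
enumeration.

**Plug-in.** Empirical outcome frequencies of a discrete sample panel, no
small-sample correction. On exhaustively enumerated gate samples (each
support outcome exactly T/|support| times) the estimate equals the exact
value, which is the property the tests exploit; on short random samples it
carries the usual downward plug-in bias, documented and untested-for.

**Gaussian copula.** Each column is rank-transformed with average ranks on
ties and mapped through Φ⁻¹(r/(T+1)) — the T+1 denominator keeps ties and
extremes finite — then a subset's entropy is ½ ln((2πe)^k det Σ̂) with the
unbiased (T−1) covariance of the transformed columns. This estimates the
dependence-carrying part of the joint entropy; because margins are standard
normal by construction, differences of such entropies (MI, TC, DTC, Ω,
gradients) estimate the corresponding copula quantities. A finite-sample
bias correction for the log-determinant (digamma terms,
−k(ln2 − ln(T−1))/2 − Σᵢ ψ((T−i)/2)/2) is applied by default and can be
switched off; the underlying estimator family admits both options and the
uncorrected variant is useful when comparing against hand-computed
covariance entropies. Correlation submatrices with an eigenvalue below
1e-10 are rejected as degenerate rather than silently inverted.

The copula estimator is exact in distribution only for data whose copula is
Gaussian; for monotone transforms of Gaussian panels it is invariant by
construction (a property test applies strictly monotone reparametrizations
and asserts identical transforms). For genuinely non-Gaussian copulas it is
a dependence-favoring approximation, as elsewhere in this literature.

## Significance testing

Both procedures reduce to one percentile sign rule: significant redundancy
when the low percentile (default 5th) of a gradient's distribution exceeds
zero, significant synergy when the high percentile (default 95th) is below
zero. Percentiles use linear interpolation between closest ranks — the
common default, fixed here because nothing in the procedure pins it down.

**Cohort test.** The distribution is the spread of the per-record gradient
across a study's records; deterministic, requires at least 3 records. The
"significant in more than half the subjects" summary provided by
`cohort_fraction` uses a strict > 0.5 threshold.

**Bootstrap test.** Per record, time indices are resampled with replacement
and the copula-estimated gradient recomputed per resample (default 1000).
Resampling is iid by default: the intended inputs are high-pass filtered,
whitening the slow structure that would otherwise demand a block scheme; a
circular block bootstrap (contiguous wrapped blocks of a chosen length) is
available for serially correlated data. Degenerate resamples (singular
covariance) are redrawn, capped at 10× the requested count. All resampling
derives from one seed and is bit-for-bit reproducible.

No multiple-comparison correction is applied by default, matching common
practice for these scan sizes (21 pairs / 35 triplets); a
Benjamini–Hochberg helper is provided for users who want an FDR gate over a
family of tests.

## Synthetic designs

The generator produces the structures the measures are meant to detect, not
realistic physiology (no hemodynamic response, no baroreflex loops):

- **Gates** as exact tables and as sampled panels, including the exhaustive
  mode above. XOR generalizes to |X|-ary alphabets as the sum mod |X|;
  COPY puts mass 1/|X| on each constant tuple.
- **common_latent**: X_i = a·Z + √(1−a²)·ε_i with loading a (default 0.9),
  giving an equicorrelated matrix with off-diagonal a² and population Ω > 0
  for n ≥ 3.
- **sum_node**: X_n = Σ_{i<n} X_i + σ·η with independent sources (default
  σ = 0.1), the standard continuous analogue of XOR, population Ω < 0.
- **mixed**: a common-latent motif on the first three variables and a
  sum-node motif on the next three, disjoint, remaining variables
  independent — used for end-to-end recovery runs.
- Default study sizes in the tests and acceptance script mirror the scales
  this kind of analysis runs at: 7-variable scans (7/21/35 multiplets),
  5-channel panels of 250 samples for single-record bootstrap work, cohorts
  of 13–100 records, convergence checks at T = 10,000.

All population covariances are closed-form, so the population Ω and
gradients are available analytically through the Gaussian entropy formula
for convergence and sign checks.

**Preprocessing.** The high-pass step subtracts a centered moving-average
baseline (window T/10, reflected edges). Only trend removal matters for the
downstream measures, so a filter family/cutoff was deliberately not
parameterized beyond the window; standardization then enforces exactly
zero mean and unit (population) variance per column.

## Numerical choices

- Probability tables must sum to 1 within 1e-9; negative mass below 1e-12
  is rejected.
- Dual-route assertions: 1e-10 relative-ish tolerance (scaled by max(1,|v|))
  for exact/plug-in backends, 1e-7 for the copula backend.
- Covariance positive-definiteness is established by Cholesky; failures
  raise a degenerate-input error naming the offending subset or column.
- Result TSVs are written with 17 significant digits and read back with a
  round-trip float parser, so write→read is bit-exact.
- Seeds: every stochastic operation takes a seed or SeedSequence; workflows
  spawn per-record and per-multiplet child seeds from one root so runs are
  reproducible and records are independent.

## What passing tests do and do not show

The synthetic cohorts have Gaussian copulas, stationary structure and (after
filtering) negligible serial correlation, so the recovery and calibration
results certify the estimator and the decision procedures under their
intended assumptions. They do not certify behavior under heavy tails,
nonstationarity, strong autocorrelation (use the block bootstrap), or
non-Gaussian copulas, and the plug-in backend's small-sample bias is
documented rather than corrected. Exhaustive search over multiplets is
combinatorial; no greedy search for extremal multiplets at large n is
attempted.
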