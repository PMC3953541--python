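# Methods

## The model

A molecule with elemental composition `C_v H_w N_x O_y S_z ...` has an
*aggregated* isotope distribution: the probability `q_j` that the molecule
carries `j` extra neutrons relative to its lightest (monoisotopic) variant,
summed over all isotopologues with the same nominal mass shift.  Formally,
`q_j` is the `j`-th coefficient of the generating polynomial

    Q(I) = prod_E ( P_{E,0} + P_{E,1} I + ... + P_{E,kmax} I^kmax )^count(E)

where `P_{E,k}` is the abundance of element `E`'s isotope with `k` extra
neutrons.  Expanding `Q` directly costs `O(n^2)` in the polynomial order
`n = sum count(E) * kmax(E)`; this package instead uses the Newton–Girard
identity linking polynomial coefficients to the power sums of polynomial
roots:

    q_j = -(1/j) * sum_{l=1}^{j} q_{j-l} * psi_l,
    psi_l = sum_E count(E) * r_{E,l},     r_{E,l} = sum_{roots rho} rho^{-l}.

Starting from the exact `q_0 = prod P_{E,0}^count(E)`, one recurrence step
per peak yields the distribution ("classic" mode, `brain_classic`).

## The two large-molecule refinements

* **Recurrence of constant length (RCL, `brain_rcl`).**  `|psi_l|` decays
  geometrically in `l` for elements whose dominant polynomial root lies
  outside the unit circle (true for C, H, N, O, S), so the summation can be
  trimmed to its most recent `d` terms once `j > d`.  Memory and per-peak
  work drop to `O(d)`.  With `d >= n_stop` the trimmed run takes bit-identical
  floating-point paths to the classic run.

* **Late starting point (LSP, `brain_lsp`).**  The recurrence is linear in
  its starting value, so ratios of consecutive peaks do not depend on it.
  To obtain the *relative* distribution on a window `[n_start, n_stop]`, the
  iteration starts at `n_start - b` with the arbitrary value 1, runs `b`
  burn-in steps to let the ratios converge, discards them, and normalizes
  the maximum reported peak to 1.  `n_start - b` may not be negative (the
  recurrence cannot start below the lightest variant).

* **Root omitting (RO, `power_sums_ro`).**  The `r_{E,l}` themselves satisfy
  a Newton–Girard recurrence in the element's abundance coefficients,
  extended through zero-abundance entries for "missing" isotopes (e.g.
  `35S`, odd-`k` platinum isotopes).  This avoids numerical root finding
  entirely and generalizes to elements of any degree.  It is the default
  route everywhere; explicit root extraction (`power_sums_closed`) is kept
  only as an independent cross-check in the test suite.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `n_stop` | last computed peak (classic) | `max(2*ceil(avg - mono), 5)`, capped at `n` | peak index (extra neutrons) |
| `d` | RCL summation memory | `ceil(log10(M) + 5)` | peaks |
| `b` | LSP burn-in steps | same rule as `d`; independently overridable | peaks |
| `alpha` | window-width multiplier | 10 | – |
| `N` | reported window width | `ceil(alpha * sqrt(1 + sigma^2))` | peaks |

`M` is the monoisotopic mass and `sigma^2` the mass variance, both computed
additively over atoms.  The `N`-peak window is centered on the round-half-up
integer offset `c = round(avg - mono)`; for even `N` the extra peak is
placed on the heavy side (the convention is otherwise arbitrary; it is fixed
here for reproducibility).  For the ~533 kDa dynein heavy chain these rules
give `n_stop = 664`, `b = d = 11`, `N = 193`, window `235..427`, which
captures more than 99.999 % of the total probability mass.

The defaults assume C/H/N/O/S-like isotope patterns.  Elements with
slowly decaying `|r_{E,l}|` (Cl, Br) need a larger `d`; elements whose
dominant root lies *inside* the unit circle make `r_{E,l}` diverge, and the
computation stops with an explicit `PowerSumOverflow` rather than returning
garbage.

## Numerical choices

* **Scaling.**  The classic iteration runs on values scaled by
  `exp(-log q_0)` (so the starting value is 1) with `log q_0` accumulated in
  log space; whenever intermediate values approach the double-precision
  ceiling the whole state is rescaled by an exact power of two (mantissas
  unchanged).  The true scale is restored on output.  If every output peak
  underflows double range, probability mode fails with an error that points
  to LSP mode.
* **Negative round-off.**  At distribution tails the recurrence can cross
  zero by ~1e-17; such values are clamped to 0 and counted
  (`AggregatedDistribution.n_clamped`), not raised as errors.
* **Gap zeros.**  A lone gap reached by a single multiplication (Pt, k = 1)
  is exactly 0; gaps reached through multi-term cancellation (S, j = 3)
  are zero only to ~1e-18 and are treated as such by the tests.
* **Chi-squared.**  Two distributions are compared on their mutually present
  peaks via `chi2 = sum (R_i^I - R_i^II)^2 / R_i^I` over consecutive-peak
  ratios `R_i = q_{i+1}/q_i`, with the first argument as reference (the
  statistic is asymmetric).  Pairs whose ratio is undefined or whose
  reference ratio is 0 are skipped and counted.

## The fixture generator

`brainiso.cli.generate_fixture` emulates protein-like test molecules using
the averagine composition (C 4.9384, H 7.7583, N 1.3577, O 1.4773,
S 0.0417 per 111.1254 Da): the template is scaled to the target
monoisotopic mass, counts are floored and the leftover atoms assigned by
largest remainder (a small seeded jitter breaks near-ties so different
seeds yield different formulas), every template element is kept at count
>= 1, and a final carbon-then-hydrogen adjustment lands the mass within
0.2 % of the target.  Generated formulas reproduce the statistical shape of
real proteins (elemental ratios, peak counts) but not their exact
compositions, post-translational modifications, or non-CHNOS content —
passing tests on them demonstrate algorithmic correctness, not biological
realism.

## Problem sizes used in tests

The oracle for correctness is explicit polynomial convolution
(`oracle_convolution`), tractable up to a configurable order cap (default
5000).  Solver-vs-oracle equivalence is checked on random CHNOS formulas of
up to 200 atoms; the full dynein computation (order 82 918, `n_stop = 664`)
runs in milliseconds and is exercised end to end by the acceptance tests.

## Known limitations

* Center masses of aggregated variants are not computed; the refinements
  here apply to the distribution only.
* No support for adducts, charge states, isotopic enrichment, or starting
  the recurrence from the heaviest variant.
* Double precision throughout: agreement between routes is ~1e-12 at best,
  and the reported chi-squared floor (~1e-14 for dynein at b = d = 11)
  reflects round-off, not model error.
* Results depend in the 4th significant digit on the isotope abundance
  table; the shipped NIST values can be overridden with a plain-text table.
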