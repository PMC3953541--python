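"""Brute-force ground truth and distribution comparison statistics.

:func:`oracle_convolution` expands the molecule's generating polynomial by
explicit discrete convolution of the element coefficient vectors — the
textbook route the iterative solvers exist to avoid.  It is exact (up to
round-off) and serves as the independent reference in tests.

:func:`chi2` is the Pearson chi-squared error statistic on consecutive-peak
ratios used to compare two computed distributions:

    chi2 = sum_i (R_i^I - R_i^II)^2 / R_i^I,   R_i = q_{i+1} / q_i

with distribution I (the first argument) as the reference.  Ratios are
scale-invariant, so probability-mode and max-one-mode distributions compare
directly.  The statistic is asymmetric in its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .brain_core import AggregatedDistribution
from .elements import IsotopeTable, MolecularFormula, polynomial_order

__all__ = ["ComparisonReport", "oracle_convolution", "chi2", "coverage"]

_DEFAULT_ORDER_CAP = 5000


@dataclass
class ComparisonReport:
    """Result of a two-distribution comparison on their mutual peak range."""

    chi2: float
    peak_range: tuple[int, int]  # mutual [first, last] extra-neutron index
    n_mutual: int  # count of mutually present peaks
    n_skipped: int  # ratio pairs dropped because of zero values
    coverage: float | None = None  # reference mass fraction inside the range

    def to_text(self) -> str:
        lines = [
            f"chi2\t{self.chi2:.12g}",
            f"peak_range\t{self.peak_range[0]}..{self.peak_range[1]}",
            f"n_mutual\t{self.n_mutual}",
            f"n_skipped\t{self.n_skipped}",
        ]
        if self.coverage is not None:
            lines.append(f"coverage\t{self.coverage:.12g}")
        return "\n".join(lines)


def oracle_convolution(formula: MolecularFormula, table: IsotopeTable | None = None,
                       n_stop: int | None = None,
                       order_cap: int = _DEFAULT_ORDER_CAP) -> AggregatedDistribution:
    """Exact aggregated distribution by iterated polynomial multiplication.

    Each element's coefficient vector is raised to its atom count by
    repeated squaring (binary exponentiation over convolution), then the
    per-element results are convolved together.  Truncation to ``n_stop``
    happens only after the full expansion.
    """
    if table is None:
        table = IsotopeTable.default()
    n = polynomial_order(formula, table)
    if n > order_cap:
        raise ValueError(f"polynomial order {n} exceeds the oracle cap {order_cap}")
    acc = np.array([1.0])
    for sym, count in formula.items():
        base = np.asarray(table.abundances(sym), dtype=float)
        acc = np.convolve(acc, _convolve_power(base, count))
    if n_stop is not None:
        acc = acc[:n_stop + 1]
    return AggregatedDistribution(0, acc, "probability")


def _convolve_power(vec: np.ndarray, count: int) -> np.ndarray:
    out = np.array([1.0])
    sq = vec
    while count:
        if count & 1:
            out = np.convolve(out, sq)
        count >>= 1
        if count:
            sq = np.convolve(sq, sq)
    return out


def chi2(reference: AggregatedDistribution,
         other: AggregatedDistribution) -> ComparisonReport:
    """Pearson chi-squared on consecutive-peak ratios over mutual peaks.

    Only pairs (i, i+1) with both members inside both distributions enter the
    sum.  Pairs where either distribution has q_i = 0, or where the reference
    ratio is 0, are skipped and counted in ``n_skipped`` (they would produce
    undefined or infinite ratios).
    """
    lo = max(reference.start_index, other.start_index)
    hi = min(reference.stop_index, other.stop_index)
    n_mutual = max(0, hi - lo + 1)
    if n_mutual < 2:
        raise ValueError("need at least 2 mutually present peaks to compare")
    a = reference.values[lo - reference.start_index: hi - reference.start_index + 1]
    b = other.values[lo - other.start_index: hi - other.start_index + 1]
    total = 0.0
    skipped = 0
    for i in range(n_mutual - 1):
        if a[i] == 0.0 or b[i] == 0.0:
            skipped += 1
            continue
        ra = a[i + 1] / a[i]
        rb = b[i + 1] / b[i]
        if ra == 0.0:
            skipped += 1
            continue
        total += (ra - rb) ** 2 / ra
    cov = None
    if reference.mode == "probability":
        denom = reference.values.sum()
        if denom > 0:
            cov = float(a.sum() / denom)
    return ComparisonReport(chi2=total, peak_range=(lo, hi), n_mutual=n_mutual,
                            n_skipped=skipped, coverage=cov)


def coverage(dist: AggregatedDistribution, window: tuple[int, int]) -> float:
    """Fraction of the distribution's total mass inside [n_start, n_stop].

    Requires probability mode; the denominator is the mass over the full
    computed range, so enlarging the window can only increase coverage.
    """
    if dist.mode != "probability":
        raise ValueError("coverage requires a probability-mode distribution")
    n_start, n_stop = window
    lo = max(n_start, dist.start_index)
    hi = min(n_stop, dist.stop_index)
    if hi < lo:
        raise ValueError("window does not overlap the computed range")
    total = dist.values.sum()
    if total <= 0:
        raise ValueError("distribution has zero total mass")
    part = dist.values[lo - dist.start_index: hi - dist.start_index + 1].sum()
    return float(part / total)
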