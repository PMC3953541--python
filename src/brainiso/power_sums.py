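"""Powered-root sums of element polynomials and the molecule-level kernel psi_l.

For an element with abundance vector ``P_0 ... P_kmax`` the generating
polynomial ``Q_E(I) = sum_k P_k I^k`` has ``kmax`` roots ``rho``.  The
quantity needed by the aggregated-distribution recurrence is the inverse
power sum

    r_{E,l} = sum over roots rho of rho^(-l)

and the molecule-level kernel is the composition-weighted inner product
``psi_l = sum_E count(E) * r_{E,l}``.

Two routes compute ``r_{E,l}``:

* :func:`power_sums_closed` finds the roots explicitly (exact for degree 1,
  numerical otherwise) and sums their inverse powers;
* :func:`power_sums_ro` ("root omitting") applies the Newton-Girard
  identities directly to the coefficient vector, extended through
  zero-abundance gap isotopes, so no root is ever extracted:

      r_{E,l} = -(1/P_0) (l P_l + sum_{j=1}^{l-1} P_{l-j} r_{E,j})   l <= kmax
      r_{E,l} = -(1/P_0) sum_{j=1}^{kmax} P_j r_{E,l-j}              l >  kmax

The root-omitting route is the default everywhere; the closed form is kept
as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import IsotopeTable, MolecularFormula

__all__ = [
    "ElementPolynomial",
    "PowerSumSeries",
    "PowerSumOverflow",
    "power_sums_closed",
    "power_sums_ro",
    "series_for",
    "psi",
    "psi_vector",
]

# |r_{E,l}| beyond this means the dominant root lies inside the unit circle and
# the series diverges faster than double precision can represent.
_GROWTH_LIMIT = 1e300


class PowerSumOverflow(OverflowError):
    """Powered-root sums exceeded the representable range before l_max."""


@dataclass(frozen=True)
class ElementPolynomial:
    """Dense abundance-coefficient vector of one element, gaps stored as 0."""

    symbol: str
    coeffs: tuple[float, ...]

    def __post_init__(self):
        c = self.coeffs
        if not c or c[0] <= 0.0:
            raise ValueError(f"{self.symbol}: lightest-isotope abundance P_0 must be positive")
        if abs(sum(c) - 1.0) > 1e-9:
            raise ValueError(f"{self.symbol}: abundances must sum to 1")
        if len(c) > 1 and c[-1] == 0.0:
            raise ValueError(f"{self.symbol}: trailing zero coefficient; trim before use")

    @classmethod
    def from_table(cls, table: IsotopeTable, symbol: str) -> "ElementPolynomial":
        ab = table.abundances(symbol)
        while len(ab) > 1 and ab[-1] == 0.0:  # defensive; tables end on a stable isotope
            ab.pop()
        return cls(symbol, tuple(ab))

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1


def power_sums_ro(poly: ElementPolynomial, l_max: int) -> np.ndarray:
    """Inverse-power root sums r_{E,1..l_max} by the root-omitting recursion.

    Pure rational arithmetic on the abundance coefficients; no root finding.
    Returns an array of length ``l_max`` (index 0 holds l = 1).
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    p = np.asarray(poly.coeffs, dtype=float)
    p0 = p[0]
    kmax = poly.degree
    r = np.empty(l_max)
    for l in range(1, l_max + 1):
        if l <= kmax:
            acc = l * p[l]
            for j in range(1, l):
                acc += p[l - j] * r[j - 1]
        else:
            acc = 0.0
            for j in range(1, kmax + 1):
                acc += p[j] * r[l - j - 1]
        r[l - 1] = -acc / p0
        if abs(r[l - 1]) > _GROWTH_LIMIT:
            raise PowerSumOverflow(
                f"{poly.symbol}: |r_l| exceeded {_GROWTH_LIMIT:g} at l={l}; "
                "the dominant polynomial root lies inside the unit circle")
    return r


def power_sums_closed(poly: ElementPolynomial, l_max: int) -> np.ndarray:
    """Inverse-power root sums from explicitly computed polynomial roots.

    Degree-1 elements use the exact single root ``rho = -P_0/P_1``; higher
    degrees use numerical root finding.  The imaginary residue of each sum
    (roots come in conjugate pairs) must vanish to 1e-9 and is discarded.
    """
    if poly.degree < 1:
        raise ValueError("monoisotopic element has no roots; handled by the caller")
    if poly.degree == 1:
        ratio = -poly.coeffs[1] / poly.coeffs[0]  # rho^-1 for rho = -P0/P1
        out = np.empty(l_max)
        acc = 1.0
        for l in range(l_max):
            acc *= ratio
            if abs(acc) > _GROWTH_LIMIT:
                raise PowerSumOverflow(
                    f"{poly.symbol}: |r_l| exceeded {_GROWTH_LIMIT:g} at l={l + 1}")
            out[l] = acc
        return out
    roots = np.roots(list(poly.coeffs)[::-1])
    if np.any(roots == 0):
        raise ArithmeticError(f"{poly.symbol}: zero root from a trimmed polynomial")
    inv = 1.0 / roots
    out = np.empty(l_max)
    powers = np.ones_like(inv)
    for l in range(1, l_max + 1):
        powers = powers * inv
        s = powers.sum()
        if abs(s.imag) > 1e-9 * max(1.0, abs(s.real)):
            raise ArithmeticError(
                f"{poly.symbol}: imaginary residue {s.imag:g} at l={l}; roots unreliable")
        out[l - 1] = s.real
        if abs(out[l - 1]) > _GROWTH_LIMIT:
            raise PowerSumOverflow(f"{poly.symbol}: |r_l| exceeded {_GROWTH_LIMIT:g} at l={l}")
    return out


@dataclass
class PowerSumSeries:
    """Lazily extended, memoized r_{E,l} series for one element."""

    poly: ElementPolynomial
    _values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def upto(self, l_max: int) -> np.ndarray:
        """Values r_{E,1..l_max}; extends and caches as needed (prefix reuse)."""
        if l_max > len(self._values):
            # recompute from scratch: the recursion is O(kmax * l_max), cheap,
            # and restarting keeps the code path identical to power_sums_ro
            self._values = power_sums_ro(self.poly, max(l_max, 2 * len(self._values), 16))
        return self._values[:l_max]

    def value(self, l: int) -> float:
        return self.upto(l)[l - 1]


_SERIES_CACHE: dict[tuple[str, str], PowerSumSeries] = {}


def series_for(table: IsotopeTable, symbol: str) -> PowerSumSeries:
    """Memoized per-(element, table-version) powered-root series."""
    key = (symbol, table.version)
    if key not in _SERIES_CACHE:
        _SERIES_CACHE[key] = PowerSumSeries(ElementPolynomial.from_table(table, symbol))
    return _SERIES_CACHE[key]


def psi(formula: MolecularFormula, series: dict[str, np.ndarray], l: int) -> float:
    """psi_l = sum over elements of count(E) * r_{E,l} (inner product)."""
    total = 0.0
    for sym, n in formula.items():
        r = series.get(sym)
        if r is None:
            continue  # monoisotopic element: no roots, contributes nothing
        if l > len(r):
            raise ValueError(f"power-sum series for {sym!r} too short for l={l}")
        total += n * r[l - 1]
    return total


def psi_vector(formula: MolecularFormula, table: IsotopeTable, l_max: int) -> np.ndarray:
    """psi_1..psi_l_max for a molecule (array of length l_max, index 0 = l=1)."""
    out = np.zeros(l_max)
    for sym, n in formula.items():
        if table.max_extra_neutrons(sym) == 0:
            continue
        out += n * series_for(table, sym).upto(l_max)
    return out
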