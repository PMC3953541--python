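"""Iterative solvers for the aggregated isotope distribution, plus parameter heuristics.

The aggregated distribution of a molecule is the coefficient vector ``q_j``
of its expanded generating polynomial: ``q_j`` is the probability of the
isotope variant with ``j`` extra neutrons relative to the lightest variant.
The classic iteration computes, starting from the exact lightest-variant
probability ``q_0``,

    q_j = -(1/j) sum_{l=1}^{j} q_{j-l} psi_l

where ``psi_l`` is the molecule's powered-root kernel (module
:mod:`.power_sums`).  Two refinements make the iteration cheap for large
molecules:

* **recurrence of constant length (RCL)** — ``|psi_l|`` decays geometrically,
  so the summation can be trimmed to its last ``d`` terms once ``j > d``;
* **late starting point (LSP)** — the recurrence is linear in its starting
  value, so consecutive-peak *ratios* do not depend on it.  Starting at an
  arbitrary peak ``n_start - b`` with value 1 and discarding ``b`` burn-in
  steps yields the relative distribution (maximum peak normalized to 1) on
  a user-chosen window, without ever visiting the light tail.

Peak indexing is 0-based throughout (j = extra neutrons); 1-based peak
numbers appear only in display output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .elements import (
    IsotopeTable,
    MolecularFormula,
    average_mass_and_variance,
    monoisotopic_mass,
    polynomial_order,
)
from .power_sums import psi_vector

__all__ = [
    "AggregatedDistribution",
    "BrainConfig",
    "UnderflowError",
    "lightest_variant_log_probability",
    "brain_classic",
    "brain_rcl",
    "brain_lsp",
    "heuristic_nstop",
    "heuristic_bd",
    "heuristic_npeaks",
    "window_from_npeaks",
]


class UnderflowError(ArithmeticError):
    """Probability-mode output fell entirely below double-precision range."""


@dataclass
class AggregatedDistribution:
    """Indexed sequence of aggregated-variant probabilities or relative intensities.

    ``values[i]`` belongs to extra-neutron index ``start_index + i``.  In
    ``"probability"`` mode values are absolute probabilities; in ``"max-one"``
    mode they are relative intensities with the maximum peak equal to 1.
    """

    start_index: int
    values: np.ndarray
    mode: str  # "probability" | "max-one"
    burn_in_discarded: bool = False
    n_clamped: int = 0  # negative round-off values clamped to zero

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("probability", "max-one"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")

    @property
    def stop_index(self) -> int:
        return self.start_index + len(self.values) - 1

    def indices(self) -> np.ndarray:
        return np.arange(self.start_index, self.start_index + len(self.values))

    def value_at(self, j: int) -> float:
        if not self.start_index <= j <= self.stop_index:
            raise IndexError(f"peak index {j} outside [{self.start_index}, {self.stop_index}]")
        return float(self.values[j - self.start_index])

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BrainConfig:
    """Bundle of algorithm parameters for the two-improvement solver.

    d: summation memory length (peaks); b: burn-in steps (peaks);
    n_start/n_stop: reported window; alpha: peak-count multiplier of the
    Rockwood-style heuristic; use_rcl/use_lsp: which refinements are active.
    None means "derive from the heuristics at run time".
    """

    d: int | None = None
    b: int | None = None
    n_start: int | None = None
    n_stop: int | None = None
    alpha: float = 10.0
    use_rcl: bool = True
    use_lsp: bool = True

    def validate(self) -> None:
        if self.d is not None and self.d < 1:
            raise ValueError("d must be >= 1")
        if self.b is not None and self.b < 0:
            raise ValueError("b must be >= 0")
        if (self.n_start is not None and self.n_stop is not None
                and not 0 <= self.n_start <= self.n_stop):
            raise ValueError("need 0 <= n_start <= n_stop")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def lightest_variant_log_probability(formula: MolecularFormula,
                                     table: IsotopeTable | None = None) -> float:
    """Natural log of q_0 = product over elements of P_{E,0}^count.

    Returned in log space; exponentiation is deferred to the caller so that
    very large molecules do not underflow prematurely.
    """
    if table is None:
        table = IsotopeTable.default()
    if len(formula) == 0:
        raise ValueError("empty formula")
    total = 0.0
    for sym, n in formula.items():
        p0 = table[sym][0].abundance
        if p0 <= 0.0:
            raise ValueError(f"element {sym!r}: lightest-isotope abundance is zero")
        total += n * math.log(p0)
    return total


# --- core recurrence -------------------------------------------------------

_RESCALE_THRESHOLD = 1e250


def _run_recurrence(psis: np.ndarray, j_begin: int, n_stop: int,
                    d: int | None, start_value: float = 1.0) -> tuple[np.ndarray, int]:
    """Run q_j = -(1/j) sum_{l=1}^{L} q_{j-l} psi_l from j_begin to n_stop.

    ``L = min(j - j_begin, d)``: terms older than the starting point do not
    exist, and RCL trims to the last ``d``.  Returns the raw value array (index
    0 = j_begin) and a power-of-two exponent shift applied whenever values
    threaten to overflow; actual values are ``u * 2**shift``.  Power-of-two
    rescaling preserves mantissas exactly, so trimmed and untrimmed runs with
    inactive trimming stay bit-identical.
    """
    length = n_stop - j_begin + 1
    u = np.zeros(length)
    u[0] = start_value
    shift = 0
    for j in range(j_begin + 1, n_stop + 1):
        i = j - j_begin
        lmax = i if d is None else min(i, d)
        # dot of psi_1..psi_L with q_{j-1}, q_{j-2}, ... (most recent first)
        window = u[i - lmax:i][::-1]
        u[i] = -np.dot(psis[:lmax], window) / j
        a = abs(u[i])
        if a > _RESCALE_THRESHOLD:
            k = int(math.ceil(math.log2(a / _RESCALE_THRESHOLD)))
            u[:i + 1] = np.ldexp(u[:i + 1], -k)
            shift += k
    return u, shift


def _clamp_negatives(values: np.ndarray) -> int:
    neg = values < 0
    n = int(neg.sum())
    if n:
        values[neg] = 0.0
    return n


def brain_classic(formula: MolecularFormula, table: IsotopeTable | None = None,
                  n_stop: int | None = None, *, _d: int | None = None) -> AggregatedDistribution:
    """Classic full-length iteration: probability mode from j = 0 to n_stop.

    Internally the recurrence runs on values scaled by exp(-log q_0) so that
    the starting value is 1; the exact q_0 is restored on output.  If the
    final rescale underflows double range entirely, an :class:`UnderflowError`
    advises the late-starting-point mode instead.
    """
    if table is None:
        table = IsotopeTable.default()
    if n_stop is None:
        n_stop = heuristic_nstop(formula, table)
    if n_stop < 0:
        raise ValueError(f"n_stop must be >= 0, got {n_stop}")
    # n_stop beyond the polynomial order is allowed: the recurrence cancels
    # exactly there and yields zero coefficients.
    logq0 = lightest_variant_log_probability(formula, table)
    psis = psi_vector(formula, table, max(n_stop, 1))
    u, shift = _run_recurrence(psis, 0, n_stop, _d)
    n_clamped = _clamp_negatives(u)
    log_scale = logq0 + shift * math.log(2.0)
    factor = math.exp(log_scale) if log_scale < 700 else math.inf
    with np.errstate(under="ignore"):
        if math.isfinite(factor) and factor > 0.0:
            q = u * factor
        else:
            q = np.zeros_like(u)
            pos = u > 0
            q[pos] = np.exp(log_scale + np.log(u[pos]))
    if n_stop > 0 and not np.any(q > 0.0):
        raise UnderflowError(
            "probability-mode output underflowed double precision; "
            "use the late-starting-point mode (brain_lsp) for this molecule")
    return AggregatedDistribution(0, q, "probability", n_clamped=n_clamped)


def brain_rcl(formula: MolecularFormula, table: IsotopeTable | None = None,
              n_stop: int | None = None, d: int | None = None) -> AggregatedDistribution:
    """Constant-memory-length iteration: the summation keeps only its last d terms.

    With ``d >= n_stop`` the trimming never activates and the result is
    bit-identical to :func:`brain_classic`.  ``d`` defaults to the
    order-of-magnitude rule :func:`heuristic_bd`.
    """
    if table is None:
        table = IsotopeTable.default()
    if d is None:
        d = heuristic_bd(monoisotopic_mass(formula, table))
    if d < 1:
        raise ValueError("d must be >= 1")
    return brain_classic(formula, table, n_stop, _d=d)


def brain_lsp(formula: MolecularFormula, table: IsotopeTable | None = None,
              n_start: int | None = None, n_stop: int | None = None,
              b: int | None = None, d: int | None = None, *,
              alpha: float = 10.0, start_value: float = 1.0,
              keep_burn_in: bool = False) -> AggregatedDistribution:
    """Late-starting-point iteration: relative intensities on a chosen window.

    The recurrence starts at peak ``n_start - b`` with an arbitrary value
    (default 1), runs ``b`` burn-in steps whose results are discarded, and
    reports ``n_start..n_stop`` normalized to a maximum of 1.  Ratios of
    consecutive reported peaks are invariant to the starting value because
    the recurrence is linear in it.  When ``d`` is given the summation is
    additionally trimmed to its last ``d`` terms (RCL composition).
    """
    if table is None:
        table = IsotopeTable.default()
    n = polynomial_order(formula, table)
    if n_start is None or n_stop is None:
        ns, nst = window_from_npeaks(formula, table, heuristic_npeaks(formula, table, alpha))
        n_start = ns if n_start is None else n_start
        n_stop = nst if n_stop is None else n_stop
    if b is None:
        b = heuristic_bd(monoisotopic_mass(formula, table))
    if not 0 <= n_start <= n_stop <= n:
        raise ValueError(f"need 0 <= n_start <= n_stop <= {n}")
    j_begin = n_start - b
    if j_begin < 0:
        raise ValueError(
            f"n_start - b = {j_begin} < 0: the recursion cannot start below the "
            "lightest variant; reduce b or use brain_classic")
    if d is not None and d < 1:
        raise ValueError("d must be >= 1")
    psis = psi_vector(formula, table, max(n_stop - j_begin, 1))
    u, _shift = _run_recurrence(psis, j_begin, n_stop, d, start_value=start_value)
    n_clamped = _clamp_negatives(u)
    if not keep_burn_in:
        u = u[n_start - j_begin:]
        start = n_start
    else:
        start = j_begin
    peak = u[(n_start - start):].max() if len(u) else 0.0
    if peak <= 0.0:
        raise ValueError("reported window contains only zero intensities")
    return AggregatedDistribution(start, u / peak, "max-one",
                                  burn_in_discarded=not keep_burn_in, n_clamped=n_clamped)


def brain2(formula: MolecularFormula, table: IsotopeTable | None = None,
           config: BrainConfig | None = None) -> AggregatedDistribution:
    """The two-improvement solver (RCL + LSP) driven by a :class:`BrainConfig`."""
    if table is None:
        table = IsotopeTable.default()
    cfg = config or BrainConfig()
    cfg.validate()
    if not cfg.use_lsp:
        if not cfg.use_rcl:
            return brain_classic(formula, table, cfg.n_stop)
        return brain_rcl(formula, table, cfg.n_stop, cfg.d)
    d = cfg.d
    if cfg.use_rcl and d is None:
        d = heuristic_bd(monoisotopic_mass(formula, table))
    return brain_lsp(formula, table, cfg.n_start, cfg.n_stop, cfg.b,
                     d if cfg.use_rcl else None, alpha=cfg.alpha)


# --- parameter heuristics --------------------------------------------------

def heuristic_nstop(formula: MolecularFormula, table: IsotopeTable | None = None) -> int:
    """Stopping peak: max(2 * ceil(average mass - monoisotopic mass), 5), capped at
    the polynomial order."""
    if table is None:
        table = IsotopeTable.default()
    if len(formula) == 0:
        raise ValueError("empty formula")
    avg, _ = average_mass_and_variance(formula, table)
    mono = monoisotopic_mass(formula, table)
    return min(max(2 * math.ceil(avg - mono), 5), polynomial_order(formula, table))


def heuristic_bd(mono_mass: float) -> int:
    """Burn-in / memory length: ceil(log10(M) + 5), i.e. five plus the number of
    digits in the integer part of the lightest-variant mass M."""
    if mono_mass <= 0:
        raise ValueError("monoisotopic mass must be positive")
    return math.ceil(math.log10(mono_mass) + 5)


def heuristic_npeaks(formula: MolecularFormula, table: IsotopeTable | None = None,
                     alpha: float = 10.0) -> int:
    """Window width: N = ceil(alpha * sqrt(1 + sigma^2)), sigma^2 the mass variance."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if table is None:
        table = IsotopeTable.default()
    _, var = average_mass_and_variance(formula, table)
    return math.ceil(alpha * math.sqrt(1.0 + var))


def window_from_npeaks(formula: MolecularFormula, table: IsotopeTable | None = None,
                       N: int | None = None) -> tuple[int, int]:
    """Center an N-peak window on the average mass.

    The center index is round-half-up of (average - monoisotopic); for even N
    the extra peak goes on the heavy side.  The window is clamped to
    [0, polynomial order].
    """
    if table is None:
        table = IsotopeTable.default()
    if N is None:
        N = heuristic_npeaks(formula, table)
    if N < 1:
        raise ValueError("N must be >= 1")
    avg, _ = average_mass_and_variance(formula, table)
    mono = monoisotopic_mass(formula, table)
    c = math.floor(avg - mono + 0.5)
    n = polynomial_order(formula, table)
    n_start = max(0, c - (N - 1) // 2)
    n_stop = min(n, n_start + N - 1)
    return n_start, n_stop
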