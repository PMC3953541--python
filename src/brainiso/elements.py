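"""Elemental isotope data, formula parsing, and per-molecule mass statistics.

An :class:`IsotopeTable` stores, for each element, a list of isotopes indexed
by *extra-neutron number* ``k`` relative to the lightest stable isotope.  The
list is dense in ``k``: isotopes that do not occur in nature (e.g. ``35S``)
are present with abundance 0, so the abundance vector is exactly the
coefficient vector of the element's generating polynomial.

A :class:`MolecularFormula` is an immutable element -> count mapping.  Mass
statistics (monoisotopic mass, average mass, mass variance) are additive over
atoms because isotope choices of distinct atoms are independent.
"""

from __future__ import annotations

import math
import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

__all__ = [
    "Isotope",
    "IsotopeTable",
    "MolecularFormula",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "average_mass_and_variance",
    "polynomial_order",
]


class FormulaError(ValueError):
    """Raised for malformed formulas or symbols absent from the isotope table."""


class Isotope(NamedTuple):
    mass: float  # Da
    abundance: float  # probability; 0 marks a non-occurring ("gap") isotope


_ABUNDANCE_TOL_BUILTIN = 1e-9
_ABUNDANCE_TOL_FILE = 1e-6


class IsotopeTable:
    """Per-element stable-isotope masses and abundances, dense in extra-neutron index.

    Parameters
    ----------
    data
        Mapping from element symbol to an ordered list of isotopes.  Index in
        the list is the extra-neutron number ``k`` relative to the lightest
        isotope.
    version
        Identifier for the data source; used to key power-sum caches.
    """

    def __init__(self, data: Mapping[str, list[Isotope]], version: str,
                 abundance_tol: float = _ABUNDANCE_TOL_BUILTIN):
        self._data = {sym: list(isos) for sym, isos in data.items()}
        self.version = version
        for sym, isos in self._data.items():
            if not isos:
                raise ValueError(f"element {sym!r} has no isotopes")
            if isos[0].abundance <= 0.0:
                raise ValueError(f"element {sym!r}: lightest isotope must have positive abundance")
            total = math.fsum(i.abundance for i in isos)
            if abs(total - 1.0) > abundance_tol:
                raise ValueError(f"element {sym!r}: abundances sum to {total!r}, not 1")
            masses = [i.mass for i in isos]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"element {sym!r}: isotope masses must strictly increase with k")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._data

    def __getitem__(self, symbol: str) -> list[Isotope]:
        try:
            return self._data[symbol]
        except KeyError:
            raise FormulaError(f"unknown element symbol {symbol!r}") from None

    def symbols(self) -> list[str]:
        return list(self._data)

    def max_extra_neutrons(self, symbol: str) -> int:
        """Degree of the element polynomial: k of the heaviest isotope."""
        return len(self[symbol]) - 1

    def abundances(self, symbol: str) -> list[float]:
        return [i.abundance for i in self[symbol]]

    @classmethod
    def default(cls) -> "IsotopeTable":
        """The NIST standard table shipped with the package (cached)."""
        global _DEFAULT_TABLE
        if _DEFAULT_TABLE is None:
            text = (resources.files("brainiso") / "data" / "isotopes.tsv").read_text()
            _DEFAULT_TABLE = cls._parse(text.splitlines(), version="nist-2018")
        return _DEFAULT_TABLE

    @classmethod
    def from_file(cls, path) -> "IsotopeTable":
        """Load a user override table.

        Plain-text rows: element symbol, extra-neutron index, mass (Da),
        abundance.  Abundances per element must sum to 1 within 1e-6.
        """
        with open(path) as fh:
            return cls._parse(fh, version=f"file:{path}", abundance_tol=_ABUNDANCE_TOL_FILE)

    @classmethod
    def _parse(cls, lines, version: str,
               abundance_tol: float = _ABUNDANCE_TOL_BUILTIN) -> "IsotopeTable":
        rows: dict[str, dict[int, Isotope]] = {}
        for lineno, line in enumerate(lines, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"isotope table line {lineno}: expected 4 fields, got {len(parts)}")
            sym, k, mass, ab = parts[0], int(parts[1]), float(parts[2]), float(parts[3])
            rows.setdefault(sym, {})[k] = Isotope(mass, ab)
        data = {}
        for sym, by_k in rows.items():
            kmax = max(by_k)
            if set(by_k) != set(range(kmax + 1)):
                missing = sorted(set(range(kmax + 1)) - set(by_k))
                raise ValueError(f"element {sym!r}: missing extra-neutron rows {missing}")
            data[sym] = [by_k[k] for k in range(kmax + 1)]
        return cls(data, version=version, abundance_tol=abundance_tol)


_DEFAULT_TABLE: IsotopeTable | None = None


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula(Mapping):
    """Immutable element -> count mapping with canonical Hill-order serialization."""

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int]):
        for sym, n in counts.items():
            if n < 0:
                raise FormulaError(f"negative count for element {sym!r}")
        items = {s: n for s, n in counts.items() if n > 0}
        # Hill order: C first, then H, then alphabetical
        def key(sym: str):
            return {"C": (0,), "H": (1,)}.get(sym, (2, sym))
        object.__setattr__(self, "counts", tuple(sorted(items.items(), key=lambda kv: key(kv[0]))))

    @classmethod
    def parse(cls, text: str, table: IsotopeTable | None = None) -> "MolecularFormula":
        return parse_formula(text, table)

    def __getitem__(self, symbol: str) -> int:
        for sym, n in self.counts:
            if sym == symbol:
                return n
        raise KeyError(symbol)

    def __iter__(self) -> Iterator[str]:
        return (sym for sym, _ in self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __str__(self) -> str:
        return "".join(f"{sym}{n if n != 1 else ''}" for sym, n in self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for sym, n in other.counts:
            merged[sym] = merged.get(sym, 0) + n
        return MolecularFormula(merged)

    def scaled(self, factor: int) -> "MolecularFormula":
        return MolecularFormula({sym: n * factor for sym, n in self.counts})

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)


def parse_formula(text: str, table: IsotopeTable | None = None) -> MolecularFormula:
    """Parse ``"C23832H37816N6528O7031S170"``-style formula strings.

    Grammar: element symbol (capital letter plus optional lowercase letter)
    followed by an optional positive integer count; repeated symbols
    accumulate.  No parentheses, isotope labels or charges.
    """
    if table is None:
        table = IsotopeTable.default()
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or not m.group(1):
            raise FormulaError(f"cannot parse formula at {text[pos:]!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in table:
            raise FormulaError(f"unknown element symbol {sym!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"count for element {sym!r} must be positive, got {n}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula, table: IsotopeTable | None = None) -> float:
    """Mass of the lightest isotope variant (Da): sum of count x lightest-isotope mass."""
    if table is None:
        table = IsotopeTable.default()
    return math.fsum(n * table[sym][0].mass for sym, n in formula.items())


def average_mass_and_variance(formula: MolecularFormula,
                              table: IsotopeTable | None = None) -> tuple[float, float]:
    """Average mass (Da) and mass variance (Da^2) of the isotope mass distribution.

    Both are additive over atoms: the mass of the molecule is a sum of
    independent per-atom isotope masses, so means and variances add.
    """
    if table is None:
        table = IsotopeTable.default()
    mean_terms = []
    var_terms = []
    for sym, n in formula.items():
        isos = table[sym]
        mu = math.fsum(i.mass * i.abundance for i in isos)
        var = math.fsum(i.abundance * (i.mass - mu) ** 2 for i in isos)
        mean_terms.append(n * mu)
        var_terms.append(n * var)
    return math.fsum(mean_terms), math.fsum(var_terms)


def polynomial_order(formula: MolecularFormula, table: IsotopeTable | None = None) -> int:
    """Order n of the expanded generating polynomial: the heaviest variant's
    extra-neutron count, sum of count x max extra neutrons per element."""
    if table is None:
        table = IsotopeTable.default()
    return sum(n * table.max_extra_neutrons(sym) for sym, n in formula.items())
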