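import numpy as np
import pytest

from brainiso import IsotopeTable, MolecularFormula, parse_formula

# human dynein heavy chain, the largest protein used throughout
DYNEIN = "C23832H37816N6528O7031S170"

# elements used for random protein-like test formulas
_CHNOS = ("C", "H", "N", "O", "S")


@pytest.fixture(scope="session")
def table() -> IsotopeTable:
    return IsotopeTable.default()


@pytest.fixture(scope="session")
def dynein() -> MolecularFormula:
    return parse_formula(DYNEIN)


def random_formula(rng: np.random.Generator, max_atoms: int = 200) -> MolecularFormula:
    """A random CHNOS formula with at least one atom and at most max_atoms."""
    while True:
        counts = {sym: int(rng.integers(0, max_atoms // len(_CHNOS) + 1)) for sym in _CHNOS}
        total = sum(counts.values())
        if 0 < total <= max_atoms:
            return MolecularFormula(counts)
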