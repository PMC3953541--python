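"""The classic, constant-memory (RCL) and late-starting-point (LSP) solvers."""

import math

import numpy as np
import pytest

from brainiso import (
    BrainConfig,
    IsotopeTable,
    MolecularFormula,
    brain2,
    brain_classic,
    brain_lsp,
    brain_rcl,
    chi2,
    heuristic_bd,
    heuristic_npeaks,
    heuristic_nstop,
    lightest_variant_log_probability,
    monoisotopic_mass,
    parse_formula,
    polynomial_order,
    window_from_npeaks,
)
from brainiso.brain_core import UnderflowError
from conftest import random_formula


class TestLogQ0:
    def test_single_and_double_carbon(self, table):
        p12 = table["C"][0].abundance
        assert lightest_variant_log_probability(parse_formula("C"), table) == \
            pytest.approx(math.log(p12), rel=1e-15)
        assert lightest_variant_log_probability(parse_formula("C2"), table) == \
            pytest.approx(2 * math.log(p12), rel=1e-15)

    def test_dynein_deep_in_log_space(self, table, dynein):
        # q_0 ~ 1.7e-135: representable, but far too small to start from
        # without care for much larger molecules
        logq0 = lightest_variant_log_probability(dynein, table)
        assert logq0 == pytest.approx(-310.375, abs=0.01)

    def test_empty_formula_rejected(self, table):
        with pytest.raises(ValueError):
            lightest_variant_log_probability(MolecularFormula({}), table)


class TestClassic:
    def test_single_carbon_exact(self, table):
        p12, p13 = table.abundances("C")
        d = brain_classic(parse_formula("C"), table, n_stop=1)
        assert d.mode == "probability"
        np.testing.assert_allclose(d.values, [p12, p13], rtol=1e-15)

    def test_single_carbon_beyond_degree_cancels(self, table):
        d = brain_classic(parse_formula("C"), table, n_stop=3)
        assert d.values[2] == 0.0 and d.values[3] == 0.0

    @pytest.mark.parametrize("sym", ["S", "Pt"])
    def test_single_atom_reproduces_abundances(self, table, sym):
        """Newton-Girard self-consistency: one atom's distribution is the
        element's own abundance vector, with exact zeros at the gaps."""
        f = parse_formula(sym)
        d = brain_classic(f, table, n_stop=polynomial_order(f, table))
        np.testing.assert_allclose(d.values, table.abundances(sym), atol=1e-12)

    def test_probability_conservation_random_formulas(self, table):
        rng = np.random.default_rng(7)
        for _ in range(10):
            f = random_formula(rng, max_atoms=150)
            d = brain_classic(f, table, n_stop=polynomial_order(f, table))
            assert d.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_underflow_raises_with_lsp_advice(self, table, dynein):
        # light tail of a ~3.2 MDa molecule: every requested peak underflows
        with pytest.raises(UnderflowError, match="brain_lsp"):
            brain_classic(dynein.scaled(6), table, n_stop=5)


class TestRCL:
    def test_large_d_bit_identical_to_classic(self, table):
        f = parse_formula("C120H200N40O30S5")
        full = brain_classic(f, table, n_stop=60)
        trimmed = brain_rcl(f, table, n_stop=60, d=60)
        np.testing.assert_array_equal(full.values, trimmed.values)

    def test_chi2_decreases_with_d(self, table):
        f = parse_formula("C100")
        ref = brain_classic(f, table, n_stop=50)
        errors = [chi2(ref, brain_rcl(f, table, n_stop=50, d=d)).chi2
                  for d in (3, 5, 10, 20, 50)]
        assert all(b <= a * 1.01 + 1e-13 for a, b in zip(errors, errors[1:]))
        assert errors[-1] < 1e-13  # d >= n_stop: identical up to round-off

    def test_default_d_from_mass_heuristic(self, table):
        f = parse_formula("C100H160N40O50S2")
        expected_d = heuristic_bd(monoisotopic_mass(f, table))
        np.testing.assert_array_equal(
            brain_rcl(f, table, n_stop=40).values,
            brain_rcl(f, table, n_stop=40, d=expected_d).values)


class TestLSP:
    def test_degenerate_lsp_is_rescaled_classic(self, table):
        f = parse_formula("C50H80N10O20")
        cls = brain_classic(f, table, n_stop=30)
        lsp = brain_lsp(f, table, n_start=0, n_stop=30, b=0)
        assert lsp.mode == "max-one"
        assert lsp.values.max() == 1.0
        np.testing.assert_allclose(lsp.values, cls.values / cls.values.max(), rtol=1e-12)

    def test_starting_value_linearity(self, table, dynein):
        a = brain_lsp(dynein, table, b=11, d=11, start_value=1.0)
        b = brain_lsp(dynein, table, b=11, d=11, start_value=1e6)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_ratio_invariance_vs_classic(self, table):
        f = parse_formula("C6000H10000N1500O2000S100")
        b = heuristic_bd(monoisotopic_mass(f, table))
        n_start, n_stop = window_from_npeaks(f, table, heuristic_npeaks(f, table))
        cls = brain_classic(f, table, n_stop=n_stop)
        lsp = brain_lsp(f, table, n_start=n_start, n_stop=n_stop, b=b)
        rc = cls.values[n_start + 1: n_stop + 1] / cls.values[n_start: n_stop]
        rl = lsp.values[1:] / lsp.values[:-1]
        np.testing.assert_allclose(rl, rc, rtol=1e-10)

    def test_burn_in_discarded_by_default(self, table, dynein):
        d = brain_lsp(dynein, table, n_start=300, n_stop=360, b=11)
        assert d.burn_in_discarded and d.start_index == 300
        kept = brain_lsp(dynein, table, n_start=300, n_stop=360, b=11, keep_burn_in=True)
        assert not kept.burn_in_discarded and kept.start_index == 289

    def test_start_below_lightest_variant_rejected(self, table):
        with pytest.raises(ValueError, match="reduce b or use brain_classic"):
            brain_lsp(parse_formula("C100"), table, n_start=5, n_stop=40, b=8)

    def test_all_zero_window_rejected(self, table):
        # a single platinum atom has an exact zero at the k = 1 gap
        with pytest.raises(ValueError, match="zero"):
            brain_lsp(parse_formula("Pt"), table, n_start=1, n_stop=1, b=1)


class TestBrain2:
    def test_dispatch_matches_components(self, table):
        f = parse_formula("C6000H10000N1500O2000S100")
        cfg = BrainConfig(b=11, d=11)
        via_cfg = brain2(f, table, cfg)
        direct = brain_lsp(f, table, b=11, d=11)
        np.testing.assert_array_equal(via_cfg.values, direct.values)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BrainConfig(d=0).validate()
        with pytest.raises(ValueError):
            BrainConfig(alpha=-1).validate()
        with pytest.raises(ValueError):
            BrainConfig(n_start=5, n_stop=3).validate()


class TestHeuristics:
    def test_nstop_floor_for_hydrogen(self, table):
        # 2*ceil(avg - mono) = 2 for a single H, but the order caps it at 1
        f = parse_formula("H")
        assert heuristic_nstop(f, table) == min(5, polynomial_order(f, table))
        assert heuristic_nstop(parse_formula("H100"), table) == 5

    def test_nstop_roughly_doubles_with_size(self, table):
        f = parse_formula("C600H1000N150O200S10")
        n1 = heuristic_nstop(f, table)
        n2 = heuristic_nstop(f.scaled(2), table)
        assert abs(n2 - 2 * n1) <= 2

    @pytest.mark.parametrize("mass,expected", [
        (112824, 11), (186387, 11), (398470, 11), (533403, 11), (1, 5), (999, 8), (1000, 8),
    ])
    def test_bd_rule_of_thumb(self, mass, expected):
        assert heuristic_bd(mass) == expected

    def test_bd_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            heuristic_bd(0)

    def test_npeaks_monoisotopic_molecule_gives_alpha(self, table):
        # phosphorus has a single stable isotope: sigma^2 = 0, N = alpha
        assert heuristic_npeaks(parse_formula("P10"), table, alpha=10) == 10

    def test_npeaks_known_variance(self):
        # custom two-isotope element with variance exactly 3 per atom
        from brainiso.elements import Isotope
        dm = math.sqrt(12.0)
        t = IsotopeTable({"X": [Isotope(1.0, 0.5), Isotope(1.0 + dm, 0.5)]}, version="synthetic")
        assert heuristic_npeaks(MolecularFormula({"X": 1}), t, alpha=10) == 20

    def test_window_single_peak_at_center(self, table):
        f = parse_formula("C600H1000N150O200S10")
        from brainiso.elements import average_mass_and_variance
        avg, _ = average_mass_and_variance(f, table)
        c = math.floor(avg - monoisotopic_mass(f, table) + 0.5)
        assert window_from_npeaks(f, table, N=1) == (c, c)

    def test_window_clamped_at_zero_for_small_molecule(self, table):
        n_start, n_stop = window_from_npeaks(parse_formula("C2H6O"), table, N=50)
        assert n_start == 0
        assert n_stop <= polynomial_order(parse_formula("C2H6O"), table)

    def test_window_contains_the_mode(self, table):
        rng = np.random.default_rng(11)
        for _ in range(5):
            f = random_formula(rng, max_atoms=200).scaled(20)
            N = heuristic_npeaks(f, table)
            if N < 50:
                continue
            n_start, n_stop = window_from_npeaks(f, table, N)
            full = brain_classic(f, table, n_stop=heuristic_nstop(f, table))
            mode = int(np.argmax(full.values))
            assert n_start <= mode <= n_stop
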