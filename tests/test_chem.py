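"""Formula parsing, masses, adducts, isotope patterns, and the fit score."""

import math

import pytest
from hypothesis import given, strategies as st

from edascreen.chem import (
    ChemError,
    ElementComposition,
    FormulaError,
    IsotopePattern,
    MassTolerance,
    adduct_mz,
    isotope_pattern,
    mass,
    mass_conc_to_micromolar,
    micromolar_to_mass_conc,
    monoisotopic_is_base,
    msigma,
    parse_formula,
    ppm_error,
)

from conftest import brute_force_pattern, n_isotope_combinations


@pytest.mark.parametrize(
    "text, expected",
    [
        ("H2O", {"H": 2, "O": 1}),
        ("C8HF15O2", {"C": 8, "H": 1, "F": 15, "O": 2}),
        ("C6H4Br2", {"C": 6, "H": 4, "Br": 2}),
        ("C17H10D8FN3O3", {"C": 17, "H": 10, "D": 8, "F": 1, "N": 3, "O": 3}),
        ("C37H69[13C]D3N2O12", {"C": 37, "H": 69, "[13C]": 1, "D": 3, "N": 2, "O": 12}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text).counts == expected


@pytest.mark.parametrize("bad", ["", "2H", "C?", "Xx3", "C1x"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_hill_round_trip():
    for text in ("H2O", "C8HF15O2", "C6H4Br2", "BrC6H4Br", "C17H10D8FN3O3"):
        comp = parse_formula(text)
        assert parse_formula(comp.hill_formula()).counts == comp.counts


def test_masses():
    water = parse_formula("H2O")
    assert mass(water, "monoisotopic") == pytest.approx(18.01056, abs=1e-4)
    assert mass(parse_formula("C8HF15O2"), "average") == pytest.approx(414.07, abs=0.01)
    with pytest.raises(ChemError):
        mass(ElementComposition({}))


def test_monoisotopic_mass_agrees_with_pyteomics():
    # independent mass scale check against the NIST table shipped by pyteomics
    from pyteomics import mass as pmass

    for text in ("H2O", "C8HF15O2", "C6H4Br2", "C38H72N2O12"):
        assert mass(parse_formula(text)) == pytest.approx(
            pmass.calculate_mass(formula=text.replace("[13C]", "")), abs=2e-5
        )


def test_adduct_mz():
    water = parse_formula("H2O")
    # protonated water: 18.010565 + 1.007276 (proton, electron-corrected)
    assert adduct_mz(water, "[M+H]+") == pytest.approx(18.010565 + 1.007276, abs=1e-4)
    assert adduct_mz(water, "[M−H]−") == pytest.approx(17.00329, abs=1e-4)
    with pytest.raises(ChemError):
        adduct_mz(water, "[M+Zz]")
    with pytest.raises(ChemError):
        adduct_mz(water, "[M+H]+", charge_sign=-1)


def test_ppm_error():
    assert ppm_error(500.0025, 500.0) == pytest.approx(5.0)
    assert ppm_error(500.0, 500.0) == 0.0
    assert ppm_error(413.97369 * (1 - 2e-6), 413.97369) == pytest.approx(-2.0, abs=1e-6)
    with pytest.raises(ChemError):
        ppm_error(100.0, 0.0)


def test_ppm_error_antisymmetric():
    theo = 413.97369
    delta = 1.3e-3
    assert ppm_error(theo + delta, theo) == pytest.approx(-ppm_error(theo - delta, theo))


class TestIsotopePattern:
    def test_carbon(self):
        p = isotope_pattern(parse_formula("C"))
        assert [round(m, 5) for m, _ in p.peaks] == [12.0, 13.00335]
        assert p.peaks[0][1] == 1.0
        assert p.peaks[1][1] == pytest.approx(0.0107 / 0.9893, abs=1e-4)

    def test_dibromobenzene_triplet(self):
        p = isotope_pattern(parse_formula("C6H4Br2"))
        dominant = sorted(p.peaks, key=lambda x: -x[1])[:3]
        by_mass = sorted(dominant)
        assert by_mass[0][1] == pytest.approx(0.514, abs=0.01)  # M
        assert by_mass[1][1] == pytest.approx(1.000, abs=1e-9)  # M+2 is base
        assert by_mass[2][1] == pytest.approx(0.486, abs=0.01)  # M+4

    @pytest.mark.parametrize(
        "formula",
        ["CH4", "H2O", "C2H6O", "SO2", "C6H4Br2", "CHCl3", "C3H4Cl2", "NO2", "C2H3Br"],
    )
    def test_matches_brute_force_enumeration(self, formula):
        comp = parse_formula(formula)
        assert comp.n_atoms() <= 12
        expected = brute_force_pattern(comp.counts)
        got = isotope_pattern(comp).peaks
        assert len(got) == len(expected)
        for (gm, gi), (em, ei) in zip(got, expected):
            assert gm == pytest.approx(em, abs=1e-9)
            assert gi == pytest.approx(ei, abs=1e-9)

    @given(
        st.fixed_dictionaries(
            {},
            optional={
                "C": st.integers(1, 6),
                "H": st.integers(1, 8),
                "N": st.integers(1, 2),
                "O": st.integers(1, 3),
                "S": st.integers(1, 2),
                "Cl": st.integers(1, 3),
                "Br": st.integers(1, 3),
            },
        ).filter(
            lambda c: c
            and sum(c.values()) <= 12
            and n_isotope_combinations(c) <= 20000
        )
    )
    def test_property_matches_brute_force(self, counts):
        comp = ElementComposition(dict(counts))
        expected = brute_force_pattern(comp.counts)
        got = isotope_pattern(comp).peaks
        assert len(got) == len(expected)
        for (gm, gi), (em, ei) in zip(got, expected):
            assert abs(gm - em) < 1e-9
            assert abs(gi - ei) < 1e-9

    @given(
        st.fixed_dictionaries(
            {},
            optional={
                "C": st.integers(1, 30),
                "H": st.integers(1, 40),
                "Cl": st.integers(0, 4),
                "Br": st.integers(0, 3),
                "O": st.integers(0, 6),
            },
        ).filter(lambda c: sum(c.values()) >= 1)
    )
    def test_invariants(self, counts):
        comp = ElementComposition(dict(counts))
        p = isotope_pattern(comp)
        intensities = [i for _, i in p.peaks]
        assert sum(1 for i in intensities if i == 1.0) == 1
        assert all(0 < i <= 1 for i in intensities)
        # monoisotopic mass never exceeds any isotopologue mass
        assert mass(comp, "monoisotopic") <= p.peaks[0][0] + 1e-9

    def test_input_validation(self):
        with pytest.raises(ChemError):
            isotope_pattern(ElementComposition({}))
        with pytest.raises(ChemError):
            isotope_pattern(parse_formula("CH4"), prune=1.5)


class TestMsigma:
    def test_identity_is_zero(self):
        p = isotope_pattern(parse_formula("C6H4Br2"))
        assert msigma(p, p) == 0.0

    def test_hand_computed_residual(self):
        theo = IsotopePattern(((100.0, 1.0), (101.0, 0.5)))
        meas = IsotopePattern(((100.0, 1.0), (101.0, 0.55)))
        assert msigma(meas, theo) == pytest.approx(1000 * math.sqrt(0.05**2 / 2), abs=0.01)

    def test_missing_theoretical_peak(self):
        theo = IsotopePattern(((100.0, 1.0), (101.0, 0.5)))
        meas = IsotopePattern(((100.0, 1.0),))
        assert msigma(meas, theo) == pytest.approx(1000 * math.sqrt(0.25 / 2), abs=0.1)

    @given(st.floats(0.0, 0.45))
    def test_strictly_increasing_in_residual(self, delta):
        theo = IsotopePattern(((100.0, 1.0), (101.0, 0.5)))
        lo = IsotopePattern(((100.0, 1.0), (101.0, 0.5 + delta)))
        hi = IsotopePattern(((100.0, 1.0), (101.0, 0.5 + delta + 0.01)))
        assert msigma(hi, theo) > msigma(lo, theo) >= 0.0


def test_monoisotopic_is_base():
    assert monoisotopic_is_base(isotope_pattern(parse_formula("C")))
    assert not monoisotopic_is_base(isotope_pattern(parse_formula("C6H4Br2")))
    assert monoisotopic_is_base(IsotopePattern(((100.0, 1.0),)))


def test_concentration_conversions():
    pfoa = parse_formula("C8HF15O2")
    assert micromolar_to_mass_conc(1.1, pfoa) == pytest.approx(455, abs=1)
    assert micromolar_to_mass_conc(0.0, pfoa) == 0.0
    round_trip = mass_conc_to_micromolar(micromolar_to_mass_conc(1.1, pfoa), pfoa)
    assert round_trip == pytest.approx(1.1, abs=1e-9)
    with pytest.raises(ChemError):
        micromolar_to_mass_conc(1.0, ElementComposition({}))


def test_mass_tolerance():
    tol = MassTolerance(ppm=10)
    assert tol.matches(100.0005, 100.0)
    assert not tol.matches(100.0015, 100.0)
    with pytest.raises(ChemError):
        MassTolerance(ppm=0)
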