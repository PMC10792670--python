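"""Formula parsing, monoisotopic masses, adduct m/z, and annotation."""

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics.mass import calculate_mass

from iris_elucidate.chem import (
    ChemicalFormula,
    FormulaError,
    IonSpecies,
    annotate_mass_shift,
    annotate_msms,
    ion_mz,
    monoisotopic_mass,
    nominal_mz,
    parse_formula,
    ppm_error,
)

ELEMENTS = ["C", "H", "N", "O", "S", "Na"]

formula_counts = st.dictionaries(
    st.sampled_from(ELEMENTS), st.integers(min_value=0, max_value=60), max_size=6
)


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C35H48O9", {"C": 35, "H": 48, "O": 9}),
            ("", {}),
            ("H2O", {"H": 2, "O": 1}),
            ("C6H8O6", {"C": 6, "H": 8, "O": 6}),
            ("NaCl", {"Na": 1, "Cl": 1}),
        ],
    )
    def test_examples(self, text, expected):
        assert parse_formula(text).counts == expected

    def test_roundtrips_to_hill_order(self):
        assert parse_formula("O9H48C35").hill() == "C35H48O9"
        assert parse_formula("C35H48O9").hill() == "C35H48O9"

    def test_unknown_element_named_in_error(self):
        with pytest.raises(FormulaError, match="Xx"):
            parse_formula("C2Xx3")

    def test_garbage_rejected(self):
        with pytest.raises(FormulaError):
            parse_formula("12C")


class TestMonoisotopicMass:
    def test_water(self):
        assert monoisotopic_mass({"H": 2, "O": 1}) == pytest.approx(
            18.010565, abs=1e-6
        )

    def test_empty_formula_has_zero_mass(self):
        assert monoisotopic_mass({}) == 0.0

    def test_dgsm_neutral(self):
        assert monoisotopic_mass("C35H48O9") == pytest.approx(612.329833, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(counts=formula_counts)
    def test_matches_independent_oracle(self, counts):
        """Masses agree with pyteomics' element-table summation to sub-ppm."""
        counts = {el: n for el, n in counts.items() if n > 0}
        ours = monoisotopic_mass(counts)
        theirs = calculate_mass(composition=counts)
        assert ours == pytest.approx(theirs, abs=1e-5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(a=formula_counts, b=formula_counts)
    def test_additivity(self, a, b):
        fa, fb = ChemicalFormula(a), ChemicalFormula(b)
        assert monoisotopic_mass(fa + fb) == pytest.approx(
            monoisotopic_mass(fa) + monoisotopic_mass(fb), abs=1e-9
        )


class TestIonMz:
    @pytest.mark.parametrize(
        "formula,ion,expected,places",
        [
            ("C35H48O9", "[M+Na]+", 635.319054, 6),
            ("C25H32O9", "[M+Na]+", 499.1939, 4),
            ("C25H32O10", "[M+Na]+", 515.1888, 4),
        ],
    )
    def test_sodiated_accurate_masses(self, formula, ion, expected, places):
        assert round(ion_mz(formula, ion), places) == expected

    def test_deprotonated_sinapic_acid(self):
        mz = ion_mz("C11H12O5", "[M-H]-")
        assert mz == pytest.approx(223.0612, abs=2e-4)
        assert nominal_mz(mz) == 223

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(counts=formula_counts)
    def test_sodium_proton_adduct_spacing(self, counts):
        """[M+Na]+ sits 21.981944 Da above [M+H]+ for every formula."""
        counts = {el: n for el, n in counts.items() if n > 0}
        counts.setdefault("C", 1)
        f = ChemicalFormula(counts)
        diff = ion_mz(f, "[M+Na]+") - ion_mz(f, "[M+H]+")
        assert diff == pytest.approx(21.981944, abs=1e-5)

    def test_electron_correction_flag(self):
        with_corr = ion_mz("C35H48O9", "[M+Na]+", electron_correction=True)
        without = ion_mz("C35H48O9", "[M+Na]+", electron_correction=False)
        assert without - with_corr == pytest.approx(0.000548580, abs=1e-8)

    def test_unsupported_ion_type_lists_supported(self):
        with pytest.raises(ValueError, match=r"\[M\+H\]\+"):
            ion_mz("H2O", "[M+K]+")

    def test_ion_species_charge_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            IonSpecies(parse_formula("H2O"), "[M+H]+", charge=-1)


class TestPpmError:
    def test_table_value(self):
        assert ppm_error(499.19597, 499.19385) == pytest.approx(4.2, abs=0.1)

    def test_identity_and_errors(self):
        assert ppm_error(635.319054, 635.319054) == 0.0
        with pytest.raises(ValueError):
            ppm_error(1.0, 0.0)


class TestMassShiftAnnotation:
    def test_library_deltas_consistent_with_formulas(self, shift_library):
        for entry in shift_library:
            assert abs(
                monoisotopic_mass(
                    {el: abs(n) for el, n in entry.delta_formula.counts.items()}
                )
                - abs(entry.delta_mass)
            ) < 1e-6

    def test_sulfonation_shift(self, shift_library):
        hits = annotate_mass_shift(475.20, 475.20 + 79.96, shift_library, tol=0.01)
        assert hits == ["sulfonation (+SO3)"]

    def test_glucuronidation_shift(self, shift_library):
        hits = annotate_mass_shift(499.19, 499.19 + 176.03, shift_library, tol=0.01)
        assert hits == ["glucuronidation (+C6H8O6)"]

    def test_zero_shift_matches_nothing(self, shift_library):
        assert annotate_mass_shift(500.0, 500.0, shift_library, tol=0.01) == []


class TestMsmsAnnotation:
    def test_mb_water_loss(self, shift_library):
        mb = IonSpecies(parse_formula("C25H32O10"), "[M+Na]+")
        (ann,) = annotate_msms(mb, [497.178], shift_library, tol=0.05)
        assert ann.losses == ("water loss (-H2O)",)
        assert abs(ann.residual_ppm) < 20

    def test_mc_so3_loss(self, shift_library):
        mc = IonSpecies(parse_formula("C25H32O12S"), "[M-H]-")
        (ann,) = annotate_msms(mc, [475.197], shift_library, tol=0.05)
        assert ann.losses == ("SO3 loss (-SO3)",)

    def test_unmatched_fragment_flagged(self, shift_library):
        ma = IonSpecies(parse_formula("C25H32O9"), "[M+Na]+")
        (ann,) = annotate_msms(ma, [222.2], shift_library, tol=0.05)
        assert not ann.annotated and ann.losses == ()

    def test_empty_fragment_list(self, shift_library):
        ma = IonSpecies(parse_formula("C25H32O9"), "[M+Na]+")
        assert annotate_msms(ma, [], shift_library) == []

    def test_combined_double_loss(self, shift_library):
        """A fragment explained only by water + geranyl loss gets both labels."""
        mb = IonSpecies(parse_formula("C25H32O10"), "[M+Na]+")
        target = mb.mz - 18.010565 - 136.125201
        (ann,) = annotate_msms(mb, [target], shift_library, tol=0.02)
        assert sorted(ann.losses) == [
            "geranyl loss (-C10H16)",
            "water loss (-H2O)",
        ]


def test_nominal_mz_rounds_half_away_from_zero():
    assert nominal_mz(223.0613) == 223
    assert nominal_mz(497.5) == 498
    assert nominal_mz(309.1309) == 309
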