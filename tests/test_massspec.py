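"""Formula arithmetic, isotope patterns, charge-state m/z, adduct reasoning."""

import pytest

from swfscreen.massspec import (
    PPANT_EVEN_ELECTRON,
    PPANT_RADICAL,
    PROTON_MASS,
    ChemicalFormula,
    disulfide_dimer,
    format_formula,
    formula_subtract,
    isotope_pattern,
    monoisotopic_mass,
    nominal_mass,
    parse_formula,
    peak_mz,
    ppant_adduct,
    ppm_error,
)

APO = "C449H704N134O140S3"
HOLO = "C460H724N136O146PS4"


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            (APO, {"C": 449, "H": 704, "N": 134, "O": 140, "S": 3}),
            ("H2O", {"H": 2, "O": 1}),
            (HOLO, {"C": 460, "H": 724, "N": 136, "O": 146, "P": 1, "S": 4}),
        ],
    )
    def test_examples(self, text, expected):
        assert parse_formula(text).counts == expected

    def test_roundtrip(self):
        for text in (APO, HOLO, "H2O", "C11H20N2O6PS"):
            assert format_formula(parse_formula(text)) == text

    @pytest.mark.parametrize("bad", ["", "Xx3", "C-2", "2H", "C4.5"])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)


class TestMasses:
    def test_water(self):
        assert monoisotopic_mass(parse_formula("H2O")) == pytest.approx(18.0106, abs=5e-4)

    def test_apo_and_holo_proteoforms(self):
        assert monoisotopic_mass(parse_formula(APO)) == pytest.approx(10309.123, abs=5e-3)
        assert monoisotopic_mass(parse_formula(HOLO)) == pytest.approx(10648.202, abs=5e-3)

    def test_additivity(self):
        a, b = parse_formula("C6H12O6"), parse_formula("H2O")
        assert monoisotopic_mass(a + b) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9
        )

    def test_cross_check_against_pyteomics(self):
        from pyteomics.mass import calculate_mass

        for text in (APO, HOLO, "C11H20N2O6PS", "H2O"):
            assert monoisotopic_mass(parse_formula(text)) == pytest.approx(
                calculate_mass(formula=text), abs=1e-3
            )


class TestFormulaArithmetic:
    def test_holo_minus_apo_is_the_radical_fragment(self):
        diff = formula_subtract(parse_formula(HOLO), parse_formula(APO))
        assert diff.counts == PPANT_RADICAL.counts
        assert format_formula(diff) == "C11H20N2O6PS"

    def test_self_subtraction_is_empty(self):
        f = parse_formula("C2H6")
        assert formula_subtract(f, f).counts == {}

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError, match="negative"):
            formula_subtract(parse_formula(APO), parse_formula(HOLO))


class TestIsotopePattern:
    def test_single_carbon_ratio(self):
        pattern = isotope_pattern(parse_formula("C"))
        assert len(pattern.peaks) == 2
        (m0, a0), (m1, a1) = pattern.peaks
        assert a0 == 1.0
        assert a1 == pytest.approx(0.0107 / 0.9893, rel=1e-6)
        assert m1 - m0 == pytest.approx(1.00336, abs=1e-4)

    def test_water_dominant_light_bin(self):
        pattern = isotope_pattern(parse_formula("H2O"))
        mono_mass, mono_ab = pattern.monoisotopic()
        assert pattern.most_intense()[0] == mono_mass
        # the light isotopologue carries > 99% of the total abundance
        assert mono_ab / sum(ab for _, ab in pattern.peaks) > 0.99
        assert pattern.raw_total == pytest.approx(1.0, abs=1e-6)

    def test_unnormalized_sum_close_to_one(self):
        for text in (APO, HOLO, "C11H20N2O6PS"):
            pattern = isotope_pattern(parse_formula(text))
            assert 1 - pattern.raw_total < 1e-6

    def test_convolution_property(self):
        f1, f2 = parse_formula("C100H160N30O25S"), parse_formula("C20H30N4O8")
        p_sum = isotope_pattern(f1 + f2)
        p1, p2 = isotope_pattern(f1), isotope_pattern(f2)
        # manual convolution of the two normalized patterns, then renormalize
        bins: dict[int, float] = {}
        base = p_sum.peaks[0][0]
        for m1, a1 in p1.peaks:
            for m2, a2 in p2.peaks:
                k = round(m1 + m2 - base)
                bins[k] = bins.get(k, 0.0) + a1 * a2
        top = max(bins.values())
        for mass, ab in p_sum.peaks[:10]:
            k = round(mass - base)
            assert bins[k] / top == pytest.approx(ab, rel=1e-3)

    def test_most_intense_bin_for_10kda_protein(self):
        pattern = isotope_pattern(parse_formula(APO))
        mono = pattern.monoisotopic()[0]
        top = pattern.most_intense()[0]
        assert 5 <= round(top - mono) <= 7


class TestChargeStates:
    def test_apo_holo_z6_most_intense(self):
        assert peak_mz(parse_formula(APO), 6).mz == pytest.approx(1720.197, abs=2e-3)
        assert peak_mz(parse_formula(HOLO), 6).mz == pytest.approx(1776.710, abs=2e-3)

    def test_z1_monoisotopic_definition(self):
        f = parse_formula("C11H20N2O6PS")
        p = peak_mz(f, 1, "monoisotopic")
        assert p.mz - monoisotopic_mass(f) == pytest.approx(PROTON_MASS, abs=1e-9)

    def test_invalid_charge(self):
        with pytest.raises(ValueError):
            peak_mz(parse_formula("H2O"), 0)


class TestPpm:
    def test_measured_vs_calculated(self):
        # recomputed from the printed values; the sign follows
        # (calculated - measured) / calculated
        assert ppm_error(1720.1949, 1720.1972) == pytest.approx(1.34, abs=0.01)
        assert ppm_error(1776.7079, 1776.7101) == pytest.approx(1.24, abs=0.01)
        assert ppm_error(5.0, 5.0) == 0.0

    def test_measured_values_match_predictions_within_2ppm(self):
        apo_calc = peak_mz(parse_formula(APO), 6).mz
        holo_calc = peak_mz(parse_formula(HOLO), 6).mz
        assert abs(ppm_error(1720.1949, apo_calc)) < 2.0
        assert abs(ppm_error(1776.7079, holo_calc)) < 2.0


class TestPhosphopantetheinylation:
    def test_radical_adduct_reproduces_holo_formula(self):
        holo = ppant_adduct(parse_formula(APO), "radical")
        assert format_formula(holo) == HOLO

    def test_nominal_masses_339_and_340(self):
        assert nominal_mass(PPANT_RADICAL) == 339
        assert nominal_mass(PPANT_EVEN_ELECTRON) == 340

    def test_adduct_shift_band(self):
        apo = parse_formula(APO)
        shift = monoisotopic_mass(ppant_adduct(apo, "radical")) - monoisotopic_mass(apo)
        assert 339.073 <= shift <= 339.083
        even_shift = monoisotopic_mass(ppant_adduct(apo, "even_electron")) - monoisotopic_mass(apo)
        # the even-electron variant exceeds the radical by one H atom
        assert even_shift - shift == pytest.approx(1.00783, abs=1e-5)

    def test_disulfide_dimer(self):
        holo = parse_formula(HOLO)
        dimer = disulfide_dimer(holo)
        assert format_formula(dimer) == "C920H1446N272O292P2S8"
        assert monoisotopic_mass(dimer) == pytest.approx(
            2 * monoisotopic_mass(holo) - 2.0157, abs=1e-3
        )

    def test_dimer_odd_charge_peaks_distinct_from_monomer(self):
        holo = parse_formula(HOLO)
        dimer = disulfide_dimer(holo)
        dimer_mzs = {z: peak_mz(dimer, z, "monoisotopic").mz for z in (7, 9, 11, 13)}
        monomer_mzs = {z: peak_mz(holo, z, "monoisotopic").mz for z in range(1, 13)}
        for dz, dmz in dimer_mzs.items():
            for mz_val in monomer_mzs.values():
                assert abs(dmz - mz_val) > 0.05
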