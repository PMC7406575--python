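"""Mass rules, adduct m/z, nomenclature, and library enumeration."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pectolyze.composition import (
    KNOWN_INCONSISTENCIES,
    AdductSpec,
    CompositionError,
    OligoComposition,
    adduct_mz,
    enumerate_library,
    format_name,
    monoisotopic_mass,
    nominal_mass,
    parse_name,
)


@st.composite
def compositions(draw):
    dp = draw(st.integers(1, 10))
    return OligoComposition(
        dp,
        draw(st.integers(0, dp)),
        draw(st.integers(0, 2 * dp)),
        draw(st.booleans()),
    )


class TestNominalMass:
    @pytest.mark.parametrize(
        "dp,m,a,expected",
        [
            (3, 3, 0, 570),
            (1, 0, 0, 176),
            (4, 3, 2, 830),
            (7, 6, 0, 1316),  # the mass rule; a published row prints 1335 in error
        ],
    )
    def test_unsaturated_examples(self, dp, m, a, expected):
        assert nominal_mass(OligoComposition(dp, m, a, unsaturated=True)) == expected

    def test_saturated_adds_one_water(self):
        unsat = nominal_mass(OligoComposition(3, 2, 1, True))
        sat = nominal_mass(OligoComposition(3, 2, 1, False))
        assert sat - unsat == 18

    @given(compositions())
    @settings(max_examples=200, deadline=None)
    def test_mass_linearity(self, comp):
        base = OligoComposition(comp.dp, 0, 0, comp.unsaturated)
        assert nominal_mass(comp) - nominal_mass(base) == 14 * comp.n_methyl + 42 * comp.n_acetyl

    def test_invalid_composition_rejected(self):
        with pytest.raises(CompositionError):
            OligoComposition(0, 0, 0)
        with pytest.raises(CompositionError):
            OligoComposition(3, 4, 0)
        with pytest.raises(CompositionError):
            OligoComposition(3, 0, 7)


class TestMonoisotopicMass:
    def test_methylated_dimer_against_elemental_formula_oracle(self):
        # independent oracle: unsaturated methylated GalA dimer is C13H18O12
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        oracle = pyteomics_mass.calculate_mass(formula="C13H18O12")
        assert monoisotopic_mass(OligoComposition(2, 1, 0)) == pytest.approx(oracle, abs=0.01)
        assert monoisotopic_mass(OligoComposition(2, 1, 0)) == pytest.approx(366.080, abs=0.01)

    def test_single_residue(self):
        assert monoisotopic_mass(OligoComposition(1, 0, 0)) == pytest.approx(176.032, abs=0.001)

    def test_rounds_to_nominal_across_reference_inventory(self, reference_table):
        for name in reference_table["name"]:
            comp, _ = parse_name(name)
            assert round(monoisotopic_mass(comp)) == nominal_mass(comp)


class TestAdductMz:
    @pytest.mark.parametrize(
        "mass,adduct,expected",
        [
            (366, AdductSpec.ammonium(1), 384),
            (1154, AdductSpec.ammonium(2), 595),
            (570, AdductSpec.deprotonated(1), 569),
            (570, AdductSpec.formate(1), 615),
        ],
    )
    def test_nominal_contract(self, mass, adduct, expected):
        assert adduct_mz(mass, adduct) == expected

    def test_strictly_increasing_in_mass_and_z2_below_z1(self):
        for adduct in (AdductSpec.deprotonated(), AdductSpec.formate(), AdductSpec.ammonium()):
            assert adduct_mz(500, adduct) < adduct_mz(501, adduct)
        assert adduct_mz(1000, AdductSpec.ammonium(2)) < adduct_mz(1000, AdductSpec.ammonium(1))

    def test_wrong_polarity_adduct_rejected(self):
        with pytest.raises(CompositionError):
            AdductSpec("ammonium", "negative", 1)
        with pytest.raises(CompositionError):
            AdductSpec("protonated", "positive", 1)


class TestNomenclature:
    @pytest.mark.parametrize(
        "name,dp,m,a,iso",
        [
            ("gA_3_m_1_a_1", 3, 1, 1, 1),
            ("gA_4_m_4_a_1 #2", 4, 4, 1, 2),
            ("gA_2_m_1", 2, 1, 0, 1),
        ],
    )
    def test_parse(self, name, dp, m, a, iso):
        comp, isomer = parse_name(name)
        assert (comp.dp, comp.n_methyl, comp.n_acetyl, isomer) == (dp, m, a, iso)
        assert comp.unsaturated

    def test_round_trip_over_reference_labels(self, reference_table):
        for name in reference_table["name"]:
            comp, iso = parse_name(name)
            assert format_name(comp, iso, explicit_isomer="#" in name) == name

    def test_malformed_name(self):
        with pytest.raises(CompositionError, match="gA_x_m"):
            parse_name("gA_x_m_2")


class TestLibrary:
    def test_dimer_enumeration_exhaustive(self):
        entries = enumerate_library((2, 2), max_acetyl=0)
        assert [e.name for e in entries] == ["gA_2_m_1", "gA_2_m_2"]

    def test_full_enumeration_count(self):
        # sum over dp=2..8 of dp methyl choices x 3 acetyl choices
        assert len(enumerate_library((2, 8), 2)) == 105

    def test_empty_range(self):
        assert enumerate_library((5, 4)) == []

    def test_reference_inventory_has_48_entries(self, reference_library):
        assert len(reference_library) == 48

    def test_isomer_entries_share_composition_and_mass(self, reference_library):
        by_comp = {}
        for e in reference_library:
            by_comp.setdefault(e.composition, []).append(e)
        for comp, group in by_comp.items():
            assert len({e.nominal_mw for e in group}) == 1
            assert len({e.isomer_index for e in group}) == len(group)


class TestReferenceRegeneration:
    def test_printed_mw_and_mz_regenerate(self, reference_table):
        """Outside three flagged inconsistent rows, the printed MW and the
        positive-mode observed m/z at the printed charge state follow exactly
        from the building-block mass rule and the ammonium adduct contract."""
        checked = 0
        for _, row in reference_table.iterrows():
            base = row["name"].split(" #")[0]
            if base in KNOWN_INCONSISTENCIES:
                continue
            comp, _ = parse_name(row["name"])
            mw = nominal_mass(comp)
            assert mw == row["mw"], row["name"]
            for z, mz in zip(str(row["charge"]).split("/"), str(row["observed_mz"]).split("/")):
                assert adduct_mz(mw, AdductSpec.ammonium(int(z))) == float(mz), row["name"]
            checked += 1
        assert checked == 45

    def test_flagged_rows_really_are_inconsistent(self, reference_table):
        rows = reference_table.set_index("name")
        comp, _ = parse_name("gA_4_m_3")
        assert adduct_mz(nominal_mass(comp), AdductSpec.ammonium(1)) == 764 != rows.loc["gA_4_m_3", "observed_mz"]
        comp, _ = parse_name("gA_7_m_6")
        assert nominal_mass(comp) == 1316 != rows.loc["gA_7_m_6", "mw"]
        assert adduct_mz(1316, AdductSpec.ammonium(2)) == float(rows.loc["gA_7_m_6", "observed_mz"])
        comp, _ = parse_name("gA_8_m_7")
        assert nominal_mass(comp) == 1506 == rows.loc["gA_8_m_7", "mw"]
        assert (comp.dp, comp.n_methyl) != (
            rows.loc["gA_8_m_7", "gala"],
            rows.loc["gA_8_m_7", "methyl"],
        )
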