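"""Lipid chemistry: formulas, masses, transitions, enumeration, RT trends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweatlipidomics.library import (
    ATOMIC_MASS,
    CLASS_RULES,
    LipidSpecies,
    UnsupportedClassError,
    elemental_formula,
    enumerate_library,
    formula_string,
    monoisotopic_mass,
    parse_label,
    read_transition_list,
    rt_pattern_check,
    transitions_for,
    write_transition_list,
)


class TestElementalFormula:
    # expected formulas from the component construction (backbone + chains,
    # one water removed per ester/amide/glycosidic bond), cross-checked
    # against reference compositions for the named species
    @pytest.mark.parametrize("label, expected", [
        ("FA 2:0", "C2H4O2"),
        ("FA 18:0", "C18H36O2"),
        ("FA 18:1", "C18H34O2"),
        ("PC 34:1", "C42H82NO8P"),
        ("LPC 18:1", "C26H52NO7P"),
        ("PE 34:1", "C39H76NO8P"),
        ("PCO 34:1", "C42H84NO7P"),
        ("PI 34:1", "C43H81O13P"),
        ("PS 34:1", "C40H76NO10P"),
        ("DG 34:1", "C37H70O5"),
        ("TG 52:2", "C55H102O6"),
        ("CE 18:1", "C45H78O2"),
        ("Cer d18:1/16:0", "C34H67NO3"),
        ("SM d18:1/16:0", "C39H79N2O6P"),
        ("HexCer d18:1/16:0", "C40H77NO8"),
    ])
    def test_known_species(self, label, expected):
        assert formula_string(elemental_formula(parse_label(label))) == expected

    def test_unsupported_class(self):
        with pytest.raises(UnsupportedClassError):
            LipidSpecies("XX", 34, 1)

    def test_invalid_composition(self):
        with pytest.raises(ValueError):
            LipidSpecies("PC", 2, 5)


class TestMonoisotopicMass:
    def test_empty_formula(self):
        assert monoisotopic_mass({}) == 0.0

    @pytest.mark.parametrize("formula, expected", [
        ({"H": 2, "O": 1}, 18.0106),
        ({"C": 18, "H": 36, "O": 2}, 284.2715),
    ])
    def test_reference_masses(self, formula, expected):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=5e-4)

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            monoisotopic_mass({"Xx": 1})

    def test_against_independent_mass_table(self):
        """Every panel species agrees with pyteomics' atomic masses."""
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        for rec in enumerate_library()[::37]:
            formula = elemental_formula(rec.species)
            oracle = pyteomics_mass.calculate_mass(
                composition=pyteomics_mass.Composition(formula))
            assert monoisotopic_mass(formula) == pytest.approx(oracle, abs=5e-4)

    @given(
        a=st.dictionaries(st.sampled_from(["C", "H", "N", "O", "P"]),
                          st.integers(0, 50), max_size=5),
        b=st.dictionaries(st.sampled_from(["S", "Na", "K", "Cl"]),
                          st.integers(0, 50), max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_additivity(self, a, b):
        """Mass of a disjoint union is the sum of the parts' masses."""
        union = {**a, **b}
        total = monoisotopic_mass(a) + monoisotopic_mass(b)
        assert monoisotopic_mass(union) == pytest.approx(total, abs=1e-9)


class TestTransitions:
    def test_fa_pseudo_transition(self):
        (rec,) = transitions_for(parse_label("FA 18:0"), "-")
        assert rec.precursor_mz == pytest.approx(283.2643, abs=1e-3)
        assert rec.product_mz == rec.precursor_mz

    def test_pc_headgroup_fragment(self):
        (rec,) = transitions_for(parse_label("PC 34:1"), "+")
        assert rec.precursor_mz == pytest.approx(760.5851, abs=1e-3)
        assert rec.product_mz == pytest.approx(184.0733, abs=1e-3)

    def test_class_not_in_polarity_is_empty(self):
        assert transitions_for(parse_label("CE 18:1"), "-") == []
        assert transitions_for(parse_label("FA 18:0"), "+") == []

    def test_ch2_spacing(self):
        """Precursor m/z climbs by one CH2 (14.0157 Da) per carbon."""
        for cls in ("PC", "TG", "FA", "PS"):
            rng = CLASS_RULES[cls]["enumerate"]["carbons"]
            mzs = [
                transitions_for(LipidSpecies(cls, n, 1), CLASS_RULES[cls]["polarity"])[0].precursor_mz
                for n in range(rng[0] + 1, rng[0] + 6)
            ]
            diffs = np.diff(mzs)
            assert np.allclose(diffs, 14.0157, atol=1e-3)


class TestEnumerateLibrary:
    def test_rectangular_range_count(self):
        recs = enumerate_library(
            {"PC": {"carbons": (30, 39), "double_bonds": (0, 2)}})
        assert len(recs) == 30

    def test_empty_ranges(self):
        assert enumerate_library({"PC": {"carbons": (30, 29),
                                         "double_bonds": (0, 2)}}) == []
        assert enumerate_library({}) == []

    def test_default_panel_size(self):
        # full theoretical panel lands near the method's ~3800 transitions
        assert 3000 <= len(enumerate_library()) <= 4500

    def test_deterministic_and_order_stable(self):
        a = enumerate_library()
        b = enumerate_library()
        assert a == b

    def test_roundtrip_through_text(self, tmp_path):
        recs = enumerate_library(
            {"Cer": CLASS_RULES["Cer"]["enumerate"],
             "FA": {"carbons": (14, 20), "double_bonds": (0, 2)}})
        path = tmp_path / "transitions.tsv"
        write_transition_list(recs, path)
        assert read_transition_list(path) == recs


class TestLabelRoundtrip:
    @pytest.mark.parametrize("label", [
        "PC 34:1", "FA 18:0", "Cer d18:1/16:0", "SM d20:1/22:3",
        "HexCer d16:0/24:0", "TG 52:2",
    ])
    def test_roundtrip(self, label):
        assert parse_label(label).label == label


class TestRtPatternCheck:
    @staticmethod
    def _species(cls, pairs):
        return [LipidSpecies(cls, c, d) for c, d in pairs]

    def test_linear_trend_no_flags(self):
        sp = self._species("PC", [(30 + i, i % 3) for i in range(10)])
        rts = [2.0 + 0.3 * s.total_carbons - 0.5 * s.total_double_bonds for s in sp]
        assert rt_pattern_check("PC", list(zip(sp, rts))) == [False] * 10

    def test_single_shifted_point_flagged(self):
        sp = self._species("PC", [(30 + i, i % 3) for i in range(10)])
        rts = [2.0 + 0.3 * s.total_carbons - 0.5 * s.total_double_bonds
               + 0.01 * (i % 4) for i, s in enumerate(sp)]
        rts[4] += 5.0
        flags = rt_pattern_check("PC", list(zip(sp, rts)))
        assert flags[4] is True
        assert sum(flags) == 1

    def test_too_few_observations(self):
        sp = self._species("PC", [(30, 0), (32, 0), (34, 0)])
        assert rt_pattern_check("PC", list(zip(sp, [1.0, 2.0, 9.0]))) == [False] * 3

    def test_degenerate_design_warns(self):
        sp = self._species("PC", [(34, 1)] * 5)
        with pytest.warns(UserWarning, match="degenerate"):
            flags = rt_pattern_check("PC", list(zip(sp, [1, 2, 3, 4, 50.0])))
        assert flags == [False] * 5
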