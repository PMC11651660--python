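"""Formula parsing, exact/average masses, adduct shifts and peak matching."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from covashift.formula_mass import (
    CompoundRecord,
    ElementComposition,
    FormulaError,
    IonSpecies,
    MassPeak,
    PROTON_MASS,
    adduct_shift,
    average_mass,
    ion_mz,
    match_shift,
    monoisotopic_mass,
    parse_formula,
    predict_modified_masses,
)

# Published high-resolution MS calc values (formula, species, m/z).
# Two species labels are corrected for obvious misprints: the 366.0088
# value equals [M+H]+ of its formula and 356.0009 equals [M+Na]+.
HRMS_CALC = [
    ("C9H9F4NO3S2", "[M+H]+", 320.0033),
    ("C9H9F4NO5S2", "[M-H]-", 349.9786),
    ("C11H11F4NO6S2", "[M-H]-", 391.9891),
    ("C10H9F4NO6S2", "[M-H]-", 377.9735),
    ("C13H15F4NO6S2", "[M-H]-", 420.0204),
    ("C16H13F4NO6S2", "[M-H]-", 454.0048),
    ("C10H9F4NO4S2", "[M-H]-", 345.9836),
    ("C8H7F4NO4S2", "[M+H]+", 321.9825),
    ("C10H9F4NO5S2", "[M-H]-", 361.9786),
    ("C8H5F4NO4S2", "[M-H]-", 317.9523),
    ("C10H11F4NO3S2", "[M+Na]+", 356.0009),
    ("C10H11F4NO5S2", "[M+H]+", 366.0088),
    ("C12H13F4NO6S2", "[M-H]-", 406.0048),
    ("C8H11NO5S2", "[M-H]-", 264.0006),
    ("C11H12F4N2O5S2", "[M+H]+", 393.0197),
    ("C18H17F4N3O6S2", "[M+H]+", 512.0568),
    ("C19H19F4N3O7S2", "[M+Na]+", 564.0493),
    ("C15H12F4N2O6S2", "[M-H]-", 455.0000),
    ("C16H14F4N2O7S2", "[M-H]-", 485.0106),
    ("C19H28F3N3O5S2", "[M+H]+", 500.1495),
    ("C18H25F3N2O6S2", "[M+H]+", 487.1179),
    ("C22H33F3N2O6S2", "[M+H]+", 543.1805),
    ("C19H27F3N2O6S2", "[M+H]+", 501.1335),
    ("C23H35F3N2O6S2", "[M+H]+", 557.1961),
    ("C26H33F3N4O6S2", "[M-H]-", 617.1721),
    ("C23H28F3N3O6S2", "[M+H]+", 564.1444),
]

ELEMENT_SYMBOLS = ["C", "H", "N", "O", "F", "S", "Na", "Cl", "P"]


def comp(d):
    return ElementComposition(dict(d))


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C10H9F4NO6S2", {"C": 10, "H": 9, "F": 4, "N": 1, "O": 6, "S": 2}),
            ("C", {"C": 1}),
            ("C2H4O2", {"C": 2, "H": 4, "O": 2}),
            ("NaCl", {"Na": 1, "Cl": 1}),
            ("CHCl3", {"C": 1, "H": 1, "Cl": 3}),
        ],
    )
    def test_parses_counts(self, text, expected):
        assert parse_formula(text).counts == expected

    @pytest.mark.parametrize("bad", ["", "  ", "Xx4", "C0H4", "H-2", "12C", "C3h8"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_unknown_symbol_named_in_error(self):
        with pytest.raises(FormulaError, match="Qq"):
            parse_formula("C2Qq3")

    @given(
        st.dictionaries(
            st.sampled_from(ELEMENT_SYMBOLS),
            st.integers(min_value=1, max_value=60),
            min_size=1,
            max_size=6,
        )
    )
    @settings(deadline=None)
    def test_hill_string_round_trips(self, counts):
        c = comp(counts)
        assert parse_formula(c.hill()).counts == c.counts


class TestMasses:
    def test_lead_carbamate_neutral_monoisotopic(self):
        # the lead CAIX carbamate: published calculated MW 563.1372 Da
        m = monoisotopic_mass(parse_formula("C23H28F3N3O6S2"))
        assert round(m, 4) == 563.1372

    def test_single_atom_masses(self):
        assert monoisotopic_mass(comp({"H": 1})) == pytest.approx(1.007825, abs=1e-6)
        assert average_mass(comp({"C": 1})) == pytest.approx(12.011, abs=1e-3)

    def test_deprotonated_plus_proton_recovers_neutral(self):
        c = parse_formula("C8H5F4NO4S2")
        assert monoisotopic_mass(c) == pytest.approx(317.9523 + 1.00728, abs=5e-4)

    def test_average_mass_of_acetate_ester(self):
        assert average_mass(parse_formula("C10H9F4NO6S2")) == pytest.approx(
            379.30, abs=0.02
        )

    @pytest.mark.parametrize("formula,species,calc", HRMS_CALC)
    def test_published_hrms_values(self, formula, species, calc):
        """Every printed HRMS calc value reproduced to +-0.0005 Da."""
        assert ion_mz(parse_formula(formula), species) == pytest.approx(
            calc, abs=5e-4
        )

    @given(
        st.dictionaries(
            st.sampled_from(ELEMENT_SYMBOLS),
            st.integers(min_value=1, max_value=40),
            min_size=1,
            max_size=6,
        ),
        st.dictionaries(
            st.sampled_from(ELEMENT_SYMBOLS),
            st.integers(min_value=1, max_value=40),
            min_size=1,
            max_size=6,
        ),
    )
    @settings(deadline=None)
    def test_mass_additivity(self, a, b):
        ca, cb = comp(a), comp(b)
        for mass in (monoisotopic_mass, average_mass):
            assert mass(ca + cb) == pytest.approx(mass(ca) + mass(cb), abs=1e-9)

    @given(
        st.dictionaries(
            st.sampled_from(ELEMENT_SYMBOLS),
            st.integers(min_value=1, max_value=40),
            min_size=1,
            max_size=6,
        )
    )
    @settings(deadline=None)
    def test_protonated_deprotonated_gap_is_two_protons(self, counts):
        c = comp(counts)
        gap = ion_mz(c, "[M+H]+") - ion_mz(c, "[M-H]-")
        assert gap == pytest.approx(2 * 1.00728, abs=1e-5)
        assert gap == pytest.approx(2 * PROTON_MASS, abs=1e-12)

    @pytest.mark.parametrize("formula", sorted({f for f, _, _ in HRMS_CALC}))
    def test_monoisotopic_agrees_with_pyteomics(self, formula):
        """Independent cross-check of the packaged isotope table."""
        pmass = pytest.importorskip("pyteomics.mass")
        c = parse_formula(formula)
        assert monoisotopic_mass(c) == pytest.approx(
            pmass.calculate_mass(formula=formula), abs=1e-4
        )

    def test_monoisotopic_below_average_for_chnofs(self):
        c = parse_formula("C23H28F3N3O6S2")
        assert monoisotopic_mass(c) < average_mass(c)

    def test_unsupported_species_rejected(self):
        with pytest.raises(ValueError):
            ion_mz(comp({"C": 1}), "[M+K]+")
        with pytest.raises(ValueError):
            IonSpecies("[M+H]+", -1)


class TestAdductShift:
    def test_carbamate_lead_shift(self):
        # compound minus phenylcarbamate leaving group: 426.0895 Da
        rec = CompoundRecord(
            "22", parse_formula("C23H28F3N3O6S2"),
            parse_formula("C7H7NO2"), "carbamate",
        )
        mono, avg = adduct_shift(rec)
        assert round(mono, 4) == 426.0895
        assert avg == pytest.approx(426.5, abs=0.2)

    def test_acetate_ester_shift_rounds_to_319(self):
        rec = CompoundRecord(
            "12", parse_formula("C10H9F4NO6S2"), parse_formula("C2H4O2"), "ester"
        )
        mono, avg = adduct_shift(rec)
        assert avg == pytest.approx(319.2, abs=0.1)
        assert round(avg) == 319

    def test_vinylsulfone_adds_whole_molecule(self):
        rec = CompoundRecord("15", parse_formula("C8H5F4NO4S2"),
                             warhead_class="vinylsulfone")
        mono, avg = adduct_shift(rec)
        assert mono == pytest.approx(monoisotopic_mass(rec.formula))
        assert avg == pytest.approx(average_mass(rec.formula))

    def test_shift_plus_leaving_group_recovers_compound(self):
        rec = CompoundRecord(
            "22", parse_formula("C23H28F3N3O6S2"),
            parse_formula("C7H7NO2"), "carbamate",
        )
        mono, avg = adduct_shift(rec)
        assert mono + monoisotopic_mass(rec.leaving_group) == pytest.approx(
            monoisotopic_mass(rec.formula), abs=1e-9
        )
        assert avg + average_mass(rec.leaving_group) == pytest.approx(
            average_mass(rec.formula), abs=1e-9
        )

    def test_leaving_group_must_be_subcomposition(self):
        with pytest.raises(FormulaError):
            CompoundRecord(
                "x", parse_formula("C2H4O2"), parse_formula("C7H7NO2"), "ester"
            )


class TestPeakMatching:
    def test_predict_modified_masses_arithmetic(self):
        out = predict_modified_masses(29574.69, 319.25, 2)
        assert out == pytest.approx([29574.69, 29893.94, 30213.19])
        assert predict_modified_masses(28060.32, 426.4, 1) == pytest.approx(
            [28060.32, 28486.72]
        )

    def test_match_recovers_singly_and_doubly_modified(self):
        # observed deconvoluted masses for an unmodified/+1/+2 pattern
        cand = CompoundRecord(
            "12", parse_formula("C10H9F4NO6S2"), parse_formula("C2H4O2"), "ester"
        )
        peaks = [MassPeak(29574.69), MassPeak(29893.97), MassPeak(30213.0)]
        out = match_shift(peaks, base=29574.69, candidates=[cand], tol=1.0,
                          max_sites=2)
        assert not out[0].matched  # base peak: zero shift never matches
        assert out[1].candidate_id == "12"
        assert out[1].error_da == pytest.approx(29893.97 - 29574.69 - 319.2446,
                                                abs=0.01)
        assert out[2].candidate_id == "12 x2"

    def test_exact_shift_gives_zero_error(self):
        cand = CompoundRecord(
            "12", parse_formula("C10H9F4NO6S2"), parse_formula("C2H4O2"), "ester"
        )
        shift = adduct_shift(cand)[1]
        out = match_shift([MassPeak(30000.0 + shift)], 30000.0, [cand], tol=0.5)
        assert out[0].matched and out[0].error_da == pytest.approx(0.0, abs=1e-9)

    def test_out_of_tolerance_unmatched_and_empty_candidates_error(self):
        cand = CompoundRecord("15", parse_formula("C8H5F4NO4S2"),
                              warhead_class="vinylsulfone")
        out = match_shift([MassPeak(30000.0 + 200.0)], 30000.0, [cand], tol=1.0)
        assert not out[0].matched and math.isnan(out[0].predicted_shift)
        with pytest.raises(ValueError):
            match_shift([MassPeak(30000.0)], 30000.0, [], tol=1.0)
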