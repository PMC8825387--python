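"""Mass arithmetic, the moiety database and signature-pair construction."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgms.chem import (
    WATER,
    Formula,
    FormulaError,
    Moiety,
    RGComposition,
    adduct_mz,
    composition_mass,
    composition_mz,
    default_database,
    deprotonated_mz,
    monoisotopic_mass,
    signature_pair_table,
)

SUGAR_RESIDUES = {"pentose": 132.0423, "deoxyhexose": 146.0579, "hexose": 162.0528}


class TestFormula:
    def test_parse_hill_notation(self):
        f = Formula.parse("C16H32O3")
        assert f.as_dict() == {"C": 16, "H": 32, "O": 3}
        assert str(f) == "C16H32O3"

    def test_implicit_single_count(self):
        assert Formula.parse("H2O").as_dict() == {"H": 2, "O": 1}

    @pytest.mark.parametrize("bad", ["", "C16H32Q3", "16CH", "C-2"])
    def test_malformed_raises(self, bad):
        with pytest.raises(FormulaError):
            Formula.parse(bad)

    def test_subtraction_never_negative(self):
        with pytest.raises(FormulaError):
            Formula.parse("CH4") - Formula.parse("C2H4")

    @given(
        a=st.dictionaries(st.sampled_from("CHON"), st.integers(1, 40),
                          min_size=1),
        b=st.dictionaries(st.sampled_from("CHON"), st.integers(1, 40),
                          min_size=1),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_add_then_subtract_roundtrip(self, a, b):
        fa, fb = Formula.from_counts(a), Formula.from_counts(b)
        assert (fa + fb) - fb == fa
        assert abs((fa + fb).mass - fa.mass - fb.mass) < 1e-9


class TestMasses:
    # hand-summed from monoisotopic atomic masses
    @pytest.mark.parametrize("formula, expected", [
        ("C16H32O3", 272.2351),
        ("H2O", 18.0106),
        ("C62H104O27", 1280.6765),
    ])
    def test_monoisotopic_mass(self, formula, expected):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("formula, expected", [
        ("C16H32O3", 271.2279),   # jalapinolic acid
        ("C15H30O3", 257.2122),
        ("C16H32O4", 287.2228),
        ("C5H10O2", 101.0608),    # five-carbon aliphatic acids
    ])
    def test_deprotonated_mz(self, formula, expected):
        assert deprotonated_mz(formula) == pytest.approx(expected, abs=5e-4)

    def test_deprotonation_requires_hydrogen(self):
        with pytest.raises(FormulaError):
            deprotonated_mz("CO2")

    def test_unknown_element_named_in_error(self):
        with pytest.raises(FormulaError, match="Xx"):
            monoisotopic_mass("Xx2O")

    @pytest.mark.parametrize("neutral, adduct, expected", [
        (1022.5662, "formate", 1067.5644),
        (1280.6765, "deprotonated", 1279.6692),
        (100.0, "deprotonated", 98.992724),
    ])
    def test_adduct_mz(self, neutral, adduct, expected):
        assert adduct_mz(neutral, adduct) == pytest.approx(expected, abs=5e-4)

    def test_adduct_errors(self):
        with pytest.raises(ValueError):
            adduct_mz(100.0, "sodiated")
        with pytest.raises(ValueError):
            adduct_mz(-1.0, "formate")


class TestDatabase:
    def test_default_counts(self, db):
        assert len(db.sugars) == 3
        assert len(db.hydroxyacyls) == 10
        assert len(db.acyls) == 22

    def test_residue_mass_formula_roundtrip(self, db):
        for m in db.all_moieties():
            assert m.residue_mass == pytest.approx(monoisotopic_mass(m.formula),
                                                   abs=1e-6)

    def test_yaml_roundtrip(self, db, tmp_path):
        path = tmp_path / "db.yaml"
        db.to_yaml(path)
        from rgms.chem import MoietyDatabase
        loaded = MoietyDatabase.from_yaml(path)
        assert {m.name for m in loaded.all_moieties()} == \
               {m.name for m in db.all_moieties()}
        assert loaded.frequent_acyls == db.frequent_acyls

    def test_unknown_moiety_class_rejected(self):
        with pytest.raises(ValueError):
            Moiety("x", "steroid", Formula.parse("C2H4O2"))


class TestSignaturePairs:
    def test_thirty_pairs(self, db):
        assert len(signature_pair_table(db)) == 30

    @pytest.mark.parametrize("ha, sugar, acyl_mz, combined_mz", [
        ("C16-OH", "deoxyhexose", 271.2279, 417.2858),
        ("C16-OH", "pentose", 271.2279, 403.2702),
        ("C15-OH", "hexose", 257.2122, 419.2650),
    ])
    def test_known_pairs(self, db, ha, sugar, acyl_mz, combined_mz):
        pair = next(p for p in signature_pair_table(db)
                    if p.hydroxyacyl == ha and p.sugar_class == sugar)
        assert pair.acyl_mz == pytest.approx(acyl_mz, abs=5e-4)
        assert pair.combined_mz == pytest.approx(combined_mz, abs=5e-4)

    def test_pair_gap_is_a_sugar_residue(self, db):
        residues = set(SUGAR_RESIDUES.values())
        for p in signature_pair_table(db):
            gap = p.combined_mz - p.acyl_mz
            assert any(abs(gap - r) < 1e-3 for r in residues)


class TestCompositionMass:
    def test_tricolorin_a(self, db):
        comp = RGComposition.make({"deoxyhexose": 3, "hexose": 1}, "C16-OH",
                                  ("C5", "C5"), "closed", "formate")
        assert composition_mass(comp, db) == pytest.approx(1022.5662, abs=5e-4)
        assert composition_mz(comp, db) == pytest.approx(1067.5644, abs=5e-4)

    def test_dichondrin_formula_assembly(self, db):
        # one pseudo-acyl carrying the full decorating-acyl formula C22H32O6:
        # the neutral composition must equal the published formula C62H104O27
        db2 = default_database()
        db2.acyls["dichondrin_acyls"] = Moiety(
            "dichondrin_acyls", "acyl", Formula.parse("C22H32O6"))
        comp = RGComposition.make({"deoxyhexose": 2, "hexose": 2}, "C16-OH",
                                  ("dichondrin_acyls",), "open", "deprotonated")
        assert composition_mass(comp, db2) == pytest.approx(
            monoisotopic_mass("C62H104O27"), abs=1e-6)
        assert composition_mz(comp, db2) == pytest.approx(1279.6692, abs=5e-4)

    def test_minimal_composition(self, db):
        comp = RGComposition.make({"hexose": 1}, "C16-OH", (), "open")
        # brute-force formula assembly: C22H42O8
        assert composition_mass(comp, db) == pytest.approx(
            monoisotopic_mass("C22H42O8"), abs=1e-6)
        assert composition_mass(comp, db) == pytest.approx(434.2880, abs=5e-4)

    def test_zero_sugars_rejected(self, db):
        comp = RGComposition(sugars=(), hydroxyacyl="C16-OH", acyls=())
        with pytest.raises(ValueError):
            composition_mass(comp, db)

    def test_sugar_additivity(self, db):
        base = RGComposition.make({"deoxyhexose": 2}, "C16-OH", ("C5",), "closed")
        for cls_, residue in SUGAR_RESIDUES.items():
            counts = dict(base.sugar_counts)
            counts[cls_] = counts.get(cls_, 0) + 1
            bigger = RGComposition.make(counts, "C16-OH", ("C5",), "closed")
            assert composition_mass(bigger, db) - composition_mass(base, db) == \
                   pytest.approx(residue, abs=1e-3)

    def test_open_closed_differ_by_water(self, db):
        for acyls in [(), ("tiglic",), ("C5", "HMBA")]:
            open_ = RGComposition.make({"deoxyhexose": 3}, "C16-OH", acyls, "open")
            closed = RGComposition.make({"deoxyhexose": 3}, "C16-OH", acyls, "closed")
            assert composition_mass(open_, db) - composition_mass(closed, db) == \
                   pytest.approx(WATER, abs=1e-9)

    def test_key_roundtrip(self):
        comp = RGComposition.make({"deoxyhexose": 3, "hexose": 1}, "C16-OH",
                                  ("C5", "C5"), "closed", "formate")
        assert RGComposition.from_key(comp.key()) == comp


def test_sugar_class_cartesian_structure(db):
    """Every (hydroxyacyl, sugar class) combination appears exactly once."""
    pairs = signature_pair_table(db)
    combos = {(p.hydroxyacyl, p.sugar_class) for p in pairs}
    assert len(combos) == len(pairs) == 30
    assert combos == set(itertools.product(db.hydroxyacyls,
                                           ("pentose", "deoxyhexose", "hexose")))
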