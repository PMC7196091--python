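"""Molecular-formula construction, accurate masses and search lists."""

import numpy as np
import pytest

from lipidflow import chem
from lipidflow.chem import (
    ADDUCTS,
    ATOMIC_MASSES,
    ELECTRON_MASS,
    Adduct,
    FattyAcid,
    LipidSpecies,
    MolecularFormula,
    adduct_mz,
    build_fa_search_list,
    build_search_list,
    enumerate_isobars,
    fa_fragment_mz,
    formula_of,
    monoisotopic_mass,
    parse_species,
    read_search_list,
    write_search_list,
)

# independent mass table for brute-force oracles (NIST values, typed in
# separately from the production table)
_ORACLE_MASS = {
    "H": 1.007825032,
    "C": 12.0,
    "N": 14.003074005,
    "O": 15.994914620,
    "P": 30.973761998,
    "Na": 22.989769282,
}
_ORACLE_ELECTRON = 5.48579909e-4


def oracle_mass(formula):
    return sum(n * _ORACLE_MASS[el] for el, n in formula.items())


def test_atomic_mass_table_standard_values():
    expected = {"H": 1.0078250, "C": 12.0, "N": 14.0030740, "O": 15.9949146,
                "P": 30.9737615, "Na": 22.9897693}
    for el, m in expected.items():
        assert ATOMIC_MASSES[el] == pytest.approx(m, abs=1e-6)
    assert ELECTRON_MASS == pytest.approx(0.0005486, abs=1e-7)


@pytest.mark.parametrize(
    "shorthand, hill",
    [
        ("PC(35:2)", "C43H82NO8P"),
        ("PE(38:2)", "C43H82NO8P"),  # shares a formula with PC(35:2)
        ("PC(34:1)", "C42H82NO8P"),
        ("PC(36:5)", "C44H78NO8P"),
    ],
)
def test_formula_of_examples(shorthand, hill):
    assert formula_of(parse_species(shorthand)).hill() == hill


def test_pc_pe_isobar_identity_over_grid():
    # diacyl PC(c:d) and PE(c+3:d) are exact isobars for all chain totals
    for c in range(28, 45):
        for d in range(0, 9):
            pc = formula_of(LipidSpecies("PC", c, d))
            pe = formula_of(LipidSpecies("PE", c + 3, d))
            assert pc == pe


def test_unsupported_class_is_loud():
    with pytest.raises(ValueError, match="backbone table"):
        LipidSpecies("XX", 34, 1)


@pytest.mark.parametrize(
    "formula, mass",
    [
        (MolecularFormula(C=43, H=82, N=1, O=8, P=1), 771.5778),
        (MolecularFormula(), 0.0),
        (MolecularFormula(H=2, O=1), 18.0106),
    ],
)
def test_monoisotopic_mass_examples(formula, mass):
    assert monoisotopic_mass(formula) == pytest.approx(mass, abs=1e-4)


def test_unknown_element_named_in_error():
    with pytest.raises(KeyError, match="Xx"):
        monoisotopic_mass(MolecularFormula(Xx=1))


@pytest.mark.parametrize(
    "shorthand, adduct, mz",
    [
        ("PC(35:2)", "+H", 772.5851),
        ("PE(38:2)", "+H", 772.5851),
        ("PC(36:5)", "+HCOO", 824.5447),
        ("PC(34:1)", "+H", 760.5851),
    ],
)
def test_adduct_mz_reproduces_printed_values(shorthand, adduct, mz):
    got = adduct_mz(formula_of(parse_species(shorthand)), ADDUCTS[adduct])
    assert abs(got - mz) / mz * 1e6 < 5  # within 5 ppm


def test_adduct_deltas_electron_corrected():
    assert ADDUCTS["+H"].mass_delta == pytest.approx(1.0072765, abs=1e-5)
    assert ADDUCTS["+HCOO"].mass_delta == pytest.approx(44.9982029, abs=1e-5)
    assert ADDUCTS["-H"].mass_delta == pytest.approx(-1.0072765, abs=1e-5)


def test_adduct_charge_sign_enforced():
    with pytest.raises(ValueError):
        Adduct("+X", "positive", 1.0, 0)
    with pytest.raises(ValueError):
        Adduct("-X", "negative", -1.0, 1)


@pytest.mark.parametrize(
    "fa, mz",
    [
        (FattyAcid(16, 0), 255.2330),
        (FattyAcid(22, 6), 327.2330),
        (FattyAcid(14, 0), 227.2017),
        (FattyAcid(17, 0), 269.2486),  # odd-chain residues are observable too
    ],
)
def test_fa_carboxylate_anion_mz(fa, mz):
    got = fa_fragment_mz(fa)
    assert abs(got - mz) / mz * 1e6 < 5


def test_adduct_mz_agrees_with_bruteforce_oracle():
    rng = np.random.default_rng(11)
    classes = sorted(chem.LIPID_CLASS_BASES)
    names = sorted(ADDUCTS)
    for _ in range(100):
        cls = classes[rng.integers(len(classes))]
        c = int(rng.integers(24, 50))
        d = int(rng.integers(0, 7))
        ad = ADDUCTS[names[rng.integers(len(names))]]
        f = formula_of(LipidSpecies(cls, c, d))
        production = adduct_mz(f, ad)
        # independent route: separate mass table, explicit ion formula
        ion = dict(f)
        if ad.name == "+H":
            ion["H"] = ion.get("H", 0) + 1
            oracle = oracle_mass(ion) - _ORACLE_ELECTRON
        elif ad.name == "+Na":
            ion["Na"] = ion.get("Na", 0) + 1
            oracle = oracle_mass(ion) - _ORACLE_ELECTRON
        elif ad.name == "+NH4":
            ion["N"] = ion.get("N", 0) + 1
            ion["H"] = ion.get("H", 0) + 4
            oracle = oracle_mass(ion) - _ORACLE_ELECTRON
        elif ad.name == "-H":
            ion["H"] -= 1
            oracle = oracle_mass(ion) + _ORACLE_ELECTRON
        elif ad.name == "+HCOO":
            ion["C"] += 1
            ion["H"] += 1
            ion["O"] = ion.get("O", 0) + 2
            oracle = oracle_mass(ion) + _ORACLE_ELECTRON
        else:  # +CH3COO
            ion["C"] += 2
            ion["H"] += 3
            ion["O"] = ion.get("O", 0) + 2
            oracle = oracle_mass(ion) + _ORACLE_ELECTRON
        assert abs(production - oracle) < 1e-4


def test_formula_arithmetic_never_negative():
    a = MolecularFormula(C=2, H=4)
    b = MolecularFormula(C=1, H=5)
    with pytest.raises(ValueError):
        _ = a - b
    assert (a + b).hill() == "C3H9"
    with pytest.raises(ValueError):
        MolecularFormula(C=-1)


# ---------------------------------------------------------------------------
# Search lists
# ---------------------------------------------------------------------------

def test_search_list_cartesian_count():
    sl = build_search_list(["PC"], (34, 36), (0, 6), "positive", adducts=["+H"])
    assert len(sl) == 21  # 3 carbon values x 7 db values


def test_cid_list_is_fa_anions_only():
    sl = build_fa_search_list((12, 24), (0, 6))
    assert sl.mode == "negative-CID"
    assert all(isinstance(e.species, FattyAcid) for e in sl)


def test_scan_range_excludes_out_of_range():
    sl = build_search_list(["TG"], (78, 82), (0, 0), "positive", adducts=["+NH4"])
    assert len(sl) == 0  # all beyond m/z 1200
    sl2 = build_search_list(["PC"], (30, 40), (0, 6), "positive")
    assert all(150 <= e.mz <= 1200 for e in sl2)


def test_search_list_deterministic_and_duplicate_free():
    sl = build_search_list(["PC", "PE"], (30, 40), (0, 4), "negative")
    mzs = [e.mz for e in sl]
    assert mzs == sorted(mzs)
    keys = [(str(e.species), e.adduct.name) for e in sl]
    assert len(keys) == len(set(keys))


def test_search_list_mz_roundtrip_from_formula():
    sl = build_search_list(["PC", "TG", "CE"], (40, 48), (0, 3), "positive")
    for e in sl:
        assert adduct_mz(formula_of(e.species), e.adduct) == pytest.approx(e.mz)


def test_search_list_tsv_roundtrip(tmp_path):
    sl = build_search_list(["PC"], (34, 36), (0, 2), "positive")
    p = tmp_path / "list.tsv"
    write_search_list(sl, p)
    back = read_search_list(p)
    assert back.mode == "positive"
    assert [e.name for e in back] == [e.name for e in sl]
    assert np.allclose([e.mz for e in back], [round(e.mz, 4) for e in sl])


# ---------------------------------------------------------------------------
# Isobar enumeration
# ---------------------------------------------------------------------------

def test_isobars_at_772_5851_contain_pc_and_pe():
    space = build_search_list(["PC", "PE"], (30, 42), (0, 6), "positive",
                              adducts=["+H"])
    hits = enumerate_isobars(772.5851, 5.0, space)
    names = {f"{s}{a.name}" for s, a, _, _ in hits}
    assert "PC(35:2)+H" in names and "PE(38:2)+H" in names


def test_isobars_at_824_5447_formate_and_acetate():
    space = build_search_list(["PC"], (30, 40), (0, 6), "negative",
                              adducts=["+HCOO", "+CH3COO"])
    hits = enumerate_isobars(824.5447, 5.0, space)
    names = {f"{s}{a.name}" for s, a, _, _ in hits}
    assert "PC(36:5)+HCOO" in names and "PC(35:5)+CH3COO" in names


def test_isobars_zero_tolerance_on_jittered_input():
    space = build_search_list(["PC"], (34, 36), (0, 2), "positive")
    assert enumerate_isobars(760.5851 * (1 + 2e-6), 0.0, space) == []


def test_isobar_enumeration_monotone_in_tolerance():
    space = build_search_list(["PC", "PE", "PS"], (30, 42), (0, 6), "negative")
    rng = np.random.default_rng(3)
    for _ in range(20):
        mz = float(rng.uniform(600, 900))
        t1, t2 = sorted(rng.uniform(0, 20, size=2))
        small = {(str(s), a.name) for s, a, _, _ in enumerate_isobars(mz, t1, space)}
        big = {(str(s), a.name) for s, a, _, _ in enumerate_isobars(mz, t2, space)}
        assert small <= big


# ---------------------------------------------------------------------------
# Species parsing / invariants
# ---------------------------------------------------------------------------

def test_parse_species_with_sn_composition():
    sp = parse_species("PC(14:0/22:6)")
    assert sp.name == "PC(36:6)"
    assert sp.sn_composition == (FattyAcid(14, 0), FattyAcid(22, 6))


def test_sn_composition_must_sum_to_totals():
    with pytest.raises(ValueError):
        LipidSpecies("PC", 36, 6,
                     sn_composition=(FattyAcid(14, 0), FattyAcid(20, 6)))


def test_double_bond_bound():
    with pytest.raises(ValueError):
        LipidSpecies("PC", 30, 16)
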