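"""Lipid nomenclature, molecular formulas and accurate-mass arithmetic.

This module is the mass-arithmetic core of the pipeline: it builds neutral
molecular formulas for lipid species named in the ``Class(carbons:double
bonds)`` shorthand, computes monoisotopic masses and adduct m/z values
(electron-corrected, singly charged), and generates the per-mode search
lists that drive signal extraction from direct-infusion spectra.

Diacyl glycerophospholipids are constructed from a per-class "base" formula
(the head group + glycerophosphate backbone with both acyl chains reduced to
their ester carbonyls removed) plus the acyl contribution ``C_c H_{2c-2d}``
for ``c`` total acyl carbons and ``d`` double bonds.  The PC(c:d) /
PE(c+3:d) isobar identity falls straight out of this construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

__all__ = [
    "ATOMIC_MASSES",
    "ELECTRON_MASS",
    "MolecularFormula",
    "FattyAcid",
    "LipidSpecies",
    "Adduct",
    "ADDUCTS",
    "DEFAULT_MODE_ADDUCTS",
    "SearchEntry",
    "SearchList",
    "LIPID_CLASS_BASES",
    "TWO_CHAIN_CLASSES",
    "formula_of",
    "monoisotopic_mass",
    "adduct_mz",
    "fa_fragment_mz",
    "build_search_list",
    "build_fa_search_list",
    "enumerate_isobars",
    "parse_species",
    "write_search_list",
    "read_search_list",
    "SCAN_RANGE",
]

# ---------------------------------------------------------------------------
# Atomic masses (monoisotopic, Da; CODATA/IUPAC values)
# ---------------------------------------------------------------------------

ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "S": 31.97207100,
}

ELECTRON_MASS: float = 0.00054857990

#: Instrument full-scan window for singly charged species (m/z).
SCAN_RANGE: Tuple[float, float] = (150.0, 1200.0)


# ---------------------------------------------------------------------------
# Molecular formulas
# ---------------------------------------------------------------------------

class MolecularFormula(dict):
    """Element -> count mapping with element-wise arithmetic.

    Counts are non-negative integers; subtraction that would drive a count
    negative raises ``ValueError`` rather than silently clipping.
    """

    def __init__(self, counts: Optional[Dict[str, int]] = None, **kw: int):
        super().__init__()
        merged = dict(counts or {})
        merged.update(kw)
        for el, n in merged.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
            if n:
                self[el] = int(n)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return MolecularFormula(out)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) - n
            if out[el] < 0:
                raise ValueError(
                    f"subtraction yields negative count for element {el}"
                )
        return MolecularFormula(out)

    def __mul__(self, k: int) -> "MolecularFormula":
        return MolecularFormula({el: n * k for el, n in self.items()})

    __rmul__ = __mul__

    def hill(self) -> str:
        """Hill-notation string (C, H, then alphabetical)."""
        parts = []
        for el in ["C", "H"] + sorted(e for e in self if e not in ("C", "H")):
            n = self.get(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts) or "(empty)"


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Sum of count x monoisotopic atomic mass over the formula, in Da."""
    total = 0.0
    for el, n in formula.items():
        try:
            total += n * ATOMIC_MASSES[el]
        except KeyError:
            raise KeyError(f"unknown element in formula: {el}") from None
    return total


# ---------------------------------------------------------------------------
# Lipid species
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class FattyAcid:
    """A fatty-acyl residue: total carbons and double bonds (e.g. 16:0)."""

    carbons: int
    double_bonds: int

    def __post_init__(self):
        if self.carbons < 2:
            raise ValueError(f"fatty acid needs >=2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("negative double-bond count")

    def __str__(self) -> str:
        return f"FA({self.carbons}:{self.double_bonds})"


#: Per-class base formula: species formula = base + C_c H_{2c-2d}.
#: Bases are derived from reference standards (POPC C42H82NO8P, POPE
#: C39H76NO8P, POPS C40H76NO10P, POPG C40H77O10P, POPI C43H81O13P,
#: POPA C37H71O8P, SM(d34:1) C39H79N2O6P, LPC(16:0) C24H50NO7P,
#: LPE(16:0) C21H44NO7P, CE(18:1) C45H78O2, tripalmitin C51H98O6,
#: DG(34:1) C37H70O5) by subtracting the acyl contribution.
LIPID_CLASS_BASES: Dict[str, MolecularFormula] = {
    "PC": MolecularFormula(C=8, H=16, N=1, O=8, P=1),
    "PE": MolecularFormula(C=5, H=10, N=1, O=8, P=1),
    "PS": MolecularFormula(C=6, H=10, N=1, O=10, P=1),
    "PG": MolecularFormula(C=6, H=11, O=10, P=1),
    "PI": MolecularFormula(C=9, H=15, O=13, P=1),
    "PA": MolecularFormula(C=3, H=5, O=8, P=1),
    "SM": MolecularFormula(C=5, H=13, N=2, O=6, P=1),
    "LPC": MolecularFormula(C=8, H=18, N=1, O=7, P=1),
    "LPE": MolecularFormula(C=5, H=12, N=1, O=7, P=1),
    "CE": MolecularFormula(C=27, H=44, O=2),
    "TG": MolecularFormula(C=3, H=2, O=6),
    "DG": MolecularFormula(C=3, H=4, O=5),
    # Ether (O-) lipids: one ester oxygen replaced by an ether linkage
    # (base - O + H2); plasmalogens (P-) carry the vinyl-ether double bond
    # on top of that (base - O), which is not counted in the d total.
    "PC-O": MolecularFormula(C=8, H=18, N=1, O=7, P=1),
    "PC-P": MolecularFormula(C=8, H=16, N=1, O=7, P=1),
    "PE-O": MolecularFormula(C=5, H=12, N=1, O=7, P=1),
    "PE-P": MolecularFormula(C=5, H=10, N=1, O=7, P=1),
}

#: Classes carrying two acyl/alkyl chains, eligible for isoform assignment.
TWO_CHAIN_CLASSES = frozenset(
    ["PC", "PE", "PS", "PG", "PI", "PA", "DG", "PC-O", "PC-P", "PE-O", "PE-P"]
)

#: Phosphorus-containing classes (visible to 31P NMR).
PHOSPHOLIPID_CLASSES = frozenset(
    c for c, f in LIPID_CLASS_BASES.items() if f.get("P", 0) > 0
)


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid identity at class + total carbons:double-bonds level.

    ``sn_composition`` optionally resolves the two chains (unordered here;
    sn-position is not inferred by this pipeline).
    """

    lipid_class: str
    carbons: int
    double_bonds: int
    sn_composition: Optional[Tuple[FattyAcid, ...]] = None

    def __post_init__(self):
        if self.lipid_class not in LIPID_CLASS_BASES:
            raise ValueError(
                f"class not in backbone table: {self.lipid_class!r} "
                f"(supported: {sorted(LIPID_CLASS_BASES)})"
            )
        if self.carbons <= 0:
            raise ValueError("carbons must be positive")
        if not (0 <= self.double_bonds <= self.carbons / 2):
            raise ValueError(
                f"double bonds {self.double_bonds} outside [0, carbons/2]"
            )
        if self.sn_composition is not None:
            sn = tuple(sorted(self.sn_composition))
            object.__setattr__(self, "sn_composition", sn)
            if sum(f.carbons for f in sn) != self.carbons or sum(
                f.double_bonds for f in sn
            ) != self.double_bonds:
                raise ValueError("sn composition does not sum to totals")

    def __str__(self) -> str:
        if self.sn_composition:
            chains = "/".join(
                f"{f.carbons}:{f.double_bonds}" for f in self.sn_composition
            )
            return f"{self.lipid_class}({chains})"
        return f"{self.lipid_class}({self.carbons}:{self.double_bonds})"

    @property
    def name(self) -> str:
        return f"{self.lipid_class}({self.carbons}:{self.double_bonds})"


def parse_species(text: str) -> LipidSpecies:
    """Parse ``'PC(36:5)'`` or ``'PC(14:0/22:6)'`` shorthand."""
    text = text.strip()
    if "(" not in text or not text.endswith(")"):
        raise ValueError(f"cannot parse lipid shorthand: {text!r}")
    cls, body = text[:-1].split("(", 1)
    if "/" in body:
        fas = tuple(
            FattyAcid(int(c), int(d))
            for c, d in (p.split(":") for p in body.split("/"))
        )
        return LipidSpecies(
            cls,
            sum(f.carbons for f in fas),
            sum(f.double_bonds for f in fas),
            sn_composition=fas,
        )
    c, d = body.split(":")
    return LipidSpecies(cls, int(c), int(d))


def formula_of(species: LipidSpecies) -> MolecularFormula:
    """Neutral molecular formula of a lipid species.

    PC(c:d) and PE(c+3:d) yield identical formulas — the diacyl PC/PE
    isobar identity exploited when disambiguating assignments.
    """
    base = LIPID_CLASS_BASES[species.lipid_class]
    c, d = species.carbons, species.double_bonds
    return base + MolecularFormula(C=c, H=2 * c - 2 * d)


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Adduct:
    """An ionised form: name, polarity, signed electron-corrected mass delta.

    ``mass_delta`` is what is added to the neutral monoisotopic mass to get
    the ion mass, so e.g. +H is the proton mass (H minus one electron).
    """

    name: str
    polarity: str  # "positive" | "negative"
    mass_delta: float
    charge: int

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if self.polarity == "positive" and self.charge <= 0:
            raise ValueError("positive adduct must carry positive charge")
        if self.polarity == "negative" and self.charge >= 0:
            raise ValueError("negative adduct must carry negative charge")


_H, _C, _N, _O = (ATOMIC_MASSES[e] for e in ("H", "C", "N", "O"))

ADDUCTS: Dict[str, Adduct] = {
    "+H": Adduct("+H", "positive", _H - ELECTRON_MASS, 1),
    "+Na": Adduct("+Na", "positive", ATOMIC_MASSES["Na"] - ELECTRON_MASS, 1),
    "+NH4": Adduct("+NH4", "positive", _N + 4 * _H - ELECTRON_MASS, 1),
    "-H": Adduct("-H", "negative", -(_H - ELECTRON_MASS), -1),
    "+HCOO": Adduct("+HCOO", "negative", _C + _H + 2 * _O + ELECTRON_MASS, -1),
    "+CH3COO": Adduct(
        "+CH3COO", "negative", 2 * _C + 3 * _H + 2 * _O + ELECTRON_MASS, -1
    ),
}

#: Default adduct sets per acquisition mode.  TGs are seen as sodium or
#: ammonium adducts in positive mode; negative mode uses deprotonation and
#: formate/acetate adduction (PCs only ionise negatively via the latter).
DEFAULT_MODE_ADDUCTS: Dict[str, Tuple[str, ...]] = {
    "positive": ("+H", "+Na", "+NH4"),
    "negative": ("-H", "+HCOO", "+CH3COO"),
}

MODES = ("positive", "negative", "negative-CID")


def adduct_mz(formula: MolecularFormula, adduct: Adduct) -> float:
    """m/z of a singly charged adduct ion of the neutral formula."""
    if adduct.charge == 0:
        raise ValueError("adduct charge must be nonzero")
    if abs(adduct.charge) != 1:
        raise ValueError("only singly charged species are supported")
    mz = (monoisotopic_mass(formula) + adduct.mass_delta) / abs(adduct.charge)
    if mz <= 0:
        raise ValueError("non-positive m/z")
    return mz


def fa_fragment_mz(fa: FattyAcid) -> float:
    """m/z of the fatty-acid carboxylate anion [CcH(2c-2d-1)O2]-.

    These are the fragment ions produced by in-source CID of phospholipids
    in negative mode, from which the fatty-acid profile is read.
    """
    c, d = fa.carbons, fa.double_bonds
    formula = MolecularFormula(C=c, H=2 * c - 2 * d - 1, O=2)
    return monoisotopic_mass(formula) + ELECTRON_MASS


# ---------------------------------------------------------------------------
# Search lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchEntry:
    """One search-list row: a species (or FA fragment) + adduct + m/z."""

    species: object  # LipidSpecies or FattyAcid
    adduct: Optional[Adduct]
    mz: float

    @property
    def name(self) -> str:
        ad = self.adduct.name if self.adduct else "-"
        return f"{self.species}{ad if self.adduct else ''}"


@dataclass
class SearchList:
    """Per-mode list of (species, adduct, theoretical m/z) to extract."""

    mode: str
    entries: List[SearchEntry] = field(default_factory=list)
    scan_range: Tuple[float, float] = SCAN_RANGE

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def mz_array(self):
        import numpy as np

        return np.array([e.mz for e in self.entries])


def build_search_list(
    classes: Iterable[str],
    carbon_range: Tuple[int, int],
    db_range: Tuple[int, int],
    mode: str,
    adducts: Optional[Dict[str, Sequence[str]]] = None,
    scan_range: Tuple[float, float] = SCAN_RANGE,
) -> SearchList:
    """Cartesian product of species x mode-appropriate adducts within the
    instrument scan range, in deterministic (m/z, name) order.

    ``carbon_range`` / ``db_range`` are inclusive ``(lo, hi)`` bounds on
    total acyl carbons and double bonds.  For ``mode='negative-CID'`` use
    :func:`build_fa_search_list` instead (fragment ions, not intact lipids).
    """
    if mode == "negative-CID":
        raise ValueError("use build_fa_search_list for the CID mode")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    c_lo, c_hi = carbon_range
    d_lo, d_hi = db_range
    if c_hi < c_lo or d_hi < d_lo:
        raise ValueError("empty carbon or double-bond range")
    if adducts is None:
        names: Sequence[str] = DEFAULT_MODE_ADDUCTS[mode]
    elif isinstance(adducts, dict):
        names = adducts.get(mode, DEFAULT_MODE_ADDUCTS[mode])
    else:
        names = adducts
    entries = []
    seen = set()
    for cls in classes:
        for c in range(c_lo, c_hi + 1):
            for d in range(d_lo, d_hi + 1):
                if d > c / 2:
                    continue
                sp = LipidSpecies(cls, c, d)
                f = formula_of(sp)
                for ad_name in names:
                    ad = ADDUCTS[ad_name]
                    if ad.polarity != mode:
                        continue
                    key = (sp.name, ad.name)
                    if key in seen:
                        continue
                    seen.add(key)
                    mz = adduct_mz(f, ad)
                    if scan_range[0] <= mz <= scan_range[1]:
                        entries.append(SearchEntry(sp, ad, mz))
    entries.sort(key=lambda e: (e.mz, str(e.species), e.adduct.name))
    if not entries:
        warnings.warn(f"empty search list for mode {mode}", stacklevel=2)
    return SearchList(mode, entries, scan_range)


def build_fa_search_list(
    carbon_range: Tuple[int, int] = (12, 24),
    db_range: Tuple[int, int] = (0, 6),
    scan_range: Tuple[float, float] = SCAN_RANGE,
) -> SearchList:
    """Search list of fatty-acid carboxylate anions for the negative-CID mode."""
    c_lo, c_hi = carbon_range
    d_lo, d_hi = db_range
    entries = []
    for c in range(c_lo, c_hi + 1):
        for d in range(d_lo, d_hi + 1):
            if 2 * c - 2 * d - 1 <= 0:
                continue
            fa = FattyAcid(c, d)
            mz = fa_fragment_mz(fa)
            if scan_range[0] <= mz <= scan_range[1]:
                entries.append(SearchEntry(fa, None, mz))
    entries.sort(key=lambda e: (e.mz, str(e.species)))
    return SearchList("negative-CID", entries, scan_range)


def enumerate_isobars(
    mz: float, tol_ppm: float, search_space: SearchList
) -> List[Tuple[object, Optional[Adduct], float, float]]:
    """All search entries within ``tol_ppm`` of ``mz``, sorted by |deviation|.

    Deviation is signed ppm, ``1e6 * (observed - theoretical)/theoretical``.
    """
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")
    out = []
    for e in search_space:
        dev = 1e6 * (mz - e.mz) / e.mz
        if abs(dev) <= tol_ppm:
            out.append((e.species, e.adduct, e.mz, dev))
    out.sort(key=lambda t: (abs(t[3]), t[2]))
    return out


# ---------------------------------------------------------------------------
# TSV export / import
# ---------------------------------------------------------------------------

_TSV_HEADER = "name\tclass\tcarbons\tdouble_bonds\tadduct\tpolarity\tmz_theoretical"


def write_search_list(slist: SearchList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mode={slist.mode}\n{_TSV_HEADER}\n")
        for e in slist:
            if isinstance(e.species, FattyAcid):
                cls, c, d = "FA", e.species.carbons, e.species.double_bonds
                ad, pol = "-", "negative"
            else:
                cls = e.species.lipid_class
                c, d = e.species.carbons, e.species.double_bonds
                ad, pol = e.adduct.name, e.adduct.polarity
            fh.write(f"{e.name}\t{cls}\t{c}\t{d}\t{ad}\t{pol}\t{e.mz:.4f}\n")


def read_search_list(path) -> SearchList:
    mode = None
    entries = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# mode="):
                mode = line.split("=", 1)[1].strip()
                continue
            if not line or line.startswith("name\t"):
                continue
            _, cls, c, d, ad_name, _pol, mz = line.split("\t")
            if cls == "FA":
                sp: object = FattyAcid(int(c), int(d))
                ad = None
            else:
                sp = LipidSpecies(cls, int(c), int(d))
                ad = ADDUCTS[ad_name]
            entries.append(SearchEntry(sp, ad, float(mz)))
    if mode is None:
        raise ValueError(f"search-list file {path} lacks a '# mode=' header")
    return SearchList(mode, entries)
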