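"""Isobar disambiguation, fatty-acid profiling and isoform assignment.

Diacyl PC(c:d) and PE(c+3:d) share one exact mass, so a positive-mode
signal alone cannot tell them apart.  Two orthogonal lines of evidence
can: (1) in negative mode a PC only ionises by picking up a formate or
acetate anion (M+44.9982 / M+59.0139) because its quaternary amine keeps
a permanent positive charge, while a PE simply deprotonates to [M-H]- at
M-1.0073 — so which negative-mode peak accompanies the signal reveals the
head group; (2) head-group abundance priors — e.g. in serum PE sits about
two orders of magnitude below PC, so the balance of probabilities favours
the PC reading even for odd-chain configurations.

The negative-CID mode fragments phospholipids into fatty-acid carboxylate
anions; matching these gives the global FA profile, and grouping them
with a precursor supports assignment of the precursor's chain
configuration, e.g. resolving PC(36:6) as PC(14:0/22:6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .chem import (
    ADDUCTS,
    FattyAcid,
    LipidSpecies,
    SearchList,
    adduct_mz,
    fa_fragment_mz,
    formula_of,
    monoisotopic_mass,
    TWO_CHAIN_CLASSES,
)
from .msio import Spectrum

__all__ = [
    "HeadgroupPrior",
    "SERUM_PRIOR",
    "FAProfile",
    "IsoformAssignment",
    "disambiguate_isobar",
    "fa_profile_from_cid",
    "enumerate_fa_pairs",
    "assign_isoforms",
]


@dataclass
class HeadgroupPrior:
    """Relative head-group abundance weights for a sample type."""

    sample_type: str
    weights: Dict[str, float]

    def __post_init__(self):
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("prior weights must be positive")

    def weight(self, lipid_class: str) -> float:
        return self.weights.get(lipid_class, 1.0)


#: Serum rule of thumb from 31P NMR: PE roughly two orders of magnitude
#: less abundant than PC.  Other classes default to uniform weight 1.
SERUM_PRIOR = HeadgroupPrior("serum", {"PC": 1.0, "PE": 0.01})


@dataclass
class RankedCandidate:
    species: LipidSpecies
    adduct: object
    mz_theoretical: float
    deviation_ppm: float
    evidence: Tuple[str, ...]
    prior_weight: float
    score: float


def _peak_near(spec: Spectrum, mz: float, tol_ppm: float) -> Optional[float]:
    if spec is None or spec.is_empty:
        return None
    lo = np.searchsorted(spec.mz, mz * (1 - tol_ppm * 1e-6))
    hi = np.searchsorted(spec.mz, mz * (1 + tol_ppm * 1e-6))
    if hi <= lo:
        return None
    j = lo + int(np.argmax(spec.intensity[lo:hi]))
    return float(spec.intensity[j])


# classes with a permanent positive charge that ionise negatively only via
# anion adduction (formate/acetate); everything else deprotonates
_ADDUCT_IONISING = frozenset(["PC", "PC-O", "PC-P", "SM", "LPC"])


def disambiguate_isobar(
    candidates: Sequence[Tuple[LipidSpecies, object, float, float]],
    neg_mode_spectrum: Optional[Spectrum] = None,
    priors: Optional[HeadgroupPrior] = None,
    tol_ppm: float = 5.0,
) -> List[RankedCandidate]:
    """Rank isobaric candidates by negative-mode evidence, then prior.

    ``candidates`` is the output of :func:`lipidflow.chem.enumerate_isobars`.
    Direct evidence dominates: candidates whose class-specific negative-mode
    ion (formate/acetate adduct for choline lipids, [M-H]- otherwise) is
    observed rank above candidates without it; within an evidence tier the
    head-group prior decides, then |deviation|.  Rationale codes record
    which evidence fired.
    """
    priors = priors or HeadgroupPrior("uniform", {})
    ranked: List[RankedCandidate] = []
    for species, adduct, mz_theor, dev in candidates:
        mass = monoisotopic_mass(formula_of(species))
        evidence: List[str] = []
        if neg_mode_spectrum is not None:
            if species.lipid_class in _ADDUCT_IONISING:
                for name in ("+HCOO", "+CH3COO"):
                    ion = mass + ADDUCTS[name].mass_delta
                    if _peak_near(neg_mode_spectrum, ion, tol_ppm) is not None:
                        evidence.append(f"neg_adduct:{name}")
            else:
                ion = mass + ADDUCTS["-H"].mass_delta
                if _peak_near(neg_mode_spectrum, ion, tol_ppm) is not None:
                    evidence.append("neg_deprotonated")
        w = priors.weight(species.lipid_class)
        ranked.append(
            RankedCandidate(
                species=species,
                adduct=adduct,
                mz_theoretical=mz_theor,
                deviation_ppm=dev,
                evidence=tuple(evidence) or ("prior_only",),
                prior_weight=w,
                score=(1.0 if evidence else 0.0) + w / (1.0 + w),
            )
        )
    ranked.sort(
        key=lambda r: (
            -(r.evidence != ("prior_only",)),
            -r.prior_weight,
            abs(r.deviation_ppm),
            str(r.species),
        )
    )
    if len(ranked) == 1:
        ranked[0].evidence = ("unique",) + tuple(
            e for e in ranked[0].evidence if e != "prior_only"
        )
    return ranked


@dataclass
class FAProfile:
    """Relative fatty-acid abundances from the negative-CID mode."""

    fractions: Dict[FattyAcid, float]
    mode: str = "negative-CID"
    flagged_empty: bool = False

    def __post_init__(self):
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError("FA fractions must sum to 1")


def fa_profile_from_cid(
    spectrum: Spectrum, fa_list: SearchList, tol_ppm: float = 5.0
) -> FAProfile:
    """Match FA carboxylate anions in a negative-CID spectrum and
    normalise their intensities to fractions (relative quantification,
    equal response factors assumed)."""
    if spectrum.mode != "negative-CID":
        raise ValueError("fa_profile_from_cid needs a negative-CID spectrum")
    hits: Dict[FattyAcid, float] = {}
    for e in fa_list:
        inten = _peak_near(spectrum, e.mz, tol_ppm)
        if inten is not None and inten > 0:
            fa = e.species
            hits[fa] = max(hits.get(fa, 0.0), inten)
    total = sum(hits.values())
    if total == 0:
        return FAProfile({}, flagged_empty=True)
    return FAProfile({fa: v / total for fa, v in hits.items()})


def enumerate_fa_pairs(
    precursor: LipidSpecies, fa_space: Iterable[FattyAcid]
) -> List[Tuple[FattyAcid, FattyAcid]]:
    """All unordered chain pairs consistent with the precursor totals.

    Pairs (a, b) with a <= b such that carbons and double bonds sum to the
    precursor's; deterministic order.
    """
    if precursor.lipid_class not in TWO_CHAIN_CLASSES:
        raise ValueError(
            f"{precursor.lipid_class} is not a two-chain class"
        )
    fas = sorted(set(fa_space))
    index = set(fas)
    pairs = []
    for a in fas:
        cb = precursor.carbons - a.carbons
        db = precursor.double_bonds - a.double_bonds
        if cb < a.carbons or (cb == a.carbons and db < a.double_bonds):
            continue
        if cb < 2 or db < 0:
            continue
        b = FattyAcid(cb, db)
        if b in index:
            pairs.append((a, b))
    pairs.sort()
    return pairs


@dataclass
class IsoformAssignment:
    """Candidate chain pairings for a precursor with fragment evidence.

    ``proportions`` are normalised over supported pairs (min-fragment
    scoring); empty when no pair has both chains evidenced.
    """

    precursor: LipidSpecies
    candidates: List[Tuple[Tuple[FattyAcid, FattyAcid], float]] = field(
        default_factory=list
    )
    proportions: Dict[Tuple[FattyAcid, FattyAcid], float] = field(
        default_factory=dict
    )
    unresolved: bool = False

    def top_pair(self) -> Optional[Tuple[FattyAcid, FattyAcid]]:
        if not self.proportions:
            return None
        return max(self.proportions, key=self.proportions.get)


def assign_isoforms(
    precursor: LipidSpecies,
    fragment_peaks: Sequence[Tuple[float, float]],
    fa_space: Iterable[FattyAcid],
    tol_ppm: float = 5.0,
) -> IsoformAssignment:
    """Score chain pairings of a precursor against its grouped fragments.

    ``fragment_peaks`` are (m/z, intensity) pairs grouped with the
    precursor upstream (co-elution or CID window).  Each enumerated pair
    scores the minimum of its two FA-anion intensities — both chains must
    be evidenced; a homoacyl pair scores its single anion's intensity.
    Proportions are the normalised scores over supported pairs.
    """
    frag = sorted(fragment_peaks)
    fmz = np.array([p[0] for p in frag])
    fint = np.array([p[1] for p in frag])
    spec = Spectrum("frag", "negative-CID", fmz, fint) if fmz.size else None

    def anion_intensity(fa: FattyAcid) -> float:
        if spec is None:
            return 0.0
        v = _peak_near(spec, fa_fragment_mz(fa), tol_ppm)
        return v or 0.0

    pairs = enumerate_fa_pairs(precursor, fa_space)
    scored = []
    for a, b in pairs:
        if a == b:
            s = anion_intensity(a)
        else:
            s = min(anion_intensity(a), anion_intensity(b))
        scored.append(((a, b), s))
    total = sum(s for _, s in scored)
    if total == 0:
        return IsoformAssignment(precursor, scored, {}, unresolved=True)
    props = {pair: s / total for pair, s in scored if s > 0}
    return IsoformAssignment(precursor, scored, props, unresolved=False)
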