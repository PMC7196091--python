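"""Synthetic three-mode DI-MS study generator with known ground truth.

Emulates a two-phenotype cohort (e.g. lean vs obese) measured by the
three-mode direct-infusion protocol: per-sample lipid compositions with
spiked group effects, positive/negative consensus spectra with ppm jitter
and multiplicative intensity noise, a negative-CID spectrum of fatty-acid
carboxylate anions derived from the species' chain compositions, QC
dilution series, IS-containing blanks, and matching pooled 31P NMR
integral tables.  Every draw flows from a single seed, so runs are
byte-identical given equal configs.

What it emulates: search-list-resolvable peaks, mass-accuracy jitter,
biological and technical intensity variation, blank contamination,
isobaric PC/PE overlaps, linear QC dilution response.  What it does not:
isotope envelopes, chromatography, instrument drift, response-factor
heterogeneity (unless configured) — so recovery results speak to the data
processing, not to instrument physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .chem import (
    FattyAcid,
    LipidSpecies,
    SearchEntry,
    SearchList,
    adduct_mz,
    build_fa_search_list,
    fa_fragment_mz,
    formula_of,
    ADDUCTS,
    PHOSPHOLIPID_CLASSES,
)
from .extraction import InternalStandard
from .msio import AcquisitionTiming, Scan, Spectrum

__all__ = [
    "SimConfig",
    "CompositionTruth",
    "DEFAULT_CLASS_GRID",
    "DEFAULT_INTERNAL_STANDARDS",
    "default_search_lists",
    "simulate_cohort",
    "simulate_spectrum",
    "simulate_scan_series",
    "simulate_qc_and_blanks",
    "simulate_nmr",
    "simulate_study",
]

#: Carbon/double-bond grids per class for the default ~460-variable study
#: composition, spanning the common mammalian-tissue lipidome classes.
DEFAULT_CLASS_GRID: Dict[str, Tuple[Tuple[int, int], Tuple[int, int]]] = {
    "PC": ((30, 40), (0, 6)),
    "PE": ((32, 42), (0, 6)),
    "PS": ((34, 40), (0, 5)),
    "PI": ((34, 38), (0, 5)),
    "PG": ((32, 36), (0, 4)),
    "SM": ((32, 42), (1, 2)),
    "LPC": ((14, 22), (0, 4)),
    "TG": ((48, 54), (0, 6)),
    "DG": ((32, 36), (0, 4)),
    "CE": ((14, 22), (0, 4)),
    "PC-O": ((32, 40), (0, 3)),
}

#: Which adduct each class is observed as, per mode (one per class per mode
#: keeps true compositions identifiable from the spectra).
CLASS_MODE_ADDUCTS: Dict[str, Dict[str, str]] = {
    "PC": {"positive": "+H", "negative": "+HCOO"},
    "PC-O": {"positive": "+H"},
    "SM": {"positive": "+H"},
    "LPC": {"positive": "+H"},
    "TG": {"positive": "+NH4"},
    "DG": {"positive": "+NH4"},
    "CE": {"positive": "+NH4"},
    "PE": {"negative": "-H"},
    "PS": {"negative": "-H"},
    "PI": {"negative": "-H"},
    "PG": {"negative": "-H"},
}


def _is_species() -> List[Tuple[str, LipidSpecies, str, str]]:
    # (name, species, adduct, mode) — species chosen outside the study grid
    return [
        ("IS_PC(28:0)", LipidSpecies("PC", 28, 0), "+H", "positive"),
        ("IS_PE(30:0)", LipidSpecies("PE", 30, 0), "-H", "negative"),
        ("IS_TG(45:0)", LipidSpecies("TG", 45, 0), "+NH4", "positive"),
    ]


DEFAULT_INTERNAL_STANDARDS: List[InternalStandard] = [
    InternalStandard(
        name=n,
        species=sp,
        adduct=ADDUCTS[ad],
        expected_mz=adduct_mz(formula_of(sp), ADDUCTS[ad]),
        modes=(mode,),
    )
    for n, sp, ad, mode in _is_species()
]


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror a placenta-scale biomarker cohort: 40 samples per
    group, ~460 variables, 2 ppm mass jitter, 20% technical and 30%
    biological intensity variation, 5-level QC dilution series and
    IS-containing blanks.
    """

    n_per_group: int = 40
    groups: Tuple[str, str] = ("lean", "obese")
    tissue: str = "placenta"
    ppm_jitter_sd: float = 2.0
    intensity_cv: float = 0.2
    biological_cv: float = 0.3
    blank_level: float = 0.0  # contamination floor in blanks (fraction of mean signal)
    n_blanks: int = 3
    qc_levels: Tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    qc_noise_cv: float = 0.05
    spikes: Dict[str, float] = field(default_factory=dict)  # species name -> fold
    n_junk: int = 0  # contaminant variables present in blanks AND samples
    isobar_inject: bool = True
    paired: bool = False
    seed: int = 0
    class_grid: Dict[str, Tuple[Tuple[int, int], Tuple[int, int]]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_GRID)
    )

    def validate(self):
        for name, v in [
            ("ppm_jitter_sd", self.ppm_jitter_sd),
            ("intensity_cv", self.intensity_cv),
            ("biological_cv", self.biological_cv),
            ("blank_level", self.blank_level),
            ("qc_noise_cv", self.qc_noise_cv),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.qc_levels) < 2:
            raise ValueError("need >=2 QC dilution levels")


@dataclass
class CompositionTruth:
    """Ground truth: per-sample fractional compositions + bookkeeping."""

    species: List[LipidSpecies]  # with sn compositions where two-chain
    fractions: pd.DataFrame  # samples x species name
    samples: pd.DataFrame  # group, tissue, sample_type, subject
    spiked: Dict[str, float]  # species name -> fold change applied to group B
    junk_species: List[LipidSpecies] = field(default_factory=list)

    def species_by_name(self) -> Dict[str, LipidSpecies]:
        return {s.name: s for s in self.species}


def _grid_species(grid) -> List[LipidSpecies]:
    out = []
    for cls, ((c_lo, c_hi), (d_lo, d_hi)) in grid.items():
        for c in range(c_lo, c_hi + 1):
            for d in range(d_lo, d_hi + 1):
                if d <= c / 2:
                    out.append(LipidSpecies(cls, c, d))
    return out


def _assign_sn(species: LipidSpecies, rng: np.random.Generator) -> LipidSpecies:
    """Give a two-chain species a random plausible chain split."""
    if species.lipid_class not in chem.TWO_CHAIN_CLASSES:
        return species
    c, d = species.carbons, species.double_bonds
    for _ in range(50):
        ca = int(rng.integers(12, min(24, c - 12) + 1))
        cb = c - ca
        if not (12 <= cb <= 24):
            continue
        da = int(rng.integers(0, min(6, d) + 1))
        db = d - da
        if not (0 <= db <= 6):
            continue
        return LipidSpecies(
            species.lipid_class, c, d,
            sn_composition=(FattyAcid(ca, da), FattyAcid(cb, db)),
        )
    return species


def default_search_lists(
    config: Optional[SimConfig] = None,
) -> Dict[str, SearchList]:
    """Search lists matching the generator's class grids (plus the ISs)."""
    grid = (config or SimConfig()).class_grid
    entries: Dict[str, List[SearchEntry]] = {"positive": [], "negative": []}
    for sp in _grid_species(grid):
        f = formula_of(sp)
        for mode, ad_name in CLASS_MODE_ADDUCTS.get(sp.lipid_class, {}).items():
            ad = ADDUCTS[ad_name]
            mz = adduct_mz(f, ad)
            if chem.SCAN_RANGE[0] <= mz <= chem.SCAN_RANGE[1]:
                entries[mode].append(SearchEntry(sp, ad, mz))
    for std in DEFAULT_INTERNAL_STANDARDS:
        mode = std.modes[0]
        entries[mode].append(SearchEntry(std.species, std.adduct, std.expected_mz))
    out = {}
    for mode, ents in entries.items():
        ents.sort(key=lambda e: (e.mz, str(e.species)))
        out[mode] = SearchList(mode, ents)
    out["negative-CID"] = build_fa_search_list()
    return out


def simulate_cohort(config: SimConfig) -> CompositionTruth:
    """Draw the study's ground-truth compositions.

    A baseline composition is drawn once (lognormal relative abundances
    over the class grid); per-sample compositions multiply in biological
    lognormal variation; group-B samples additionally multiply the spiked
    species by their fold changes; fractions are renormalised to sum to 1.
    Paired designs reuse each subject's biological draw in both groups.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = [_assign_sn(sp, rng) for sp in _grid_species(config.class_grid)]
    names = [sp.name for sp in species]
    unknown = set(config.spikes) - set(names)
    if unknown:
        raise ValueError(f"spike on unknown variable(s): {sorted(unknown)}")
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=len(names))
    baseline /= baseline.sum()

    n = config.n_per_group
    ga, gb = config.groups
    sample_ids = [f"{ga}_{i + 1:03d}" for i in range(n)] + [
        f"{gb}_{i + 1:03d}" for i in range(n)
    ]
    groups = [ga] * n + [gb] * n
    subjects = (
        [f"subj_{i + 1:03d}" for i in range(n)] * 2
        if config.paired
        else [f"subj_{i + 1:03d}" for i in range(2 * n)]
    )
    sigma_b = np.sqrt(np.log(1 + config.biological_cv**2))
    if config.paired:
        bio = rng.lognormal(0.0, sigma_b, size=(n, len(names)))
        bio = np.vstack([bio, bio])
    else:
        bio = rng.lognormal(0.0, sigma_b, size=(2 * n, len(names)))
    fold = np.ones(len(names))
    for sp_name, f in config.spikes.items():
        fold[names.index(sp_name)] = f
    comp = baseline * bio
    comp[n:] *= fold
    comp /= comp.sum(axis=1, keepdims=True)
    fractions = pd.DataFrame(comp, index=pd.Index(sample_ids, name="sample_id"),
                             columns=names)
    samples = pd.DataFrame(
        {
            "group": groups,
            "tissue": config.tissue,
            "sample_type": "study",
            "subject": subjects,
        },
        index=fractions.index,
    )
    return CompositionTruth(
        species=species,
        fractions=fractions,
        samples=samples,
        spiked=dict(config.spikes),
    )


def _noisy(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv <= 0:
        return values.copy()
    sigma = np.sqrt(np.log(1 + cv**2))
    return values * rng.lognormal(-sigma**2 / 2, sigma, size=values.shape)


def _jitter(mz: np.ndarray, sd_ppm: float, rng: np.random.Generator) -> np.ndarray:
    if sd_ppm <= 0:
        return mz.copy()
    return mz * (1 + rng.normal(0.0, sd_ppm * 1e-6, size=mz.shape))


def simulate_spectrum(
    sample_fracs: pd.Series,
    truth: CompositionTruth,
    mode: str,
    config: SimConfig,
    rng: np.random.Generator,
    sample_id: str = "",
    include_is: bool = True,
    is_intensity: float = 0.05,
    scale: float = 1.0,
) -> Spectrum:
    """One sample's consensus spectrum in one mode.

    Peaks sit at theoretical adduct m/z jittered by Gaussian ppm noise;
    intensities are fraction x scale with multiplicative lognormal noise
    (equal response factors).  The negative-CID mode instead emits
    fatty-acid anion peaks whose intensities sum the chain contributions
    of negative-ionising phospholipids.  Internal standards are added in
    their modes at a fixed nominal intensity.
    """
    by_name = truth.species_by_name()
    mzs: List[float] = []
    ints: List[float] = []
    if mode == "negative-CID":
        fa_int: Dict[FattyAcid, float] = {}
        for name, frac in sample_fracs.items():
            sp = by_name.get(name)
            if sp is None or sp.lipid_class not in PHOSPHOLIPID_CLASSES:
                continue
            if sp.sn_composition:
                for fa in sp.sn_composition:
                    fa_int[fa] = fa_int.get(fa, 0.0) + frac / len(sp.sn_composition)
        for fa, inten in fa_int.items():
            mzs.append(fa_fragment_mz(fa))
            ints.append(inten * scale)
    else:
        for name, frac in sample_fracs.items():
            sp = by_name.get(name)
            if sp is None:
                continue
            ad_name = CLASS_MODE_ADDUCTS.get(sp.lipid_class, {}).get(mode)
            if ad_name is None:
                continue
            mzs.append(adduct_mz(formula_of(sp), ADDUCTS[ad_name]))
            ints.append(frac * scale)
        if include_is:
            for std in DEFAULT_INTERNAL_STANDARDS:
                if mode in std.modes:
                    mzs.append(std.expected_mz)
                    ints.append(is_intensity * scale)
    mz = _jitter(np.array(mzs), config.ppm_jitter_sd, rng)
    inten = _noisy(np.array(ints), config.intensity_cv, rng)
    keep = inten > 0  # a zero-abundance species produces no peak
    mz, inten = mz[keep], inten[keep]
    order = np.argsort(mz, kind="stable")
    return Spectrum(sample_id, mode, mz[order], inten[order], n_scans=1)


def simulate_scan_series(
    sample_fracs: pd.Series,
    truth: CompositionTruth,
    config: SimConfig,
    rng: np.random.Generator,
    timing: Optional[AcquisitionTiming] = None,
    sample_id: str = "",
) -> List[Scan]:
    """A 1 Hz scan series spanning the three timing windows, for
    segmentation and averaging tests."""
    timing = timing or AcquisitionTiming()
    scans: List[Scan] = []
    t = timing.start_delay
    for mode, window, pol, cid in [
        ("positive", timing.positive_window, "positive", False),
        ("negative", timing.negative_window, "negative", False),
        ("negative-CID", timing.cid_window, "negative", True),
    ]:
        for k in range(int(round(window))):
            spec = simulate_spectrum(
                sample_fracs, truth, mode, config, rng, sample_id
            )
            scans.append(
                Scan(time=t + k, polarity=pol, cid=cid,
                     mz=spec.mz, intensity=spec.intensity)
            )
        t += window
    return scans


def simulate_qc_and_blanks(
    truth: CompositionTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> Tuple[Dict[str, Dict[str, Spectrum]], pd.DataFrame, Dict[str, float]]:
    """QC dilution series + IS-containing blanks.

    QC samples are the pooled mean composition scaled linearly by their
    dilution level (with small technical noise); blanks carry the internal
    standards plus, when ``blank_level > 0`` or junk species exist, a
    contamination floor.  Returns (spectra, sample metadata, qc levels).
    """
    mean_comp = truth.fractions.mean(axis=0)
    spectra: Dict[str, Dict[str, Spectrum]] = {}
    meta_rows = []
    qc_levels: Dict[str, float] = {}
    qc_cfg = replace(config, intensity_cv=config.qc_noise_cv)
    for i, level in enumerate(config.qc_levels):
        sid = f"QC_{i + 1:02d}"
        qc_levels[sid] = float(level)
        spectra[sid] = {
            mode: simulate_spectrum(
                mean_comp, truth, mode, qc_cfg, rng, sid, scale=level
            )
            for mode in ("positive", "negative", "negative-CID")
        }
        meta_rows.append({"sample_id": sid, "group": "", "tissue": config.tissue,
                          "sample_type": "qc"})
    junk_names = [sp.name for sp in truth.junk_species]
    blank_comp = pd.Series(0.0, index=mean_comp.index)
    if junk_names:
        blank_comp = pd.concat(
            [blank_comp, pd.Series(config.blank_level, index=junk_names)]
        )
    for i in range(config.n_blanks):
        sid = f"BLANK_{i + 1:02d}"
        spectra[sid] = {
            mode: simulate_spectrum(
                blank_comp, truth, mode, qc_cfg, rng, sid
            )
            for mode in ("positive", "negative", "negative-CID")
        }
        meta_rows.append({"sample_id": sid, "group": "", "tissue": config.tissue,
                          "sample_type": "blank"})
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return spectra, meta, qc_levels


#: PE integral split across its three resonances (decision; not a
#: measured quantity — any positive split summing to 1 behaves the same).
PE_RESONANCE_SPLIT = {0.55: 0.5, 0.30: 0.3, 0.15: 0.2}


def simulate_nmr(
    truth: CompositionTruth,
    group: str,
    config: SimConfig,
    rng: np.random.Generator,
    integral_noise_sd: float = 0.05,
    total: float = 100.0,
) -> List[Tuple[float, float]]:
    """Pooled 31P integral table for one phenotype group.

    Phospholipid-class mole fractions of the pooled group composition are
    mapped to integrals at the default shift-window centres, PE split
    50/30/20 over its three resonances, with small Gaussian integral
    noise.
    """
    ids = truth.samples.index[truth.samples["group"] == group]
    pooled = truth.fractions.loc[ids].mean(axis=0)
    by_name = truth.species_by_name()
    class_tot: Dict[str, float] = {}
    for name, frac in pooled.items():
        sp = by_name[name]
        if sp.lipid_class in PHOSPHOLIPID_CLASSES:
            class_tot[sp.lipid_class] = class_tot.get(sp.lipid_class, 0.0) + frac
    norm = sum(class_tot.values())
    centre = {"PA": 4.30, "PG": 0.45, "PC-P": 0.055, "PC": 0.0, "SM": -0.09,
              "PS": -0.155, "PC-O": -0.21, "LPC": -0.27, "PI": -0.35}
    peaks: List[Tuple[float, float]] = []
    for cls, tot in sorted(class_tot.items()):
        share = tot / norm * total
        if cls == "PE":
            for shift, w in PE_RESONANCE_SPLIT.items():
                peaks.append((shift, share * w))
        elif cls in centre:
            peaks.append((centre[cls], share))
    if integral_noise_sd > 0:
        peaks = [
            (s, max(v + rng.normal(0.0, integral_noise_sd), 0.0))
            for s, v in peaks
        ]
    return peaks


#: Six phospholipid spikes emulating a placenta-scale biomarker study,
#: fold changes spanning 1.5-2.5.
PLACENTA_SPIKES: Dict[str, float] = {
    "PC(36:4)": 2.5,
    "PE(38:6)": 2.3,
    "LPC(20:4)": 2.1,
    "PC-O(40:0)": 1.9,
    "PE(36:2)": 1.7,
    "SM(38:1)": 1.5,
}


def simulate_study(config: SimConfig):
    """Full study bundle: truth, per-sample per-mode spectra, metadata.

    Returns a dict with keys ``truth``, ``spectra`` (sample -> mode ->
    Spectrum), ``samples`` (metadata incl. QCs and blanks), ``qc_levels``,
    ``search_lists``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = simulate_cohort(config)
    if config.n_junk > 0:
        # contaminants: species parked outside the study grid (odd TG range)
        junk = [LipidSpecies("TG", 55 + i // 7, i % 7) for i in range(config.n_junk)]
        truth.junk_species = junk

    search_lists = default_search_lists(config)
    if truth.junk_species:
        extra = []
        for sp in truth.junk_species:
            ad = ADDUCTS[CLASS_MODE_ADDUCTS["TG"]["positive"]]
            extra.append(SearchEntry(sp, ad, adduct_mz(formula_of(sp), ad)))
        pos = search_lists["positive"]
        merged = sorted(pos.entries + extra, key=lambda e: (e.mz, str(e.species)))
        search_lists["positive"] = SearchList("positive", merged)

    spectra: Dict[str, Dict[str, Spectrum]] = {}
    junk_names = [sp.name for sp in truth.junk_species]
    all_species = truth.species + truth.junk_species
    full_truth = CompositionTruth(
        species=all_species,
        fractions=truth.fractions,
        samples=truth.samples,
        spiked=truth.spiked,
        junk_species=truth.junk_species,
    )
    for sid in truth.fractions.index:
        fr = truth.fractions.loc[sid].copy()
        if junk_names:
            fr = pd.concat(
                [fr, pd.Series(config.blank_level, index=junk_names)]
            )
        spectra[sid] = {
            mode: simulate_spectrum(fr, full_truth, mode, config, rng, sid)
            for mode in ("positive", "negative", "negative-CID")
        }
    qc_spectra, qc_meta, qc_levels = simulate_qc_and_blanks(
        full_truth, config, rng
    )
    spectra.update(qc_spectra)
    samples = pd.concat([truth.samples, qc_meta])
    if "subject" not in samples:
        samples["subject"] = ""
    samples["subject"] = samples["subject"].fillna("")
    return {
        "truth": full_truth,
        "spectra": spectra,
        "samples": samples,
        "qc_levels": qc_levels,
        "search_lists": search_lists,
    }


def run_discovery_pipeline(config: SimConfig, tol_ppm: float = 9.0):
    """Full round trip: simulate -> extract -> filter -> normalise -> discover.

    Candidate-biomarker discovery runs on the quantification modes
    (positive and negative); the CID fatty-acid profile is a separate
    analysis and is excluded from the variable set.  Returns the
    biomarker table, the processed matrix and the truth.
    """
    from .extraction import extract_cohort
    from .qc import QCDesign, apply_filters, normalize_total
    from .stats import discover_biomarkers

    study = simulate_study(config)
    matrix = extract_cohort(
        study["spectra"], study["search_lists"], tol_ppm, study["samples"]
    )
    design = QCDesign(
        study["qc_levels"],
        list(matrix.samples.index[matrix.samples["sample_type"] == "blank"]),
    )
    filtered, report = apply_filters(matrix, design)
    normed = normalize_total(filtered)
    quant = normed.subset_variables(
        normed.variables.index[normed.variables["mode"].isin(["positive", "negative"])]
    )
    table = discover_biomarkers(quant, seed=config.seed, paired=config.paired)
    return {
        "table": table,
        "matrix": quant,
        "truth": study["truth"],
        "report": report,
    }


def score_recovery(table: "pd.DataFrame", variables: pd.DataFrame,
                   spiked: Dict[str, float]) -> Dict[str, float]:
    """Sensitivity and false-selection count for one discovery run.

    Exactly isobaric variables (same mode, theoretical m/z within 5e-4)
    share one physical signal; selections are therefore counted at the
    distinct-signal level.  A spiked species counts as recovered when any
    signal containing one of its variables is selected; a selected signal
    none of whose variables belongs to a spiked species is a false
    selection.
    """
    meta = variables.loc[table.index]
    key = list(zip(meta["mode"], meta["mz_theoretical"].round(3)))
    signal_species: Dict[tuple, set] = {}
    signal_selected: Dict[tuple, bool] = {}
    for vid, k in zip(table.index, key):
        signal_species.setdefault(k, set()).add(meta.loc[vid, "species"])
        signal_selected[k] = signal_selected.get(k, False) or bool(
            table.loc[vid, "selected"]
        )
    recovered = set()
    n_false = 0
    for k, selected in signal_selected.items():
        if not selected:
            continue
        hit = signal_species[k] & set(spiked)
        if hit:
            recovered |= hit
        else:
            n_false += 1
    sensitivity = len(recovered) / len(spiked) if spiked else float("nan")
    return {
        "sensitivity": sensitivity,
        "n_false": n_false,
        "recovered": sorted(recovered),
    }
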