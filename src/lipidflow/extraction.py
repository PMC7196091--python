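"""Search-list signal extraction and intensity-matrix assembly.

Consensus spectra are matched against per-mode search lists within a ppm
tolerance.  The tolerance can be chosen from the cohort size (the mass
accuracy achievable over a long acquisition degrades with batch length:
5 ppm settles small cohorts of <100 samples, 9 ppm is needed for large
ones of >500) or diagnosed from the deviations of spiked internal
standards.  Matches across samples are assembled into a samples x
variables intensity matrix carrying sample metadata and per-variable
mode tags; missing signals stay missing (NaN) until filtering decides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import Adduct, FattyAcid, LipidSpecies, SearchList
from .msio import Spectrum

__all__ = [
    "PeakMatch",
    "InternalStandard",
    "IntensityMatrix",
    "select_ppm_cutoff",
    "is_deviation_report",
    "match_peaks",
    "build_matrix",
]


def select_ppm_cutoff(n_samples: int) -> float:
    """Deviation cut-off (ppm) appropriate for a cohort of ``n_samples``.

    5 ppm below 100 samples, 9 ppm above 500, linearly interpolated
    (rounded to 1 decimal) in between.  Monotone non-decreasing in n.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_samples < 100:
        return 5.0
    if n_samples > 500:
        return 9.0
    return round(5.0 + 4.0 * (n_samples - 100) / 400.0, 1)


@dataclass(frozen=True)
class PeakMatch:
    """One matched signal: search entry index, observed m/z, intensity,
    signed ppm deviation."""

    entry_index: int
    variable: str
    observed_mz: float
    intensity: float
    deviation_ppm: float


@dataclass(frozen=True)
class InternalStandard:
    """A spiked standard used to gauge per-mode mass accuracy."""

    name: str
    species: LipidSpecies
    adduct: Adduct
    expected_mz: float
    modes: tuple = ("positive", "negative")


def match_peaks(
    spectrum: Spectrum, search_list: SearchList, tol_ppm: float
) -> List[PeakMatch]:
    """Match each search entry to the most intense peak within +/-tol_ppm.

    Ties on intensity break to the smallest |deviation|, then lowest m/z.
    A single peak may satisfy several entries (isobars share a peak);
    entries with no peak in their window are simply absent from the output.
    """
    if spectrum.mode != search_list.mode:
        raise ValueError(
            f"spectrum mode {spectrum.mode!r} != search-list mode {search_list.mode!r}"
        )
    if spectrum.is_empty or len(search_list) == 0:
        return []
    pk_mz, pk_int = spectrum.mz, spectrum.intensity
    targets = search_list.mz_array()
    lo = np.searchsorted(pk_mz, targets * (1 - tol_ppm * 1e-6), side="left")
    hi = np.searchsorted(pk_mz, targets * (1 + tol_ppm * 1e-6), side="right")
    width = hi - lo
    maxw = int(width.max()) if width.size else 0
    n = targets.size
    best_int = np.full(n, -np.inf)
    best_absdev = np.full(n, np.inf)
    best_idx = np.full(n, -1)
    for k in range(maxw):
        idx = lo + k
        valid = idx < hi
        cand_int = np.where(valid, pk_int[np.minimum(idx, pk_mz.size - 1)], -np.inf)
        cand_mz = pk_mz[np.minimum(idx, pk_mz.size - 1)]
        absdev = np.abs(1e6 * (cand_mz - targets) / targets)
        better = valid & (
            (cand_int > best_int)
            | ((cand_int == best_int) & (absdev < best_absdev))
            | (
                (cand_int == best_int)
                & (absdev == best_absdev)
                & (cand_mz < np.where(best_idx >= 0, pk_mz[np.maximum(best_idx, 0)], np.inf))
            )
        )
        best_int = np.where(better, cand_int, best_int)
        best_absdev = np.where(better, absdev, best_absdev)
        best_idx = np.where(better, idx, best_idx)
    out = []
    for i in np.flatnonzero(best_idx >= 0):
        j = best_idx[i]
        dev = 1e6 * (pk_mz[j] - targets[i]) / targets[i]
        out.append(
            PeakMatch(
                entry_index=int(i),
                variable=search_list.entries[i].name,
                observed_mz=float(pk_mz[j]),
                intensity=float(pk_int[j]),
                deviation_ppm=float(dev),
            )
        )
    return out


def is_deviation_report(
    spectra: Dict[str, Dict[str, Spectrum]],
    standards: Sequence[InternalStandard],
    tol_ppm: float = 20.0,
) -> pd.DataFrame:
    """Per-standard, per-mode deviation statistics across samples.

    ``spectra`` maps sample id -> mode -> Spectrum.  Plotting these
    deviations indicates the general mass deviation of the measurement
    period and hence which cut-off to run with.  Standards matched in no
    spectrum of a mode are reported with NaN stats and ``missing=True``.
    """
    if not standards:
        raise ValueError("no internal standards supplied")
    rows = []
    for std in standards:
        for mode in std.modes:
            devs = []
            for sid, per_mode in spectra.items():
                spec = per_mode.get(mode)
                if spec is None or spec.is_empty:
                    continue
                lo = np.searchsorted(spec.mz, std.expected_mz * (1 - tol_ppm * 1e-6))
                hi = np.searchsorted(spec.mz, std.expected_mz * (1 + tol_ppm * 1e-6))
                if hi > lo:
                    j = lo + int(np.argmax(spec.intensity[lo:hi]))
                    devs.append(1e6 * (spec.mz[j] - std.expected_mz) / std.expected_mz)
            rows.append(
                {
                    "standard": std.name,
                    "mode": mode,
                    "n_matched": len(devs),
                    "mean_ppm": float(np.mean(devs)) if devs else np.nan,
                    "sd_ppm": float(np.std(devs, ddof=1)) if len(devs) > 1 else np.nan,
                    "missing": len(devs) == 0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Intensity matrix
# ---------------------------------------------------------------------------

@dataclass
class IntensityMatrix:
    """Samples x lipid-variables table with metadata.

    ``values``: DataFrame (rows = samples, columns = variable ids, NaN =
    missing).  ``samples``: per-sample metadata (group, tissue,
    sample_type).  ``variables``: per-variable metadata (species, adduct,
    mode, theoretical m/z).  Variable ids are ``"<species><adduct>|<mode>"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    variables: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate variable ids")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative intensities")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, ids) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.loc[ids], self.samples.loc[ids], self.variables
        )

    def subset_variables(self, cols) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values[cols], self.samples, self.variables.loc[cols]
        )

    def to_csv(self, values_path, meta_path=None) -> None:
        self.values.to_csv(values_path)
        if meta_path is not None:
            meta = {
                "samples": self.samples.reset_index().to_dict(orient="records"),
                "variables": self.variables.reset_index().to_dict(orient="records"),
            }
            with open(meta_path, "w", encoding="utf-8") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def from_csv(cls, values_path, meta_path) -> "IntensityMatrix":
        values = pd.read_csv(values_path, index_col=0)
        with open(meta_path, encoding="utf-8") as fh:
            meta = json.load(fh)
        samples = pd.DataFrame(meta["samples"]).set_index("sample_id")
        variables = pd.DataFrame(meta["variables"]).set_index("variable")
        return cls(values, samples.loc[values.index], variables.loc[values.columns])


def build_matrix(
    matches: Dict[str, Dict[str, List[PeakMatch]]],
    search_lists: Dict[str, SearchList],
    sample_meta: Optional[pd.DataFrame] = None,
) -> IntensityMatrix:
    """Assemble per-sample, per-mode peak matches into an IntensityMatrix.

    ``matches``: sample id -> mode -> matches from :func:`match_peaks`.
    Every search-list entry becomes a column even if never matched —
    dropping empty variables is the filtering stage's decision, not the
    extraction stage's.
    """
    var_ids, var_meta = [], []
    col_of = {}
    for mode, slist in search_lists.items():
        for e in slist.entries:
            vid = f"{e.name}|{mode}"
            if vid in col_of:
                raise ValueError(f"duplicate variable id {vid}")
            col_of[vid] = len(var_ids)
            var_ids.append(vid)
            if isinstance(e.species, FattyAcid):
                sp_name, cls = str(e.species), "FA"
            else:
                sp_name, cls = e.species.name, e.species.lipid_class
            var_meta.append(
                {
                    "variable": vid,
                    "species": sp_name,
                    "lipid_class": cls,
                    "adduct": e.adduct.name if e.adduct else "-",
                    "mode": mode,
                    "mz_theoretical": round(e.mz, 4),
                }
            )
    sample_ids = list(matches)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    data = np.full((len(sample_ids), len(var_ids)), np.nan)
    for i, sid in enumerate(sample_ids):
        for mode, mlist in matches[sid].items():
            slist = search_lists[mode]
            for m in mlist:
                vid = f"{slist.entries[m.entry_index].name}|{mode}"
                data[i, col_of[vid]] = m.intensity
    values = pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"),
                          columns=var_ids)
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {"group": "", "tissue": "", "sample_type": "study"},
            index=values.index,
        )
    else:
        sample_meta = sample_meta.loc[sample_ids]
    variables = pd.DataFrame(var_meta).set_index("variable")
    return IntensityMatrix(values, sample_meta, variables)


def extract_cohort(
    spectra: Dict[str, Dict[str, Spectrum]],
    search_lists: Dict[str, SearchList],
    tol_ppm: Optional[float] = None,
    sample_meta: Optional[pd.DataFrame] = None,
) -> IntensityMatrix:
    """Convenience: match every sample's per-mode spectra and build the matrix.

    When ``tol_ppm`` is None it is selected from the cohort size via
    :func:`select_ppm_cutoff`.
    """
    if tol_ppm is None:
        tol_ppm = select_ppm_cutoff(len(spectra))
    matches = {
        sid: {
            mode: match_peaks(spec, search_lists[mode], tol_ppm)
            for mode, spec in per_mode.items()
            if mode in search_lists
        }
        for sid, per_mode in spectra.items()
    }
    return build_matrix(matches, search_lists, sample_meta)
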