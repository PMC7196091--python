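"""Variable-retention filters and total-signal normalization.

The filtering sequence mirrors how an untargeted DI-MS lipidomics matrix
is cleaned before analysis: (1) mass-deviation exclusion happens at match
time (tolerance informed by internal standards and cohort size);
(2) variables must respond linearly across QC dilution levels;
(3) variables must exceed a signal-to-noise ratio of >3 against
IS-containing blank samples; (4) variables present in fewer than 25% of
samples of every group (per tissue) are excluded.  Surviving intensities
are then normalised to each sample's total signal within its ionisation
mode, yielding fractional abundances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .extraction import IntensityMatrix

__all__ = [
    "QCDesign",
    "FilterConfig",
    "FilterReport",
    "qc_correlation_filter",
    "snr_filter",
    "presence_filter",
    "normalize_total",
    "apply_filters",
]


@dataclass
class QCDesign:
    """QC sample ids with known relative concentration levels, plus blanks."""

    qc_levels: Dict[str, float]  # sample id -> relative concentration
    blank_ids: List[str]

    def __post_init__(self):
        if len(set(self.qc_levels.values())) < 2:
            raise ValueError("QC design needs >=2 distinct concentration levels")
        if not self.blank_ids:
            raise ValueError("QC design needs >=1 blank sample")


@dataclass
class FilterConfig:
    r_min: float = 0.75
    snr_threshold: float = 3.0
    presence_min_fraction: float = 0.25
    strict_presence: bool = False  # True: every group must reach the fraction
    enable_qc_correlation: bool = True
    enable_snr: bool = True
    enable_presence: bool = True


@dataclass
class FilterReport:
    """Per-variable pass flags, thresholds used, and survivor counts."""

    flags: pd.DataFrame  # columns: deviation_pass, qc_corr_pass, snr_pass, presence_pass
    thresholds: Dict[str, object] = field(default_factory=dict)
    stage_counts: Dict[str, int] = field(default_factory=dict)
    skipped: List[str] = field(default_factory=list)
    flagged_samples: List[str] = field(default_factory=list)

    def retained(self) -> pd.Index:
        keep = np.ones(len(self.flags), dtype=bool)
        for col in self.flags.columns:
            keep &= self.flags[col].fillna(True).to_numpy(dtype=bool)
        return self.flags.index[keep]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "thresholds": self.thresholds,
                    "stage_counts": self.stage_counts,
                    "skipped": self.skipped,
                    "flags": self.flags.fillna(True).astype(bool)
                    .reset_index().to_dict(orient="records"),
                },
                fh,
                indent=1,
            )

    def summary(self) -> str:
        lines = ["filter stage        survivors"]
        for stage, n in self.stage_counts.items():
            lines.append(f"{stage:<20}{n}")
        if self.skipped:
            lines.append("skipped stages: " + ", ".join(self.skipped))
        return "\n".join(lines)


def qc_correlation_filter(
    matrix: IntensityMatrix, design: QCDesign, r_min: float = 0.75
) -> pd.Series:
    """Pass variables whose QC intensity tracks QC concentration.

    Pearson correlation on log intensities vs log concentration over the
    QC dilution series; pass iff r >= r_min with >=3 QC observations.
    Constant (zero-variance) responses get r = 0 and fail.
    """
    qc_ids = [s for s in design.qc_levels if s in matrix.values.index]
    if len({design.qc_levels[s] for s in qc_ids}) < 2:
        # not evaluable: flag every variable rather than silently passing
        return pd.Series(np.nan, index=matrix.values.columns, name="qc_corr_pass")
    conc = np.log(np.array([design.qc_levels[s] for s in qc_ids], dtype=float))
    sub = matrix.values.loc[qc_ids]
    out = {}
    for var in sub.columns:
        y = sub[var].to_numpy(dtype=float)
        ok = np.isfinite(y) & (y > 0)
        if ok.sum() < 3:
            out[var] = False
            continue
        ly = np.log(y[ok])
        x = conc[ok]
        if np.ptp(ly) == 0 or np.ptp(x) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(x, ly)[0, 1])
        out[var] = bool(r >= r_min)
    return pd.Series(out, name="qc_corr_pass")


def snr_filter(
    matrix: IntensityMatrix,
    blank_ids: Sequence[str],
    threshold: float = 3.0,
) -> pd.Series:
    """Pass variables with SNR > threshold against IS-containing blanks.

    SNR = median study-sample intensity / median blank intensity, with
    missing treated as zero signal; a variable absent from all blanks has
    infinite SNR and passes.
    """
    blank_ids = [b for b in blank_ids if b in matrix.values.index]
    if not blank_ids:
        raise ValueError("no blank samples in matrix")
    study_ids = matrix.samples.index[matrix.samples["sample_type"] == "study"]
    study = matrix.values.loc[study_ids].fillna(0.0).median(axis=0)
    blank = matrix.values.loc[blank_ids].fillna(0.0).median(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = study.to_numpy() / blank.to_numpy()
    passed = (blank.to_numpy() == 0) | (snr > threshold)
    return pd.Series(passed, index=matrix.values.columns, name="snr_pass")


def presence_filter(
    matrix: IntensityMatrix,
    min_fraction: float = 0.25,
    strict: bool = False,
) -> pd.Series:
    """Apply the 25%-presence rule per sample group within each tissue.

    Default reading: a variable is excluded only when its non-missing
    fraction is below ``min_fraction`` in *every* group — a variable
    genuinely present in one phenotype only (e.g. confined to one group's
    kidneys) is kept.  ``strict=True`` instead requires every group to
    reach the fraction.  The threshold is "fewer than": exactly 25%
    presence retains.
    """
    meta = matrix.samples
    study = meta[meta["sample_type"] == "study"]
    if study.empty or (study["group"] == "").all():
        raise ValueError("presence filter requires >=1 non-empty study group")
    passed = np.ones(matrix.n_variables, dtype=bool)
    for tissue, tmeta in study.groupby("tissue"):
        fracs = []
        for _, gmeta in tmeta.groupby("group"):
            if gmeta.empty:
                raise ValueError("empty sample group")
            sub = matrix.values.loc[gmeta.index]
            fracs.append(sub.notna().mean(axis=0).to_numpy())
        fr = np.vstack(fracs)  # groups x variables
        if strict:
            ok = (fr >= min_fraction).all(axis=0)
        else:
            ok = (fr >= min_fraction).any(axis=0)
        passed &= ok
    return pd.Series(passed, index=matrix.values.columns, name="presence_pass")


def normalize_total(matrix: IntensityMatrix) -> IntensityMatrix:
    """Normalise each signal to the sample's total signal in its mode.

    Ionisation efficiency differs between modes, so fractions are only
    meaningful within a mode: per sample and mode the retained variables
    sum to 1.  Samples with zero total in a mode are flagged (values set
    missing) rather than erroring out.
    """
    values = matrix.values.copy()
    flagged = set()
    for mode, vmeta in matrix.variables.groupby("mode"):
        cols = vmeta.index
        block = values[cols]
        totals = block.sum(axis=1, skipna=True)
        zero = totals <= 0
        flagged.update(values.index[zero])
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = block.div(totals.where(~zero), axis=0)
        values[cols] = norm
    out = IntensityMatrix(values, matrix.samples, matrix.variables)
    out.flagged_samples = sorted(flagged)  # type: ignore[attr-defined]
    return out


def apply_filters(
    matrix: IntensityMatrix,
    design: Optional[QCDesign] = None,
    config: Optional[FilterConfig] = None,
) -> tuple[IntensityMatrix, FilterReport]:
    """Run the retention stages in order and report per-stage survivors.

    Order: deviation (applied upstream at match time) -> QC correlation
    -> SNR vs blanks -> group presence.  The returned matrix contains
    study samples only, restricted to retained variables; blanks and QCs
    have served their purpose.
    """
    config = config or FilterConfig()
    nvar = matrix.n_variables
    flags = pd.DataFrame(index=matrix.values.columns)
    flags.index.name = "variable"
    # stage 0: deviation exclusion happens at match time (entries outside
    # the active tolerance were never matched) — recorded as all-pass here
    flags["deviation_pass"] = True
    counts = {"input": nvar, "deviation": nvar}
    skipped = []
    surviving = np.ones(nvar, dtype=bool)

    if config.enable_qc_correlation and design is not None:
        qc = qc_correlation_filter(matrix, design, config.r_min)
        flags["qc_corr_pass"] = qc
        surviving &= qc.fillna(False).to_numpy(dtype=bool) | qc.isna().to_numpy()
    else:
        flags["qc_corr_pass"] = np.nan
        skipped.append("qc_correlation")
    counts["qc_correlation"] = int(surviving.sum())

    if config.enable_snr and design is not None:
        snr = snr_filter(matrix, design.blank_ids, config.snr_threshold)
        flags["snr_pass"] = snr
        surviving &= snr.to_numpy(dtype=bool)
    else:
        flags["snr_pass"] = np.nan
        skipped.append("snr")
    counts["snr"] = int(surviving.sum())

    if config.enable_presence:
        pres = presence_filter(
            matrix, config.presence_min_fraction, config.strict_presence
        )
        flags["presence_pass"] = pres
        surviving &= pres.to_numpy(dtype=bool)
    else:
        flags["presence_pass"] = np.nan
        skipped.append("presence")
    counts["presence"] = int(surviving.sum())

    report = FilterReport(
        flags=flags,
        thresholds={
            "r_min": config.r_min,
            "snr": config.snr_threshold,
            "presence_min_fraction": config.presence_min_fraction,
            "strict_presence": config.strict_presence,
        },
        stage_counts=counts,
        skipped=skipped,
    )
    keep_cols = matrix.values.columns[surviving]
    study_ids = matrix.samples.index[matrix.samples["sample_type"] == "study"]
    filtered = IntensityMatrix(
        matrix.values.loc[study_ids, keep_cols],
        matrix.samples.loc[study_ids],
        matrix.variables.loc[keep_cols],
    )
    return filtered, report
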