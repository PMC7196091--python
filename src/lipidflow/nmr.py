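"""31P NMR head-group quantification and MS ionisation-efficiency factors.

Phosphorus NMR sees every phospholipid head group once per molecule, so
resonance integrals are directly proportional to molar amounts —
orthogonal to MS, where ionisation efficiency differs wildly between
classes.  This module converts an integral table (chemical shift,
integral) into class mole fractions, applying a noise threshold of 0.01%
of the total signal and summing multi-resonance classes (PE shows
resonances at 0.55, 0.30 and 0.15 ppm in this solvent system, with
plasmalogen PC at ~0.05 ppm).  Comparing the NMR mole fractions with the
MS signal fractions of the same classes yields per-head-group relative
ionisation-efficiency factors — the "reality check" channel.

Spectral processing (FT, deconvolution) is upstream: the input here is
the integral table, not an FID.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ShiftAssignmentTable",
    "DEFAULT_SHIFT_TABLE",
    "NMRIntegralTable",
    "integrate_classes",
    "ionisation_efficiency",
    "read_integral_csv",
]


@dataclass
class ShiftAssignmentTable:
    """Non-overlapping chemical-shift windows mapped to class labels."""

    windows: List[Tuple[float, float, str]]  # (lo ppm, hi ppm, class)

    def __post_init__(self):
        spans = sorted((lo, hi) for lo, hi, _ in self.windows)
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise ValueError(
                    f"overlapping shift windows: ({lo1},{hi1}) and ({lo2},{hi2})"
                )
        for lo, hi, _ in self.windows:
            if hi <= lo:
                raise ValueError("window hi must exceed lo")

    def assign(self, shift: float) -> Optional[str]:
        for lo, hi, cls in self.windows:
            if lo <= shift < hi:
                return cls
        return None


#: Default windows.  PE multiplets at 0.55/0.30/0.15 ppm and plasmalogen
#: PC at ~0.05 ppm follow the solvent-system assignments described for
#: the CUBO-type system; the remaining classes are approximate package
#: defaults and fully overridable — shift behaviour is solvent-dependent.
DEFAULT_SHIFT_TABLE = ShiftAssignmentTable(
    [
        (4.27, 4.33, "PA"),
        (0.42, 0.48, "PG"),
        (0.52, 0.58, "PE"),
        (0.27, 0.33, "PE"),
        (0.12, 0.18, "PE"),
        (0.03, 0.08, "PC-P"),
        (-0.03, 0.03, "PC"),
        (-0.12, -0.06, "SM"),
        (-0.18, -0.13, "PS"),
        (-0.23, -0.19, "PC-O"),
        (-0.30, -0.24, "LPC"),
        (-0.38, -0.32, "PI"),
    ]
)


@dataclass
class NMRIntegralTable:
    """Assigned integrals and head-group mole fractions for one pooled sample."""

    rows: pd.DataFrame  # shift_ppm, integral, assigned_class
    total_signal: float
    class_integrals: Dict[str, float] = field(default_factory=dict)
    mole_fractions: Dict[str, float] = field(default_factory=dict)
    unknown_fraction: float = 0.0
    n_discarded: int = 0


def integrate_classes(
    peaks: Sequence[Tuple[float, float]],
    table: ShiftAssignmentTable = DEFAULT_SHIFT_TABLE,
    noise_frac: float = 0.0001,
) -> NMRIntegralTable:
    """Assign integrals to head-group classes and compute mole fractions.

    Integrals below ``noise_frac`` of the total (default 0.01%) are
    discarded.  Multi-window classes (PE) are summed; peaks falling in no
    window are pooled under "unknown" and excluded from the mole-fraction
    normalisation.  Peak input order does not matter.
    """
    if not len(peaks):
        raise ValueError("empty integral table")
    arr = sorted((float(s), float(v)) for s, v in peaks)
    if any(v < 0 for _, v in arr):
        raise ValueError("negative integrals")
    total = sum(v for _, v in arr)
    if total <= 0:
        raise ValueError("zero total signal")
    rows = []
    class_integrals: Dict[str, float] = {}
    unknown = 0.0
    discarded = 0
    for shift, integral in arr:
        if integral < noise_frac * total:
            discarded += 1
            continue
        cls = table.assign(shift)
        rows.append(
            {"shift_ppm": shift, "integral": integral,
             "assigned_class": cls or "unknown"}
        )
        if cls is None:
            unknown += integral
        else:
            class_integrals[cls] = class_integrals.get(cls, 0.0) + integral
    assigned_total = sum(class_integrals.values())
    fractions = (
        {c: v / assigned_total for c, v in class_integrals.items()}
        if assigned_total > 0
        else {}
    )
    return NMRIntegralTable(
        rows=pd.DataFrame(rows, columns=["shift_ppm", "integral", "assigned_class"]),
        total_signal=total,
        class_integrals=class_integrals,
        mole_fractions=fractions,
        unknown_fraction=unknown / total,
        n_discarded=discarded,
    )


def ionisation_efficiency(
    ms_class_fractions: Dict[str, float],
    nmr_fractions: Dict[str, float],
    reference_class: str = "PC",
) -> pd.DataFrame:
    """Relative MS ionisation-efficiency factor per head group.

    factor = (MS signal fraction) / (NMR mole fraction), normalised so the
    reference class (PC) is 1.  Classes absent from either input, or with
    zero NMR fraction, are flagged as not cross-checkable.
    """
    classes = sorted(set(ms_class_fractions) | set(nmr_fractions))
    rows = []
    raw: Dict[str, float] = {}
    for cls in classes:
        ms = ms_class_fractions.get(cls)
        nmr = nmr_fractions.get(cls)
        if ms is None or nmr is None or nmr == 0:
            rows.append(
                {"lipid_class": cls, "ms_fraction": ms, "nmr_fraction": nmr,
                 "efficiency": np.nan, "flag": "not_cross_checkable"}
            )
            continue
        raw[cls] = ms / nmr
        rows.append(
            {"lipid_class": cls, "ms_fraction": ms, "nmr_fraction": nmr,
             "efficiency": raw[cls], "flag": ""}
        )
    df = pd.DataFrame(rows).set_index("lipid_class")
    ref = raw.get(reference_class)
    if ref:
        df["efficiency"] = df["efficiency"] / ref
    return df


def read_integral_csv(path) -> List[Tuple[float, float]]:
    """Read an NMR integral table CSV with columns shift_ppm, integral."""
    df = pd.read_csv(path)
    missing = {"shift_ppm", "integral"} - set(df.columns)
    if missing:
        raise ValueError(f"integral CSV lacks columns {sorted(missing)}")
    return list(zip(df["shift_ppm"].astype(float), df["integral"].astype(float)))
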