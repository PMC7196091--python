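"""Reading and shaping direct-infusion MS acquisitions.

A sample is sprayed once and the instrument walks through three ionisation
modes in sequence: positive, then negative, then negative with in-source
fragmentation (CID).  With a 1 Hz scan rate the acquisition is a time
series of centroided scans that this module segments into the three mode
windows and collapses into one consensus spectrum per sample per mode.

Accepted inputs are open formats only: mzML (read via pyteomics) or a
plain peak-table TSV (UTF-8, tab-separated, header row, dot decimal
separator) with columns ``time, polarity, cid, mz, intensity``.
"""

from __future__ import annotations

import base64
import logging
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger("lipidflow")

__all__ = [
    "Scan",
    "Spectrum",
    "AcquisitionTiming",
    "read_scans",
    "segment_acquisition",
    "average_scans",
    "write_peak_table",
    "write_spectrum",
    "read_spectrum",
    "write_mzml",
    "read_manifest",
]


@dataclass
class Scan:
    """One centroided scan: relative acquisition time, mode flags, peaks."""

    time: float  # s, relative to aspiration start
    polarity: Optional[str] = None  # "positive" | "negative" | None
    cid: Optional[bool] = None
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities in scan")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            logger.warning("scan at t=%.1fs has unsorted m/z; re-sorting", self.time)
            order = np.argsort(self.mz, kind="stable")
            self.mz, self.intensity = self.mz[order], self.intensity[order]


@dataclass
class Spectrum:
    """Consensus peak list for one sample in one ionisation mode."""

    sample_id: str
    mode: str  # "positive" | "negative" | "negative-CID"
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_scans: int = 0

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz, self.intensity = self.mz[order], self.intensity[order]

    @property
    def is_empty(self) -> bool:
        return self.mz.size == 0


@dataclass
class AcquisitionTiming:
    """Mode-switch schedule of one spray, in seconds.

    Defaults follow the acquisition protocol: data start 20 s after
    aspiration begins, 72 s positive, then 66 s negative, then 66 s
    negative with CID.
    """

    start_delay: float = 20.0
    positive_window: float = 72.0
    negative_window: float = 66.0
    cid_window: float = 66.0

    def __post_init__(self):
        for v in (self.start_delay, self.positive_window,
                  self.negative_window, self.cid_window):
            if v < 0:
                raise ValueError("timing windows must be >= 0")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_scans(path, fmt: Optional[str] = None) -> List[Scan]:
    """Read centroided scans from mzML or peak-table TSV, time-sorted.

    ``fmt`` is inferred from the extension when not given.  Profile-mode
    mzML spectra raise an error: this pipeline consumes centroids only.
    """
    path = str(path)
    if fmt is None:
        fmt = "mzml" if path.lower().endswith(".mzml") else "tsv"
    if fmt == "mzml":
        scans = _read_mzml(path)
    elif fmt == "tsv":
        scans = _read_tsv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    scans.sort(key=lambda s: s.time)
    return scans


def _read_tsv(path) -> List[Scan]:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"malformed peak table {path}: {exc}") from exc
    required = {"time", "polarity", "cid", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} lacks columns {sorted(missing)}")
    scans = []
    for (t, pol, cid), grp in df.groupby(["time", "polarity", "cid"], sort=True):
        scans.append(
            Scan(
                time=float(t),
                polarity=None if pd.isna(pol) else str(pol),
                cid=bool(cid),
                mz=grp["mz"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
            )
        )
    return scans


def _read_mzml(path) -> List[Scan]:
    try:
        return _read_mzml_pyteomics(path)
    except ImportError:
        return _read_mzml_lxml(path)
    except Exception as exc:  # pyteomics needs psims for CV handling
        if "psims" in str(exc):
            return _read_mzml_lxml(path)
        raise


def _read_mzml_lxml(path) -> List[Scan]:
    """Minimal mzML reader (centroided MS1 subset) built on lxml.

    Reads what this pipeline consumes: scan start time, polarity, filter
    string, centroid/profile flag and the 32/64-bit (optionally
    zlib-compressed) m/z and intensity arrays.
    """
    from lxml import etree

    scans = []
    ns = "{http://psi.hupo.org/ms/mzml}"
    for i, (_, el) in enumerate(
        etree.iterparse(str(path), tag=(f"{ns}spectrum", "spectrum"))
    ):
        cv_names = {c.get("name") for c in el.iter(f"{ns}cvParam", "cvParam")}
        if "profile spectrum" in cv_names:
            raise ValueError(
                f"scan {i} in {path} is profile-mode; centroided data required"
            )
        pol = None
        if "positive scan" in cv_names:
            pol = "positive"
        elif "negative scan" in cv_names:
            pol = "negative"
        t = float(i)
        cid = False
        for c in el.iter(f"{ns}cvParam", "cvParam"):
            if c.get("name") == "scan start time":
                t = float(c.get("value"))
            elif c.get("name") == "filter string":
                cid = "cid" in (c.get("value") or "").lower()
        arrays = {}
        for bda in el.iter(f"{ns}binaryDataArray", "binaryDataArray"):
            names = {c.get("name") for c in bda.iter(f"{ns}cvParam", "cvParam")}
            node = bda.find(f"{ns}binary")
            if node is None:
                node = bda.find("binary")
            raw = base64.b64decode((node.text or "").encode("ascii"))
            if "zlib compression" in names:
                raw = zlib.decompress(raw)
            dtype = "<f4" if "32-bit float" in names else "<f8"
            arr = np.frombuffer(raw, dtype=dtype).astype(float)
            if "m/z array" in names:
                arrays["mz"] = arr
            elif "intensity array" in names:
                arrays["intensity"] = arr
        el.clear()
        scans.append(
            Scan(
                time=t,
                polarity=pol,
                cid=cid,
                mz=arrays.get("mz", np.empty(0)),
                intensity=arrays.get("intensity", np.empty(0)),
            )
        )
    return scans


def _read_mzml_pyteomics(path) -> List[Scan]:
    from pyteomics import mzml as _mzml

    scans = []
    with _mzml.read(path) as reader:
        for i, sp in enumerate(reader):
            if "profile spectrum" in sp:
                raise ValueError(
                    f"scan {i} in {path} is profile-mode; centroided data required"
                )
            pol = None
            if "positive scan" in sp:
                pol = "positive"
            elif "negative scan" in sp:
                pol = "negative"
            t = np.nan
            try:
                t = float(
                    sp["scanList"]["scan"][0]["scan start time"]
                )  # minutes or seconds per unit accession; pyteomics keeps value
            except (KeyError, IndexError, TypeError):
                pass
            cid = bool(sp.get("filter string") and "cid" in str(sp["filter string"]).lower())
            scans.append(
                Scan(
                    time=t if np.isfinite(t) else float(i),
                    polarity=pol,
                    cid=cid,
                    mz=sp["m/z array"],
                    intensity=sp["intensity array"],
                )
            )
    return scans


def read_manifest(path):
    """Sample manifest CSV: sample_id, group, tissue, sample_type[, path].

    ``sample_type`` must be one of study/qc/blank.  Returns a DataFrame
    indexed by sample_id.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"sample_id", "group", "tissue", "sample_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    bad = set(df["sample_type"]) - {"study", "qc", "blank"}
    if bad:
        raise ValueError(f"unknown sample_type values: {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in manifest")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# Segmentation and averaging
# ---------------------------------------------------------------------------

def segment_acquisition(
    scans: Sequence[Scan], timing: Optional[AcquisitionTiming] = None
) -> Tuple[List[Scan], List[Scan], List[Scan], int]:
    """Partition a spray's scans into (positive, negative, negative-CID).

    Window boundaries are relative to ``timing.start_delay``.  Scans whose
    own polarity/CID metadata contradicts their window are dropped with a
    warning; the dropped count is returned so callers can report it.
    """
    timing = timing or AcquisitionTiming()
    t0 = timing.start_delay
    b1 = t0 + timing.positive_window
    b2 = b1 + timing.negative_window
    b3 = b2 + timing.cid_window
    windows: Tuple[List[Scan], List[Scan], List[Scan]] = ([], [], [])
    dropped = 0
    for s in scans:
        if s.time < t0 or s.time >= b3:
            continue
        if s.time < b1:
            idx, pol, cid = 0, "positive", False
        elif s.time < b2:
            idx, pol, cid = 1, "negative", False
        else:
            idx, pol, cid = 2, "negative", True
        if (s.polarity is not None and s.polarity != pol) or (
            s.cid is not None and s.cid != cid
        ):
            dropped += 1
            continue
        windows[idx].append(s)
    if dropped:
        logger.warning("segment_acquisition dropped %d mislabelled scans", dropped)
    return windows[0], windows[1], windows[2], dropped


def average_scans(
    scans: Sequence[Scan],
    sample_id: str = "",
    mode: str = "positive",
    mz_bin_ppm: float = 5.0,
) -> Spectrum:
    """Merge a window's scans into one consensus spectrum.

    Peaks within ``mz_bin_ppm`` of each other across scans are merged:
    intensity is the mean over all scans in the window (absence counts as
    0), m/z the intensity-weighted mean.  The result does not depend on
    scan order.
    """
    scans = [s for s in scans if s.mz.size]
    n = len(scans)
    if n == 0:
        return Spectrum(sample_id, mode, n_scans=0)
    all_mz = np.concatenate([s.mz for s in scans])
    all_int = np.concatenate([s.intensity for s in scans])
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int = all_mz[order], all_int[order]
    # cluster: start a new bin where the gap to the previous peak exceeds
    # the ppm bin width at that m/z
    gaps = np.diff(all_mz) / all_mz[:-1] * 1e6
    new_bin = np.concatenate([[True], gaps > mz_bin_ppm])
    bin_idx = np.cumsum(new_bin) - 1
    nbins = bin_idx[-1] + 1
    sum_int = np.bincount(bin_idx, weights=all_int, minlength=nbins)
    sum_wmz = np.bincount(bin_idx, weights=all_int * all_mz, minlength=nbins)
    counts = np.bincount(bin_idx, minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mz_out = np.where(sum_int > 0, sum_wmz / sum_int, 0.0)
        # unweighted fallback for all-zero-intensity bins
        zero = sum_int == 0
        if zero.any():
            sum_mz = np.bincount(bin_idx, weights=all_mz, minlength=nbins)
            mz_out[zero] = sum_mz[zero] / counts[zero]
    int_out = sum_int / n  # absences count as zero
    return Spectrum(sample_id, mode, mz_out, int_out, n_scans=n)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_peak_table(scans: Sequence[Scan], path) -> None:
    """Write scans to the peak-table TSV dialect."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time\tpolarity\tcid\tmz\tintensity\n")
        for s in scans:
            pol = s.polarity or ""
            cid = int(bool(s.cid))
            for mz, it in zip(s.mz, s.intensity):
                fh.write(f"{s.time:.3f}\t{pol}\t{cid}\t{mz:.6f}\t{it:.6g}\n")


def write_spectrum(spec: Spectrum, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# sample_id={spec.sample_id}\tmode={spec.mode}\tn_scans={spec.n_scans}\n")
        fh.write("mz\tintensity\n")
        for mz, it in zip(spec.mz, spec.intensity):
            fh.write(f"{mz:.6f}\t{it:.8g}\n")


def read_spectrum(path) -> Spectrum:
    sample_id, mode, n_scans = "", "positive", 0
    mzs, its = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for part in line[1:].strip().split("\t"):
                    k, _, v = part.partition("=")
                    if k == "sample_id":
                        sample_id = v
                    elif k == "mode":
                        mode = v
                    elif k == "n_scans":
                        n_scans = int(v)
                continue
            if not line or line.startswith("mz\t"):
                continue
            a, b = line.split("\t")
            mzs.append(float(a))
            its.append(float(b))
    return Spectrum(sample_id, mode, np.array(mzs), np.array(its), n_scans)


def _b64(arr: np.ndarray) -> str:
    raw = struct.pack(f"<{arr.size}d", *arr.astype(float))
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def write_mzml(scans: Sequence[Scan], path, sample_id: str = "sample") -> None:
    """Write a minimal centroided mzML document readable by pyteomics.

    Covers exactly what :func:`read_scans` consumes — scan start time,
    polarity, centroid flag, zlib-compressed 64-bit m/z and intensity
    arrays.  Not a general-purpose mzML writer.
    """
    chunks = []
    for i, s in enumerate(scans):
        pol_cv = (
            '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
            if s.polarity == "positive"
            else '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>'
        )
        filt = "cid" if s.cid else "full"
        mz64, int64 = _b64(s.mz), _b64(s.intensity)
        chunks.append(f"""
      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{s.mz.size}">
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        {pol_cv}
        <cvParam cvRef="MS" accession="MS:1000512" name="filter string" value="{filt}"/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.time}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    body = "".join(chunks)
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1"><software id="lipidflow" version="0"/></softwareList>
  <instrumentConfigurationList count="1"><instrumentConfiguration id="IC1"/></instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="dp1"><processingMethod order="1" softwareRef="lipidflow"/></dataProcessing>
  </dataProcessingList>
  <run id="{sample_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{len(scans)}" defaultDataProcessingRef="dp1">{body}
    </spectrumList>
  </run>
</mzML>
"""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(doc)
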