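"""Tolerance selection, peak matching and matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from lipidflow.chem import ADDUCTS, LipidSpecies, SearchEntry, SearchList
from lipidflow.extraction import (
    InternalStandard,
    build_matrix,
    extract_cohort,
    is_deviation_report,
    match_peaks,
    select_ppm_cutoff,
)
from lipidflow.msio import Spectrum
from lipidflow.simulate import SimConfig, simulate_study


@pytest.mark.parametrize("n, ppm", [(50, 5.0), (99, 5.0), (600, 9.0),
                                    (501, 9.0), (300, 7.0), (100, 5.0),
                                    (500, 9.0)])
def test_ppm_cutoff_rule(n, ppm):
    assert select_ppm_cutoff(n) == ppm


def test_ppm_cutoff_monotone_and_bounded():
    vals = [select_ppm_cutoff(n) for n in range(1, 1000, 7)]
    assert all(5.0 <= v <= 9.0 for v in vals)
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_ppm_cutoff_rejects_empty_cohort():
    with pytest.raises(ValueError):
        select_ppm_cutoff(0)


def _single_entry_list(mz=772.5851, mode="positive"):
    sp = LipidSpecies("PC", 35, 2)
    return SearchList(mode, [SearchEntry(sp, ADDUCTS["+H"], mz)])


def test_match_exact_peak_zero_deviation():
    sl = _single_entry_list()
    spec = Spectrum("s", "positive", np.array([772.5851]), np.array([100.0]))
    (m,) = match_peaks(spec, sl, 5.0)
    assert m.deviation_ppm == pytest.approx(0.0, abs=1e-9)
    assert m.intensity == 100.0


def test_match_outside_tolerance_missed():
    sl = _single_entry_list()
    spec = Spectrum("s", "positive",
                    np.array([772.5851 * (1 + 10e-6)]), np.array([100.0]))
    assert match_peaks(spec, sl, 5.0) == []


@pytest.mark.parametrize("int_plus2, int_minus4, expect_dev", [
    (5.0, 10.0, -4.0),   # most intense wins
    (10.0, 5.0, +2.0),
    (7.0, 7.0, +2.0),    # tie -> smallest |deviation|
])
def test_match_picks_most_intense_then_nearest(int_plus2, int_minus4, expect_dev):
    target = 772.5851
    sl = _single_entry_list(target)
    mzs = np.sort([target * (1 + 2e-6), target * (1 - 4e-6)])
    ints = [int_minus4, int_plus2] if mzs[0] < target else [int_plus2, int_minus4]
    spec = Spectrum("s", "positive", mzs, np.array(ints, dtype=float))
    (m,) = match_peaks(spec, sl, 5.0)
    assert m.deviation_ppm == pytest.approx(expect_dev, abs=0.01)


def test_match_mode_mismatch_errors():
    sl = _single_entry_list(mode="positive")
    spec = Spectrum("s", "negative", np.array([772.5851]), np.array([1.0]))
    with pytest.raises(ValueError, match="mode"):
        match_peaks(spec, sl, 5.0)


def test_isobars_share_one_peak():
    pc = LipidSpecies("PC", 35, 2)
    pe = LipidSpecies("PE", 38, 2)
    sl = SearchList("positive", [SearchEntry(pc, ADDUCTS["+H"], 772.5851),
                                 SearchEntry(pe, ADDUCTS["+H"], 772.5851)])
    spec = Spectrum("s", "positive", np.array([772.5851]), np.array([42.0]))
    matches = match_peaks(spec, sl, 5.0)
    assert len(matches) == 2
    assert all(m.intensity == 42.0 for m in matches)


def test_match_count_monotone_in_tolerance():
    rng = np.random.default_rng(9)
    entries = [SearchEntry(LipidSpecies("PC", c, d), ADDUCTS["+H"],
                           700.0 + 10 * c + d)
               for c in range(30, 40) for d in range(0, 4)]
    entries.sort(key=lambda e: e.mz)
    sl = SearchList("positive", entries)
    mz = np.sort(np.concatenate([
        np.array([e.mz for e in entries]) * (1 + rng.normal(0, 4e-6, len(entries))),
    ]))
    spec = Spectrum("s", "positive", mz, rng.uniform(1, 10, mz.size))
    counts = [len(match_peaks(spec, sl, t)) for t in (1, 2, 5, 9, 15)]
    assert counts == sorted(counts)


def test_is_deviation_report_recovers_systematic_shift():
    sp = LipidSpecies("PC", 28, 0)
    std = InternalStandard("IS1", sp, ADDUCTS["+H"], 650.4755, ("positive",))
    rng = np.random.default_rng(4)
    spectra = {}
    for i in range(30):
        mz = std.expected_mz * (1 + (3 + rng.normal(0, 0.5)) * 1e-6)
        spectra[f"s{i}"] = {
            "positive": Spectrum(f"s{i}", "positive", np.array([mz]),
                                 np.array([5.0]))
        }
    rep = is_deviation_report(spectra, [std])
    row = rep.iloc[0]
    assert row["n_matched"] == 30
    assert row["mean_ppm"] == pytest.approx(3.0, abs=2 * row["sd_ppm"])


def test_is_deviation_report_flags_missing_standard():
    std = InternalStandard("ISx", LipidSpecies("PC", 28, 0), ADDUCTS["+H"],
                           650.4755, ("positive",))
    spectra = {"s0": {"positive": Spectrum("s0", "positive",
                                           np.array([900.0]), np.array([1.0]))}}
    rep = is_deviation_report(spectra, [std])
    assert bool(rep.iloc[0]["missing"]) is True


def test_exact_spectra_zero_deviation_report():
    std = InternalStandard("IS1", LipidSpecies("PC", 28, 0), ADDUCTS["+H"],
                           650.4755, ("positive",))
    spectra = {f"s{i}": {"positive": Spectrum(f"s{i}", "positive",
                                              np.array([std.expected_mz]),
                                              np.array([1.0]))}
               for i in range(5)}
    rep = is_deviation_report(spectra, [std])
    assert rep.iloc[0]["mean_ppm"] == pytest.approx(0.0, abs=1e-9)


def test_build_matrix_shapes_and_missing():
    sl = _single_entry_list()
    spec_hit = Spectrum("a", "positive", np.array([772.5851]), np.array([3.0]))
    spec_miss = Spectrum("b", "positive", np.array([500.0]), np.array([3.0]))
    matches = {
        "a": {"positive": match_peaks(spec_hit, sl, 5.0)},
        "b": {"positive": match_peaks(spec_miss, sl, 5.0)},
    }
    m = build_matrix(matches, {"positive": sl})
    assert m.values.shape == (2, 1)
    assert m.values.iloc[0, 0] == 3.0
    assert np.isnan(m.values.iloc[1, 0])  # unmatched stays missing, column kept


def test_build_matrix_two_adducts_two_columns():
    sp = LipidSpecies("PC", 34, 1)
    sl = SearchList("positive", [SearchEntry(sp, ADDUCTS["+H"], 760.5851),
                                 SearchEntry(sp, ADDUCTS["+Na"], 782.5670)])
    spec = Spectrum("a", "positive", np.array([760.5851, 782.5670]),
                    np.array([1.0, 2.0]))
    m = build_matrix({"a": {"positive": match_peaks(spec, sl, 5.0)}},
                     {"positive": sl})
    assert m.n_variables == 2


def test_synthetic_cohort_recovery_and_deviation_sd():
    """>=99% of true variables recovered at 9 ppm; deviation sd ~ jitter sd."""
    cfg = SimConfig(seed=21, n_per_group=8, n_blanks=1,
                    qc_levels=(0.5, 1.0))
    study = simulate_study(cfg)
    from lipidflow.extraction import match_peaks as mp

    recovered, expected = 0, 0
    devs = []
    for sid in study["truth"].fractions.index:
        for mode in ("positive", "negative"):
            sl = study["search_lists"][mode]
            matches = mp(study["spectra"][sid][mode], sl, 9.0)
            # count only true (non-IS) entries
            true_names = {f"{sp}" for sp in study["truth"].fractions.columns}
            exp = sum(1 for e in sl if str(e.species) in true_names)
            got = {m.entry_index for m in matches}
            rec = sum(1 for i, e in enumerate(sl)
                      if str(e.species) in true_names and i in got)
            expected += exp
            recovered += rec
            devs.extend(m.deviation_ppm for m in matches)
    assert recovered / expected >= 0.99
    assert np.std(devs) == pytest.approx(2.0, abs=0.5)


def test_extract_cohort_auto_tolerance():
    cfg = SimConfig(seed=3, n_per_group=4, n_blanks=1, qc_levels=(0.5, 1.0))
    study = simulate_study(cfg)
    m = extract_cohort(study["spectra"], study["search_lists"],
                       sample_meta=study["samples"])
    assert m.n_samples == len(study["spectra"])
    assert (m.variables["mode"].isin(
        ["positive", "negative", "negative-CID"])).all()
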