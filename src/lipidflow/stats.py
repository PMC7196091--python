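"""Abundance statistics, enzyme-ratio markers and biomarker discovery.

Candidate-biomarker (CBM) discovery couples a sparse partial least
squares discriminant analysis (sPLS-DA) with per-variable two-group t
tests.  Because untargeted lipidomics variables are strongly correlated,
the multiple-testing threshold uses the dependent-variable Bonferroni
rule alpha / sqrt(n) (e.g. p = 0.0022 for 500 variables) rather than the
conventional alpha / n.  A variable is called a candidate biomarker when
it both carries a nonzero sPLS-DA loading on some component and passes
the adjusted t-test threshold.

The sPLS-DA here is a NIPALS-style PLS1 against a +/-1 class code on
centred, unit-variance data, with each component's variable-weight vector
soft-thresholded to exactly ``keepX`` nonzero entries before deflation
(mixOmics-style sparsity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .extraction import IntensityMatrix

__all__ = [
    "RatioMarker",
    "DEFAULT_MARKERS",
    "SplsdaModel",
    "dependent_bonferroni",
    "test_variables",
    "enzyme_ratios",
    "fit_splsda",
    "discover_biomarkers",
    "abundance_summary",
    "pca_scores",
]


def dependent_bonferroni(alpha: float, n_variables: int) -> float:
    """Significance threshold adjusted for n dependent variables:
    alpha / sqrt(n)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_variables < 1:
        raise ValueError("n_variables must be >= 1")
    return alpha / math.sqrt(n_variables)


def standard_bonferroni(alpha: float, n_variables: int) -> float:
    """Conventional alpha / n correction (non-default alternative)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_variables < 1:
        raise ValueError("n_variables must be >= 1")
    return alpha / n_variables


# ---------------------------------------------------------------------------
# Per-variable tests
# ---------------------------------------------------------------------------

def _two_group_arrays(
    matrix: IntensityMatrix, group_col: str = "group"
) -> Tuple[np.ndarray, np.ndarray, Tuple[str, str]]:
    groups = matrix.samples[group_col]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    a = matrix.values.loc[groups == labels[0]].to_numpy(dtype=float)
    b = matrix.values.loc[groups == labels[1]].to_numpy(dtype=float)
    return a, b, (labels[0], labels[1])


def test_variables(
    matrix: IntensityMatrix,
    paired: bool = False,
    subject_col: str = "subject",
    log_transform: bool = False,
) -> pd.Series:
    """Two-sided t test per variable between the two sample groups.

    Welch (unequal variances) for unpaired designs; for ``paired=True``
    samples are matched by ``subject_col`` across the two groups (e.g.
    fasting vs 2 h within participant).  Variables with fewer than two
    observations per group yield NaN.
    """
    if paired:
        groups = matrix.samples["group"]
        labels = sorted(groups.unique())
        if len(labels) != 2:
            raise ValueError("exactly two groups required")
        va = matrix.values[groups == labels[0]].copy()
        vb = matrix.values[groups == labels[1]].copy()
        sa = matrix.samples.loc[va.index, subject_col]
        sb = matrix.samples.loc[vb.index, subject_col]
        common = sorted(set(sa) & set(sb))
        a = va.set_index(sa).loc[common].to_numpy(dtype=float)
        b = vb.set_index(sb).loc[common].to_numpy(dtype=float)
    else:
        a, b, _ = _two_group_arrays(matrix)
    if log_transform:
        with np.errstate(divide="ignore", invalid="ignore"):
            a, b = np.log(a), np.log(b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if paired:
            res = sps.ttest_rel(a, b, axis=0, nan_policy="omit")
        else:
            res = sps.ttest_ind(
                a, b, axis=0, equal_var=False, nan_policy="omit"
            )
    p = np.asarray(res.pvalue, dtype=float)
    n_a = np.sum(np.isfinite(a), axis=0)
    n_b = np.sum(np.isfinite(b), axis=0)
    p = np.where((n_a >= 2) & (n_b >= 2), p, np.nan)
    return pd.Series(p, index=matrix.values.columns, name="p_value")


# ---------------------------------------------------------------------------
# Enzyme-activity ratio markers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioMarker:
    """A lipid-pair abundance ratio used as an enzyme-activity proxy."""

    name: str
    numerator: str
    denominator: str

    def __post_init__(self):
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator must differ")


#: Built-in marker table: fatty-acid elongase, stearoyl-CoA desaturase
#: (SCD), and the delta-5/delta-6 desaturases FADS1/FADS2.
DEFAULT_MARKERS: Tuple[RatioMarker, ...] = (
    RatioMarker("elongase", "FA(18:0)", "FA(16:0)"),
    RatioMarker("elongase_PC", "PC(36:4)", "PC(34:2)"),
    RatioMarker("SCD", "CE(16:1)", "CE(16:0)"),
    RatioMarker("SCD_CE18", "CE(18:3)", "CE(18:2)"),
    RatioMarker("SCD_PC", "PC(32:1)", "PC(32:0)"),
    RatioMarker("FADS1", "PC(38:4)", "PC(38:3)"),
    RatioMarker("FADS1_TG", "TG(54:4)", "TG(54:3)"),
    RatioMarker("FADS2", "PC(36:3)", "PC(36:2)"),
    RatioMarker("FADS2_TG", "TG(50:3)", "TG(50:2)"),
)


def _species_columns(matrix: IntensityMatrix, species: str) -> List[str]:
    meta = matrix.variables
    return list(meta.index[meta["species"] == species])


def enzyme_ratios(
    matrix: IntensityMatrix,
    markers: Sequence[RatioMarker] = DEFAULT_MARKERS,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample marker ratios plus per-group summaries.

    Ratios run on normalised intensities; a species observed via several
    adducts contributes its summed fraction.  Markers whose variables are
    absent from the matrix are skipped with a warning; zero denominators
    yield a missing ratio for that sample.
    """
    per_sample = {}
    for mk in markers:
        num_cols = _species_columns(matrix, mk.numerator)
        den_cols = _species_columns(matrix, mk.denominator)
        if not num_cols or not den_cols:
            warnings.warn(f"marker {mk.name}: variables not in matrix; skipped")
            continue
        num = matrix.values[num_cols].sum(axis=1, min_count=1)
        den = matrix.values[den_cols].sum(axis=1, min_count=1)
        ratio = num / den.where(den > 0)
        per_sample[mk.name] = ratio
    ratios = pd.DataFrame(per_sample)
    rows = []
    if not ratios.empty and "group" in matrix.samples:
        for g, gmeta in matrix.samples.groupby("group"):
            sub = ratios.loc[ratios.index.intersection(gmeta.index)]
            for mk in ratios.columns:
                rows.append(
                    {
                        "marker": mk,
                        "group": g,
                        "mean": sub[mk].mean(),
                        "sd": sub[mk].std(),
                        "n": int(sub[mk].notna().sum()),
                    }
                )
    summary = pd.DataFrame(rows)
    if not summary.empty:
        piv = summary.pivot(index="marker", columns="group", values="mean")
        if piv.shape[1] == 2:
            g0, g1 = piv.columns
            direction = np.sign(piv[g1] - piv[g0])
            summary = summary.merge(
                direction.rename("direction_second_vs_first"),
                left_on="marker",
                right_index=True,
                how="left",
            )
    return ratios, summary


# ---------------------------------------------------------------------------
# Sparse PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class SplsdaModel:
    n_components: int
    keepx: int
    loadings: np.ndarray  # variables x components, soft-thresholded weights
    scores: np.ndarray  # samples x components
    x_loadings: np.ndarray  # regression loadings p (variables x components)
    y_weights: np.ndarray  # per-component y coefficient
    kept_counts: List[int]
    variable_ids: List[str]
    class_labels: Tuple[str, str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    seed: Optional[int] = None

    def selected_variables(self) -> List[str]:
        nz = np.any(self.loadings != 0, axis=1)
        return [v for v, keep in zip(self.variable_ids, nz) if keep]


def _soft_threshold_top(w: np.ndarray, keepx: int) -> np.ndarray:
    """Keep the keepx largest-|w| entries, soft-thresholded by the next one."""
    if keepx >= w.size:
        return w.copy()
    absw = np.abs(w)
    # threshold at the (keepx+1)-th largest magnitude
    lam = np.partition(absw, -keepx - 1)[-keepx - 1]
    out = np.sign(w) * np.maximum(absw - lam, 0.0)
    # enforce exactly keepx nonzeros in the face of ties
    nz = np.flatnonzero(out)
    if nz.size > keepx:
        order = nz[np.argsort(-np.abs(out[nz]), kind="stable")]
        out[order[keepx:]] = 0.0
    return out


def fit_splsda(
    matrix: IntensityMatrix,
    ncomp: int = 2,
    keepx: int = 10,
    seed: Optional[int] = None,
) -> SplsdaModel:
    """Fit a two-class sparse PLS-DA on centred, unit-variance data.

    The class membership is coded +/-1; each component's weight vector
    w proportional to X'y is soft-thresholded to exactly ``keepx`` nonzero
    entries and normalised, scores t = Xw are extracted and X and y are
    deflated by the regression loadings.  The algorithm is closed-form per
    component, hence deterministic; ``seed`` is recorded for provenance.
    Constant variables are dropped with a warning before fitting (their
    loadings are reported as zero).
    """
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    a, b, labels = _two_group_arrays(matrix)
    X_full = np.vstack([a, b])
    y = np.concatenate([-np.ones(len(a)), np.ones(len(b))])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 samples per class")
    if np.isnan(X_full).any():
        X_full = np.where(np.isnan(X_full), np.nanmean(X_full, axis=0), X_full)
    nvar_full = X_full.shape[1]
    sd = X_full.std(axis=0, ddof=1)
    keep_mask = sd > 0
    if not keep_mask.all():
        warnings.warn(
            f"dropping {int((~keep_mask).sum())} constant variable(s) before sPLS-DA"
        )
    X = X_full[:, keep_mask]
    if keepx > X.shape[1]:
        raise ValueError("keepX exceeds the number of usable variables")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    Xc = (X - mean) / scale
    yc = y - y.mean()

    nvar = Xc.shape[1]
    W = np.zeros((nvar, ncomp))
    P = np.zeros((nvar, ncomp))
    T = np.zeros((Xc.shape[0], ncomp))
    C = np.zeros(ncomp)
    kept = []
    Xd, yd = Xc.copy(), yc.copy()
    for h in range(ncomp):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w = _soft_threshold_top(w, keepx)
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        if tt == 0:
            break
        p = Xd.T @ t / tt
        c = yd @ t / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - t * c
        W[:, h], P[:, h], T[:, h], C[h] = w, p, t, c
        kept.append(int(np.count_nonzero(w)))

    # re-embed dropped constant variables with zero loadings
    W_full = np.zeros((nvar_full, ncomp))
    P_full = np.zeros((nvar_full, ncomp))
    W_full[keep_mask] = W
    P_full[keep_mask] = P
    mean_full = np.zeros(nvar_full)
    scale_full = np.ones(nvar_full)
    mean_full[keep_mask] = mean
    scale_full[keep_mask] = scale
    return SplsdaModel(
        n_components=ncomp,
        keepx=keepx,
        loadings=W_full,
        scores=T,
        x_loadings=P_full,
        y_weights=C,
        kept_counts=kept,
        variable_ids=list(matrix.values.columns),
        class_labels=labels,
        x_mean=mean_full,
        x_scale=scale_full,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Candidate-biomarker discovery
# ---------------------------------------------------------------------------

def discover_biomarkers(
    matrix: IntensityMatrix,
    alpha: float = 0.05,
    ncomp: int = 2,
    keepx: int = 10,
    seed: Optional[int] = None,
    paired: bool = False,
    correction: str = "dependent",
) -> pd.DataFrame:
    """Candidate biomarkers: sPLS-DA selection intersected with adjusted t.

    Returns the full per-variable table (group means/sds, p value, the
    threshold used, component loadings, selected flag); ``selected`` is
    True iff the variable has a nonzero loading on any component AND its
    p value beats alpha / sqrt(n_variables) (or alpha / n with
    ``correction='standard'``).
    """
    nvar = matrix.n_variables
    if correction == "dependent":
        threshold = dependent_bonferroni(alpha, nvar)
    elif correction == "standard":
        threshold = standard_bonferroni(alpha, nvar)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    p = test_variables(matrix, paired=paired)
    model = fit_splsda(matrix, ncomp=ncomp, keepx=min(keepx, nvar), seed=seed)
    a, b, labels = _two_group_arrays(matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a, mean_b = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
        sd_a, sd_b = np.nanstd(a, axis=0, ddof=1), np.nanstd(b, axis=0, ddof=1)
    nonzero = np.any(model.loadings != 0, axis=1)
    selected = nonzero & (p.to_numpy() < threshold)
    out = pd.DataFrame(
        {
            f"mean_{labels[0]}": mean_a,
            f"mean_{labels[1]}": mean_b,
            f"sd_{labels[0]}": sd_a,
            f"sd_{labels[1]}": sd_b,
            "p_value": p.to_numpy(),
            "threshold": threshold,
            "loading_c1": model.loadings[:, 0],
            "loading_c2": model.loadings[:, 1] if ncomp > 1 else 0.0,
            "splsda_selected": nonzero,
            "selected": selected,
        },
        index=matrix.values.columns,
    )
    return out


# ---------------------------------------------------------------------------
# Abundance summaries
# ---------------------------------------------------------------------------

def abundance_summary(
    matrix: IntensityMatrix, by_class: bool = False
) -> pd.DataFrame:
    """Group means, sds and log2 fold changes per variable or lipid class.

    With ``by_class=True`` member-variable fractions are summed per sample
    before comparison (e.g. total PE vs total PC per sample).
    """
    values = matrix.values
    if by_class:
        classes = matrix.variables["lipid_class"]
        values = values.T.groupby(classes).sum(min_count=1).T
    groups = matrix.samples["group"]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a = values.loc[groups == labels[0]]
    b = values.loc[groups == labels[1]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        lfc = np.log2(mb / ma)
    return pd.DataFrame(
        {
            f"mean_{labels[0]}": ma,
            f"mean_{labels[1]}": mb,
            f"sd_{labels[0]}": a.std(axis=0),
            f"sd_{labels[1]}": b.std(axis=0),
            "log2_fold_change": lfc,
        }
    )


def pca_scores(matrix: IntensityMatrix, n_components: int = 2) -> pd.DataFrame:
    """Thin convenience PCA projection for score plots."""
    from sklearn.decomposition import PCA

    X = matrix.values.to_numpy(dtype=float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    pcs = PCA(n_components=n_components).fit_transform(X - X.mean(axis=0))
    return pd.DataFrame(
        pcs,
        index=matrix.values.index,
        columns=[f"PC{i + 1}" for i in range(pcs.shape[1])],
    )
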