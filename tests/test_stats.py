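"""Adjusted thresholds, t tests, enzyme ratios and sparse PLS-DA."""

import numpy as np
import pandas as pd
import pytest

from lipidflow.stats import (
    DEFAULT_MARKERS,
    RatioMarker,
    abundance_summary,
    dependent_bonferroni,
    discover_biomarkers,
    enzyme_ratios,
    fit_splsda,
    test_variables as welch_t_per_variable,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Dependent-variable Bonferroni
# ---------------------------------------------------------------------------

def test_threshold_for_500_variables_prints_0_0022():
    thr = dependent_bonferroni(0.05, 500)
    assert float(f"{thr:.2g}") == 0.0022


@pytest.mark.parametrize("alpha, n, expected, tol", [
    (0.05, 1, 0.05, 1e-12),
    (0.05, 455, 0.002344, 1e-6),
])
def test_threshold_values(alpha, n, expected, tol):
    assert dependent_bonferroni(alpha, n) == pytest.approx(expected, abs=tol)


def test_threshold_scales_as_inverse_sqrt():
    for n in (10, 100, 455):
        assert dependent_bonferroni(0.05, 4 * n) == pytest.approx(
            dependent_bonferroni(0.05, n) / 2
        )
    ns = range(1, 200, 13)
    vals = [dependent_bonferroni(0.01, n) for n in ns]
    assert all(b < a for a, b in zip(vals, vals[1:]))


def test_threshold_rejects_bad_inputs():
    with pytest.raises(ValueError):
        dependent_bonferroni(0.0, 10)
    with pytest.raises(ValueError):
        dependent_bonferroni(0.05, 0)


# ---------------------------------------------------------------------------
# Per-variable t tests
# ---------------------------------------------------------------------------

def test_identical_groups_give_large_p():
    x = np.tile(np.linspace(1, 2, 10).reshape(-1, 1), (2, 5))
    m = make_matrix(np.vstack([x, x]), groups=["A"] * 20 + ["B"] * 20)
    p = welch_t_per_variable(m)
    assert (p > 0.99).all()


def test_power_at_three_pooled_sds():
    """A 3-sd shift at n=20/group beats p<0.0022 with power >= 0.9."""
    rng = np.random.default_rng(31)
    reps, hits = 500, 0
    n = 20
    for _ in range(reps):
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(3.0, 1.0, n)
        m = make_matrix(np.concatenate([a, b]).reshape(-1, 1) + 10.0,
                        groups=["A"] * n + ["B"] * n)
        hits += float(welch_t_per_variable(m).iloc[0]) < 0.0022
    assert hits / reps >= 0.9


def test_paired_design_spiked_variable_minimal_p():
    """Within-subject 0 h vs 2 h design: the one spiked variable wins."""
    rng = np.random.default_rng(37)
    n, p = 12, 30
    base = rng.lognormal(0, 0.3, size=(n, p))
    t0 = base * rng.normal(1, 0.05, size=(n, p))
    t2 = base * rng.normal(1, 0.05, size=(n, p))
    t2[:, 4] *= 1.6
    values = np.vstack([t0, t2])
    m = make_matrix(values, groups=["0h"] * n + ["2h"] * n)
    m.samples["subject"] = [f"p{i}" for i in range(n)] * 2
    pvals = welch_t_per_variable(m, paired=True)
    assert pvals.idxmin() == "v4"
    assert pvals["v4"] < dependent_bonferroni(0.05, p)


def test_too_few_observations_yield_nan():
    data = np.ones((4, 1))
    data[0, 0] = np.nan
    data[1, 0] = np.nan  # group A has 0 observations
    m = make_matrix(data, groups=["A", "A", "B", "B"])
    assert np.isnan(welch_t_per_variable(m).iloc[0])


def test_more_than_two_groups_rejected():
    m = make_matrix(np.ones((3, 2)), groups=["A", "B", "C"])
    with pytest.raises(ValueError):
        welch_t_per_variable(m)


# ---------------------------------------------------------------------------
# Enzyme-activity ratios
# ---------------------------------------------------------------------------

def test_builtin_marker_table_contains_named_ratios():
    table = {(mk.name, mk.numerator, mk.denominator) for mk in DEFAULT_MARKERS}
    assert ("elongase", "FA(18:0)", "FA(16:0)") in table
    assert ("SCD", "CE(16:1)", "CE(16:0)") in table
    assert ("FADS1", "PC(38:4)", "PC(38:3)") in table
    assert ("FADS2", "PC(36:3)", "PC(36:2)") in table
    assert ("FADS2_TG", "TG(50:3)", "TG(50:2)") in table


def test_ratio_arithmetic():
    m = make_matrix([[0.06, 0.03]], species=["TG(50:2)", "TG(50:3)"])
    marker = RatioMarker("FADS2_inv", "TG(50:2)", "TG(50:3)")
    ratios, _ = enzyme_ratios(m, [marker])
    assert ratios["FADS2_inv"].iloc[0] == pytest.approx(2.0)


def test_ratio_zero_denominator_missing():
    m = make_matrix([[0.06, 0.0]], species=["TG(50:2)", "TG(50:3)"])
    ratios, _ = enzyme_ratios(m, [RatioMarker("x", "TG(50:2)", "TG(50:3)")])
    assert np.isnan(ratios["x"].iloc[0])


def test_missing_marker_skipped_with_warning():
    m = make_matrix([[1.0]], species=["PC(34:1)"])
    with pytest.warns(UserWarning, match="skipped"):
        ratios, _ = enzyme_ratios(m, [RatioMarker("x", "TG(50:2)", "TG(50:3)")])
    assert ratios.empty


def test_ratio_direction_recovered_across_reps():
    """Group B ratio 1.5x group A: direction recovered in >=95% of reps."""
    rng = np.random.default_rng(41)
    reps, correct = 200, 0
    n = 10
    for _ in range(reps):
        den = rng.lognormal(0, 0.2, size=2 * n) * 0.04
        num_a = den[:n] * 1.0 * rng.lognormal(0, 0.2, n)
        num_b = den[n:] * 1.5 * rng.lognormal(0, 0.2, n)
        values = np.column_stack([np.concatenate([num_a, num_b]), den])
        m = make_matrix(values, groups=["A"] * n + ["B"] * n,
                        species=["TG(50:3)", "TG(50:2)"])
        ratios, summary = enzyme_ratios(
            m, [RatioMarker("FADS2_TG", "TG(50:3)", "TG(50:2)")]
        )
        means = summary.set_index("group")["mean"]
        correct += means["B"] > means["A"]
    assert correct / reps >= 0.95


# ---------------------------------------------------------------------------
# Sparse PLS-DA
# ---------------------------------------------------------------------------

def _separable_matrix(seed, n=30, p=200, k=5, shift=2.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, size=(2 * n, p))
    x[n:, :k] += shift
    return make_matrix(x - x.min() + 1.0, groups=["A"] * n + ["B"] * n)


def test_splsda_recovers_informative_variables():
    hits = 0
    runs = 100
    for seed in range(runs):
        m = _separable_matrix(seed)
        model = fit_splsda(m, ncomp=1, keepx=5, seed=seed)
        top = set(np.flatnonzero(model.loadings[:, 0]))
        hits += top == {0, 1, 2, 3, 4}
    assert hits / runs >= 0.9


def test_splsda_keepx_bounds_nonzeros():
    m = _separable_matrix(3)
    model = fit_splsda(m, ncomp=2, keepx=7)
    assert all(np.count_nonzero(model.loadings[:, h]) <= 7 for h in range(2))


def test_splsda_permutation_null_centres_on_chance():
    """Permuted labels: component-1 class separation is chance-level."""
    rng = np.random.default_rng(47)
    m = _separable_matrix(5, n=20, p=50, k=3, shift=1.5)
    real = fit_splsda(m, ncomp=1, keepx=10)
    t = real.scores[:, 0]
    y = np.array([0] * 20 + [1] * 20)

    def sep(t, y):
        return abs(t[y == 1].mean() - t[y == 0].mean()) / t.std(ddof=1)

    real_sep = sep(t, y)
    null_seps = []
    for _ in range(100):
        perm = rng.permutation(y)
        groups = np.where(perm == 0, "A", "B")
        m2 = make_matrix(m.values.to_numpy(), groups=groups)
        null = fit_splsda(m2, ncomp=1, keepx=10)
        null_seps.append(sep(null.scores[:, 0], perm))
    # the observed separation sits far outside the permutation null
    assert real_sep > np.quantile(null_seps, 0.95)
    assert np.mean(null_seps) < real_sep / 2


def test_splsda_dense_limit_matches_sklearn_pls():
    """keepX = n_variables: weights coincide with NIPALS PLS (sklearn)."""
    from sklearn.cross_decomposition import PLSRegression

    m = _separable_matrix(11, n=15, p=20, k=3)
    model = fit_splsda(m, ncomp=2, keepx=20)
    X = m.values.to_numpy()
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    y = np.array([-1.0] * 15 + [1.0] * 15)
    skl = PLSRegression(n_components=2, scale=False).fit(X, y - y.mean())
    for h in range(2):
        w_mine = model.loadings[:, h]
        w_skl = skl.x_weights_[:, h]
        sign = np.sign(w_mine @ w_skl)
        assert np.allclose(w_mine, sign * w_skl, atol=1e-8)


def test_splsda_seed_reproducible_to_1e10():
    m = _separable_matrix(13)
    a = fit_splsda(m, ncomp=2, keepx=10, seed=99)
    b = fit_splsda(m, ncomp=2, keepx=10, seed=99)
    assert np.max(np.abs(a.loadings - b.loadings)) < 1e-10
    assert np.max(np.abs(a.scores - b.scores)) < 1e-10


def test_splsda_drops_constant_variable():
    x = np.random.default_rng(0).normal(5, 1, size=(20, 5))
    x[:, 2] = 3.0
    m = make_matrix(x, groups=["A"] * 10 + ["B"] * 10)
    with pytest.warns(UserWarning, match="constant"):
        model = fit_splsda(m, ncomp=1, keepx=3)
    assert np.all(model.loadings[2] == 0)


# ---------------------------------------------------------------------------
# Biomarker discovery and abundance summaries
# ---------------------------------------------------------------------------

def test_discover_single_variable_large_effect():
    rng = np.random.default_rng(53)
    a = rng.normal(1.0, 0.1, size=(10, 1))
    b = rng.normal(3.0, 0.1, size=(10, 1))
    m = make_matrix(np.vstack([a, b]), groups=["A"] * 10 + ["B"] * 10)
    table = discover_biomarkers(m, keepx=1, ncomp=1)
    assert bool(table["selected"].iloc[0]) is True
    assert table["threshold"].iloc[0] == pytest.approx(0.05)  # n=1 -> alpha


def test_discover_selected_implies_both_conditions(two_group_matrix):
    table = discover_biomarkers(two_group_matrix, seed=0)
    sel = table[table["selected"]]
    assert (sel["p_value"] < sel["threshold"]).all()
    assert ((sel["loading_c1"] != 0) | (sel["loading_c2"] != 0)).all()


def test_abundance_equal_groups_zero_log2fc():
    x = np.tile(np.linspace(1, 2, 8).reshape(-1, 1), (2, 4))
    m = make_matrix(np.vstack([x, x]), groups=["A"] * 16 + ["B"] * 16)
    s = abundance_summary(m)
    assert np.allclose(s["log2_fold_change"], 0.0)


def test_abundance_by_class_sums_members():
    m = make_matrix([[0.2, 0.3, 0.5], [0.1, 0.4, 0.5]],
                    groups=["A", "B"])
    m.variables["lipid_class"] = ["PC", "PC", "PE"]
    s = abundance_summary(m, by_class=True)
    assert s.loc["PC", "mean_A"] == pytest.approx(0.5)
    assert s.loc["PC", "mean_B"] == pytest.approx(0.5)
    # total PE : PC ratio per sample is therefore computable
    assert s.loc["PE", "mean_A"] == pytest.approx(0.5)
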