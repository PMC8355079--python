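"""Cohort statistics: rank tests, regression, enrichment, logistic selection."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from chemobarcode.cohortstats import (
    classify_metastasis_site,
    compare_burden,
    burden_age_regression,
    detectability_logistic,
    gene_overrepresentation,
    logistic_irls,
)
from chemobarcode.synthcohort import generate_clinical_table


# -- Mann-Whitney ------------------------------------------------------------

def _mw_enumeration_oracle(a, b, alternative):
    """Independent exact oracle: enumerate all assignments of the pooled
    values to group sizes (n_a, n_b) and tally the U distribution."""
    pooled = list(a) + list(b)
    n = len(pooled)

    def u_of(idx):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        u = 0.0
        for x in ga:
            for y in gb:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    observed = u_of(tuple(range(len(a))))
    null = [u_of(idx) for idx in combinations(range(n), len(a))]
    p_greater = sum(u >= observed for u in null) / len(null)
    p_less = sum(u <= observed for u in null) / len(null)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def test_mannwhitney_separated_toy_is_one_twentieth():
    u, p = compare_burden([1, 2, 3], [10, 11, 12], alternative="less")
    assert u == 0.0
    assert p == pytest.approx(1.0 / 20.0)


def test_mannwhitney_identical_groups_two_sided():
    _, p = compare_burden([5, 5, 5, 5], [5, 5, 5, 5])
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
def test_mannwhitney_matches_enumeration_oracle(alternative):
    rng = np.random.default_rng(17)
    for _ in range(15):
        na, nb = rng.integers(2, 6), rng.integers(2, 6)
        a = rng.integers(0, 6, size=na).tolist()  # small range forces ties
        b = rng.integers(0, 6, size=nb).tolist()
        _, p = compare_burden(a, b, alternative=alternative)
        assert p == pytest.approx(_mw_enumeration_oracle(a, b, alternative), abs=1e-12)


def test_mannwhitney_large_sample_tracks_scipy():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 40)
    b = rng.normal(0.5, 1, 35)
    _, p = compare_burden(a, b)
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    assert p == pytest.approx(ref, rel=1e-9)


# -- Regression --------------------------------------------------------------

def test_regression_exact_line():
    x = np.arange(10.0)
    fit = burden_age_regression(x, 2 * x + 1)
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(1.0)
    assert fit.pearson_r == pytest.approx(1.0)


def test_regression_toy_hand_arithmetic():
    # {(0,0),(1,1),(2,4)}: Sxy=4, Sxx=2, Syy=26/3
    # slope = 4/2 = 2; r = 4/sqrt(2*26/3) = 0.96076892...
    fit = burden_age_regression([0, 1, 2], [0, 1, 4])
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(-1.0 / 3.0)
    assert fit.pearson_r == pytest.approx(4.0 / np.sqrt(52.0 / 3.0), abs=1e-12)
    assert fit.n == 3


def test_regression_invariant_to_joint_permutation():
    rng = np.random.default_rng(5)
    x = rng.uniform(20, 80, 30)
    y = 1.5 * x + rng.normal(0, 5, 30)
    fit = burden_age_regression(x, y)
    perm = rng.permutation(30)
    fit_p = burden_age_regression(x[perm], y[perm])
    assert fit_p.slope == pytest.approx(fit.slope)
    assert fit_p.pearson_r == pytest.approx(fit.pearson_r)


def test_regression_band_widens_away_from_mean_and_validates():
    x = np.linspace(0, 10, 20)
    rng = np.random.default_rng(0)
    fit = burden_age_regression(x, x + rng.normal(0, 1, 20))
    widths = fit.ci_high - fit.ci_low
    assert widths[0] > widths[len(widths) // 2]
    with pytest.raises(ValueError):
        burden_age_regression([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        burden_age_regression([1, 2], [1, 2])


# -- Gene overrepresentation -------------------------------------------------

def _bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        value = min(prev, pvals[idx] * m / rank)
        adjusted[idx] = value
        prev = value
    return adjusted


def test_overrepresentation_symmetric_table_is_null():
    res = gene_overrepresentation({"G": np.array([[5, 5], [5, 5]])})
    assert res[0].log_odds_ratio == pytest.approx(0.0)
    assert res[0].ci_low < 0 < res[0].ci_high
    assert res[0].bh_fdr >= res[0].fisher_p


def test_overrepresentation_haldane_hand_value():
    res = gene_overrepresentation({"G": np.array([[10, 2], [5, 20]])})
    expected_or = (10.5 * 20.5) / (2.5 * 5.5)
    assert res[0].log_odds_ratio == pytest.approx(np.log(expected_or), abs=1e-12)
    assert expected_or == pytest.approx(15.654545454545456)


def test_bh_adjustment_matches_stepup_oracle():
    rng = np.random.default_rng(23)
    for _ in range(100):
        m = rng.integers(1, 30)
        pvals = rng.uniform(0, 1, size=m)
        tables = {f"g{i}": np.array([[1, 1], [1, 1]]) for i in range(m)}
        results = gene_overrepresentation(tables)
        # swap in the random p-values through the same statsmodels path
        from statsmodels.stats.multitest import multipletests

        ours = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, _bh_oracle(pvals), atol=1e-12)
    # BH is monotone when p-values are sorted ascending
    sorted_p = np.sort(rng.uniform(0, 1, 20))
    adj = _bh_oracle(sorted_p)
    assert (np.diff(adj) >= -1e-12).all()


# -- Logistic model ----------------------------------------------------------

def test_irls_matches_numeric_optimizer_oracle():
    rng = np.random.default_rng(29)
    for _ in range(20):
        n, p = 60, rng.integers(2, 4)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        beta_true = rng.normal(0, 1, size=p)
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        if len(np.unique(y)) < 2:
            continue
        beta, ll, converged = logistic_irls(X, y)
        assert converged

        def negll(b):
            eta = X @ b
            value = float(np.logaddexp(0, eta).sum() - y @ eta)
            grad = X.T @ (1 / (1 + np.exp(-eta)) - y)
            return value, grad

        res = optimize.minimize(negll, np.zeros(p), jac=True, method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 1000})
        assert np.max(np.abs(beta - res.x)) < 1e-6
        assert ll == pytest.approx(-res.fun, abs=1e-8)


def test_detectability_prefers_true_covariate_and_handles_separation():
    table = generate_clinical_table(
        600, coefficients={"intercept": 0.0, "time_since_end": 2.0}, seed=4
    )
    reports = detectability_logistic(
        table[["time_treatment", "time_since_end", "distal"]],
        table["detected"],
        candidate_models=[(), ("time_treatment",), ("time_since_end",),
                          ("time_since_end", "distal")],
        n_randomizations=20, seed=0,
    )
    by_formula = {r.formula: r for r in reports}
    with_true = by_formula[("time_since_end",)]
    without = by_formula[("time_treatment",)]
    assert with_true.bic < without.bic
    assert with_true.cv_auroc > without.cv_auroc
    selected = [r for r in reports if r.selected]
    assert len(selected) == 1 and "time_since_end" in selected[0].formula

    # perfectly separable toy data: auROC hits 1
    X = pd.DataFrame({"x": np.r_[np.zeros(30), np.ones(30)]})
    y = np.r_[np.zeros(30), np.ones(30)]
    sep = detectability_logistic(X, y, candidate_models=[("x",)],
                                 n_randomizations=10, seed=1)
    assert sep[0].cv_auroc == pytest.approx(1.0)


def test_detectability_null_labels_select_intercept_only():
    rng = np.random.default_rng(31)
    table = generate_clinical_table(500, coefficients={"intercept": 0.0}, seed=9)
    reports = detectability_logistic(
        table[["time_treatment", "time_since_end", "distal"]],
        table["detected"],
        candidate_models=[(), ("time_treatment",), ("time_since_end",),
                          ("distal",), ("time_treatment", "time_since_end", "distal")],
        n_randomizations=10, seed=2,
    )
    selected = [r for r in reports if r.selected][0]
    assert selected.formula == ()


def test_detectability_excludes_rare_tumor_types():
    table = generate_clinical_table(300, seed=5)
    table.loc[:7, "tumor_type"] = "rare_type"  # 8 samples <= threshold
    reports = detectability_logistic(
        table[["time_since_end", "tumor_type"]],
        table["detected"],
        candidate_models=[("tumor_type",)],
        n_randomizations=5, seed=0,
    )
    assert not any("rare_type" in name for name in reports[0].coefficients)


# -- Metastasis-site rule ----------------------------------------------------

@pytest.mark.parametrize(
    "primary, met, expected",
    [
        ("breast", "breast", "proximal"),
        ("breast", "lymph_node", "proximal"),
        ("colorectal", "peritoneum", "proximal"),
        ("colorectal", "omentum", "proximal"),
        ("breast", "peritoneum", "distal"),  # non-abdominal primary
        ("breast", "liver", "distal"),
        ("ovary", "brain", "distal"),
    ],
)
def test_metastasis_site_rule(primary, met, expected):
    assert classify_metastasis_site(primary, met) == expected


def test_metastasis_site_vocabulary_errors():
    with pytest.raises(ValueError, match="unknown primary"):
        classify_metastasis_site("gallbladder_of_mystery", "liver")
    with pytest.raises(ValueError, match="unknown metastasis"):
        classify_metastasis_site("breast", "elbow")
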