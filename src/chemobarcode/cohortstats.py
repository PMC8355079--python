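"""Cohort-level statistics for the barcode analyses.

Burden comparisons (Mann-Whitney, exact for small cohorts), mutation
burden vs age regression with confidence bands, per-gene mutation
overrepresentation with Benjamini-Hochberg control, the
treatment-detectability multivariate logistic model with BIC and
cross-validated auROC model selection, and the proximal/distal
metastasis-site rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

# ---------------------------------------------------------------------------
# Mann-Whitney burden comparison
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 12  # combined size at or below which the exact null is enumerated


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a (number of (a, b) pairs with a > b, ties counting 1/2)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def compare_burden(group_a, group_b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U (for group_a) and p-value.

    Exact enumeration of all rank splits when n_a + n_b <= 12 (handles
    ties); otherwise the tie-corrected normal approximation with
    mid-ranks and continuity correction. ``alternative`` is "two-sided"
    or "greater" (group_a stochastically larger).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    u = _u_statistic(a, b)
    if a.size + b.size <= _EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        n = pooled.size
        stats_null = []
        for idx in combinations(range(n), a.size):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            stats_null.append(_u_statistic(pooled[mask], pooled[~mask]))
        stats_null = np.asarray(stats_null)
        p_greater = float((stats_null >= u).mean())
        p_less = float((stats_null <= u).mean())
    else:
        res_g = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
        res_l = stats.mannwhitneyu(a, b, alternative="less", method="asymptotic")
        p_greater, p_less = float(res_g.pvalue), float(res_l.pvalue)
    if alternative == "greater":
        return u, p_greater
    if alternative == "less":
        return u, p_less
    return u, min(1.0, 2.0 * min(p_greater, p_less))


# ---------------------------------------------------------------------------
# Burden vs age regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    x: np.ndarray
    ci_low: np.ndarray  # 95% confidence band for the mean response at x
    ci_high: np.ndarray

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def burden_age_regression(ages, counts) -> RegressionFit:
    """OLS of mutation count on age with Pearson r and a 95% mean-response band."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("ages are all equal; regression is degenerate")
    n = x.size
    slope, intercept, r, p, _ = stats.linregress(x, y)
    resid = y - (intercept + slope * x)
    s2 = (resid**2).sum() / (n - 2)
    sxx = ((x - x.mean()) ** 2).sum()
    se_mean = np.sqrt(s2 * (1.0 / n + (x - x.mean()) ** 2 / sxx))
    tcrit = stats.t.ppf(0.975, n - 2)
    fitted = intercept + slope * x
    return RegressionFit(
        slope=float(slope), intercept=float(intercept), pearson_r=float(r),
        p_value=float(p), n=n, x=x,
        ci_low=fitted - tcrit * se_mean, ci_high=fitted + tcrit * se_mean,
    )


# ---------------------------------------------------------------------------
# Gene overrepresentation
# ---------------------------------------------------------------------------


@dataclass
class ORResult:
    gene: str
    log_odds_ratio: float
    ci_low: float
    ci_high: float
    fisher_p: float
    bh_fdr: float


def gene_overrepresentation(tables: dict[str, np.ndarray]) -> list[ORResult]:
    """Per-gene 2x2 enrichment: Haldane-corrected log-OR, Wald CI, Fisher p, BH FDR.

    Each table is [[mutated_A, unmutated_A], [mutated_B, unmutated_B]].
    The 0.5 Haldane correction applies to every cell for the odds ratio
    and its CI; the Fisher exact test uses the raw counts.
    """
    genes = list(tables)
    results = []
    pvals = []
    for gene in genes:
        t = np.asarray(tables[gene], dtype=float)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError(f"{gene}: table must be a non-negative 2x2")
        c = t + 0.5
        log_or = float(np.log(c[0, 0] * c[1, 1] / (c[0, 1] * c[1, 0])))
        se = float(np.sqrt((1.0 / c).sum()))
        _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        pvals.append(float(p))
        results.append((gene, log_or, log_or - 1.959963984540054 * se,
                        log_or + 1.959963984540054 * se, float(p)))
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        ORResult(gene=g, log_odds_ratio=lo, ci_low=cl, ci_high=ch, fisher_p=p, bh_fdr=float(q))
        for (g, lo, cl, ch, p), q in zip(results, fdr)
    ]


# ---------------------------------------------------------------------------
# Logistic detectability model
# ---------------------------------------------------------------------------


def logistic_irls(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, float, bool]:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Returns (coefficients, loglik, converged). Complete separation drives
    coefficients to large values; the fit is then reported at the
    iteration cap with converged=False.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(X.T @ wx, wx.T @ z, rcond=None)[0]
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    loglik = float((y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)).sum())
    return beta, loglik, converged


@dataclass
class LogisticModelReport:
    formula: tuple[str, ...]  # covariate subset
    coefficients: dict[str, float]
    loglik: float
    bic: float
    cv_auroc: float
    converged: bool
    selected: bool = False


def _build_design(
    features: pd.DataFrame, covariates: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; continuous covariates z-scored,
    categorical one-hot (first level dropped), 'a:b' as product columns."""
    cols: list[np.ndarray] = [np.ones(len(features))]
    names = ["intercept"]

    def column(name: str) -> list[tuple[str, np.ndarray]]:
        series = features[name]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            levels = sorted(series.unique())
            return [(f"{name}[{lv}]", (series == lv).to_numpy(float)) for lv in levels[1:]]
        v = series.to_numpy(float)
        uniq = np.unique(v)
        if set(uniq).issubset({0.0, 1.0}):
            return [(name, v)]
        sd = v.std()
        return [(name, (v - v.mean()) / (sd if sd > 0 else 1.0))]

    for cov in covariates:
        if ":" in cov:
            left, right = cov.split(":", 1)
            for lname, lcol in column(left):
                for rname, rcol in column(right):
                    cols.append(lcol * rcol)
                    names.append(f"{lname}:{rname}")
        else:
            for cname, ccol in column(cov):
                cols.append(ccol)
                names.append(cname)
    return np.column_stack(cols), names


def detectability_logistic(
    features: pd.DataFrame,
    labels,
    candidate_models: list[tuple[str, ...]],
    cv_fraction: float = 0.3,
    n_randomizations: int = 100,
    seed: int = 0,
    min_type_count: int = 10,
) -> list[LogisticModelReport]:
    """Fit candidate logistic models of footprint detectability and select one.

    Tumor types with ``min_type_count`` samples or fewer are excluded
    before fitting. Each candidate (a tuple of covariate names, ':' for
    interactions) is fit by IRLS; BIC = -2 loglik + p ln n; cv_auroc is
    the mean test auROC over ``n_randomizations`` random 30% holdouts.
    The selected model has the lowest BIC, ties broken by higher auROC.
    """
    features = features.copy()
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    if "tumor_type" in features.columns:
        keep = features.groupby("tumor_type")["tumor_type"].transform("size") > min_type_count
        features = features.loc[keep].reset_index(drop=True)
        labels = labels[keep.to_numpy()]
    n = len(features)
    rng = np.random.default_rng(seed)
    splits = []
    n_test = max(1, int(round(cv_fraction * n)))
    for _ in range(n_randomizations):
        perm = rng.permutation(n)
        splits.append((perm[n_test:], perm[:n_test]))

    reports = []
    for model in candidate_models:
        X, names = _build_design(features, tuple(model))
        beta, loglik, converged = logistic_irls(X, labels)
        bic = -2.0 * loglik + X.shape[1] * np.log(n)
        aucs = []
        for train, test in splits:
            if len(np.unique(labels[test])) < 2 or len(np.unique(labels[train])) < 2:
                continue
            b, _, _ = logistic_irls(X[train], labels[train])
            scores = X[test] @ b
            aucs.append(roc_auc_score(labels[test], scores))
        cv_auroc = float(np.mean(aucs)) if aucs else float("nan")
        reports.append(
            LogisticModelReport(
                formula=tuple(model),
                coefficients={nm: float(b) for nm, b in zip(names, beta)},
                loglik=loglik, bic=float(bic), cv_auroc=cv_auroc, converged=converged,
            )
        )
    order = sorted(
        range(len(reports)),
        key=lambda i: (reports[i].bic, -(reports[i].cv_auroc if np.isfinite(reports[i].cv_auroc) else -1.0)),
    )
    reports[order[0]].selected = True
    return reports


# ---------------------------------------------------------------------------
# Metastasis-site classification
# ---------------------------------------------------------------------------

ABDOMINAL_PRIMARIES = frozenset({
    "colorectal", "colon", "rectum", "stomach", "pancreas", "liver", "ovary",
    "uterus", "kidney", "bladder", "urinary_tract",
})
PRIMARY_SITES = frozenset({
    "breast", "lung", "prostate", "skin", "esophagus", "head_and_neck",
}) | ABDOMINAL_PRIMARIES
METASTASIS_SITES = PRIMARY_SITES | frozenset({"lymph_node", "omentum", "peritoneum",
                                              "brain", "bone", "adrenal"})


def classify_metastasis_site(primary_site: str, metastasis_site: str) -> str:
    """Proximal iff same organ, a lymph node, or omentum/peritoneum for an
    abdominal primary; otherwise distal."""
    primary = primary_site.strip().lower().replace(" ", "_")
    met = metastasis_site.strip().lower().replace(" ", "_")
    if primary not in PRIMARY_SITES:
        raise ValueError(f"unknown primary site {primary_site!r}; known: {sorted(PRIMARY_SITES)}")
    if met not in METASTASIS_SITES:
        raise ValueError(f"unknown metastasis site {metastasis_site!r}; known: {sorted(METASTASIS_SITES)}")
    if met == primary or met == "lymph_node":
        return "proximal"
    if primary in ABDOMINAL_PRIMARIES and met in ("omentum", "peritoneum"):
        return "proximal"
    return "distal"
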