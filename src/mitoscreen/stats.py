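"""Distribution-adaptive two-group testing, correlation analysis, and the
membrane-potential regression.

Test selection follows the assay's decision scheme: normally distributed
data are compared by unpaired Welch t-test; non-normal but symmetric data
by Mann-Whitney U; asymmetric data by a permutation test (default 1e7
permutations at full scale, configurable).  Normality is assessed by
Shapiro-Wilk per group (both must pass); symmetry by the Cabilio-Masaro
and Mira statistics about the median, and a sample is called asymmetric
if either test rejects.  Categorical contingency tables use Fisher's
exact test; families of tests are Bonferroni-corrected.

Pearson correlations are categorised as negligible (|r| < 0.30), low
(0.30 < |r| < 0.50), moderate (0.50 < |r| < 0.70) or high; the
correlation matrix is ordered by average-linkage hierarchical clustering
on Euclidean distances between the features' correlation vectors.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

__all__ = [
    "TestResult",
    "select_test",
    "symmetry_tests",
    "welch_t",
    "mann_whitney",
    "permutation_test",
    "fisher_exact",
    "bonferroni",
    "compare_groups",
    "correlation_matrix",
    "CorrelationReport",
    "fit_membrane_potential_model",
    "RegressionResult",
    "doubling_time",
]


@dataclass
class TestResult:
    """Outcome of one two-sample (or contingency) test."""

    feature: str
    test: str
    statistic: float
    p_value: float
    p_bonferroni: float | None = None
    mean_a: float | None = None
    mean_b: float | None = None
    median_a: float | None = None
    median_b: float | None = None
    n_a: int | None = None
    n_b: int | None = None


def _vec(x, min_n, name="sample"):
    x = np.asarray(x, dtype=np.float64).ravel()
    if len(x) < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations")
    return x


# ---------------------------------------------------------------------------
# Symmetry tests (about the median)
# ---------------------------------------------------------------------------

_CM_VAR = 0.5708  # asymptotic variance of sqrt(n)(mean-median)/sd, normal law


def symmetry_tests(sample, alpha: float = 0.05):
    """Cabilio-Masaro and Mira asymptotic tests of symmetry.

    Both studentize the mean-median distance.  Cabilio-Masaro compares
    ``sqrt(n)(mean - median)/sd`` with its normal-law asymptotic variance
    (0.5708); Mira studentizes the Bonferroni measure ``2(mean - median)``
    with a distribution-free plug-in variance using a Gaussian-kernel
    density estimate at the median.  Returns
    ``(stat_cm, p_cm, stat_mira, p_mira, asymmetric)`` where
    ``asymmetric`` is True if either test rejects at ``alpha``
    (the scheme's "any test indicates asymmetry" rule).
    """
    x = _vec(sample, 10)
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("constant sample: symmetry undefined")
    n = len(x)
    med = float(np.median(x))
    mean = float(x.mean())

    stat_cm = math.sqrt(n) * (mean - med) / s
    p_cm = 2.0 * sps.norm.sf(abs(stat_cm) / math.sqrt(_CM_VAR))

    # Mira: gamma = 2(mean - median); var estimate via density at median.
    # The KDE smooths the density peak by its bandwidth h; the
    # normal-reference factor sqrt(1 + h^2/s^2) undoes that bias.
    gamma = 2.0 * (mean - med)
    kde = sps.gaussian_kde(x)
    h = float(kde.factor) * s
    f_med = float(kde(med)[0]) * math.sqrt(1.0 + (h / s) ** 2)
    f_med = max(f_med, 1e-12)
    mad_med = float(np.abs(x - med).mean())
    var_gamma = 4.0 * (s ** 2 + 1.0 / (4.0 * f_med ** 2)
                       - mad_med / f_med)
    var_gamma = max(var_gamma, 1e-12)
    stat_mira = math.sqrt(n) * gamma / math.sqrt(var_gamma)
    p_mira = 2.0 * sps.norm.sf(abs(stat_mira))

    asymmetric = bool(p_cm < alpha or p_mira < alpha)
    return stat_cm, p_cm, stat_mira, p_mira, asymmetric


def select_test(sample_a, sample_b, alpha_dist: float = 0.05) -> str:
    """Choose the two-sample test by distribution shape.

    Returns ``"welch_t"`` if both samples pass Shapiro-Wilk normality at
    ``alpha_dist``; otherwise ``"mann_whitney"`` if both samples are
    symmetric (neither symmetry test rejects in either sample);
    otherwise ``"permutation"``.
    """
    a = _vec(sample_a, 3, "sample_a")
    b = _vec(sample_b, 3, "sample_b")
    normal = all(sps.shapiro(x).pvalue >= alpha_dist for x in (a, b))
    if normal:
        return "welch_t"
    symmetric = True
    for x in (a, b):
        if len(x) < 10 or x.std(ddof=1) == 0:
            symmetric = False
            break
        *_, asym = symmetry_tests(x, alpha=alpha_dist)
        if asym:
            symmetric = False
            break
    return "mann_whitney" if symmetric else "permutation"


# ---------------------------------------------------------------------------
# Two-sample tests
# ---------------------------------------------------------------------------

def _describe(res: TestResult, a, b) -> TestResult:
    res.mean_a, res.mean_b = float(np.mean(a)), float(np.mean(b))
    res.median_a, res.median_b = float(np.median(a)), float(np.median(b))
    res.n_a, res.n_b = len(a), len(b)
    return res


def welch_t(sample_a, sample_b, feature: str = "") -> TestResult:
    """Unpaired two-sided t-test with Welch's correction."""
    a = _vec(sample_a, 2, "sample_a")
    b = _vec(sample_b, 2, "sample_b")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return _describe(TestResult(feature, "welch_t", float(t), float(p)),
                     a, b)


def mann_whitney(sample_a, sample_b, feature: str = "") -> TestResult:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    The reported U is the statistic of ``sample_a`` (number of (a, b)
    pairs with a > b, ties counting 1/2).  Exact enumeration is used for
    min(n) <= 8 without ties, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = _vec(sample_a, 1, "sample_a")
    b = _vec(sample_b, 1, "sample_b")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) \
        else "asymptotic"
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return _describe(TestResult(feature, "mann_whitney", float(u), float(p)),
                     a, b)


def permutation_test(sample_a, sample_b, n_perm: int = 10 ** 7,
                     seed: int | np.random.Generator | None = 0,
                     feature: str = "",
                     exact_limit: int = 10 ** 6) -> TestResult:
    """Two-sided permutation test on the difference of means.

    Monte-Carlo p uses the add-one convention
    ``(1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm)`` (guarantees p > 0);
    when the number of distinct group-A assignments is at most
    ``exact_limit`` the full enumeration is used instead and the p-value
    is the exact proportion.  Seed-reproducible.
    """
    a = _vec(sample_a, 3, "sample_a")
    b = _vec(sample_b, 3, "sample_b")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    t_obs = a.mean() - b.mean()
    total = math.comb(na + nb, na)
    if total <= exact_limit:
        from itertools import combinations

        idx = np.fromiter(
            (i for comb in combinations(range(na + nb), na) for i in comb),
            dtype=np.intp, count=total * na).reshape(total, na)
        sums = pooled[idx].sum(axis=1)
        t_perm = sums / na - (pooled.sum() - sums) / nb
        hits = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
        p = hits / total
        return _describe(
            TestResult(feature, "permutation", float(t_obs), float(p)),
            a, b)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    hits = 0
    chunk = max(1, min(n_perm, 2_000_000 // (na + nb)))
    done = 0
    base = np.broadcast_to(np.arange(na + nb), (chunk, na + nb))
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.ascontiguousarray(base[:m]), axis=1)
        sums = pooled[perm[:, :na]].sum(axis=1)
        t_perm = sums / na - (pooled.sum() - sums) / nb
        hits += int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
        done += m
    p = (1 + hits) / (1 + n_perm)
    return _describe(
        TestResult(feature, "permutation", float(t_obs), float(p)), a, b)


def fisher_exact(table, feature: str = "") -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums, over the hypergeometric support with the observed
    margins, the probabilities of all tables at most as probable as the
    observed one.  Computed by exact integer enumeration (math.comb), so
    ties are handled exactly.  A zero margin gives p = 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    t = t.astype(np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    k = a + c  # first-column margin
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return TestResult(feature, "fisher_exact", float("nan"), 1.0)
    lo, hi = max(0, k - r2), min(r1, k)
    # integer weights proportional to hypergeometric probabilities
    w = {x: math.comb(r1, x) * math.comb(r2, k - x) for x in range(lo, hi + 1)}
    w_obs = w[a]
    total = sum(w.values())
    p = sum(v for v in w.values() if v <= w_obs) / total
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    res = TestResult(feature, "fisher_exact", float(odds), float(min(p, 1.0)))
    res.n_a, res.n_b = r1, r2
    return res


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: p * m capped at 1 (m = family size)."""
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def compare_groups(table: pd.DataFrame, features, group_col: str = "group",
                   case_label: str = "case", alpha_dist: float = 0.05,
                   n_perm: int = 10 ** 5, seed: int = 0) -> pd.DataFrame:
    """Distribution-adaptive two-group comparison over a feature family.

    For each feature the test is chosen by :func:`select_test` and run;
    the family's p-values are Bonferroni-adjusted.  Returns one row per
    feature with test name, statistic, raw and adjusted p, group
    means/medians and group sizes.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for feat in features:
        sub = table[[feat, group_col]].dropna()
        a = sub.loc[sub[group_col] == case_label, feat].to_numpy()
        b = sub.loc[sub[group_col] != case_label, feat].to_numpy()
        name = select_test(a, b, alpha_dist=alpha_dist)
        if name == "welch_t":
            res = welch_t(a, b, feature=feat)
        elif name == "mann_whitney":
            res = mann_whitney(a, b, feature=feat)
        else:
            res = permutation_test(a, b, n_perm=n_perm, seed=rng,
                                   feature=feat)
        rows.append(res)
    out = pd.DataFrame([vars(r) for r in rows])
    out["p_bonferroni"] = bonferroni(out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Correlation analysis
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with categorical interpretation."""

    r: pd.DataFrame
    pairs: pd.DataFrame  # feature_a, feature_b, r, category
    leaf_order: list[str] = field(default_factory=list)
    linkage: np.ndarray | None = None
    excluded: list[str] = field(default_factory=list)


def categorize_r(r: float) -> str:
    a = abs(r)
    if a < 0.30:
        return "negligible"
    if a < 0.50:
        return "low"
    if a < 0.70:
        return "moderate"
    return "high"


def correlation_matrix(features: pd.DataFrame) -> CorrelationReport:
    """Pearson correlation matrix over feature columns with category
    labels and an average-linkage clustering order.

    Constant columns are excluded (logged in the report).  The leaf order
    comes from average-linkage hierarchical clustering on Euclidean
    distances between the features' correlation vectors.
    """
    num = features.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 rows")
    excluded = [c for c in num.columns if num[c].nunique() <= 1]
    num = num.drop(columns=excluded)
    r = num.corr(method="pearson")
    pairs = []
    cols = list(r.columns)
    for i, fa in enumerate(cols):
        for fb in cols[i + 1:]:
            val = float(r.loc[fa, fb])
            pairs.append(dict(feature_a=fa, feature_b=fb, r=val,
                              category=categorize_r(val)))
    link = hierarchy.linkage(r.to_numpy(), method="average",
                             metric="euclidean")
    order = [cols[i] for i in hierarchy.leaves_list(link)]
    return CorrelationReport(r=r, pairs=pd.DataFrame(pairs),
                             leaf_order=order, linkage=link,
                             excluded=excluded)


# ---------------------------------------------------------------------------
# Membrane-potential regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """OLS summary: term names, estimates, t values, p values, R^2."""

    terms: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "estimate": self.estimates,
                             "std_error": self.std_errors,
                             "t_value": self.t_values,
                             "p_value": self.p_values})


DEFAULT_REGRESSION_TERMS = ["MitoVolumeMean", "MitoSkel", "MitoEndpoints",
                            "MitoNodeDegree"]


def fit_membrane_potential_model(
        table: pd.DataFrame, response: str = "TMRM_MitoMask",
        morphology_terms: list[str] | None = None,
        diagnosis_col: str = "group", case_label: str = "case",
        age_col: str = "age", gender_col: str = "gender",
) -> RegressionResult:
    """OLS of TMRM fluorescence on mitochondrial morphology + covariates.

    Predictors: MitoVolumeMean, MitoSkel, MitoEndpoints, MitoNodeDegree,
    diagnosis (0/1, case = 1), age, and gender (0/1, male = 1), plus an
    intercept.  Gender reference level is female; diagnosis reference is
    control.  Raises on rank deficiency, naming the offending columns.
    """
    import statsmodels.api as sm

    terms = list(morphology_terms or DEFAULT_REGRESSION_TERMS)
    df = table.copy()
    X = df[terms].astype(float).copy()
    if diagnosis_col in df:
        X["diagnosis"] = (df[diagnosis_col] == case_label).astype(float)
    if age_col in df:
        X["age"] = df[age_col].astype(float)
    if gender_col in df:
        X["gender"] = (df[gender_col].astype(str)
                       .str.upper().str.startswith("M")).astype(float)
    y = df[response].astype(float)
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X[keep], y[keep]
    if len(X) < X.shape[1] + 2:
        raise ValueError("too few rows for the number of predictors")
    Xc = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        bad = [c for c in X.columns
               if np.linalg.matrix_rank(
                   Xc.drop(columns=[c]).to_numpy()) == rank]
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    fit = sm.OLS(y, Xc).fit()
    return RegressionResult(
        terms=list(Xc.columns), estimates=fit.params.to_numpy(),
        std_errors=fit.bse.to_numpy(), t_values=fit.tvalues.to_numpy(),
        p_values=fit.pvalues.to_numpy(), r_squared=float(fit.rsquared),
        n=int(fit.nobs))


def doubling_time(n0: float, n1: float, delta_t: float) -> float:
    """Culture doubling time in days between two passages.

    ``delta_t * ln 2 / ln(n1 / n0)``; larger values mean slower growth.
    Returns NaN when the culture did not grow (n1 <= n0) -- flagged as
    undefined rather than reported negative.
    """
    if n0 <= 0 or n1 <= 0 or delta_t <= 0:
        raise ValueError("counts and interval must be positive")
    if n1 <= n0:
        import warnings

        warnings.warn("no growth between passages: doubling time undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return delta_t * math.log(2.0) / math.log(n1 / n0)
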