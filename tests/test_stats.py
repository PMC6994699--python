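"""Statistical machinery vs independent oracles: enumeration for U,
permutation and Fisher tests, normal equations for OLS, simulation for
test selection and calibration."""
import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

from mitoscreen import stats as st


# ---------------------------------------------------------------------------
# Enumeration oracles (independent of the implementation paths)
# ---------------------------------------------------------------------------

def perm_p_oracle(a, b):
    """Exhaustive two-sided permutation p for the mean difference."""
    pooled = list(a) + list(b)
    na = len(a)
    t_obs = abs(np.mean(a) - np.mean(b))
    hits = total = 0
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        t = abs(np.mean(ga) - np.mean(gb))
        hits += t >= t_obs - 1e-12
        total += 1
    return hits / total


def mwu_p_oracle(a, b):
    """Exhaustive two-sided Mann-Whitney p via the permutation null of
    the U statistic (valid without ties)."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(ga, gb):
        return sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)

    u_obs = u_stat(a, b)
    mid = len(a) * len(b) / 2.0
    hits = total = 0
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        hits += abs(u_stat(ga, gb) - mid) >= abs(u_obs - mid) - 1e-12
        total += 1
    return hits / total


def fisher_p_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p (sum of table probabilities at
    most the observed one) via Fractions of binomial coefficients."""
    r1, r2, k = a + b, c + d, a + c
    lo, hi = max(0, k - r2), min(r1, k)
    weights = {x: Fraction(math.comb(r1, x) * math.comb(r2, k - x))
               for x in range(lo, hi + 1)}
    total = sum(weights.values())
    p = sum(w for w in weights.values() if w <= weights[a]) / total
    return float(p)


# ---------------------------------------------------------------------------
# Two-sample tests
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_known_example(self):
        res = st.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0  # U of sample_a: no pair a > b
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_u_half(self):
        res = st.mann_whitney([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert res.statistic == pytest.approx(9 / 2)

    def test_exact_mode_matches_enumeration(self, rng):
        for _ in range(20):
            na = int(rng.integers(2, 6))
            nb = int(rng.integers(2, 11 - na))
            x = rng.normal(size=na + nb)
            while len(np.unique(x)) < len(x):
                x = rng.normal(size=na + nb)
            a, b = x[:na], x[na:]
            res = st.mann_whitney(a, b)
            assert res.p_value == pytest.approx(mwu_p_oracle(a, b),
                                                abs=1e-12)


class TestPermutation:
    def test_identical_constant_groups(self):
        assert st.permutation_test([5, 5, 5], [5, 5, 5]).p_value == 1.0

    def test_separated_groups_enumeration(self):
        res = st.permutation_test([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(0.1)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            na = int(rng.integers(3, 6))
            nb = int(rng.integers(3, 11 - na)) if na < 8 else 3
            a = rng.normal(size=na)
            b = rng.normal(size=max(3, nb))
            res = st.permutation_test(a, b)
            assert res.p_value == pytest.approx(perm_p_oracle(a, b),
                                                abs=1e-12)

    def test_monte_carlo_close_to_exact(self, rng):
        """Monte-Carlo p within 3 binomial SE of the full enumeration."""
        for _ in range(5):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 6)
            exact = st.permutation_test(a, b).p_value
            n_perm = 100_000
            mc = st.permutation_test(a, b, n_perm=n_perm, seed=1,
                                     exact_limit=1).p_value
            se = math.sqrt(exact * (1 - exact) / n_perm)
            assert abs(mc - exact) <= 3 * se + 2 / n_perm

    def test_seed_reproducible(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        p1 = st.permutation_test(a, b, n_perm=5000, seed=42).p_value
        p2 = st.permutation_test(a, b, n_perm=5000, seed=42).p_value
        assert p1 == p2


class TestWelch:
    def test_identical_groups(self):
        res = st.welch_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_variance_both_groups_fails(self):
        with pytest.raises(ValueError):
            st.welch_t([2, 2, 2], [3, 3, 3])

    def test_power_under_separation(self, rng):
        rej = sum(
            st.welch_t(rng.normal(0, 1, 1000),
                       rng.normal(1, 1, 1000)).p_value < 0.05
            for _ in range(50))
        assert rej >= 50 * 0.99


class TestFisher:
    def test_balanced_table(self):
        assert st.fisher_exact([[5, 5], [5, 5]]).p_value == 1.0

    def test_gender_table_matches_oracle(self):
        res = st.fisher_exact([[25, 4], [16, 17]])
        assert res.p_value == pytest.approx(fisher_p_oracle(25, 4, 16, 17),
                                            abs=1e-12)

    def test_row_swap_symmetry(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(0, 15, 4)
            t1 = st.fisher_exact([[a, b], [c, d]]).p_value
            t2 = st.fisher_exact([[c, d], [a, b]]).p_value
            assert t1 == pytest.approx(t2, abs=1e-14)

    def test_zero_margin_convention(self):
        assert st.fisher_exact([[0, 0], [2, 3]]).p_value == 1.0
        assert st.fisher_exact([[0, 4], [0, 3]]).p_value == 1.0

    def test_matches_scipy_loosely(self, rng):
        from scipy.stats import fisher_exact as scipy_fisher

        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            ours = st.fisher_exact([[a, b], [c, d]]).p_value
            theirs = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)

    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            st.fisher_exact([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            st.fisher_exact([[1.5, 2], [3, 4]])


class TestBonferroni:
    def test_examples(self):
        assert st.bonferroni([0.01]).tolist() == [0.01]
        assert st.bonferroni([0.02, 0.5]).tolist() == [0.04, 1.0]
        assert st.bonferroni([0.003] * 14)[0] == pytest.approx(0.042)

    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_and_order_preserving(self, ps):
        adj = st.bonferroni(ps)
        assert np.all(adj >= np.asarray(ps))
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# Symmetry tests and test selection
# ---------------------------------------------------------------------------

class TestSymmetry:
    def test_antisymmetric_sample_zero_statistics(self):
        x = np.array([0.5, 1.0, 2.0, 4.5, -0.5, -1.0, -2.0, -4.5, 3.0, -3.0])
        s1, p1, s2, p2, asym = st.symmetry_tests(x)
        assert s1 == 0.0 and s2 == 0.0
        assert not asym

    def test_constant_sample_fails(self):
        with pytest.raises(ValueError):
            st.symmetry_tests([1.0] * 20)

    def test_type_i_error_normal_null(self, rng):
        n_rep, n = 600, 200
        rej1 = rej2 = 0
        for _ in range(n_rep):
            x = rng.normal(0, 1, n)
            _, p1, _, p2, _ = st.symmetry_tests(x)
            rej1 += p1 < 0.05
            rej2 += p2 < 0.05
        assert 0.03 <= rej1 / n_rep <= 0.08
        assert 0.03 <= rej2 / n_rep <= 0.08

    def test_power_exponential(self, rng):
        rej = sum(st.symmetry_tests(rng.exponential(1, 200))[4]
                  for _ in range(100))
        assert rej >= 90


class TestSelectTest:
    def test_gaussian_prefers_welch(self, rng):
        # both samples pass Shapiro with prob 0.95^2 ~ 0.90; allow two
        # binomial SDs below that
        hits = sum(
            st.select_test(rng.normal(0, 1, 200),
                           rng.normal(0, 1, 200)) == "welch_t"
            for _ in range(100))
        assert hits >= 85

    def test_laplace_prefers_mann_whitney(self, rng):
        picks = [st.select_test(rng.laplace(0, 1, 500),
                                rng.laplace(0, 1, 500))
                 for _ in range(40)]
        assert picks.count("mann_whitney") > 20

    def test_exponential_prefers_permutation(self, rng):
        hits = sum(
            st.select_test(rng.exponential(1, 500),
                           rng.exponential(1, 500)) == "permutation"
            for _ in range(40))
        assert hits >= 36

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            st.select_test([1, 2], [3, 4, 5])


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

class TestCorrelations:
    def test_self_and_anticorrelation(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "neg": -x, "z": rng.normal(size=50)})
        rep = st.correlation_matrix(df)
        assert rep.r.loc["x", "x"] == pytest.approx(1.0)
        pair = rep.pairs.set_index(["feature_a", "feature_b"])
        assert pair.loc[("x", "neg"), "r"] == pytest.approx(-1.0)
        assert pair.loc[("x", "neg"), "category"] == "high"

    def test_category_thresholds(self):
        assert st.categorize_r(0.47) == "low"
        assert st.categorize_r(-0.29) == "negligible"
        assert st.categorize_r(0.55) == "moderate"
        assert st.categorize_r(0.9) == "high"

    def test_constant_column_excluded(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30),
                           "b": rng.normal(size=30),
                           "const": 1.0})
        rep = st.correlation_matrix(df)
        assert rep.excluded == ["const"]
        assert "const" not in rep.r.columns

    def test_leaf_order_covers_all_features(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 6)),
                          columns=list("abcdef"))
        rep = st.correlation_matrix(df)
        assert sorted(rep.leaf_order) == list("abcdef")


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

class TestRegression:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(4)
        n = 60
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        df = pd.DataFrame({"MitoVolumeMean": x1, "MitoSkel": x2,
                           "TMRM_MitoMask": 2 * x1 - 3 * x2 + 5})
        res = st.fit_membrane_potential_model(
            df, morphology_terms=["MitoVolumeMean", "MitoSkel"],
            diagnosis_col="none", age_col="none", gender_col="none")
        est = dict(zip(res.terms, res.estimates))
        assert est["const"] == pytest.approx(5.0, abs=1e-10)
        assert est["MitoVolumeMean"] == pytest.approx(2.0, abs=1e-10)
        assert est["MitoSkel"] == pytest.approx(-3.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        n, p = 80, 4
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        cols = ["MitoVolumeMean", "MitoSkel", "MitoEndpoints",
                "MitoNodeDegree"]
        df = pd.DataFrame(X, columns=cols)
        df["TMRM_MitoMask"] = y
        res = st.fit_membrane_potential_model(
            df, diagnosis_col="none", age_col="none", gender_col="none")
        Xc = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        assert np.allclose(res.estimates, beta, rtol=1e-8)
        # t = estimate / SE identity
        assert np.allclose(res.t_values,
                           res.estimates / res.std_errors)

    def test_null_r_squared_scale(self, rng):
        n, p = 400, 4
        r2s = []
        for _ in range(40):
            X = rng.normal(size=(n, p))
            df = pd.DataFrame(X, columns=["MitoVolumeMean", "MitoSkel",
                                          "MitoEndpoints",
                                          "MitoNodeDegree"])
            df["TMRM_MitoMask"] = rng.normal(size=n)
            res = st.fit_membrane_potential_model(
                df, diagnosis_col="none", age_col="none", gender_col="none")
            r2s.append(res.r_squared)
        assert np.mean(r2s) == pytest.approx(p / (n - 1), rel=0.5)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"MitoVolumeMean": x, "MitoSkel": x,
                           "TMRM_MitoMask": rng.normal(size=40)})
        with pytest.raises(ValueError, match="Mito"):
            st.fit_membrane_potential_model(
                df, morphology_terms=["MitoVolumeMean", "MitoSkel"],
                diagnosis_col="none", age_col="none", gender_col="none")

    def test_simulator_negative_branching_coupling(self):
        """The generative membrane-potential law couples negatively to
        skeleton size; the regression recovers the sign."""
        from mitoscreen import simulate as sim

        neg = 0
        for s in range(10):
            cfg = sim.SimulationConfig(seed=500 + s)
            cells = sim.simulate_cohort_features(
                cfg, 6, 6, cells_per_subject=80, conditions=("baseline",))
            res = st.fit_membrane_potential_model(cells)
            est = dict(zip(res.terms, res.estimates))
            neg += est["MitoSkel"] < 0
        assert neg >= 9


class TestDoublingTime:
    def test_doubling_examples(self):
        assert st.doubling_time(100, 200, 3) == pytest.approx(3.0)
        assert st.doubling_time(100, 400, 4) == pytest.approx(2.0)

    def test_no_growth_flagged_nan(self):
        with pytest.warns(RuntimeWarning):
            out = st.doubling_time(100, 100, 3)
        assert math.isnan(out)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            st.doubling_time(0, 10, 1)


def test_compare_groups_applies_bonferroni(rng):
    df = pd.DataFrame({
        "group": ["case"] * 30 + ["control"] * 30,
        "f1": np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)],
        "f2": rng.normal(0, 1, 60),
    })
    out = st.compare_groups(df, ["f1", "f2"], seed=0)
    assert np.allclose(out["p_bonferroni"],
                       np.minimum(1.0, out["p_value"] * 2))
    assert set(out["test"]) <= {"welch_t", "mann_whitney", "permutation"}
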