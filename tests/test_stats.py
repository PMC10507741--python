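import itertools

import numpy as np
import pandas as pd
import pytest

import fshdmbb as f
from fshdmbb.stats import build_design


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def normal_equations(y, X):
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def rank_sum_enumeration_p(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in a)
    centre = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[pooled[i]] for i in combo)
        total += 1
        if abs(w - centre) >= abs(obs - centre) - 1e-12:
            count += 1
    return count / total


def signed_rank_enumeration_p(diffs):
    """Exact two-sided signed-rank p over all 2^n sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    n = len(d)
    centre = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - centre) >= abs(w_obs - centre) - 1e-12:
            count += 1
    return count / 2**n


def bh_oracle(p):
    """Step-up adjustment computed the slow, literal way."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top, 1.0)
        adj[i] = val
        prev = val
    return adj


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

class TestOls:
    def test_exact_linear_relation_recovers_slope_with_zero_residual(self):
        x = np.arange(10, dtype=float)
        X = pd.DataFrame({"Intercept": np.ones(10), "x": x})
        res = f.ols_fit(2 * x, X)
        assert res["x"].estimate == pytest.approx(2.0, abs=1e-12)
        assert res["x"].p == pytest.approx(0.0, abs=1e-12)

    def test_intercept_only_model_fits_the_mean(self, rng):
        y = rng.normal(5, 2, 15)
        res = f.ols_fit(y, pd.DataFrame({"Intercept": np.ones(15)}))
        assert res["Intercept"].estimate == pytest.approx(y.mean(), abs=1e-12)

    def test_matches_normal_equations_on_random_designs(self, rng):
        for _ in range(100):
            n, p = 20, 3
            X = pd.DataFrame(
                rng.standard_normal((n, p)), columns=[f"x{j}" for j in range(p)]
            )
            X.insert(0, "Intercept", 1.0)
            y = rng.standard_normal(n)
            res = f.ols_fit(y, X)
            beta = normal_equations(y, X)
            for j, name in enumerate(X.columns):
                assert res[name].estimate == pytest.approx(beta[j], abs=1e-10)

    def test_rank_deficient_design_raises_listing_alias(self):
        X = pd.DataFrame({"Intercept": np.ones(6), "a": np.arange(6.0)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="b"):
            f.ols_fit(np.arange(6.0), X)

    def test_wald_p_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 25
        X = pd.DataFrame({"Intercept": np.ones(n), "x": rng.standard_normal(n)})
        y = 0.4 * X["x"].to_numpy() + rng.standard_normal(n)
        ours = f.ols_fit(y, X)["x"]
        ref = sm.OLS(y, X.to_numpy()).fit()
        assert ours.p == pytest.approx(ref.pvalues[1], abs=1e-10)
        assert ours.se == pytest.approx(ref.bse[1], abs=1e-10)


class TestPairedAdjustedFit:
    @staticmethod
    def _paired(rng, n_subjects=8, diff=None):
        subj = np.repeat([f"p{i}" for i in range(n_subjects)], 2)
        tirm = np.tile(["neg", "pos"], n_subjects)
        base = np.repeat(rng.normal(0, 2, n_subjects), 2)
        d = diff if diff is not None else rng.normal(1, 0.5, n_subjects)
        score = base.copy()
        score[1::2] += d
        age = np.repeat(rng.uniform(30, 60, n_subjects), 2)
        sex = np.repeat(rng.choice(["M", "F"], n_subjects), 2)
        return score, tirm, subj, age, sex, d

    def test_constant_pair_difference_is_recovered_exactly(self, rng):
        score, tirm, subj, age, sex, _ = self._paired(rng, diff=np.full(8, 0.7))
        res = f.paired_adjusted_fit(score, tirm, subj, age, sex)
        assert res.estimate == pytest.approx(0.7, abs=1e-10)

    def test_coefficient_equals_mean_paired_difference(self, rng):
        score, tirm, subj, age, sex, d = self._paired(rng)
        res = f.paired_adjusted_fit(score, tirm, subj, age, sex)
        assert res.estimate == pytest.approx(np.mean(d), abs=1e-10)

    def test_symmetric_differences_give_zero_coefficient(self, rng):
        d = np.array([0.5, -0.5, 1.2, -1.2, 0.3, -0.3])
        score, tirm, subj, age, sex, _ = self._paired(rng, n_subjects=6, diff=d)
        res = f.paired_adjusted_fit(score, tirm, subj, age, sex)
        assert res.estimate == pytest.approx(0.0, abs=1e-10)

    def test_subject_without_two_samples_raises(self):
        with pytest.raises(ValueError, match="exactly 2"):
            f.paired_adjusted_fit([1.0, 2.0, 3.0], ["neg", "pos", "neg"], ["a", "a", "b"])


class TestLogit:
    def test_intercept_only_fits_log_odds(self):
        y = np.array([1] * 6 + [0] * 4)
        res = f.logit_fit(y, pd.DataFrame({"Intercept": np.ones(10)}))
        assert res["Intercept"].estimate == pytest.approx(np.log(6 / 4), abs=1e-6)

    def test_binary_covariate_recovers_table_log_odds_ratio(self):
        # exposed: 20 events / 10 non-events; unexposed: 5 / 15
        y = np.array([1] * 20 + [0] * 10 + [1] * 5 + [0] * 15)
        x = np.array([1.0] * 30 + [0.0] * 20)
        X = pd.DataFrame({"Intercept": np.ones(50), "x": x})
        res = f.logit_fit(y, X)
        assert res["x"].estimate == pytest.approx(np.log(20 * 15 / (10 * 5)), abs=1e-5)

    def test_perfect_separation_raises(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        X = pd.DataFrame({"Intercept": np.ones(6), "x": [1.0, 2, 3, 10, 11, 12]})
        with pytest.raises(ValueError, match="separation"):
            f.logit_fit(y, X)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            f.logit_fit(np.ones(5), pd.DataFrame({"Intercept": np.ones(5)}))


class TestPearson:
    def test_identity_and_anti_identity(self):
        x = np.arange(10, dtype=float)
        assert f.pearson_test(x, x).estimate == pytest.approx(1.0)
        assert f.pearson_test(x, -x).estimate == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        r_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert f.pearson_test(x, y).estimate == pytest.approx(r_oracle, abs=1e-12)

    def test_symmetric_and_affine_invariant(self, rng):
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        a = f.pearson_test(x, y)
        b = f.pearson_test(y, x)
        c = f.pearson_test(3.5 * x + 2, 0.1 * y - 7)
        assert a.p == pytest.approx(b.p, abs=1e-12)
        assert a.estimate == pytest.approx(c.estimate, abs=1e-10)

    def test_missing_values_deleted_casewise(self):
        x = np.array([1.0, 2, 3, 4, np.nan])
        y = np.array([2.0, 4, 6, 8, 100.0])
        res = f.pearson_test(x, y)
        assert res.n == 4 and res.estimate == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            f.pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWilcoxonRankSum:
    def test_identical_groups_give_p_one(self):
        res = f.wilcoxon_rank_sum([1.5, 2.5], [1.0, 3.0])
        assert res.p == pytest.approx(1.0)

    def test_fully_separated_triples_give_exact_tenth(self):
        res = f.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_matches_enumeration_oracle_on_random_tie_free_inputs(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
            pool = rng.choice(np.arange(100), size=n1 + n2, replace=False).astype(float)
            a, b = pool[:n1], pool[n1:]
            assert f.wilcoxon_rank_sum(a, b).p == pytest.approx(
                rank_sum_enumeration_p(a, b), abs=1e-12
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            f.wilcoxon_rank_sum([], [1.0])


class TestWilcoxonSignedRank:
    def test_all_positive_differences_hit_the_exact_floor(self):
        res = f.wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert res.p == pytest.approx(2 / 2**6, abs=1e-12)

    def test_symmetric_pairs_centre_the_statistic(self):
        res = f.wilcoxon_signed_rank([2.0, -2.0, 1.0, -1.0])
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_matches_enumeration_oracle_on_random_inputs(self, rng):
        for _ in range(20):
            d = rng.choice(np.arange(1, 60), size=8, replace=False).astype(float)
            d *= rng.choice([-1, 1], size=8)
            assert f.wilcoxon_signed_rank(d).p == pytest.approx(
                signed_rank_enumeration_p(d), abs=1e-12
            )

    def test_zero_differences_dropped_then_all_zero_raises(self):
        res = f.wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert res.n == 6
        with pytest.raises(ValueError, match="zero"):
            f.wilcoxon_signed_rank([0.0, 0.0])


class TestBhAdjust:
    def test_textbook_example(self):
        out = f.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_capped(self):
        assert np.allclose(f.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert f.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(500):
            p = rng.uniform(size=rng.integers(1, 12))
            assert np.allclose(f.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_never_below_raw_p_and_permutation_consistent(self, rng):
        p = rng.uniform(size=9)
        adj = f.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        perm = rng.permutation(9)
        adj_perm = f.bh_adjust(p[perm])
        assert np.allclose(adj_perm, adj[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f.bh_adjust([0.5, 1.2])


class TestBuildDesign:
    def test_categoricals_one_hot_with_first_level_reference(self):
        df = pd.DataFrame({"sex": ["M", "F", "M"], "age_years": [40.0, 50.0, 60.0]})
        X = build_design(df, ["sex", "age_years"])
        assert list(X.columns) == ["Intercept", "sex[M]", "age_years"]
        assert X["sex[M]"].tolist() == [1.0, 0.0, 1.0]

    def test_missing_rows_dropped_casewise(self):
        df = pd.DataFrame({"x": [1.0, np.nan, 3.0]})
        X = build_design(df, ["x"])
        assert len(X) == 2
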