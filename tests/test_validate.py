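import itertools

import numpy as np
import pandas as pd
import pytest

import fshdmbb as f
from fshdmbb.data_io import Signature


def auc_pair_counting(scores, labels):
    """AUC for 'lower score predicts positive' via exhaustive pair counting."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    conc = ties = 0
    for p in pos:
        for n in neg:
            if p < n:
                conc += 1
            elif p == n:
                ties += 1
    return (conc + 0.5 * ties) / (len(pos) * len(neg))


class TestRandomMatchedSignatures:
    def test_sizes_and_disjoint_arms(self):
        uni = [f"g{i}" for i in range(500)]
        sigs = f.random_matched_signatures(uni, 64, 79, 20, seed=3)
        assert len(sigs) == 20
        for s in sigs:
            assert len(s.up_genes) == 64 and len(s.down_genes) == 79
            assert not set(s.up_genes) & set(s.down_genes)

    def test_true_signature_genes_excluded(self):
        uni = [f"g{i}" for i in range(300)]
        exclude = uni[:143]
        sigs = f.random_matched_signatures(uni, 64, 79, 10, exclude=exclude, seed=0)
        for s in sigs:
            assert not set(s.genes) & set(exclude)

    def test_same_seed_reproduces_identical_draws(self):
        uni = [f"g{i}" for i in range(400)]
        a = f.random_matched_signatures(uni, 10, 12, 5, seed=42)
        b = f.random_matched_signatures(uni, 10, 12, 5, seed=42)
        assert [(s.up_genes, s.down_genes) for s in a] == [
            (s.up_genes, s.down_genes) for s in b
        ]

    def test_exactly_sized_universe_flagged_degenerate(self):
        uni = [f"g{i}" for i in range(5)]
        with pytest.warns(UserWarning, match="degenerate"):
            sigs = f.random_matched_signatures(uni, 2, 3, 2, seed=1)
        assert set(sigs[0].genes) == set(sigs[1].genes) == set(uni)

    def test_insufficient_universe_raises(self):
        with pytest.raises(ValueError, match="universe too small"):
            f.random_matched_signatures(["a", "b"], 2, 3, 1)


class TestEmpiricalPvalue:
    def test_published_style_count_arithmetic(self):
        nulls = np.concatenate([np.full(32, 5.0), np.full(968, 1.0)])
        assert f.empirical_pvalue(5.0, nulls) == pytest.approx(0.032)
        nulls = np.concatenate([np.full(6, 5.0), np.full(994, 1.0)])
        assert f.empirical_pvalue(5.0, nulls) == pytest.approx(0.006)

    def test_observed_beyond_every_null_and_boundary(self):
        nulls = np.arange(10, dtype=float)
        assert f.empirical_pvalue(100.0, nulls) == 0.0
        assert f.empirical_pvalue(-1.0, nulls) == 1.0

    def test_counting_identity_with_ties(self, rng):
        nulls = rng.integers(0, 5, 50).astype(float)
        obs = 2.0
        ge = f.empirical_pvalue(obs, nulls, "greater")
        le = f.empirical_pvalue(obs, nulls, "less")
        assert ge + le >= 1.0

    def test_pseudocount_variant(self):
        assert f.empirical_pvalue(1.0, np.zeros(99), pseudocount=True) == pytest.approx(
            1 / 100
        )


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        # lower scores in the severe class
        res = f.roc_auc([0.1, 0.2, 0.9, 1.0], [True, True, False, False])
        assert res.auc == 1.0

    def test_matches_pair_counting_exhaustively_for_small_inputs(self, rng):
        for n1, n2 in itertools.product(range(1, 6), range(1, 6)):
            scores = np.concatenate(
                [rng.integers(0, 4, n1), rng.integers(0, 4, n2)]
            ).astype(float)
            labels = np.array([True] * n1 + [False] * n2)
            assert f.roc_auc(scores, labels).auc == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12
            )

    def test_matches_pair_counting_on_random_instances(self, rng):
        for _ in range(200):
            n = rng.integers(4, 20)
            labels = np.zeros(n, dtype=bool)
            labels[: rng.integers(1, n)] = True
            scores = rng.normal(size=n).round(1)
            assert f.roc_auc(scores, labels).auc == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12
            )

    def test_curve_is_monotone(self, rng):
        res = f.roc_auc(rng.normal(size=30), rng.random(30) > 0.5)
        assert (np.diff(res.sensitivity) >= 0).all()
        assert (np.diff(res.specificity) <= 0).all()

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            f.roc_auc([1.0, 2.0], [True, True])


class TestAgeStratified:
    @staticmethod
    def _cohort(rng, n=60, effect_older=-2.0, effect_younger=0.0):
        age = rng.uniform(30, 70, n)
        lam = rng.integers(0, 16, n).astype(float)
        severe = lam > 7.5
        cut = age.mean()
        score = rng.normal(0, 1, n)
        score += np.where((age >= cut) & severe, effect_older, 0.0)
        score += np.where((age < cut) & severe, effect_younger, 0.0)
        info = pd.DataFrame(
            {
                "age_years": age,
                "lamperti": lam,
                "sex": rng.choice(["M", "F"], n),
                "cohort": rng.choice(["a", "b"], n),
            }
        )
        return pd.Series(score, index=info.index), info

    def test_effect_planted_only_in_older_stratum_is_localized(self, rng):
        scores, info = self._cohort(rng)
        strata, cut = f.age_stratified_analysis(scores, info)
        assert strata["older"].p < 0.01 and strata["older"].estimate < 0
        assert strata["younger"].p > 0.05

    def test_identical_planted_effects_give_comparable_coefficients(self, rng):
        scores, info = self._cohort(rng, n=120, effect_older=-1.5, effect_younger=-1.5)
        strata, _ = f.age_stratified_analysis(scores, info)
        assert strata["older"].estimate == pytest.approx(
            strata["younger"].estimate, abs=1.0
        )

    def test_default_cut_is_mean_age(self, rng):
        scores, info = self._cohort(rng)
        _, cut = f.age_stratified_analysis(scores, info)
        assert cut == pytest.approx(info["age_years"].mean())

    def test_empty_stratum_raises(self, rng):
        scores, info = self._cohort(rng, n=20)
        with pytest.raises(ValueError, match="empty"):
            f.age_stratified_analysis(scores, info, age_cut=10.0)


class TestSignatureNullTest:
    def test_zero_resamples_rejected(self, rng):
        spec = f.CohortSpec.null()
        em, clin = f.generate_validation_cohort(spec, seed=rng)
        with pytest.raises(ValueError, match="resample"):
            f.signature_null_test(em, clin, spec.signature(), n_resamples=0)

    def test_null_statistics_share_the_observed_model(self):
        spec = f.CohortSpec.null(genes_total=400, n_up=10, n_dn=12)
        em, clin = f.generate_validation_cohort(spec, seed=5)
        res = f.signature_null_test(em, clin, spec.signature(), model="status",
                                    n_resamples=50, seed=5)
        assert len(res.nulls) == 50
        assert res.matching == {"n_up": 10, "n_dn": 12, "n_excluded": 22,
                                "model": "status"}
        assert 0.0 <= res.p <= 1.0
        # observed term recomputed through the scalar OLS path agrees
        assert abs(res.observed_term.stat) == pytest.approx(res.observed, abs=1e-8)

    def test_planted_deficit_beats_every_null(self):
        spec = f.CohortSpec(genes_total=800)
        em, clin = f.generate_validation_cohort(spec, seed=11)
        res = f.signature_null_test(em, clin, spec.signature(), model="status",
                                    n_resamples=100, seed=11)
        assert res.p <= 1 / 100

    def test_same_seed_is_deterministic(self):
        spec = f.CohortSpec.null(genes_total=400, n_up=10, n_dn=12)
        em, clin = f.generate_validation_cohort(spec, seed=7)
        a = f.signature_null_test(em, clin, spec.signature(), n_resamples=30, seed=9)
        b = f.signature_null_test(em, clin, spec.signature(), n_resamples=30, seed=9)
        assert np.array_equal(a.nulls, b.nulls) and a.p == b.p
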