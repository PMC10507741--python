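import numpy as np
import pandas as pd
import pytest

import fshdmbb as f
from fshdmbb.data_io import ExpressionMatrix, Signature


def _stratum(rng, genes, subjects, planted=None):
    """One tissue stratum with optional genes forced equal to a clinical vector."""
    values = pd.DataFrame(
        7 + rng.standard_normal((len(genes), len(subjects))),
        index=genes,
        columns=[f"{s}_x" for s in subjects],
    )
    if planted:
        for g, vec in planted.items():
            values.loc[g] = vec
    ann = pd.DataFrame(
        {
            "cohort": "c",
            "tissue": "muscle",
            "tirm": "neg",
            "group": "fshd",
            "subject_id": subjects,
        },
        index=values.columns,
    )
    return ExpressionMatrix(values, samples=ann)


@pytest.fixture
def clinical(rng):
    n = 24
    return pd.DataFrame(
        {
            "subject_id": [f"p{i}" for i in range(n)],
            "lamperti": rng.integers(0, 16, n).astype(float),
            "ricci": rng.uniform(0, 10, n),
            "duration_years": rng.uniform(2, 50, n),
        }
    )


class TestGeneClinicalScreen:
    def test_gene_equal_to_clinical_vector_has_r_one(self, rng, clinical):
        genes = ["g1", "g2", "g3"]
        subjects = clinical["subject_id"].tolist()
        em = _stratum(rng, genes, subjects,
                      planted={"g1": clinical["lamperti"].to_numpy()})
        out = f.gene_clinical_screen(em, clinical, ["lamperti"], genes)
        row = out[(out["gene"] == "g1")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-20

    def test_matches_looped_pearson_test(self, rng, clinical):
        genes = [f"g{i}" for i in range(5)]
        subjects = clinical["subject_id"].tolist()
        em = _stratum(rng, genes, subjects)
        out = f.gene_clinical_screen(em, clinical, ["lamperti", "ricci"], genes)
        assert len(out) == 10
        clin = clinical.set_index("subject_id")
        for _, row in out.iterrows():
            ref = f.pearson_test(
                em.values.loc[row["gene"]].to_numpy(),
                clin.loc[subjects, row["variable"]].to_numpy(),
            )
            assert row["r"] == pytest.approx(ref.estimate, abs=1e-10)
            assert row["p"] == pytest.approx(ref.p, abs=1e-10)

    def test_missing_clinical_values_deleted_casewise(self, rng, clinical):
        clinical = clinical.copy()
        clinical.loc[0:4, "ricci"] = np.nan
        genes = ["g1"]
        em = _stratum(rng, genes, clinical["subject_id"].tolist())
        out = f.gene_clinical_screen(em, clinical, ["ricci"], genes)
        assert out["n"].iloc[0] == len(clinical) - 5

    def test_constant_variable_raises_naming_it(self, rng, clinical):
        clinical = clinical.assign(ricci=3.0)
        em = _stratum(rng, ["g1"], clinical["subject_id"].tolist())
        with pytest.raises(ValueError, match="ricci"):
            f.gene_clinical_screen(em, clinical, ["ricci"], ["g1"])


class TestRefineSignature:
    @staticmethod
    def _screens(rng, parent, n=24):
        """Pure-noise screens for both strata."""
        clinical = pd.DataFrame(
            {
                "subject_id": [f"p{i}" for i in range(n)],
                "lamperti": rng.uniform(0, 15, n),
            }
        )
        subjects = clinical["subject_id"].tolist()
        screens = {}
        for stratum in ("tirm_neg", "tirm_pos"):
            em = _stratum(rng, list(parent.genes), subjects)
            screens[stratum] = f.gene_clinical_screen(
                em, clinical, ["lamperti"], list(parent.genes), stratum
            )
        return screens

    def test_selection_monotone_in_alpha(self, rng):
        parent = Signature("par", tuple(f"u{i}" for i in range(30)),
                           tuple(f"d{i}" for i in range(30)))
        screens = self._screens(rng, parent)
        picks = []
        for alpha in (0.01, 0.05, 0.2, 0.5):
            res = f.refine_signature(parent, screens, ["lamperti"], alpha)
            sel = set() if res.signature is None else set(res.signature.genes)
            picks.append(sel)
        for smaller, larger in zip(picks, picks[1:]):
            assert smaller <= larger

    def test_alpha_zero_selects_nothing(self, rng):
        parent = Signature("par", ("u0", "u1"), ("d0", "d1"))
        screens = self._screens(rng, parent)
        with pytest.warns(UserWarning, match="no genes"):
            res = f.refine_signature(parent, screens, ["lamperti"], alpha=0.0)
        assert res.signature is None and res.n_up == 0 and res.n_dn == 0

    def test_arm_membership_preserved(self, rng):
        parent = Signature("par", tuple(f"u{i}" for i in range(20)),
                           tuple(f"d{i}" for i in range(20)))
        screens = self._screens(rng, parent)
        res = f.refine_signature(parent, screens, ["lamperti"], alpha=0.5)
        assert set(res.signature.up_genes) <= set(parent.up_genes)
        assert set(res.signature.down_genes) <= set(parent.down_genes)

    def test_unmeasured_parent_genes_reported_not_selected(self, rng):
        parent = Signature("par", ("u0", "u1", "ghost"), ("d0", "d1"))
        measured = Signature("par", ("u0", "u1"), ("d0", "d1"))
        screens = self._screens(rng, measured)
        res = f.refine_signature(parent, screens, ["lamperti"], alpha=1.0)
        assert res.unmeasured == ("ghost",)
        assert "ghost" not in (res.signature.genes if res.signature else ())

    def test_refined_score_depends_only_on_selected_genes(self, rng):
        parent = Signature("par", tuple(f"u{i}" for i in range(10)),
                           tuple(f"d{i}" for i in range(10)))
        screens = self._screens(rng, parent)
        res = f.refine_signature(parent, screens, ["lamperti"], alpha=0.6)
        sig = res.signature
        assert sig is not None and sig.two_armed
        expr = pd.Series(rng.normal(7, 1, len(parent.genes)), index=parent.genes)
        before = f.score_tstat(expr, sig)
        unselected = [g for g in parent.genes if g not in sig.genes]
        expr_perturbed = expr.copy()
        expr_perturbed[unselected] += rng.normal(0, 5, len(unselected))
        assert f.score_tstat(expr_perturbed, sig) == before

    def test_planted_correlated_genes_recovered_above_null_rate(self, rng):
        n = 24
        clinical = pd.DataFrame(
            {"subject_id": [f"p{i}" for i in range(n)], "llff": rng.uniform(3, 56, n)}
        )
        subjects = clinical["subject_id"].tolist()
        genes = [f"g{i}" for i in range(60)]
        planted = {
            g: clinical["llff"].to_numpy() * 0.2 + rng.normal(0, 0.5, n)
            for g in genes[:15]
        }
        screens = {}
        for stratum in ("tirm_neg", "tirm_pos"):
            em = _stratum(rng, genes, subjects, planted=planted)
            screens[stratum] = f.gene_clinical_screen(em, clinical, ["llff"], genes, stratum)
        parent = Signature("lymphoblast_like", tuple(genes))
        res = f.refine_mean_signature(parent, screens, "llff", alpha=0.05)
        selected = set(res.signature.up_genes)
        assert len(selected & set(genes[:15])) >= 12  # planted genes found
        null_rate = len(selected & set(genes[15:])) / 45
        assert null_rate < 0.5

    def test_mean_refinement_rejects_two_armed_parent(self, rng):
        parent = Signature("par", ("u0",), ("d0",))
        with pytest.raises(ValueError, match="single-arm"):
            f.refine_mean_signature(parent, {}, "llff")
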