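"""End-to-end orchestration of the biomarker analysis.

``run_pipeline`` drives the full chain on an in-memory data bundle:
normalize each tissue matrix, score the signatures, test FSHD-vs-control
discrimination and the paired inflamed/non-inflamed contrast, screen
severity correlations, refine a parent signature when one is supplied,
correlate the biomarker between isogenic muscle and blood, validate in an
independent blood cohort (covariate-adjusted regressions, matched
random-signature resampling, mild/severe ROC, age-stratified analysis),
meta-analyze independent muscle studies, and test arm over-representation.
Every stochastic stage consumes a named sub-seed derived from the master
seed, so a re-run with the same inputs is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, LOG_NORMALIZED, RAW_COUNTS, Signature
from .enrich import ora_fisher
from .meta import MetaResult, run_meta
from .normalize import log_transform, median_of_ratios, quantile_normalize, z_normalize_within
from .refine import gene_clinical_screen, refine_signature
from .scoring import score_battery
from .stats import AssociationResult, build_design, ols_fit, paired_adjusted_fit, pearson_test
from .validate import (
    LAMPERTI_SEVERE_CUT,
    age_stratified_analysis,
    roc_auc,
    signature_null_test,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "cross_tissue_correlation"]

SEVERITY_VARIABLES = (
    "ricci",
    "lamperti",
    "mrc_sum",
    "mvc_ta",
    "llff",
    "d4z4_units",
    "duration_years",
)


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis."""

    alpha: float = 0.05
    n_resamples: int = 1000
    seed: int = 0
    severe_cut: float = LAMPERTI_SEVERE_CUT
    log_offset: float = 1.0
    refine_variables: tuple = ("ricci", "lamperti", "duration_years")
    refine_alpha: float = 0.05
    welch: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")


@dataclass
class AnalysisReport:
    """Per-stage result tables plus a flag summary.

    ``results`` holds the fitted objects keyed by stage;
    ``summary`` is a tidy frame (analysis, signature, estimate, p,
    significant) mirroring the tick-table layout of the original analyses,
    every flag traceable to a stored result.
    """

    tables: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    summary: pd.DataFrame | None = None
    seeds: dict = field(default_factory=dict)


def cross_tissue_correlation(
    scores_muscle: pd.Series,
    subjects_muscle: pd.Series,
    scores_blood: pd.Series,
    subjects_blood: pd.Series,
) -> AssociationResult:
    """Pearson correlation of a biomarker between isogenic muscle and blood.

    Samples are paired by subject id; subjects present in only one tissue
    are excluded with a log note.  Needs >= 3 complete pairs.
    """
    mus = pd.DataFrame({"score": scores_muscle, "subject": subjects_muscle}).dropna()
    blo = pd.DataFrame({"score": scores_blood, "subject": subjects_blood}).dropna()
    mus = mus.groupby("subject")["score"].mean()
    blo = blo.groupby("subject")["score"].mean()
    shared = mus.index.intersection(blo.index)
    dropped = len(mus) + len(blo) - 2 * len(shared)
    if dropped:
        log.info("cross_tissue_correlation: %d unpaired subjects excluded", dropped)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 paired subjects (got {len(shared)})")
    return pearson_test(mus[shared].to_numpy(), blo[shared].to_numpy())


def _normalize_stage(em: ExpressionMatrix, offset: float) -> ExpressionMatrix:
    if em.scale == RAW_COUNTS:
        _, em = median_of_ratios(em)
        em = log_transform(em, offset=offset)
    return quantile_normalize(em)


def _concat(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    values = pd.concat([a.values, b.values], axis=1)
    ann = pd.concat([a.samples, b.samples])
    return ExpressionMatrix(values, a.scale, ann)


def _clinical_frame(em: ExpressionMatrix, clinical: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in clinical.columns if c != "subject_id"]
    joined = em.samples.join(
        clinical.set_index("subject_id")[cols], on="subject_id", rsuffix="_clin"
    )
    return joined


def run_pipeline(data: dict, config: PipelineConfig | None = None) -> AnalysisReport:
    """Run every stage supported by the supplied data bundle.

    ``data`` keys (all optional except the first four):

    * ``muscle_tirm_neg`` / ``muscle_tirm_pos`` / ``pbmc`` --
      :class:`ExpressionMatrix` objects with sample annotations;
    * ``clinical`` -- subject-level clinical table;
    * ``biomarker`` -- the two-armed signature to validate (defaults to
      the refined signature when only ``parent`` is given);
    * ``parent`` -- a parent signature to refine against the severity
      screens;
    * ``validation`` -- ``(expression, clinical)`` for an independent
      blood cohort;
    * ``studies`` -- ``[(expression, name), ...]`` for the muscle
      meta-analysis;
    * ``collections`` -- gene-set collection (GMT signatures) for
      over-representation of the biomarker arms.
    """
    config = config or PipelineConfig()
    report = AnalysisReport()
    rows: list[dict] = []
    seed_seq = np.random.SeedSequence(config.seed)
    sub_seeds = {
        name: s
        for name, s in zip(
            ("resample_status", "resample_severity"), seed_seq.spawn(2)
        )
    }
    report.seeds = {k: v.entropy for k, v in sub_seeds.items()}

    clinical = data["clinical"]

    # ---- normalize -------------------------------------------------------
    neg = _normalize_stage(data["muscle_tirm_neg"], config.log_offset)
    pos = _normalize_stage(data["muscle_tirm_pos"], config.log_offset)
    muscle = _concat(neg, pos)
    pbmc = _normalize_stage(data["pbmc"], config.log_offset)

    # ---- refine (optional) ----------------------------------------------
    parent: Signature | None = data.get("parent")
    refined = None
    if parent is not None:
        fshd_neg = neg.subset_samples(
            list(neg.samples.index[(neg.samples["group"] == "fshd")])
        )
        genes = [g for g in parent.genes if g in neg.values.index]
        screens = {
            "tirm_neg": gene_clinical_screen(
                fshd_neg, clinical, list(config.refine_variables), genes, stratum="tirm_neg"
            ),
            "tirm_pos": gene_clinical_screen(
                pos, clinical, list(config.refine_variables), genes, stratum="tirm_pos"
            ),
        }
        refined = refine_signature(parent, screens, list(config.refine_variables),
                                   config.refine_alpha)
        report.results["refinement"] = refined
        report.tables["refinement_screen"] = refined.screen

    biomarker: Signature | None = data.get("biomarker")
    if biomarker is None:
        if refined is None or refined.signature is None:
            raise ValueError("bundle needs a biomarker signature (or a refinable parent)")
        biomarker = refined.signature
    signatures = [biomarker] + list(data.get("signatures", []))

    # ---- score -----------------------------------------------------------
    muscle_scores = score_battery(muscle, signatures, welch=config.welch)
    pbmc_scores = score_battery(pbmc, signatures, welch=config.welch)
    report.tables["scores_muscle"] = muscle_scores
    report.tables["scores_pbmc"] = pbmc_scores

    minfo = _clinical_frame(muscle, clinical)
    binfo = _clinical_frame(pbmc, clinical)
    mwide = muscle_scores.pivot(index="sample_id", columns="signature", values="score").loc[minfo.index]
    bwide = pbmc_scores.pivot(index="sample_id", columns="signature", values="score").loc[binfo.index]

    name = biomarker.name

    # ---- discriminate: FSHD vs control, adjusting for age and sex --------
    neg_ctrl = minfo["tirm"].isin(["neg", "na"])
    frame = minfo[neg_ctrl].copy()
    X = build_design(frame, ["group", "age_years", "sex"])
    res = ols_fit(mwide.loc[X.index, name], X)["group[fshd]"]
    report.results["status_muscle"] = res
    rows.append(
        {
            "analysis": "fshd_vs_control_muscle",
            "signature": name,
            "estimate": res.estimate,
            "p": res.p,
            "significant": res.p < config.alpha,
        }
    )

    frame = binfo.copy()
    Xb = build_design(frame, ["group", "age_years", "sex"])
    res_b = ols_fit(bwide.loc[Xb.index, name], Xb)["group[fshd]"]
    report.results["status_pbmc"] = res_b
    rows.append(
        {
            "analysis": "fshd_vs_control_pbmc",
            "signature": name,
            "estimate": res_b.estimate,
            "p": res_b.p,
            "significant": res_b.p < config.alpha,
        }
    )

    # ---- paired TIRM contrast -------------------------------------------
    fshd_m = minfo[minfo["group"] == "fshd"]
    paired_subjects = fshd_m["subject_id"].value_counts()
    paired_subjects = paired_subjects[paired_subjects == 2].index
    pframe = fshd_m[fshd_m["subject_id"].isin(paired_subjects)]
    tirm_res = paired_adjusted_fit(
        mwide.loc[pframe.index, name],
        pframe["tirm"],
        pframe["subject_id"],
        age=pframe["age_years"],
        sex=pframe["sex"],
    )
    report.results["tirm_paired"] = tirm_res
    rows.append(
        {
            "analysis": "tirm_pos_vs_neg",
            "signature": name,
            "estimate": tirm_res.estimate,
            "p": tirm_res.p,
            "significant": tirm_res.p < config.alpha,
        }
    )

    # ---- severity correlations in each muscle stratum --------------------
    sev_rows = []
    for stratum, mask in (("tirm_neg", minfo["tirm"] == "neg"), ("tirm_pos", minfo["tirm"] == "pos")):
        sub = minfo[mask]
        for var in SEVERITY_VARIABLES:
            if var not in sub.columns:
                continue
            v = pd.to_numeric(sub[var], errors="coerce")
            if v.notna().sum() < 3 or np.nanstd(v) == 0:
                continue
            r = pearson_test(mwide.loc[sub.index, name], v)
            sev_rows.append(
                {
                    "stratum": stratum,
                    "variable": var,
                    "r": r.estimate,
                    "p": r.p,
                    "n": r.n,
                    "significant": r.p < config.alpha,
                }
            )
    severity = pd.DataFrame(sev_rows)
    report.tables["severity_muscle"] = severity
    lam = severity[(severity["stratum"] == "tirm_neg") & (severity["variable"] == "lamperti")]
    if len(lam):
        rows.append(
            {
                "analysis": "severity_lamperti_tirm_neg",
                "signature": name,
                "estimate": float(lam["r"].iloc[0]),
                "p": float(lam["p"].iloc[0]),
                "significant": bool(lam["significant"].iloc[0]),
            }
        )

    # ---- cross-tissue correlation ---------------------------------------
    fshd_pairs_m = minfo[(minfo["group"] == "fshd") & (minfo["tirm"] == "neg")]
    fshd_pairs_b = binfo[binfo["group"] == "fshd"]
    xt = cross_tissue_correlation(
        mwide.loc[fshd_pairs_m.index, name],
        fshd_pairs_m["subject_id"],
        bwide.loc[fshd_pairs_b.index, name],
        fshd_pairs_b["subject_id"],
    )
    report.results["cross_tissue"] = xt
    rows.append(
        {
            "analysis": "muscle_blood_correlation",
            "signature": name,
            "estimate": xt.estimate,
            "p": xt.p,
            "significant": xt.p < config.alpha,
        }
    )

    # ---- independent blood validation ------------------------------------
    if "validation" in data and data["validation"] is not None:
        vem, vclin = data["validation"]
        vem = _normalize_per_cohort(vem, config.log_offset)
        vinfo = _clinical_frame(vem, vclin)
        vscores = score_battery(vem, [biomarker], welch=config.welch)
        vs = vscores.set_index("sample_id")["score"].loc[vinfo.index]
        vz = z_normalize_within(vs, vinfo["cohort"])
        report.tables["validation_scores"] = vscores

        X = build_design(vinfo, ["group", "age_years", "sex", "cohort"])
        sres = ols_fit(vz.loc[X.index], X)["group[fshd]"]
        report.results["validation_status"] = sres
        rows.append(
            {
                "analysis": "validation_status",
                "signature": name,
                "estimate": sres.estimate,
                "p": sres.p,
                "significant": sres.p < config.alpha,
            }
        )

        fmask = vinfo["group"] == "fshd"
        fv = vinfo[fmask]
        Xs = build_design(fv, ["lamperti", "age_years", "sex", "cohort"])
        lres = ols_fit(vz.loc[Xs.index], Xs)["lamperti"]
        report.results["validation_severity"] = lres
        rows.append(
            {
                "analysis": "validation_severity",
                "signature": name,
                "estimate": lres.estimate,
                "p": lres.p,
                "significant": lres.p < config.alpha,
            }
        )

        for model, key in (("status", "resample_status"), ("severity", "resample_severity")):
            rs = signature_null_test(
                vem,
                vclin,
                biomarker,
                model=model,
                n_resamples=config.n_resamples,
                seed=np.random.default_rng(sub_seeds[key]),
                welch=config.welch,
            )
            report.results[key] = rs
            rows.append(
                {
                    "analysis": key,
                    "signature": name,
                    "estimate": rs.observed,
                    "p": rs.p,
                    "significant": rs.p < config.alpha,
                }
            )

        severe = fv["lamperti"] > config.severe_cut
        roc_all = roc_auc(vz.loc[fv.index], severe)
        report.results["roc_all"] = roc_all
        strata, cut = age_stratified_analysis(
            vz.loc[fv.index], fv, severe_cut=config.severe_cut
        )
        report.results["age_stratified"] = strata
        report.results["age_cut"] = cut
        older = fv["age_years"] >= cut
        roc_older = roc_auc(vz.loc[fv.index][older], severe[older])
        report.results["roc_older"] = roc_older
        for stratum_name, res_s in strata.items():
            rows.append(
                {
                    "analysis": f"validation_severity_{stratum_name}",
                    "signature": name,
                    "estimate": res_s.estimate,
                    "p": res_s.p,
                    "significant": res_s.p < config.alpha,
                }
            )

    # ---- meta-analysis ----------------------------------------------------
    if "studies" in data and data["studies"]:
        meta = run_meta(data["studies"], biomarker, welch=config.welch)
        report.results["meta"] = meta
        report.tables["meta_forest"] = meta.forest_table()
        rows.append(
            {
                "analysis": "meta_fisher_combined",
                "signature": name,
                "estimate": meta.pooled,
                "p": meta.fisher_p,
                "significant": meta.fisher_p < config.alpha,
            }
        )

    # ---- over-representation ----------------------------------------------
    if "collections" in data and data["collections"]:
        universe = list(muscle.values.index)
        up_in = [g for g in biomarker.up_genes if g in muscle.values.index]
        dn_in = [g for g in biomarker.down_genes if g in muscle.values.index]
        report.tables["enrichment_up"] = ora_fisher(up_in, data["collections"], universe)
        report.tables["enrichment_dn"] = ora_fisher(dn_in, data["collections"], universe)

    report.summary = pd.DataFrame(rows)
    return report


def _normalize_per_cohort(em: ExpressionMatrix, offset: float) -> ExpressionMatrix:
    """Normalize a multi-cohort matrix cohort by cohort (size factors, log,
    quantile), then re-assemble; mirrors per-study processing."""
    if em.samples is None or "cohort" not in em.samples.columns:
        return _normalize_stage(em, offset)
    parts = []
    for cohort in pd.unique(em.samples["cohort"]):
        ids = list(em.samples.index[em.samples["cohort"] == cohort])
        parts.append(_normalize_stage(em.subset_samples(ids), offset))
    values = pd.concat([p.values for p in parts], axis=1)[list(em.values.columns)]
    return ExpressionMatrix(values, LOG_NORMALIZED, em.samples)
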