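"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study design: FSHD subjects contribute isogenic
non-inflamed (TIRM-) and inflamed (TIRM+) muscle biopsies plus peripheral
blood mononucleated cells (PBMCs), controls contribute muscle and PBMC
samples, and a planted up/down gene signature is repressed in FSHD samples
in proportion to clinical severity.  A subject-level latent trait shared
(with weight rho) between muscle and blood produces the muscle-blood score
concordance; clinical covariates come from a Gaussian copula whose target
correlations mirror the observed severity-score structure (Ricci and
Lamperti strongly positively correlated, both negatively correlated with
the MRC sum score, D4Z4 repeat length inversely related to lower-limb fat
fraction, disease duration uncorrelated with everything).

Effect sizes are expressed on the score (t-statistic) scale: the planted
group effect is the FSHD score deficit in units of the control-group score
SD, and the severity slope is the extra score depression per Lamperti
point.  Default effects are deliberately strong: they were fixed by an
a-priori power analysis so that every planted signal (group deficit,
severity association, muscle-blood concordance, older-stratum interaction)
is recoverable with high probability at the study's own sample sizes,
which is what makes the generator useful for verifying the pipeline.  Set
them lower (or use :meth:`CohortSpec.null`) to emulate weaker, more
realistic signals or the absence of any.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, LOG_NORMALIZED, RAW_COUNTS, Signature

__all__ = [
    "CohortSpec",
    "generate_clinical",
    "generate_expression",
    "generate_validation_cohort",
    "generate_multistudy",
    "nearest_positive_definite",
]

#: clinical variables drawn from the copula, in order
_COPULA_VARS = ("age_years", "ricci", "lamperti", "mrc_sum", "mvc_ta", "llff",
                "d4z4_units", "duration_years")

#: target (latent) correlations among FSHD clinical variables
_DEFAULT_TARGETS = {
    ("ricci", "lamperti"): 0.89,
    ("ricci", "mrc_sum"): -0.72,
    ("lamperti", "mrc_sum"): -0.73,
    ("ricci", "mvc_ta"): -0.53,
    ("lamperti", "mvc_ta"): -0.52,
    ("mrc_sum", "mvc_ta"): 0.62,
    ("ricci", "llff"): 0.61,
    ("lamperti", "llff"): 0.60,
    ("mrc_sum", "llff"): -0.63,
    ("d4z4_units", "llff"): -0.57,
    ("age_years", "ricci"): 0.30,
    ("age_years", "lamperti"): 0.35,
}


@dataclass
class CohortSpec:
    """Design of a synthetic cohort.

    Cohort structure defaults mirror the study: 26 FSHD subjects (one of
    them FSHD2) of whom 24 give isogenic TIRM-/TIRM+ muscle biopsy pairs
    and 15 give PBMCs (13 overlapping the biopsied set); 23 controls of
    whom 11 give muscle and 14 give PBMCs.  The validation cohort mirrors
    the independent blood data set: two cohorts of 39 FSHD + 11 control
    and 15 FSHD + 18 control samples.

    Effect-size parameters (see module docstring for the scale):

    group_effect
        FSHD score deficit in control-score-SD units (0 disables).
    severity_slope
        Score depression per Lamperti point, in t-score units.
    rho
        Muscle-blood concordance of the subject-level biomarker
        displacement.
    latent_sd
        SD (t-score units) of the subject-level latent biomarker trait.
    tirm_signature_effect
        Extra score depression in TIRM+ muscle (t-score units).
    tirm_dux4_effect
        Up-shift of the DUX4-responsive gene block in TIRM+ muscle
        (expression-SD units).
    older_stratum_only
        If True, the severity slope applies only to FSHD subjects older
        than the FSHD mean age (the age-interaction scenario).
    """

    # subjects
    n_fshd: int = 26
    n_control: int = 23
    n_fshd2: int = 1
    n_fshd_muscle: int = 24
    n_fshd_pbmc: int = 15
    n_pbmc_with_muscle: int = 13
    n_control_muscle: int = 11
    n_control_pbmc: int = 14
    # genes and the planted signature
    genes_total: int = 2000
    n_up: int = 64
    n_dn: int = 79
    n_dux4: int = 100
    # effects (t-score scale unless noted)
    group_effect: float = 3.5
    severity_slope: float = 2.2
    rho: float = 0.8
    latent_sd: float = 2.5
    tirm_signature_effect: float = 0.8
    tirm_dux4_effect: float = 1.0
    older_stratum_only: bool = False
    # clinical model
    clinical_targets: dict = field(default_factory=lambda: dict(_DEFAULT_TARGETS))
    fshd_age_mean: float = 50.3
    fshd_age_sd: float = 9.0
    control_age_mean: float = 38.3
    control_age_sd: float = 11.0
    fshd_male_frac: float = 0.46
    control_male_frac: float = 0.61
    # noise model
    expr_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    counts: bool = False
    dispersion: float = 0.1
    depth: float = 2e6
    # validation (independent blood) cohort: (n_fshd, n_control) per cohort
    validation_cohorts: tuple = (("nijmegen", 39, 11), ("newcastle", 15, 18))
    validation_age_mean: float = 49.6
    validation_age_sd: float = 12.0
    validation_lamperti_mean: float = 7.7
    validation_lamperti_sd: float = 3.5
    validation_age_lamperti_r: float = 0.35

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.n_fshd_muscle > self.n_fshd or self.n_fshd_pbmc > self.n_fshd:
            raise ValueError("sampled FSHD subsets exceed n_fshd")
        if self.n_pbmc_with_muscle > min(self.n_fshd_muscle, self.n_fshd_pbmc):
            raise ValueError("muscle-PBMC overlap exceeds the sampled subsets")
        if self.n_control_muscle > self.n_control or self.n_control_pbmc > self.n_control:
            raise ValueError("sampled control subsets exceed n_control")
        if self.n_up + self.n_dn + self.n_dux4 > self.genes_total:
            raise ValueError("signature plus DUX4 block exceed genes_total")
        for pair, r in self.clinical_targets.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"target correlation out of range for {pair}: {r}")

    # ---- derived helpers ----------------------------------------------------
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.genes_total + 1)]

    def signature(self) -> Signature:
        g = self.gene_ids()
        return Signature("planted", tuple(g[: self.n_up]),
                         tuple(g[self.n_up : self.n_up + self.n_dn]))

    def dux4_signature(self) -> Signature:
        g = self.gene_ids()
        a = self.n_up + self.n_dn
        return Signature("dux4_like", tuple(g[a : a + self.n_dux4]))

    @classmethod
    def null(cls, **overrides) -> "CohortSpec":
        """An all-null spec: no planted effects, independent clinical
        variables.  Used for type-I-error and selection-rate calibration."""
        base = dict(
            group_effect=0.0,
            severity_slope=0.0,
            latent_sd=0.0,
            tirm_signature_effect=0.0,
            tirm_dux4_effect=0.0,
            clinical_targets={},
            validation_age_lamperti_r=0.0,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

def nearest_positive_definite(a: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Higham-style repair: clip negative eigenvalues, restore unit diagonal."""
    a = (a + a.T) / 2
    w, v = np.linalg.eigh(a)
    if w.min() > eps:
        return a
    w = np.clip(w, eps, None)
    b = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(b))
    b = b / np.outer(d, d)
    np.fill_diagonal(b, 1.0)
    return b


def _copula_matrix(targets: dict) -> np.ndarray:
    k = len(_COPULA_VARS)
    c = np.eye(k)
    pos = {v: i for i, v in enumerate(_COPULA_VARS)}
    for (u, v), r in targets.items():
        c[pos[u], pos[v]] = c[pos[v], pos[u]] = r
    repaired = nearest_positive_definite(c)
    if np.abs(repaired - c).max() > 0.1:
        raise ValueError("target correlation matrix is too far from positive definite")
    return repaired


def _grid(x: np.ndarray, mean: float, sd: float, lo: float, hi: float,
          step: float | None = None) -> np.ndarray:
    out = mean + sd * x
    if step:
        out = np.round(out / step) * step
    return np.clip(out, lo, hi)


def generate_clinical(spec: CohortSpec, seed=None) -> pd.DataFrame:
    """Subject-level clinical table for the in-house cohort.

    FSHD severity variables are drawn from a Gaussian copula with the
    spec's target correlation matrix (nearest-positive-definite repaired)
    and mapped to each variable's scale: Ricci 0-10 in 0.5 steps, Lamperti
    0-15 integer, MRC sum capped at 60, MVC and LLFF log-normal, D4Z4 an
    integer 1-10 for FSHD1 subjects only.  Controls score 60/60 on MRC and
    carry no severity variables; FSHD subjects are older on average.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    corr = _copula_matrix(spec.clinical_targets)
    chol = np.linalg.cholesky(corr)

    z = (chol @ rng.standard_normal((len(_COPULA_VARS), spec.n_fshd))).T
    rows = []
    for i in range(spec.n_fshd):
        zi = dict(zip(_COPULA_VARS, z[i]))
        fshd2 = i >= spec.n_fshd - spec.n_fshd2
        rows.append(
            {
                "subject_id": f"F{i + 1:02d}",
                "group": "fshd",
                "fshd_type": "fshd2" if fshd2 else "fshd1",
                "age_years": float(
                    _grid(np.array([zi["age_years"]]), spec.fshd_age_mean,
                          spec.fshd_age_sd, 18, 80)[0]
                ),
                "sex": "M" if rng.random() < spec.fshd_male_frac else "F",
                "ricci": float(_grid(np.array([zi["ricci"]]), 4.9, 1.6, 0, 10, 0.5)[0]),
                "lamperti": float(_grid(np.array([zi["lamperti"]]), 5.8, 2.8, 0, 15, 1)[0]),
                "mrc_sum": float(_grid(np.array([zi["mrc_sum"]]), 51.6, 8.0, 12, 60, 1)[0]),
                "mvc_ta": float(np.exp(4.1 + 0.6 * zi["mvc_ta"])),
                "llff": float(np.clip(np.exp(np.log(12.0) + 0.6 * zi["llff"]), 0, 100)),
                "d4z4_units": (
                    float(np.clip(np.round(7.0 + 1.5 * zi["d4z4_units"]), 1, 10))
                    if not fshd2
                    else np.nan
                ),
                "duration_years": float(
                    _grid(np.array([zi["duration_years"]]), 24.0, 12.0, 1, 60, 1)[0]
                ),
            }
        )
    for i in range(spec.n_control):
        rows.append(
            {
                "subject_id": f"C{i + 1:02d}",
                "group": "control",
                "fshd_type": "control",
                "age_years": float(
                    np.clip(spec.control_age_mean + spec.control_age_sd * rng.standard_normal(),
                            18, 80)
                ),
                "sex": "M" if rng.random() < spec.control_male_frac else "F",
                "ricci": np.nan,
                "lamperti": np.nan,
                "mrc_sum": 60.0,
                "mvc_ta": np.nan,
                "llff": np.nan,
                "d4z4_units": np.nan,
                "duration_years": np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _score_se(spec: CohortSpec) -> float:
    """Sampling SE of the planted signature's score: converts t-score-scale
    displacements into per-arm expression shifts."""
    return spec.expr_sd * np.sqrt(1.0 / spec.n_up + 1.0 / spec.n_dn)


def _group_shift(spec: CohortSpec) -> float:
    """FSHD score deficit in t-units; control score SD ~ sqrt(1 + latent^2)."""
    return spec.group_effect * np.sqrt(1.0 + spec.latent_sd**2)


def _apply_displacement(x: np.ndarray, spec: CohortSpec, t_units: np.ndarray) -> None:
    """Shift signature arms in-place so each sample's t-score drops by
    ``t_units[j]``: up genes down by half the mean-difference shift, down
    genes up by the other half."""
    delta = t_units * _score_se(spec)
    x[: spec.n_up, :] -= delta / 2.0
    x[spec.n_up : spec.n_up + spec.n_dn, :] += delta / 2.0


def _base_matrix(spec: CohortSpec, n_samples: int, rng: np.random.Generator,
                 baseline: np.ndarray) -> np.ndarray:
    return baseline[:, None] + spec.expr_sd * rng.standard_normal((spec.genes_total, n_samples))


def _severity_term(spec: CohortSpec, clin: pd.DataFrame, subjects: list[str]) -> np.ndarray:
    """Per-subject severity displacement (t-units), centred on the FSHD
    mean Lamperti so the group effect is the deficit of the average
    patient; zero for controls and, in the age-interaction scenario, for
    FSHD subjects at or below the FSHD mean age."""
    c = clin.set_index("subject_id")
    lam = c.loc[subjects, "lamperti"].to_numpy(dtype=float)
    grp = c.loc[subjects, "group"].to_numpy()
    age = c.loc[subjects, "age_years"].to_numpy(dtype=float)
    is_fshd_all = clin["group"] == "fshd"
    if spec.older_stratum_only:
        cut = float(clin.loc[is_fshd_all, "age_years"].mean())
        older_fshd = is_fshd_all & (clin["age_years"] > cut)
        centre = float(clin.loc[older_fshd, "lamperti"].mean()) if older_fshd.any() else 0.0
        out = np.where(
            (grp == "fshd") & (age > cut),
            spec.severity_slope * (np.nan_to_num(lam) - centre),
            0.0,
        )
    else:
        centre = float(clin.loc[is_fshd_all, "lamperti"].mean())
        out = np.where(
            grp == "fshd", spec.severity_slope * (np.nan_to_num(lam) - centre), 0.0
        )
    return out


def _render_counts(x_log2: np.ndarray, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial count rendering of a log2 expression matrix."""
    mu = 2.0**x_log2
    mu = mu / mu.sum(axis=0, keepdims=True) * spec.depth
    if spec.dispersion <= 0:
        return rng.poisson(mu).astype(float)
    shape = 1.0 / spec.dispersion
    lam = rng.gamma(shape, mu * spec.dispersion)
    return rng.poisson(lam).astype(float)


def _package(spec: CohortSpec, x: np.ndarray, sample_ids: list[str],
             ann: pd.DataFrame, rng: np.random.Generator) -> ExpressionMatrix:
    if spec.counts:
        x = _render_counts(x, spec, rng)
        scale = RAW_COUNTS
    else:
        scale = LOG_NORMALIZED
    values = pd.DataFrame(x, index=spec.gene_ids(), columns=sample_ids)
    return ExpressionMatrix(values, scale=scale, samples=ann)


def generate_expression(spec: CohortSpec, clinical: pd.DataFrame, seed=None) -> dict:
    """In-house expression matrices: muscle_tirm_neg (FSHD TIRM- plus
    control muscle), muscle_tirm_pos (FSHD TIRM+), and pbmc.

    Signature up-genes are shifted down and down-genes up in FSHD samples
    by (group effect + severity slope x Lamperti) on the score scale; a
    subject-level latent trait enters the muscle displacement directly and
    the blood displacement with weight rho, producing the muscle-blood
    score correlation; TIRM+ biopsies additionally up-shift a DUX4-like
    gene block and mildly deepen the signature repression.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subj_ids = clinical["subject_id"].tolist()
    if len(set(subj_ids)) != len(subj_ids):
        raise ValueError("duplicate subject ids in clinical table")
    fshd = [s for s in subj_ids if s.startswith("F")]
    ctrl = [s for s in subj_ids if s.startswith("C")]
    if len(fshd) != spec.n_fshd or len(ctrl) != spec.n_control:
        raise ValueError("clinical table does not match the cohort spec")

    fshd_muscle = fshd[: spec.n_fshd_muscle]
    fshd_pbmc = fshd[: spec.n_pbmc_with_muscle] + fshd[
        spec.n_fshd_muscle : spec.n_fshd_muscle + (spec.n_fshd_pbmc - spec.n_pbmc_with_muscle)
    ]
    ctrl_muscle = ctrl[: spec.n_control_muscle]
    ctrl_pbmc = ctrl[-spec.n_control_pbmc :]

    latent = pd.Series(rng.standard_normal(len(subj_ids)), index=subj_ids)
    blood_noise = pd.Series(rng.standard_normal(len(subj_ids)), index=subj_ids)
    clin = clinical.set_index("subject_id")
    gshift = _group_shift(spec)

    def _muscle_displacement(subjects: list[str], tirm_pos: bool) -> np.ndarray:
        sev = _severity_term(spec, clinical, subjects)
        grp = clin.loc[subjects, "group"].to_numpy()
        is_f = (grp == "fshd").astype(float)
        t = is_f * (gshift + sev) + spec.latent_sd * latent[subjects].to_numpy()
        if tirm_pos:
            t = t + is_f * spec.tirm_signature_effect
        return t

    def _blood_displacement(subjects: list[str]) -> np.ndarray:
        sev = _severity_term(spec, clinical, subjects)
        grp = clin.loc[subjects, "group"].to_numpy()
        is_f = (grp == "fshd").astype(float)
        d = is_f * (gshift + sev) + spec.latent_sd * latent[subjects].to_numpy()
        return spec.rho * d + np.sqrt(1 - spec.rho**2) * spec.latent_sd * blood_noise[
            subjects
        ].to_numpy()

    baseline = spec.baseline_mean + spec.baseline_sd * rng.standard_normal(spec.genes_total)
    dux_lo = spec.n_up + spec.n_dn
    dux_hi = dux_lo + spec.n_dux4
    out = {}

    # TIRM- muscle: FSHD biopsies plus control muscle
    subs = fshd_muscle + ctrl_muscle
    x = _base_matrix(spec, len(subs), rng, baseline)
    _apply_displacement(x, spec, _muscle_displacement(subs, tirm_pos=False))
    ids = [f"{s}_MUSneg" for s in subs]
    ann = pd.DataFrame(
        {
            "cohort": "inhouse",
            "tissue": "muscle",
            "tirm": ["neg"] * len(fshd_muscle) + ["na"] * len(ctrl_muscle),
            "group": clin.loc[subs, "group"].to_numpy(),
            "subject_id": subs,
        },
        index=ids,
    )
    out["muscle_tirm_neg"] = _package(spec, x, ids, ann, rng)

    # TIRM+ muscle: FSHD only
    x = _base_matrix(spec, len(fshd_muscle), rng, baseline)
    _apply_displacement(x, spec, _muscle_displacement(fshd_muscle, tirm_pos=True))
    x[dux_lo:dux_hi, :] += spec.tirm_dux4_effect * spec.expr_sd
    ids = [f"{s}_MUSpos" for s in fshd_muscle]
    ann = pd.DataFrame(
        {
            "cohort": "inhouse",
            "tissue": "muscle",
            "tirm": "pos",
            "group": "fshd",
            "subject_id": fshd_muscle,
        },
        index=ids,
    )
    out["muscle_tirm_pos"] = _package(spec, x, ids, ann, rng)

    # PBMC: FSHD and control blood
    subs = fshd_pbmc + ctrl_pbmc
    x = _base_matrix(spec, len(subs), rng, baseline)
    _apply_displacement(x, spec, _blood_displacement(subs))
    ids = [f"{s}_PBMC" for s in subs]
    ann = pd.DataFrame(
        {
            "cohort": "inhouse",
            "tissue": "pbmc",
            "tirm": "na",
            "group": clin.loc[subs, "group"].to_numpy(),
            "subject_id": subs,
        },
        index=ids,
    )
    out["pbmc"] = _package(spec, x, ids, ann, rng)
    return out


def generate_validation_cohort(spec: CohortSpec, seed=None) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Independent blood validation cohort: two sub-cohorts of FSHD and
    control PBMC-type samples with per-cohort baseline (platform) shifts.

    Lamperti scores correlate with age (Gaussian copula, target r from the
    spec), so the older stratum is more severe on average; in the
    age-interaction scenario the planted severity effect is confined to
    subjects above the FSHD mean age.  Returns the combined expression
    matrix (annotated with cohort and group) and a clinical table.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for cohort, n_f, n_c in spec.validation_cohorts:
        for i in range(n_f + n_c):
            is_f = i < n_f
            za = rng.standard_normal()
            r = spec.validation_age_lamperti_r
            zl = r * za + np.sqrt(1 - r**2) * rng.standard_normal()
            age = float(np.clip(spec.validation_age_mean + spec.validation_age_sd * za, 18, 85))
            lam = float(
                np.clip(
                    np.round(spec.validation_lamperti_mean + spec.validation_lamperti_sd * zl),
                    0,
                    15,
                )
            )
            rows.append(
                {
                    "subject_id": f"{cohort[:3].upper()}{i + 1:03d}",
                    "group": "fshd" if is_f else "control",
                    "fshd_type": "fshd1" if is_f else "control",
                    "cohort": cohort,
                    "age_years": age,
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "lamperti": lam if is_f else np.nan,
                }
            )
    clinical = pd.DataFrame(rows)

    subjects = clinical["subject_id"].tolist()
    gshift = _group_shift(spec)
    sev = _severity_term(spec, clinical, subjects)
    is_f = (clinical["group"] == "fshd").to_numpy(dtype=float)
    latent = rng.standard_normal(len(subjects))
    enoise = rng.standard_normal(len(subjects))
    d = is_f * (gshift + sev) + spec.latent_sd * latent
    t = spec.rho * d + np.sqrt(1 - spec.rho**2) * spec.latent_sd * enoise

    baseline = spec.baseline_mean + spec.baseline_sd * rng.standard_normal(spec.genes_total)
    x = _base_matrix(spec, len(subjects), rng, baseline)
    # per-cohort platform shift on every gene
    for cohort, _, _ in spec.validation_cohorts:
        mask = (clinical["cohort"] == cohort).to_numpy()
        x[:, mask] += 0.4 * rng.standard_normal(spec.genes_total)[:, None]
    _apply_displacement(x, spec, t)

    ids = [f"{s}_BLOOD" for s in subjects]
    ann = pd.DataFrame(
        {
            "cohort": clinical["cohort"].to_numpy(),
            "tissue": "pbmc",
            "tirm": "na",
            "group": clinical["group"].to_numpy(),
            "subject_id": subjects,
        },
        index=ids,
    )
    return _package(spec, x, ids, ann, rng), clinical


def generate_multistudy(spec: CohortSpec, k_studies: int = 7, seed=None,
                        n_fshd_range=(12, 26), n_control_range=(8, 20)) -> list:
    """Independent muscle-biopsy studies with per-study platform effects.

    Each study redraws its gene baselines and applies a global scale
    factor (platform differences removed by within-study quantile
    normalization), over a shared planted FSHD score deficit.  Study sizes
    are drawn within the given bounds.  Returns ``[(matrix, name), ...]``.
    """
    if k_studies < 1:
        raise ValueError("need at least one study")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gshift = _group_shift(spec)
    out = []
    for k in range(k_studies):
        n_f = int(rng.integers(n_fshd_range[0], n_fshd_range[1] + 1))
        n_c = int(rng.integers(n_control_range[0], n_control_range[1] + 1))
        name = f"study_{k + 1}"
        baseline = spec.baseline_mean + spec.baseline_sd * rng.standard_normal(spec.genes_total)
        x = spec.expr_sd * rng.standard_normal((spec.genes_total, n_f + n_c)) + baseline[:, None]
        is_f = np.array([1.0] * n_f + [0.0] * n_c)
        t = is_f * gshift + spec.latent_sd * rng.standard_normal(n_f + n_c)
        _apply_displacement(x, spec, t)
        x *= float(rng.uniform(0.8, 1.2))  # platform scale difference
        ids = [f"{name}_S{i + 1:03d}" for i in range(n_f + n_c)]
        ann = pd.DataFrame(
            {
                "cohort": name,
                "tissue": "muscle",
                "tirm": "na",
                "group": ["fshd"] * n_f + ["control"] * n_c,
                "subject_id": ids,
            },
            index=ids,
        )
        out.append((_package(spec, x, ids, ann, rng), name))
    return out
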