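"""Validation machinery for a refined biomarker.

Three complementary checks of whether an observed biomarker-phenotype
association could arise by chance or generalize as a classifier:

* a matched random-signature resampling null -- many random gene sets of
  the same up/down arm sizes, drawn from the measured universe excluding
  the true biomarker's genes, pushed through the identical scoring,
  within-cohort z-normalization and multivariate regression, with an
  empirical p counting how many associate at least as strongly (Wald |t|);
* ROC/AUC classification of mild versus severe disease (Lamperti 1-7
  versus 8-15) from the biomarker score; and
* an age-stratified association analysis splitting patients at the cohort
  mean age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .data_io import ExpressionMatrix, Signature, match_signature
from .normalize import z_normalize_within
from .scoring import _battery_one
from .stats import AssociationResult, build_design, ols_fit

__all__ = [
    "ResamplingResult",
    "RocResult",
    "random_matched_signatures",
    "empirical_pvalue",
    "signature_null_test",
    "roc_auc",
    "age_stratified_analysis",
    "LAMPERTI_SEVERE_CUT",
]

#: Lamperti scores 1-7 are "mild", 8-15 "severe"
LAMPERTI_SEVERE_CUT = 7.5


@dataclass
class ResamplingResult:
    """Observed association strength against a matched random-signature null."""

    observed: float  # Wald |t| of the target term for the true signature
    nulls: np.ndarray  # same statistic for each random signature
    p: float  # empirical p = (# nulls >= observed) / N
    n_resamples: int
    observed_term: AssociationResult | None = None
    matching: dict = field(default_factory=dict)  # arm sizes, exclusion set size


@dataclass
class RocResult:
    """ROC curve and AUC; orientation is fixed so AUC > 0.5 means a lower
    score predicts the positive (severe) class."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_class: str = "severe"


def random_matched_signatures(
    universe,
    n_up: int,
    n_dn: int,
    n_signatures: int,
    exclude=(),
    seed=None,
) -> list[Signature]:
    """Draw random signatures matched in arm sizes to a true signature.

    Each signature samples ``n_up + n_dn`` genes without replacement from
    ``universe`` minus ``exclude`` (the true biomarker's genes), so its two
    arms never overlap; distinct random signatures may share genes, since
    mutually disjoint sets of this size would exceed any transcriptome.
    Seeded and reproducible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = sorted(set(map(str, universe)) - set(map(str, exclude)))
    k = n_up + n_dn
    if len(eligible) < k:
        raise ValueError(
            f"universe too small: {len(eligible)} eligible genes for {k} needed"
        )
    if len(eligible) == k:
        warnings.warn(
            "universe exactly matches the signature size; all random "
            "signatures contain the same genes (degenerate null)"
        )
    eligible = np.asarray(eligible, dtype=object)
    out = []
    for i in range(n_signatures):
        pick = rng.choice(len(eligible), size=k, replace=False)
        genes = eligible[pick]
        out.append(Signature(f"random_{i}", tuple(genes[:n_up]), tuple(genes[n_up:])))
    return out


def empirical_pvalue(
    observed: float,
    nulls,
    direction: str = "greater",
    pseudocount: bool = False,
) -> float:
    """Empirical p-value: fraction of null statistics at least as extreme.

    ``direction``: "greater" counts nulls >= observed, "less" counts
    nulls <= observed, "two_sided" compares magnitudes.  With
    ``pseudocount`` the conservative (count+1)/(N+1) estimator is used;
    the default is the plain count/N arithmetic (32/1000 = 0.032).
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("need at least one null statistic")
    if direction == "greater":
        count = int(np.sum(nulls >= observed))
    elif direction == "less":
        count = int(np.sum(nulls <= observed))
    elif direction == "two_sided":
        count = int(np.sum(np.abs(nulls) >= abs(observed)))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if pseudocount:
        return (count + 1) / (nulls.size + 1)
    return count / nulls.size


def _score_signatures_fast(em: ExpressionMatrix, sigs: list[Signature], welch: bool = True) -> np.ndarray:
    """(n_samples x n_signatures) t-scores; signatures must be pre-matched."""
    values = em.values.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(em.values.index)}
    cols = []
    for sig in sigs:
        up = np.fromiter((pos[g] for g in sig.up_genes), dtype=int, count=len(sig.up_genes))
        dn = np.fromiter((pos[g] for g in sig.down_genes), dtype=int, count=len(sig.down_genes))
        cols.append(_battery_one(values, up, dn, welch))
    return np.column_stack(cols)


def _wald_t_columns(X: np.ndarray, Y: np.ndarray, j: int) -> np.ndarray:
    """Wald t of design column ``j`` for every response column of ``Y``."""
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ (X.T @ Y)
    resid = Y - X @ B
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / (n - p)
    se = np.sqrt(xtx_inv[j, j] * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return B[j] / se


def signature_null_test(
    em: ExpressionMatrix,
    clinical: pd.DataFrame,
    true_sig: Signature,
    model: str = "status",
    n_resamples: int = 1000,
    seed=None,
    welch: bool = True,
) -> ResamplingResult:
    """Resampling null for the association of a biomarker with status or severity.

    The true signature and ``n_resamples`` random signatures matched in arm
    sizes (drawn from the measured genes excluding the true genes) are each
    scored per sample, z-normalized within cohort, and fitted with the same
    multivariate model: ``score ~ status + age + sex + cohort`` over all
    samples (``model="status"``) or ``score ~ lamperti + age + sex +
    cohort`` over FSHD samples only (``model="severity"``).  Association
    strength is the Wald |t| of the target term; the empirical p is the
    fraction of random signatures at least as strong.
    """
    if n_resamples < 1:
        raise ValueError("need at least one resample")
    if model not in ("status", "severity"):
        raise ValueError(f"unknown model {model!r}")
    if em.samples is None:
        raise ValueError("expression matrix needs sample annotations")

    matched, _ = match_signature(true_sig, em)
    n_up, n_dn = len(matched.up_genes), len(matched.down_genes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    randoms = random_matched_signatures(
        em.values.index, n_up, n_dn, n_resamples, exclude=matched.genes, seed=rng
    )

    info = em.samples.join(
        clinical.set_index("subject_id")[
            [c for c in ("age_years", "sex", "lamperti") if c in clinical.columns]
        ],
        on="subject_id",
    )

    if model == "status":
        keep = info.index
        target_builder = ["group", "age_years", "sex", "cohort"]
    else:
        keep = info.index[info["group"] == "fshd"]
        target_builder = ["lamperti", "age_years", "sex", "cohort"]
    sub = em.subset_samples(list(keep))
    info = info.loc[keep]

    scores = _score_signatures_fast(sub, [matched] + randoms, welch=welch)
    # within-cohort z-normalization, vectorized across signatures
    cohorts = info["cohort"] if "cohort" in info.columns else pd.Series("all", index=info.index)
    Z = np.empty_like(scores)
    for _, idx in pd.Series(np.arange(len(info)), index=info.index).groupby(cohorts):
        rows = idx.to_numpy()
        block = scores[rows]
        sd = block.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero score variance within a cohort")
        Z[rows] = (block - block.mean(axis=0)) / sd

    frame = info.copy()
    terms = [t for t in target_builder if t in frame.columns]
    X = build_design(frame, terms)
    if len(X) != len(frame):
        kept_rows = [frame.index.get_loc(i) for i in X.index]
        Z = Z[kept_rows]
    names = list(X.columns)
    target = "group[fshd]" if model == "status" else "lamperti"
    if target not in names:
        raise ValueError(f"target term {target!r} absent from design ({names})")
    j = names.index(target)

    tvals = np.abs(_wald_t_columns(np.asarray(X, dtype=float), Z, j))
    observed, nulls = float(tvals[0]), tvals[1:]
    p = empirical_pvalue(observed, nulls, direction="greater")

    obs_res = ols_fit(Z[:, 0], X)[target]
    return ResamplingResult(
        observed=observed,
        nulls=nulls,
        p=p,
        n_resamples=n_resamples,
        observed_term=obs_res,
        matching={"n_up": n_up, "n_dn": n_dn, "n_excluded": len(matched.genes), "model": model},
    )


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC for classifying severe disease from the score.

    ``labels`` flag the positive (severe) class; the predictor is the
    negated score, so AUC > 0.5 means lower biomarker scores predict
    severity.  AUC equals the pair-counting probability
    (concordant + ties/2) / (n_pos * n_neg).
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pred = -s
    fpr, tpr, thresholds = roc_curve(y, pred)
    return RocResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=float(roc_auc_score(y, pred)),
    )


def age_stratified_analysis(
    scores: pd.Series,
    sample_info: pd.DataFrame,
    age_cut: float | None = None,
    severe_cut: float = LAMPERTI_SEVERE_CUT,
) -> tuple[dict[str, AssociationResult], float]:
    """Severity association fitted separately in younger and older patients.

    ``sample_info`` (aligned with ``scores``) needs ``age_years`` and
    ``lamperti``, plus ``sex``/``cohort`` when available.  Patients are
    split at ``age_cut`` (default: the arithmetic mean age of the analyzed
    patients); within each stratum the model
    ``score ~ severe + age + sex + cohort`` is fitted, where ``severe``
    is Lamperti above ``severe_cut``, and the severe term is reported.
    Returns ({"younger": ..., "older": ...}, age_cut_used).
    """
    info = sample_info.copy()
    info["score"] = np.asarray(scores, dtype=float)
    info = info.dropna(subset=["age_years", "lamperti"])
    if age_cut is None:
        age_cut = float(info["age_years"].mean())
    info["severe"] = np.where(info["lamperti"] > severe_cut, "severe", "mild")

    out: dict[str, AssociationResult] = {}
    for name, mask in (
        ("younger", info["age_years"] < age_cut),
        ("older", info["age_years"] >= age_cut),
    ):
        stratum = info[mask]
        if len(stratum) == 0:
            raise ValueError(f"empty {name} stratum at age cut {age_cut:.1f}")
        if stratum["severe"].nunique() < 2:
            raise ValueError(
                f"{name} stratum has only one severity class "
                f"(n={len(stratum)}) -- cannot fit the model"
            )
        terms = ["severe", "age_years"] + [
            c for c in ("sex", "cohort") if c in stratum.columns
        ]
        X = build_design(stratum, terms)
        if len(X) <= X.shape[1]:
            raise ValueError(
                f"{name} stratum too small for the model (n={len(X)}, p={X.shape[1]})"
            )
        res = ols_fit(stratum.loc[X.index, "score"], X, drop_aliased=True)
        key = next(k for k in res if k.startswith("severe["))
        out[name] = res[key]
    return out, age_cut
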