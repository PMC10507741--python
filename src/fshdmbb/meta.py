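"""Multi-study meta-analysis of biomarker discrimination.

Each study contributes the mean biomarker difference between FSHD and
control muscle biopsies (with its normal-theory standard error and a
two-tailed Wilcoxon rank-sum p-value); studies are pooled with the
DerSimonian-Laird random-effects estimator, and overall significance is
assessed by Fisher's combined probability test over the per-study Wilcoxon
p-values.  Every study is log-transformed and quantile normalized within
itself before scoring -- never across studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import ExpressionMatrix, LOG_NORMALIZED, Signature
from .normalize import log_transform, quantile_normalize
from .scoring import score_battery
from .stats import wilcoxon_rank_sum

__all__ = [
    "StudyEffect",
    "MetaResult",
    "study_effect",
    "dersimonian_laird",
    "fisher_combined",
    "run_meta",
]


@dataclass
class StudyEffect:
    """Per-study FSHD-minus-control mean score difference."""

    study: str
    n_fshd: int
    n_control: int
    diff: float
    se: float
    ci_low: float
    ci_high: float
    p_wilcoxon: float


@dataclass
class MetaResult:
    """Random-effects pooled effect plus combined significance."""

    effects: list[StudyEffect]
    q: float
    tau2: float
    pooled: float
    pooled_se: float
    ci_low: float
    ci_high: float
    fisher_stat: float
    fisher_df: int
    fisher_p: float
    estimator: str = "DerSimonian-Laird"

    def forest_table(self) -> pd.DataFrame:
        """Plot-ready forest table (one row per study plus the pooled row)."""
        rows = [
            {
                "study": e.study,
                "n_fshd": e.n_fshd,
                "n_control": e.n_control,
                "diff": e.diff,
                "lo95": e.ci_low,
                "hi95": e.ci_high,
                "p": e.p_wilcoxon,
                "stars": _stars(e.p_wilcoxon),
            }
            for e in self.effects
        ]
        rows.append(
            {
                "study": "pooled (RE)",
                "n_fshd": sum(e.n_fshd for e in self.effects),
                "n_control": sum(e.n_control for e in self.effects),
                "diff": self.pooled,
                "lo95": self.ci_low,
                "hi95": self.ci_high,
                "p": self.fisher_p,
                "stars": _stars(self.fisher_p),
            }
        )
        return pd.DataFrame(rows)


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def study_effect(scores_fshd, scores_control, study: str = "") -> StudyEffect:
    """Mean score difference (FSHD - control) with SE, 95% CI and Wilcoxon p.

    ``SE = sqrt(s1^2/n1 + s2^2/n2)``; the CI is the normal
    estimate +/- 1.96 SE.  Both arms need >= 2 samples.
    """
    a = np.asarray(scores_fshd, dtype=float)
    b = np.asarray(scores_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"study {study!r}: both arms need >= 2 samples")
    diff = float(a.mean() - b.mean())
    se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
    p = wilcoxon_rank_sum(a, b).p
    return StudyEffect(
        study=study,
        n_fshd=len(a),
        n_control=len(b),
        diff=diff,
        se=se,
        ci_low=diff - 1.96 * se,
        ci_high=diff + 1.96 * se,
        p_wilcoxon=p,
    )


def dersimonian_laird(effects: list[tuple[float, float]]) -> dict:
    """DerSimonian-Laird random-effects pooling of (estimate, SE) pairs.

    Fixed-effect weights ``w_i = 1/SE_i^2`` give
    ``Q = sum w_i (theta_i - theta_FE)^2`` and
    ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))``; the pooled
    estimate re-weights by ``1/(SE_i^2 + tau2)`` with a normal 95% CI.
    When ``Q <= k-1`` the pooled estimate coincides with the fixed-effect
    inverse-variance mean.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("need at least one study")
    est = np.array([e[0] for e in effects], dtype=float)
    se = np.array([e[1] for e in effects], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    k = len(est)
    w = 1.0 / se**2
    theta_fe = float(np.sum(w * est) / np.sum(w))
    q = float(np.sum(w * (est - theta_fe) ** 2))
    if k == 1:
        tau2 = 0.0
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * est) / np.sum(w_re))
    pooled_se = float(np.sqrt(1.0 / np.sum(w_re)))
    return {
        "q": q,
        "tau2": float(tau2),
        "pooled": pooled,
        "pooled_se": pooled_se,
        "ci_low": pooled - 1.96 * pooled_se,
        "ci_high": pooled + 1.96 * pooled_se,
    }


def fisher_combined(pvec) -> tuple[float, int, float]:
    """Fisher's combined probability test: ``X2 = -2 sum ln p_i`` on 2k df.

    All p must lie in (0, 1]; a zero p raises (floor it first if needed).
    Monotone (decreasing any p decreases the combined p) and invariant to
    input order.
    """
    p = np.asarray(pvec, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0):
        raise ValueError("p-values must be > 0 (apply a floor to zeros first)")
    if np.any(p > 1):
        raise ValueError("p-values must be <= 1")
    x2 = float(-2.0 * np.log(p).sum()) + 0.0
    df = 2 * p.size
    return x2, df, float(sps.chi2.sf(x2, df))


def run_meta(
    studies: list[tuple[ExpressionMatrix, str]] | list[ExpressionMatrix],
    sig: Signature,
    welch: bool = True,
) -> MetaResult:
    """Score a signature within each study and meta-analyze discrimination.

    Each study is an :class:`ExpressionMatrix` whose sample annotations
    carry a ``group`` label (fshd/control), optionally paired with a study
    name.  Raw-count studies are log2-transformed first; every study is
    quantile normalized within itself, scored, summarized by
    :func:`study_effect`, pooled by DerSimonian-Laird and combined with
    Fisher's test over the per-study Wilcoxon p-values.
    """
    norm: list[tuple[str, ExpressionMatrix]] = []
    for i, entry in enumerate(studies):
        em, name = entry if isinstance(entry, tuple) else (entry, f"study_{i + 1}")
        if em.samples is None or "group" not in em.samples.columns:
            raise ValueError(f"study {name!r}: needs group annotations")
        if em.scale != LOG_NORMALIZED:
            em = log_transform(em)
        norm.append((name, quantile_normalize(em)))

    effects: list[StudyEffect] = []
    for name, em in norm:
        try:
            table = score_battery(em, [sig], welch=welch)
        except ValueError as err:
            raise ValueError(f"study {name!r}: {err}") from err
        scores = table.set_index("sample_id")["score"]
        grp = em.samples["group"]
        eff = study_effect(
            scores[grp[grp == "fshd"].index],
            scores[grp[grp == "control"].index],
            study=name,
        )
        effects.append(eff)

    dl = dersimonian_laird([(e.diff, e.se) for e in effects])
    x2, df, p = fisher_combined([e.p_wilcoxon for e in effects])
    return MetaResult(
        effects=effects,
        q=dl["q"],
        tau2=dl["tau2"],
        pooled=dl["pooled"],
        pooled_se=dl["pooled_se"],
        ci_low=dl["ci_low"],
        ci_high=dl["ci_high"],
        fisher_stat=x2,
        fisher_df=df,
        fisher_p=p,
    )
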