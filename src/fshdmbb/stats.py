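"""Statistical primitives used throughout the analysis.

Covariate-adjusted linear and logistic regression, Pearson correlation
tests, Wilcoxon rank tests and Benjamini-Hochberg adjustment, each with the
exact conventions the rest of the package relies on: two-sided p-values
everywhere; categorical covariates one-hot encoded against a first-level
reference; exactly aliased design columns pruned loudly (the paired
inflamed-vs-non-inflamed model absorbs age and sex into subject dummies);
rank tests exact by enumeration for small tie-free samples and normal
approximated with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

log = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "build_design",
    "ols_fit",
    "paired_adjusted_fit",
    "logit_fit",
    "pearson_test",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "bh_adjust",
]

#: exact rank tests up to this many total observations (tie-free inputs only)
EXACT_THRESHOLD = 25


@dataclass
class AssociationResult:
    """One fitted term (or one test) with its uncertainty.

    ``model`` is one of ols, logit, pearson, wilcoxon_rs, wilcoxon_sr.
    For correlation tests ``estimate`` is r; for rank tests ``stat`` is the
    rank statistic and ``estimate`` repeats it.
    """

    term: str
    estimate: float
    se: float
    stat: float
    p: float
    n: int
    model: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of range: {self.p}")


def build_design(
    df: pd.DataFrame,
    terms: list[str],
    categorical: tuple[str, ...] = ("sex", "cohort", "subject_id", "group", "tirm"),
) -> pd.DataFrame:
    """Build an OLS/logit design frame with intercept from named columns.

    Categorical columns are one-hot encoded with the first level (sorted)
    as reference; numeric columns pass through.  Rows with any missing
    value among the requested terms are dropped (case-wise deletion).
    """
    sub = df[terms].dropna()
    cols = {"Intercept": pd.Series(1.0, index=sub.index)}
    for t in terms:
        col = sub[t]
        if t in categorical or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                cols[f"{t}[{lev}]"] = (col.astype(str) == lev).astype(float)
        else:
            cols[t] = col.astype(float)
    return pd.DataFrame(cols, index=sub.index)


def _prune_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop exactly collinear columns, keeping the earliest independent set."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def ols_fit(
    y,
    X: pd.DataFrame,
    drop_aliased: bool = False,
) -> dict[str, AssociationResult]:
    """Ordinary least squares with Wald t-tests per term.

    Parameters
    ----------
    y
        Response vector aligned with the rows of ``X``.
    X
        Design frame (include an intercept column; see :func:`build_design`).
    drop_aliased
        If True, exactly collinear columns are pruned with a logged note
        (needed e.g. when subject dummies absorb age/sex); otherwise a
        rank-deficient design raises, listing the aliased terms.

    Returns a mapping term -> :class:`AssociationResult` with t statistics
    on n - p degrees of freedom and two-sided p-values.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    A = np.asarray(X, dtype=float)
    if y.shape[0] != A.shape[0]:
        raise ValueError("y and X have different lengths")

    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        A2, kept, dropped = _prune_aliased(A, names)
        if not drop_aliased:
            raise ValueError(f"rank-deficient design; aliased terms: {dropped}")
        log.info("ols_fit: pruned aliased design columns: %s", dropped)
        A, names = A2, kept

    n, p = A.shape
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")

    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    df_resid = n - p
    sigma2 = rss / df_resid
    xtx_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        tvals = np.where((se == 0) & (beta == 0), 0.0, tvals)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    return {
        name: AssociationResult(
            term=name,
            estimate=float(beta[j]),
            se=float(se[j]),
            stat=float(tvals[j]),
            p=float(min(pvals[j], 1.0)),
            n=n,
            model="ols",
            covariates=tuple(nm for nm in names if nm != name),
        )
        for j, name in enumerate(names)
    }


def paired_adjusted_fit(
    score,
    tirm_status,
    subject_id,
    age=None,
    sex=None,
) -> AssociationResult:
    """Paired inflamed-vs-non-inflamed comparison via OLS with subject dummies.

    Fits ``score ~ tirm + subject (+ age + sex)``; age and sex are
    constant within subject and therefore exactly aliased with the subject
    dummies -- they are pruned automatically with a logged note.  With two
    samples per subject the fitted tirm coefficient equals the mean of the
    within-pair differences.
    """
    df = pd.DataFrame(
        {
            "score": np.asarray(score, dtype=float),
            "tirm": np.asarray(tirm_status).astype(str),
            "subject_id": np.asarray(subject_id).astype(str),
        }
    )
    counts = df.groupby("subject_id").size()
    bad = counts[counts != 2]
    if len(bad):
        raise ValueError(f"subjects without exactly 2 samples: {bad.index.tolist()}")
    if age is not None:
        df["age_years"] = np.asarray(age, dtype=float)
    if sex is not None:
        df["sex"] = np.asarray(sex).astype(str)
    terms = ["tirm", "subject_id"] + [c for c in ("age_years", "sex") if c in df.columns]
    X = build_design(df, terms)
    res = ols_fit(df.loc[X.index, "score"], X, drop_aliased=True)
    tirm_terms = [k for k in res if k.startswith("tirm[")]
    if len(tirm_terms) != 1:
        raise ValueError(f"expected one tirm contrast, found {tirm_terms}")
    return res[tirm_terms[0]]


def logit_fit(y, X: pd.DataFrame) -> dict[str, AssociationResult]:
    """Maximum-likelihood logistic regression with Wald z-tests.

    ``y`` must contain both outcome classes.  Perfect separation raises
    rather than silently diverging.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("logit response must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    A = np.asarray(X, dtype=float)
    names = list(X.columns)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, A).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as err:
        raise ValueError(f"perfect separation in logit fit: {err}") from None
    mu = fit.predict(A)
    if np.max(np.abs(fit.params)) > 1e3 or np.all((mu < 1e-8) | (mu > 1 - 1e-8)):
        raise ValueError("perfect separation in logit fit (diverging coefficients)")
    return {
        name: AssociationResult(
            term=name,
            estimate=float(fit.params[j]),
            se=float(fit.bse[j]),
            stat=float(fit.tvalues[j]),
            p=float(fit.pvalues[j]),
            n=len(y),
            model="logit",
            covariates=tuple(nm for nm in names if nm != name),
        )
        for j, name in enumerate(names)
    }


def pearson_test(x, y) -> AssociationResult:
    """Pearson correlation with the two-sided t-based p-value.

    Missing values are deleted case-wise; needs >= 3 complete pairs and
    non-zero variance in both variables.  ``t = r*sqrt((n-2)/(1-r^2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs (got {n})")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) < 1.0:
        tstat = r * np.sqrt((n - 2) / (1 - r * r))
    else:
        tstat = np.inf * np.sign(r)
    return AssociationResult(
        term="pearson_r", estimate=r, se=float("nan"), stat=float(tstat),
        p=float(p), n=n, model="pearson",
    )


def wilcoxon_rank_sum(a, b, exact_threshold: int = EXACT_THRESHOLD) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumeration when ``len(a)+len(b) <= exact_threshold`` and
    there are no ties; otherwise the normal approximation with tie
    correction and continuity correction.  ``stat`` is the Mann-Whitney U
    of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= exact_threshold and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return AssociationResult(
        term="rank_sum", estimate=float(res.statistic), se=float("nan"),
        stat=float(res.statistic), p=float(res.pvalue), n=len(a) + len(b),
        model="wilcoxon_rs",
    )


def wilcoxon_signed_rank(diffs, exact_threshold: int = EXACT_THRESHOLD) -> AssociationResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped first (Wilcoxon's original treatment).
    Exact p when the remaining n is small and the absolute differences are
    tie-free; otherwise normal approximation with continuity correction.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero")
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= exact_threshold and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         correction=True, method=method)
    return AssociationResult(
        term="signed_rank", estimate=float(res.statistic), se=float("nan"),
        stat=float(res.statistic), p=float(min(res.pvalue, 1.0)), n=len(d),
        model="wilcoxon_sr",
    )


def bh_adjust(pvec) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Monotone, capped at 1, never smaller than the raw p, and invariant to
    permutations of the input (after un-permuting).
    """
    p = np.asarray(pvec, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out
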