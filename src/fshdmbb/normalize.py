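"""Normalization chain applied before biomarker scoring.

Raw counts are scaled by median-of-ratios size factors (the DESeq2
normalization rule, re-implemented directly), log2-transformed with a
pseudo-count, and quantile normalized within each study; biomarker scores
computed downstream can additionally be z-normalized within cohort before
cross-cohort modelling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import ExpressionMatrix, LOG_NORMALIZED, RAW_COUNTS

__all__ = [
    "median_of_ratios",
    "log_transform",
    "quantile_normalize",
    "z_normalize_within",
]


def median_of_ratios(em: ExpressionMatrix) -> tuple[pd.Series, ExpressionMatrix]:
    """Median-of-ratios size factors and the size-factor-scaled matrix.

    For each sample j, ``s_j = median_g(k_gj / geomean_g(k_g.))`` over genes
    with strictly positive counts in every sample; counts are divided by
    ``s_j``.  Multiplying one sample's counts by c rescales the per-gene
    geometric means by c^(1/n), so individual factors pick up that shared
    constant; the factor *ratios* s_j/s_i are exactly equivariant in c.

    Raises if the matrix is not raw counts or no gene is strictly positive
    in all samples.
    """
    if em.scale != RAW_COUNTS:
        raise ValueError("median_of_ratios expects a raw_counts matrix")
    k = em.values.to_numpy(dtype=float)
    eligible = (k > 0).all(axis=1)
    if not eligible.any():
        raise ValueError("no gene with strictly positive counts in all samples")
    ke = k[eligible]
    log_geomean = np.log(ke).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ke) - log_geomean)
    s = np.median(ratios, axis=0)
    factors = pd.Series(s, index=em.values.columns, name="size_factor")
    scaled = em.values / s
    return factors, ExpressionMatrix(scaled, scale=RAW_COUNTS, samples=em.samples)


def log_transform(em: ExpressionMatrix, offset: float = 1.0, base: float = 2.0) -> ExpressionMatrix:
    """``log_base(x + offset)``; default log2 with pseudo-count 1.

    The base shifts every sample by a shared monotone scale, so group
    comparisons of t-type scores are unaffected by the choice.
    """
    x = em.values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("log_transform requires non-negative values")
    if offset <= 0 and (x == 0).any():
        raise ValueError("zero values need a positive pseudo-count")
    out = np.log(x + offset) / np.log(base)
    return ExpressionMatrix(
        pd.DataFrame(out, index=em.values.index, columns=em.values.columns),
        scale=LOG_NORMALIZED,
        samples=em.samples,
    )


def quantile_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the cross-sample rank-mean distribution.

    The reference vector is the mean over samples of the sorted value
    vectors; each sample's values are replaced by the reference value at
    their rank, ties receiving the mean of the reference values at their
    tied ranks.  Idempotent; after normalization every per-sample sorted
    vector is identical.
    """
    if em.n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returned unchanged")
        return em
    x = em.values.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        qn = np.empty_like(col)
        qn[order] = ref
        # average the reference values over tied ranks
        ranks = rankdata(col, method="average")
        if np.unique(col).size != col.size:
            s = pd.Series(qn).groupby(pd.Series(col)).transform("mean").to_numpy()
            qn = s
        out[:, j] = qn
        del ranks
    return em.with_values(
        pd.DataFrame(out, index=em.values.index, columns=em.values.columns)
    )


def z_normalize_within(scores: pd.Series, groups: pd.Series) -> pd.Series:
    """Z-normalize values within each group (cohort): mean 0, sample SD 1.

    Uses the n-1 sample standard deviation.  A group with fewer than two
    values or zero variance raises, naming the group.  Invariant to affine
    transforms of the input within a group.
    """
    scores = pd.Series(scores)
    groups = pd.Series(groups, index=scores.index)
    out = pd.Series(index=scores.index, dtype=float, name=scores.name)
    for g, idx in scores.groupby(groups).groups.items():
        vals = scores.loc[idx]
        if len(vals) < 2:
            raise ValueError(f"cohort {g!r} has fewer than 2 samples")
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cohort {g!r} has zero score variance")
        out.loc[idx] = (vals - vals.mean()) / sd
    return out
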