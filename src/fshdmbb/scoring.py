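"""Single-sample biomarker scores.

A two-armed signature is scored within one sample as the two-sample
t-statistic contrasting the log expression of its up-regulated genes with
its down-regulated genes (Welch by default); a positive score means the
up arm exceeds the down arm, so in the FSHD convention a lower score
reflects greater repression of the up-regulated targets.  Single-arm
signatures are scored as the mean log expression of their genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, LOG_NORMALIZED, Signature, match_signature

__all__ = ["score_tstat", "score_mean", "score_battery"]


def _tstat(up: np.ndarray, dn: np.ndarray, welch: bool) -> float:
    n1, n2 = len(up), len(dn)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"t-statistic needs >= 2 genes per arm (got {n1}, {n2})")
    d = up.mean() - dn.mean()
    v1 = up.var(ddof=1)
    v2 = dn.var(ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
    if se2 == 0:
        if d == 0:
            return 0.0
        raise ValueError("degenerate arm variances with unequal means (infinite t)")
    return float(d / np.sqrt(se2))


def score_tstat(sample_expr: pd.Series, sig: Signature, welch: bool = True) -> float:
    """Single-sample t-statistic score of a two-armed signature.

    Parameters
    ----------
    sample_expr
        Log-scale expression of one sample, indexed by gene symbol.
        All signature genes must be present (restrict with
        :func:`~fshdmbb.data_io.match_signature` first).
    sig
        Two-armed signature (both arms >= 2 genes after matching).
    welch
        Use the unequal-variance (Welch) t by default; set False for the
        pooled-variance Student's t.

    The score is invariant to permuting genes within an arm, to adding a
    constant to the whole sample, and to positive rescaling; swapping the
    arms negates it exactly.
    """
    if not sig.two_armed:
        raise ValueError(f"signature {sig.name!r} has no down arm; use score_mean")
    missing = [g for g in sig.genes if g not in sample_expr.index]
    if missing:
        raise ValueError(f"signature {sig.name!r}: genes not in sample: {missing[:5]}")
    up = sample_expr.loc[list(sig.up_genes)].to_numpy(dtype=float)
    dn = sample_expr.loc[list(sig.down_genes)].to_numpy(dtype=float)
    return _tstat(up, dn, welch)


def score_mean(sample_expr: pd.Series, sig: Signature) -> float:
    """Mean log expression of a single-arm signature's genes in one sample."""
    genes = list(sig.up_genes) if sig.up_genes else list(sig.down_genes)
    missing = [g for g in genes if g not in sample_expr.index]
    if missing:
        raise ValueError(f"signature {sig.name!r}: genes not in sample: {missing[:5]}")
    if not genes:
        raise ValueError(f"signature {sig.name!r} has no genes")
    return float(sample_expr.loc[genes].to_numpy(dtype=float).mean())


def _battery_one(values: np.ndarray, up_idx: np.ndarray, dn_idx: np.ndarray | None,
                 welch: bool) -> np.ndarray:
    """Vectorized per-sample scores for one matched signature over a
    (genes x samples) array."""
    if dn_idx is None:
        return values[up_idx].mean(axis=0)
    up = values[up_idx]
    dn = values[dn_idx]
    n1, n2 = up.shape[0], dn.shape[0]
    d = up.mean(axis=0) - dn.mean(axis=0)
    v1 = up.var(axis=0, ddof=1)
    v2 = dn.var(axis=0, ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
    zero = se2 == 0
    if zero.any():
        if (d[zero] != 0).any():
            raise ValueError("degenerate arm variances with unequal means (infinite t)")
        se2 = np.where(zero, 1.0, se2)
        d = np.where(zero, 0.0, d)
    return d / np.sqrt(se2)


def score_battery(
    em: ExpressionMatrix,
    sigs: list[Signature],
    method: str = "auto",
    welch: bool = True,
) -> pd.DataFrame:
    """Score every sample of a log-normalized matrix against each signature.

    Two-armed signatures get the t-statistic score, single-arm ones the
    mean score (``method="auto"``); ``"tstat"`` or ``"mean"`` forces one
    method for all.  Returns a long-format table with one row per
    (sample, signature): sample_id, signature, score, method,
    coverage_up, coverage_dn.  Scores are computed on whatever normalized
    scale the matrix carries; no internal re-normalization.
    """
    if em.scale != LOG_NORMALIZED:
        raise ValueError("score_battery expects a log_normalized matrix")
    if method not in ("auto", "tstat", "mean"):
        raise ValueError(f"unknown scoring method {method!r}")
    values = em.values.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(em.values.index)}
    rows = []
    for sig in sigs:
        matched, rep = match_signature(sig, em)
        use_t = matched.two_armed if method == "auto" else method == "tstat"
        if use_t and not matched.two_armed:
            raise ValueError(f"signature {sig.name!r} is single-arm; cannot t-score")
        up_idx = np.array([gene_pos[g] for g in matched.up_genes], dtype=int)
        dn_idx = (
            np.array([gene_pos[g] for g in matched.down_genes], dtype=int)
            if use_t
            else None
        )
        if not use_t and not matched.up_genes:
            up_idx = np.array([gene_pos[g] for g in matched.down_genes], dtype=int)
        try:
            scores = _battery_one(values, up_idx, dn_idx, welch)
        except ValueError as err:
            raise ValueError(f"signature {sig.name!r}: {err}") from err
        for sample, s in zip(em.values.columns, scores):
            rows.append(
                {
                    "sample_id": sample,
                    "signature": sig.name,
                    "score": float(s),
                    "method": "tstat" if use_t else "mean",
                    "coverage_up": rep["coverage_up"],
                    "coverage_dn": rep["coverage_dn"],
                }
            )
    out = pd.DataFrame(rows)
    if not np.isfinite(out["score"]).all():
        bad = out[~np.isfinite(out["score"])].iloc[0]
        raise ValueError(
            f"non-finite score for sample {bad['sample_id']!r}, "
            f"signature {bad['signature']!r}"
        )
    return out


def scores_wide(score_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long score table to samples x signatures."""
    return score_table.pivot(index="sample_id", columns="signature", values="score")
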