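"""Signature refinement by per-gene clinical-correlation screening.

A parent signature (e.g. 311 up- / 290 down-regulated PAX7 target genes) is
screened gene by gene: within each tissue stratum (non-inflamed TIRM- and
inflamed TIRM+ muscle, screened separately) the expression of every parent
gene is Pearson-correlated with each clinical severity variable.  A gene is
retained when any of these correlations reaches raw p < alpha in either
stratum -- a union rule with no multiplicity adjustment, so under a pure
null the expected retention rate is ``1 - (1-alpha)^(variables*strata)``
for independent screens.  Arm membership is preserved, yielding a refined
sub-signature scored exactly like its parent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import ExpressionMatrix, Signature

__all__ = [
    "RefinementResult",
    "gene_clinical_screen",
    "refine_signature",
    "refine_mean_signature",
]


@dataclass
class RefinementResult:
    """Outcome of a screen-and-select refinement."""

    parent: str
    signature: Signature | None  # refined sub-signature (arms preserved); None if empty
    screen: pd.DataFrame  # gene, stratum, variable, r, p, n
    alpha: float
    variables: tuple[str, ...]
    strata: tuple[str, ...]
    unmeasured: tuple[str, ...] = ()  # parent genes absent from the data

    @property
    def n_up(self) -> int:
        return len(self.signature.up_genes) if self.signature else 0

    @property
    def n_dn(self) -> int:
        return len(self.signature.down_genes) if self.signature else 0


def _pearson_block(values: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized Pearson r and two-sided p of each row of ``values``
    against ``v`` (complete cases of ``v`` only)."""
    ok = np.isfinite(v)
    v = v[ok]
    x = values[:, ok]
    n = len(v)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs (got {n})")
    if np.std(v) == 0:
        raise ValueError("constant clinical variable")
    xc = x - x.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ vc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(denom == 0, np.nan, p)  # constant gene: undefined, excluded
    return r, p, n


def gene_clinical_screen(
    em: ExpressionMatrix,
    clinical: pd.DataFrame,
    variables: list[str],
    genes: list[str] | None = None,
    stratum: str = "",
) -> pd.DataFrame:
    """Pearson screen of each gene against each clinical variable.

    ``em`` holds one tissue stratum; samples are matched to clinical rows
    via the ``subject_id`` annotation.  Missing clinical values are deleted
    case-wise per variable (each variable uses its own complete cases).
    Returns a long frame (gene, stratum, variable, r, p, n).  A constant
    variable raises, naming it.
    """
    if em.samples is None or "subject_id" not in em.samples.columns:
        raise ValueError("expression matrix needs subject_id annotations")
    genes = list(genes) if genes is not None else list(em.values.index)
    missing = [g for g in genes if g not in em.values.index]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")

    clin = clinical.set_index("subject_id")
    subj = em.samples["subject_id"]
    unmatched = [s for s in subj if s not in clin.index]
    if unmatched:
        raise ValueError(f"subjects without clinical rows: {unmatched[:5]}")
    values = em.values.loc[genes].to_numpy(dtype=float)

    frames = []
    for var in variables:
        if var not in clin.columns:
            raise ValueError(f"clinical variable {var!r} not found")
        v = pd.to_numeric(clin.loc[subj, var], errors="coerce").to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            raise ValueError(f"clinical variable {var!r} is constant")
        r, p, n = _pearson_block(values, v)
        frames.append(
            pd.DataFrame(
                {"gene": genes, "stratum": stratum, "variable": var, "r": r, "p": p, "n": n}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _select(parent_genes, screen: pd.DataFrame, alpha: float) -> set[str]:
    pmin = screen.groupby("gene")["p"].min()
    return {g for g in parent_genes if g in pmin.index and pmin[g] < alpha}


def refine_signature(
    parent: Signature,
    screens: dict[str, pd.DataFrame],
    variables: list[str],
    alpha: float = 0.05,
) -> RefinementResult:
    """Select parent genes whose screen reaches p < alpha anywhere.

    ``screens`` maps stratum name -> the output of
    :func:`gene_clinical_screen` for that stratum (restricted to the
    requested variables).  A gene is selected iff its minimum p over
    (variables x strata) is below ``alpha``; arms are preserved.  Selection
    is monotone in alpha.  An empty selection warns rather than raising.
    Parent genes absent from every screen are unselectable and reported in
    ``unmeasured``.
    """
    if not screens:
        raise ValueError("need at least one stratum screen")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    allscreen = pd.concat(
        [s[s["variable"].isin(variables)].assign(stratum=name) for name, s in screens.items()],
        ignore_index=True,
    )
    screened_genes = set(allscreen["gene"])
    unmeasured = tuple(g for g in parent.genes if g not in screened_genes)
    selected = _select(parent.genes, allscreen.dropna(subset=["p"]), alpha)
    up = tuple(g for g in parent.up_genes if g in selected)
    dn = tuple(g for g in parent.down_genes if g in selected)
    if not up and not dn:
        warnings.warn(f"refinement of {parent.name!r} selected no genes at alpha={alpha}")
        sig = None
    else:
        sig = Signature(f"{parent.name}_refined", up, dn)
    return RefinementResult(
        parent=parent.name,
        signature=sig,
        screen=allscreen,
        alpha=alpha,
        variables=tuple(variables),
        strata=tuple(screens),
        unmeasured=unmeasured,
    )


def refine_mean_signature(
    parent: Signature,
    screens: dict[str, pd.DataFrame],
    variable: str,
    alpha: float = 0.05,
) -> RefinementResult:
    """Refine a single-arm (mean-type) signature against one variable.

    Same union rule as :func:`refine_signature` with a single clinical
    variable; the refined signature is scored as the mean expression of
    the selected genes.
    """
    if parent.two_armed:
        raise ValueError("refine_mean_signature expects a single-arm parent")
    return refine_signature(parent, screens, [variable], alpha)
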