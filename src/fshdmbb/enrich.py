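"""Over-representation analysis of signature arms by Fisher's exact test.

Each candidate gene set from a collection (GMT) is crossed with the query
gene list inside a fixed gene universe -- by default all genes measured in
the matrix the signature was refined from, since selection happened within
the measured set -- and tested on the resulting 2x2 table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import Signature
from .stats import bh_adjust

__all__ = ["ora_fisher"]


def ora_fisher(query, collection, universe) -> pd.DataFrame:
    """Fisher's exact over-representation of a query list in each category.

    Parameters
    ----------
    query
        Gene list of interest (e.g. one arm of a refined signature);
        must be a subset of ``universe``.
    collection
        List of :class:`~fshdmbb.data_io.Signature` objects or a mapping
        ``name -> gene iterable``; each category is intersected with the
        universe before testing.
    universe
        The background gene set.

    Returns one row per category with overlap count, set sizes, the
    conditional odds ratio, the two-sided Fisher p (point-probability
    method), the one-sided enrichment p, and BH q across the collection.
    """
    uni = set(map(str, universe))
    if not uni:
        raise ValueError("empty universe")
    q = set(map(str, query))
    if not q <= uni:
        extra = sorted(q - uni)
        raise ValueError(f"query genes outside the universe: {extra[:5]}")

    if isinstance(collection, dict):
        items = [(name, set(map(str, genes))) for name, genes in collection.items()]
    else:
        items = [
            (sig.name, set(map(str, sig.genes))) if isinstance(sig, Signature) else sig
            for sig in collection
        ]

    rows = []
    for name, genes in items:
        cat = genes & uni
        a = len(q & cat)
        b = len(q - cat)
        c = len(cat - q)
        d = len(uni) - a - b - c
        table = np.array([[a, b], [c, d]])
        odds, p_two = sps.fisher_exact(table, alternative="two-sided")
        _, p_greater = sps.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "set": name,
                "overlap": a,
                "n_query": len(q),
                "n_set": len(cat),
                "n_universe": len(uni),
                "odds_ratio": float(odds),
                "p": float(p_two),
                "p_enrich": float(p_greater),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
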