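"""Hypergeometric over-representation of gene sets in region-derived lists.

Gene lists extracted from recurrently altered regions are unranked, so the
appropriate enrichment statistic is the hypergeometric upper tail: with a
universe of N genes of which K belong to a set, and a list of n genes of
which k are in the set, p = P(X >= k) for X ~ Hypergeometric(N, K, n).
P values across sets are adjusted with Benjamini–Hochberg.

The default universe for an aCGH analysis is the genes covered by the
probe map — the array-constrained background — not the whole genome.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = ["bh_adjust", "hypergeometric_enrich"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrich(
    gene_list, sets: GeneSetCollection, universe
) -> pd.DataFrame:
    """Over-representation of each gene set in ``gene_list``.

    ``gene_list`` must be a subset of ``universe``; each set is intersected
    with the universe before testing (sets left empty by the intersection
    are skipped with a warning).  Returns rows sorted by p with columns
    ``set, N, K, n, k, p, q``.
    """
    universe = set(universe)
    genes = set(gene_list)
    if not universe:
        raise ValueError("universe is empty")
    if not genes:
        raise ValueError("gene list is empty")
    stray = genes - universe
    if stray:
        raise ValueError(f"gene list not contained in universe, e.g. {sorted(stray)[:3]}")
    big_n = len(universe)
    n = len(genes)
    rows = []
    for name, members in sets:
        in_universe = set(members) & universe
        if not in_universe:
            warnings.warn(f"gene set '{name}' has no members in the universe; skipped")
            continue
        big_k = len(in_universe)
        k = len(in_universe & genes)
        # upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"set": name, "N": big_n, "K": big_k, "n": n, "k": k,
                     "p": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["set", "N", "K", "n", "k", "p"])
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result = result.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        result["q"] = pd.Series(dtype=float)
    return result
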