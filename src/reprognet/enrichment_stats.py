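"""Gene-set over-representation with exact hypergeometric statistics.

Given a query gene list, a GMT collection of terms and a background
universe, each term is tested with the two-sided hypergeometric test
(minimum-likelihood definition) and the p-values are corrected with the
Bonferroni step-down (Holm) procedure, the convention of the ontology
tools this analysis style relies on.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hypergeom_one_sided",
    "hypergeom_two_sided",
    "holm_adjust",
    "ora",
]


def hypergeom_one_sided(k: int, N: int, m: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, m, n) (over-representation tail)."""
    return float(sps.hypergeom.sf(k - 1, N, m, n))


def hypergeom_two_sided(k: int, N: int, m: int, n: int) -> float:
    """Exact two-sided p by the minimum-likelihood rule.

    Sum of P(X = j) over every j in the support whose point probability
    does not exceed P(X = k) (up to a small relative tolerance for
    floating-point ties) — the standard exact two-sided convention.
    """
    lo = max(0, n + m - N)
    hi = min(m, n)
    if not lo <= k <= hi:
        raise ValueError(f"overlap k={k} outside support [{lo}, {hi}]")
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, N, m, n)
    cutoff = pmf[k - lo] * (1.0 + 1e-9)
    return float(min(pmf[pmf <= cutoff].sum(), 1.0))


def holm_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Bonferroni step-down (Holm) adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def ora(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    two_sided: bool = True,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every term of ``collection``.

    Terms are intersected with the universe before testing; the query
    must be a subset of the universe.  Results are sorted by adjusted p,
    then by overlap size descending (larger terms first among ties, the
    reporting convention for ontology summaries), then term name.

    Columns: term, overlap k, term size m, query size n, universe N,
    p_raw, p_adjusted, genes (comma-joined overlap).
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query set")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for term in sorted(collection):
        members = set(collection[term]) & universe
        m = len(members)
        if m == 0:
            continue
        hit = members & query
        k = len(hit)
        p = (
            hypergeom_two_sided(k, N, m, n)
            if two_sided
            else hypergeom_one_sided(k, N, m, n)
        )
        rows.append(
            {
                "term": term,
                "k": k,
                "m": m,
                "n": n,
                "N": N,
                "p_raw": p,
                "genes": ",".join(sorted(hit)),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "k", "m", "n", "N", "p_raw", "genes"]
    )
    if len(out):
        out["p_adjusted"] = holm_adjust(out["p_raw"])
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    out = out.sort_values(
        ["p_adjusted", "k", "term"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return out[["term", "k", "m", "n", "N", "p_raw", "p_adjusted", "genes"]]
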