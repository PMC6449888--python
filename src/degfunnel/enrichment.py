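"""Hypergeometric over-representation of a query gene list in flat gene
sets against an expressed-gene background.

For a background of N genes containing K members of a set, and a query of
n genes overlapping the set in k, the enrichment p-value is the upper
tail P(X >= k) for X ~ Hypergeometric(N, K, n).  Raw p-values are
reported unadjusted; retained sets satisfy K < max_size (strict) and
p < p_max (strict).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection


class EnrichmentError(ValueError):
    pass


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise EnrichmentError(
            f"inconsistent counts: N={N}, K={K}, n={n}, k={k} "
            "(need 0 <= k <= min(K, n) <= N)"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k); scipy computes in log space internally
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str],
    background: set[str],
    sets: GeneSetCollection,
    max_size: int = 100,
    p_max: float = 0.1,
) -> pd.DataFrame:
    """Enrichment records for sets with K < max_size, k >= 1, p < p_max.

    Set sizes K are computed within the background universe only; the
    query must be contained in the background.  Records are sorted by
    ascending p, ties broken by set id.
    """
    offenders = query - background
    if offenders:
        raise EnrichmentError(
            f"query genes missing from background: {sorted(offenders)[:10]}"
        )
    N = len(background)
    n = len(query)
    rows = []
    for sid, members in sets.items():
        in_bg = members & background
        K = len(in_bg)
        if K == 0 or K >= max_size:
            continue
        overlap = sorted(in_bg & query)
        k = len(overlap)
        if k < 1:
            continue
        p = hypergeom_upper_tail(N, K, n, k)
        rows.append({
            "set_id": sid,
            "set_name": sets.names.get(sid, sid),
            "K": K,
            "k": k,
            "n": n,
            "N": N,
            "p": p,
            "members": ",".join(overlap),
        })
    table = pd.DataFrame(rows, columns=["set_id", "set_name", "K", "k", "n", "N", "p", "members"])
    table = table[table["p"] < p_max]
    table = table.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    return table
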