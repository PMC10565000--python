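"""Over-representation analysis of a gene list against GMT gene sets.

One-sided Fisher's exact test per set: with universe size N, query size q,
set size m (after intersecting the set with the universe) and overlap k,
p = sum over i >= k of C(m, i) * C(N - m, q - i) / C(N, q) — the upper
hypergeometric tail.  Bonferroni adjustment is over the sets actually
tested.  With a targeted panel the universe is the tested panel genes, not
the genome; a genome-wide background would wildly inflate significance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetLibrary
from .stats import bonferroni

MIN_SET_UNIVERSE_GENES = 2


def enrich(query_genes, library: GeneSetLibrary, universe_genes) -> pd.DataFrame:
    """Fisher enrichment of the query against every library set.

    Query genes outside the universe are dropped with a warning column in
    attrs; sets with fewer than 2 universe genes are skipped.  The odds
    ratio uses a Haldane correction of 0.5 when any contingency cell is 0.
    """
    universe = {g.upper() for g in universe_genes}
    if not universe:
        raise ValueError("empty universe")
    query = {g.upper() for g in query_genes}
    dropped = sorted(query - universe)
    query &= universe
    if not query:
        raise ValueError("empty query after intersecting with the universe")
    n_universe = len(universe)
    n_query = len(query)

    rows = []
    for name in sorted(library.sets):
        genes = {g.upper() for g in library.sets[name]} & universe
        m = len(genes)
        if m < MIN_SET_UNIVERSE_GENES:
            continue
        overlap = sorted(query & genes)
        k = len(overlap)
        # upper tail: P(X >= k) for X ~ Hypergeom(N, m, q)
        p = float(stats.hypergeom.sf(k - 1, n_universe, m, n_query))
        p = min(1.0, p)
        a = k
        b = n_query - k
        c = m - k
        d = n_universe - n_query - m + k
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (a * d) / (b * c)
        rows.append({
            "set": name, "overlap": k, "set_size": m,
            "query_size": n_query, "universe_size": n_universe,
            "odds_ratio": float(odds), "p_raw": p,
            "overlap_genes": ";".join(overlap),
        })
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "query_size",
                                        "universe_size", "odds_ratio", "p_raw",
                                        "overlap_genes"])
    n_sets = len(table)
    table["p_adj_bonferroni"] = bonferroni(table["p_raw"].to_numpy(), n_sets) \
        if n_sets else pd.Series(dtype=float)
    with np.errstate(divide="ignore"):
        table["neg_log10_p_adj"] = np.where(
            table["p_adj_bonferroni"] > 0,
            -np.log10(table["p_adj_bonferroni"]), np.inf) if n_sets else np.nan
    table.attrs["n_sets_tested"] = n_sets
    table.attrs["query_dropped"] = dropped
    return table


def rank_pathways(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significant sets sorted by -log10 adjusted p (ties: overlap, then name)."""
    sig = table[table["p_adj_bonferroni"] < alpha].copy()
    sig = sig.sort_values(
        by=["neg_log10_p_adj", "overlap", "set"],
        ascending=[False, False, True],
        ignore_index=True,
    )
    return sig
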