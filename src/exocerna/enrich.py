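"""Hypergeometric over-representation analysis of a query gene set.

Generic ORA against term->gene annotation sets (GMT-style).  For a term of
size K in a universe of size M, a query of size N and an observed overlap
x, the enrichment p-value is the hypergeometric upper tail P[X >= x].  The
background universe defaults to the expressed genes rather than the whole
genome.  Terms are called significant at raw p < 0.05; a BH-adjusted
column is emitted for transparency only.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(overlap: int, universe: int, term: int, query: int) -> float:
    """P[X >= overlap] for X ~ Hypergeometric(universe, term, query)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, term, query))


def ora(
    query: set[str],
    annotations: dict[str, list[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of the query in each annotation term.

    Query genes outside the universe are dropped with a warning; each
    term is restricted to the universe.  Rows are sorted by p (ties by
    term id).
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        logger.warning("dropping %d query genes outside the universe", len(stray))
        query &= universe
    if not query:
        raise ValueError("empty query after restriction to the universe")
    m, n_query = len(universe), len(query)
    rows = []
    for term_id in sorted(annotations):
        term_genes = set(annotations[term_id]) & universe
        k = len(term_genes)
        if k == 0:
            continue
        x = len(term_genes & query)
        p = hypergeom_upper_tail(x, m, k, n_query)
        expected = n_query * k / m
        fold = (x / n_query) / (k / m) if x else 0.0
        rows.append((term_id, k, x, n_query, m, fold, expected, p))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_size", "overlap", "query_size",
                 "universe_size", "fold_enrichment", "expected_overlap", "p"],
    )
    if len(out):
        out["p_adj_bh"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p"] < alpha
        out = out.sort_values(["p", "term_id"]).reset_index(drop=True)
    else:
        out["p_adj_bh"] = []
        out["significant"] = []
    return out
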