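"""PPI subgraph induction and degree-based hub-gene ranking.

Mirrors the STRING + cytoHubba "Degree" workflow: keep interactions among
a gene set with confidence score strictly above a threshold (0.4 by
default, STRING's medium confidence), then rank the connected genes by
degree.  Isolated genes are not part of the induced network.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 0.4


def induce_subgraph(
    genes: set[str], edges: pd.DataFrame, threshold: float = DEFAULT_SCORE_THRESHOLD
) -> nx.Graph:
    """Undirected simple graph of above-threshold interactions within ``genes``.

    ``edges`` needs columns gene_a, gene_b, score with scores in [0, 1];
    edges must score strictly above ``threshold``.  Self-loops are dropped
    with a warning; parallel edges keep the highest score.
    """
    scores = edges["score"].to_numpy(dtype=float)
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("PPI scores must lie in [0, 1]")
    genes = set(genes)
    g = nx.Graph()
    n_loops = 0
    for a, b, s in edges[["gene_a", "gene_b", "score"]].itertuples(index=False):
        if a == b:
            n_loops += 1
            continue
        if a in genes and b in genes and s > threshold:
            if not g.has_edge(a, b) or g[a][b]["score"] < s:
                g.add_edge(a, b, score=float(s))
    if n_loops:
        logger.warning("dropped %d self-loop PPI edges", n_loops)
    return g


def hub_genes(graph: nx.Graph, top_k: int = 10) -> list[tuple[str, int]]:
    """Top genes by degree; ties broken lexicographically by gene id."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ranked = sorted(graph.degree, key=lambda item: (-item[1], item[0]))
    if ranked and ranked[1:] and ranked[0][1] == ranked[1][1]:
        logger.info("degree tie at the top rank; lexicographic order applied")
    return [(g, int(d)) for g, d in ranked[:top_k]]
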