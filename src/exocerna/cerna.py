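"""Directional lncRNA-miRNA-mRNA (ceRNA) network construction.

Sponge logic implies opposite regulation of a miRNA and the lncRNA/mRNA it
targets, so two directional networks are built per dataset:

* ``up_mir``:   up-regulated miRNAs vs down-regulated lncRNAs and mRNAs;
* ``down_mir``: down-regulated miRNAs vs up-regulated lncRNAs and mRNAs.

Construction per polarity runs two branches.  The lncRNA branch intersects
the miRNA set's predicted lncRNA targets with the oppositely regulated DE
lncRNAs and reverse-identifies the miRNAs hitting that overlap; the mRNA
branch does the same against DE mRNAs.  The final miRNA set is the
intersection of the two reverse-identified sets, and lncRNA/mRNA nodes are
retained only while still linked to a surviving miRNA, so the result is a
tripartite graph with no isolated nodes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .synthetic_data import TargetTables

logger = logging.getLogger(__name__)

UP_MIR = "up_mir"
DOWN_MIR = "down_mir"

DESet = dict[str, dict[str, set[str]]]  # rna_class -> {"up": set, "down": set}


@dataclass
class CeRNANetwork:
    """Tripartite directional ceRNA network.

    ``graph`` holds typed nodes (attributes ``rna_class`` and ``direction``)
    and lncRNA-miRNA / miRNA-mRNA edges only; every node has degree >= 1.
    """

    polarity: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def nodes_of_class(self, rna_class: str) -> set[str]:
        return {
            n for n, d in self.graph.nodes(data=True) if d["rna_class"] == rna_class
        }

    @property
    def lncrnas(self) -> set[str]:
        return self.nodes_of_class("lncRNA")

    @property
    def mirnas(self) -> set[str]:
        return self.nodes_of_class("miRNA")

    @property
    def mrnas(self) -> set[str]:
        return self.nodes_of_class("mRNA")

    def validate(self) -> None:
        classes = nx.get_node_attributes(self.graph, "rna_class")
        dirs = nx.get_node_attributes(self.graph, "direction")
        mir_dir = {dirs[n] for n in self.graph if classes[n] == "miRNA"}
        partner_dir = {dirs[n] for n in self.graph if classes[n] != "miRNA"}
        if len(mir_dir) > 1 or len(partner_dir) > 1:
            raise ValueError("mixed regulation directions within a node class")
        if mir_dir and partner_dir and mir_dir == partner_dir:
            raise ValueError("miRNAs must be regulated opposite to their partners")
        for u, v in self.graph.edges:
            pair = {classes[u], classes[v]}
            if pair not in ({"lncRNA", "miRNA"}, {"miRNA", "mRNA"}):
                raise ValueError(f"non-tripartite edge {u}-{v}")
        if any(d == 0 for _, d in self.graph.degree):
            raise ValueError("isolated node in ceRNA network")


def dedupe_pairs(pairs) -> set[tuple[str, str]]:
    """Unique (miRNA, target) pairs; warns when duplicates are dropped."""
    pairs = list(pairs)
    unique = set(pairs)
    if len(unique) < len(pairs):
        logger.warning("dropped %d duplicate target pairs", len(pairs) - len(unique))
    return unique


def targets_of(mirnas: set[str], table: set[tuple[str, str]]) -> set[str]:
    """Union of predicted targets over the given miRNAs."""
    return {target for mir, target in table if mir in mirnas}


def overlap_with_de(partner_set: set[str], de_set: set[str]) -> set[str]:
    """Intersection of predicted targets with a DE feature set (Venn step)."""
    return set(partner_set) & set(de_set)


def reverse_identify(
    overlap: set[str], table: set[tuple[str, str]], candidates: set[str]
) -> set[str]:
    """Candidate miRNAs with at least one predicted target in the overlap."""
    return {mir for mir, target in table if mir in candidates and target in overlap}


def build_network(
    de_sets: DESet, tables: TargetTables, polarity: str = UP_MIR
) -> CeRNANetwork:
    """Two-branch intersection / reverse-identification construction."""
    if polarity not in (UP_MIR, DOWN_MIR):
        raise ValueError(f"polarity must be '{UP_MIR}' or '{DOWN_MIR}'")
    mir_dir = "up" if polarity == UP_MIR else "down"
    partner_dir = "down" if polarity == UP_MIR else "up"
    mirs = de_sets["miRNA"][mir_dir]
    de_lnc = de_sets["lncRNA"][partner_dir]
    de_mrna = de_sets["mRNA"][partner_dir]
    _check_disjoint_ids(de_sets)

    mir_to_lnc = dedupe_pairs(tables.mir_to_lnc)
    mir_to_mrna = dedupe_pairs(tables.mir_to_mrna)

    lnc_overlap = overlap_with_de(targets_of(mirs, mir_to_lnc), de_lnc)
    mirs_a = reverse_identify(lnc_overlap, mir_to_lnc, mirs)
    mrna_overlap = overlap_with_de(targets_of(mirs, mir_to_mrna), de_mrna)
    mirs_b = reverse_identify(mrna_overlap, mir_to_mrna, mirs)
    final_mirs = mirs_a & mirs_b

    lnc_edges = {
        (m, t) for m, t in mir_to_lnc if m in final_mirs and t in lnc_overlap
    }
    mrna_edges = {
        (m, t) for m, t in mir_to_mrna if m in final_mirs and t in mrna_overlap
    }
    # a miRNA must keep partners on both sides to remain a ceRNA axis hub;
    # the two-branch reverse identification guarantees that already
    net = CeRNANetwork(polarity=polarity)
    g = net.graph
    for mir, lnc in lnc_edges:
        g.add_node(lnc, rna_class="lncRNA", direction=partner_dir)
        g.add_node(mir, rna_class="miRNA", direction=mir_dir)
        g.add_edge(lnc, mir)
    for mir, mrna in mrna_edges:
        g.add_node(mrna, rna_class="mRNA", direction=partner_dir)
        g.add_node(mir, rna_class="miRNA", direction=mir_dir)
        g.add_edge(mir, mrna)
    # drop miRNAs that lost one side (not in final set) and then any partner
    # left without a surviving miRNA neighbour
    stray = [n for n, d in g.nodes(data=True) if d["rna_class"] == "miRNA"
             and n not in final_mirs]
    g.remove_nodes_from(stray)
    g.remove_nodes_from([n for n, deg in g.degree if deg == 0])
    nx.set_node_attributes(net.graph, dict(g.degree), "degree")
    net.validate()
    return net


def _check_disjoint_ids(de_sets: DESet) -> None:
    seen: set[str] = set()
    for rna_class, dirs in de_sets.items():
        ids = dirs["up"] | dirs["down"]
        if seen & ids:
            raise ValueError(
                f"feature ids collide across classes: {sorted(seen & ids)[:5]}"
            )
        seen |= ids


def extract_triplets(net: CeRNANetwork) -> list[tuple[str, str, str]]:
    """All lncRNA-miRNA-mRNA axes (length-2 paths through a miRNA)."""
    classes = nx.get_node_attributes(net.graph, "rna_class")
    triplets = []
    for mir in sorted(net.mirnas):
        nbrs = list(net.graph.neighbors(mir))
        lncs = sorted(n for n in nbrs if classes[n] == "lncRNA")
        mrnas = sorted(n for n in nbrs if classes[n] == "mRNA")
        triplets.extend((l, mir, g) for l, g in itertools.product(lncs, mrnas))
    return triplets


def network_summary(net: CeRNANetwork) -> dict:
    """Class counts, edge count and per-node degree table."""
    degree = pd.DataFrame(
        [
            (n, d["rna_class"], d["direction"], deg)
            for (n, d), (_, deg) in zip(
                sorted(net.graph.nodes(data=True)), sorted(net.graph.degree)
            )
        ],
        columns=["feature_id", "rna_class", "direction", "degree"],
    ).sort_values(["rna_class", "feature_id"]).reset_index(drop=True)
    return {
        "polarity": net.polarity,
        "n_lncrna": len(net.lncrnas),
        "n_mirna": len(net.mirnas),
        "n_mrna": len(net.mrnas),
        "n_edges": net.graph.number_of_edges(),
        "n_triplets": len(extract_triplets(net)),
        "degree_table": degree,
    }


def load_network(prefix) -> CeRNANetwork:
    """Rebuild a network from the node/edge TSVs written by export_network."""
    nodes = pd.read_csv(f"{prefix}_nodes.tsv", sep="\t", dtype=str)
    edges = pd.read_csv(f"{prefix}_edges.tsv", sep="\t", dtype=str)
    polarity = UP_MIR
    mir_dirs = set(nodes.loc[nodes["rna_class"] == "miRNA", "direction"])
    if mir_dirs == {"down"}:
        polarity = DOWN_MIR
    net = CeRNANetwork(polarity=polarity)
    for row in nodes.itertuples(index=False):
        net.graph.add_node(row.feature_id, rna_class=row.rna_class,
                           direction=row.direction, degree=int(row.degree))
    for row in edges.itertuples(index=False):
        net.graph.add_edge(row.source, row.target)
    net.validate()
    return net


def export_network(net: CeRNANetwork, prefix) -> None:
    """Write node/edge TSVs plus GraphML and SIF renderings."""
    from pathlib import Path

    prefix = Path(prefix)
    summary = network_summary(net)
    summary["degree_table"].to_csv(f"{prefix}_nodes.tsv", sep="\t", index=False)
    classes = nx.get_node_attributes(net.graph, "rna_class")
    edges = sorted(
        (u, v) if classes[u] != "miRNA" else (v, u) for u, v in net.graph.edges
    )
    pd.DataFrame(edges, columns=["source", "target"]).to_csv(
        f"{prefix}_edges.tsv", sep="\t", index=False
    )
    nx.write_graphml(net.graph, f"{prefix}.graphml")
    with open(f"{prefix}.sif", "w", encoding="utf-8") as fh:
        for u, v in edges:
            fh.write(f"{u}\ttargets\t{v}\n")
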