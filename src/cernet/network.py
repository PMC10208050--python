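"""Tripartite ceRNA network: assembly, pruning, hub ranking, subnets, export.

The network is an undirected graph over three node classes — lncRNA, miRNA,
mRNA — with edges only between lncRNA-miRNA and miRNA-mRNA (the competing
endogenous RNA topology: a lncRNA sponges miRNAs that would otherwise
repress their mRNA targets). Construction unions the two edge tables and
then prunes to a fixed point: a miRNA must keep at least one lncRNA
neighbor AND one mRNA neighbor (otherwise it cannot mediate competition),
and lncRNA/mRNA nodes must keep degree >= 1. Candidate lncRNAs are ranked
by degree, with lexicographic tie-breaking for determinism.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import pandas as pd

from .interactions import InteractionTable

logger = logging.getLogger(__name__)

NODE_TYPES = ("lncRNA", "miRNA", "mRNA")
EDGE_LABELS = {("lncRNA", "miRNA"): "lnc-mi", ("miRNA", "mRNA"): "mi-m"}


class CeRNANetwork:
    """Thin wrapper over an undirected networkx graph with typed nodes/edges."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self.graph.nodes(data="node_type") if t == node_type)

    def node_type(self, node: str) -> str:
        return self.graph.nodes[node]["node_type"]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple[str, str, str]]:
        """(source, interaction, target) triples, lncRNA/miRNA first, sorted."""
        rows = []
        for u, v, data in self.graph.edges(data=True):
            tu, tv = self.node_type(u), self.node_type(v)
            if (tu, tv) not in EDGE_LABELS:
                u, v, tu, tv = v, u, tv, tu
            rows.append((u, EDGE_LABELS[(tu, tv)], v))
        return sorted(rows)


def validate_network(net: CeRNANetwork) -> None:
    """Assert the tripartite ceRNA invariants; raise ValueError on violation."""
    g = net.graph
    for n, t in g.nodes(data="node_type"):
        if t not in NODE_TYPES:
            raise ValueError(f"node {n!r} has invalid type {t!r}")
        if g.degree(n) < 1:
            raise ValueError(f"isolated node {n!r}")
    for u, v in g.edges():
        pair = frozenset((net.node_type(u), net.node_type(v)))
        if pair not in (frozenset(("lncRNA", "miRNA")), frozenset(("miRNA", "mRNA"))):
            raise ValueError(f"forbidden edge {u!r}-{v!r} ({sorted(pair)})")
    for m in list(g.nodes):
        if net.node_type(m) != "miRNA":
            continue
        types = {net.node_type(x) for x in g.neighbors(m)}
        if not {"lncRNA", "mRNA"} <= types:
            raise ValueError(f"miRNA {m!r} lacks a neighbor on one side")


def _prune(g: nx.Graph) -> None:
    """Iteratively drop one-sided miRNAs and isolated lncRNA/mRNA nodes (fixed point)."""
    changed = True
    while changed:
        changed = False
        drop = []
        for n, t in g.nodes(data="node_type"):
            if t == "miRNA":
                types = {g.nodes[x]["node_type"] for x in g.neighbors(n)}
                if not {"lncRNA", "mRNA"} <= types:
                    drop.append(n)
            elif g.degree(n) == 0:
                drop.append(n)
        if drop:
            g.remove_nodes_from(drop)
            changed = True


def build_cerna_network(lnc_mi: InteractionTable, mi_m: InteractionTable) -> CeRNANetwork:
    """Union the lncRNA-miRNA and miRNA-mRNA edges and prune to a valid network.

    Node types are assigned from table roles; an identifier appearing in two
    different roles is an error.
    """
    if lnc_mi.kind != "lncRNA-miRNA":
        raise ValueError("first table must be lncRNA-miRNA")
    if mi_m.kind != "miRNA-mRNA":
        raise ValueError("second table must be miRNA-mRNA")
    roles: dict[str, str] = {}
    conflicts = []

    def assign(node: str, t: str) -> None:
        if roles.setdefault(node, t) != t:
            conflicts.append((node, roles[node], t))

    for _, row in lnc_mi.df.iterrows():
        assign(row["regulator"], "lncRNA")
        assign(row["target"], "miRNA")
    for _, row in mi_m.df.iterrows():
        assign(row["regulator"], "miRNA")
        assign(row["target"], "mRNA")
    if conflicts:
        raise ValueError(f"identifiers with conflicting node types: {sorted(set(conflicts))}")

    g = nx.Graph()
    for node, t in roles.items():
        g.add_node(node, node_type=t)
    for _, row in lnc_mi.df.iterrows():
        g.add_edge(row["regulator"], row["target"], etype="lnc-mi", source_db=row["source_db"])
    for _, row in mi_m.df.iterrows():
        g.add_edge(row["regulator"], row["target"], etype="mi-m", source_db=row["source_db"])
    _prune(g)
    return CeRNANetwork(g)


def node_degrees(net: CeRNANetwork) -> pd.DataFrame:
    """Table of (id, node_type, degree), sorted by degree desc then id."""
    rows = [
        {"id": n, "node_type": t, "degree": net.graph.degree(n)}
        for n, t in net.graph.nodes(data="node_type")
    ]
    df = pd.DataFrame(rows, columns=["id", "node_type", "degree"])
    return df.sort_values(["degree", "id"], ascending=[False, True]).reset_index(drop=True)


def rank_lncrnas(net: CeRNANetwork, top_k: int | None = None) -> list[tuple[str, int]]:
    """lncRNAs sorted by degree descending, ties broken lexicographically."""
    if top_k is not None and top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    ranked = sorted(
        ((n, net.graph.degree(n)) for n in net.nodes_of_type("lncRNA")),
        key=lambda item: (-item[1], item[0]),
    )
    return ranked[:top_k] if top_k is not None else ranked


def extract_subnetwork(net: CeRNANetwork, lncrna_id: str) -> CeRNANetwork:
    """Subnet of one lncRNA: its miRNAs, their mRNA targets, and the touching edges."""
    if lncrna_id not in net.graph:
        raise ValueError(f"unknown node {lncrna_id!r}")
    if net.node_type(lncrna_id) != "lncRNA":
        raise ValueError(f"{lncrna_id!r} is not a lncRNA node")
    g = net.graph
    sub = nx.Graph()
    sub.add_node(lncrna_id, node_type="lncRNA")
    for m in g.neighbors(lncrna_id):
        sub.add_node(m, node_type="miRNA")
        sub.add_edge(lncrna_id, m, **g.edges[lncrna_id, m])
        for x in g.neighbors(m):
            if net.node_type(x) == "mRNA":
                sub.add_node(x, node_type="mRNA")
                sub.add_edge(m, x, **g.edges[m, x])
    return CeRNANetwork(sub)


def network_summary(net: CeRNANetwork) -> dict[str, int]:
    """Counts by node type plus total edges."""
    return {
        "n_lncrna": len(net.nodes_of_type("lncRNA")),
        "n_mirna": len(net.nodes_of_type("miRNA")),
        "n_mrna": len(net.nodes_of_type("mRNA")),
        "n_edges": net.n_edges,
    }


def export_network(net: CeRNANetwork, fmt: str, path) -> None:
    """Write the network as SIF, GraphML, or edge-TSV (all Cytoscape-readable).

    Output ordering is stable-sorted for byte-reproducible runs.
    """
    edges = net.edge_list()
    if not edges:
        warnings.warn("exporting an empty network")
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, label, v in edges:
                fh.write(f"{u}\t{label}\t{v}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\tinteraction\ttarget\tsource_db\n")
            for u, label, v in edges:
                db = net.graph.edges[u, v].get("source_db", "")
                fh.write(f"{u}\t{label}\t{v}\t{db}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for n in sorted(net.graph.nodes):
            g.add_node(n, node_type=net.node_type(n))
        for u, label, v in edges:
            g.add_edge(u, v, etype=label, source_db=net.graph.edges[u, v].get("source_db", ""))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; use sif, graphml, or tsv")


def read_edge_tsv(path) -> CeRNANetwork:
    """Re-import an edge-TSV export (round-trip counterpart of export_network)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    g = nx.Graph()
    type_by_label = {"lnc-mi": ("lncRNA", "miRNA"), "mi-m": ("miRNA", "mRNA")}
    for _, row in df.iterrows():
        tu, tv = type_by_label[row["interaction"]]
        g.add_node(row["source"], node_type=tu)
        g.add_node(row["target"], node_type=tv)
        g.add_edge(
            row["source"], row["target"], etype=row["interaction"],
            source_db=row.get("source_db", ""),
        )
    return CeRNANetwork(g)
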