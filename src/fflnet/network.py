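"""Co-regulatory network assembly, centralities, hubs and walktrap modules.

Significant FFL records merge into one typed graph per functional cluster:
nodes are miRNAs, TFs, primary and secondary targets (a gene that is primary
in any motif is typed primary — the regulatory role dominates); edges carry
their interaction kind (mirna_target, tf_target, ppi; an edge supported by
several kinds stores them ';'-joined).  Centralities and community detection
use the undirected simple-graph view.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import igraph
import networkx as nx
import numpy as np
import pandas as pd

from .clustering import geneset_enrichment

logger = logging.getLogger(__name__)

NODE_TYPES = ("mirna", "tf", "primary_target", "secondary_target")


def merge_motifs(records: pd.DataFrame, tf_map=None,
                 de_table: pd.DataFrame | None = None) -> nx.Graph:
    """Union of all nodes/edges of the given (significant) FFL records.

    Adds TF->miRNA regulatory edges for record pairs whose TF binds the
    miRNA's promoter (``tf_map.mirna_targets``), and annotates nodes with
    log2FC / DE flags from ``de_table`` when provided.
    """
    g = nx.Graph()

    def add_node(name, ntype):
        if name in g.nodes:
            # primary role dominates secondary for doubly-used genes
            if g.nodes[name]["type"] == "secondary_target" and ntype == "primary_target":
                g.nodes[name]["type"] = ntype
            return
        g.add_node(name, type=ntype)

    def add_edge(u, v, kind):
        if g.has_edge(u, v):
            kinds = set(g[u][v]["kind"].split(";")) | {kind}
            g[u][v]["kind"] = ";".join(sorted(kinds))
        else:
            g.add_edge(u, v, kind=kind)

    for row in records.itertuples(index=False):
        add_node(row.mirna, "mirna")
        add_node(row.tf, "tf")
        add_node(row.primary_target, "primary_target")
        add_edge(row.mirna, row.primary_target, "mirna_target")
        if row.motif_type == "ffl3":
            add_edge(row.tf, row.primary_target, "tf_target")
        else:
            add_node(row.secondary_target, "secondary_target")
            add_edge(row.tf, row.secondary_target, "tf_target")
            add_edge(row.primary_target, row.secondary_target, "ppi")
        if tf_map is not None and row.mirna in tf_map.mirna_targets.get(row.tf, set()):
            add_edge(row.tf, row.mirna, "tf_target")

    if de_table is not None:
        for n in g.nodes:
            if n in de_table.index:
                g.nodes[n]["log2fc"] = float(de_table.at[n, "log2fc"])
                g.nodes[n]["de"] = True
            else:
                g.nodes[n]["log2fc"] = 0.0
                g.nodes[n]["de"] = False
    return g


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Exact degree and betweenness (unnormalized shortest-path counts).

    Betweenness sums, over unordered node pairs (s, t), the fraction of
    shortest s-t paths passing through the node.
    """
    deg = dict(net.degree())
    btw = nx.betweenness_centrality(net, normalized=False)
    out = pd.DataFrame({
        "node": list(net.nodes),
        "type": [net.nodes[n].get("type", "") for n in net.nodes],
        "degree": [deg[n] for n in net.nodes],
        "betweenness": [btw[n] for n in net.nodes],
    }).set_index("node")
    return out.sort_index()


def call_hubs(net: nx.Graph, fraction_mirna: float = 0.25,
              fraction_tf: float = 0.25, fraction_target: float = 0.05,
              cent: pd.DataFrame | None = None) -> set:
    """Top degree fraction per node type (targets pooled across both roles).

    The count is ceil(fraction x type size); ties at the cut break by higher
    betweenness, then lexicographic id.
    """
    for f in (fraction_mirna, fraction_tf, fraction_target):
        if not 0 < f <= 1:
            raise ValueError("hub fractions must be in (0, 1]")
    if cent is None:
        cent = centralities(net)
    type_groups = {
        "mirna": fraction_mirna,
        "tf": fraction_tf,
        "target": fraction_target,
    }
    hubs: set = set()
    pooled = cent.copy()
    pooled["group"] = pooled["type"].map(
        lambda t: "target" if t.endswith("_target") else t)
    for group, frac in type_groups.items():
        sub = pooled[pooled["group"] == group]
        if sub.empty:
            continue
        n_hub = math.ceil(frac * len(sub))
        # stable sort on the index first makes the id tie-break explicit
        ranked = sub.sort_index().sort_values(
            ["degree", "betweenness"], ascending=False, kind="stable")
        hubs.update(ranked.index[:n_hub])
    return hubs


@dataclass
class ModulePartition:
    assignment: pd.Series            # node -> module id (int)
    modularity: float

    def members(self, module_id) -> list:
        return sorted(self.assignment.index[self.assignment == module_id])

    @property
    def module_ids(self) -> list:
        return sorted(self.assignment.unique())


def walktrap_modules(net: nx.Graph, steps: int = 4) -> ModulePartition:
    """Random-walk (walktrap) community detection, cut at max modularity.

    Connected components are processed independently; module ids are assigned
    in order of each component's lexicographically smallest node, so the
    labeling is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    assignment = {}
    next_id = 0
    components = sorted(nx.connected_components(net), key=lambda c: min(c))
    for comp in components:
        nodes = sorted(comp)
        if len(nodes) == 1:
            assignment[nodes[0]] = next_id
            next_id += 1
            continue
        sub = net.subgraph(nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        ig = igraph.Graph(n=len(nodes),
                          edges=[(idx[u], idx[v]) for u, v in sub.edges()])
        clustering = ig.community_walktrap(steps=steps).as_clustering()
        for local_id, cluster in enumerate(clustering):
            for vid in cluster:
                assignment[nodes[vid]] = next_id + local_id
        next_id += len(clustering)
    series = pd.Series(assignment, name="module").sort_index()
    part = ModulePartition(series, modularity=_modularity(net, series))
    logger.info("walktrap: %d modules, modularity=%.3f",
                len(part.module_ids), part.modularity)
    return part


def _modularity(net: nx.Graph, assignment: pd.Series) -> float:
    communities = [set(assignment.index[assignment == m])
                   for m in sorted(assignment.unique())]
    if net.number_of_edges() == 0:
        return 0.0
    return nx.community.modularity(net, communities)


def module_table(net: nx.Graph, partition: ModulePartition) -> pd.DataFrame:
    """Per-module node/edge counts and member miRNAs/TFs."""
    rows = []
    for mid in partition.module_ids:
        members = partition.members(mid)
        sub = net.subgraph(members)
        types = {n: net.nodes[n].get("type", "") for n in members}
        rows.append({
            "module": mid,
            "n_nodes": sub.number_of_nodes(),
            "n_edges": sub.number_of_edges(),
            "mirnas": ",".join(sorted(n for n, t in types.items() if t == "mirna")),
            "tfs": ",".join(sorted(n for n, t in types.items() if t == "tf")),
        })
    return pd.DataFrame(rows).set_index("module")


def annotate_modules(net: nx.Graph, partition: ModulePartition, sets: dict,
                     enrich_fdr: float = 0.05) -> pd.DataFrame:
    """Label each module with its top enriched gene set (or "-" if none).

    The enrichment universe is the network's gene nodes (miRNAs excluded);
    p-values are BH-corrected within each module's family of sets.
    """
    universe = {n for n in net.nodes if net.nodes[n].get("type") != "mirna"}
    table = module_table(net, partition)
    labels, pvals = [], []
    for mid in table.index:
        genes = set(partition.members(mid)) & universe
        enr = geneset_enrichment(genes, universe, sets)
        sig = enr[enr["fdr"] < enrich_fdr]
        if sig.empty:
            labels.append("-")
            pvals.append(np.nan)
        else:
            labels.append(sig.index[0])
            pvals.append(float(sig["p"].iloc[0]))
    table["label"] = labels
    table["label_p"] = pvals
    return table


def average_degree_by_type(net: nx.Graph) -> pd.Series:
    """Mean degree per node type (targets pooled), for degree-profile reports."""
    deg = dict(net.degree())
    groups: dict = {}
    for n in net.nodes:
        t = net.nodes[n].get("type", "")
        group = "target" if t.endswith("_target") else t
        groups.setdefault(group, []).append(deg[n])
    return pd.Series({g: float(np.mean(v)) for g, v in sorted(groups.items())})
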