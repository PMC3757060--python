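"""Network assembly, centralities, hubs, walktrap modules, annotation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import betweenness_by_path_counting
from fflnet.motifs import FFL_COLUMNS
from fflnet.network import (ModulePartition, annotate_modules,
                            average_degree_by_type, call_hubs, centralities,
                            merge_motifs, module_table, walktrap_modules)


def _records(rows):
    return pd.DataFrame(rows, columns=FFL_COLUMNS)


class _TFMap:
    def __init__(self, mirna_targets=None):
        self.mirna_targets = mirna_targets or {}


# ---------------------------------------------------------------------------
# merging

def test_single_ffl3_builds_three_nodes():
    rec = _records([("C1", "ffl3", "m", "tf", "g", "", 0.01, 0.01)])
    net = merge_motifs(rec, tf_map=_TFMap({"tf": {"m"}}))
    assert set(net.nodes) == {"m", "tf", "g"}
    assert net.number_of_edges() == 3      # miRNA->g, TF->g, TF->miRNA
    assert net["tf"]["m"]["kind"] == "tf_target"


def test_ffl3_without_mirna_tfbs_has_two_edges():
    rec = _records([("C1", "ffl3", "m", "tf", "g", "", 0.01, 0.01)])
    net = merge_motifs(rec, tf_map=_TFMap({}))
    assert net.number_of_edges() == 2


def test_shared_target_edges_are_deduplicated():
    rec = _records([("C1", "ffl3", "m1", "tf", "g", "", 0.01, 0.01),
                    ("C1", "ffl3", "m2", "tf", "g", "", 0.01, 0.01)])
    net = merge_motifs(rec)
    assert net.number_of_nodes() == 4
    assert net.number_of_edges() == 3      # m1-g, m2-g, tf-g


def test_empty_records_give_empty_network():
    net = merge_motifs(_records([]))
    assert net.number_of_nodes() == 0


def test_primary_role_dominates_secondary():
    rec = _records([
        ("C1", "ffl4", "m", "tf", "p1", "x", 0.01, 0.01),
        ("C1", "ffl3", "m", "tf", "x", "", 0.01, 0.01),
    ])
    net = merge_motifs(rec)
    assert net.nodes["x"]["type"] == "primary_target"
    rec_rev = rec.iloc[::-1].reset_index(drop=True)
    assert merge_motifs(rec_rev).nodes["x"]["type"] == "primary_target"


def test_node_attributes_carry_de_statistics():
    rec = _records([("C1", "ffl3", "m", "tf", "g", "", 0.01, 0.01)])
    de = pd.DataFrame({"log2fc": [-1.5, 0.9]}, index=["m", "g"])
    net = merge_motifs(rec, de_table=de)
    assert net.nodes["m"]["log2fc"] == -1.5
    assert net.nodes["m"]["de"] is True
    assert net.nodes["tf"]["de"] is False


def test_merge_is_invariant_to_record_order(study_result):
    for cid in study_result.networks:
        sub = study_result.records[study_result.records.cluster == cid]
        net1 = merge_motifs(sub)
        net2 = merge_motifs(sub.sample(frac=1.0, random_state=1))
        assert set(net2.nodes) == set(net1.nodes)
        assert set(map(frozenset, net2.edges)) == set(map(frozenset, net1.edges))
        assert {n: d["type"] for n, d in net1.nodes(data=True)} == \
               {n: d["type"] for n, d in net2.nodes(data=True)}


# ---------------------------------------------------------------------------
# centralities

def test_star_graph_degrees():
    g = nx.star_graph(5)
    cent = centralities(nx.relabel_nodes(g, str))
    assert cent.loc["0", "degree"] == 5
    assert (cent.drop("0")["degree"] == 1).all()


def test_path_betweenness_counts_interior_pairs():
    g = nx.path_graph(["a", "b", "c"])
    cent = centralities(g)
    assert cent.loc["b", "betweenness"] == 1.0
    assert cent.loc["a", "betweenness"] == 0.0


def test_betweenness_matches_brute_force_on_random_graph():
    g = nx.gnp_random_graph(30, 0.15, seed=4)
    g = nx.relabel_nodes(g, str)
    cent = centralities(g)
    oracle = betweenness_by_path_counting(g)
    for node, expected in oracle.items():
        assert cent.loc[node, "betweenness"] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# hubs

def _typed_star(n_mirna, n_tf, n_target):
    g = nx.Graph()
    for i in range(n_mirna):
        g.add_node(f"m{i}", type="mirna")
    for i in range(n_tf):
        g.add_node(f"t{i}", type="tf")
    for i in range(n_target):
        g.add_node(f"g{i}", type="primary_target")
    # degree ladder inside each type
    nodes = list(g.nodes)
    for i, u in enumerate(nodes):
        for v in nodes[:i % 7]:
            if u != v:
                g.add_edge(u, v)
    return g


def test_hub_counts_follow_the_ceiling_rule():
    g = _typed_star(12, 8, 200)
    hubs = call_hubs(g)
    by_type = {"mirna": 0, "tf": 0, "target": 0}
    for h in hubs:
        t = g.nodes[h]["type"]
        by_type["target" if t.endswith("_target") else t] += 1
    assert by_type["mirna"] == 3       # ceil(0.25 * 12)
    assert by_type["tf"] == 2          # ceil(0.25 * 8)
    assert by_type["target"] == 10     # ceil(0.05 * 200)


def test_equal_degrees_break_ties_deterministically():
    g = nx.Graph()
    for name in ("b", "a", "c", "d"):
        g.add_node(name, type="mirna")
    g.add_edges_from([("a", "b"), ("c", "d")])
    hubs = call_hubs(g, fraction_mirna=0.25)
    assert hubs == {"a"}


def test_invalid_fractions_rejected():
    with pytest.raises(ValueError):
        call_hubs(nx.Graph(), fraction_mirna=0.0)


# ---------------------------------------------------------------------------
# walktrap modules

def test_two_cliques_joined_by_one_edge_are_recovered():
    g = nx.union(nx.complete_graph(5), nx.complete_graph(5), rename=("a", "b"))
    g.add_edge("a0", "b0")
    part = walktrap_modules(g)
    modules = {frozenset(part.members(m)) for m in part.module_ids}
    assert modules == {frozenset(f"a{i}" for i in range(5)),
                       frozenset(f"b{i}" for i in range(5))}


def test_complete_graph_is_one_module():
    part = walktrap_modules(nx.complete_graph(8))
    assert len(part.module_ids) == 1


def test_singletons_and_components_are_independent():
    g = nx.Graph()
    g.add_node("lonely")
    g.add_edges_from([("x", "y"), ("y", "z")])
    part = walktrap_modules(g)
    assert part.assignment["lonely"] != part.assignment["x"]


def test_empty_network_is_an_error():
    with pytest.raises(ValueError):
        walktrap_modules(nx.Graph())


def test_partition_covers_nodes_exactly_and_beats_trivial_modularity(study_result):
    for cid, net in study_result.networks.items():
        part = walktrap_modules(net)
        assert set(part.assignment.index) == set(net.nodes)
        trivial = nx.community.modularity(net, [set(net.nodes)])
        assert part.modularity >= trivial - 1e-12


def test_planted_partition_graphs_are_recovered():
    """Adjusted Rand index vs the planted 4x20 partition, 20 graphs."""
    from sklearn.metrics import adjusted_rand_score
    scores = []
    for seed in range(20):
        g = nx.planted_partition_graph(4, 20, 0.5, 0.02, seed=seed)
        g = nx.relabel_nodes(g, str)
        part = walktrap_modules(g)
        truth = [int(n) // 20 for n in part.assignment.index]
        scores.append(adjusted_rand_score(truth, part.assignment.to_numpy()))
    assert np.mean(scores) >= 0.9


# ---------------------------------------------------------------------------
# module annotation

def test_module_matching_a_term_exactly_gets_that_label():
    g = nx.Graph()
    genes_a = [f"a{i}" for i in range(6)]
    genes_b = [f"b{i}" for i in range(6)]
    for n in genes_a + genes_b:
        g.add_node(n, type="primary_target")
    g.add_edges_from((u, v) for i, u in enumerate(genes_a) for v in genes_a[i + 1:])
    g.add_edges_from((u, v) for i, u in enumerate(genes_b) for v in genes_b[i + 1:])
    g.add_edge("a0", "b0")
    part = walktrap_modules(g)
    sets = {"setA": set(genes_a), "setB": set(genes_b)}
    table = annotate_modules(g, part, sets, enrich_fdr=0.05)
    labels = set(table["label"])
    assert labels == {"setA", "setB"}


def test_module_without_enrichment_is_labeled_dash():
    g = nx.Graph()
    g.add_edge("x", "y")
    g.nodes["x"]["type"] = g.nodes["y"]["type"] = "primary_target"
    part = walktrap_modules(g)
    table = annotate_modules(g, part, {"t": {"other"}}, enrich_fdr=0.05)
    assert (table["label"] == "-").all()


def test_module_table_counts_nodes_and_edges(study_result):
    for cid, net in study_result.networks.items():
        part = walktrap_modules(net)
        table = module_table(net, part)
        assert table["n_nodes"].sum() == net.number_of_nodes()


# ---------------------------------------------------------------------------
# degree profile

def test_regulator_average_degree_exceeds_target_average(study_result):
    """miRNAs and TFs sit at the high end of the degree distribution when
    motifs share regulators."""
    for cid, net in study_result.networks.items():
        avg = average_degree_by_type(net)
        assert avg["mirna"] > avg["target"]
        assert avg["tf"] > avg["target"]
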