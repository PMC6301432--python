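import math

import networkx as nx
import numpy as np
import pytest

from netpanel.structure import (
    MissingLayerError,
    assemble_graph,
    group_structure_comparison,
    node_metrics,
)

from conftest import toy_dataset
from oracles import brute_force_metrics, random_graph


def test_single_ego_star():
    ds = toy_dataset({"A": {1: {"confidant": ["a", "b", "c", "d", "e"]},
                            2: {"confidant": []}}})
    g = assemble_graph(ds, edge_kinds=("confidant",))
    assert g.number_of_nodes() == 6
    assert g.degree["A"] == 5
    assert all(g.degree[n] == 1 for n in g.nodes if n != "A")


def test_confidant_and_sexual_nominations_stay_separate_nodes_when_unlinked():
    # without cross-kind identity information, the instrument cannot merge
    ds = toy_dataset({"A": {1: {"confidant": ["x"], "sexual": ["x"]}}})
    g = assemble_graph(ds, edge_kinds=("confidant", "sexual"))
    assert g.number_of_nodes() == 3
    assert g.degree["A"] == 2


def test_ground_truth_identity_merges_edge_kinds(sim_small, dataset_small):
    """With true identities, a confidant who is also a sex partner is one
    edge carrying both kinds, and the edge count equals the number of
    unique ground-truth pairs."""
    g = assemble_graph(dataset_small, edge_kinds=("confidant", "sexual"),
                       merge_alters=True)
    truth = sim_small.ground_truth
    em = dict(zip(truth.ego_members["ego_id"], truth.ego_members["member"]))
    node_of = {m: e for e, m in em.items()}
    pairs = set()
    both_kinds = {}
    for r in truth.nomination_members.itertuples(index=False):
        u = r.ego_id
        v = node_of.get(r.member, r.member)
        if u == v:
            continue
        e = tuple(sorted((u, v)))
        pairs.add(e)
        both_kinds.setdefault(e, set()).add(r.kind)
    assert g.number_of_edges() == len(pairs)
    merged = [e for e, kinds in both_kinds.items() if len(kinds) == 2]
    assert merged, "fixture should contain at least one confidant+sexual pair"
    for u, v in merged:
        assert g[u][v]["kinds"] == {"confidant", "sexual"}


def test_rds_layer_requires_recruitment_information():
    ds = toy_dataset({"A": {1: {"confidant": ["a"]}}})
    with pytest.raises(MissingLayerError):
        assemble_graph(ds, edge_kinds=("rds",))
    with pytest.raises(ValueError):
        assemble_graph(ds, edge_kinds=())


def test_wave_filter_restricts_nomination_edges():
    ds = toy_dataset({"A": {1: {"confidant": ["a"]}, 2: {"confidant": ["b"]}}})
    g1 = assemble_graph(ds, edge_kinds=("confidant",), waves=(1,))
    g12 = assemble_graph(ds, edge_kinds=("confidant",))
    assert g1.number_of_edges() == 1
    assert g12.number_of_edges() == 2


def test_path_graph_betweenness_by_hand():
    m = node_metrics(nx.path_graph(3))
    assert m.loc[1, "betweenness"] == pytest.approx(1.0)
    assert m.loc[0, "betweenness"] == 0.0
    assert m.loc[1, "degree"] == 2
    assert m.loc[0, "avg_path_length"] == pytest.approx(1.5)


def test_complete_graph_symmetry():
    m = node_metrics(nx.complete_graph(4))
    assert np.allclose(m["betweenness"], 0.0)
    assert np.allclose(m["closeness"], 1.0)
    assert np.allclose(m["avg_path_length"], 1.0)


def test_isolated_node_flags():
    g = nx.Graph()
    g.add_nodes_from(["i", "u", "v"])
    g.add_edge("u", "v")
    m = node_metrics(g)
    assert m.loc["i", "betweenness"] == 0.0
    assert m.loc["i", "closeness"] == 0.0
    assert math.isnan(m.loc["i", "avg_path_length"])


def test_metrics_match_brute_force_oracle_on_random_graphs():
    rng = np.random.default_rng(2024)
    for _ in range(40):
        nodes, edges = random_graph(rng)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        got = node_metrics(g)
        want = brute_force_metrics(nodes, edges)
        for v in nodes:
            for key in ("degree", "betweenness", "closeness"):
                assert got.loc[v, key] == pytest.approx(want[v][key], abs=1e-9)
            a, b = got.loc[v, "avg_path_length"], want[v]["avg_path_length"]
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, abs=1e-9)


def test_component_correction_never_exceeds_within_component_closeness():
    rng = np.random.default_rng(7)
    for _ in range(20):
        nodes_a, edges_a = random_graph(rng, n_max=5)
        offset = len(nodes_a)
        nodes_b, edges_b = random_graph(rng, n_max=5)
        nodes = nodes_a + [v + offset for v in nodes_b]
        edges = edges_a + [(u + offset, v + offset) for u, v in edges_b]
        whole = brute_force_metrics(nodes, edges)
        part = brute_force_metrics(nodes_a, edges_a)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        got = node_metrics(g)
        for v in nodes_a:
            assert got.loc[v, "closeness"] == pytest.approx(whole[v]["closeness"], abs=1e-12)
            assert got.loc[v, "closeness"] <= part[v]["closeness"] + 1e-12


def test_adding_an_edge_never_decreases_degree():
    rng = np.random.default_rng(3)
    nodes, edges = random_graph(rng)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    before = dict(g.degree())
    missing = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]
               if not g.has_edge(u, v)]
    if missing:
        u, v = missing[0]
        g.add_edge(u, v)
        after = dict(g.degree())
        assert after[u] == before[u] + 1 and after[v] == before[v] + 1
        assert all(after[w] >= before[w] for w in nodes)


def test_group_comparison_hand_means():
    ds = toy_dataset(
        {"A": {1: {"confidant": ["a", "b"]}},
         "B": {1: {"confidant": ["c"]}},
         "C": {1: {"confidant": ["d", "e", "f"]}},
         "D": {1: {"confidant": []}}},
        groups={"A": "TGW", "B": "TGW", "C": "MSM", "D": "MSM"})
    g = assemble_graph(ds, edge_kinds=("confidant",))
    comparison = group_structure_comparison(node_metrics(g), ds.respondents)
    deg = comparison.set_index("metric").loc["degree"]
    assert deg["mean_tgw"] == pytest.approx((2 + 1) / 2)
    assert deg["mean_msm"] == pytest.approx((3 + 0) / 2)
    assert deg["n_tgw"] == 2 and deg["n_msm"] == 2


def test_identical_metric_vectors_are_degenerate_flagged():
    ds = toy_dataset(
        {"A": {1: {"confidant": ["a"]}}, "B": {1: {"confidant": ["b"]}},
         "C": {1: {"confidant": ["c"]}}, "D": {1: {"confidant": ["d"]}}},
        groups={"A": "TGW", "B": "TGW", "C": "MSM", "D": "MSM"})
    g = assemble_graph(ds, edge_kinds=("confidant",))
    comparison = group_structure_comparison(node_metrics(g), ds.respondents)
    assert (comparison["flag"] == "degenerate").all()
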