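"""Topology metrics: hand-computed cases, oracle equivalence, invariants."""

import math
import random

import networkx as nx
import pytest

from pleurosim import generate_graph, to_reaction_graph, topology_report
from pleurosim.netanalysis import (
    DirectedGraph,
    GraphEdge,
    GraphNode,
    betweenness_centrality,
    hub_ranking,
    neighborhood_connectivity_distribution,
    node_metrics,
)


def _graph(edges, nodes=None):
    ids = nodes or sorted({u for e in edges for u in e[:2]})
    return DirectedGraph(
        nodes=[GraphNode(i, "species") for i in ids],
        edges=[GraphEdge(u, v, "link") for u, v in edges],
    )


def test_directed_path_metrics_by_hand():
    rep = topology_report(_graph([("a", "b"), ("b", "c")]))
    assert rep.shortest_path_count == 3
    assert rep.characteristic_path_length == pytest.approx(4 / 3)
    assert rep.diameter == 2
    assert rep.radius == 1
    assert rep.connected_components == 1


def test_triangle_has_unit_clustering():
    edges = [("a", "b"), ("b", "a"), ("b", "c"), ("c", "b"), ("a", "c"), ("c", "a")]
    rep = topology_report(_graph(edges))
    assert rep.clustering_coefficient == pytest.approx(1.0)


def test_star_is_maximally_centralized():
    edges = [("c", f"l{i}") for i in range(4)]
    rep = topology_report(_graph(edges))
    assert rep.centralization == pytest.approx(1.0)
    dist = neighborhood_connectivity_distribution(_graph(edges))
    assert dist == {1: 4.0, 4: 1.0}


def test_empty_graph_reports_absent_path_metrics():
    rep = topology_report(DirectedGraph())
    assert rep.node_count == 0
    assert rep.diameter is None and rep.radius is None
    assert rep.characteristic_path_length is None


def test_edgeless_nodes_form_singleton_components():
    g = generate_graph(5, 0, seed=1)
    assert topology_report(g).connected_components == 5


def test_betweenness_of_path_interior_node():
    bc = betweenness_centrality(_graph([("a", "b"), ("b", "c")]))
    assert bc["b"] > bc["a"] == bc["c"] == 0.0


def test_hub_ranking_path_and_overflow():
    g = _graph([("a", "b"), ("b", "c")])
    assert hub_ranking(g, "betweenness", 1) == ["b"]
    assert len(hub_ranking(g, "betweenness", 10)) == 3
    assert hub_ranking(g, "in_degree", 1) != []
    with pytest.raises(ValueError):
        hub_ranking(g, "betweenness", 0)


def test_regular_ring_has_constant_neighborhood_connectivity():
    n = 8
    edges = [(f"n{i}", f"n{(i + 1) % n}") for i in range(n)]
    dist = neighborhood_connectivity_distribution(_graph(edges))
    assert dist == {2: 2.0}


def test_node_metrics_degrees_sum_to_edge_count(fruiting_graph):
    metrics = node_metrics(fruiting_graph)
    assert sum(m.in_degree for m in metrics.values()) == len(fruiting_graph.edges)
    assert sum(m.out_degree for m in metrics.values()) == len(fruiting_graph.edges)


def _floyd_warshall(graph):
    ids = graph.node_ids
    idx = {u: i for i, u in enumerate(ids)}
    inf = float("inf")
    n = len(ids)
    d = [[inf] * n for _ in range(n)]
    for i in range(n):
        d[i][i] = 0
    for e in graph.edges:
        d[idx[e.source]][idx[e.target]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return ids, d


def _to_nx(graph):
    g = nx.DiGraph()
    g.add_nodes_from(graph.node_ids)
    g.add_edges_from((e.source, e.target) for e in graph.edges)
    return g


@pytest.mark.parametrize("seed", range(100))
def test_metrics_match_bruteforce_and_networkx_on_random_graphs(seed):
    """Every topology metric agrees with a Floyd-Warshall enumeration and
    with networkx on random directed graphs of up to 30 nodes."""
    rng = random.Random(seed)
    n = rng.randint(2, 30)
    bipartite = bool(seed % 3 == 0)
    cap = 2 * (n // 2) * ((n + 1) // 2) if bipartite else n * (n - 1)
    m = rng.randint(0, min(60, cap))
    graph = generate_graph(n, m, seed=seed, bipartite=bipartite)
    rep = topology_report(graph)

    ids, d = _floyd_warshall(graph)
    finite = [d[i][j] for i in range(len(ids)) for j in range(len(ids))
              if i != j and d[i][j] < float("inf")]
    assert rep.shortest_path_count == len(finite)
    if finite:
        assert rep.characteristic_path_length == pytest.approx(sum(finite) / len(finite), abs=1e-9)
        eccs = []
        for i in range(len(ids)):
            reach = [d[i][j] for j in range(len(ids)) if j != i and d[i][j] < float("inf")]
            if reach:
                eccs.append(max(reach))
        assert rep.diameter == max(eccs)
        assert rep.radius == min(eccs)
        # internal consistency: mean * count == total distance
        assert rep.characteristic_path_length * rep.shortest_path_count == pytest.approx(
            sum(finite), abs=1e-6)

    g = _to_nx(graph)
    assert rep.connected_components == nx.number_weakly_connected_components(g)
    assert rep.clustering_coefficient == pytest.approx(
        nx.average_clustering(g.to_undirected()), abs=1e-9)
    if n > 1:
        assert rep.density == pytest.approx(nx.density(g), abs=1e-12)

    ours = betweenness_centrality(graph)
    theirs = nx.betweenness_centrality(g, normalized=n > 2)
    for node in ids:
        assert ours[node] == pytest.approx(theirs[node], abs=1e-9)


def test_bipartite_graphs_have_zero_clustering_and_no_self_loops():
    for seed in range(5):
        g = generate_graph(16, 30, seed=seed, bipartite=True)
        rep = topology_report(g)
        assert rep.clustering_coefficient == 0.0
        assert rep.self_loops == 0


def test_curated_graph_is_bipartite_species_reaction(fruiting_graph):
    kinds = {n.id: n.kind for n in fruiting_graph.nodes}
    for e in fruiting_graph.edges:
        assert kinds[e.source] != kinds[e.target]


def test_single_reaction_converts_to_three_nodes_two_edges(small_synthetic, fruiting_model):
    from pleurosim import Model
    from pleurosim.core import Compartment, CompartmentKind, Reaction, Species, SpeciesRole

    model = Model(
        id="one",
        compartments=[Compartment("fungal_cell", "cell", CompartmentKind.fungal_cell)],
        species=[
            Species("a", "A", SpeciesRole.simple_molecule, "fungal_cell"),
            Species("b", "B", SpeciesRole.simple_molecule, "fungal_cell"),
        ],
        reactions=[Reaction("re1", "a to b", reactants=(("a", 1),), products=(("b", 1),))],
    )
    g = to_reaction_graph(model)
    assert len(g.nodes) == 3
    assert len(g.edges) == 2


def test_modifier_contributes_an_edge_into_the_reaction_node():
    from pleurosim import Model, Modifier, ModifierMode
    from pleurosim.core import Compartment, CompartmentKind, Reaction, Species, SpeciesRole

    model = Model(
        id="cat",
        compartments=[Compartment("fungal_cell", "cell", CompartmentKind.fungal_cell)],
        species=[
            Species("a", "A", SpeciesRole.simple_molecule, "fungal_cell"),
            Species("b", "B", SpeciesRole.simple_molecule, "fungal_cell"),
            Species("e", "E", SpeciesRole.protein, "fungal_cell"),
        ],
        reactions=[Reaction("re1", "a to b", reactants=(("a", 1),), products=(("b", 1),),
                            modifiers=(Modifier("e", ModifierMode.catalyst),))],
    )
    g = to_reaction_graph(model)
    assert GraphEdge("e", "re1", "modifier") in g.edges
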