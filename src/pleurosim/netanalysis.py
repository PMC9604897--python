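"""Directed bipartite species-reaction graphs and topology statistics.

A kinetic model maps onto a directed bipartite graph: one node per
reaction, one node per species that participates in at least one reaction,
and edges reactant->reaction, reaction->product and modifier->reaction.
This is the graph a pathway-analysis tool derives from an SBML file, and
the topology suite below reproduces the standard "simple parameters"
panel: node/edge counts, weakly connected components, mean clustering
coefficient, directed diameter/radius, the count of reachable ordered
pairs, characteristic path length, average neighbor count, density,
degree heterogeneity, degree centralization and self-loop count.

Conventions (chosen to match the behavior of the usual network-analyzer
tooling, and asserted against independent oracles in the test suite):

* path metrics (diameter, radius, characteristic path length, shortest
  path count) follow *directed* edges;
* components, clustering, neighborhood connectivity, heterogeneity and
  centralization use the underlying *undirected* adjacency;
* radius is the minimum eccentricity over nodes that reach at least one
  other node, so a source feeding a single sink attains radius 1;
* betweenness accumulates shortest-path counts as exact rationals.

Everything here is implemented from first principles (BFS, Brandes); no
graph library is used at run time.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Literal, Optional

from .core import Model, require_valid


@dataclass(frozen=True)
class GraphNode:
    id: str
    kind: str  # "species" or "reaction"
    label: str = ""


@dataclass(frozen=True)
class GraphEdge:
    source: str
    target: str
    kind: str  # "reactant", "product" or "modifier"


@dataclass
class DirectedGraph:
    nodes: list[GraphNode] = field(default_factory=list)
    edges: list[GraphEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate node ids")
        seen = set()
        for e in self.edges:
            if (e.source, e.target) in seen:
                raise ValueError(f"duplicate edge {e.source}->{e.target}")
            seen.add((e.source, e.target))

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def successors(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {n.id: [] for n in self.nodes}
        for e in self.edges:
            adj[e.source].append(e.target)
        return adj

    def predecessors(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {n.id: [] for n in self.nodes}
        for e in self.edges:
            adj[e.target].append(e.source)
        return adj

    def undirected_neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n.id: set() for n in self.nodes}
        for e in self.edges:
            if e.source != e.target:
                adj[e.source].add(e.target)
                adj[e.target].add(e.source)
        return adj


def is_bipartite_species_reaction(graph: DirectedGraph) -> bool:
    """True when every edge joins a species node and a reaction node."""
    kind = {n.id: n.kind for n in graph.nodes}
    return all(kind[e.source] != kind[e.target] for e in graph.edges)


def to_reaction_graph(model: Model) -> DirectedGraph:
    """Derive the directed bipartite species-reaction graph of a model.

    Species that participate in no reaction (neither reactant, product nor
    modifier) are dropped, matching how pathway exports omit unconnected
    elements.  Node order follows model order (species first), so the
    conversion is deterministic.
    """
    require_valid(model)
    used: set[str] = set()
    for r in model.reactions:
        used.update(r.reactant_ids())
        used.update(r.product_ids())
        used.update(r.modifier_ids())

    nodes = [GraphNode(s.id, "species", s.name) for s in model.species if s.id in used]
    nodes += [GraphNode(r.id, "reaction", r.name) for r in model.reactions]

    edges: list[GraphEdge] = []
    seen: set[tuple[str, str]] = set()

    def add(src: str, dst: str, kind: str) -> None:
        if (src, dst) not in seen:
            seen.add((src, dst))
            edges.append(GraphEdge(src, dst, kind))

    for r in model.reactions:
        for sid in r.reactant_ids():
            add(sid, r.id, "reactant")
        for sid in r.product_ids():
            add(r.id, sid, "product")
        for m in r.modifiers:
            add(m.species, r.id, "modifier")

    return DirectedGraph(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# shortest paths (directed BFS; unit edge weights)
# ---------------------------------------------------------------------------

def _bfs_distances(start: str, succ: dict[str, list[str]]) -> dict[str, int]:
    dist = {start: 0}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in succ[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_pairs_directed_distances(graph: DirectedGraph) -> dict[str, dict[str, int]]:
    succ = graph.successors()
    return {u: _bfs_distances(u, succ) for u in graph.node_ids}


def weakly_connected_components(graph: DirectedGraph) -> list[set[str]]:
    adj = graph.undirected_neighbors()
    seen: set[str] = set()
    comps: list[set[str]] = []
    for start in graph.node_ids:
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        seen.add(start)
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.add(v)
                    queue.append(v)
        comps.append(comp)
    return comps


def mean_clustering_coefficient(graph: DirectedGraph) -> Optional[float]:
    """Mean local clustering coefficient over the undirected skeleton.

    Nodes of degree < 2 contribute 0.  Bipartite graphs contain no
    triangles, so their mean coefficient is exactly 0.
    """
    if not graph.nodes:
        return None
    adj = graph.undirected_neighbors()
    total = 0.0
    for u in graph.node_ids:
        nbrs = adj[u]
        k = len(nbrs)
        if k < 2:
            continue
        links = 0
        for v in nbrs:
            links += sum(1 for w in adj[v] if w in nbrs)
        total += links / (k * (k - 1))  # each link counted once per direction
    return total / len(graph.nodes)


@dataclass(frozen=True)
class TopologyReport:
    """The "simple topology parameters" panel for one directed graph.

    Counts are exact integers; real-valued fields are unrounded (use
    :meth:`rounded` for the 2-decimal presentation used in comparisons).
    Path metrics are ``None`` when no node reaches any other.
    """

    node_count: int
    edge_count: int
    connected_components: int
    clustering_coefficient: Optional[float]
    diameter: Optional[int]
    radius: Optional[int]
    shortest_path_count: int
    characteristic_path_length: Optional[float]
    avg_neighbors: Optional[float]
    density: Optional[float]
    heterogeneity: Optional[float]
    centralization: Optional[float]
    self_loops: int

    def rounded(self) -> dict[str, Optional[float]]:
        """Presentation values: reals rounded half-up to 2 decimals."""
        def r2(x: Optional[float]) -> Optional[float]:
            if x is None:
                return None
            return math.floor(x * 100 + 0.5) / 100

        d = {
            "node_count": self.node_count,
            "edge_count": self.edge_count,
            "connected_components": self.connected_components,
            "clustering_coefficient": r2(self.clustering_coefficient),
            "diameter": self.diameter,
            "radius": self.radius,
            "shortest_path_count": self.shortest_path_count,
            "characteristic_path_length": r2(self.characteristic_path_length),
            "avg_neighbors": r2(self.avg_neighbors),
            "density": r2(self.density),
            "heterogeneity": r2(self.heterogeneity),
            "centralization": r2(self.centralization),
            "self_loops": self.self_loops,
        }
        return d


def topology_report(graph: DirectedGraph) -> TopologyReport:
    n = len(graph.nodes)
    m = len(graph.edges)
    self_loops = sum(1 for e in graph.edges if e.source == e.target)

    if n == 0:
        return TopologyReport(0, 0, 0, None, None, None, 0, None, None, None, None, None, 0)

    comps = weakly_connected_components(graph)

    dists = all_pairs_directed_distances(graph)
    finite: list[int] = []
    eccentricities: list[int] = []
    for u, du in dists.items():
        reach = [d for v, d in du.items() if v != u]
        finite.extend(reach)
        if reach:
            eccentricities.append(max(reach))

    pair_count = len(finite)
    diameter = max(eccentricities) if eccentricities else None
    radius = min(eccentricities) if eccentricities else None
    cpl = (sum(finite) / pair_count) if pair_count else None

    adj = graph.undirected_neighbors()
    degrees = [len(adj[u]) for u in graph.node_ids]
    undirected_edges = sum(degrees) // 2
    avg_neighbors = 2.0 * undirected_edges / n
    density = m / (n * (n - 1)) if n > 1 else None

    mean_deg = sum(degrees) / n
    heterogeneity = None
    if mean_deg > 0:
        var = sum((k - mean_deg) ** 2 for k in degrees) / n
        heterogeneity = math.sqrt(var) / mean_deg

    centralization = None
    if n > 2:
        kmax = max(degrees)
        centralization = sum(kmax - k for k in degrees) / ((n - 1) * (n - 2))

    return TopologyReport(
        node_count=n,
        edge_count=m,
        connected_components=len(comps),
        clustering_coefficient=mean_clustering_coefficient(graph),
        diameter=diameter,
        radius=radius,
        shortest_path_count=pair_count,
        characteristic_path_length=cpl,
        avg_neighbors=avg_neighbors,
        density=density,
        heterogeneity=heterogeneity,
        centralization=centralization,
        self_loops=self_loops,
    )


# ---------------------------------------------------------------------------
# per-node metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeMetrics:
    node: str
    in_degree: int
    out_degree: int
    betweenness: float
    neighborhood_connectivity: Optional[float]
    eccentricity: Optional[int]


def betweenness_centrality(graph: DirectedGraph, normalized: bool = True) -> dict[str, float]:
    """Directed betweenness via Brandes' algorithm.

    Shortest-path counts and dependency accumulation use exact rationals,
    so equal-count ties split without floating-point drift; the result is
    converted to float at the end.  Normalization divides by
    ``(n-1)(n-2)``, the number of ordered source/target pairs excluding
    the node itself.
    """
    succ = graph.successors()
    ids = graph.node_ids
    bc: dict[str, Fraction] = {v: Fraction(0) for v in ids}

    for s in ids:
        # single-source shortest paths with path counting
        dist: dict[str, int] = {s: 0}
        sigma: dict[str, Fraction] = {v: Fraction(0) for v in ids}
        sigma[s] = Fraction(1)
        preds: dict[str, list[str]] = {v: [] for v in ids}
        order: list[str] = []
        queue = deque([s])
        while queue:
            u = queue.popleft()
            order.append(u)
            for v in succ[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta: dict[str, Fraction] = {v: Fraction(0) for v in ids}
        for w in reversed(order):
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1 + delta[w])
            if w != s:
                bc[w] += delta[w]

    n = len(ids)
    scale = Fraction(1)
    if normalized and n > 2:
        scale = Fraction(1, (n - 1) * (n - 2))
    return {v: float(bc[v] * scale) for v in ids}


def node_metrics(graph: DirectedGraph) -> dict[str, NodeMetrics]:
    succ = graph.successors()
    pred = graph.predecessors()
    adj = graph.undirected_neighbors()
    bc = betweenness_centrality(graph)
    dists = all_pairs_directed_distances(graph)

    out: dict[str, NodeMetrics] = {}
    for u in graph.node_ids:
        nbrs = adj[u]
        ncon = sum(len(adj[v]) for v in nbrs) / len(nbrs) if nbrs else None
        reach = [d for v, d in dists[u].items() if v != u]
        out[u] = NodeMetrics(
            node=u,
            in_degree=len(pred[u]),
            out_degree=len(succ[u]),
            betweenness=bc[u],
            neighborhood_connectivity=ncon,
            eccentricity=max(reach) if reach else None,
        )
    return out


def neighborhood_connectivity_distribution(graph: DirectedGraph) -> dict[int, float]:
    """Mean neighborhood connectivity per observed undirected degree k.

    For each node, neighborhood connectivity is the mean undirected degree
    of its neighbors; nodes are then grouped by their own degree and
    averaged.  Isolated nodes (k=0) are omitted.
    """
    adj = graph.undirected_neighbors()
    by_k: dict[int, list[float]] = {}
    for u in graph.node_ids:
        nbrs = adj[u]
        if not nbrs:
            continue
        val = sum(len(adj[v]) for v in nbrs) / len(nbrs)
        by_k.setdefault(len(nbrs), []).append(val)
    return {k: sum(vals) / len(vals) for k, vals in sorted(by_k.items())}


def hub_ranking(
    graph: DirectedGraph,
    metric: Literal["in_degree", "betweenness"] = "betweenness",
    k: int = 10,
    kind: Optional[str] = None,
) -> list[str]:
    """Top-k node ids by a centrality metric; ties break lexicographically.

    ``kind`` optionally restricts the ranking to species or reaction nodes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if metric == "in_degree":
        pred = graph.predecessors()
        score = {u: float(len(pred[u])) for u in graph.node_ids}
    elif metric == "betweenness":
        score = betweenness_centrality(graph)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    pool = [n.id for n in graph.nodes if kind is None or n.kind == kind]
    pool.sort(key=lambda u: (-score[u], u))
    return pool[:k]
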