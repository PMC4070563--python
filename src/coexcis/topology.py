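"""Topological battery for co-expression networks.

Degree distribution and log-log power-law fit, clustering coefficients,
shortest-path metrics, betweenness and closeness centralities, shared-
neighbour statistics, neighbourhood connectivity, topological coefficients,
connected components, density, hubs, and list overlap.

Conventions: closeness is component-restricted (reachable nodes only);
betweenness is Brandes' unordered-pair count, optionally normalised by
(n-1)(n-2)/2; the topological coefficient follows the visualisation-tool
definition, T(n) = mean over partners m sharing >= 1 neighbour of
J(n, m) / deg(n) with J = |shared neighbours| (+1 when n and m are adjacent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import networkx as nx


@dataclass
class TopologyReport:
    """Bundle of per-node tables, distributions and summaries for one graph."""

    degree: dict[str, int]
    clustering: dict[str, float]
    closeness: dict[str, float]
    betweenness: dict[str, float]
    topological_coefficient: dict[str, float]
    neighborhood_connectivity: dict[str, float]
    degree_dist: dict[int, int]
    path_length_dist: dict[int, int]
    shared_neighbor_dist: dict[int, int]
    component_summary: dict
    density: float
    density_ordered_pairs: float
    powerlaw: tuple | None = None


def degree_distribution(net: nx.Graph) -> dict[int, int]:
    """Exact histogram: degree -> number of nodes with that degree."""
    dist: dict[int, int] = {}
    for _, d in net.degree():
        dist[d] = dist.get(d, 0) + 1
    return dict(sorted(dist.items()))


def powerlaw_fit(dist: dict[int, int], min_degree: int = 1) -> tuple[float, float, float]:
    """OLS fit of log10(frequency) on log10(degree) over degrees >= min_degree.

    Returns (exponent, intercept, r_squared) with the exponent reported as the
    negated slope, so a d^-2 law gives exponent 2.
    """
    pts = [(d, f) for d, f in dist.items() if d >= min_degree and d > 0 and f > 0]
    if len(pts) < 3:
        raise ValueError("need at least 3 distinct degrees with nonzero frequency")
    x = np.log10([d for d, _ in pts])
    y = np.log10([f for _, f in pts])
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-slope), float(intercept), r2


def clustering_by_degree(net: nx.Graph) -> tuple[dict[str, float], dict[int, float]]:
    """Per-node clustering coefficients and the mean-coefficient-by-degree curve."""
    coeffs = nx.clustering(net)
    by_degree: dict[int, list[float]] = {}
    for node, c in coeffs.items():
        by_degree.setdefault(net.degree(node), []).append(c)
    curve = {d: float(np.mean(cs)) for d, cs in sorted(by_degree.items())}
    return dict(coeffs), curve


def path_metrics(net: nx.Graph) -> tuple[dict[int, int], dict[str, float]]:
    """Shortest-path length distribution and component-restricted closeness.

    The distribution counts ordered pairs of distinct, mutually reachable
    nodes.  closeness(n) = (number reachable from n) / (sum of distances).
    """
    dist: dict[int, int] = {}
    closeness: dict[str, float] = {}
    for node in net.nodes:
        lengths = nx.single_source_shortest_path_length(net, node)
        total = 0
        reachable = 0
        for other, d in lengths.items():
            if other == node:
                continue
            dist[d] = dist.get(d, 0) + 1
            total += d
            reachable += 1
        closeness[node] = reachable / total if total > 0 else 0.0
    return dict(sorted(dist.items())), closeness


def betweenness_all(net: nx.Graph, normalized: bool = False) -> dict[str, float]:
    """Brandes betweenness; raw counts unordered pairs, normalised divides by
    (n-1)(n-2)/2."""
    return dict(nx.betweenness_centrality(net, normalized=normalized))


def neighborhood_stats(
    net: nx.Graph,
) -> tuple[dict[int, int], dict[str, float], dict[str, float]]:
    """Shared-neighbour distribution, neighbourhood connectivity, topological
    coefficients.

    The shared-neighbour distribution counts unordered node pairs by
    |N(u) & N(v)| (pairs sharing at least one neighbour).
    """
    neigh = {n: set(net.neighbors(n)) for n in net.nodes}
    shared_dist: dict[int, int] = {}
    for u, v in combinations(net.nodes, 2):
        s = len(neigh[u] & neigh[v])
        if s > 0:
            shared_dist[s] = shared_dist.get(s, 0) + 1
    conn = {
        n: (float(np.mean([net.degree(m) for m in neigh[n]])) if neigh[n] else 0.0)
        for n in net.nodes
    }
    tc: dict[str, float] = {}
    for n in net.nodes:
        deg = net.degree(n)
        if deg == 0:
            tc[n] = 0.0
            continue
        ratios = []
        for m in net.nodes:
            if m == n:
                continue
            shared = len(neigh[n] & neigh[m])
            if shared == 0:
                continue
            j = shared + (1 if net.has_edge(n, m) else 0)
            ratios.append(j / deg)
        tc[n] = float(np.mean(ratios)) if ratios else 0.0
    return dict(sorted(shared_dist.items())), conn, tc


def components(net: nx.Graph, member_threshold: int = 6) -> dict:
    """Connected-component summary, sizes descending.

    Reports the total component count, the count with >= member_threshold
    nodes, all sizes, and the main (largest) component's node and edge counts
    with its edge share of the whole graph.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), sorted(c)[0]))
    sizes = [len(c) for c in comps]
    main = net.subgraph(comps[0])
    total_edges = net.number_of_edges()
    return {
        "n_components": len(comps),
        "n_components_at_threshold": sum(1 for s in sizes if s >= member_threshold),
        "member_threshold": member_threshold,
        "sizes": sizes,
        "main_component_nodes": main.number_of_nodes(),
        "main_component_edges": main.number_of_edges(),
        "main_component_edge_share": (
            main.number_of_edges() / total_edges if total_edges else 0.0
        ),
    }


def main_component(net: nx.Graph) -> nx.Graph:
    """Largest connected component as an independent graph."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), sorted(c)[0]))
    return net.subgraph(comps[0]).copy()


def density(net: nx.Graph) -> tuple[float, float]:
    """(undirected density 2E/(n(n-1)), ordered-pair density E/(n(n-1))).

    The second value treats the edge count as ordered pairs; dense-subnetwork
    statistics in some tools print the ordered-pair convention.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    e = net.number_of_edges()
    return 2.0 * e / (n * (n - 1)), e / (n * (n - 1))


def hubs(net: nx.Graph, min_degree: int = 50) -> list[str]:
    """Nodes with degree >= min_degree (inclusive), sorted by ID."""
    return sorted(n for n, d in net.degree() if d >= min_degree)


def top_betweenness(net: nx.Graph, n: int = 90, normalized: bool = False) -> list[str]:
    """The n highest-betweenness nodes; all nodes tied at the cut-off value
    are included, with lexicographic ordering inside ties."""
    bc = betweenness_all(net, normalized=normalized)
    ranked = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) <= n:
        return [node for node, _ in ranked]
    cutoff = ranked[n - 1][1]
    return [node for node, v in ranked if v >= cutoff]


def overlap_with_list(genes, reference) -> dict:
    """Intersection of a gene list with a reference list, with counts."""
    g, r = set(genes), set(reference)
    inter = g & r
    return {
        "overlap": sorted(inter),
        "n_overlap": len(inter),
        "n_genes": len(g),
        "n_reference": len(r),
    }


def topology_report(net: nx.Graph, member_threshold: int = 6) -> TopologyReport:
    """Run the full battery on one graph."""
    deg = dict(net.degree())
    coeffs, _curve = clustering_by_degree(net)
    pl_dist, closeness = path_metrics(net)
    bc = betweenness_all(net, normalized=True)
    shared, conn, tc = neighborhood_stats(net)
    comp = components(net, member_threshold)
    dens = density(net) if net.number_of_nodes() >= 2 else (0.0, 0.0)
    ddist = degree_distribution(net)
    try:
        pl = powerlaw_fit(ddist)
    except ValueError:
        pl = None
    return TopologyReport(
        degree=deg,
        clustering=coeffs,
        closeness=closeness,
        betweenness=bc,
        topological_coefficient=tc,
        neighborhood_connectivity=conn,
        degree_dist=ddist,
        path_length_dist=pl_dist,
        shared_neighbor_dist=shared,
        component_summary=comp,
        density=dens[0],
        density_ordered_pairs=dens[1],
        powerlaw=pl,
    )
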