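"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles (plain loops, no
networkx, no package code) so it can stand as an independent reference for
the metrics and constructions under test.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


# --- graph helpers (adjacency as dict node -> set of neighbours) -----------


def adjacency(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bf_degree(adj):
    return {n: len(adj[n]) for n in adj}


def bf_clustering(adj):
    out = {}
    for n, nb in adj.items():
        d = len(nb)
        if d < 2:
            out[n] = 0.0
            continue
        links = sum(1 for a, b in combinations(sorted(nb), 2) if b in adj[a])
        out[n] = 2.0 * links / (d * (d - 1))
    return out


def bf_distances(adj, source):
    """BFS distances by hand."""
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def bf_path_length_distribution(adj):
    dist = {}
    for s in adj:
        for t, d in bf_distances(adj, s).items():
            if t != s:
                dist[d] = dist.get(d, 0) + 1
    return dist


def bf_closeness(adj):
    out = {}
    for n in adj:
        d = bf_distances(adj, n)
        total = sum(v for k, v in d.items() if k != n)
        reach = len(d) - 1
        out[n] = reach / total if total > 0 else 0.0
    return out


def bf_all_shortest_paths(adj, s, t):
    """Enumerate every shortest s-t path (list of node lists)."""
    dist = bf_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(path)
            return
        for nb in adj[node]:
            if dist.get(nb) == dist[node] + 1 and dist.get(nb, 1e9) <= dist[t]:
                walk(nb, path + [nb])

    walk(s, [s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def bf_betweenness(adj, normalized=False):
    """Fraction-of-shortest-paths betweenness summed over unordered pairs."""
    nodes = sorted(adj)
    out = {n: 0.0 for n in nodes}
    for s, t in combinations(nodes, 2):
        paths = bf_all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for n in nodes:
            if n in (s, t):
                continue
            through = sum(1 for p in paths if n in p)
            out[n] += through / len(paths)
    if normalized:
        n = len(nodes)
        denom = (n - 1) * (n - 2) / 2
        if denom > 0:
            out = {k: v / denom for k, v in out.items()}
    return out


def bf_shared_neighbor_distribution(adj):
    dist = {}
    for u, v in combinations(sorted(adj), 2):
        s = len(adj[u] & adj[v])
        if s > 0:
            dist[s] = dist.get(s, 0) + 1
    return dist


def bf_neighborhood_connectivity(adj):
    return {
        n: (sum(len(adj[m]) for m in adj[n]) / len(adj[n]) if adj[n] else 0.0)
        for n in adj
    }


def bf_topological_coefficient(adj):
    out = {}
    for n in adj:
        deg = len(adj[n])
        if deg == 0:
            out[n] = 0.0
            continue
        ratios = []
        for m in adj:
            if m == n:
                continue
            shared = len(adj[n] & adj[m])
            if shared == 0:
                continue
            ratios.append((shared + (1 if m in adj[n] else 0)) / deg)
        out[n] = sum(ratios) / len(ratios) if ratios else 0.0
    return out


def bf_components(adj):
    seen = set()
    comps = []
    for n in sorted(adj):
        if n in seen:
            continue
        comp = set(bf_distances(adj, n))
        comps.append(comp)
        seen |= comp
    return sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))


def bf_edge_clustering_coefficient(adj):
    out = {}
    for u in adj:
        for v in adj[u]:
            if u < v:
                denom = min(len(adj[u]) - 1, len(adj[v]) - 1)
                z = len(adj[u] & adj[v])
                out[(u, v)] = 0.0 if denom <= 0 else (z + 1) / denom
    return out


# --- matrix-side oracles ----------------------------------------------------


def bf_pearson(x, y):
    """Direct formula: sum((x-xbar)(y-ybar)) / (n sx sy), population sd."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xb, yb = x.mean(), y.mean()
    sx = np.sqrt(((x - xb) ** 2).mean())
    sy = np.sqrt(((y - yb) ** 2).mean())
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - xb) * (y - yb)).mean() / (sx * sy))


def bf_aracne(weights, mode, tol):
    """Triple-scan DPI by explicit loops."""
    w = np.array(weights, dtype=float)
    n = w.shape[0]
    remove = np.zeros_like(w, dtype=bool)
    for i, j, k in permutations(range(n), 3):
        if i < j:
            bound = min(w[i, k], w[j, k])
            if mode == "additive":
                if w[i, j] < bound - tol:
                    remove[i, j] = remove[j, i] = True
            else:
                if w[i, j] < tol * bound:
                    remove[i, j] = remove[j, i] = True
    out = w.copy()
    out[remove] = 0.0
    return out


def bf_clr(weights):
    w = np.array(weights, dtype=float)
    n = w.shape[0]
    z = np.zeros((n, n))
    for i in range(n):
        row = [w[i, j] for j in range(n) if j != i]
        mu = np.mean(row)
        sd = np.std(row)
        for j in range(n):
            if j != i and sd > 0:
                z[i, j] = max(0.0, (w[i, j] - mu) / sd)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = np.sqrt(z[i, j] ** 2 + z[j, i] ** 2)
    return out


def bf_mrnet(weights):
    w = np.array(weights, dtype=float)
    n = w.shape[0]
    out = np.zeros((n, n))
    for y in range(n):
        selected = []
        remaining = [x for x in range(n) if x != y]
        while remaining:
            scores = {}
            for x in remaining:
                red = np.mean([w[x, k] for k in selected]) if selected else 0.0
                scores[x] = w[x, y] - red
            best = min([x for x in remaining if scores[x] == max(scores.values())])
            if scores[best] <= 0:
                break
            out[y, best] = max(out[y, best], scores[best])
            selected.append(best)
            remaining.remove(best)
    return np.maximum(out, out.T)


def rand_index(labels_a, labels_b, items):
    """Plain Rand index over unordered item pairs."""
    agree = total = 0
    for u, v in combinations(sorted(items), 2):
        same_a = labels_a[u] == labels_a[v]
        same_b = labels_b[u] == labels_b[v]
        agree += 1 if same_a == same_b else 0
        total += 1
    return agree / total if total else 1.0
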