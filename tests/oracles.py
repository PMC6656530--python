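"""Independent brute-force oracles used by the test suite.

Deliberately avoids networkx and the package's own code: shortest paths by
breadth-first search over adjacency dicts, clustering by explicit triangle
and triplet counting.
"""

from collections import deque
from itertools import combinations


def adjacency(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def components(adj):
    seen = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(comp)
    return comps


def bfs_distances(adj, source, within):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v in within and v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def brute_force_measures(nodes, edges):
    """Reference values for the standard network measures.

    Diameter and average shortest-path length are over the largest connected
    component; clustering is 3 * triangles / connected triplets.  Returns
    None entries where a measure is undefined.
    """
    nodes = list(nodes)
    edges = [tuple(sorted(e)) for e in edges]
    edges = sorted(set(edges))
    n = len(nodes)
    m = len(edges)
    adj = adjacency(nodes, edges)
    degs = {u: len(adj[u]) for u in nodes}
    largest = max(components(adj), key=len)
    if len(largest) >= 2:
        dsum = 0
        dmax = 0
        npairs = 0
        for u in largest:
            dist = bfs_distances(adj, u, largest)
            for v in largest:
                if v != u:
                    dsum += dist[v]
                    dmax = max(dmax, dist[v])
                    npairs += 1
        diameter = float(dmax)
        aspl = dsum / npairs
    else:
        diameter = None
        aspl = None
    triangles = 0
    for u, v, w in combinations(nodes, 3):
        if v in adj[u] and w in adj[u] and w in adj[v]:
            triangles += 1
    triplets = sum(d * (d - 1) // 2 for d in degs.values())
    clustering = 3.0 * triangles / triplets if triplets > 0 else 0.0
    degree_list = sorted(degs.values())
    mid = n // 2
    if n % 2:
        median_degree = float(degree_list[mid])
    else:
        median_degree = (degree_list[mid - 1] + degree_list[mid]) / 2.0
    return {
        "n_nodes": n,
        "n_edges": m,
        "density": 2.0 * m / (n * (n - 1)) if n > 1 else None,
        "diameter": diameter,
        "aspl": aspl,
        "mean_degree": 2.0 * m / n,
        "median_degree": median_degree,
        "clustering": clustering,
    }


def all_graphs(labels):
    """Yield (edges tuple) for every labelled graph on the given nodes."""
    pairs = list(combinations(sorted(labels), 2))
    for mask in range(2 ** len(pairs)):
        yield tuple(p for b, p in enumerate(pairs) if mask >> b & 1)
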