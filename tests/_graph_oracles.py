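"""Independent reference computations for graph metrics.

Betweenness and clustering come from python-igraph; efficiencies are
computed from scipy shortest-path distances; modularity is evaluated by
the definition Q = Σ_c (e_c/m − (d_c/2m)²).  None of these touch networkx,
so they are an independent route from the package implementation.
"""

import igraph as ig
import numpy as np
from scipy.sparse.csgraph import shortest_path


def ig_graph(adj: np.ndarray) -> "ig.Graph":
    return ig.Graph.Adjacency((adj > 0).tolist(), mode="undirected")


def betweenness(adj, normalized=True):
    g = ig_graph(adj)
    b = np.array(g.betweenness())
    n = adj.shape[0]
    if normalized and n > 2:
        b = b * 2.0 / ((n - 1) * (n - 2))
    return b


def clustering(adj):
    g = ig_graph(adj)
    c = np.array(g.transitivity_local_undirected(mode="zero"))
    return c


def efficiency_from_distances(dist):
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(dist)] = 0.0
    n = dist.shape[0]
    return inv.sum() / (n * (n - 1)) if n > 1 else 0.0


def global_efficiency(adj):
    dist = shortest_path(adj, method="D", unweighted=True)
    return efficiency_from_distances(dist)


def local_efficiency(adj):
    n = adj.shape[0]
    vals = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(adj[v] > 0)
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals[v] = global_efficiency(sub)
    return vals


def modularity_value(adj, communities):
    """Q from its definition, for a given partition (list of node sets)."""
    m = adj.sum() / 2.0
    if m == 0:
        return 0.0
    q = 0.0
    for comm in communities:
        comm = list(comm)
        sub = adj[np.ix_(comm, comm)]
        e_c = sub.sum() / 2.0
        d_c = adj[comm].sum()
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q
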