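"""Directed weighted social networks and their metrics.

Networks are built from dyadic interaction-count matrices: an edge i -> j
exists when animal i directed at least one event of the category at animal
j, and carries the occurrence count as weight.  Global structure is
summarized by density, average path length and out-degree centralization;
individual roles by in/out-degree, betweenness, closeness, Bonacich power
and hub centrality.  Following the convention that density is "the
proportion of possible ties", the global and path-based metrics use binary
tie existence; weights enter only the hub/authority iteration (and the
optional weighted modes).
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .events import DyadMatrix


def to_digraph(m: DyadMatrix) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(m.animals)
    n = len(m.animals)
    for i in range(n):
        for j in range(n):
            if m.counts[i, j] > 0:
                g.add_edge(m.animals[i], m.animals[j], weight=int(m.counts[i, j]))
    return g


def _require_n2(g: nx.DiGraph) -> int:
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("network metrics need at least 2 nodes")
    return n


def network_density(g: nx.DiGraph) -> float:
    """Distinct directed ties / n(n-1)."""
    n = _require_n2(g)
    return g.number_of_edges() / (n * (n - 1))


def average_path_length(g: nx.DiGraph) -> float:
    """Mean unweighted shortest-path length over reachable ordered pairs.

    NaN when no ordered pair is reachable (edgeless network).
    """
    _require_n2(g)
    lengths = []
    for source, dists in nx.all_pairs_shortest_path_length(g):
        lengths.extend(d for t, d in dists.items() if t != source)
    return float(np.mean(lengths)) if lengths else float("nan")


def outdegree_centralization(g: nx.DiGraph) -> float:
    """Freeman centralization of binary out-degree for a digraph.

    sum_i (max_outdeg - outdeg_i) / (n-1)^2 : 0 for equal out-degrees,
    1 for a single node initiating toward everyone else with no other ties.
    """
    n = _require_n2(g)
    deg = np.array([d for _, d in g.out_degree()])
    return float((deg.max() - deg).sum() / (n - 1) ** 2)


def bonacich_power(
    g: nx.DiGraph, beta: float | None = None, normalized: bool = True
) -> dict:
    """Bonacich power centrality on the binary adjacency.

    c(alpha, beta) = alpha (I - beta A)^{-1} A 1, with alpha scaled so that
    sum(c^2) = n.  beta defaults to 0.9 / lambda_max of the binary
    adjacency (positive attenuation: power accrues from connections to
    nodes that are themselves connected).
    """
    nodes = list(g.nodes)
    n = _require_n2(g)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    if beta is None:
        lam = np.max(np.abs(np.linalg.eigvals(a))) if a.any() else 0.0
        beta = 0.9 / lam if lam > 0 else 0.0
    c = np.linalg.solve(np.eye(n) - beta * a, a @ np.ones(n))
    if normalized:
        norm = np.sqrt((c**2).sum())
        if norm > 0:
            c = c * np.sqrt(n) / norm
    return dict(zip(nodes, c))


def hub_centrality(
    g: nx.DiGraph, tol: float = 1e-10, max_iter: int = 10_000
) -> dict:
    """Hub scores of the mutually reinforcing hub/authority iteration.

    Runs on the weighted adjacency and is invariant to weight rescaling;
    scores are normalized to max 1.  An edgeless network gets all zeros.
    """
    nodes = list(g.nodes)
    _require_n2(g)
    if g.number_of_edges() == 0:
        return {v: 0.0 for v in nodes}
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    h = np.ones(len(nodes))
    for _ in range(max_iter):
        auth = a.T @ h
        if auth.max() > 0:
            auth = auth / auth.max()
        h_new = a @ auth
        if h_new.max() > 0:
            h_new = h_new / h_new.max()
        if np.abs(h_new - h).max() < tol:
            h = h_new
            break
        h = h_new
    else:
        raise RuntimeError("hub/authority iteration did not converge")
    return dict(zip(nodes, h))


def node_metrics(g: nx.DiGraph) -> pd.DataFrame:
    """Per-node metric table: degrees, betweenness, closeness, Bonacich
    power, hub centrality.

    Betweenness and closeness use the directed unweighted graph.
    Closeness of node v is computed on outgoing distances over the nodes v
    reaches: (r / (n-1)) * (r / sum of distances), with r the number of
    reached nodes (unreachable pairs are excluded, then scaled by the
    reached fraction); 0 when v reaches nobody.
    """
    nodes = list(g.nodes)
    n = _require_n2(g)
    betw = nx.betweenness_centrality(g, normalized=False)
    closeness = {}
    for v in nodes:
        dists = nx.single_source_shortest_path_length(g, v)
        dists.pop(v, None)
        r = len(dists)
        closeness[v] = (
            (r / (n - 1)) * (r / sum(dists.values())) if r else 0.0
        )
    power = bonacich_power(g)
    hubs = hub_centrality(g)
    return pd.DataFrame(
        {
            "in_degree": [g.in_degree(v) for v in nodes],
            "out_degree": [g.out_degree(v) for v in nodes],
            "betweenness": [betw[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "bonacich_power": [power[v] for v in nodes],
            "hub_centrality": [hubs[v] for v in nodes],
        },
        index=pd.Index(nodes, name="animal"),
    )


def global_metrics(g: nx.DiGraph) -> dict:
    return {
        "density": network_density(g),
        "average_path_length": average_path_length(g),
        "outdegree_centralization": outdegree_centralization(g),
    }


def write_edge_list(m: DyadMatrix, path) -> None:
    rows = []
    n = len(m.animals)
    for i in range(n):
        for j in range(n):
            if m.counts[i, j] > 0:
                rows.append((m.animals[i], m.animals[j], int(m.counts[i, j])))
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, index=False
    )
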