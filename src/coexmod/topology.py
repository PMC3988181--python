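"""Topology diagnostics for the thresholded co-expression network.

Summaries that characterize whether the network behaves like a biological
(scale-free, modular) network rather than an Erdos-Renyi random graph:
degree distribution with a log-log power-law fit, per-node clustering
coefficients, the C(k) curve, and the closed-form random-graph expectation
of the clustering coefficient (which equals the edge density).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TopologyReport",
    "mean_degree",
    "graph_density",
    "clustering_coefficient",
    "topology_report",
]


def mean_degree(n_nodes: int, n_edges: int) -> float:
    """Average node degree, 2E/N."""
    return 2.0 * n_edges / n_nodes


def graph_density(n_nodes: int, n_edges: int) -> float:
    """Edge density 2E/(N(N-1)); also the ER expectation of the clustering
    coefficient for a random graph with the same N and E."""
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    mean_degree: float
    density: float
    avg_clustering: float
    degree_hist: pd.DataFrame  # columns k, count
    ck_curve: pd.DataFrame  # columns k, mean_c
    powerlaw_exponent: float
    powerlaw_r2: float
    random_expected_c: float

    def to_frame(self) -> pd.DataFrame:
        keys = [
            "n_nodes", "n_edges", "mean_degree", "density", "avg_clustering",
            "powerlaw_exponent", "powerlaw_r2", "random_expected_c",
        ]
        return pd.DataFrame(
            {"key": keys, "value": [getattr(self, k) for k in keys]}
        )


def _as_graph(net) -> nx.Graph:
    return net if isinstance(net, nx.Graph) else net.to_graph()


def clustering_coefficient(net, node) -> float:
    """C_i = 2 e_i / (k_i (k_i - 1)): fraction of neighbor pairs that are
    themselves connected; 0 for nodes of degree < 2."""
    g = _as_graph(net)
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    neigh = list(g.adj[node])
    k = len(neigh)
    if k < 2:
        return 0.0
    nset = set(neigh)
    links = sum(len(nset.intersection(g.adj[v])) for v in neigh) // 2
    return 2.0 * links / (k * (k - 1))


def topology_report(net, include_low_degree: bool = True) -> TopologyReport:
    """All topology diagnostics for a network.

    ``include_low_degree`` keeps degree<2 nodes (with C_i = 0) in the
    clustering average, which is the "average over all nodes" convention;
    set False to average over degree>=2 nodes only.

    The power-law fit is an ordinary least-squares regression of
    log10(count) on log10(k) over the nonzero bins of the raw degree
    histogram; the reported exponent is minus the slope.
    """
    g = _as_graph(net)
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise ValueError("topology report undefined for a network of < 2 nodes")
    degrees = np.array([d for _, d in g.degree()])
    cvals = np.array([clustering_coefficient(g, v) for v in g.nodes()])

    if include_low_degree:
        avg_c = float(cvals.mean())
    else:
        keep = degrees >= 2
        avg_c = float(cvals[keep].mean()) if keep.any() else 0.0

    ks, counts = np.unique(degrees, return_counts=True)
    degree_hist = pd.DataFrame({"k": ks, "count": counts})
    ck = (
        pd.DataFrame({"k": degrees, "c": cvals})
        .groupby("k", sort=True)["c"]
        .mean()
        .reset_index()
        .rename(columns={"c": "mean_c"})
    )

    pos = degree_hist[(degree_hist["k"] > 0) & (degree_hist["count"] > 0)]
    if len(pos) >= 2:
        fit = stats.linregress(np.log10(pos["k"]), np.log10(pos["count"]))
        exponent, r2 = -fit.slope, fit.rvalue**2
    else:
        exponent, r2 = np.nan, np.nan

    return TopologyReport(
        n_nodes=n,
        n_edges=m,
        mean_degree=mean_degree(n, m),
        density=graph_density(n, m),
        avg_clustering=avg_c,
        degree_hist=degree_hist,
        ck_curve=ck,
        powerlaw_exponent=float(exponent),
        powerlaw_r2=float(r2),
        random_expected_c=graph_density(n, m),
    )
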