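"""Hub / bottleneck classification of a gene network.

Hubs are nodes whose degree is strictly greater than the mean degree
plus one SD; bottlenecks are nodes whose (unnormalized) betweenness
centrality is strictly greater than its mean plus one SD; nodes passing
both are hub-bottlenecks.  Shortest paths use hop counts (edge weights
are display-only in the source networks), betweenness counts unordered
node pairs on undirected graphs and ordered pairs on directed graphs,
with endpoints excluded.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd


def _check(graph: nx.Graph) -> None:
    if any(u == v for u, v in graph.edges()):
        raise ValueError("self-loops are not allowed")


def compute_degrees(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree; directed graphs also report in/out-degree
    (total degree = in + out)."""
    _check(graph)
    nodes = list(graph.nodes())
    out = pd.DataFrame({"node": nodes})
    out["degree"] = [graph.degree(n) for n in nodes]
    if graph.is_directed():
        out["in_degree"] = [graph.in_degree(n) for n in nodes]
        out["out_degree"] = [graph.out_degree(n) for n in nodes]
    return out


def compute_betweenness(graph: nx.Graph) -> pd.DataFrame:
    """Unnormalized shortest-path betweenness, endpoints excluded.

    Node pairs in different components contribute nothing.
    """
    _check(graph)
    bc = nx.betweenness_centrality(graph, normalized=False, weight=None)
    return pd.DataFrame({"node": list(bc.keys()), "betweenness": list(bc.values())})


def classify_nodes(
    degrees: pd.DataFrame,
    betweenness: pd.DataFrame,
    degree_column: str = "degree",
    sd_ddof: int = 0,
) -> pd.DataFrame:
    """Label nodes as hub / bottleneck / hub-bottleneck / none.

    Thresholds are mean + 1 SD of each metric over all nodes, with strict
    inequality; SD is the population SD by default (``sd_ddof=0``).
    ``degree_column`` selects which degree flavor drives hub calls on
    directed graphs (``degree``, ``in_degree`` or ``out_degree``).
    """
    if degrees.empty:
        raise ValueError("empty graph: no nodes to classify")
    merged = degrees.merge(betweenness, on="node")
    if len(merged) != len(degrees) or len(merged) != len(betweenness):
        raise ValueError("degree and betweenness tables cover different nodes")
    deg = merged[degree_column].to_numpy(dtype=float)
    btw = merged["betweenness"].to_numpy(dtype=float)
    deg_thr = deg.mean() + deg.std(ddof=sd_ddof)
    btw_thr = btw.mean() + btw.std(ddof=sd_ddof)
    is_hub = deg > deg_thr
    is_bottleneck = btw > btw_thr
    label = np.where(
        is_hub & is_bottleneck, "hub-bottleneck",
        np.where(is_hub, "hub", np.where(is_bottleneck, "bottleneck", "none")),
    )
    out = merged.copy()
    out["degree_threshold"] = deg_thr
    out["betweenness_threshold"] = btw_thr
    out["label"] = label
    return out


def analyze_graph(graph: nx.Graph, **kwargs) -> pd.DataFrame:
    """Degrees + betweenness + classification in one call."""
    return classify_nodes(compute_degrees(graph), compute_betweenness(graph), **kwargs)
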