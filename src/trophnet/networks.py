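"""Weighted signed interaction networks and their topology.

Resolved pairs (positive or negative regime) become undirected edges whose
weight is the interaction intensity (coculture A590); unresolved pairs never
enter a network. One network is built per fertilizer treatment (including
cross-fraction edges) and one subnetwork per treatment x aggregate fraction
(only edges whose both endpoints sit in the fraction). Metrics mirror the
usual Gephi summary: node/edge counts, sign percentages, average (weighted)
degree, Louvain modularity, mean local clustering, and mean shortest-path
length on the largest connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidInputError, LabelingError

EDGE_SIGNS = ("positive", "negative")


@dataclass(frozen=True)
class NetworkMetrics:
    network_id: str
    nodes: int
    edges: int
    positive_pct: float | None
    negative_pct: float | None
    avg_degree: float
    avg_weighted_degree: float
    modularity: float | None
    avg_clustering_coefficient: float
    avg_path_length: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def build_network(interactions: pd.DataFrame, metadata: pd.DataFrame,
                  treatment: str, fraction: str | None = None) -> nx.Graph:
    """Assemble the interaction network for a treatment or treatment x fraction.

    Only resolved pairs become edges; isolated strains are dropped. Node
    attributes carry treatment and fraction, edge attributes sign and weight.
    """
    meta = metadata.set_index("strain_id")
    if treatment not in set(meta["treatment"]):
        raise InvalidInputError(f"unknown treatment {treatment!r}")
    if fraction is not None and fraction not in set(meta["fraction"]):
        raise InvalidInputError(f"unknown fraction {fraction!r}")

    members = meta[meta["treatment"] == treatment]
    if fraction is not None:
        members = members[members["fraction"] == fraction]
    member_ids = set(members.index)

    resolved = interactions[interactions["regime"].isin(EDGE_SIGNS)]
    name = treatment if fraction is None else f"{treatment}_{fraction}"
    G = nx.Graph(network_id=name)
    for row in resolved.itertuples(index=False):
        if row.strain_a in member_ids and row.strain_b in member_ids:
            weight = float(row.intensity)
            if weight <= 0:
                raise InvalidInputError(
                    f"edge weight must be > 0 for pair {row.strain_a}-{row.strain_b}")
            G.add_edge(row.strain_a, row.strain_b, sign=row.regime, weight=weight)
    for node in G.nodes:
        G.nodes[node]["treatment"] = meta.loc[node, "treatment"]
        G.nodes[node]["fraction"] = meta.loc[node, "fraction"]
    return G


def annotate_breadth(G: nx.Graph, breadth: pd.DataFrame) -> nx.Graph:
    """Attach breadth class labels (specialist/intermediate/generalist) to nodes."""
    labels = breadth.set_index("strain_id")["class_label"]
    missing = set(G.nodes) - set(labels.index)
    if missing:
        raise LabelingError(f"no breadth class for strains: {sorted(missing)[:5]}")
    nx.set_node_attributes(G, labels.loc[list(G.nodes)].to_dict(), "breadth_class")
    return G


def sign_percentages(G: nx.Graph) -> tuple[float, float]:
    """(positive %, negative %) of resolved edges; undefined on empty graphs."""
    n_edges = G.number_of_edges()
    if n_edges == 0:
        raise DegenerateInputError("sign percentages undefined with zero edges")
    n_pos = sum(1 for _, _, s in G.edges(data="sign") if s == "positive")
    return (100.0 * n_pos / n_edges, 100.0 * (n_edges - n_pos) / n_edges)


def topology_metrics(G: nx.Graph, seed: int = 0) -> NetworkMetrics:
    """Topological summary of one interaction network.

    Clustering and path length are unweighted (path length on the largest
    connected component when the graph is disconnected); modularity comes
    from a seeded Louvain pass on edge weights and is therefore reproducible
    for a fixed seed but only approximately stable across seeds.
    """
    N, E = G.number_of_nodes(), G.number_of_edges()
    if N == 0:
        raise DegenerateInputError("metrics undefined on an empty network")
    pos_pct = neg_pct = None
    if E > 0:
        pos_pct, neg_pct = sign_percentages(G)
    avg_degree = 2.0 * E / N
    avg_wdeg = 2.0 * sum(w for _, _, w in G.edges(data="weight")) / N

    modularity = None
    if E > 0:
        communities = nx.community.louvain_communities(G, weight="weight", seed=seed)
        modularity = float(nx.community.modularity(G, communities, weight="weight"))

    clustering = float(nx.average_clustering(G)) if N > 0 else 0.0

    path_length = None
    if E > 0:
        largest = max(nx.connected_components(G), key=len)
        sub = G.subgraph(largest)
        if sub.number_of_nodes() > 1:
            path_length = float(nx.average_shortest_path_length(sub))
    return NetworkMetrics(G.graph.get("network_id", ""), N, E, pos_pct, neg_pct,
                          avg_degree, avg_wdeg, modularity, clustering, path_length)


def metrics_table(metrics: list[NetworkMetrics]) -> pd.DataFrame:
    """Stack per-network metrics into a display table with rounded companions."""
    df = pd.DataFrame([m.as_dict() for m in metrics])
    for col, ndig in [("positive_pct", 2), ("negative_pct", 2), ("avg_degree", 3),
                      ("avg_weighted_degree", 3), ("modularity", 3),
                      ("avg_clustering_coefficient", 3), ("avg_path_length", 3)]:
        df[f"{col}_disp"] = df[col].round(ndig)
    return df


def export_graph(G: nx.Graph, path, fmt: str | None = None) -> None:
    """Write a network as GraphML or GEXF; attributes round-trip exactly."""
    path = str(path)
    if fmt is None:
        fmt = "gexf" if path.endswith(".gexf") else "graphml"
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "gexf":
        nx.write_gexf(G, path)
    else:
        raise InvalidInputError(f"unknown graph format {fmt!r}")


def import_graph(path, fmt: str | None = None) -> nx.Graph:
    path = str(path)
    if fmt is None:
        fmt = "gexf" if path.endswith(".gexf") else "graphml"
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "gexf":
        G = nx.read_gexf(path)
        G.graph.pop("mode", None)
        return G
    raise InvalidInputError(f"unknown graph format {fmt!r}")
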