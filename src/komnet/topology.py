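"""Topological analysis of reconstructed metabolic networks.

The central quantity is the load score of a node n:

    load_score(n) = sum_{s != n != t} (sigma_st(n) / sigma_st) / (k_n * E)

where sigma_st is the number of shortest paths between s and t,
sigma_st(n) the number of those passing through n (endpoints excluded,
unordered pairs), k_n the node degree and E the total number of edges
in the network. High-load nodes ("load points") carry many metabolite
conversion routes relative to their connectivity and serve as a proxy
for an enzyme's contribution to community-wide metabolic flux.

Choke points are enzymes that uniquely consume and/or produce some
metabolite; they are special cases of load points.

Path finding runs on the simple underlying graph; the degree / total
edge count can follow either the ``parallel`` convention (counting one
edge per shared metabolite, the default) or the ``simple`` convention
(counting connected node pairs once).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .netrecon import MetabolicNetwork, ReactionPairMap

__all__ = [
    "TopologyTable",
    "betweenness",
    "load_score",
    "weighted_load_score",
    "choke_points",
    "network_summary",
    "compute_topology",
]

EDGE_COUNT_CONVENTIONS = ("parallel", "simple")


@dataclass
class TopologyTable:
    """Per-node topological measures plus network-level summaries.

    ``nodes`` is indexed by node id with columns: members (";"-joined
    KO ids), degree, betweenness, load_score, weighted_load_score,
    choke_point, unique_metabolites, isolated.
    """

    nodes: pd.DataFrame
    total_edges_parallel: int
    total_edges_simple: int
    avg_shortest_path: float
    convention: str = "parallel"
    normalized_betweenness: bool = False

    def betweenness_by_ko(self) -> dict[str, float]:
        """Expand node betweenness to member KOs (each KO inherits its node's value)."""
        out: dict[str, float] = {}
        for node_id, row in self.nodes.iterrows():
            for ko in str(row["members"]).split(";"):
                out[ko] = float(row["betweenness"])
        return out

    def to_tsv(self, path) -> None:
        df = self.nodes.copy()
        df.insert(0, "node_id", df.index)
        df["weighted_load_score"] = df["weighted_load_score"].map(
            lambda v: "NA" if pd.isna(v) else repr(float(v))
        )
        df["unique_metabolites"] = df["unique_metabolites"].map(
            lambda s: s if s else "NA"
        )
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read_tsv(cls, path, **meta) -> "TopologyTable":
        df = pd.read_csv(path, sep="\t", dtype={"node_id": str, "members": str}, keep_default_na=False)
        df["weighted_load_score"] = df["weighted_load_score"].replace("NA", "nan").astype(float)
        df["unique_metabolites"] = df["unique_metabolites"].replace("NA", "")
        df["choke_point"] = df["choke_point"].astype(str).isin(("True", "true", "1"))
        df["isolated"] = df["isolated"].astype(str).isin(("True", "true", "1"))
        for col in ("degree",):
            df[col] = df[col].astype(int)
        for col in ("betweenness", "load_score"):
            df[col] = df[col].astype(float)
        df = df.set_index("node_id")
        meta.setdefault("total_edges_parallel", 0)
        meta.setdefault("total_edges_simple", 0)
        meta.setdefault("avg_shortest_path", float("nan"))
        return cls(nodes=df, **meta)


def betweenness(
    net: MetabolicNetwork, normalized: bool = False
) -> dict[str, float]:
    """Brandes betweenness centrality on the simple underlying graph.

    Sums sigma_st(n)/sigma_st over unordered node pairs {s, t} with
    s != n != t; pairs in different components contribute zero. With
    ``normalized`` the sum is divided by (N-1)(N-2)/2 — load-score
    *ranking* on a fixed network is invariant to that constant.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("cannot compute betweenness of an empty network")
    g = net.simple_graph()
    return {
        n: float(b)
        for n, b in nx.betweenness_centrality(g, normalized=normalized).items()
    }


def _degrees(net: MetabolicNetwork, convention: str) -> dict[str, int]:
    if convention == "parallel":
        return {n: int(d) for n, d in net.graph.degree()}
    return {n: int(d) for n, d in net.simple_graph().degree()}


def _total_edges(net: MetabolicNetwork, convention: str) -> int:
    return net.n_edges_parallel if convention == "parallel" else net.n_edges_simple


def load_score(
    net: MetabolicNetwork,
    edge_count_convention: str = "parallel",
    betweenness_values: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Load score per node: betweenness / (degree * total edge count).

    Isolated (degree-0) nodes receive score 0 rather than a division
    error. ``edge_count_convention`` selects whether parallel metabolite
    edges count toward degree and the edge total.
    """
    if edge_count_convention not in EDGE_COUNT_CONVENTIONS:
        raise ValueError(
            f"unknown edge_count_convention {edge_count_convention!r}; "
            f"expected one of {EDGE_COUNT_CONVENTIONS}"
        )
    b = dict(betweenness_values) if betweenness_values is not None else betweenness(net)
    deg = _degrees(net, edge_count_convention)
    total = _total_edges(net, edge_count_convention)
    out: dict[str, float] = {}
    for n in net.graph.nodes:
        if deg[n] == 0 or total == 0:
            out[n] = 0.0
        else:
            out[n] = b[n] / (deg[n] * total)
    return out


def metabolite_occurrence(net: MetabolicNetwork) -> dict[str, int]:
    """Number of network nodes whose pair-set contains each metabolite."""
    occ: dict[str, int] = {}
    for n in net.graph.nodes:
        for m in net.node_metabolites(n):
            occ[m] = occ.get(m, 0) + 1
    return occ


def weighted_load_score(
    net: MetabolicNetwork, edge_count_convention: str = "parallel"
) -> dict[str, float]:
    """Load score with metabolite-occurrence-weighted shortest paths.

    Each edge labelled with metabolite m gets affinity 1/occurrence(m),
    where occurrence(m) counts the nodes whose pair-set contains m; its
    reciprocal — the occurrence itself — is the Dijkstra path length of
    the edge. Routes through common (currency-like) metabolites are
    thus long and avoided, concentrating load points within pathways.
    Parallel edges between a node pair collapse to the rarest (closest)
    metabolite; betweenness is then Dijkstra-based. This variant is
    reported separately and is not used for default keystone selection.
    """
    occ = metabolite_occurrence(net)
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        w = float(occ[d["metabolite"]])
        if g.has_edge(u, v):
            g[u][v]["weight"] = min(g[u][v]["weight"], w)
        else:
            g.add_edge(u, v, weight=w)
    b = nx.betweenness_centrality(g, normalized=False, weight="weight")
    deg = _degrees(net, edge_count_convention)
    total = _total_edges(net, edge_count_convention)
    return {
        n: 0.0 if deg[n] == 0 or total == 0 else float(b[n]) / (deg[n] * total)
        for n in net.graph.nodes
    }


def choke_points(
    pair_map: ReactionPairMap, ko_subset: Iterable[str]
) -> dict[str, frozenset[str]]:
    """KOs that uniquely consume and/or produce some metabolite.

    Returns a map KO -> its unique metabolites (those appearing in no
    other subset member's pair-set); KOs without unique metabolites are
    absent from the result.
    """
    subset = sorted(set(ko_subset))
    occ: dict[str, int] = {}
    for ko in subset:
        for m in pair_map.metabolites(ko):
            occ[m] = occ.get(m, 0) + 1
    out: dict[str, frozenset[str]] = {}
    for ko in subset:
        unique = frozenset(m for m in pair_map.metabolites(ko) if occ[m] == 1)
        if unique:
            out[ko] = unique
    return out


def _avg_shortest_path(g: nx.Graph) -> tuple[float, int, int]:
    """Mean shortest-path length over connected unordered node pairs.

    Returns (average, connected pair count, disconnected pair count).
    """
    n = g.number_of_nodes()
    total_pairs = n * (n - 1) // 2
    path_sum = 0
    connected_pairs = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        k = sub.number_of_nodes()
        if k < 2:
            continue
        connected_pairs += k * (k - 1) // 2
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            path_sum += sum(dists.values())
    avg = (path_sum / 2) / connected_pairs if connected_pairs else float("nan")
    return avg, connected_pairs, total_pairs - connected_pairs


def network_summary(net: MetabolicNetwork) -> dict:
    """Node/edge counts, components, average shortest path, degree quantiles."""
    g = net.simple_graph()
    avg, connected_pairs, disconnected_pairs = _avg_shortest_path(g)
    deg = np.array([d for _, d in net.graph.degree()], dtype=float)
    quantiles = (
        {
            f"q{int(q * 100)}": float(np.quantile(deg, q))
            for q in (0.0, 0.25, 0.5, 0.75, 1.0)
        }
        if deg.size
        else {}
    )
    return {
        "n_nodes": int(net.graph.number_of_nodes()),
        "n_edges_parallel": int(net.n_edges_parallel),
        "n_edges_simple": int(net.n_edges_simple),
        "n_components": int(nx.number_connected_components(g)),
        "avg_shortest_path": avg,
        "connected_pairs": int(connected_pairs),
        "disconnected_pairs": int(disconnected_pairs),
        "degree_quantiles": quantiles,
    }


def compute_topology(
    net: MetabolicNetwork,
    edge_count_convention: str = "parallel",
    normalized_betweenness: bool = False,
    with_weighted: bool = False,
) -> TopologyTable:
    """Full per-node topology table for a reconstructed network.

    Choke-point detection runs on the node pair-sets of the network
    itself, so collapsed groups are assessed as single enzymes.
    """
    b = betweenness(net, normalized=normalized_betweenness)
    ls = load_score(net, edge_count_convention, betweenness_values=b)
    wls = (
        weighted_load_score(net, edge_count_convention) if with_weighted else None
    )
    deg = _degrees(net, edge_count_convention)

    node_pairs = ReactionPairMap(
        pairs={n: net.pair_set(n) for n in net.graph.nodes}
    )
    cps = choke_points(node_pairs, net.graph.nodes)

    g = net.simple_graph()
    avg, _, _ = _avg_shortest_path(g)

    rows = []
    for n in net.node_ids:
        rows.append(
            {
                "members": ";".join(net.members(n)),
                "degree": deg[n],
                "betweenness": b[n],
                "load_score": ls[n],
                "weighted_load_score": wls[n] if wls is not None else float("nan"),
                "choke_point": n in cps,
                "unique_metabolites": ";".join(sorted(cps.get(n, ()))),
                "isolated": deg[n] == 0,
            }
        )
    nodes = pd.DataFrame(rows, index=pd.Index(net.node_ids, name="node_id"))
    return TopologyTable(
        nodes=nodes,
        total_edges_parallel=net.n_edges_parallel,
        total_edges_simple=net.n_edges_simple,
        avg_shortest_path=avg,
        convention=edge_count_convention,
        normalized_betweenness=normalized_betweenness,
    )
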