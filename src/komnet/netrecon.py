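"""Community-wide metabolic network reconstruction from KO reaction pairs.

Enzymes (grouped by KO) are nodes; metabolites are undirected edges.
Each KO carries a pair-set of (substrate, product) metabolite pairs,
emulating KEGG RPAIR annotations. Two nodes are connected by one edge
per metabolite they share (``shared_metabolite`` mode, the default
connectivity-centred view) or per metabolite produced by one and
consumed by the other (``complementary`` mode). Parallel edges for
distinct shared metabolites are retained; topology code decides whether
to count them.

Networks are rendered non-redundant by collapsing KOs with identical
pair-sets into a single node group — typically subunits of the same
enzyme complex.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionPairMap",
    "MetabolicNetwork",
    "EDGE_MODES",
    "build_network",
    "season_subset",
    "collapse_redundant",
    "export_network",
    "import_network",
]

EDGE_MODES = ("shared_metabolite", "complementary")

Pair = tuple[str, str]


@dataclass(frozen=True)
class ReactionPairMap:
    """Map KO id -> set of (substrate, product) metabolite pairs."""

    pairs: Mapping[str, frozenset[Pair]]

    def __post_init__(self) -> None:
        for ko, ps in self.pairs.items():
            for s, p in ps:
                if not s or not p:
                    raise ValueError(f"empty metabolite id in pair-set of {ko!r}")

    def metabolites(self, ko: str) -> frozenset[str]:
        """All metabolites (substrates and products) touched by a KO."""
        return frozenset(m for pair in self.pairs.get(ko, frozenset()) for m in pair)

    def substrates(self, ko: str) -> frozenset[str]:
        return frozenset(s for s, _ in self.pairs.get(ko, frozenset()))

    def products(self, ko: str) -> frozenset[str]:
        return frozenset(p for _, p in self.pairs.get(ko, frozenset()))

    @classmethod
    def read_tsv(cls, path) -> "ReactionPairMap":
        """Read TSV with columns ko_id, substrate, product (one pair/line)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if not {"ko_id", "substrate", "product"}.issubset(df.columns):
            raise ValueError(
                f"pair map {path} must have columns ko_id, substrate, product"
            )
        pairs: dict[str, set[Pair]] = {}
        for ko, s, p in zip(df["ko_id"], df["substrate"], df["product"]):
            pairs.setdefault(ko, set()).add((s, p))
        return cls(pairs={k: frozenset(v) for k, v in pairs.items()})

    @classmethod
    def read_json(cls, path) -> "ReactionPairMap":
        """Read JSON of the form {ko: [[substrate, product], ...], ...}."""
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            pairs={ko: frozenset((s, p) for s, p in ps) for ko, ps in raw.items()}
        )

    def to_tsv(self, path) -> None:
        rows = [
            {"ko_id": ko, "substrate": s, "product": p}
            for ko in sorted(self.pairs)
            for s, p in sorted(self.pairs[ko])
        ]
        pd.DataFrame(rows, columns=["ko_id", "substrate", "product"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )


@dataclass
class MetabolicNetwork:
    """Undirected multigraph of KO-group nodes with metabolite-labelled edges.

    Node keys are group ids (the lexicographically smallest member KO);
    node attributes: ``members`` (sorted tuple of KO ids) and
    ``pair_set`` (frozenset of (substrate, product) pairs). Edge
    attribute ``metabolite`` labels each parallel edge.
    """

    graph: nx.MultiGraph
    mode: str = "shared_metabolite"
    collapsed: bool = False

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    def members(self, node: str) -> tuple[str, ...]:
        return self.graph.nodes[node]["members"]

    def pair_set(self, node: str) -> frozenset[Pair]:
        return self.graph.nodes[node]["pair_set"]

    @property
    def all_kos(self) -> frozenset[str]:
        return frozenset(
            ko for n in self.graph.nodes for ko in self.graph.nodes[n]["members"]
        )

    def node_metabolites(self, node: str) -> frozenset[str]:
        return frozenset(m for pair in self.pair_set(node) for m in pair)

    def simple_graph(self) -> nx.Graph:
        """Underlying simple graph (parallel metabolite edges merged)."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(self.graph.edges())
        return g

    @property
    def n_edges_parallel(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_edges_simple(self) -> int:
        return self.simple_graph().number_of_edges()

    def edge_triples(self) -> set[tuple[str, str, str]]:
        """Canonical (min_node, max_node, metabolite) triples."""
        return {
            (min(u, v), max(u, v), d["metabolite"])
            for u, v, d in self.graph.edges(data=True)
        }


def _edges_for_pair_sets(
    pair_sets: Mapping[str, frozenset[Pair]], mode: str
) -> set[tuple[str, str, str]]:
    """Edge triples (u, v, metabolite) for nodes with given pair-sets.

    shared_metabolite: edge per metabolite appearing (in any role) in
    both pair-sets. complementary: metabolite must be a product of one
    node and a substrate of the other. Never creates self-loops.
    """
    if mode not in EDGE_MODES:
        raise ValueError(f"unknown edge mode {mode!r}; expected one of {EDGE_MODES}")

    edges: set[tuple[str, str, str]] = set()
    if mode == "shared_metabolite":
        by_met: dict[str, list[str]] = {}
        for node, ps in pair_sets.items():
            for m in {x for pair in ps for x in pair}:
                by_met.setdefault(m, []).append(node)
        for m, nodes in by_met.items():
            nodes = sorted(nodes)
            for i, u in enumerate(nodes):
                for v in nodes[i + 1 :]:
                    edges.add((u, v, m))
    else:
        producers: dict[str, list[str]] = {}
        consumers: dict[str, list[str]] = {}
        for node, ps in pair_sets.items():
            for s, _ in ps:
                consumers.setdefault(s, []).append(node)
            for _, p in ps:
                producers.setdefault(p, []).append(node)
        for m, prod in producers.items():
            for u in prod:
                for v in consumers.get(m, ()):
                    if u != v:
                        edges.add((min(u, v), max(u, v), m))
    return edges


def build_network(
    pair_map: ReactionPairMap,
    ko_subset: Iterable[str],
    mode: str = "shared_metabolite",
) -> MetabolicNetwork:
    """Build the redundant (one node per KO) metabolic network.

    KOs absent from the pair map, or with empty pair-sets, are dropped
    with a logged warning: only KOs with metabolic annotation enter the
    network.
    """
    subset = set(ko_subset)
    if not subset:
        raise ValueError("ko_subset is empty; nothing to build a network from")
    if mode not in EDGE_MODES:
        raise ValueError(f"unknown edge mode {mode!r}; expected one of {EDGE_MODES}")

    kept = {ko for ko in subset if pair_map.pairs.get(ko)}
    dropped = subset - kept
    if dropped:
        logger.warning(
            "%d KO(s) lack reaction-pair annotation and are excluded from the "
            "network (e.g. %s)",
            len(dropped),
            sorted(dropped)[:5],
        )
    if not kept:
        raise ValueError("no KO in the subset has a non-empty pair-set")

    g = nx.MultiGraph()
    pair_sets = {ko: pair_map.pairs[ko] for ko in kept}
    for ko in sorted(kept):
        g.add_node(ko, members=(ko,), pair_set=pair_sets[ko])
    for u, v, m in sorted(_edges_for_pair_sets(pair_sets, mode)):
        g.add_edge(u, v, metabolite=m)
    return MetabolicNetwork(graph=g, mode=mode, collapsed=False)


def season_subset(
    pair_map: ReactionPairMap, kota: Mapping[str, float]
) -> set[str]:
    """KOs with transcript signal (KOTA > 0) and metabolic annotation.

    Networks are rendered season-specific by keeping only KOs with
    mapped metatranscriptomic reads from that sampling date.
    """
    return {ko for ko, v in kota.items() if v > 0 and pair_map.pairs.get(ko)}


def collapse_redundant(net: MetabolicNetwork) -> MetabolicNetwork:
    """Merge KOs with identical pair-sets into single node groups.

    Edges are recomputed between groups under the network's edge mode,
    so between any two groups there is exactly one edge per qualifying
    metabolite. Idempotent; the union of members over groups equals the
    input KO set.
    """
    groups: dict[frozenset[Pair], list[str]] = {}
    for node in net.graph.nodes:
        ps = net.pair_set(node)
        groups.setdefault(ps, []).extend(net.members(node))

    g = nx.MultiGraph()
    pair_sets: dict[str, frozenset[Pair]] = {}
    for ps, members in groups.items():
        members = tuple(sorted(set(members)))
        gid = members[0]
        g.add_node(gid, members=members, pair_set=ps)
        pair_sets[gid] = ps
    for u, v, m in sorted(_edges_for_pair_sets(pair_sets, net.mode)):
        g.add_edge(u, v, metabolite=m)
    return MetabolicNetwork(graph=g, mode=net.mode, collapsed=True)


def _serialize_pairs(ps: frozenset[Pair]) -> str:
    return ";".join(f"{s}>{p}" for s, p in sorted(ps))


def _parse_pairs(s: str) -> frozenset[Pair]:
    if not s:
        return frozenset()
    out = []
    for item in s.split(";"):
        sub, _, prod = item.partition(">")
        out.append((sub, prod))
    return frozenset(out)


def export_network(net: MetabolicNetwork, path, format: str = "graphml") -> None:
    """Write a network to disk.

    ``graphml`` is the full-fidelity format (node members and pair-sets,
    edge metabolite labels; round-trips exactly via
    :func:`import_network`). ``sif`` and ``edge_tsv`` are plain edge
    lists (node id, metabolite, node id) for interchange with graph
    viewers; importing them recovers topology and edge labels but not
    group membership beyond the node ids.
    """
    if format == "graphml":
        g = nx.MultiGraph()
        g.graph["mode"] = net.mode
        g.graph["collapsed"] = net.collapsed
        for n in net.graph.nodes:
            g.add_node(
                n,
                members=";".join(net.members(n)),
                pair_set=_serialize_pairs(net.pair_set(n)),
            )
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, metabolite=d["metabolite"])
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, m in sorted(net.edge_triples()):
                fh.write(f"{u}\t{m}\t{v}\n")
            for n in net.node_ids:
                if net.graph.degree(n) == 0:
                    fh.write(f"{n}\n")
    elif format == "edge_tsv":
        rows = [
            {"node_a": u, "node_b": v, "metabolite": m}
            for u, v, m in sorted(net.edge_triples())
        ]
        pd.DataFrame(rows, columns=["node_a", "node_b", "metabolite"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_network(path, format: str = "graphml") -> MetabolicNetwork:
    """Read a network written by :func:`export_network`."""
    if format == "graphml":
        raw = nx.read_graphml(path, force_multigraph=True)
        g = nx.MultiGraph()
        for n, d in raw.nodes(data=True):
            g.add_node(
                n,
                members=tuple(d["members"].split(";")),
                pair_set=_parse_pairs(d.get("pair_set", "")),
            )
        for u, v, d in raw.edges(data=True):
            g.add_edge(u, v, metabolite=d["metabolite"])
        return MetabolicNetwork(
            graph=g,
            mode=raw.graph.get("mode", "shared_metabolite"),
            collapsed=bool(raw.graph.get("collapsed", False)),
        )
    if format in ("sif", "edge_tsv"):
        g = nx.MultiGraph()

        def add_node(n: str) -> None:
            if n not in g:
                g.add_node(n, members=(n,), pair_set=frozenset())

        if format == "sif":
            with open(path) as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) == 1 and parts[0]:
                        add_node(parts[0])
                    elif len(parts) == 3:
                        u, m, v = parts
                        add_node(u)
                        add_node(v)
                        g.add_edge(u, v, metabolite=m)
        else:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
            for _, row in df.iterrows():
                add_node(row["node_a"])
                add_node(row["node_b"])
                g.add_edge(row["node_a"], row["node_b"], metabolite=row["metabolite"])
        return MetabolicNetwork(graph=g)
    raise ValueError(f"unknown import format {format!r}")
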