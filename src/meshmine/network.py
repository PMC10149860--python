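"""Typed term co-occurrence networks and Cytoscape-compatible exports.

Each matched MeSH term is a node typed by its vocabulary category (disease or
digital-health approach); an undirected edge between two nodes records how
many publications matched both terms. Node ``count`` (occurrences) and edge
``weight`` (co-occurrences) are the attributes a viewer like Cytoscape uses
for sizing and edge width. Sub-networks are built by selecting seed nodes and
taking the induced subgraph on the seeds plus their first-degree neighbours;
seeds are re-typed ``"selected"`` in the output.

No layout, colouring, or community statistics are computed here — networks are
exported (GraphML, SIF, attribute TSVs) for downstream viewers.
"""

from __future__ import annotations

from typing import IO, Iterable, Optional, Sequence, Union

import networkx as nx

from .counting import CooccurrenceTable, CountTable, canonical_pair

NODE_TYPES = ("disease", "digital_health", "age_group", "gender", "selected")
SIF_RELATION = "cooccurs_with"


class TermNetwork:
    """An undirected term graph with typed, counted nodes and weighted edges.

    Thin wrapper over :class:`networkx.Graph`; node attributes are ``label``,
    ``node_type`` and ``count``, the single edge attribute is ``weight``.
    Node identity is the normalized term string; the label preserves the
    vocabulary's original casing.
    """

    def __init__(self, graph: Optional[nx.Graph] = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()

    def add_node(self, node_id: str, label: str, node_type: str, count: int) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node_type {node_type!r}")
        self.graph.add_node(node_id, label=label, node_type=node_type,
                            count=int(count))

    def add_edge(self, a: str, b: str, weight: int) -> None:
        if a not in self.graph or b not in self.graph:
            missing = [n for n in (a, b) if n not in self.graph]
            raise ValueError(f"edge endpoints not in network: {missing}")
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        self.graph.add_edge(a, b, weight=int(weight))

    @property
    def nodes(self) -> dict[str, dict]:
        return {n: dict(d) for n, d in self.graph.nodes(data=True)}

    @property
    def edges(self) -> dict[tuple[str, str], int]:
        return {canonical_pair(a, b): d["weight"]
                for a, b, d in self.graph.edges(data=True)}

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "TermNetwork":
        return TermNetwork(self.graph.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


def build_network(occ_tables: Sequence[CountTable], cooc: CooccurrenceTable,
                  edge_threshold: int = 1,
                  include_isolated: bool = False) -> TermNetwork:
    """Assemble the typed co-occurrence network.

    Edges are created for every pair with count >= ``edge_threshold``; each
    node takes its type from the first occurrence table that contains the term
    and its ``count`` attribute from that table. With ``include_isolated``,
    matched terms (occurrence count >= 1) without a surviving edge are added
    as isolated nodes. A pair term absent from every occurrence table is a
    validation error.
    """
    if edge_threshold < 1:
        raise ValueError("edge_threshold must be >= 1")

    info: dict[str, tuple[str, str, int]] = {}  # term -> (label, type, count)
    for table in occ_tables:
        for term, count in table.counts.items():
            if term not in info:
                label = table.display.get(term, term)
                info[term] = (label, table.category, count)

    net = TermNetwork()
    kept = [(pair, c) for pair, c in sorted(cooc.counts.items())
            if c >= edge_threshold]
    missing = sorted({t for (a, b), _ in kept for t in (a, b) if t not in info})
    if missing:
        raise ValueError(
            f"co-occurrence terms missing from occurrence tables: {missing}")
    for (a, b), _ in kept:
        for term in (a, b):
            if term not in net.graph:
                label, ntype, count = info[term]
                net.add_node(term, label=label, node_type=ntype, count=count)
    for (a, b), count in kept:
        net.add_edge(a, b, weight=count)

    if include_isolated:
        for term in sorted(info):
            label, ntype, count = info[term]
            if count >= 1 and term not in net.graph:
                net.add_node(term, label=label, node_type=ntype, count=count)
    return net


def first_degree_subnetwork(net: TermNetwork,
                            seed_nodes: Iterable[str]) -> TermNetwork:
    """Induced subgraph on seed nodes plus their first-degree neighbours.

    All edges of the parent network with both endpoints retained are kept
    (including neighbour-neighbour edges). Seed nodes are re-typed
    ``"selected"``; the input network is left unmodified.
    """
    seeds = set(seed_nodes)
    unknown = sorted(s for s in seeds if s not in net.graph)
    if unknown:
        raise ValueError(f"unknown seed node ids: {unknown}")
    keep = set(seeds)
    for seed in seeds:
        keep.update(net.graph.neighbors(seed))
    sub = TermNetwork(net.graph.subgraph(keep).copy())
    for seed in seeds:
        sub.graph.nodes[seed]["node_type"] = "selected"
    return sub


# ---------------------------------------------------------------------------
# Exports (deterministic element order: nodes by id, edges by canonical pair)
# ---------------------------------------------------------------------------

def _sorted_graph(net: TermNetwork) -> nx.Graph:
    g = nx.Graph()
    for node in sorted(net.graph.nodes):
        g.add_node(node, **net.graph.nodes[node])
    for a, b in sorted(canonical_pair(a, b) for a, b in net.graph.edges):
        g.add_edge(a, b, **net.graph.edges[a, b])
    return g


def export_graphml(net: TermNetwork, sink: Union[str, IO]) -> None:
    """Write GraphML with label/node_type/count node keys and a weight edge key."""
    g = _sorted_graph(net)
    if isinstance(sink, str):
        nx.write_graphml(g, sink, encoding="utf-8", prettyprint=True)
    else:
        for chunk in nx.generate_graphml(g, encoding="utf-8", prettyprint=True):
            sink.write(chunk + "\n")


def export_sif(net: TermNetwork, sink: Union[str, IO]) -> None:
    """Write a tab-delimited SIF file (relation ``cooccurs_with``).

    Isolated nodes are written as single-column lines, the convention
    Cytoscape uses for unconnected nodes.
    """
    lines: list[str] = []
    connected: set[str] = set()
    for a, b in sorted(canonical_pair(x, y) for x, y in net.graph.edges):
        lines.append(f"{a}\t{SIF_RELATION}\t{b}")
        connected.update((a, b))
    for node in sorted(set(net.graph.nodes) - connected):
        lines.append(node)
    payload = "".join(line + "\n" for line in lines)
    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(payload)
    else:
        sink.write(payload)


def export_attributes(net: TermNetwork, node_sink: Union[str, IO],
                      edge_sink: Union[str, IO]) -> None:
    """Write node and edge attribute tables as TSV.

    Node table: term, label, node_type, count (sorted by term). Edge table:
    term_a, term_b, weight (canonical pair order, sorted).
    """
    node_lines = ["term\tlabel\tnode_type\tcount"]
    for node in sorted(net.graph.nodes):
        d = net.graph.nodes[node]
        node_lines.append(f"{node}\t{d['label']}\t{d['node_type']}\t{d['count']}")
    edge_lines = ["term_a\tterm_b\tweight"]
    for a, b in sorted(canonical_pair(x, y) for x, y in net.graph.edges):
        edge_lines.append(f"{a}\t{b}\t{net.graph.edges[a, b]['weight']}")

    for sink, lines in ((node_sink, node_lines), (edge_sink, edge_lines)):
        payload = "".join(line + "\n" for line in lines)
        if isinstance(sink, str):
            with open(sink, "w", encoding="utf-8") as fh:
                fh.write(payload)
        else:
            sink.write(payload)
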