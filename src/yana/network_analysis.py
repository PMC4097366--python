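"""Confidence-thresholded PPI subnetworks, neighbor augmentation, and
cross-species overlap.

The workflow: induce the subnetwork of modifier hits on a high-confidence
interaction map (the *primary* network), extract connected-component
clusters, optionally keep only modifiers with >= k interactions to other
modifiers, then *extend* the yeast network with first-degree neighbors so
that hits invisible to the primary map — *orphans* — can be reconnected
through a shared neighbor (*orphan rescue*).  Finally, the extended yeast
network is translated through ortholog tables and intersected with the
human primary network to nominate cross-species targets.

Confidence scores follow the STRING convention: integers 0-1000 on disk,
divided by 1000 on load, thresholded inclusively (>= 0.900 is the
"highest confidence" preset of the experiments channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .ortholog_map import OrthologTable, consensus_map

__all__ = [
    "PPINetwork",
    "NetworkCluster",
    "OverlapReport",
    "load_edges",
    "write_edges",
    "primary_network",
    "clusters",
    "degree_filter",
    "extend_with_neighbors",
    "rescue_orphans",
    "cross_species_overlap",
    "export_graph",
    "import_graphml",
]

DEFAULT_MIN_CONF = 0.900


@dataclass
class PPINetwork:
    """Weighted undirected interaction network for one species.

    Wraps an ``networkx.Graph`` whose edges carry a ``confidence`` in
    [0, 1]; ``threshold`` records the construction cutoff (every edge
    confidence is >= it).  Node ``role`` attributes (hit / rescued /
    neighbor) are set by the augmentation steps.
    """

    species: str
    graph: nx.Graph = field(default_factory=nx.Graph)
    channel: str = "experiments"
    threshold: float = DEFAULT_MIN_CONF

    def __post_init__(self) -> None:
        for u, v, conf in self.graph.edges(data="confidence"):
            if u == v:
                raise ValueError(f"self-loop on {u}")
            if conf is None or not self.threshold <= conf <= 1:
                raise ValueError(
                    f"edge {u}-{v} confidence {conf} outside [{self.threshold}, 1]"
                )

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def roles(self) -> dict[str, str]:
        return {n: d.get("role", "hit") for n, d in self.graph.nodes(data=True)}

    def orphans(self) -> set[str]:
        """Hit nodes with no edge to any other node of this network."""
        return {
            n
            for n, d in self.graph.nodes(data=True)
            if self.graph.degree(n) == 0 and d.get("role", "hit") == "hit"
        }


@dataclass
class NetworkCluster:
    """One connected component with per-node roles."""

    members: set[str]
    roles: dict[str, str]
    species: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster has at least 2 members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OverlapReport:
    """Human symbols present in both species' networks, with provenance.

    ``provenance[symbol]`` lists the (yeast_gene, yeast_role) pairs whose
    ortholog mapping produced the shared symbol.
    """

    shared: set[str]
    provenance: dict[str, list[tuple[str, str]]]

    def __len__(self) -> int:
        return len(self.shared)


# ---------------------------------------------------------------------------
# edge list I/O (STRING-style: geneA <tab> geneB <tab> integer score 0-1000)
# ---------------------------------------------------------------------------

def load_edges(
    path: str | Path,
    min_conf: float = DEFAULT_MIN_CONF,
    *,
    species: str = "pombe",
    channel: str = "experiments",
) -> PPINetwork:
    """Load a STRING-style edge TSV, keeping edges with confidence >= min_conf.

    Scores are integers on the 0-1000 scale, divided by 1000; the threshold
    is inclusive.  Symmetric duplicates (A-B and B-A) collapse to one edge
    keeping the maximum confidence.  Self-loops are ignored.  A score
    outside [0, 1000] is a parse error naming the line.
    """
    graph = nx.Graph()
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        lines = []
        if first and not first.lower().startswith(("genea", "#")):
            lines.append((1, first))
        lines.extend((i, ln.rstrip("\n")) for i, ln in enumerate(fh, start=2))
    for lineno, line in lines:
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 fields")
        a, b, score_s = parts
        try:
            score = int(score_s)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer score {score_s!r}") from None
        if not 0 <= score <= 1000:
            raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1000]")
        conf = score / 1000.0
        if a == b or conf < min_conf:
            continue
        if graph.has_edge(a, b):
            conf = max(conf, graph.edges[a, b]["confidence"])
        graph.add_edge(a, b, confidence=conf)
    return PPINetwork(species, graph, channel, min_conf)


def write_edges(network: PPINetwork, path: str | Path) -> None:
    """Write edges back to the 0-1000 integer TSV, lexicographic order."""
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tscore\n")
        for u, v, conf in sorted(
            (tuple(sorted((u, v))) + (c,) for u, v, c in
             network.graph.edges(data="confidence"))
        ):
            fh.write(f"{u}\t{v}\t{round(conf * 1000)}\n")


# ---------------------------------------------------------------------------
# subnetwork construction
# ---------------------------------------------------------------------------

def primary_network(hits: Iterable[str], network: PPINetwork) -> PPINetwork:
    """Subgraph induced on the hit set; hits without edges stay as orphans.

    Every hit becomes a node (role ``hit``) even if the interaction map
    never mentions it; only edges between two hits survive.
    """
    hits = set(hits)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(hits), role="hit")
    for u, v, conf in network.graph.edges(data="confidence"):
        if u in hits and v in hits:
            graph.add_edge(u, v, confidence=conf)
    return PPINetwork(network.species, graph, network.channel, network.threshold)


def clusters(network: PPINetwork, min_size: int = 2) -> list[NetworkCluster]:
    """Connected components with >= min_size members.

    Sorted by size descending, ties by lexicographically smallest member.
    """
    roles = network.roles()
    comps = [
        set(c) for c in nx.connected_components(network.graph) if len(c) >= min_size
    ]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [
        NetworkCluster(c, {n: roles[n] for n in c}, network.species) for c in comps
    ]


def degree_filter(
    hits: Iterable[str], network: PPINetwork, k: int = 2
) -> PPINetwork:
    """Keep hits with >= k interactions to other hits, in a single pass.

    Degrees are measured once, against the unfiltered hit-induced
    subgraph, then the subgraph is re-induced on the survivors — this is
    deliberately not an iterative k-core, so a node kept for its k
    modifier interactions stays kept even if some of its partners fall.
    """
    if k < 1:
        if k == 0:
            return network
        raise ValueError("k must be >= 1")
    sub = primary_network(hits, network)
    survivors = {n for n in sub.graph.nodes if sub.graph.degree(n) >= k}
    return primary_network(survivors, sub)


def extend_with_neighbors(hits: Iterable[str], full: PPINetwork) -> PPINetwork:
    """Augment the hit set with every first-degree neighbor in ``full``.

    Node set = hits plus all nodes adjacent to a hit; edge set = all
    qualifying edges among that node set (neighbor-neighbor edges
    included).  Roles: ``hit`` or ``neighbor``.
    """
    hits = set(hits)
    extended = set(hits)
    for h in hits:
        if h in full.graph:
            extended.update(full.graph.neighbors(h))
    graph = nx.Graph()
    for n in sorted(extended):
        graph.add_node(n, role="hit" if n in hits else "neighbor")
    for u, v, conf in full.graph.edges(data="confidence"):
        if u in extended and v in extended:
            graph.add_edge(u, v, confidence=conf)
    return PPINetwork(full.species, graph, full.channel, full.threshold)


def rescue_orphans(
    hits: Iterable[str], primary: PPINetwork, extended: PPINetwork
) -> dict[str, set[str]]:
    """Neighbors that reconnect at least two orphan hits.

    An *orphan* is a hit with degree 0 in the primary (hit-only) network.
    A non-hit node of the extended network adjacent to >= 2 orphans is
    *rescued*: it joins the orphans into a cluster the primary map could
    not see.  Returns rescued node -> the orphans it rescues; also marks
    the rescued nodes' role in ``extended``.
    """
    hits = set(hits)
    orphans = {h for h in hits if h in primary.graph and primary.graph.degree(h) == 0}
    rescued: dict[str, set[str]] = {}
    for n in extended.graph.nodes:
        if n in hits:
            continue
        linked = {o for o in extended.graph.neighbors(n) if o in orphans}
        if len(linked) >= 2:
            rescued[n] = linked
            extended.graph.nodes[n]["role"] = "rescued"
    return rescued


def cross_species_overlap(
    pombe_extended: PPINetwork,
    human_primary: PPINetwork,
    tables: Sequence[OrthologTable],
    policy: str = "union",
) -> OverlapReport:
    """Humanize the extended yeast network and intersect with the human one.

    Every yeast node (hit, rescued or neighbor) is translated through the
    ortholog tables; symbols also present in the human primary network are
    reported with the yeast gene(s) and role(s) that produced them.
    Symbols shared by both species' maps are the cross-validated target
    nominations.
    """
    roles = pombe_extended.roles()
    human_nodes = human_primary.nodes
    shared: set[str] = set()
    provenance: dict[str, list[tuple[str, str]]] = {}
    for gene in sorted(pombe_extended.graph.nodes):
        for sym in sorted(consensus_map(gene, tables, policy).human_symbols):
            if sym in human_nodes:
                shared.add(sym)
                provenance.setdefault(sym, []).append((gene, roles[gene]))
    return OverlapReport(shared, provenance)


# ---------------------------------------------------------------------------
# graph export (Cytoscape-compatible)
# ---------------------------------------------------------------------------

def export_graph(network: PPINetwork, path: str | Path, format: str = "graphml") -> None:
    """Write the network as SIF or GraphML with deterministic ordering.

    SIF lines are ``A pp B`` (lexicographic); GraphML carries node
    attributes ``species`` and ``role`` and the edge attribute
    ``confidence``.  Two exports of the same network are byte-identical.
    """
    fmt = format.lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            isolated = sorted(n for n in network.graph.nodes
                              if network.graph.degree(n) == 0)
            for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
                fh.write(f"{u} pp {v}\n")
            for n in isolated:
                fh.write(f"{n}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        roles = network.roles()
        for n in sorted(network.graph.nodes):
            g.add_node(n, species=network.species, role=roles[n])
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            g.add_edge(u, v, confidence=float(network.graph.edges[u, v]["confidence"]))
        with open(path, "wb") as fh:
            for line in nx.generate_graphml(g, named_key_ids=True):
                fh.write(line.encode() + b"\n")
    else:
        raise ValueError(f"unknown export format {format!r}; use 'sif' or 'graphml'")


def import_graphml(path: str | Path, threshold: float = DEFAULT_MIN_CONF) -> PPINetwork:
    """Read back a GraphML export into a :class:`PPINetwork`."""
    g = nx.read_graphml(path)
    species = None
    graph = nx.Graph()
    for n, d in g.nodes(data=True):
        species = d.get("species", species)
        graph.add_node(n, role=d.get("role", "hit"))
    for u, v, d in g.edges(data=True):
        graph.add_edge(u, v, confidence=float(d["confidence"]))
    return PPINetwork(species or "pombe", graph, threshold=threshold)
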