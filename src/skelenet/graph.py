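"""Directed evidence multigraph and primitive graph operations.

The :class:`InteractionGraph` is a directed multigraph over official gene
symbols: parallel edges between the same ordered pair are allowed only when
they carry distinct interaction types (a pair may legitimately interact both
physically and genetically), and self-loops are allowed.  Storage is a
:class:`networkx.MultiDiGraph` keyed by interaction type; the shortest-path
machinery is an unweighted BFS over the node-level adjacency — parallel
typed edges never multiply paths, and edges carry no weights.
"""

from __future__ import annotations

import csv
from collections import Counter, deque
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

import networkx as nx

from .model import (
    DirectedInteraction,
    DriverClass,
    Evidence,
    GeneNode,
    InteractionType,
    PathResult,
    SourceDB,
)


class NeighborDirection(str, Enum):
    PARENTS = "PARENTS"    # in-neighbors
    CHILDREN = "CHILDREN"  # out-neighbors
    BOTH = "BOTH"


class InteractionGraph:
    """Directed multigraph of typed gene interactions with evidence."""

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction -------------------------------------------------

    def add_node(self, node: GeneNode) -> None:
        existing = self._g.nodes.get(node.symbol)
        if existing is None:
            self._g.add_node(node.symbol, data=node)

    def add_edge(self, edge: DirectedInteraction) -> None:
        """Insert an edge, merging evidence into an existing same-typed edge."""
        for symbol in (edge.src, edge.dst):
            if symbol not in self._g:
                self._g.add_node(symbol, data=GeneNode(symbol))
        key = edge.itype.value
        if self._g.has_edge(edge.src, edge.dst, key=key):
            self._g[edge.src][edge.dst][key]["evidences"].extend(edge.evidences)
        else:
            self._g.add_edge(edge.src, edge.dst, key=key,
                             itype=edge.itype, evidences=list(edge.evidences))

    # -- access -------------------------------------------------------

    @property
    def nodes(self) -> dict[str, GeneNode]:
        return {s: d["data"] for s, d in self._g.nodes(data=True)}

    def node(self, symbol: str) -> GeneNode:
        try:
            return self._g.nodes[symbol]["data"]
        except KeyError:
            raise KeyError(f"unknown gene symbol: {symbol!r}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[DirectedInteraction]:
        for src, dst, data in self._g.edges(data=True):
            yield DirectedInteraction(src, dst, data["itype"], data["evidences"])

    def edge_types_between(self, src: str, dst: str) -> frozenset[InteractionType]:
        if not self._g.has_edge(src, dst):
            return frozenset()
        return frozenset(d["itype"] for d in self._g[src][dst].values())

    def parents(self, symbol: str) -> set[str]:
        self.node(symbol)
        return set(self._g.predecessors(symbol))

    def children(self, symbol: str) -> set[str]:
        self.node(symbol)
        return set(self._g.successors(symbol))

    def driver_symbols(self) -> set[str]:
        return {s for s, n in self.nodes.items() if n.is_driver}

    def induced_subgraph(self, symbols: Iterable[str]) -> "InteractionGraph":
        """Subgraph over ``symbols`` with all edges joining two members."""
        keep = set(symbols)
        sub = InteractionGraph()
        for symbol in keep:
            sub.add_node(self.node(symbol))
        for edge in self.edges():
            if edge.src in keep and edge.dst in keep:
                sub.add_edge(edge)
        return sub

    def topology_key(self) -> tuple:
        """Hashable summary of the topology, for purity checks."""
        return (
            tuple(sorted(self._g.nodes)),
            tuple(sorted((u, v, k) for u, v, k in self._g.edges(keys=True))),
        )

    @property
    def nx(self) -> nx.MultiDiGraph:
        """The underlying networkx multigraph (read-only use)."""
        return self._g


_SYMBOL_OK = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789-_.@")


def _check_canonical_form(symbol: str) -> None:
    if not symbol or any(c not in _SYMBOL_OK for c in symbol):
        raise ValueError(f"driver symbol not in canonical form: {symbol!r}")


def build_graph(
    edges: Iterable[DirectedInteraction],
    drivers: Optional[dict[str, DriverClass]] = None,
) -> InteractionGraph:
    """Assemble the merged interaction graph.

    The node set is every edge endpoint plus every driver symbol — drivers
    with no interactions become isolated nodes so their disconnection is
    visible rather than silently lost.  Duplicate (src, dst, type) edges
    merge with evidence union.
    """
    graph = InteractionGraph()
    drivers = drivers or {}
    for symbol, dclass in drivers.items():
        _check_canonical_form(symbol)
        if isinstance(dclass, str):
            dclass = DriverClass(dclass)
        graph.add_node(GeneNode(symbol, is_driver=True, driver_class=dclass))
    for edge in edges:
        graph.add_edge(edge)
    return graph


def load_driver_table(path: Path) -> dict[str, DriverClass]:
    """Read a driver list TSV (symbol, driver_class)."""
    drivers: dict[str, DriverClass] = {}
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != ("symbol", "driver_class"):
            raise ValueError(f"{path}: expected header ('symbol', 'driver_class')")
        for row in reader:
            if not row or not row[0].strip():
                continue
            symbol, dclass = row[0].strip(), row[1].strip().upper()
            drivers[symbol] = DriverClass(dclass)
    return drivers


# -- shortest paths ----------------------------------------------------


def bfs_distances(
    adjacency, source: str, allowed: Optional[set[str]] = None
) -> dict[str, int]:
    """Unweighted BFS distances from ``source`` along ``adjacency(v)``."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adjacency(u):
            if allowed is not None and v not in allowed:
                continue
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_shortest_paths(
    graph: InteractionGraph,
    src: str,
    dst: str,
    allowed: Optional[set[str]] = None,
    max_paths: Optional[int] = None,
) -> list[PathResult]:
    """All minimal-length directed paths src -> dst, as node sequences.

    Computed on the shortest-path DAG: forward BFS from ``src`` and reverse
    BFS from ``dst`` mark exactly the edges (u, v) with
    ``d(src,u) + 1 + d(v,dst) == d(src,dst)``; a depth-first walk over that
    DAG choosing successors in sorted order emits the complete path list in
    lexicographic order.  Returns an empty list when ``dst`` is unreachable.
    Direction matters: a path B -> A exists only via edges oriented that way.
    """
    for symbol in (src, dst):
        graph.node(symbol)
    if allowed is not None:
        allowed = set(allowed)
        missing = {src, dst} - allowed
        if missing:
            raise ValueError(f"allowed set must contain the query genes: {sorted(missing)}")
    if src == dst:
        return [PathResult([src])]
    d_fwd = bfs_distances(graph.children, src, allowed)
    if dst not in d_fwd:
        return []
    d_rev = bfs_distances(graph.parents, dst, allowed)
    total = d_fwd[dst]

    def dag_successors(u: str) -> list[str]:
        out = [
            v
            for v in graph.children(u)
            if (allowed is None or v in allowed)
            and v in d_rev
            and d_fwd[u] + 1 + d_rev[v] == total
        ]
        return sorted(out)

    paths: list[PathResult] = []
    stack: list[str] = [src]

    def walk(u: str) -> bool:
        if u == dst:
            nodes = list(stack)
            types = [
                graph.edge_types_between(a, b) for a, b in zip(nodes, nodes[1:])
            ]
            paths.append(PathResult(nodes, types))
            return max_paths is not None and len(paths) >= max_paths
        for v in dag_successors(u):
            stack.append(v)
            if walk(v):
                return True
            stack.pop()
        return False

    walk(src)
    return paths


def neighbors(
    graph: InteractionGraph, symbol: str, direction: NeighborDirection
) -> set[str]:
    """Parents (in-neighbors), children (out-neighbors), or their union.

    A self-loop makes a node its own parent and child.
    """
    if direction is NeighborDirection.PARENTS:
        return graph.parents(symbol)
    if direction is NeighborDirection.CHILDREN:
        return graph.children(symbol)
    return graph.parents(symbol) | graph.children(symbol)


# -- statistics --------------------------------------------------------


@dataclass
class GraphStats:
    """Degree and redundancy summaries of a (sub)graph.

    Each directed edge contributes one out-degree at its source and one
    in-degree at its target (a self-loop contributes one of each to the
    same node), so ``avg_degree == 2 * n_edges / n_nodes`` and the average
    in- and out-degrees are each ``n_edges / n_nodes``.  ``n_nonredundant``
    counts distinct unordered endpoint pairs, collapsing direction and
    parallel types; a self-loop counts as the single pair {A}.
    """

    n_nodes: int
    n_edges: int
    n_nonredundant: int
    avg_degree: float
    avg_in_degree: float
    avg_out_degree: float
    in_degree_histogram: dict[int, int] = field(default_factory=dict)
    out_degree_histogram: dict[int, int] = field(default_factory=dict)


def compute_stats(
    graph: InteractionGraph, node_subset: Optional[set[str]] = None
) -> GraphStats:
    """Compute :class:`GraphStats`, optionally on an induced subgraph."""
    if node_subset is None:
        symbols = set(graph.nodes)
    else:
        symbols = set(node_subset)
        for s in symbols:
            graph.node(s)
    in_deg = Counter({s: 0 for s in symbols})
    out_deg = Counter({s: 0 for s in symbols})
    n_edges = 0
    pairs: set[frozenset[str]] = set()
    for edge in graph.edges():
        if edge.src in symbols and edge.dst in symbols:
            n_edges += 1
            out_deg[edge.src] += 1
            in_deg[edge.dst] += 1
            pairs.add(frozenset((edge.src, edge.dst)))
    n = len(symbols)
    return GraphStats(
        n_nodes=n,
        n_edges=n_edges,
        n_nonredundant=len(pairs),
        avg_degree=(2 * n_edges / n) if n else 0.0,
        avg_in_degree=(n_edges / n) if n else 0.0,
        avg_out_degree=(n_edges / n) if n else 0.0,
        in_degree_histogram=dict(Counter(in_deg.values())),
        out_degree_histogram=dict(Counter(out_deg.values())),
    )


# -- serialization -----------------------------------------------------

EDGELIST_COLUMNS = ("src", "dst", "itype", "n_evidences", "sources")


def write_edgelist_tsv(graph: InteractionGraph, path: Path) -> None:
    """Write the documented edge-list TSV (src, dst, itype, n_evidences, sources)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(EDGELIST_COLUMNS)
        for edge in sorted(graph.edges(), key=lambda e: (e.src, e.dst, e.itype.value)):
            sources = ",".join(sorted({ev.source_db.value for ev in edge.evidences}))
            writer.writerow([edge.src, edge.dst, edge.itype.value,
                             len(edge.evidences), sources])


def read_edgelist_tsv(path: Path) -> list[DirectedInteraction]:
    """Read the edge-list TSV back.

    Lossy on evidence detail by design (the TSV stores only tallies): each
    edge is rebuilt with one placeholder evidence per listed source database.
    """
    edges: list[DirectedInteraction] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != EDGELIST_COLUMNS:
            raise ValueError(f"{path}: expected header {EDGELIST_COLUMNS}")
        for row in reader:
            if not row or not row[0].strip():
                continue
            src, dst, itype, _n, sources = row
            evidences = [
                Evidence(SourceDB(s), detail="imported")
                for s in sources.split(",") if s
            ]
            edges.append(DirectedInteraction(src, dst, InteractionType(itype),
                                             evidences or [Evidence(SourceDB.BIOGRID, "imported")]))
    return edges


def write_graphml(graph: InteractionGraph, path: Path) -> None:
    """Export to GraphML with flattened string/number attributes."""
    out = nx.MultiDiGraph()
    for symbol, node in graph.nodes.items():
        out.add_node(
            symbol,
            is_driver=node.is_driver,
            driver_class=node.driver_class.value,
            level="" if node.level is None else str(node.level),
        )
    for edge in graph.edges():
        out.add_edge(
            edge.src,
            edge.dst,
            key=edge.itype.value,
            itype=edge.itype.value,
            n_evidences=len(edge.evidences),
            sources=",".join(sorted({ev.source_db.value for ev in edge.evidences})),
        )
    nx.write_graphml(out, path)
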