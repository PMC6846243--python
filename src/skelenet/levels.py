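"""Skeleton construction and level expansion to saturation.

The *skeleton* is the reduction of the whole interactome to the union, over
every ordered pair of driver genes, of all minimal-length directed paths
between them.  It is then expanded in *levels*: level k adds all parents
and children of the level-(k-1) nodes, plus every edge induced among the
accumulated nodes (including interactions linking two nodes that both
arrived at level k).  Expansion repeats until no new node appears —
*saturation*.  Nodes never reached, including genes whose interactions form
islands disjoint from the skeleton, carry the WHOLE label and only appear
in the whole graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import WHOLE
from .graph import InteractionGraph, bfs_distances


@dataclass
class SkeletonResult:
    """Skeleton node/edge sets plus the drivers that joined no path.

    Supports two-tuple unpacking as ``(nodes, edges)``.  ``edges`` holds
    ordered endpoint pairs; every typed parallel edge between a consecutive
    pair of path nodes belongs to the skeleton.
    """

    nodes: set[str]
    edges: set[tuple[str, str]]
    unconnected_drivers: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter((self.nodes, self.edges))


def build_skeleton(graph: InteractionGraph, drivers: Iterable[str]) -> SkeletonResult:
    """Union of all shortest directed paths between every ordered driver pair.

    Shortest paths are computed independently per ordered pair (no global
    Steiner-style approximation): for pair (a, b) the forward BFS from a and
    the reverse BFS from b mark every node v with
    ``d(a,v) + d(v,b) == d(a,b)`` — exactly the nodes on some minimal path —
    and every edge (u, v) with ``d(a,u) + 1 + d(v,b) == d(a,b)``.  Drivers
    unreachable from and to every other driver are excluded and reported as
    unconnected.
    """
    drivers = sorted(set(drivers))
    missing = [d for d in drivers if d not in graph]
    if missing:
        raise KeyError(f"driver symbols absent from graph: {missing}")
    if len(drivers) < 2:
        raise ValueError("skeleton construction needs at least 2 driver genes")

    fwd = {d: bfs_distances(graph.children, d) for d in drivers}
    rev = {d: bfs_distances(graph.parents, d) for d in drivers}

    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    connected: set[str] = set()
    for a in drivers:
        da = fwd[a]
        for b in drivers:
            if a == b or b not in da:
                continue
            total = da[b]
            db = rev[b]
            on_path = {v for v, d in da.items() if v in db and d + db[v] == total}
            nodes.update(on_path)
            connected.update((a, b))
            for u in on_path:
                du = da[u]
                for v in graph.children(u):
                    if v in db and du + 1 + db[v] == total:
                        edges.add((u, v))
    return SkeletonResult(
        nodes=nodes,
        edges=edges,
        unconnected_drivers=[d for d in drivers if d not in connected],
    )


@dataclass
class LevelRow:
    """One row of the per-level expansion table."""

    level: int
    new_nodes: int
    new_edges: int
    total_nodes: int
    total_edges: int


@dataclass
class LevelDecomposition:
    """Per-node level labels and per-level growth tallies.

    ``level_of`` maps each graph node to the first level at which it
    appears (0 = skeleton) or to WHOLE when expansion never reaches it.
    ``saturation_level`` is the last level that added nodes; expanding the
    saturation set returns it unchanged.
    """

    level_of: dict[str, object]
    saturation_level: int
    per_level: list[LevelRow]
    unconnected_drivers: list[str] = field(default_factory=list)

    def nodes_at_most(self, level: int) -> set[str]:
        return {
            s
            for s, lv in self.level_of.items()
            if isinstance(lv, int) and lv <= level
        }

    def whole_nodes(self) -> set[str]:
        return {s for s, lv in self.level_of.items() if lv == WHOLE}


def _induced_edge_count(graph: InteractionGraph, symbols: set[str]) -> int:
    return sum(1 for e in graph.edges() if e.src in symbols and e.dst in symbols)


def expand_levels(
    graph: InteractionGraph,
    skeleton_nodes: set[str],
    max_level: Optional[int] = None,
    unconnected_drivers: Optional[Iterable[str]] = None,
) -> LevelDecomposition:
    """Grow the skeleton level by level until saturation.

    Level k (k >= 1) adds every parent and child of a level-(k-1) node; the
    level-k edge set is all edges induced among the accumulated nodes, so
    within-level interactions between two newly added genes are counted at
    the level they both arrive.  Expansion follows the parent/child relation
    in both orientations.  Stops at the first step adding no node, or at
    ``max_level``.
    """
    skeleton_nodes = set(skeleton_nodes)
    missing = skeleton_nodes - set(graph.nodes)
    if missing:
        raise KeyError(f"skeleton nodes absent from graph: {sorted(missing)}")

    level_of: dict[str, object] = {s: 0 for s in skeleton_nodes}
    current = set(skeleton_nodes)
    prev_edges = _induced_edge_count(graph, current)
    per_level = [
        LevelRow(0, len(current), prev_edges, len(current), prev_edges)
    ]
    level = 0
    while max_level is None or level < max_level:
        frontier = set()
        for s in current:
            frontier |= graph.parents(s) | graph.children(s)
        new_nodes = frontier - current
        if not new_nodes:
            break
        level += 1
        current |= new_nodes
        for s in sorted(new_nodes):
            level_of[s] = level
        total_edges = _induced_edge_count(graph, current)
        per_level.append(
            LevelRow(level, len(new_nodes), total_edges - prev_edges,
                     len(current), total_edges)
        )
        prev_edges = total_edges
    for symbol in graph.nodes:
        level_of.setdefault(symbol, WHOLE)
    return LevelDecomposition(
        level_of=level_of,
        saturation_level=level,
        per_level=per_level,
        unconnected_drivers=sorted(unconnected_drivers or ()),
    )


def decompose(graph: InteractionGraph, drivers: Iterable[str],
              max_level: Optional[int] = None) -> tuple[SkeletonResult, LevelDecomposition]:
    """Convenience: skeleton plus its level decomposition in one call."""
    skeleton = build_skeleton(graph, drivers)
    decomposition = expand_levels(
        graph, skeleton.nodes, max_level=max_level,
        unconnected_drivers=skeleton.unconnected_drivers,
    )
    return skeleton, decomposition


def apply_levels(graph: InteractionGraph, decomposition: LevelDecomposition) -> None:
    """Write each node's level label onto the graph's GeneNode records."""
    for symbol, level in decomposition.level_of.items():
        graph.node(symbol).level = level


def whole_graph(
    graph: InteractionGraph, decomposition: LevelDecomposition
) -> tuple[set[str], set[tuple[str, str, object]]]:
    """The complete node and edge sets, including WHOLE-level islands.

    Every edge missing from the saturation-level set has at least one
    WHOLE-labelled endpoint (islands whose interactions — often
    self-references — never touch the expanded core).
    """
    nodes = set(graph.nodes)
    edges = {(e.src, e.dst, e.itype) for e in graph.edges()}
    return nodes, edges


def write_level_table(decomposition: LevelDecomposition, graph: InteractionGraph, path) -> None:
    """Export per-node levels as TSV (symbol, level, is_driver, driver_class)."""
    import csv

    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["symbol", "level", "is_driver", "driver_class"])
        for symbol in sorted(decomposition.level_of):
            node = graph.node(symbol)
            writer.writerow([
                symbol,
                decomposition.level_of[symbol],
                int(node.is_driver),
                node.driver_class.value,
            ])


def write_level_summary(decomposition: LevelDecomposition, path) -> None:
    """Export the per-level growth table (level, new/total node and edge counts)."""
    import csv

    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["level", "new_nodes", "new_edges", "total_nodes", "total_edges"])
        for row in decomposition.per_level:
            writer.writerow([row.level, row.new_nodes, row.new_edges,
                             row.total_nodes, row.total_edges])
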