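"""The three user-facing query semantics over a level-decomposed graph.

1. *Direct interactors* — what interacts directly with the gene(s) of
   interest?  Returns the induced subgraph over the query genes and their
   parents and children, optionally restricted to a level cap; calling it
   again on a returned node expands the view iteratively.
2. *Shortest paths between two genes* — every minimal-length directed path
   from the first gene to the second.  Edges are directional, so the
   reverse direction requires swapping the query genes; an empty result
   carries a hint when the reverse orientation would succeed.
3. *Connection to a level* — the shortest routes linking a gene of interest
   (e.g. a candidate not yet disease-associated) to any node at or below a
   target level.  The engine is directed while the question ("is it
   connected?") is not, so both orientations are searched and reported
   separately, tagged OUTBOUND (gene -> level) and INBOUND (level -> gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .model import WHOLE, PathResult
from .graph import InteractionGraph, all_shortest_paths, bfs_distances
from .levels import LevelDecomposition

#: Default cap on returned paths; all-shortest-path sets can explode
#: combinatorially on dense graphs.
DEFAULT_MAX_PATHS = 1000


@dataclass(frozen=True)
class QueryScope:
    """Restrict a query to nodes at or below a level cap.

    ``level_cap=WHOLE`` means no restriction.  The query genes themselves
    are always admitted regardless of their level.
    """

    level_cap: Union[int, str] = WHOLE

    def admits(self, level: object) -> bool:
        if self.level_cap == WHOLE:
            return True
        return isinstance(level, int) and level <= self.level_cap

    def nodes(
        self,
        graph: InteractionGraph,
        decomposition: Optional[LevelDecomposition],
        always: Iterable[str] = (),
    ) -> set[str]:
        if self.level_cap == WHOLE or decomposition is None:
            return set(graph.nodes)
        keep = {
            s for s, lv in decomposition.level_of.items() if self.admits(lv)
        }
        keep.update(always)
        return keep


@dataclass
class PathQueryResult:
    """Result of a shortest-path query: the paths, their common length, flags."""

    paths: list[PathResult]
    truncated: bool = False
    reverse_exists: bool = False  # hint: swapping the genes would find paths

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    @property
    def length(self) -> Optional[int]:
        return self.paths[0].n_edges if self.paths else None


def query_direct(
    graph: InteractionGraph,
    genes: Iterable[str],
    scope: QueryScope = QueryScope(),
    decomposition: Optional[LevelDecomposition] = None,
) -> InteractionGraph:
    """Induced subgraph over the query genes plus their direct interactors.

    Isolated query genes appear with degree zero.  Interactors outside the
    scope's level cap are excluded.
    """
    genes = list(genes)
    for g in genes:
        graph.node(g)  # raises naming the unknown symbol
    admitted = scope.nodes(graph, decomposition, always=genes)
    keep = set(genes)
    for g in genes:
        keep |= (graph.parents(g) | graph.children(g)) & admitted
    return graph.induced_subgraph(keep)


def query_paths_between(
    graph: InteractionGraph,
    gene_a: str,
    gene_b: str,
    scope: QueryScope = QueryScope(),
    decomposition: Optional[LevelDecomposition] = None,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> PathQueryResult:
    """All shortest directed paths gene_a -> gene_b within scope.

    ``gene_a == gene_b`` yields the single zero-length path — a defined
    degenerate answer rather than an error.  When no forward path exists
    the result is empty with ``reverse_exists`` set if gene_b -> gene_a
    would succeed.
    """
    graph.node(gene_a)
    graph.node(gene_b)
    allowed = scope.nodes(graph, decomposition, always=(gene_a, gene_b))
    paths = all_shortest_paths(graph, gene_a, gene_b, allowed=allowed,
                               max_paths=max_paths + 1)
    truncated = len(paths) > max_paths
    if truncated:
        paths = paths[:max_paths]
    reverse = False
    if not paths:
        back = bfs_distances(graph.children, gene_b, allowed)
        reverse = gene_a in back
    return PathQueryResult(paths=paths, truncated=truncated, reverse_exists=reverse)


@dataclass
class ConnectResult:
    """Shortest connections between a gene and a network level, per direction."""

    outbound: list[PathResult] = field(default_factory=list)  # gene -> level
    inbound: list[PathResult] = field(default_factory=list)   # level -> gene
    outbound_distance: Optional[int] = None
    inbound_distance: Optional[int] = None
    truncated: bool = False


def query_connect_to_level(
    graph: InteractionGraph,
    gene: str,
    target_level: int,
    decomposition: LevelDecomposition,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> ConnectResult:
    """Shortest paths from ``gene`` to any node at level <= ``target_level``.

    The target set excludes the gene itself, so a gene already inside the
    level cap reports its nearest *other* member (direct neighbors at
    distance one, typically).  Both orientations are computed; each list is
    empty when no connection exists in that direction.
    """
    graph.node(gene)
    if target_level > decomposition.saturation_level:
        raise ValueError(
            f"target_level {target_level} exceeds saturation level "
            f"{decomposition.saturation_level}"
        )
    targets = decomposition.nodes_at_most(target_level) - {gene}
    result = ConnectResult()
    for direction in ("outbound", "inbound"):
        adjacency = graph.children if direction == "outbound" else graph.parents
        dist = bfs_distances(adjacency, gene)
        reached = {t: dist[t] for t in targets if t in dist}
        if not reached:
            continue
        d_star = min(reached.values())
        paths: list[PathResult] = []
        for t in sorted(t for t, d in reached.items() if d == d_star):
            if direction == "outbound":
                found = all_shortest_paths(graph, gene, t,
                                           max_paths=max_paths + 1 - len(paths))
            else:
                found = all_shortest_paths(graph, t, gene,
                                           max_paths=max_paths + 1 - len(paths))
            paths.extend(found)
            if len(paths) > max_paths:
                result.truncated = True
                paths = paths[:max_paths]
                break
        setattr(result, direction, paths)
        setattr(result, f"{direction}_distance", d_star)
    return result
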