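"""Independent brute-force oracles used to cross-check the graph machinery.

These deliberately avoid the package's BFS predecessor-DAG code paths:
shortest paths are found by exhaustive depth-first enumeration of simple
paths with branch-and-bound on the best length seen so far, and the
skeleton oracle is a plain union over ordered driver pairs.
"""

from __future__ import annotations

import random

from skelenet.graph import InteractionGraph, build_graph
from skelenet.model import DirectedInteraction, DriverClass, Evidence, InteractionType, SourceDB


def enumerate_shortest_paths(adjacency: dict[str, set[str]], src: str, dst: str) -> list[list[str]]:
    """All minimal-length simple directed paths src -> dst, by exhaustive DFS."""
    if src == dst:
        return [[src]]
    best: list[int] = [len(adjacency) + 1]
    found: list[list[str]] = []
    path = [src]
    on_path = {src}

    def dfs(u: str) -> None:
        if len(path) - 1 >= best[0]:
            return
        for v in sorted(adjacency.get(u, ())):
            if v == dst:
                length = len(path)
                if length < best[0]:
                    best[0] = length
                    found.clear()
                if length == best[0]:
                    found.append(path + [v])
            elif v not in on_path:
                path.append(v)
                on_path.add(v)
                dfs(v)
                path.pop()
                on_path.remove(v)

    dfs(src)
    return sorted(found)


def adjacency_of(graph: InteractionGraph) -> dict[str, set[str]]:
    return {s: graph.children(s) for s in graph.nodes}


def skeleton_oracle(graph: InteractionGraph, drivers: list[str]):
    """Union of brute-force minimal paths over every ordered driver pair."""
    adjacency = adjacency_of(graph)
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    connected: set[str] = set()
    for a in drivers:
        for b in drivers:
            if a == b:
                continue
            paths = enumerate_shortest_paths(adjacency, a, b)
            if paths:
                connected.update((a, b))
            for path in paths:
                nodes.update(path)
                edges.update(zip(path, path[1:]))
    return nodes, edges, sorted(set(drivers) - connected)


def random_digraph(seed: int) -> tuple[InteractionGraph, list[str]]:
    """A small random directed multigraph plus a random driver subset."""
    rng = random.Random(seed)
    n = rng.randint(4, 12)
    symbols = [f"N{i:02d}" for i in range(n)]
    edges = []
    for u in symbols:
        for v in symbols:
            p = 0.03 if u == v else 0.2  # sparse self-loops
            if rng.random() < p:
                itype = rng.choice(list(InteractionType))
                edges.append(
                    DirectedInteraction(
                        u, v, itype,
                        [Evidence(rng.choice(list(SourceDB)), detail="synthetic")],
                    )
                )
                if rng.random() < 0.1:  # occasional parallel typed edge
                    other = rng.choice([t for t in InteractionType if t is not itype])
                    edges.append(
                        DirectedInteraction(
                            u, v, other, [Evidence(SourceDB.BIOGRID, detail="synthetic")]
                        )
                    )
    drivers = rng.sample(symbols, rng.randint(2, min(5, n)))
    graph = build_graph(edges, {d: DriverClass.NON_SYNDROMIC for d in drivers})
    return graph, drivers
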