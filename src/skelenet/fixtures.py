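"""Deterministic synthetic inputs with known ground truth.

Real interactome builds pull from external database releases; everything
here is generated instead, in the same three source dialects, so every
pipeline stage is testable without downloads.  The random model is a
directed Erdős–Rényi backbone over a gene universe plus *planted chains* —
unidirectional paths of chosen lengths between consecutive driver genes —
so the fixtures have both diffuse connectivity and shortest paths that are
known by construction.  Alias spellings and rows that the parsers must drop
(non-human pairs, evidence-free associations, sub-threshold or
non-nomenclature text-mining hits) are injected deliberately.

The manifest records the expected parser output and independently computed
ground truth (skeleton, level labels) via :mod:`networkx`, so tests can
compare the package's own algorithms against an external route.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .model import (
    WHOLE,
    DirectedInteraction,
    DriverClass,
    Evidence,
    InteractionType,
    SourceDB,
)

_GENETIC_SYSTEMS = ("dosage lethality", "dosage rescue", "synthetic lethality")
_PHYSICAL_SYSTEMS = ("two hybrid", "fret", "affinity capture-ms", "co-crystal structure")
_UNTYPED_SYSTEM = "unclassified assay"
_HUMAN = 9606
_MOUSE = 10090
PPAXE_THRESHOLD = 0.5


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    seed: int
    n_genes: int = 30
    n_drivers: int = 5
    p_edge: float = 0.05
    frac_genetic: float = 0.15
    frac_unknown: float = 0.15
    alias_rate: float = 0.2
    n_isolated: int = 2
    planted_chains: list[int] = field(default_factory=lambda: [2, 3])

    def __post_init__(self) -> None:
        for name in ("p_edge", "frac_genetic", "frac_unknown", "alias_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if self.frac_genetic + self.frac_unknown > 1.0:
            raise ValueError("type fractions exceed 1")
        if self.n_drivers > self.n_genes:
            raise ValueError("n_drivers cannot exceed n_genes")
        if self.n_drivers < 2:
            raise ValueError("need at least 2 drivers")
        if any(length < 1 for length in self.planted_chains):
            raise ValueError("planted chain lengths must be >= 1")
        longest = max((length - 1 for length in self.planted_chains), default=0)
        pool = self.n_genes - self.n_drivers - self.n_isolated
        if longest > pool:
            raise ValueError(
                f"planted chains need up to {longest} intermediate genes "
                f"but only {pool} non-driver connectable genes exist"
            )

    @classmethod
    def from_yaml(cls, path: Path) -> "FixtureSpec":
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)


@dataclass
class _Record:
    """One conceptual interaction before distribution into a source file."""

    a: str
    b: str
    itype: InteractionType
    directed: bool  # True: emits a->b only; False: emits both directions
    written_a: str = ""  # spelling (possibly alias) used in the file
    written_b: str = ""


def _expected_edges(records: list[_Record]) -> list[tuple[str, str, str]]:
    """Directed (src, dst, itype) multiset the parsers must emit, raw spellings."""
    out = []
    for r in records:
        out.append((r.written_a, r.written_b, r.itype.value))
        if not r.directed:
            out.append((r.written_b, r.written_a, r.itype.value))
    return sorted(out)


def _canonical_edges(records: list[_Record]) -> list[tuple[str, str, str]]:
    """Unique canonical (src, dst, itype) triples after unaliasing + merge."""
    seen = set()
    for r in records:
        seen.add((r.a, r.b, r.itype.value))
        if not r.directed:
            seen.add((r.b, r.a, r.itype.value))
    return sorted(seen)


def _oracle_skeleton(digraph: nx.DiGraph, drivers: list[str]):
    """Ground-truth skeleton via networkx all-shortest-paths enumeration."""
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    connected: set[str] = set()
    for a in drivers:
        for b in drivers:
            if a == b:
                continue
            try:
                paths = list(nx.all_shortest_paths(digraph, a, b))
            except nx.NetworkXNoPath:
                continue
            connected.update((a, b))
            for path in paths:
                nodes.update(path)
                edges.update(zip(path, path[1:]))
    return nodes, edges, sorted(set(drivers) - connected)


def _oracle_levels(digraph: nx.DiGraph, skeleton_nodes: set[str]):
    """Ground-truth first-appearance levels by plain set expansion."""
    level_of: dict[str, object] = {s: 0 for s in skeleton_nodes}
    current = set(skeleton_nodes)
    level = 0
    while True:
        frontier = set()
        for s in current:
            frontier |= set(digraph.successors(s)) | set(digraph.predecessors(s))
        new = frontier - current
        if not new:
            break
        level += 1
        for s in new:
            level_of[s] = level
        current |= new
    for s in digraph.nodes:
        level_of.setdefault(s, WHOLE)
    return level_of, level


def generate(spec: FixtureSpec, out_dir: Path) -> dict:
    """Write one synthetic dataset and return (and save) its manifest.

    Output is byte-identical for identical specs.  The manifest carries the
    expected raw/canonical edge lists, the alias map, kept/dropped row
    tallies, and networkx-derived skeleton and level ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    genes = [f"GEN{i:03d}" for i in range(1, spec.n_genes + 1)]
    drivers = genes[: spec.n_drivers]
    isolated = genes[spec.n_genes - spec.n_isolated:] if spec.n_isolated else []
    connectable = [g for g in genes if g not in isolated]
    chain_pool = [g for g in connectable if g not in drivers]

    driver_classes = {
        d: rng.choice([DriverClass.SYNDROMIC, DriverClass.NON_SYNDROMIC, DriverClass.BOTH])
        for d in drivers
    }
    aliased = {g: f"ALS{g}" for g in genes if rng.random() < spec.alias_rate}

    records: list[_Record] = []
    seen_pairs: set[tuple[str, str]] = set()

    # Planted unidirectional chains between consecutive driver pairs.
    for j, length in enumerate(spec.planted_chains):
        i = j % (spec.n_drivers - 1)
        a, b = drivers[i], drivers[i + 1]
        inner = rng.sample(chain_pool, length - 1)
        path = [a, *inner, b]
        for u, v in zip(path, path[1:]):
            if (u, v) not in seen_pairs:
                seen_pairs.update([(u, v), (v, u)])
                records.append(_Record(u, v, InteractionType.GENETIC, directed=True))

    # Erdős–Rényi backbone over unordered connectable pairs, plus rare
    # self-references.
    for i, u in enumerate(connectable):
        for v in connectable[i + 1:]:
            if (u, v) in seen_pairs or rng.random() >= spec.p_edge:
                continue
            seen_pairs.update([(u, v), (v, u)])
            r = rng.random()
            if r < spec.frac_genetic:
                itype, directed = InteractionType.GENETIC, True
            elif r < spec.frac_genetic + spec.frac_unknown:
                itype, directed = InteractionType.UNKNOWN, False
            else:
                itype, directed = InteractionType.PHYSICAL, False
            if rng.random() < 0.5:
                u, v = v, u
            records.append(_Record(u, v, itype, directed))
    for g in connectable:
        if rng.random() < spec.p_edge / 4:
            records.append(_Record(g, g, InteractionType.UNKNOWN, directed=False))

    # Spelling used in the files: alias with probability 1/2 per occurrence.
    for r in records:
        r.written_a = aliased[r.a] if r.a in aliased and rng.random() < 0.5 else r.a
        r.written_b = aliased[r.b] if r.b in aliased and rng.random() < 0.5 else r.b

    biogrid_rows: list[list[str]] = []
    string_rows: list[list[str]] = []
    action_rows: list[list[str]] = []
    ppaxe_rows: list[list[str]] = []
    for r in records:
        a, b = r.written_a, r.written_b
        if r.itype is InteractionType.GENETIC:
            if rng.random() < 0.5:
                biogrid_rows.append([a, b, str(_HUMAN), str(_HUMAN), "genetic",
                                     rng.choice(_GENETIC_SYSTEMS), "unknown"])
            else:
                biogrid_rows.append([a, b, str(_HUMAN), str(_HUMAN), "-",
                                     rng.choice(_GENETIC_SYSTEMS), "unknown"])
        elif r.itype is InteractionType.UNKNOWN:
            if rng.random() < 0.3:
                biogrid_rows.append([a, b, str(_HUMAN), str(_HUMAN), "-",
                                     _UNTYPED_SYSTEM, "unknown"])
            else:
                score = 0.5 + 0.5 * rng.random()
                ppaxe_rows.append([a, b, f"{score:.3f}", str(rng.randrange(10_000_000, 35_000_000))])
        else:  # PHYSICAL
            if rng.random() < 0.5:
                label = rng.choice(["physical", "-"])
                biogrid_rows.append([a, b, str(_HUMAN), str(_HUMAN), label,
                                     rng.choice(_PHYSICAL_SYSTEMS), "unknown"])
            else:
                experimental = rng.randrange(100, 900)
                database = rng.randrange(0, 900)
                textmining = rng.randrange(0, 900)
                string_rows.append([a, b, str(_HUMAN), str(_HUMAN), "0", "0",
                                    str(experimental), str(database), str(textmining)])

    # Rows the parsers must drop.
    n_junk = max(1, spec.n_genes // 10)
    dropped = {"biogrid_taxid": 0, "string_no_evidence": 0,
               "ppaxe_low_score": 0, "ppaxe_bad_symbol": 0}
    for _ in range(n_junk):
        u, v = rng.sample(connectable, 2)
        biogrid_rows.append([u, v, str(_HUMAN), str(_MOUSE), "physical",
                             rng.choice(_PHYSICAL_SYSTEMS), "unknown"])
        dropped["biogrid_taxid"] += 1
        u, v = rng.sample(connectable, 2)
        string_rows.append([u, v, str(_HUMAN), str(_HUMAN), "0", "0", "0", "0",
                            str(rng.randrange(400, 900))])
        dropped["string_no_evidence"] += 1
        u, v = rng.sample(connectable, 2)
        ppaxe_rows.append([u, v, f"{0.49 * rng.random():.3f}",
                           str(rng.randrange(10_000_000, 35_000_000))])
        dropped["ppaxe_low_score"] += 1
        u = rng.choice(connectable)
        ppaxe_rows.append([u, f"NOTAGENE{rng.randrange(100)}", "0.950",
                           str(rng.randrange(10_000_000, 35_000_000))])
        dropped["ppaxe_bad_symbol"] += 1

    def write_tsv(name: str, header: tuple[str, ...], rows: list[list[str]]) -> None:
        with open(out_dir / name, "w", encoding="utf-8", newline="") as handle:
            handle.write("\t".join(header) + "\n")
            for row in rows:
                handle.write("\t".join(row) + "\n")

    from .sources import (
        BIOGRID_COLUMNS,
        PPAXE_COLUMNS,
        STRING_ACTIONS_COLUMNS,
        STRING_LINKS_COLUMNS,
    )

    write_tsv("biogrid.tsv", BIOGRID_COLUMNS, biogrid_rows)
    write_tsv("string_links.tsv", STRING_LINKS_COLUMNS, string_rows)
    write_tsv("string_actions.tsv", STRING_ACTIONS_COLUMNS, action_rows)
    write_tsv("ppaxe.tsv", PPAXE_COLUMNS, ppaxe_rows)
    write_tsv(
        "aliases.tsv",
        ("alias", "official_symbol"),
        [[g, g] for g in genes] + sorted([a, g] for g, a in aliased.items()),
    )
    write_tsv(
        "drivers.tsv",
        ("symbol", "driver_class"),
        [[d, driver_classes[d].value] for d in drivers],
    )
    write_tsv(
        "expression.tsv",
        ("symbol", "value"),
        [[g, f"{rng.gauss(0.0, 2.0):.4f}"] for g in genes],
    )

    canonical = _canonical_edges(records)
    # Ground truth mirrors the built graph's node set: edge endpoints plus
    # drivers (isolated non-drivers never appear in any source file).
    digraph = nx.DiGraph()
    digraph.add_nodes_from(drivers)
    digraph.add_edges_from((s, d) for s, d, _ in canonical)
    skel_nodes, skel_edges, unconnected = _oracle_skeleton(digraph, drivers)
    level_of, saturation = _oracle_levels(digraph, skel_nodes)

    n_undirected = sum(1 for r in records if not r.directed)
    n_directed = sum(1 for r in records if r.directed)
    manifest = {
        "spec": {
            "seed": spec.seed,
            "n_genes": spec.n_genes,
            "n_drivers": spec.n_drivers,
            "p_edge": spec.p_edge,
            "frac_genetic": spec.frac_genetic,
            "frac_unknown": spec.frac_unknown,
            "alias_rate": spec.alias_rate,
            "n_isolated": spec.n_isolated,
            "planted_chains": list(spec.planted_chains),
        },
        "genes": genes,
        "drivers": {d: driver_classes[d].value for d in drivers},
        "isolated": isolated,
        "aliases": aliased,
        "ppaxe_threshold": PPAXE_THRESHOLD,
        "n_undirected_kept": n_undirected,
        "n_directed_kept": n_directed,
        "dropped_rows": dropped,
        "expected_raw_edges": [list(e) for e in _expected_edges(records)],
        "expected_canonical_edges": [list(e) for e in canonical],
        "ground_truth": {
            "skeleton_nodes": sorted(skel_nodes),
            "skeleton_edges": sorted(list(e) for e in skel_edges),
            "unconnected_drivers": unconnected,
            "level_of": {s: level_of[s] for s in sorted(level_of)},
            "saturation_level": saturation,
        },
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return manifest


# -- bundled worked example -------------------------------------------


@dataclass
class WorkedExample:
    """Hand-crafted dataset with a documented expected decomposition.

    Structure: a six-gene skeleton core over four connected retinal driver
    genes, two expansion shells, within-shell "curved" interactions, a
    whole-graph island with a self-loop, an isolated driver (mirroring
    mitochondrially encoded genes with no curated interactions) and an
    isolated non-driver.
    """

    edges: list[DirectedInteraction]
    drivers: dict[str, DriverClass]
    expected_levels: dict[str, object]
    expected_saturation: int
    expected_unconnected_drivers: list[str]
    expected_skeleton_nodes: set[str]


def _ev(source: SourceDB, detail: str) -> list[Evidence]:
    return [Evidence(source, detail=detail)]


def worked_example() -> WorkedExample:
    B, S, P = SourceDB.BIOGRID, SourceDB.STRING, SourceDB.PPAXE
    PH, GE, UN = InteractionType.PHYSICAL, InteractionType.GENETIC, InteractionType.UNKNOWN
    edges = [
        # skeleton core (level 0)
        DirectedInteraction("RHO", "SIRT1", PH, _ev(B, "two hybrid")),
        DirectedInteraction("SIRT1", "CRX", PH, _ev(S, "experimental")),
        DirectedInteraction("CRX", "SMAD4", PH, _ev(B, "affinity capture-ms")),
        DirectedInteraction("SMAD4", "NRL", PH, _ev(S, "database")),
        DirectedInteraction("NRL", "RHO", GE, _ev(B, "dosage rescue")),
        DirectedInteraction("NRL", "RHO", PH, _ev(B, "two hybrid")),  # parallel typed pair
        DirectedInteraction("CRX", "CERKL", PH, _ev(B, "fret")),
        DirectedInteraction("CERKL", "SIRT1", PH, _ev(S, "experimental")),
        # first shell (level 1)
        DirectedInteraction("PDE6B", "RHO", PH, _ev(B, "two hybrid")),
        DirectedInteraction("VHL", "CERKL", PH, _ev(S, "experimental")),
        DirectedInteraction("CERKL", "PPM1A", PH, _ev(B, "affinity capture-ms")),
        DirectedInteraction("SMAD4", "HNRNPK", UN, _ev(P, "text-mining")),
        DirectedInteraction("RHO", "RP1", PH, _ev(S, "database")),
        DirectedInteraction("NRL", "NR2E3", PH, _ev(B, "co-crystal structure")),
        DirectedInteraction("VHL", "PDE6B", PH, _ev(S, "experimental")),  # within-shell
        # second shell (level 2)
        DirectedInteraction("PIAS3", "VHL", PH, _ev(B, "two hybrid")),
        DirectedInteraction("HNRNPK", "MICAL3", UN, _ev(P, "text-mining")),
        DirectedInteraction("PRKN", "PDE6B", GE, _ev(B, "dosage lethality")),
        DirectedInteraction("PRKN", "PIAS3", PH, _ev(S, "experimental")),  # within-shell
        DirectedInteraction("CUL2", "VHL", PH, _ev(B, "affinity capture-ms")),
        DirectedInteraction("NR2E3", "ARL3", PH, _ev(S, "database")),
        # whole-graph island + self-reference
        DirectedInteraction("OPN1LW", "OPN1MW", PH, _ev(B, "two hybrid")),
        DirectedInteraction("GRK1", "GRK1", UN, _ev(P, "text-mining")),
    ]
    drivers = {
        "RHO": DriverClass.NON_SYNDROMIC,
        "CRX": DriverClass.NON_SYNDROMIC,
        "NRL": DriverClass.NON_SYNDROMIC,
        "CERKL": DriverClass.BOTH,
        "MT-ND4": DriverClass.SYNDROMIC,  # isolated: no curated interactions
    }
    expected_levels: dict[str, object] = {}
    for s in ("RHO", "CRX", "NRL", "CERKL", "SIRT1", "SMAD4"):
        expected_levels[s] = 0
    for s in ("PDE6B", "VHL", "PPM1A", "HNRNPK", "RP1", "NR2E3"):
        expected_levels[s] = 1
    for s in ("PIAS3", "MICAL3", "PRKN", "CUL2", "ARL3"):
        expected_levels[s] = 2
    for s in ("OPN1LW", "OPN1MW", "GRK1", "MT-ND4", "RBP3"):
        expected_levels[s] = WHOLE
    return WorkedExample(
        edges=edges,
        drivers=drivers,
        expected_levels=expected_levels,
        expected_saturation=2,
        expected_unconnected_drivers=["MT-ND4"],
        expected_skeleton_nodes={"RHO", "CRX", "NRL", "CERKL", "SIRT1", "SMAD4"},
    )


def worked_example_graph():
    """The worked example as a built graph (includes the isolated RBP3 node)."""
    from .graph import build_graph
    from .model import GeneNode

    example = worked_example()
    graph = build_graph(example.edges, example.drivers)
    graph.add_node(GeneNode("RBP3"))  # isolated non-driver
    return graph, example
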