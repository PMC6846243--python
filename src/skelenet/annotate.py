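"""Annotation layers, session persistence and interchange exports.

Annotation layers are generic numeric maps projected onto nodes (for
example retina absolute expression, or fold change versus other tissues);
projecting a layer never alters topology and layers can be swapped on the
fly.  Sessions capture a researcher's customized view — node set, edges,
annotations and exact layout positions — in versioned JSON, so a restored
session lays nodes out exactly as they were left.  Exports cover the
Cytoscape.js elements structure, GraphML, an edge-list TSV and Neo4j-style
bulk-import CSVs; all exports are pure (the graph is never mutated).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .model import (
    DirectedInteraction,
    DriverClass,
    Evidence,
    GeneNode,
    InteractionType,
    SourceDB,
)
from .graph import InteractionGraph

SESSION_FORMAT = "skelenet-session"
SESSION_VERSION = "1.0"


@dataclass
class AnnotationLayer:
    """A named numeric node-annotation map with a default for missing genes."""

    name: str
    values: dict[str, float]
    default: float = 0.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("annotation layer needs a non-empty name")
        for symbol, value in self.values.items():
            if not math.isfinite(value):
                raise ValueError(
                    f"layer {self.name!r}: non-finite value for {symbol!r}"
                )
        if not math.isfinite(self.default):
            raise ValueError(f"layer {self.name!r}: non-finite default")


def load_annotation_layer(path: Path, name: Optional[str] = None,
                          default: float = 0.0) -> AnnotationLayer:
    """Read a layer from a two-column TSV (symbol, value)."""
    path = Path(path)
    values: dict[str, float] = {}
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != ("symbol", "value"):
            raise ValueError(f"{path}: expected header ('symbol', 'value')")
        for row in reader:
            if not row or not row[0].strip():
                continue
            values[row[0].strip()] = float(row[1])
    return AnnotationLayer(name=name or path.stem, values=values, default=default)


def attach_layer(graph: InteractionGraph, layer: AnnotationLayer) -> InteractionGraph:
    """Project a layer onto every node; idempotent and topology-preserving."""
    for symbol, node in graph.nodes.items():
        node.annotations[layer.name] = layer.values.get(symbol, layer.default)
    return graph


# -- sessions ----------------------------------------------------------


@dataclass
class Session:
    """A persisted network view with exact layout positions."""

    nodes: list[dict]
    edges: list[dict]
    metadata: dict = field(default_factory=dict)


def _evidence_dict(ev: Evidence) -> dict:
    return {
        "source_db": ev.source_db.value,
        "detail": ev.detail,
        "reference": ev.reference,
        "score": ev.score,
    }


def save_session(
    graph: InteractionGraph,
    positions: dict[str, tuple[float, float]],
    path: Path,
    metadata: Optional[dict] = None,
) -> None:
    """Write a session file.  Every node must have a finite position."""
    missing = sorted(set(graph.nodes) - set(positions))
    if missing:
        raise ValueError(f"missing layout positions for: {missing}")
    for symbol, (x, y) in positions.items():
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValueError(f"non-finite position for {symbol!r}")
    nodes = []
    for symbol in sorted(graph.nodes):
        node = graph.node(symbol)
        x, y = positions[symbol]
        nodes.append(
            {
                "symbol": symbol,
                "level": node.level,
                "driver_class": node.driver_class.value,
                "annotations": dict(node.annotations),
                "position": {"x": x, "y": y},
            }
        )
    edges = [
        {
            "src": e.src,
            "dst": e.dst,
            "itype": e.itype.value,
            "evidences": [_evidence_dict(ev) for ev in e.evidences],
        }
        for e in sorted(graph.edges(), key=lambda e: (e.src, e.dst, e.itype.value))
    ]
    document = {
        "format": SESSION_FORMAT,
        "version": SESSION_VERSION,
        "metadata": metadata or {},
        "elements": {"nodes": nodes, "edges": edges},
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(document, handle, indent=1)
        handle.write("\n")


def load_session(path: Path) -> Session:
    """Read a session file, validating structure field by field."""
    with open(path, encoding="utf-8") as handle:
        try:
            document = json.load(handle)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: malformed session JSON ({exc})") from exc
    if document.get("format") != SESSION_FORMAT:
        raise ValueError(f"{path}: not a {SESSION_FORMAT} file")
    major = str(document.get("version", "")).split(".")[0]
    if major != SESSION_VERSION.split(".")[0]:
        raise ValueError(f"{path}: unsupported session version {document.get('version')!r}")
    elements = document.get("elements", {})
    nodes = elements.get("nodes", [])
    edges = elements.get("edges", [])
    symbols = set()
    for i, record in enumerate(nodes):
        for fieldname in ("symbol", "position"):
            if fieldname not in record:
                raise ValueError(f"{path}: node {i} missing field {fieldname!r}")
        pos = record["position"]
        if not all(isinstance(pos.get(k), (int, float)) and math.isfinite(pos[k])
                   for k in ("x", "y")):
            raise ValueError(f"{path}: node {record['symbol']!r} has a bad position")
        record.setdefault("level", None)          # older minor versions
        record.setdefault("driver_class", DriverClass.NONE.value)
        record.setdefault("annotations", {})
        symbols.add(record["symbol"])
    for i, record in enumerate(edges):
        for fieldname in ("src", "dst", "itype"):
            if fieldname not in record:
                raise ValueError(f"{path}: edge {i} missing field {fieldname!r}")
        if record["src"] not in symbols or record["dst"] not in symbols:
            raise ValueError(
                f"{path}: edge {record['src']}->{record['dst']} references "
                "a node absent from the session"
            )
        record.setdefault("evidences", [])
    return Session(nodes=nodes, edges=edges, metadata=document.get("metadata", {}))


def session_to_graph(
    session: Session,
) -> tuple[InteractionGraph, dict[str, tuple[float, float]]]:
    """Rebuild an :class:`InteractionGraph` and its positions from a session."""
    graph = InteractionGraph()
    positions: dict[str, tuple[float, float]] = {}
    for record in session.nodes:
        dclass = DriverClass(record["driver_class"])
        graph.add_node(
            GeneNode(
                symbol=record["symbol"],
                is_driver=dclass is not DriverClass.NONE,
                driver_class=dclass,
                level=record["level"],
                annotations=dict(record["annotations"]),
            )
        )
        positions[record["symbol"]] = (record["position"]["x"], record["position"]["y"])
    for record in session.edges:
        evidences = [
            Evidence(
                source_db=SourceDB(ev["source_db"]),
                detail=ev["detail"],
                reference=ev.get("reference"),
                score=ev.get("score"),
            )
            for ev in record["evidences"]
        ] or [Evidence(SourceDB.BIOGRID, detail="imported")]
        graph.add_edge(
            DirectedInteraction(record["src"], record["dst"],
                                InteractionType(record["itype"]), evidences)
        )
    return graph, positions


# -- interchange exports ----------------------------------------------


def export_cytoscape_json(
    graph: InteractionGraph,
    positions: Optional[dict[str, tuple[float, float]]] = None,
) -> dict:
    """Emit the Cytoscape.js ``elements`` structure.

    Parallel typed edges become separate edge elements, one per interaction
    type, mirroring the multi-arrow rendering convention.
    """
    positions = positions or {}
    nodes = []
    for symbol in sorted(graph.nodes):
        node = graph.node(symbol)
        element: dict = {
            "data": {
                "id": symbol,
                "level": node.level,
                "driver_class": node.driver_class.value,
                "annotations": dict(node.annotations),
            }
        }
        if symbol in positions:
            x, y = positions[symbol]
            element["position"] = {"x": x, "y": y}
        nodes.append(element)
    edges = [
        {
            "data": {
                "id": f"{e.src}--{e.itype.value}--{e.dst}",
                "source": e.src,
                "target": e.dst,
                "itype": e.itype.value,
                "n_evidences": len(e.evidences),
            }
        }
        for e in sorted(graph.edges(), key=lambda e: (e.src, e.dst, e.itype.value))
    ]
    document = {"elements": {"nodes": nodes, "edges": edges}}
    validate_cytoscape(document)
    return document


def validate_cytoscape(document: dict) -> None:
    """Structural validation of a Cytoscape.js elements document."""
    elements = document.get("elements")
    if not isinstance(elements, dict):
        raise ValueError("cytoscape document must contain an 'elements' object")
    node_ids = set()
    for element in elements.get("nodes", []):
        data = element.get("data", {})
        if not isinstance(data.get("id"), str) or not data["id"]:
            raise ValueError("every node element needs a non-empty data.id")
        node_ids.add(data["id"])
    for element in elements.get("edges", []):
        data = element.get("data", {})
        for key in ("source", "target"):
            if data.get(key) not in node_ids:
                raise ValueError(
                    f"edge {data.get('id')!r} references unknown node {data.get(key)!r}"
                )


def export_neo4j_bulk(graph: InteractionGraph, out_dir: Path) -> tuple[Path, Path]:
    """Write property-graph bulk-import CSVs (nodes + relationships).

    No database needs to be present; the files follow the
    ``symbol:ID`` / ``:START_ID`` / ``:END_ID`` / ``:TYPE`` header
    convention of graph bulk importers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes_path = out_dir / "nodes.csv"
    rels_path = out_dir / "relationships.csv"
    with open(nodes_path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["symbol:ID", ":LABEL", "level", "driver_class"])
        for symbol in sorted(graph.nodes):
            node = graph.node(symbol)
            label = "Driver;Gene" if node.is_driver else "Gene"
            writer.writerow([symbol, label,
                             "" if node.level is None else node.level,
                             node.driver_class.value])
    with open(rels_path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow([":START_ID", ":END_ID", ":TYPE", "n_evidences"])
        for e in sorted(graph.edges(), key=lambda e: (e.src, e.dst, e.itype.value)):
            writer.writerow([e.src, e.dst, e.itype.value, len(e.evidences)])
    return nodes_path, rels_path
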