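"""Parsers for the three interaction-source dialects.

Three tab-separated dialects are supported (column layouts frozen in
``docs/formats.md``; the fixture generator and the parsers share these
definitions):

* **BioGRID-like** — curated physical and genetic interactions with an
  experiment system per row.  Rows whose physical/genetic label is missing
  get their type deduced from the experiment system via an
  :class:`~skelenet.model.ExperimentTypeMap`; systems not in the map leave
  the row untyped.
* **STRING-like** — protein pairs with per-channel evidence scores, plus an
  optional actions file carrying directionality tags.  Pairs without any
  score in the configured evidence channels are discarded (prediction-only
  associations).
* **PPaxe-like** — text-mining output: gene pair, classifier score in
  [0, 1], PubMed id.  Filtered by score threshold and by membership of both
  symbols in the official nomenclature.

Undirected surviving records are expanded to both directions (A->B and
B->A); genetic records are taken as unidirectional in listed order.  All
readers are gzip-transparent and skip (but count) malformed rows.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import yaml

from .model import (
    DEFAULT_TYPE_MAP,
    Direction,
    DirectedInteraction,
    Evidence,
    ExperimentTypeMap,
    InteractionType,
    RawRecord,
    SourceDB,
)

logger = logging.getLogger(__name__)

# Frozen dialect headers (see docs/formats.md).
BIOGRID_COLUMNS = (
    "gene_a",
    "gene_b",
    "taxid_a",
    "taxid_b",
    "interaction_label",
    "experiment_system",
    "direction",
)
STRING_CHANNELS = ("neighborhood", "coexpression", "experimental", "database", "textmining")
STRING_LINKS_COLUMNS = ("gene_a", "gene_b", "taxid_a", "taxid_b") + STRING_CHANNELS
STRING_ACTIONS_COLUMNS = ("gene_a", "gene_b", "direction")
PPAXE_COLUMNS = ("gene_a", "gene_b", "score", "pmid")

#: STRING channels that count as actual evidence (not prediction/text-mining).
DEFAULT_EVIDENCE_CHANNELS = frozenset({"experimental", "database"})

_EMPTY = {"", "-", "na", "none"}


@dataclass
class ParseReport:
    """Kept/dropped tallies for one source file."""

    source: SourceDB
    kept: int = 0
    dropped_taxid: int = 0
    dropped_score: int = 0
    dropped_symbol: int = 0
    malformed: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def dropped(self) -> int:
        return self.dropped_taxid + self.dropped_score + self.dropped_symbol

    def log(self) -> None:
        logger.info(
            "%s: kept %d records (dropped %d, malformed %d)",
            self.source.value,
            self.kept,
            self.dropped,
            self.malformed,
        )


def _open_text(path: Path):
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot read interaction file: {path}")
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8", newline="")
    return open(path, "rt", encoding="utf-8", newline="")


def _rows(path: Path, columns: tuple[str, ...]) -> Iterator[tuple[int, dict]]:
    """Yield (line_number, row_dict) from a headered TSV, checking the header."""
    with _open_text(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header {columns}")
        if tuple(header) != columns:
            raise ValueError(
                f"{path}: unexpected header {tuple(header)!r}; this dialect "
                f"requires {columns!r}"
            )
        for lineno, values in enumerate(reader, start=2):
            if not values or (len(values) == 1 and not values[0].strip()):
                continue
            yield lineno, dict(zip(columns, values)) if len(values) == len(columns) else {
                "__bad__": values
            }


def _expand(record: RawRecord, itype: InteractionType, evidence: Evidence) -> list[DirectedInteraction]:
    """Turn one raw record into directed edges.

    Genetic interactions are unidirectional in listed order; physical and
    untyped interactions with no direction tag are assumed bidirectional.
    """
    a, b = record.symbol_a, record.symbol_b
    if itype is InteractionType.GENETIC:
        pairs = [(a, b)]
    elif record.direction_tag is Direction.A_TO_B:
        pairs = [(a, b)]
    elif record.direction_tag is Direction.B_TO_A:
        pairs = [(b, a)]
    else:
        pairs = [(a, b), (b, a)]
    return [DirectedInteraction(s, d, itype, [evidence]) for s, d in pairs]


def parse_biogrid(
    path: Path,
    taxid: int = 9606,
    type_map: ExperimentTypeMap = DEFAULT_TYPE_MAP,
) -> tuple[list[DirectedInteraction], ParseReport]:
    """Parse a BioGRID-like TSV into directed typed edges.

    Rows where either interactor belongs to another organism (including
    artificially induced trans-species interactions) are dropped.  The
    interaction type comes from the explicit physical/genetic label when
    present, else is deduced from the experiment system, else UNKNOWN.
    """
    if taxid <= 0:
        raise ValueError("taxid must be positive")
    report = ParseReport(SourceDB.BIOGRID)
    edges: list[DirectedInteraction] = []
    for lineno, row in _rows(path, BIOGRID_COLUMNS):
        if "__bad__" in row:
            report.malformed += 1
            logger.warning("%s:%d: malformed row skipped", path, lineno)
            continue
        try:
            ta, tb = int(row["taxid_a"]), int(row["taxid_b"])
            record = RawRecord(
                source_db=SourceDB.BIOGRID,
                symbol_a=row["gene_a"].strip(),
                symbol_b=row["gene_b"].strip(),
                taxid_a=ta,
                taxid_b=tb,
                itype_label=row["interaction_label"].strip().lower() or None,
                experiment_system=row["experiment_system"].strip() or None,
                direction_tag=_parse_direction(row["direction"]),
            )
        except (KeyError, ValueError) as exc:
            report.malformed += 1
            logger.warning("%s:%d: malformed row skipped (%s)", path, lineno, exc)
            continue
        if record.taxid_a != taxid or record.taxid_b != taxid:
            report.dropped_taxid += 1
            continue
        label = record.itype_label if record.itype_label not in _EMPTY else None
        if label == "physical":
            itype = InteractionType.PHYSICAL
        elif label == "genetic":
            itype = InteractionType.GENETIC
        else:
            itype = type_map.deduce(record.experiment_system) or InteractionType.UNKNOWN
        evidence = Evidence(SourceDB.BIOGRID, detail=record.experiment_system or "unspecified")
        edges.extend(_expand(record, itype, evidence))
        report.kept += 1
    report.log()
    return edges, report


def _parse_direction(value: str) -> Direction:
    value = value.strip().lower()
    if value in _EMPTY or value == "unknown":
        return Direction.UNKNOWN
    if value == "a_to_b":
        return Direction.A_TO_B
    if value == "b_to_a":
        return Direction.B_TO_A
    raise ValueError(f"bad direction tag {value!r}")


def parse_string(
    links_path: Path,
    actions_path: Optional[Path] = None,
    taxid: int = 9606,
    evidence_channels: frozenset[str] = DEFAULT_EVIDENCE_CHANNELS,
) -> tuple[list[DirectedInteraction], ParseReport]:
    """Parse STRING-like protein links, keeping only evidence-backed pairs.

    A pair survives when at least one configured evidence channel has a
    positive score; prediction-only pairs (e.g. text-mining or co-expression
    alone) are discarded.  Direction tags from the actions file orient the
    pair; untagged pairs are assumed bidirectional.  Surviving links are
    typed PHYSICAL: they are protein–protein associations.
    """
    unknown = frozenset(evidence_channels) - set(STRING_CHANNELS)
    if unknown:
        raise ValueError(f"unknown STRING channels: {sorted(unknown)}")
    directions: dict[tuple[str, str], Direction] = {}
    if actions_path is not None:
        for lineno, row in _rows(actions_path, STRING_ACTIONS_COLUMNS):
            if "__bad__" in row:
                logger.warning("%s:%d: malformed action row skipped", actions_path, lineno)
                continue
            try:
                tag = _parse_direction(row["direction"])
            except ValueError as exc:
                logger.warning("%s:%d: %s", actions_path, lineno, exc)
                continue
            directions[(row["gene_a"].strip(), row["gene_b"].strip())] = tag

    report = ParseReport(SourceDB.STRING)
    edges: list[DirectedInteraction] = []
    seen_pairs: set[tuple[str, str]] = set()
    for lineno, row in _rows(links_path, STRING_LINKS_COLUMNS):
        if "__bad__" in row:
            report.malformed += 1
            logger.warning("%s:%d: malformed row skipped", links_path, lineno)
            continue
        try:
            scores = {c: float(row[c]) for c in STRING_CHANNELS if row[c].strip() not in _EMPTY}
            record = RawRecord(
                source_db=SourceDB.STRING,
                symbol_a=row["gene_a"].strip(),
                symbol_b=row["gene_b"].strip(),
                taxid_a=int(row["taxid_a"]),
                taxid_b=int(row["taxid_b"]),
                channel_scores=scores,
            )
        except (KeyError, ValueError) as exc:
            report.malformed += 1
            logger.warning("%s:%d: malformed row skipped (%s)", links_path, lineno, exc)
            continue
        if record.taxid_a != taxid or record.taxid_b != taxid:
            report.dropped_taxid += 1
            continue
        qualifying = {
            c: s for c, s in record.channel_scores.items() if c in evidence_channels and s > 0
        }
        if not qualifying:
            report.dropped_score += 1
            continue
        pair = (record.symbol_a, record.symbol_b)
        record.direction_tag = directions.get(pair, Direction.UNKNOWN)
        seen_pairs.add(pair)
        evidences = [
            Evidence(SourceDB.STRING, detail=channel, score=score)
            for channel, score in sorted(qualifying.items())
        ]
        a, b = record.symbol_a, record.symbol_b
        if record.direction_tag is Direction.A_TO_B:
            oriented = [(a, b)]
        elif record.direction_tag is Direction.B_TO_A:
            oriented = [(b, a)]
        else:
            oriented = [(a, b), (b, a)]
        for s, d in oriented:
            edges.append(DirectedInteraction(s, d, InteractionType.PHYSICAL, list(evidences)))
        report.kept += 1
    orphans = set(directions) - seen_pairs
    if orphans:
        report.notes.append(f"{len(orphans)} action records without a matching link ignored")
        logger.warning("%d STRING action records reference absent pairs; ignored", len(orphans))
    report.log()
    return edges, report


def parse_ppaxe(
    path: Path,
    score_threshold: float = 0.5,
    valid_symbols: Optional[set[str]] = None,
    alias_table=None,
) -> tuple[list[DirectedInteraction], ParseReport]:
    """Parse text-mining output, filtering by score and official nomenclature.

    The classifier cannot distinguish genetic from protein interactions, so
    every surviving record is typed UNKNOWN and expanded to both directions
    (no directionality is inferred by the miner).  Evidence carries the
    PubMed id the interaction was extracted from.

    ``valid_symbols`` is the official symbol universe; when an
    ``alias_table`` is given, symbols are unaliased before the membership
    check so that alias spellings of official genes survive.
    """
    if not (0.0 <= score_threshold <= 1.0):
        raise ValueError("score_threshold must be within [0, 1]")
    report = ParseReport(SourceDB.PPAXE)
    edges: list[DirectedInteraction] = []
    warned_pmid = False
    for lineno, row in _rows(path, PPAXE_COLUMNS):
        if "__bad__" in row:
            report.malformed += 1
            logger.warning("%s:%d: malformed row skipped", path, lineno)
            continue
        try:
            record = RawRecord(
                source_db=SourceDB.PPAXE,
                symbol_a=row["gene_a"].strip(),
                symbol_b=row["gene_b"].strip(),
                taxid_a=9606,
                taxid_b=9606,
                score=float(row["score"]),
                pmid=row["pmid"].strip() or None,
            )
        except (KeyError, ValueError) as exc:
            report.malformed += 1
            logger.warning("%s:%d: malformed row skipped (%s)", path, lineno, exc)
            continue
        if record.score < score_threshold:
            report.dropped_score += 1
            continue
        if valid_symbols is not None:
            resolved = []
            for symbol in (record.symbol_a, record.symbol_b):
                if alias_table is not None:
                    official = alias_table.resolve(symbol)
                else:
                    official = symbol if symbol in valid_symbols else None
                resolved.append(official)
            if any(r is None or r not in valid_symbols for r in resolved):
                report.dropped_symbol += 1
                continue
        if record.pmid is None and not warned_pmid:
            logger.warning("%s: records without a PMID; evidence reference left empty", path)
            warned_pmid = True
        evidence = Evidence(SourceDB.PPAXE, detail="text-mining",
                            reference=record.pmid, score=record.score)
        edges.extend(_expand(record, InteractionType.UNKNOWN, evidence))
        report.kept += 1
    report.log()
    return edges, report


@dataclass
class SourceConfig:
    """Per-source ingestion options, loadable from YAML."""

    taxid: int = 9606
    evidence_channels: frozenset[str] = DEFAULT_EVIDENCE_CHANNELS
    ppaxe_threshold: float = 0.5
    type_map: ExperimentTypeMap = DEFAULT_TYPE_MAP

    @classmethod
    def from_yaml(cls, path: Path) -> "SourceConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        kwargs: dict = {}
        if "taxid" in raw:
            kwargs["taxid"] = int(raw["taxid"])
        if "evidence_channels" in raw:
            kwargs["evidence_channels"] = frozenset(raw["evidence_channels"])
        if "ppaxe_threshold" in raw:
            kwargs["ppaxe_threshold"] = float(raw["ppaxe_threshold"])
        if "type_map" in raw:
            kwargs["type_map"] = ExperimentTypeMap(
                physical_systems=frozenset(raw["type_map"].get("physical", ())),
                genetic_systems=frozenset(raw["type_map"].get("genetic", ())),
            )
        return cls(**kwargs)
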