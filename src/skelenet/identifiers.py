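"""Gene-symbol unaliasing against an official nomenclature table.

Interaction sources spell the same gene many ways (historic aliases,
mixed-case text-mining hits).  Before graph construction every endpoint is
rewritten to its one official symbol; edges that collapse onto the same
(src, dst, type) triple after rewriting are merged with their evidence
concatenated.  Matching is case-insensitive.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .model import DirectedInteraction

logger = logging.getLogger(__name__)


@dataclass
class AliasTable:
    """Alias -> official-symbol mapping.

    Every canonical symbol implicitly maps to itself.  An alias mapping to
    two different canonicals is a data error and rejected at load time.
    """

    canonical: set[str]
    alias_to_canonical: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.alias_to_canonical.values()) - self.canonical
        if bad:
            raise ValueError(f"aliases map to unknown canonical symbols: {sorted(bad)}")
        self._lookup = {c.lower(): c for c in self.canonical}
        for alias, official in self.alias_to_canonical.items():
            key = alias.lower()
            existing = self._lookup.get(key)
            if existing is not None and existing != official:
                raise ValueError(
                    f"alias {alias!r} maps to both {existing!r} and {official!r}"
                )
            self._lookup[key] = official

    def resolve(self, symbol: str) -> Optional[str]:
        """Return the official symbol for ``symbol``, or None if unknown."""
        if not symbol:
            raise ValueError("cannot resolve an empty symbol")
        return self._lookup.get(symbol.lower())


def load_alias_table(path: Path) -> AliasTable:
    """Load an alias table from a two-column TSV (alias, official_symbol).

    A row whose alias equals its official symbol declares the canonical
    symbol itself.  Duplicate conflicting alias rows raise.
    """
    canonical: set[str] = set()
    aliases: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != ("alias", "official_symbol"):
            raise ValueError(f"{path}: expected header ('alias', 'official_symbol')")
        rows = [tuple(r) for r in reader if r and any(f.strip() for f in r)]
    for row in rows:
        if len(row) != 2:
            raise ValueError(f"{path}: bad alias row {row!r}")
        _, official = row
        canonical.add(official.strip())
    for alias, official in rows:
        alias, official = alias.strip(), official.strip()
        if alias.lower() in {a.lower() for a in aliases} and aliases.get(alias) != official:
            prev = next(v for k, v in aliases.items() if k.lower() == alias.lower())
            if prev != official:
                raise ValueError(f"{path}: alias {alias!r} maps to {prev!r} and {official!r}")
        aliases[alias] = official
    return AliasTable(canonical=canonical, alias_to_canonical=aliases)


@dataclass
class UnaliasReport:
    """Counts from one unaliasing pass."""

    renamed: int = 0
    dropped: int = 0
    merged: int = 0
    unresolved_symbols: set[str] = field(default_factory=set)


def unalias_edges(
    edges: list[DirectedInteraction],
    table: AliasTable,
    drop_unknown: bool = True,
) -> tuple[list[DirectedInteraction], UnaliasReport]:
    """Rewrite every endpoint to its official symbol and merge collapsing edges.

    Edges with an unresolvable endpoint are dropped when ``drop_unknown``,
    otherwise kept verbatim (flagged in the report).  Merging concatenates
    evidence lists, so evidence records are conserved across the pass for
    every edge that is not dropped.  Output order is first-appearance order,
    making the pass deterministic and idempotent.
    """
    report = UnaliasReport()
    merged: dict[tuple, DirectedInteraction] = {}
    for edge in edges:
        src = table.resolve(edge.src)
        dst = table.resolve(edge.dst)
        if src is None or dst is None:
            report.unresolved_symbols.update(
                s for s, r in ((edge.src, src), (edge.dst, dst)) if r is None
            )
            if drop_unknown:
                report.dropped += 1
                continue
            src, dst = edge.src, edge.dst
        elif src != edge.src or dst != edge.dst:
            report.renamed += 1
        key = (src, dst, edge.itype)
        if key in merged:
            merged[key].evidences.extend(edge.evidences)
            report.merged += 1
        else:
            merged[key] = DirectedInteraction(src, dst, edge.itype, list(edge.evidences))
    if report.unresolved_symbols:
        logger.info("unaliasing: %d symbols unresolved", len(report.unresolved_symbols))
    return list(merged.values()), report
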