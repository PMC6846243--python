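"""Core record types shared across the toolkit.

The interactome is modelled as a directed multigraph over official gene
symbols.  Edges are typed (physical, genetic, or unknown for text-mining
derived interactions) and each typed edge carries one or more provenance
:class:`Evidence` records naming the source database, the experiment or
evidence channel, and an optional literature reference and score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class SourceDB(str, Enum):
    """Interaction source database."""

    BIOGRID = "BIOGRID"
    STRING = "STRING"
    PPAXE = "PPAXE"


class InteractionType(str, Enum):
    """Edge type: physical protein contact, genetic interaction, or untyped."""

    PHYSICAL = "PHYSICAL"
    GENETIC = "GENETIC"
    UNKNOWN = "UNKNOWN"


class Direction(str, Enum):
    """Directionality tag of a raw interaction record."""

    A_TO_B = "A_TO_B"
    B_TO_A = "B_TO_A"
    UNKNOWN = "UNKNOWN"


class DriverClass(str, Enum):
    """Clinical class of a driver gene.

    Syndromic drivers cause disease with extra-ocular manifestations,
    non-syndromic without; BOTH marks genes reported in either form and
    NONE marks non-driver genes.
    """

    SYNDROMIC = "SYNDROMIC"
    NON_SYNDROMIC = "NON_SYNDROMIC"
    BOTH = "BOTH"
    NONE = "NONE"


#: Sentinel level label for nodes outside every expansion shell
#: (the whole-graph remainder).
WHOLE = "whole"


@dataclass(frozen=True)
class Evidence:
    """One provenance record supporting a directed interaction."""

    source_db: SourceDB
    detail: str  # experiment system, evidence channel, or "text-mining"
    reference: Optional[str] = None  # PMID or external id
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.source_db, SourceDB):
            object.__setattr__(self, "source_db", SourceDB(self.source_db))


@dataclass
class RawRecord:
    """A parsed source row before normalization into directed edges."""

    source_db: SourceDB
    symbol_a: str
    symbol_b: str
    taxid_a: int
    taxid_b: int
    itype_label: Optional[str] = None
    experiment_system: Optional[str] = None
    direction_tag: Direction = Direction.UNKNOWN
    channel_scores: dict[str, float] = field(default_factory=dict)
    score: Optional[float] = None
    pmid: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.symbol_a or not self.symbol_b:
            raise ValueError("interactor symbols must be non-empty")
        if any(v < 0 for v in self.channel_scores.values()):
            raise ValueError("channel scores must be non-negative")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score!r} outside [0, 1]")


@dataclass
class DirectedInteraction:
    """A typed directed edge src -> dst with non-empty supporting evidence.

    Self-references (src == dst) are permitted; many text-mined and
    autoregulatory interactions are self-loops.
    """

    src: str
    dst: str
    itype: InteractionType
    evidences: list[Evidence]

    def __post_init__(self) -> None:
        if not isinstance(self.itype, InteractionType):
            self.itype = InteractionType(self.itype)
        if not self.evidences:
            raise ValueError(f"edge {self.src}->{self.dst} has no evidence")

    @property
    def key(self) -> tuple[str, str, InteractionType]:
        """Merge identity: parallel edges are distinct only by type."""
        return (self.src, self.dst, self.itype)


@dataclass(frozen=True)
class ExperimentTypeMap:
    """Deduction table from experiment system names to interaction types.

    Systems listed in neither set yield no deduction (callers fall back to
    :data:`InteractionType.UNKNOWN`).
    """

    physical_systems: frozenset[str]
    genetic_systems: frozenset[str]

    def __post_init__(self) -> None:
        phys = frozenset(s.lower() for s in self.physical_systems)
        gen = frozenset(s.lower() for s in self.genetic_systems)
        if phys & gen:
            raise ValueError(f"ambiguous experiment systems: {sorted(phys & gen)}")
        object.__setattr__(self, "physical_systems", phys)
        object.__setattr__(self, "genetic_systems", gen)

    def deduce(self, experiment_system: Optional[str]) -> Optional[InteractionType]:
        if experiment_system is None:
            return None
        system = experiment_system.lower()
        if system in self.physical_systems:
            return InteractionType.PHYSICAL
        if system in self.genetic_systems:
            return InteractionType.GENETIC
        return None


#: Default experiment-type deduction table.  Physical systems are direct
#: protein-contact assays; genetic systems are phenotype-based dosage and
#: rescue assays.  Systems absent from both sets stay untyped.
DEFAULT_TYPE_MAP = ExperimentTypeMap(
    physical_systems=frozenset(
        {
            "affinity capture-luminescence",
            "affinity capture-ms",
            "affinity capture-rna",
            "affinity capture-western",
            "co-crystal structure",
            "co-fractionation",
            "co-purification",
            "far western",
            "fret",
            "pca",
            "proximity label-ms",
            "reconstituted complex",
            "two hybrid",
        }
    ),
    genetic_systems=frozenset(
        {
            "dosage growth defect",
            "dosage lethality",
            "dosage rescue",
            "negative genetic",
            "phenotypic enhancement",
            "phenotypic suppression",
            "positive genetic",
            "synthetic growth defect",
            "synthetic lethality",
            "synthetic rescue",
        }
    ),
)


@dataclass
class GeneNode:
    """A gene in the interactome with driver status and annotation layers."""

    symbol: str
    is_driver: bool = False
    driver_class: DriverClass = DriverClass.NONE
    level: object = None  # int >= 0, WHOLE, or None before decomposition
    annotations: dict[str, float] = field(default_factory=dict)
    variant_count: Optional[int] = None

    def __post_init__(self) -> None:
        if not isinstance(self.driver_class, DriverClass):
            self.driver_class = DriverClass(self.driver_class)
        if self.is_driver != (self.driver_class is not DriverClass.NONE):
            raise ValueError(
                f"{self.symbol}: is_driver must match driver_class "
                f"({self.driver_class.value})"
            )
        if isinstance(self.level, int) and self.level < 0:
            raise ValueError(f"{self.symbol}: negative level {self.level}")
        if self.variant_count is not None and self.variant_count < 0:
            raise ValueError(f"{self.symbol}: negative variant_count")


@dataclass
class PathResult:
    """A shortest directed path, as an ordered node sequence.

    ``edge_types[i]`` is the set of interaction types of the parallel edges
    joining ``nodes[i]`` to ``nodes[i+1]`` — a path is a node sequence, so
    parallel typed edges never multiply paths.
    """

    nodes: list[str]
    edge_types: list[frozenset[InteractionType]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.edge_types and len(self.edge_types) != len(self.nodes) - 1:
            raise ValueError("edge_types must have one entry per step")

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1


def is_finite_number(x: object) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)
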