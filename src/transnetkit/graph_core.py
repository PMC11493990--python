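"""Multilayer trans-omics network data model.

A trans-omics network links molecules measured in different omics layers
(mRNA, protein, metabolite) to inferred regulators (transcription factors,
miRNAs, metabolic reactions, transporters) through typed, optionally signed
edges.  All builders and analyses in this package operate on the
:class:`TransOmicsNetwork` container defined here.

Nodes are keyed by ``(id, layer, compartment)`` so that the same metabolite
measured in tissue and in blood is represented by two distinct nodes — the
metabolite-exchange network relies on this distinction.  Parallel edges
between the same pair of nodes are permitted only when their ``edge_type``
differs (a metabolite can be both a substrate and an allosteric activator
of the same reaction); exact ``(source, target, edge_type)`` duplicates
collapse to a single edge that keeps the first evidence string seen.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple

import networkx as nx

__all__ = [
    "Layer",
    "Compartment",
    "Direction",
    "EdgeType",
    "Sign",
    "Molecule",
    "RegulationEdge",
    "TransOmicsNetwork",
    "NodeKey",
    "DirectionConflictError",
    "validate_network",
    "subgraph_by_layers",
    "merge_networks",
]


class Layer(str, enum.Enum):
    """Omics layer / molecular category of a node."""

    TF = "TF"
    MIRNA = "miRNA"
    MRNA = "mRNA"
    PROTEIN = "protein"
    REACTION = "reaction"
    METABOLITE = "metabolite"
    TRANSPORTER = "transporter"


class Compartment(str, enum.Enum):
    TISSUE = "tissue"
    BLOOD = "blood"
    NONE = "none"


class Direction(str, enum.Enum):
    """Response direction of a measured molecule.

    Knowledge-base-only nodes (inferred TFs, reactions, ...) default to
    ``UNKNOWN``; only measured molecules carry increased/decreased.
    """

    INCREASED = "increased"
    DECREASED = "decreased"
    UNCHANGED = "unchanged"
    UNKNOWN = "unknown"


class EdgeType(str, enum.Enum):
    TF_TARGET = "tf_target"
    MIRNA_TARGET = "mirna_target"
    PPI = "ppi"
    ENZYME_MRNA = "enzyme_mrna"
    SUBSTRATE = "substrate"
    PRODUCT = "product"
    ALLOSTERIC_ACTIVATION = "allosteric_activation"
    ALLOSTERIC_INHIBITION = "allosteric_inhibition"
    TRANSPORTER_MRNA = "transporter_mrna"
    TRANSPORT_SUBSTRATE = "transport_substrate"


#: Edge types that carry a differential-regulation sign once built from
#: measured molecules (builders C and D).
SIGNED_EDGE_TYPES = frozenset(
    {
        EdgeType.ENZYME_MRNA,
        EdgeType.SUBSTRATE,
        EdgeType.PRODUCT,
        EdgeType.ALLOSTERIC_ACTIVATION,
        EdgeType.ALLOSTERIC_INHIBITION,
        EdgeType.TRANSPORTER_MRNA,
        EdgeType.TRANSPORT_SUBSTRATE,
    }
)


class Sign(str, enum.Enum):
    ACTIVATING = "activating"
    INHIBITING = "inhibiting"
    UNSIGNED = "unsigned"


NodeKey = Tuple[str, Layer, Compartment]


class DirectionConflictError(ValueError):
    """Raised when merging assigns conflicting concrete directions to a node."""


@dataclass(frozen=True)
class Molecule:
    """A typed network node.

    ``(id, layer, compartment)`` is the unique node key.  ``pathway_id`` is
    an optional annotation used by pathway layouts (reaction nodes carry the
    id of the metabolic pathway they belong to).
    """

    id: str
    layer: Layer
    compartment: Compartment = Compartment.NONE
    direction: Direction = Direction.UNKNOWN
    pathway_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Molecule id must be non-empty")
        object.__setattr__(self, "layer", Layer(self.layer))
        object.__setattr__(self, "compartment", Compartment(self.compartment))
        object.__setattr__(self, "direction", Direction(self.direction))

    @property
    def key(self) -> NodeKey:
        return (self.id, self.layer, self.compartment)


@dataclass(frozen=True)
class RegulationEdge:
    """A typed, optionally signed, directed interaction.

    PPI edges are stored once per unordered pair in canonical (sorted key)
    order and are treated as bidirectional by all analyses.
    """

    source: NodeKey
    target: NodeKey
    edge_type: EdgeType
    sign: Sign = Sign.UNSIGNED
    evidence: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "edge_type", EdgeType(self.edge_type))
        object.__setattr__(self, "sign", Sign(self.sign))
        source = _coerce_key(self.source)
        target = _coerce_key(self.target)
        if self.edge_type is EdgeType.PPI and source > target:
            source, target = target, source
        object.__setattr__(self, "source", source)
        object.__setattr__(self, "target", target)

    @property
    def key(self) -> Tuple[NodeKey, NodeKey, EdgeType]:
        return (self.source, self.target, self.edge_type)


def _coerce_key(key: Sequence) -> NodeKey:
    ident, layer, compartment = key
    return (str(ident), Layer(layer), Compartment(compartment))


class TransOmicsNetwork:
    """Directed multigraph with typed, signed edges.

    The central artifact of every builder.  ``metadata`` records build
    parameters (thresholds, knowledge-base provenance) so a network is
    self-describing.
    """

    def __init__(self, metadata: Optional[Mapping] = None) -> None:
        self._nodes: dict[NodeKey, Molecule] = {}
        self._edges: dict[Tuple[NodeKey, NodeKey, EdgeType], RegulationEdge] = {}
        self.metadata: dict = dict(metadata or {})

    # -- construction -------------------------------------------------
    def add_molecule(self, mol: Molecule) -> Molecule:
        """Add a node; re-adding the same key keeps the existing record
        unless the new one carries a concrete direction and the old one
        does not."""
        existing = self._nodes.get(mol.key)
        if existing is None:
            self._nodes[mol.key] = mol
            return mol
        if (
            existing.direction is Direction.UNKNOWN
            and mol.direction is not Direction.UNKNOWN
        ):
            self._nodes[mol.key] = replace(
                existing, direction=mol.direction, pathway_id=existing.pathway_id or mol.pathway_id
            )
        elif existing.pathway_id is None and mol.pathway_id is not None:
            self._nodes[mol.key] = replace(existing, pathway_id=mol.pathway_id)
        return self._nodes[mol.key]

    def add_edge(self, edge: RegulationEdge) -> RegulationEdge:
        """Add an edge; exact (source, target, edge_type) duplicates collapse
        to the first edge added."""
        return self._edges.setdefault(edge.key, edge)

    # -- accessors ----------------------------------------------------
    @property
    def nodes(self) -> Tuple[Molecule, ...]:
        return tuple(self._nodes.values())

    @property
    def edges(self) -> Tuple[RegulationEdge, ...]:
        return tuple(self._edges.values())

    @property
    def node_keys(self) -> frozenset:
        return frozenset(self._nodes)

    def get_node(self, key: Sequence) -> Molecule:
        return self._nodes[_coerce_key(key)]

    def has_node(self, key: Sequence) -> bool:
        return _coerce_key(key) in self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges_incident(self, key: Sequence) -> Iterator[RegulationEdge]:
        k = _coerce_key(key)
        for edge in self._edges.values():
            if edge.source == k or edge.target == k:
                yield edge

    def __eq__(self, other) -> bool:
        if not isinstance(other, TransOmicsNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return f"TransOmicsNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    # -- graph views --------------------------------------------------
    def to_multidigraph(self) -> nx.MultiDiGraph:
        """Full-fidelity networkx view; node ids are the node keys, edge
        keys are edge types."""
        g = nx.MultiDiGraph()
        for key, mol in self._nodes.items():
            g.add_node(
                key,
                layer=mol.layer.value,
                compartment=mol.compartment.value,
                direction=mol.direction.value,
                pathway_id=mol.pathway_id or "",
            )
        for edge in self._edges.values():
            g.add_edge(
                edge.source,
                edge.target,
                key=edge.edge_type.value,
                edge_type=edge.edge_type.value,
                sign=edge.sign.value,
                evidence=edge.evidence,
            )
        return g

    def to_simple_undirected(self) -> nx.Graph:
        """Simple undirected projection: direction, edge type multiplicity
        and self-loops are dropped.  Global topology metrics (degree
        distribution, density, clustering, assortativity) are defined on
        this projection."""
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        for edge in self._edges.values():
            if edge.source != edge.target:
                g.add_edge(edge.source, edge.target)
        return g


# ---------------------------------------------------------------------------
# module operations
# ---------------------------------------------------------------------------

def validate_network(net: TransOmicsNetwork) -> list[str]:
    """Check the container invariants; returns a list of human-readable
    violations (empty iff the network is well formed)."""
    violations: list[str] = []
    keys = net.node_keys
    for edge in net.edges:
        if edge.source not in keys:
            violations.append(f"dangling endpoint: edge {edge.key} source not in nodes")
        if edge.target not in keys:
            violations.append(f"dangling endpoint: edge {edge.key} target not in nodes")
        if edge.edge_type is EdgeType.PPI:
            if edge.sign is not Sign.UNSIGNED:
                violations.append(f"ppi must be unsigned: edge {edge.key}")
            if edge.source == edge.target:
                violations.append(f"ppi self-loop: edge {edge.key}")
            if edge.source > edge.target:
                violations.append(f"ppi not canonical order: edge {edge.key}")
    for mol in net.nodes:
        if not mol.id:
            violations.append(f"empty node id: {mol.key}")
    return violations


def subgraph_by_layers(
    net: TransOmicsNetwork, layers: Iterable[Layer]
) -> TransOmicsNetwork:
    """Restrict to nodes whose layer is in ``layers`` and edges with both
    endpoints retained.  Metadata is preserved."""
    layer_set = {Layer(l) for l in layers}
    if not layer_set:
        raise ValueError("layers must be a non-empty set of Layer values")
    out = TransOmicsNetwork(metadata=net.metadata)
    for mol in net.nodes:
        if mol.layer in layer_set:
            out.add_molecule(mol)
    kept = out.node_keys
    for edge in net.edges:
        if edge.source in kept and edge.target in kept:
            out.add_edge(edge)
    return out


def merge_networks(nets: Sequence[TransOmicsNetwork]) -> TransOmicsNetwork:
    """Union of networks.

    Node sets merge by key; an ``unknown`` direction is absorbed by any
    concrete direction, while two conflicting concrete directions raise
    :class:`DirectionConflictError` (inputs are per-condition, so a true
    conflict indicates user error).  Exact-duplicate edges collapse.
    """
    out = TransOmicsNetwork()
    conflicts: list[NodeKey] = []
    for net in nets:
        out.metadata.update(net.metadata)
        for mol in net.nodes:
            existing = out._nodes.get(mol.key)
            if (
                existing is not None
                and existing.direction is not Direction.UNKNOWN
                and mol.direction is not Direction.UNKNOWN
                and existing.direction is not mol.direction
            ):
                conflicts.append(mol.key)
                continue
            out.add_molecule(mol)
        for edge in net.edges:
            out.add_edge(edge)
    if conflicts:
        raise DirectionConflictError(
            "conflicting directions for node keys: "
            + ", ".join(repr(k) for k in sorted(set(conflicts)))
        )
    return out
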