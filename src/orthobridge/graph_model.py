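"""Minimal in-memory labeled-property graph.

Nodes carry a non-empty set of labels plus key-value properties; edges are
directed, typed, and may carry properties of their own.  A schema registry
constrains which labels and edge types are admissible; strict mode is used
by the build pipeline so that malformed ETL output fails fast, while ad-hoc
exploration can switch it off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

Scalar = str | int | float | bool
Properties = dict[str, Scalar | list]

__all__ = ["Node", "Edge", "PropertyGraph", "SchemaRegistry", "GraphError", "DEFAULT_SCHEMA"]


class GraphError(ValueError):
    """Raised on constraint violations (duplicate IDs, dangling endpoints,
    schema violations)."""


@dataclass
class Node:
    node_id: str
    labels: frozenset[str]
    properties: Properties = field(default_factory=dict)


@dataclass
class Edge:
    edge_type: str
    source: str
    target: str
    properties: Properties = field(default_factory=dict)

    def key(self) -> tuple[str, str, str]:
        return (self.edge_type, self.source, self.target)


#: Core node labels.  The registry is explicitly extensible: instances may
#: register further labels/edge types for new data layers.
CORE_LABELS = frozenset(
    {
        "Gene",
        "RNA",
        "Protein",
        "Chromosome",
        "Species",
        "Orthogroup",
        "Synteny",
        "QTL",
        "BiparentalPopulation",
        "DiversityPanel",
        "Trait",
        "Marker",
        "Population",
        "Site",
        "Sample",
        "Condition",
        "RNASeq",
        "GeneFamily",
        "FunctionalAnnotation",
        "GO",
        "PO",
        "PECO",
        "MapMan",
        "OntologyTerm",
        "Resource",
    }
)

#: Edge type -> set of admissible (source label, target label) pairs.
CORE_EDGE_TYPES: dict[str, frozenset[tuple[str, str]]] = {
    "HAS_TRANSCRIPT": frozenset({("Gene", "RNA")}),
    "TRANSLATES_TO": frozenset({("RNA", "Protein")}),
    "LOCATED_ON": frozenset({("Gene", "Chromosome"), ("QTL", "Chromosome"), ("Marker", "Chromosome")}),
    "BELONGS_TO_SPECIES": frozenset({("Chromosome", "Species"), ("Gene", "Species")}),
    "MEMBER_OF": frozenset({("Gene", "Orthogroup")}),
    "IS_ORTHOLOGOUS_TO": frozenset({("Gene", "Gene")}),
    "IN_SYNTENY_BLOCK": frozenset({("Gene", "Synteny")}),
    "SPANS": frozenset({("Synteny", "Chromosome")}),
    "COLOCALIZES_WITH": frozenset({("Gene", "QTL")}),
    "IS_CLOSEST_TO_PEAK": frozenset({("Gene", "QTL")}),
    "HAS_TRAIT": frozenset({("QTL", "Trait")}),
    "STUDIED_IN": frozenset({("QTL", "Population")}),
    "OBSERVED_AT": frozenset({("QTL", "Site")}),
    "HAS_MARKER": frozenset({("QTL", "Marker")}),
    "EXPRESSED_IN": frozenset({("Gene", "Condition")}),
    "MEASURED_IN": frozenset({("Gene", "Sample")}),
    "BELONGS_TO": frozenset({("Sample", "Condition")}),
    "ANNOTATED_WITH": frozenset(
        {("Condition", "PO"), ("Condition", "PECO"), ("Protein", "GO"), ("Gene", "GO")}
    ),
    "SCO": frozenset(
        {("GO", "GO"), ("PO", "PO"), ("PECO", "PECO"), ("MapMan", "MapMan")}
    ),
    "PART_OF": frozenset(
        {("GO", "GO"), ("PO", "PO"), ("PECO", "PECO"), ("MapMan", "MapMan")}
    ),
    "HAS_DOMAIN": frozenset({("Protein", "FunctionalAnnotation")}),
    "HAS_ANNOTATION": frozenset(
        {("Gene", "FunctionalAnnotation"), ("Gene", "GeneFamily"), ("Gene", "MapMan")}
    ),
    "FROM_RESOURCE": frozenset(
        {("GO", "Resource"), ("PO", "Resource"), ("PECO", "Resource"), ("MapMan", "Resource")}
    ),
}


class SchemaRegistry:
    """Allowed labels and (edge type, source label, target label) triples."""

    def __init__(
        self,
        labels: Iterable[str] = CORE_LABELS,
        edge_types: Mapping[str, Iterable[tuple[str, str]]] = CORE_EDGE_TYPES,
    ):
        self.labels: set[str] = set(labels)
        self.edge_types: dict[str, set[tuple[str, str]]] = {
            t: set(pairs) for t, pairs in edge_types.items()
        }

    def register_label(self, label: str) -> None:
        self.labels.add(label)

    def register_edge_type(self, edge_type: str, source: str, target: str) -> None:
        self.edge_types.setdefault(edge_type, set()).add((source, target))

    def check_node(self, labels: frozenset[str]) -> None:
        unknown = labels - self.labels
        if unknown:
            raise GraphError(f"unknown node label(s): {sorted(unknown)}")

    def check_edge(
        self, edge_type: str, src_labels: frozenset[str], dst_labels: frozenset[str]
    ) -> None:
        pairs = self.edge_types.get(edge_type)
        if pairs is None:
            raise GraphError(f"unknown edge type: {edge_type}")
        if not any((a in src_labels and b in dst_labels) for a, b in pairs):
            raise GraphError(
                f"edge {edge_type} not allowed between labels "
                f"{sorted(src_labels)} -> {sorted(dst_labels)}"
            )


DEFAULT_SCHEMA = SchemaRegistry()


class PropertyGraph:
    """Node/edge stores with a label index and adjacency lists.

    Strict mode (default) validates every insertion against the schema
    registry.
    """

    def __init__(self, schema: SchemaRegistry | None = None, strict: bool = True):
        self.schema = schema if schema is not None else SchemaRegistry()
        self.strict = strict
        self._nodes: dict[str, Node] = {}
        self._edges: dict[tuple[str, str, str], Edge] = {}
        self._label_index: dict[str, set[str]] = {}
        self._out: dict[str, set[tuple[str, str, str]]] = {}
        self._in: dict[str, set[tuple[str, str, str]]] = {}

    # -- mutation ----------------------------------------------------------

    def add_node(
        self,
        node_id: str,
        labels: Iterable[str],
        properties: Properties | None = None,
    ) -> Node:
        label_set = frozenset(labels)
        if not label_set:
            raise GraphError(f"node {node_id}: empty label set")
        if node_id in self._nodes:
            raise GraphError(f"duplicate node ID: {node_id}")
        if self.strict:
            self.schema.check_node(label_set)
        node = Node(node_id, label_set, dict(properties or {}))
        self._nodes[node_id] = node
        for lab in label_set:
            self._label_index.setdefault(lab, set()).add(node_id)
        self._out.setdefault(node_id, set())
        self._in.setdefault(node_id, set())
        return node

    def merge_node(
        self,
        node_id: str,
        labels: Iterable[str],
        properties: Properties | None = None,
    ) -> Node:
        """Idempotent insert: create the node or extend labels/properties of
        the existing one."""
        if node_id not in self._nodes:
            return self.add_node(node_id, labels, properties)
        node = self._nodes[node_id]
        new_labels = node.labels | frozenset(labels)
        if self.strict:
            self.schema.check_node(new_labels)
        for lab in new_labels - node.labels:
            self._label_index.setdefault(lab, set()).add(node_id)
        node.labels = new_labels
        node.properties.update(properties or {})
        return node

    def add_edge(
        self,
        edge_type: str,
        source: str,
        target: str,
        properties: Properties | None = None,
    ) -> Edge:
        for endpoint in (source, target):
            if endpoint not in self._nodes:
                raise GraphError(f"edge endpoint does not exist: {endpoint}")
        if self.strict:
            self.schema.check_edge(
                edge_type, self._nodes[source].labels, self._nodes[target].labels
            )
        edge = Edge(edge_type, source, target, dict(properties or {}))
        key = edge.key()
        if key in self._edges:  # merge: refresh properties, keep one edge
            self._edges[key].properties.update(edge.properties)
            return self._edges[key]
        self._edges[key] = edge
        self._out[source].add(key)
        self._in[target].add(key)
        return edge

    # -- access ------------------------------------------------------------

    def node(self, node_id: str) -> Node:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise GraphError(f"unknown node: {node_id}") from None

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def nodes(self, label: str | None = None) -> list[Node]:
        if label is None:
            return [self._nodes[i] for i in sorted(self._nodes)]
        return [self._nodes[i] for i in sorted(self._label_index.get(label, ()))]

    def edges(self, edge_type: str | None = None) -> list[Edge]:
        keys = sorted(self._edges)
        if edge_type is not None:
            keys = [k for k in keys if k[0] == edge_type]
        return [self._edges[k] for k in keys]

    def neighbors(
        self,
        node_id: str,
        edge_type: str | None = None,
        direction: str = "any",
    ) -> list[tuple[Edge, Node]]:
        """Adjacent (edge, node) pairs; duplicate-free, sorted for
        reproducible traversal order."""
        if node_id not in self._nodes:
            raise GraphError(f"unknown node: {node_id}")
        if direction not in ("out", "in", "any"):
            raise GraphError(f"invalid direction {direction!r}")
        keys: set[tuple[str, str, str]] = set()
        if direction in ("out", "any"):
            keys |= self._out[node_id]
        if direction in ("in", "any"):
            keys |= self._in[node_id]
        out: list[tuple[Edge, Node]] = []
        for key in sorted(keys):
            edge = self._edges[key]
            if edge_type is not None and edge.edge_type != edge_type:
                continue
            other = edge.target if edge.source == node_id else edge.source
            out.append((edge, self._nodes[other]))
        return out

    # -- stats / comparison -------------------------------------------------

    @property
    def num_nodes(self) -> int:
        return len(self._nodes)

    @property
    def num_edges(self) -> int:
        return len(self._edges)

    def label_counts(self) -> dict[str, int]:
        return {lab: len(ids) for lab, ids in sorted(self._label_index.items()) if ids}

    def equals(self, other: "PropertyGraph") -> bool:
        """Full structural equality: node IDs, label sets, properties and
        edges (with properties) all match."""
        if set(self._nodes) != set(other._nodes):
            return False
        for nid, node in self._nodes.items():
            o = other._nodes[nid]
            if node.labels != o.labels or node.properties != o.properties:
                return False
        if set(self._edges) != set(other._edges):
            return False
        for key, edge in self._edges.items():
            if edge.properties != other._edges[key].properties:
                return False
        return True

    def __iter__(self) -> Iterator[Node]:
        return iter(self.nodes())
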