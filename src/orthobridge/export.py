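"""Bulk-import CSV serialization of a property graph, plus the reload path
used for round-trip verification.

The emitted dialect follows the graph-database bulk-import convention:
one node file per distinct label set with an ``id:ID`` column, typed
property columns (``:int``, ``:float``, ``:string``, ``:string[]``) and a
``:LABEL`` column; one edge file per relationship type with ``:START_ID``,
``:END_ID`` and ``:TYPE`` columns.  Rows are sorted by node/edge ID so the
export is byte-identical across runs on the same graph.  A tab-separated
manifest lists every file in import order (nodes first).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .graph_model import Edge, GraphError, Node, PropertyGraph

__all__ = ["ImportManifest", "write_bulk_csv", "read_bulk_csv", "ExportError"]

LIST_SEP = ";"


class ExportError(ValueError):
    """Raised on unserializable properties or malformed import files."""


@dataclass(frozen=True)
class ManifestEntry:
    role: str  # "node" | "edge"
    label: str  # label set ("A;B") or edge type
    path: str  # file path relative to the manifest


@dataclass
class ImportManifest:
    directory: Path
    entries: list[ManifestEntry]

    MANIFEST_NAME = "import_manifest.tsv"

    def write(self) -> Path:
        path = self.directory / self.MANIFEST_NAME
        lines = [f"{e.role}\t{e.label}\t{e.path}" for e in self.entries]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "ImportManifest":
        path = Path(path)
        entries = []
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            role, label, rel = line.split("\t")
            entries.append(ManifestEntry(role, label, rel))
        return cls(directory=path.parent, entries=entries)


# ---------------------------------------------------------------------------
# Type suffixes
# ---------------------------------------------------------------------------


def _value_type(value) -> str:
    if isinstance(value, bool):
        raise ExportError("boolean properties are not supported by the dialect")
    if isinstance(value, int):
        return "int"
    if isinstance(value, float):
        return "float"
    if isinstance(value, str):
        return "string"
    if isinstance(value, (list, tuple)):
        if not all(isinstance(v, str) for v in value):
            raise ExportError("only string lists are supported")
        return "string[]"
    raise ExportError(f"unsupported property type: {type(value).__name__}")


def _merge_type(a: str | None, b: str) -> str:
    if a is None or a == b:
        return b
    if {a, b} == {"int", "float"}:
        return "float"
    raise ExportError(f"conflicting property types {a} vs {b}")


def _column_types(items: Sequence[Node] | Sequence[Edge]) -> dict[str, str]:
    types: dict[str, str | None] = {}
    for item in items:
        for key, value in item.properties.items():
            types[key] = _merge_type(types.get(key), _value_type(value))
    return {k: t for k, t in sorted(types.items())}  # type: ignore[misc]


def _format(value, typ: str) -> str:
    if typ == "string[]":
        return LIST_SEP.join(value)
    if typ == "float":
        return repr(float(value))
    return str(value)


def _parse(text: str, typ: str):
    if text == "":
        return None
    if typ == "int":
        return int(text)
    if typ == "float":
        return float(text)
    if typ == "string[]":
        return text.split(LIST_SEP)
    return text


# ---------------------------------------------------------------------------
# Write
# ---------------------------------------------------------------------------


def _label_key(labels: frozenset[str]) -> str:
    return ";".join(sorted(labels))


def write_bulk_csv(graph: PropertyGraph, out_dir: str | Path) -> ImportManifest:
    """Serialize the graph into bulk-import CSV files plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []

    by_labels: dict[str, list[Node]] = {}
    for node in graph.nodes():
        by_labels.setdefault(_label_key(node.labels), []).append(node)
    for label_key in sorted(by_labels):
        nodes = sorted(by_labels[label_key], key=lambda n: n.node_id)
        col_types = _column_types(nodes)
        fname = f"nodes_{label_key.replace(';', '_')}.csv"
        header = ["id:ID"] + [f"{k}:{t}" for k, t in col_types.items()] + [":LABEL"]
        with open(out_dir / fname, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for node in nodes:
                row = [node.node_id]
                for key, typ in col_types.items():
                    value = node.properties.get(key)
                    row.append("" if value is None else _format(value, typ))
                row.append(label_key)
                writer.writerow(row)
        entries.append(ManifestEntry("node", label_key, fname))

    by_type: dict[str, list[Edge]] = {}
    for edge in graph.edges():
        by_type.setdefault(edge.edge_type, []).append(edge)
    for edge_type in sorted(by_type):
        edges = sorted(by_type[edge_type], key=lambda e: e.key())
        col_types = _column_types(edges)
        fname = f"edges_{edge_type}.csv"
        header = (
            [":START_ID", ":END_ID"]
            + [f"{k}:{t}" for k, t in col_types.items()]
            + [":TYPE"]
        )
        with open(out_dir / fname, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for edge in edges:
                row = [edge.source, edge.target]
                for key, typ in col_types.items():
                    value = edge.properties.get(key)
                    row.append("" if value is None else _format(value, typ))
                row.append(edge_type)
                writer.writerow(row)
        entries.append(ManifestEntry("edge", edge_type, fname))

    manifest = ImportManifest(out_dir, entries)
    manifest.write()
    return manifest


# ---------------------------------------------------------------------------
# Read (round-trip verification)
# ---------------------------------------------------------------------------


def _split_header(col: str) -> tuple[str, str]:
    if ":" not in col:
        raise ExportError(f"header column {col!r} lacks a type suffix")
    name, typ = col.rsplit(":", 1)
    return name, typ


def read_bulk_csv(manifest: ImportManifest | str | Path) -> PropertyGraph:
    """Reload a bulk-CSV export into a new (non-strict) property graph."""
    if not isinstance(manifest, ImportManifest):
        manifest = ImportManifest.read(manifest)
    graph = PropertyGraph(strict=False)
    for entry in manifest.entries:
        path = manifest.directory / entry.path
        if not path.exists():
            raise ExportError(f"manifest references missing file {path}")
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if entry.role == "node":
                if header[0] != "id:ID" or header[-1] != ":LABEL":
                    raise ExportError(f"{path}: malformed node header {header!r}")
                prop_cols = [_split_header(c) for c in header[1:-1]]
                for row in reader:
                    props = {}
                    for (name, typ), text in zip(prop_cols, row[1:-1]):
                        value = _parse(text, typ)
                        if value is not None:
                            props[name] = value
                    graph.add_node(row[0], row[-1].split(";"), props)
            elif entry.role == "edge":
                if header[:2] != [":START_ID", ":END_ID"] or header[-1] != ":TYPE":
                    raise ExportError(f"{path}: malformed edge header {header!r}")
                prop_cols = [_split_header(c) for c in header[2:-1]]
                for row in reader:
                    props = {}
                    for (name, typ), text in zip(prop_cols, row[2:-1]):
                        value = _parse(text, typ)
                        if value is not None:
                            props[name] = value
                    if not graph.has_node(row[0]) or not graph.has_node(row[1]):
                        raise ExportError(
                            f"{path}: edge references absent node {row[0]} or {row[1]}"
                        )
                    graph.add_edge(row[-1], row[0], row[1], props)
            else:
                raise ExportError(f"unknown manifest role {entry.role!r}")
    return graph
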