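"""Readers and writers for the network formats the toolkit touches.

Three formats are supported, all preserving node attributes, coordinates and
node order:

* **Cytoscape.js JSON** (``.cyjs``) — ``elements.nodes[].data`` for the
  attribute row and ``elements.nodes[].position`` for ``{x, y[, z]}``.
* **GraphML** — node attributes under declared keys; coordinates under the
  ``x``/``y``/``z`` attribute names (written as doubles).
* **SIF** plus a side-car TSV layout table (``name``/``x``/``y``[/``z``]).

Coordinate convention throughout: x grows rightward, y grows **downward**
(Cytoscape's rendering convention), z defaults to 0. All writers emit UTF-8;
the TSV uses ``.`` as the decimal separator.
"""

from __future__ import annotations

import csv
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx

from .errors import FormatError, ValidationError
from .model import (
    INTEGER,
    OTHER,
    STRING,
    ColumnDef,
    Coordinates,
    EdgeRecord,
    NetworkGraph,
    NetworkView,
    NodeRecord,
    SessionRegistry,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, os.PathLike]


@dataclass
class LoadedNetwork:
    """A network read from disk together with its view state.

    Selection flags ride along with the coordinates so that "select
    unmapped" results survive a write/read cycle through any format.
    """

    graph: NetworkGraph
    positions: dict[int, Coordinates] = field(default_factory=dict)
    selected: dict[int, bool] = field(default_factory=dict)

    def register(self, registry: SessionRegistry, make_current: bool = False) -> tuple[int, int]:
        return registry.register_network(
            self.graph, self.positions, self.selected, make_current=make_current
        )


@dataclass(frozen=True)
class LayoutTableRow:
    """One row of a side-car coordinate table, keyed by node name."""

    key: str
    x: float
    y: float
    z: float = 0.0


# ---------------------------------------------------------------------------
# helpers


def _is_integral_number(value: object) -> bool:
    if isinstance(value, bool):
        return False
    if isinstance(value, int):
        return True
    return isinstance(value, float) and value.is_integer()


def _assign_node_ids(raw_ids: Sequence[str]) -> dict[str, int]:
    """Map raw file identifiers to integer node ids.

    If every raw id parses as an integer those integers are kept (this is
    what Cytoscape exports and what our writers emit, so round-trips keep
    ids stable); otherwise nodes are numbered 0..n-1 in file order.
    """
    if len(set(raw_ids)) != len(raw_ids):
        raise FormatError("duplicate node ids in input")
    try:
        return {raw: int(raw) for raw in raw_ids}
    except ValueError:
        return {raw: i for i, raw in enumerate(raw_ids)}


def _infer_columns(rows: Sequence[dict[str, object]]) -> list[ColumnDef]:
    """Column kinds by inspection for untyped input (cyjs JSON).

    A column is integer iff every present value is an integral number;
    anything else is coerced to a string column.
    """
    order: list[str] = []
    for row in rows:
        for key in row:
            if key not in order:
                order.append(key)
    columns = []
    for name in order:
        present = [row[name] for row in rows if name in row and row[name] is not None]
        kind = INTEGER if present and all(_is_integral_number(v) for v in present) else STRING
        columns.append(ColumnDef(name, kind))
    return columns


def _coerce(value: object, kind: str) -> object:
    if value is None:
        return None
    if kind == INTEGER:
        return int(value)  # type: ignore[arg-type]
    if kind == STRING:
        if isinstance(value, bool):
            return "true" if value else "false"
        return str(value)
    return value


# ---------------------------------------------------------------------------
# Cytoscape.js JSON


def read_cyjs(path: PathLike) -> LoadedNetwork:
    """Read a Cytoscape.js JSON document; node order is the array order."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: top-level JSON value must be an object")
    elements = doc.get("elements", {})
    node_elements = elements.get("nodes", []) or []
    edge_elements = elements.get("edges", []) or []

    raw_ids: list[str] = []
    data_rows: list[dict] = []
    for i, element in enumerate(node_elements):
        data = element.get("data")
        if not isinstance(data, dict) or "id" not in data:
            raise FormatError(f"{path}: node element #{i} has no data.id")
        raw_ids.append(str(data["id"]))
        data_rows.append(data)
    id_map = _assign_node_ids(raw_ids)

    attr_rows = [
        {k: v for k, v in row.items() if k not in ("id", "selected")} for row in data_rows
    ]
    columns = _infer_columns(attr_rows)
    kinds = {c.name: c.value_kind for c in columns}

    nodes: list[NodeRecord] = []
    positions: dict[int, Coordinates] = {}
    selected: dict[int, bool] = {}
    for element, raw, row in zip(node_elements, raw_ids, attr_rows):
        node_id = id_map[raw]
        attrs = {k: _coerce(v, kinds[k]) for k, v in row.items() if v is not None}
        nodes.append(NodeRecord(node_id, attrs))
        pos = element.get("position", {}) or {}
        positions[node_id] = (
            float(pos.get("x", 0.0)),
            float(pos.get("y", 0.0)),
            float(pos.get("z", 0.0)),
        )
        flag = element.get("data", {}).get("selected", element.get("selected", False))
        selected[node_id] = bool(flag)

    edges: list[EdgeRecord] = []
    for i, element in enumerate(edge_elements):
        data = element.get("data", {})
        try:
            src, tgt = str(data["source"]), str(data["target"])
        except KeyError:
            raise FormatError(f"{path}: edge element #{i} lacks source/target") from None
        if src not in id_map or tgt not in id_map:
            raise FormatError(f"{path}: edge element #{i} references an unknown node")
        edges.append(EdgeRecord(id_map[src], id_map[tgt], data.get("interaction")))

    name = (doc.get("data") or {}).get("name") or path.stem
    graph = NetworkGraph(name=name, columns=columns, nodes=nodes, edges=edges)
    graph.validate()
    return LoadedNetwork(graph, positions, selected)


def write_cyjs(graph: NetworkGraph, view: NetworkView, path: PathLike) -> None:
    """Write a Cytoscape.js JSON document, positions taken from ``view``.

    The selected flag is written explicitly (true *or* false) into every
    node's data record so selections survive a round-trip.
    """
    _check_view_covers(graph, view)
    node_elements = []
    for node in graph.nodes:
        nv = view.node_view(node.node_id)
        data = {"id": str(node.node_id)}
        data.update({k: v for k, v in node.attributes.items() if v is not None})
        data["selected"] = bool(nv.selected)
        node_elements.append(
            {"data": data, "position": {"x": nv.x, "y": nv.y, "z": nv.z}}
        )
    edge_elements = []
    for edge in graph.edges:
        data = {"source": str(edge.source_id), "target": str(edge.target_id)}
        if edge.interaction is not None:
            data["interaction"] = edge.interaction
        edge_elements.append({"data": data})
    doc = {
        "format_version": "1.0",
        "data": {"name": graph.name},
        "elements": {"nodes": node_elements, "edges": edge_elements},
    }
    Path(path).write_text(json.dumps(doc, ensure_ascii=False, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# GraphML


def read_graphml(path: PathLike) -> LoadedNetwork:
    """Read GraphML; declared long/int keys become integer columns, string
    keys become string columns, every other declared type becomes ``other``
    (present for fidelity, unusable for matching)."""
    try:
        g = nx.read_graphml(path, force_multigraph=True)
    except Exception as exc:  # networkx raises several lxml/expat flavors
        raise FormatError(f"{path}: cannot parse GraphML ({exc})") from exc

    raw_ids = [str(n) for n in g.nodes]
    id_map = _assign_node_ids(raw_ids)

    order: list[str] = []
    kinds: dict[str, str] = {}
    for _, attrs in g.nodes(data=True):
        for key, value in attrs.items():
            if key in ("x", "y", "z", "selected"):
                continue
            if key not in order:
                order.append(key)
            if isinstance(value, bool):
                kind = OTHER
            elif isinstance(value, int):
                kind = INTEGER
            elif isinstance(value, str):
                kind = STRING
            else:
                kind = OTHER
            previous = kinds.get(key)
            kinds[key] = kind if previous in (None, kind) else OTHER

    nodes, positions, selected = [], {}, {}
    for raw, attrs in g.nodes(data=True):
        node_id = id_map[str(raw)]
        row = {}
        for key in order:
            if key in attrs:
                row[key] = _coerce(attrs[key], kinds[key]) if kinds[key] != OTHER else attrs[key]
        nodes.append(NodeRecord(node_id, row))
        coords = []
        for axis in ("x", "y", "z"):
            value = attrs.get(axis, 0.0)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise FormatError(f"{path}: coordinate key {axis!r} is declared non-numeric")
            coords.append(float(value))
        positions[node_id] = tuple(coords)
        selected[node_id] = bool(attrs.get("selected", False))

    edges = [
        EdgeRecord(id_map[str(u)], id_map[str(v)], data.get("interaction"))
        for u, v, data in g.edges(data=True)
    ]
    name = g.graph.get("name") or Path(path).stem
    graph = NetworkGraph(
        name=name,
        columns=[ColumnDef(n, kinds[n]) for n in order],
        nodes=nodes,
        edges=edges,
    )
    graph.validate()
    return LoadedNetwork(graph, positions, selected)


def write_graphml(graph: NetworkGraph, view: NetworkView, path: PathLike) -> None:
    _check_view_covers(graph, view)
    g = nx.MultiDiGraph(name=graph.name)
    for node in graph.nodes:
        nv = view.node_view(node.node_id)
        attrs = {k: v for k, v in node.attributes.items() if v is not None}
        g.add_node(str(node.node_id), x=nv.x, y=nv.y, z=nv.z, selected=bool(nv.selected), **attrs)
    for edge in graph.edges:
        attrs = {} if edge.interaction is None else {"interaction": edge.interaction}
        g.add_edge(str(edge.source_id), str(edge.target_id), **attrs)
    nx.write_graphml(g, path, encoding="utf-8")


# ---------------------------------------------------------------------------
# SIF + layout table


def read_sif(path: PathLike) -> NetworkGraph:
    """Read a SIF edge list; nodes appear in first-encounter order.

    Fields split on tabs when the line contains a tab, otherwise on any
    whitespace run. A line with a single field declares an isolated node;
    ``A interaction B [C ...]`` declares one edge per trailing target.
    """
    path = Path(path)
    order: dict[str, int] = {}
    edges: list[EdgeRecord] = []

    def node_id(name: str) -> int:
        if name not in order:
            order[name] = len(order)
        return order[name]

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")] if "\t" in line else line.split()
            fields = [f for f in fields if f]
            if len(fields) == 1:
                node_id(fields[0])
            elif len(fields) == 2:
                raise FormatError(
                    f"{path}:{lineno}: SIF line has an interaction but no target node"
                )
            else:
                src, interaction = fields[0], fields[1]
                for target in fields[2:]:
                    edges.append(EdgeRecord(node_id(src), node_id(target), interaction))

    nodes = [NodeRecord(i, {"name": name}) for name, i in order.items()]
    graph = NetworkGraph(
        name=path.name,
        columns=[ColumnDef("name", STRING)],
        nodes=nodes,
        edges=edges,
    )
    graph.validate()
    return graph


def read_layout_table(path: PathLike) -> list[LayoutTableRow]:
    """Read a TSV coordinate table with header ``name``/``x``/``y``[/``z``]."""
    path = Path(path)
    rows: list[LayoutTableRow] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for required in ("name", "x", "y"):
            if required not in header:
                raise FormatError(f"{path}: layout table lacks required column {required!r}")
        for lineno, record in enumerate(reader, start=2):
            try:
                key = record["name"]
                row = LayoutTableRow(
                    key,
                    float(record["x"]),
                    float(record["y"]),
                    float(record["z"]) if record.get("z") not in (None, "") else 0.0,
                )
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed layout row ({exc})") from exc
            if key in seen:
                raise FormatError(f"{path}:{lineno}: duplicate layout key {key!r}")
            seen.add(key)
            rows.append(row)
    return rows


def layout_from_table(
    graph: NetworkGraph, rows: Sequence[LayoutTableRow], key_column: str = "name"
) -> tuple[dict[int, Coordinates], int]:
    """Join layout rows onto a graph by name; unknown names are skipped with
    a logged warning. Returns ``(positions, applied_row_count)``."""
    by_name = {str(node.get(key_column)): node.node_id for node in graph.nodes}
    positions: dict[int, Coordinates] = {}
    applied = 0
    for row in rows:
        node = by_name.get(row.key)
        if node is None:
            logger.warning("layout row %r names no node in network %r; skipped", row.key, graph.name)
            continue
        positions[node] = (row.x, row.y, row.z)
        applied += 1
    return positions, applied


def write_sif(graph: NetworkGraph, path: PathLike) -> None:
    # Every node is declared first as a bare line: redundant for connected
    # nodes but it pins first-appearance order, so reading the file back
    # yields the nodes in exactly the order they are stored here.
    named = {n.node_id: str(n.get("name") or n.node_id) for n in graph.nodes}
    lines = [named[node.node_id] for node in graph.nodes]
    for edge in graph.edges:
        lines.append(f"{named[edge.source_id]}\t{edge.interaction or 'pp'}\t{named[edge.target_id]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_layout_table(graph: NetworkGraph, view: NetworkView, path: PathLike) -> None:
    _check_view_covers(graph, view)
    lines = ["name\tx\ty\tz"]
    for node in graph.nodes:
        nv = view.node_view(node.node_id)
        name = str(node.get("name") or node.node_id)
        lines.append(f"{name}\t{nv.x!r}\t{nv.y!r}\t{nv.z!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# format dispatch


FORMATS = ("cyjs", "graphml", "sif")


def sniff_format(path: PathLike) -> str:
    suffix = Path(path).suffix.lower()
    mapping = {".cyjs": "cyjs", ".json": "cyjs", ".graphml": "graphml", ".xml": "graphml", ".sif": "sif"}
    try:
        return mapping[suffix]
    except KeyError:
        raise FormatError(f"cannot infer network format from suffix {suffix!r}") from None


def load_network(
    path: PathLike, fmt: Optional[str] = None, layout_path: Optional[PathLike] = None
) -> LoadedNetwork:
    """Read a network in any supported format; for SIF an optional side-car
    layout table supplies coordinates (nodes without a row sit at the origin)."""
    fmt = fmt or sniff_format(path)
    if fmt == "cyjs":
        return read_cyjs(path)
    if fmt == "graphml":
        return read_graphml(path)
    if fmt == "sif":
        graph = read_sif(path)
        positions: dict[int, Coordinates] = {}
        if layout_path is not None:
            positions, _ = layout_from_table(graph, read_layout_table(layout_path))
        return LoadedNetwork(graph, positions, {})
    raise ValidationError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def save_network(
    graph: NetworkGraph, view: NetworkView, path: PathLike, fmt: Optional[str] = None
) -> None:
    """Write a network in any supported format; SIF output writes the edge
    list to ``path`` and the coordinates to a sibling ``.layout.tsv``."""
    fmt = fmt or sniff_format(path)
    if fmt == "cyjs":
        write_cyjs(graph, view, path)
    elif fmt == "graphml":
        write_graphml(graph, view, path)
    elif fmt == "sif":
        write_sif(graph, path)
        write_layout_table(graph, view, Path(path).with_suffix(".layout.tsv"))
    else:
        raise ValidationError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def _check_view_covers(graph: NetworkGraph, view: NetworkView) -> None:
    if set(view.node_views) != set(graph.node_ids()):
        raise ValidationError(
            f"view {view.view_suid} does not cover the node set of network {graph.name!r}"
        )
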