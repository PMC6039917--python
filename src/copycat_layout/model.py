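"""In-memory model of attributed networks, their rendered views, and a session.

The vocabulary mirrors Cytoscape's: a *network* is a graph plus a typed node
attribute table; a *view* assigns each node screen coordinates (x rightward,
y **downward**, z defaulting to 0) and a selected flag, and carries a viewport
(zoom plus center point). Networks and views live in a session registry and
are addressed by SUIDs — session-unique positive integers that are never
reused within one session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

from .errors import NotFoundError, ValidationError

#: Value kinds a node-table column may declare. Only ``string`` and
#: ``integer`` columns are usable as mapping keys; everything else is
#: carried for I/O fidelity under ``other``.
STRING = "string"
INTEGER = "integer"
OTHER = "other"

VALUE_KINDS = (STRING, INTEGER, OTHER)

#: First SUID handed out by a fresh session. Arbitrary non-zero base so that
#: SUIDs are visibly not list indices; tests must never hard-code it.
SUID_BASE = 52

Coordinates = tuple[float, float, float]

RawValue = Union[str, int, float, None]


@dataclass(frozen=True, slots=True)
class AttributeValue:
    """A typed scalar used as a mapping key.

    Exactly two kinds exist for matching purposes: ``string`` (compared by
    exact string equality) and ``integer`` (compared numerically). Two values
    are equal iff both kind and content agree, so an integer 7 never matches
    the string ``"7"`` — the kinds must have been validated as identical
    before any matching happens.
    """

    kind: str
    value: Union[str, int]

    def __post_init__(self) -> None:
        if self.kind not in (STRING, INTEGER):
            raise ValidationError(f"attribute values must be string or integer, not {self.kind!r}")
        if self.kind == INTEGER and (isinstance(self.value, bool) or not isinstance(self.value, int)):
            raise ValidationError(f"integer attribute value expected, got {self.value!r}")
        if self.kind == STRING and not isinstance(self.value, str):
            raise ValidationError(f"string attribute value expected, got {self.value!r}")

    @classmethod
    def of(cls, raw: RawValue, kind: str) -> Optional["AttributeValue"]:
        """Build a key from a raw table value, or ``None`` if the value is missing.

        A node with a missing value in the mapping column can never match;
        callers treat ``None`` as "contributes nothing / counts as unmapped".
        """
        if raw is None:
            return None
        if kind == INTEGER:
            return cls(INTEGER, int(raw))
        return cls(STRING, str(raw))


@dataclass(frozen=True)
class ColumnDef:
    """Declared node-table column: a unique name plus a value kind."""

    name: str
    value_kind: str = STRING

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("column names must be non-empty")
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"unknown value kind {self.value_kind!r}")


@dataclass
class NodeRecord:
    """A node and its attribute row; missing values are simply absent keys."""

    node_id: int
    attributes: dict[str, RawValue] = field(default_factory=dict)

    def get(self, column: str) -> RawValue:
        return self.attributes.get(column)


@dataclass
class EdgeRecord:
    """An edge between two node ids. Carried for I/O fidelity only: the
    layout-transfer algorithm never consults edges."""

    source_id: int
    target_id: int
    interaction: Optional[str] = None


@dataclass
class NetworkGraph:
    """An attributed network: nodes in a stable, input-preserving order.

    Node order matters — it defines which duplicate mapping value is the
    "last encountered" one during map construction.
    """

    name: str = ""
    columns: list[ColumnDef] = field(default_factory=list)
    nodes: list[NodeRecord] = field(default_factory=list)
    edges: list[EdgeRecord] = field(default_factory=list)
    suid: Optional[int] = None

    def validate(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate node ids in network {self.name!r}")
        declared = {c.name for c in self.columns}
        if len(declared) != len(self.columns):
            raise ValidationError(f"duplicate column names in network {self.name!r}")
        for node in self.nodes:
            undeclared = set(node.attributes) - declared
            if undeclared:
                raise ValidationError(
                    f"node {node.node_id} carries undeclared columns {sorted(undeclared)}"
                )
        id_set = set(ids)
        for edge in self.edges:
            if edge.source_id not in id_set or edge.target_id not in id_set:
                raise ValidationError(
                    f"edge {edge.source_id}->{edge.target_id} references a missing node"
                )

    def column(self, name: str) -> ColumnDef:
        for col in self.columns:
            if col.name == name:
                return col
        raise NotFoundError(f"no column {name!r} in the node table of network {self.name!r}")

    def column_kind(self, name: str) -> str:
        return self.column(name).value_kind

    def node_ids(self) -> list[int]:
        return [n.node_id for n in self.nodes]


def column_kind(graph: NetworkGraph, column_name: str) -> str:
    """Declared kind of a node-table column; :class:`NotFoundError` if absent."""
    return graph.column_kind(column_name)


@dataclass
class NodeViewState:
    """Per-node rendering state: screen coordinates and the selected flag."""

    node_id: int
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    selected: bool = False

    @property
    def position(self) -> Coordinates:
        return (self.x, self.y, self.z)

    def move_to(self, position: Coordinates) -> None:
        self.x, self.y, self.z = position


@dataclass
class Viewport:
    """Rendered window state of a view: zoom (scale) and center point."""

    zoom: float = 1.0
    center_x: float = 0.0
    center_y: float = 0.0

    def __post_init__(self) -> None:
        if not self.zoom > 0:
            raise ValidationError(f"viewport zoom must be positive, got {self.zoom}")


@dataclass
class NetworkView:
    """A rendered view of one network: exactly one NodeViewState per node."""

    view_suid: int
    network_suid: int
    node_views: dict[int, NodeViewState] = field(default_factory=dict)
    viewport: Viewport = field(default_factory=Viewport)

    def node_view(self, node_id: int) -> NodeViewState:
        try:
            return self.node_views[node_id]
        except KeyError:
            raise NotFoundError(f"view {self.view_suid} has no node {node_id}") from None

    def selected_node_ids(self) -> list[int]:
        return [nv.node_id for nv in self.node_views.values() if nv.selected]


def _bounding_box_center(positions: Iterable[Coordinates]) -> tuple[float, float]:
    xs, ys = [], []
    for x, y, _z in positions:
        xs.append(x)
        ys.append(y)
    if not xs:
        return (0.0, 0.0)
    return ((min(xs) + max(xs)) / 2.0, (min(ys) + max(ys)) / 2.0)


@dataclass
class SessionRegistry:
    """SUID-addressed store of networks and views, with a ``current`` pointer.

    SUIDs are allocated monotonically from one counter shared by networks and
    views, so a view SUID can never collide with a network SUID.
    """

    networks: dict[int, NetworkGraph] = field(default_factory=dict)
    views: dict[int, NetworkView] = field(default_factory=dict)
    current_view: Optional[int] = None
    suid_counter: int = SUID_BASE

    def new_suid(self) -> int:
        suid = self.suid_counter
        self.suid_counter += 1
        return suid

    def register_network(
        self,
        graph: NetworkGraph,
        layout: Optional[Mapping[int, tuple]] = None,
        selected: Optional[Mapping[int, bool]] = None,
        make_current: bool = False,
    ) -> tuple[int, int]:
        """Register a network plus its primary view; returns ``(suid, view_suid)``.

        ``layout`` maps node ids to (x, y) or (x, y, z); missing entries
        default to the origin. The viewport starts at zoom 1.0 centered on
        the bounding box of the node positions (the origin for an empty
        network).
        """
        graph.validate()
        suid = self.new_suid()
        graph.suid = suid
        self.networks[suid] = graph

        view_suid = self.new_suid()
        layout = layout or {}
        selected = selected or {}
        node_views: dict[int, NodeViewState] = {}
        for node in graph.nodes:
            pos = layout.get(node.node_id, (0.0, 0.0, 0.0))
            x, y = float(pos[0]), float(pos[1])
            z = float(pos[2]) if len(pos) > 2 else 0.0
            node_views[node.node_id] = NodeViewState(
                node.node_id, x, y, z, bool(selected.get(node.node_id, False))
            )
        cx, cy = _bounding_box_center(nv.position for nv in node_views.values())
        view = NetworkView(view_suid, suid, node_views, Viewport(1.0, cx, cy))
        self.views[view_suid] = view
        if make_current or self.current_view is None:
            self.current_view = view_suid
        return suid, view_suid

    def network(self, suid: int) -> NetworkGraph:
        try:
            return self.networks[suid]
        except KeyError:
            raise NotFoundError(f"no network with SUID {suid}") from None

    def network_for_view(self, view: NetworkView) -> NetworkGraph:
        return self.network(view.network_suid)

    def views_of_network(self, suid: int) -> list[int]:
        self.network(suid)  # 404 on unknown network
        return [v.view_suid for v in self.views.values() if v.network_suid == suid]

    def resolve_view(self, selector: Union[int, str]) -> NetworkView:
        """Resolve an integer view SUID or the keyword ``"current"``."""
        if isinstance(selector, str):
            if selector == "current":
                if self.current_view is None:
                    raise NotFoundError("no current view in this session")
                return self.views[self.current_view]
            try:
                selector = int(selector)
            except ValueError:
                raise NotFoundError(
                    f"view selector must be an integer SUID or 'current', got {selector!r}"
                ) from None
        try:
            return self.views[selector]
        except KeyError:
            raise NotFoundError(f"no view with SUID {selector}") from None

    def find_view_by_network_name(self, name: str) -> NetworkView:
        """Primary view of the network called ``name``.

        Name collisions resolve deterministically to the lowest-SUID network;
        the primary view of a network is its first-registered (lowest-SUID)
        view.
        """
        candidates = sorted(s for s, g in self.networks.items() if g.name == name)
        if not candidates:
            raise NotFoundError(f"no network named {name!r}")
        suid = candidates[0]
        view_suids = sorted(self.views_of_network(suid))
        if not view_suids:
            raise NotFoundError(f"network {name!r} has no view")
        return self.views[view_suids[0]]


def resolve_view(registry: SessionRegistry, selector: Union[int, str]) -> NetworkView:
    return registry.resolve_view(selector)


def find_view_by_network_name(registry: SessionRegistry, name: str) -> NetworkView:
    return registry.find_view_by_network_name(name)
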