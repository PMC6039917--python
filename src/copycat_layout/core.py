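"""Attribute-keyed layout transfer between two network views.

The algorithm is two linear passes. Pass one walks the **source** network in
stored node order and builds a hash map from mapping-column value to that
node's view coordinates; when several source nodes share a value, the last
encountered one wins. Pass two walks the **target** network and, for every
node whose mapping value appears in the map, overwrites its (x, y, z) with
the mapped coordinates — several target nodes sharing one value are all
stacked at the same point. The whole transfer is O(N + M) time and O(N)
memory in the source (N) and target (M) node counts, and never looks at
edges.

Matching is by *value*, not by node: a duplicated source value matched by
any target node counts every source node carrying that value as mapped.
Values compare equal only within one kind — the two mapping columns must
both be string columns or both integer columns — and a node with a missing
value in its mapping column can never match.

Two optional post-passes: select the unmapped nodes on both sides (clearing
every prior selection first, so the selection equals exactly the unmapped
sets), and lay the unmapped target nodes out on a grid to the top right of
the mapped nodes' bounding box. Finally the target viewport (zoom and
center) is cloned from the source so both views render at the same scale
and location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

from .errors import ColumnKindError, ValidationError
from .model import (
    INTEGER,
    STRING,
    AttributeValue,
    Coordinates,
    NetworkGraph,
    NetworkView,
    SessionRegistry,
)

#: Default spacing, in view units, between grid-placed unmapped nodes.
DEFAULT_GRID_SPACING = 80.0

PositionMap = dict[AttributeValue, Coordinates]


@dataclass
class CopycatParams:
    """Parameters of one layout-transfer call.

    Both mapping columns default to ``name``; selection and gridding of
    unmapped nodes are independent opt-ins. ``grid_spacing`` is the grid
    cell size in view units.
    """

    source_column: str = "name"
    target_column: str = "name"
    select_unmapped: bool = False
    grid_unmapped: bool = False
    grid_spacing: float = DEFAULT_GRID_SPACING

    def __post_init__(self) -> None:
        if not self.source_column or not self.target_column:
            raise ValidationError("mapping column names must be non-empty")


@dataclass
class CopycatResult:
    """Counts and id lists describing one transfer.

    ``mapped_node_count + unmapped_node_count`` always equals the target
    network's node count. The id lists identify the unmapped nodes on each
    side (the target list pairs with ``unmapped_node_count``; the source
    list is what a subsequent "selected nodes" query on the source returns
    when selection was requested).
    """

    mapped_node_count: int
    unmapped_node_count: int
    unmapped_target_ids: list[int] = field(default_factory=list)
    unmapped_source_ids: list[int] = field(default_factory=list)

    def to_data(self) -> dict:
        return {
            "mappedNodeCount": self.mapped_node_count,
            "unmappedNodeCount": self.unmapped_node_count,
            "unmappedTargetNodes": list(self.unmapped_target_ids),
            "unmappedSourceNodes": list(self.unmapped_source_ids),
        }


def validate_mapping_columns(
    source: NetworkGraph, target: NetworkGraph, params: CopycatParams
) -> str:
    """Check both mapping columns exist and share one matchable kind.

    Returns the common kind (``string`` or ``integer``). Raises
    :class:`NotFoundError` if either column is absent from its node table
    and :class:`ValidationError` if the kinds differ or are not matchable
    (floating-point, boolean and list columns cannot key a match).
    """
    source_kind = source.column_kind(params.source_column)
    target_kind = target.column_kind(params.target_column)
    if source_kind != target_kind:
        raise ColumnKindError(
            f"mapping columns disagree in type: source {params.source_column!r} is "
            f"{source_kind}, target {params.target_column!r} is {target_kind}"
        )
    if source_kind not in (STRING, INTEGER):
        raise ColumnKindError(
            f"mapping columns must both be string or integer typed, not {source_kind}"
        )
    return source_kind


def build_source_position_map(
    source_view: NetworkView, source_graph: NetworkGraph, source_column: str, kind: str
) -> PositionMap:
    """Pass one: map each present source value to its node's coordinates.

    Iterates in stored node order so a later node carrying a duplicate value
    overwrites the earlier one; nodes with a missing value contribute
    nothing.
    """
    pmap: PositionMap = {}
    for node in source_graph.nodes:
        key = AttributeValue.of(node.get(source_column), kind)
        if key is not None:
            pmap[key] = source_view.node_view(node.node_id).position
    return pmap


def transfer_positions(
    target_view: NetworkView,
    target_graph: NetworkGraph,
    target_column: str,
    pmap: PositionMap,
    kind: str,
) -> tuple[list[int], list[int]]:
    """Pass two: move every matched target node onto its source coordinates.

    Unmatched nodes (value missing or absent from the map) are left exactly
    where they were. Returns ``(matched_ids, unmatched_ids)`` — two disjoint
    lists, in stored node order, covering every target node.
    """
    matched: list[int] = []
    unmatched: list[int] = []
    for node in target_graph.nodes:
        key = AttributeValue.of(node.get(target_column), kind)
        position = pmap.get(key) if key is not None else None
        if position is None:
            unmatched.append(node.node_id)
        else:
            target_view.node_view(node.node_id).move_to(position)
            matched.append(node.node_id)
    return matched, unmatched


def matched_value_set(
    target_graph: NetworkGraph, target_column: str, kind: str, matched_ids: list[int]
) -> set[AttributeValue]:
    """The set of mapping values the matched target nodes carry."""
    wanted = set(matched_ids)
    return {
        AttributeValue.of(node.get(target_column), kind)
        for node in target_graph.nodes
        if node.node_id in wanted
    }


def unmapped_source_node_ids(
    source_graph: NetworkGraph,
    source_column: str,
    kind: str,
    matched_values: set[AttributeValue],
) -> list[int]:
    """Source nodes whose value no target node matched (missing value counts
    as unmapped — there is no key to compare)."""
    out = []
    for node in source_graph.nodes:
        key = AttributeValue.of(node.get(source_column), kind)
        if key is None or key not in matched_values:
            out.append(node.node_id)
    return out


def select_unmapped(
    source_view: NetworkView,
    target_view: NetworkView,
    unmapped_source_ids: list[int],
    unmapped_target_ids: list[int],
) -> tuple[int, int]:
    """Select exactly the unmapped nodes on both sides.

    All prior selection flags in both views are cleared first, so a
    subsequent "selected nodes" query returns precisely the unmapped sets.
    Returns the two selection sizes (source, target).
    """
    for view in (source_view, target_view):
        for nv in view.node_views.values():
            nv.selected = False
    for node_id in unmapped_source_ids:
        source_view.node_view(node_id).selected = True
    for node_id in unmapped_target_ids:
        target_view.node_view(node_id).selected = True
    return len(unmapped_source_ids), len(unmapped_target_ids)


def grid_unmapped(
    target_view: NetworkView,
    unmatched_ids: list[int],
    matched_ids: list[int],
    spacing: float = DEFAULT_GRID_SPACING,
) -> None:
    """Place unmatched target nodes on a regular grid top-right of the
    mapped nodes.

    The grid anchors at ``(max_x + spacing, min_y)`` of the mapped nodes'
    bounding box — one cell to the right of its top-right corner, since y
    grows downward — or at the origin when nothing was mapped. Cells fill
    row-major in stored node order with ``ceil(sqrt(k))`` columns; z is left
    unchanged.
    """
    if not unmatched_ids:
        return
    if matched_ids:
        xs = [target_view.node_view(i).x for i in matched_ids]
        ys = [target_view.node_view(i).y for i in matched_ids]
        anchor_x, anchor_y = max(xs) + spacing, min(ys)
    else:
        anchor_x, anchor_y = 0.0, 0.0
    n_cols = math.ceil(math.sqrt(len(unmatched_ids)))
    for index, node_id in enumerate(unmatched_ids):
        row, col = divmod(index, n_cols)
        nv = target_view.node_view(node_id)
        nv.x = anchor_x + col * spacing
        nv.y = anchor_y + row * spacing


def clone_viewport(
    source_view: NetworkView,
    target_view: NetworkView,
    source_graph: Optional[NetworkGraph] = None,
) -> None:
    """Copy zoom and center from source to target so both views render at
    the same scale and location. An empty source view (no nodes) has nothing
    meaningful to clone; the target viewport is left untouched."""
    if source_graph is not None and not source_graph.nodes:
        return
    target_view.viewport.zoom = source_view.viewport.zoom
    target_view.viewport.center_x = source_view.viewport.center_x
    target_view.viewport.center_y = source_view.viewport.center_y


def copycat(
    registry: SessionRegistry,
    source_view_sel: Union[int, str],
    target_view_sel: Union[int, str],
    params: Optional[CopycatParams] = None,
) -> CopycatResult:
    """Run the full layout transfer between two views in a session.

    Resolves the view selectors (integer SUIDs or ``"current"``), validates
    the mapping columns, runs the two passes, applies the optional
    selection and grid post-passes (selection first, so both options
    compose), and clones the viewport. Raises :class:`ValidationError` when
    source and target resolve to the same view.
    """
    params = params or CopycatParams()
    source_view = registry.resolve_view(source_view_sel)
    target_view = registry.resolve_view(target_view_sel)
    if source_view.view_suid == target_view.view_suid:
        raise ValidationError("source and target must reference different views")
    source_graph = registry.network_for_view(source_view)
    target_graph = registry.network_for_view(target_view)

    kind = validate_mapping_columns(source_graph, target_graph, params)
    pmap = build_source_position_map(source_view, source_graph, params.source_column, kind)
    matched, unmatched = transfer_positions(
        target_view, target_graph, params.target_column, pmap, kind
    )
    values_hit = matched_value_set(target_graph, params.target_column, kind, matched)
    unmapped_source = unmapped_source_node_ids(
        source_graph, params.source_column, kind, values_hit
    )

    if params.select_unmapped:
        select_unmapped(source_view, target_view, unmapped_source, unmatched)
    if params.grid_unmapped:
        grid_unmapped(target_view, unmatched, matched, params.grid_spacing)
    clone_viewport(source_view, target_view, source_graph)

    return CopycatResult(
        mapped_node_count=len(matched),
        unmapped_node_count=len(unmatched),
        unmapped_target_ids=unmatched,
        unmapped_source_ids=unmapped_source,
    )
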