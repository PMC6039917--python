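"""Synthetic network-pair generator and a brute-force matching oracle.

The generator builds a (source, target) pair of attributed, laid-out
networks with controlled value overlap, duplicate values, missing values and
random edges, together with *independently derived* ground-truth mapping
expectations — the expectations are computed from the construction plan, not
by running the matcher. The brute-force oracle re-derives the matching
semantics with a naive O(N·M) all-pairs scan (last equal source node wins).
Agreement of the fast two-pass implementation with both is the central
correctness check of the package.

Mapping values come from a universe of zero-padded decimal strings, so
lexicographic equality is plain string equality with no locale sensitivity.
Edges are generated but never consulted by the expectations, which makes the
edge-independence property directly testable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .errors import ValidationError
from .io import LoadedNetwork, read_cyjs
from .model import (
    INTEGER,
    STRING,
    ColumnDef,
    Coordinates,
    EdgeRecord,
    NetworkGraph,
    NodeRecord,
    SessionRegistry,
)

_NAME_WIDTH = 6  # zero-padded width; supports the largest benchmark sizes
_FRESH_OFFSET = 500_000  # fresh target names start here, disjoint from source


@dataclass(frozen=True)
class PairSpec:
    """Recipe for one synthetic source/target pair.

    ``overlap_fraction`` of the target nodes carry values drawn (without
    replacement) from the source's distinct values; ``missing_rate`` of them
    carry no value at all; the rest get fresh values absent from the source.
    ``duplicate_rate`` of the source nodes repeat an earlier source value.
    Coordinates are uniform in ``[-coordinate_range, coordinate_range]``²
    with z = 0. Everything is deterministic under ``seed``; ``edge_seed``
    (defaulting to a value derived from ``seed``) controls only the random
    edge sets, so two pairs differing only in ``edge_seed`` have identical
    nodes, values and coordinates.
    """

    n_source: int = 50
    n_target: int = 50
    overlap_fraction: float = 0.6
    duplicate_rate: float = 0.0
    missing_rate: float = 0.0
    coordinate_range: float = 500.0
    seed: int = 0
    value_kind: str = STRING
    edge_seed: Optional[int] = None

    def validate(self) -> None:
        for name in ("overlap_fraction", "duplicate_rate", "missing_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {rate}")
        if self.n_source < 0 or self.n_target < 0:
            raise ValidationError("node counts must be non-negative")
        if self.value_kind not in (STRING, INTEGER):
            raise ValidationError(f"value_kind must be string or integer, not {self.value_kind}")


@dataclass
class PairExpectation:
    """Ground truth for one generated pair, derived from the construction
    plan alone (never from running any matcher)."""

    mapped_target_ids: set[int] = field(default_factory=set)
    unmapped_target_ids: set[int] = field(default_factory=set)
    unmapped_source_ids: set[int] = field(default_factory=set)
    shared_values: set[object] = field(default_factory=set)


@dataclass
class GeneratedPair:
    source: LoadedNetwork
    target: LoadedNetwork
    expected: PairExpectation
    spec: PairSpec


def _value(index: int, kind: str) -> object:
    return index if kind == INTEGER else f"{index:0{_NAME_WIDTH}d}"


def _random_edges(rng: random.Random, node_ids: list[int], count: int) -> list[EdgeRecord]:
    if len(node_ids) < 2:
        return []
    return [
        EdgeRecord(rng.choice(node_ids), rng.choice(node_ids), "pp") for _ in range(count)
    ]


def generate_pair(spec: PairSpec) -> GeneratedPair:
    """Build a deterministic source/target pair plus ground-truth sets.

    Raises :class:`ValidationError` for an infeasible recipe — when the
    requested overlap demands more shared values than the source has
    distinct ones, or overlap and missingness together exceed the target
    size.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    kind = spec.value_kind
    coord = lambda: (  # noqa: E731 - tiny local sampler
        rng.uniform(-spec.coordinate_range, spec.coordinate_range),
        rng.uniform(-spec.coordinate_range, spec.coordinate_range),
        0.0,
    )

    # --- source: unique values, then a duplicate_rate fraction repeating one
    n_dup = round(spec.duplicate_rate * spec.n_source)
    n_unique = spec.n_source - n_dup
    if n_dup and n_unique == 0:
        raise ValidationError("duplicate_rate leaves no unique source value to repeat")
    unique_values = [_value(i, kind) for i in range(n_unique)]
    source_values = list(unique_values)
    source_values += [rng.choice(unique_values) for _ in range(n_dup)]
    rng.shuffle(source_values)

    source_nodes = [
        NodeRecord(i, {"name": v}) for i, v in enumerate(source_values)
    ]
    source_positions: dict[int, Coordinates] = {n.node_id: coord() for n in source_nodes}

    # --- target: shared / missing / fresh partition, then shuffled
    k_shared = round(spec.overlap_fraction * spec.n_target)
    k_missing = round(spec.missing_rate * spec.n_target)
    if k_shared > len(unique_values):
        raise ValidationError(
            f"overlap demands {k_shared} shared values but the source has only "
            f"{len(unique_values)} distinct ones"
        )
    if k_shared + k_missing > spec.n_target:
        raise ValidationError("overlap_fraction and missing_rate together exceed the target size")
    k_fresh = spec.n_target - k_shared - k_missing

    shared = rng.sample(unique_values, k_shared)
    fresh = [_value(_FRESH_OFFSET + i, kind) for i in range(k_fresh)]
    plan: list[object] = list(shared) + [None] * k_missing + list(fresh)
    rng.shuffle(plan)

    target_nodes = []
    expected = PairExpectation(shared_values=set(shared))
    for i, value in enumerate(plan):
        attrs = {} if value is None else {"name": value}
        target_nodes.append(NodeRecord(i, attrs))
        (expected.mapped_target_ids if value in expected.shared_values and value is not None
         else expected.unmapped_target_ids).add(i)
    target_positions: dict[int, Coordinates] = {n.node_id: coord() for n in target_nodes}

    shared_set = expected.shared_values
    expected.unmapped_source_ids = {
        n.node_id for n in source_nodes if n.attributes.get("name") not in shared_set
    }

    # --- edges: sparse, random, and by construction irrelevant to the truth
    edge_rng = random.Random(spec.edge_seed if spec.edge_seed is not None else spec.seed + 7)
    source_edges = _random_edges(edge_rng, [n.node_id for n in source_nodes], spec.n_source)
    target_edges = _random_edges(edge_rng, [n.node_id for n in target_nodes], spec.n_target)

    columns = [ColumnDef("name", kind)]
    source = LoadedNetwork(
        NetworkGraph("synthetic-source", list(columns), source_nodes, source_edges),
        source_positions,
    )
    target = LoadedNetwork(
        NetworkGraph("synthetic-target", list(columns), target_nodes, target_edges),
        target_positions,
    )
    source.graph.validate()
    target.graph.validate()
    return GeneratedPair(source, target, expected, spec)


@dataclass
class BruteForceResult:
    """Assignment and bookkeeping produced by the naive all-pairs matcher."""

    assignment: dict[int, Coordinates]  # target node id -> transferred coords
    matched_target_ids: list[int]
    unmatched_target_ids: list[int]
    unmapped_source_ids: list[int]

    @property
    def mapped_node_count(self) -> int:
        return len(self.matched_target_ids)

    @property
    def unmapped_node_count(self) -> int:
        return len(self.unmatched_target_ids)


def _values_equal(a: object, b: object, kind: str) -> bool:
    if a is None or b is None:
        return False
    if kind == INTEGER:
        return int(a) == int(b)  # type: ignore[arg-type]
    return str(a) == str(b)


def brute_force_copycat(
    source: LoadedNetwork,
    target: LoadedNetwork,
    source_column: str = "name",
    target_column: str = "name",
) -> BruteForceResult:
    """Naive O(N·M) re-derivation of the matching semantics.

    For every target node, scan *all* source nodes in stored order and keep
    the coordinates of the last one whose value is equal (string equality
    for string columns, numeric for integer columns). Source nodes whose
    value equals no matched target value — or who have no value — are
    unmapped.
    """
    kind = source.graph.column_kind(source_column)
    assert kind == target.graph.column_kind(target_column)

    assignment: dict[int, Coordinates] = {}
    matched, unmatched = [], []
    for t in target.graph.nodes:
        tv = t.get(target_column)
        hit = None
        for s in source.graph.nodes:  # full scan; the LAST equal node wins
            if _values_equal(s.get(source_column), tv, kind):
                hit = s.node_id
        if hit is None:
            unmatched.append(t.node_id)
        else:
            assignment[t.node_id] = source.positions.get(hit, (0.0, 0.0, 0.0))
            matched.append(t.node_id)

    matched_set = set(matched)
    unmapped_source = []
    for s in source.graph.nodes:
        sv = s.get(source_column)
        hit_any = any(
            _values_equal(sv, t.get(target_column), kind)
            for t in target.graph.nodes
            if t.node_id in matched_set
        )
        if not hit_any:
            unmapped_source.append(s.node_id)
    return BruteForceResult(assignment, matched, unmatched, unmapped_source)


# ---------------------------------------------------------------------------
# the worked eight-vs-nine-node fixture


def _fixture_path(name: str):
    return resources.files("copycat_layout") / "fixtures" / name


def worked_example_fixture() -> tuple[LoadedNetwork, LoadedNetwork]:
    """The shipped worked example: a laid-out source with nodes A–H and a
    derived target with nodes A–G plus two novel nodes N and O."""
    with resources.as_file(_fixture_path("worked_source.cyjs")) as p:
        source = read_cyjs(p)
    with resources.as_file(_fixture_path("worked_target.cyjs")) as p:
        target = read_cyjs(p)
    return source, target


def worked_example_session() -> tuple[SessionRegistry, dict]:
    """A fresh session with the worked fixture registered; returns the
    registry and the SUIDs of both networks and views."""
    registry = SessionRegistry()
    source, target = worked_example_fixture()
    s_suid, s_view = source.register(registry)
    t_suid, t_view = target.register(registry)
    return registry, {
        "source_suid": s_suid,
        "source_view_suid": s_view,
        "target_suid": t_suid,
        "target_view_suid": t_view,
    }
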