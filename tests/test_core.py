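"""Layout transfer semantics: last-wins map, stacking, value-level matching,
selection, grid placement, viewport cloning, and the algebraic properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copycat_layout.core import (
    CopycatParams,
    build_source_position_map,
    clone_viewport,
    copycat,
    grid_unmapped,
    transfer_positions,
    validate_mapping_columns,
)
from copycat_layout.errors import ColumnKindError, NotFoundError, ValidationError
from copycat_layout.model import AttributeValue, SessionRegistry
from copycat_layout.testkit import PairSpec, brute_force_copycat, generate_pair

from conftest import make_loaded, view_snapshot


def register_pair(source, target, **params):
    registry = SessionRegistry()
    _, source_view = source.register(registry)
    _, target_view = target.register(registry)
    return registry, source_view, target_view, CopycatParams(**params)


# ---------------------------------------------------------------------------
# pass one: the source position map


def test_last_encountered_duplicate_source_value_wins(registry):
    loaded = make_loaded(["X", "X"], [(0, 0), (5, 5)])
    _, view_suid = loaded.register(registry)
    pmap = build_source_position_map(registry.views[view_suid], loaded.graph, "name", "string")
    assert pmap == {AttributeValue("string", "X"): (5.0, 5.0, 0.0)}


def test_empty_source_gives_empty_map(registry):
    loaded = make_loaded([])
    _, view_suid = loaded.register(registry)
    assert build_source_position_map(registry.views[view_suid], loaded.graph, "name", "string") == {}


def test_missing_source_value_contributes_no_key(registry):
    loaded = make_loaded(["A", None], [(1, 1), (2, 2)])
    _, view_suid = loaded.register(registry)
    pmap = build_source_position_map(registry.views[view_suid], loaded.graph, "name", "string")
    assert set(pmap) == {AttributeValue("string", "A")}


# ---------------------------------------------------------------------------
# pass two: transfer


def test_duplicate_target_values_stack_at_source_coordinates():
    source = make_loaded(["X"], [(5, 5)])
    target = make_loaded(["X", "X"], [(0, 0), (9, 9)], id_base=100)
    registry, sv, tv, params = register_pair(source, target)
    copycat(registry, sv, tv, params)
    view = registry.views[tv]
    assert view.node_views[100].position == (5.0, 5.0, 0.0)
    assert view.node_views[101].position == (5.0, 5.0, 0.0)


def test_empty_map_leaves_all_coordinates_unchanged(registry):
    target = make_loaded(["A", "B"], [(1, 2), (3, 4)])
    _, view_suid = target.register(registry)
    matched, unmatched = transfer_positions(
        registry.views[view_suid], target.graph, "name", {}, "string"
    )
    assert matched == [] and unmatched == [0, 1]
    assert registry.views[view_suid].node_views[0].position == (1.0, 2.0, 0.0)


def test_identical_networks_transfer_bit_exactly():
    coords = [(0.1, -2.7), (3.14159, 8.5), (-7.25, 0.0)]
    source = make_loaded(["a", "b", "c"], coords)
    target = make_loaded(["a", "b", "c"], [(0, 0)] * 3, id_base=10)
    registry, sv, tv, params = register_pair(source, target)
    result = copycat(registry, sv, tv, params)
    assert result.mapped_node_count == 3 and result.unmapped_node_count == 0
    for i, (x, y) in enumerate(coords):
        assert registry.views[tv].node_views[10 + i].position == (x, y, 0.0)


def test_integer_kind_matches_numerically():
    source = make_loaded([7, 8], [(1, 1), (2, 2)], kind="integer")
    target = make_loaded([8], [(0, 0)], kind="integer", id_base=50)
    registry, sv, tv, params = register_pair(source, target)
    result = copycat(registry, sv, tv, params)
    assert result.mapped_node_count == 1
    assert registry.views[tv].node_views[50].position == (2.0, 2.0, 0.0)


# ---------------------------------------------------------------------------
# column validation


def test_validate_columns_happy_and_sad_paths():
    string_net = make_loaded(["a"]).graph
    int_net = make_loaded([1], kind="integer").graph
    assert validate_mapping_columns(string_net, string_net, CopycatParams()) == "string"
    assert validate_mapping_columns(int_net, int_net, CopycatParams()) == "integer"
    with pytest.raises(ColumnKindError):
        validate_mapping_columns(string_net, int_net, CopycatParams())
    with pytest.raises(NotFoundError):
        validate_mapping_columns(string_net, string_net, CopycatParams(target_column="foo"))


# ---------------------------------------------------------------------------
# selection of unmapped nodes


def test_selection_matches_worked_example_sets():
    source = make_loaded(list("ABCDEFGH"), [(i * 10, 0) for i in range(8)])
    target = make_loaded(list("ABCDEFG") + ["N", "O"], [(0, i * 10) for i in range(9)], id_base=100)
    registry, sv, tv, params = register_pair(source, target, select_unmapped=True)
    result = copycat(registry, sv, tv, params)
    assert registry.views[sv].selected_node_ids() == [7]       # H
    assert registry.views[tv].selected_node_ids() == [107, 108]  # N, O
    assert (result.mapped_node_count, result.unmapped_node_count) == (7, 2)


def test_identical_networks_select_nothing():
    source = make_loaded(["a", "b"], [(0, 0), (1, 1)])
    target = make_loaded(["a", "b"], [(5, 5), (6, 6)], id_base=10)
    registry, sv, tv, params = register_pair(source, target, select_unmapped=True)
    copycat(registry, sv, tv, params)
    assert registry.views[sv].selected_node_ids() == []
    assert registry.views[tv].selected_node_ids() == []


def test_duplicate_source_values_count_as_mapped_when_value_matches():
    """Matching is by value: one target hit marks every source node
    carrying that value as mapped."""
    source = make_loaded(["X", "X"], [(0, 0), (5, 5)])
    target = make_loaded(["X"], [(9, 9)], id_base=10)
    registry, sv, tv, params = register_pair(source, target, select_unmapped=True)
    result = copycat(registry, sv, tv, params)
    assert registry.views[sv].selected_node_ids() == []
    assert result.unmapped_source_ids == []


def test_select_true_clears_stale_selections():
    source = make_loaded(["a"], [(0, 0)])
    target = make_loaded(["a"], [(1, 1)], id_base=10)
    registry, sv, tv, params = register_pair(source, target, select_unmapped=True)
    registry.views[sv].node_views[0].selected = True
    registry.views[tv].node_views[10].selected = True
    copycat(registry, sv, tv, params)
    assert registry.views[sv].selected_node_ids() == []
    assert registry.views[tv].selected_node_ids() == []


def test_select_false_leaves_prior_selections_untouched():
    source = make_loaded(["a"], [(0, 0)])
    target = make_loaded(["a", "z"], [(1, 1), (2, 2)], id_base=10)
    registry, sv, tv, params = register_pair(source, target)
    registry.views[tv].node_views[10].selected = True
    copycat(registry, sv, tv, params)
    assert registry.views[tv].selected_node_ids() == [10]


def test_missing_target_value_is_unmapped_and_selected():
    source = make_loaded(["a"], [(4, 4)])
    target = make_loaded(["a", None], [(0, 0), (1, 1)], id_base=20)
    registry, sv, tv, params = register_pair(source, target, select_unmapped=True)
    result = copycat(registry, sv, tv, params)
    assert result.unmapped_target_ids == [21]
    assert registry.views[tv].selected_node_ids() == [21]
    assert registry.views[tv].node_views[21].position == (1.0, 1.0, 0.0)


# ---------------------------------------------------------------------------
# grid placement


def test_grid_noop_without_unmatched(registry):
    target = make_loaded(["a"], [(3, 3)])
    _, view_suid = target.register(registry)
    grid_unmapped(registry.views[view_suid], [], [0])
    assert registry.views[view_suid].node_views[0].position == (3.0, 3.0, 0.0)


def test_grid_single_node_anchor():
    """Anchor sits one spacing right of the mapped bounding box, at its top."""
    source = make_loaded(["a", "b"], [(0, 0), (100, 40)])
    target = make_loaded(["a", "b", "zz"], [(0, 0), (0, 0), (-5, -5)], id_base=10)
    registry, sv, tv, params = register_pair(source, target, grid_unmapped=True)
    copycat(registry, sv, tv, params)
    assert registry.views[tv].node_views[12].position == (180.0, 0.0, 0.0)


def test_grid_five_nodes_three_columns_row_major():
    source = make_loaded(["m"], [(100, 0)])
    extras = ["u1", "u2", "u3", "u4", "u5"]
    target = make_loaded(["m"] + extras, [(0, 0)] * 6, id_base=10)
    registry, sv, tv, params = register_pair(source, target, grid_unmapped=True)
    copycat(registry, sv, tv, params)
    view = registry.views[tv]
    anchor = (100.0 + 80.0, 0.0)
    expected = [
        (anchor[0] + 0 * 80, anchor[1] + 0 * 80),
        (anchor[0] + 1 * 80, anchor[1] + 0 * 80),
        (anchor[0] + 2 * 80, anchor[1] + 0 * 80),
        (anchor[0] + 0 * 80, anchor[1] + 1 * 80),
        (anchor[0] + 1 * 80, anchor[1] + 1 * 80),
    ]
    got = [(view.node_views[11 + i].x, view.node_views[11 + i].y) for i in range(5)]
    assert got == expected


def test_grid_without_mapped_nodes_anchors_at_origin():
    source = make_loaded(["nomatch"], [(50, 50)])
    target = make_loaded(["a", "b"], [(7, 7), (8, 8)], id_base=10)
    registry, sv, tv, params = register_pair(source, target, grid_unmapped=True)
    copycat(registry, sv, tv, params)
    view = registry.views[tv]
    assert (view.node_views[10].x, view.node_views[10].y) == (0.0, 0.0)
    assert (view.node_views[11].x, view.node_views[11].y) == (80.0, 0.0)


def test_grid_respects_custom_spacing_and_keeps_z():
    source = make_loaded(["a"], [(0, 0)])
    target = make_loaded(["a", "u"], [(0, 0, 0), (1, 1, 3.5)], id_base=10)
    registry, sv, tv, params = register_pair(
        source, target, grid_unmapped=True, grid_spacing=10.0
    )
    copycat(registry, sv, tv, params)
    nv = registry.views[tv].node_views[11]
    assert (nv.x, nv.y, nv.z) == (10.0, 0.0, 3.5)


# ---------------------------------------------------------------------------
# viewport cloning


def test_clone_viewport_copies_zoom_and_center():
    source = make_loaded(["a"], [(0, 0)])
    target = make_loaded(["a"], [(0, 0)], id_base=10)
    registry, sv, tv, params = register_pair(source, target)
    registry.views[sv].viewport.zoom = 2.0
    registry.views[sv].viewport.center_x = 10.0
    registry.views[sv].viewport.center_y = -5.0
    copycat(registry, sv, tv, params)
    vp = registry.views[tv].viewport
    assert (vp.zoom, vp.center_x, vp.center_y) == (2.0, 10.0, -5.0)
    # idempotent
    copycat(registry, sv, tv, params)
    assert (vp.zoom, vp.center_x, vp.center_y) == (2.0, 10.0, -5.0)


def test_clone_viewport_skipped_for_empty_source(registry):
    source = make_loaded([])
    target = make_loaded(["a"], [(0, 0)])
    _, sv = source.register(registry)
    _, tv = target.register(registry)
    registry.views[tv].viewport.zoom = 3.0
    clone_viewport(registry.views[sv], registry.views[tv], source.graph)
    assert registry.views[tv].viewport.zoom == 3.0


# ---------------------------------------------------------------------------
# orchestration errors


def test_copycat_rejects_identical_views(demo_session):
    registry, suids = demo_session
    with pytest.raises(ValidationError, match="different views"):
        copycat(registry, suids["source_view_suid"], suids["source_view_suid"])


def test_copycat_propagates_resolution_errors(demo_session):
    registry, suids = demo_session
    with pytest.raises(NotFoundError):
        copycat(registry, 999999, suids["target_view_suid"])


# ---------------------------------------------------------------------------
# properties: conservation, idempotence, edge independence, oracle agreement


def run_against_oracle(spec: PairSpec):
    pair = generate_pair(spec)
    registry = SessionRegistry()
    _, sv = pair.source.register(registry)
    _, tv = pair.target.register(registry)
    result = copycat(registry, sv, tv, CopycatParams(select_unmapped=True))
    oracle = brute_force_copycat(pair.source, pair.target)
    return pair, registry, sv, tv, result, oracle


def assert_matches_oracle(pair, registry, sv, tv, result, oracle):
    assert result.mapped_node_count == oracle.mapped_node_count
    assert result.unmapped_node_count == oracle.unmapped_node_count
    assert set(result.unmapped_target_ids) == set(oracle.unmatched_target_ids)
    assert set(result.unmapped_source_ids) == set(oracle.unmapped_source_ids)
    view = registry.views[tv]
    for node_id, coords in oracle.assignment.items():
        assert view.node_views[node_id].position == coords
    assert set(view.selected_node_ids()) == set(oracle.unmatched_target_ids)
    assert set(registry.views[sv].selected_node_ids()) == set(oracle.unmapped_source_ids)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**20),
    n_source=st.integers(1, 40),
    n_target=st.integers(0, 40),
    overlap=st.sampled_from([0.0, 0.25, 0.5, 1.0]),
    duplicate_rate=st.sampled_from([0.0, 0.3]),
    missing_rate=st.sampled_from([0.0, 0.3]),
    kind=st.sampled_from(["string", "integer"]),
)
def test_copycat_agrees_with_brute_force_oracle(
    seed, n_source, n_target, overlap, duplicate_rate, missing_rate, kind
):
    spec = PairSpec(
        n_source=n_source,
        n_target=n_target,
        overlap_fraction=overlap,
        duplicate_rate=duplicate_rate,
        missing_rate=missing_rate,
        seed=seed,
        value_kind=kind,
    )
    try:
        pair, registry, sv, tv, result, oracle = run_against_oracle(spec)
    except ValidationError:
        return  # infeasible recipe (overlap exceeds distinct source values)
    assert_matches_oracle(pair, registry, sv, tv, result, oracle)
    # conservation
    assert result.mapped_node_count + result.unmapped_node_count == len(pair.target.graph.nodes)


@pytest.mark.parametrize("grid", [False, True])
def test_copycat_is_idempotent(grid):
    spec = PairSpec(n_source=30, n_target=30, overlap_fraction=0.6,
                    duplicate_rate=0.1, missing_rate=0.1, seed=11)
    pair = generate_pair(spec)
    registry = SessionRegistry()
    _, sv = pair.source.register(registry)
    _, tv = pair.target.register(registry)
    params = CopycatParams(select_unmapped=True, grid_unmapped=grid)
    first = copycat(registry, sv, tv, params)
    snap = (view_snapshot(registry.views[sv]), view_snapshot(registry.views[tv]))
    second = copycat(registry, sv, tv, params)
    assert (view_snapshot(registry.views[sv]), view_snapshot(registry.views[tv])) == snap
    assert first == second


def test_edges_never_influence_the_result():
    base = PairSpec(n_source=25, n_target=25, overlap_fraction=0.5, seed=3, edge_seed=1)
    rewired = PairSpec(n_source=25, n_target=25, overlap_fraction=0.5, seed=3, edge_seed=2)
    outputs = []
    for spec in (base, rewired):
        pair, registry, sv, tv, result, _ = run_against_oracle(spec)
        outputs.append((result, view_snapshot(registry.views[tv]), view_snapshot(registry.views[sv])))
    edges_a = generate_pair(base).target.graph.edges
    edges_b = generate_pair(rewired).target.graph.edges
    assert [(e.source_id, e.target_id) for e in edges_a] != [
        (e.source_id, e.target_id) for e in edges_b
    ]  # the edge sets really differ
    assert outputs[0] == outputs[1]
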