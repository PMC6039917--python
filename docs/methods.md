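# Methods

## The operation

copycat-layout aligns two rendered network views. A *view* assigns each
node of an attributed network a screen position (x rightward, y downward,
z normally 0) and a selected flag, and carries a viewport (zoom scale plus
center point). The transfer matches nodes between the source and target
networks through the values of one node-table column per side and moves
matched target nodes onto the source coordinates.

The matcher is deliberately value-based, not node-based. Pass one reduces
the source view to a hash map `value → coordinates`; node identity is
erased at that point, which fixes the semantics of every duplicate case:

* several **source** nodes share a value → the last one in stored node
  order supplies the coordinates (map overwrite);
* several **target** nodes share a value → all are moved to the same
  point (stacking);
* a source value matched by *any* target node counts **every** source node
  carrying it as mapped — none of them is selected as unmapped;
* a node with a missing value in its mapping column can never match: it
  contributes nothing in pass one and counts as unmapped in pass two.

Values compare within one kind only. Both mapping columns must be
string-typed or both integer-typed; string values match on exact string
equality, integer values numerically. A string `"7"` never matches an
integer `7` — the kind agreement is validated before any matching, and
columns of any other kind (floating point, boolean) are rejected as
mapping keys outright, because rounding and locale would make "equality"
ambiguous.

Stored node order is part of the data model contract: every reader
preserves file order, and registration preserves reader order, so "last
encountered" is reproducible across formats and round-trips.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `source_column`, `target_column` | `"name"` | mapping columns; may differ by name but must agree in kind |
| `select_unmapped` | false | select unmapped nodes on both sides (clearing prior selections first) |
| `grid_unmapped` | false | grid-place unmatched target nodes; independent of `select_unmapped` |
| `grid_spacing` | 80 view units | grid cell size and the gap between the mapped bounding box and the grid |

Selection semantics were genuinely open: with `select_unmapped=true` we
first clear every selection flag in both views, so the post-condition is
crisp — the selected set *equals* the unmapped set, which is what a
downstream "get selected nodes" query needs. With `select_unmapped=false`
all flags are left untouched (running the layout must not silently destroy
a user's selection). Gridding runs after selection so the two options
compose; gridding without selecting is allowed.

The grid anchors at `(max_x + spacing, min_y)` of the **mapped** target
nodes' bounding box — one cell to the right of its top-right corner, y
growing downward — and falls back to the origin when nothing mapped.
"Top right" is a convention this package defines precisely so it can be
tested; the cell walk is row-major in stored node order with
`ceil(sqrt(k))` columns. Because the anchor depends only on mapped nodes,
whose positions are fixed after pass two, the whole operation is
idempotent: a second identical run changes nothing.

Viewport cloning copies zoom and center verbatim. "Location" is modeled as
the view center (not a top-left pan offset); an empty source network has
no meaningful viewport to clone, so the target viewport is then left
untouched. Z coordinates transfer when present; formats without z read and
write 0.

## Complexity

Pass one is O(N) time and memory, pass two O(M) time with dictionary
lookups, the post-passes O(N + M); nothing touches edges. The benchmark
(acceptance script and test) times the transfer alone — session building
excluded — at N = M ∈ {10³, 10⁴, 10⁵} with 60 % value overlap, takes the
best of three runs with the garbage collector paused to keep collector
pauses out of the measurement, and fits log time against log N by least
squares. The fitted slope on these sizes is ≈ 1.1–1.2 rather than exactly
1.0: per-operation dictionary costs grow slightly as the hash tables
outgrow the CPU caches, which is a property of the memory hierarchy, not
of the algorithm; the test bound (< 1.3) distinguishes this comfortably
from quadratic behavior.

## The service surface

The REST facade is a plain WSGI application (standard library only)
mirroring the Cytoscape Automation conventions: a PUT *Function* endpoint
with view SUIDs in the URL, a POST *Command* endpoint addressing networks
by name, and the CIResponse envelope `{"data": ..., "errors": [...]}` with
`errors[0].status` always equal to the HTTP status. Unresolvable views and
mapping-column problems (absent column *or* kind mismatch) are 404s —
the column family deliberately follows the wire contract rather than the
library's validation-vs-lookup distinction; malformed payloads and
same-view (or same-network) requests are 400s. Error `type` strings are
namespaced URNs (`urn:cytoscape:ci:copycat-app:v1:errors:<status>`).
Name-addressed calls operate on the network's *primary* view (its
first-registered one); if two loaded networks share a name, the
lowest-SUID one wins — a deterministic choice in preference to an error,
since name addressing is inherently fragile. The Command endpoint accepts
booleans as JSON booleans or the strings `"true"`/`"false"`, because
shell-style clients commonly send strings. A one-line command-string
parser (`layout copycat key=value ...`) is provided for script parity.

SUIDs are allocated monotonically from one per-session counter (starting
at an arbitrary non-zero base), shared by networks and views, so the two
id spaces can never collide and ids are never reused within a session.

## The synthetic-pair generator

Property tests and the acceptance sweeps run on pairs from
`copycat_layout.testkit.generate_pair`, controlled by a `PairSpec`:

* **values** come from a universe of zero-padded decimal strings (or plain
  integers for integer-kind runs), so lexicographic equality is exact
  string equality with no locale sensitivity;
* `overlap_fraction` of the target nodes draw their value from the
  source's distinct values without replacement (a recipe demanding more
  shared values than the source has distinct ones is rejected);
  `missing_rate` of them carry no value; the rest get fresh values absent
  from the source; `duplicate_rate` of the source nodes repeat an earlier
  source value;
* coordinates are uniform in `[-500, 500]²` (z = 0) by default; node
  counts default to 50/50 and the sweeps vary them from empty to 50;
* sparse random edges are attached but never consulted when the ground
  truth is derived, which is what makes the edge-independence property a
  real test: a separate `edge_seed` regenerates the same pair with
  different edges;
* the expected mapped/unmapped sets are computed from the construction
  plan alone, giving a second derivation that is independent of both the
  implementation and the brute-force matcher.

The brute-force oracle (`brute_force_copycat`) re-derives the semantics
naively: for each target node it scans *all* source nodes in stored order
and keeps the last equal one — O(N·M) by construction and sharing no code
with the two-pass implementation.

What the generator does **not** emulate: realistic biological topology
(no scale-free or modular structure — irrelevant here, since edges cannot
influence the result), meaningful attribute tables beyond the mapping
column, multi-view sessions, and visual styles. Passing tests therefore
demonstrate the matching, placement and contract semantics, not anything
about the biological plausibility of the inputs.

## Numerical and format conventions

* Coordinates transfer bit-exactly — assignment, never arithmetic — and
  the round-trip tests require full-precision equality through JSON and
  GraphML (Python's lossless float repr).
* cyjs column typing is inferred: a column is integer iff every present
  value is an integral JSON number; all-digit *strings* such as `"0007"`
  stay strings, so zero-padding survives round-trips.
* The SIF writer declares every node as a bare line before the edge lines;
  redundant, but it pins first-appearance order so SIF round-trips
  preserve node order like the other formats. SIF lines split on tabs when
  a tab is present (allowing spaces inside names), otherwise on
  whitespace. Layout-table rows naming unknown nodes are skipped with a
  logged warning rather than failing, since side-car tables commonly drift
  from the edge list.
* Degenerate inputs: an empty source yields an empty map (every target
  node unmapped, nothing moves, viewport untouched); an empty target
  yields counts (0, 0); registering a network with no layout places all
  nodes at the origin with a default viewport (zoom 1, centered on the
  layout bounding box, origin if empty).

## Known limitations

One primary view per network; no visual styles, edge views, or nested
groups; no CX/XGMML/GML formats; no generative layout for unmapped nodes
beyond the grid (neighbor-based position prediction is out of scope); no
edge-overlap analysis; the service has no authentication and is meant for
localhost automation workflows.
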