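# copycat-layout

Attribute-keyed **network layout transfer**: copy node coordinates from a
laid-out *source* network view onto a *target* view by matching values in a
chosen node-table column, flag or grid-place the nodes that did not match,
and clone the viewport so both views render at the same scale and location.

This is the everyday problem of visual differential network analysis in
systems biology: you have spent time laying out a network (a pathway, a
regulatory network, an interactome slice), the data changes or you derive a
subnetwork, and you want the new network drawn *in the same positions* so
common and disjoint nodes are obvious at a glance. The package provides that
operation three ways — as a Python library, a command-line tool, and a small
REST service speaking the Cytoscape-Automation-style request/response
contract — without requiring a running Cytoscape desktop.

## The algorithm

Let the source network have N nodes and the target M nodes, each node
carrying a value in its network's *mapping column* (default `name`; both
columns must be string-typed or both integer-typed).

1. **Pass one** — walk the source nodes in stored order and build a hash map
   `value → (x, y, z)` from the source view. Duplicated values overwrite:
   the **last encountered** source node wins.
2. **Pass two** — walk the target nodes; every node whose value is in the
   map is moved to the mapped coordinates, exactly (bit-for-bit). Several
   target nodes sharing one value all **stack** at the same point.
   Unmatched nodes (value missing, or absent from the map) keep their
   coordinates.
3. Optionally, **select unmapped** nodes on both sides: target nodes that
   found no source coordinates, and source nodes whose value no target node
   matched. Prior selections are cleared first, so the selection equals
   exactly the unmapped sets. Matching is by value, so a duplicated source
   value matched once counts *all* its carriers as mapped.
4. Optionally, place the unmatched target nodes on a regular **grid** to
   the top right of the mapped nodes' bounding box (row-major,
   `ceil(sqrt(k))` columns, 80-unit spacing by default).
5. Clone the source **viewport** (zoom and center) onto the target.

The transfer runs in O(N + M) time and O(N) memory and is independent of
the edge sets — edges are read and written for file fidelity but never
consulted.

Coordinate convention everywhere: x grows rightward, **y grows downward**
(the rendering convention of Cytoscape exports), z defaults to 0.

## Worked example

The package ships a small worked fixture: a laid-out source network with
nodes A–H and a derived target with nodes A–G plus two novel nodes N and O.

```sh
copycat apply --source source.cyjs --target target.cyjs \
              --select-unmapped --out aligned.cyjs
```

prints

```json
{
 "mappedNodeCount": 7,
 "unmappedNodeCount": 2,
 "unmappedTargetNodes": [107, 108],
 "unmappedSourceNodes": [8]
}
```

Seven target nodes (A–G) were matched and now sit exactly on their source
coordinates; two target nodes (N and O, ids 107 and 108) had no counterpart
and one source node (H, id 8) was matched by nothing — all three end up
selected in the written files, ready for a downstream "what changed?" query.
The same call is available in-process:

```python
from copycat_layout import CopycatParams, SessionRegistry, copycat, load_network

registry = SessionRegistry()
_, source_view = load_network("source.cyjs").register(registry)
_, target_view = load_network("target.cyjs").register(registry)
result = copycat(registry, source_view, target_view,
                 CopycatParams(select_unmapped=True))
print(result.mapped_node_count, result.unmapped_node_count)  # 7 2
```

and over HTTP (`copycat serve --port 1234 source.cyjs target.cyjs`):

```sh
curl -X PUT -H 'Content-Type: application/json' \
  -d '{"sourceColumn": "name", "targetColumn": "name", "selectUnmapped": true}' \
  http://localhost:1234/v1/apply/layouts/copycat/${sourceViewSUID}/${targetViewSUID}
# -> {"data": {"mappedNodeCount": 7, "unmappedNodeCount": 2, ...}, "errors": []}
```

The service exposes two variants of the endpoint — the PUT *Function* form
above (view SUIDs, or the keyword `current`, in the URL) and a POST
*Command* form at `/v1/commands/layout/copycat` addressing networks by name
(`sourceNetwork` / `targetNetwork` in the payload; boolean options also
accepted as the strings `"true"`/`"false"`) — plus the discovery endpoints
`GET /v1/networks`, `/v1/networks/{suid}/views`,
`/v1/networks/{suid}/nodes/selected` and
`/v1/networks/{suid}/tables/defaultnode/columns`. Errors come back in the
same envelope with `errors[0].status` equal to the HTTP status: 404 for
unresolvable views and missing or type-mismatched mapping columns, 400 for
malformed requests (including source == target). PNG export of views is out
of scope here; render the written `.cyjs`/GraphML files with any Cytoscape
or Cytoscape.js toolchain.

## File formats

* **Cytoscape.js JSON** (`.cyjs`) — attributes in `data`, positions in
  `position`; column types inferred (all-integral → integer, else string).
* **GraphML** — coordinates under the `x`/`y`/`z` keys; declared `long`/`int`
  keys become integer columns, `string` keys string columns, anything else
  (e.g. `double`) is carried but unusable for matching.
* **SIF** edge list plus an optional TSV layout table
  (`name`/`x`/`y`[/`z`]).

All readers preserve node order (it defines "last encountered"); all
writers persist selection flags so selections survive a pipeline.

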