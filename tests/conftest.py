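import io as stdio
import json
from wsgiref.util import setup_testing_defaults

import pytest

from copycat_layout.model import (
    ColumnDef,
    EdgeRecord,
    NetworkGraph,
    NodeRecord,
    SessionRegistry,
)
from copycat_layout.io import LoadedNetwork
from copycat_layout.service import CopycatService
from copycat_layout.testkit import worked_example_session


def make_loaded(values, coords=None, *, kind="string", name="net", edges=(), id_base=0):
    """Build a LoadedNetwork from a list of mapping values (None = missing)
    and an optional parallel list of (x, y[, z]) coordinates."""
    nodes = []
    positions = {}
    for i, value in enumerate(values):
        node_id = id_base + i
        nodes.append(NodeRecord(node_id, {} if value is None else {"name": value}))
        if coords is not None:
            c = coords[i]
            positions[node_id] = (float(c[0]), float(c[1]), float(c[2]) if len(c) > 2 else 0.0)
    graph = NetworkGraph(
        name=name,
        columns=[ColumnDef("name", kind)],
        nodes=nodes,
        edges=[EdgeRecord(id_base + a, id_base + b, "pp") for a, b in edges],
    )
    graph.validate()
    return LoadedNetwork(graph, positions)


def view_snapshot(view):
    """Everything observable about a view, for idempotence comparisons."""
    return (
        {nid: (nv.x, nv.y, nv.z, nv.selected) for nid, nv in view.node_views.items()},
        (view.viewport.zoom, view.viewport.center_x, view.viewport.center_y),
    )


class WSGIClient:
    """Calls the WSGI app in-process, no sockets involved."""

    def __init__(self, app):
        self.app = app

    def request(self, method, path, body=None):
        if isinstance(body, bytes):
            raw = body
        elif body is not None:
            raw = json.dumps(body).encode("utf-8")
        else:
            raw = b""
        environ = {}
        setup_testing_defaults(environ)
        environ.update(
            REQUEST_METHOD=method,
            PATH_INFO=path,
            CONTENT_LENGTH=str(len(raw)),
            CONTENT_TYPE="application/json",
        )
        environ["wsgi.input"] = stdio.BytesIO(raw)
        captured = {}

        def start_response(status, headers):
            captured["status"] = int(status.split()[0])

        payload = b"".join(self.app(environ, start_response))
        return captured["status"], json.loads(payload)

    def get(self, path):
        return self.request("GET", path)

    def put(self, path, body=None):
        return self.request("PUT", path, body)

    def post(self, path, body=None):
        return self.request("POST", path, body)


@pytest.fixture
def demo_session():
    """(registry, suids) for a fresh session holding the worked fixture."""
    return worked_example_session()


@pytest.fixture
def demo_client(demo_session):
    registry, suids = demo_session
    return WSGIClient(CopycatService(registry)), registry, suids


@pytest.fixture
def registry():
    return SessionRegistry()
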