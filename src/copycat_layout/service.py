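"""HTTP facade exposing the layout transfer over the Cytoscape Automation
wire contract.

Two variants of the same operation are served, mirroring the Function /
Command split of Cytoscape Automation:

* ``PUT /v1/apply/layouts/copycat/{sourceViewSUID}/{targetViewSUID}`` — the
  Function variant; view SUIDs (or the keyword ``current``) in the URL, the
  remaining parameters in a JSON payload.
* ``POST /v1/commands/layout/copycat`` — the Command variant; everything in
  the payload, with networks addressed **by name** (``sourceNetwork`` /
  ``targetNetwork``); the layout operates on each network's primary view.
  Boolean options are accepted as JSON booleans or the strings
  ``"true"``/``"false"``.

Every copycat response is a CIResponse envelope: ``{"data": {...},
"errors": []}`` on success, ``{"data": {}, "errors": [{status, type,
message}]}`` on failure, with the HTTP status equal to ``errors[0].status``.
Unresolvable views and missing or type-mismatched mapping columns are 404s;
malformed requests (including source == target) are 400s.

Discovery endpoints sufficient for a scripted workflow are also served:
``GET /v1/networks``, ``GET /v1/networks/{suid}/views``,
``GET /v1/networks/{suid}/nodes/selected`` and
``GET /v1/networks/{suid}/tables/defaultnode/columns``.

The app is a plain WSGI callable, served with the standard library's
``wsgiref`` server; there is no framework dependency.
"""

from __future__ import annotations

import json
import logging
import re
import shlex
from typing import Iterable, Optional
from wsgiref.simple_server import WSGIRequestHandler, make_server

from . import io as netio
from .core import CopycatParams, copycat
from .errors import ColumnKindError, CopycatError, NotFoundError, ValidationError
from .model import SessionRegistry

logger = logging.getLogger(__name__)

DEFAULT_PORT = 1234

_ERROR_TYPE = "urn:cytoscape:ci:copycat-app:v1:errors:{code}"

_FUNCTION_RE = re.compile(r"^/v1/apply/layouts/copycat/([^/]+)/([^/]+)$")
_VIEWS_RE = re.compile(r"^/v1/networks/(\d+)/views$")
_SELECTED_RE = re.compile(r"^/v1/networks/(\d+)/nodes/selected$")
_COLUMNS_RE = re.compile(r"^/v1/networks/(\d+)/tables/defaultnode/columns$")

_STATUS_LINE = {200: "200 OK", 400: "400 Bad Request", 404: "404 Not Found",
                405: "405 Method Not Allowed", 500: "500 Internal Server Error"}


class _BadRequest(CopycatError):
    """Request malformed before it reaches the model (bad JSON, bad types)."""


def _error_envelope(status: int, message: str) -> dict:
    return {
        "data": {},
        "errors": [
            {"status": status, "type": _ERROR_TYPE.format(code=status), "message": message}
        ],
    }


def _coerce_bool(value: object, name: str) -> bool:
    """Booleans arrive as JSON booleans or, from shell-style clients, as the
    strings "true"/"false"."""
    if isinstance(value, bool):
        return value
    if isinstance(value, str) and value.lower() in ("true", "false"):
        return value.lower() == "true"
    raise _BadRequest(f"parameter {name!r} must be a boolean (or 'true'/'false'), got {value!r}")


def _params_from_payload(payload: dict) -> CopycatParams:
    if not isinstance(payload, dict):
        raise _BadRequest("payload must be a JSON object")
    source_column = payload.get("sourceColumn", "name")
    target_column = payload.get("targetColumn", "name")
    if not isinstance(source_column, str) or not isinstance(target_column, str):
        raise _BadRequest("sourceColumn and targetColumn must be strings")
    try:
        return CopycatParams(
            source_column=source_column,
            target_column=target_column,
            select_unmapped=_coerce_bool(payload.get("selectUnmapped", False), "selectUnmapped"),
            grid_unmapped=_coerce_bool(payload.get("gridUnmapped", False), "gridUnmapped"),
        )
    except ValidationError as exc:
        raise _BadRequest(str(exc)) from exc


def parse_command_string(line: str) -> dict:
    """Parse a Cytoscape Command Tool line ``layout copycat key=value ...``
    into a Command-variant payload dict. Values may be shell-quoted."""
    tokens = shlex.split(line)
    if tokens[:2] != ["layout", "copycat"]:
        raise ValidationError(f"not a copycat command line: {line!r}")
    payload = {}
    for token in tokens[2:]:
        key, sep, value = token.partition("=")
        if not sep or not key:
            raise ValidationError(f"expected key=value, got {token!r}")
        payload[key] = value
    return payload


class CopycatService:
    """WSGI application over one session registry."""

    def __init__(self, registry: SessionRegistry):
        self.registry = registry

    # -- WSGI plumbing ------------------------------------------------------

    def __call__(self, environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "")
        try:
            body = self._read_body(environ)
            status, payload = self.dispatch(method, path, body)
        except _BadRequest as exc:
            status, payload = 400, _error_envelope(400, str(exc))
        except (NotFoundError, ColumnKindError) as exc:
            status, payload = 404, _error_envelope(404, str(exc))
        except ValidationError as exc:
            status, payload = 400, _error_envelope(400, str(exc))
        except CopycatError as exc:
            status, payload = 500, _error_envelope(500, str(exc))
        data = json.dumps(payload).encode("utf-8")
        start_response(
            _STATUS_LINE.get(status, f"{status} Error"),
            [("Content-Type", "application/json"),
             ("Content-Length", str(len(data)))],
        )
        return [data]

    @staticmethod
    def _read_body(environ) -> dict:
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        raw = environ["wsgi.input"].read(length) if length else b""
        if not raw:
            return {}
        try:
            return json.loads(raw.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise _BadRequest(f"request body is not valid JSON: {exc}") from exc

    # -- routing ------------------------------------------------------------

    def dispatch(self, method: str, path: str, body: dict) -> tuple[int, object]:
        m = _FUNCTION_RE.match(path)
        if m:
            if method != "PUT":
                return 405, _error_envelope(405, "the Function variant requires PUT")
            return self.apply_function(m.group(1), m.group(2), body)
        if path == "/v1/commands/layout/copycat":
            if method != "POST":
                return 405, _error_envelope(405, "the Command variant requires POST")
            return self.apply_command(body)
        if method == "GET":
            if path == "/v1/networks":
                return 200, sorted(self.registry.networks)
            m = _VIEWS_RE.match(path)
            if m:
                return 200, self.registry.views_of_network(int(m.group(1)))
            m = _SELECTED_RE.match(path)
            if m:
                return 200, self._selected_nodes(int(m.group(1)))
            m = _COLUMNS_RE.match(path)
            if m:
                network = self.registry.network(int(m.group(1)))
                return 200, [
                    {"name": c.name, "type": c.value_kind} for c in network.columns
                ]
        raise NotFoundError(f"no such endpoint: {method} {path}")

    # -- handlers -----------------------------------------------------------

    def apply_function(self, source_sel: str, target_sel: str, body: dict) -> tuple[int, dict]:
        params = _params_from_payload(body)
        for name, sel in (("sourceViewSUID", source_sel), ("targetViewSUID", target_sel)):
            if sel != "current" and not sel.lstrip("-").isdigit():
                raise _BadRequest(f"{name} must be an integer or the word 'current', got {sel!r}")
        result = copycat(self.registry, source_sel, target_sel, params)
        return 200, {"data": result.to_data(), "errors": []}

    def apply_command(self, body: dict) -> tuple[int, dict]:
        if not isinstance(body, dict):
            raise _BadRequest("payload must be a JSON object")
        params = _params_from_payload(body)
        try:
            source_name, target_name = body["sourceNetwork"], body["targetNetwork"]
        except KeyError as exc:
            raise _BadRequest(f"missing required parameter {exc.args[0]!r}") from None
        if source_name == target_name:
            raise _BadRequest("sourceNetwork and targetNetwork must reference different networks")
        source_view = self.registry.find_view_by_network_name(str(source_name))
        target_view = self.registry.find_view_by_network_name(str(target_name))
        result = copycat(self.registry, source_view.view_suid, target_view.view_suid, params)
        return 200, {"data": result.to_data(), "errors": []}

    def _selected_nodes(self, network_suid: int) -> list[int]:
        self.registry.network(network_suid)
        for view_suid in sorted(self.registry.views_of_network(network_suid)):
            return self.registry.views[view_suid].selected_node_ids()
        return []


def build_session(paths: Iterable, layout_paths: Optional[dict] = None) -> SessionRegistry:
    """Load network files into a fresh session, one primary view each."""
    registry = SessionRegistry()
    layout_paths = layout_paths or {}
    for path in paths:
        loaded = netio.load_network(path, layout_path=layout_paths.get(str(path)))
        suid, view_suid = loaded.register(registry)
        logger.info("loaded %s as network %d (view %d)", path, suid, view_suid)
    return registry


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, fmt, *args):  # route access logs through logging
        logger.debug("%s - %s", self.address_string(), fmt % args)


def serve(registry: SessionRegistry, host: str = "127.0.0.1", port: int = DEFAULT_PORT):
    """Run the service on wsgiref's reference server (blocking)."""
    app = CopycatService(registry)
    with make_server(host, port, app, handler_class=_QuietHandler) as httpd:
        logger.info("serving on http://%s:%d/v1", host, port)
        httpd.serve_forever()
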