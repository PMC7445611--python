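"""Thin HTTP adapter over :class:`~seqreport.repository.ResourceRepository`.

Routes (JSON bodies identical to the library serialization):

* ``POST /<Type>`` — create
* ``GET /<Type>/<id>`` — read
* ``PUT /<Type>/<id>`` — update
* ``GET /<Type>/<id>/_history`` — history
* ``GET /<Type>?param=value`` — search

The library API is the primary contract; this facade exists so the
repository can be exercised over REST.  Bearer tokens are honored when the
repository has a token table configured.
"""

from __future__ import annotations

import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import parse_qsl, urlparse

from .errors import (
    AuthorizationError,
    ConflictError,
    NotFoundError,
    SearchParameterError,
    SeqReportError,
)
from .fhir_model import Bundle, FhirResource, from_json, to_json
from .repository import ResourceRepository

__all__ = ["make_server", "serve_forever"]


def _handler_for(repo: ResourceRepository):
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args):  # keep test output quiet
            pass

        def _token(self):
            auth = self.headers.get("Authorization", "")
            return auth.removeprefix("Bearer ").strip() or None

        def _send(self, status: int, payload: str):
            body = payload.encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/fhir+json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def _error(self, status: int, message: str):
            self._send(status, json.dumps({"error": message}) + "\n")

        def _read_body(self) -> FhirResource | Bundle:
            length = int(self.headers.get("Content-Length", 0))
            return from_json(self.rfile.read(length).decode("utf-8"))

        def do_GET(self):
            url = urlparse(self.path)
            parts = [p for p in url.path.split("/") if p]
            token = self._token()
            try:
                if len(parts) == 1:
                    params = dict(parse_qsl(url.query))
                    bundle = repo.search(parts[0], token=token, **params)
                    self._send(200, to_json(bundle))
                elif len(parts) == 2:
                    self._send(200, to_json(repo.read(parts[0], parts[1], token=token)))
                elif len(parts) == 3 and parts[2] == "_history":
                    versions = repo.history(parts[0], parts[1], token=token)
                    hist = Bundle(bundle_type="collection", entries=versions)
                    self._send(200, to_json(hist))
                else:
                    self._error(404, "unknown route")
            except NotFoundError as exc:
                self._error(404, str(exc))
            except SearchParameterError as exc:
                self._error(400, str(exc))
            except AuthorizationError as exc:
                self._error(403, str(exc))

        def do_POST(self):
            parts = [p for p in urlparse(self.path).path.split("/") if p]
            try:
                resource = self._read_body()
                if len(parts) != 1 or (
                    isinstance(resource, FhirResource)
                    and resource.resource_type != parts[0]
                ):
                    self._error(400, "type mismatch between route and body")
                    return
                result = repo.create(resource, token=self._token())
                if isinstance(result, list):
                    payload = {"created": [{"id": i, "versionId": v} for i, v in result]}
                else:
                    payload = {"id": result[0], "versionId": result[1]}
                self._send(201, json.dumps(payload) + "\n")
            except ConflictError as exc:
                self._error(409, str(exc))
            except AuthorizationError as exc:
                self._error(403, str(exc))
            except SeqReportError as exc:
                self._error(400, str(exc))

        def do_PUT(self):
            parts = [p for p in urlparse(self.path).path.split("/") if p]
            if len(parts) != 2:
                self._error(404, "PUT expects /<Type>/<id>")
                return
            try:
                resource = self._read_body()
                if not isinstance(resource, FhirResource):
                    self._error(400, "body must be a single resource")
                    return
                version = repo.update(parts[0], parts[1], resource,
                                      token=self._token())
                self._send(200, json.dumps({"id": parts[1], "versionId": version}) + "\n")
            except NotFoundError as exc:
                self._error(404, str(exc))
            except AuthorizationError as exc:
                self._error(403, str(exc))
            except SeqReportError as exc:
                self._error(400, str(exc))

    return Handler


def make_server(repo: ResourceRepository, host: str = "127.0.0.1",
                port: int = 0) -> ThreadingHTTPServer:
    """Build (but do not start) the HTTP server; port 0 picks a free port."""
    return ThreadingHTTPServer((host, port), _handler_for(repo))


def serve_forever(repo: ResourceRepository, host: str = "127.0.0.1",
                  port: int = 8080, *, background: bool = False):
    server = make_server(repo, host, port)
    if background:
        thread = threading.Thread(target=server.serve_forever, daemon=True)
        thread.start()
        return server
    server.serve_forever()
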