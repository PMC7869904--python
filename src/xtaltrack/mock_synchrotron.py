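"""Mock synchrotron endpoint for shipment submissions.

Two transports implement the same two-method surface:

* :class:`MockSynchrotron` — in-process; records every payload, can be
  told to fail, and is the default when the configured endpoint is
  ``mock:``.
* :class:`HttpTransport` — POSTs the JSON payload to an HTTP endpoint via
  stdlib ``urllib``; paired with :func:`serve_mock` which runs the mock
  behind ``http.server`` for end-to-end CLI exercises on localhost.

Authentication is a username/password pair checked only for presence —
real synchrotron auth is out of scope.
"""

from __future__ import annotations

import json
import threading
import urllib.error
import urllib.request
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .errors import TransportError


class MockSynchrotron:
    """In-process stand-in for the synchrotron's shipment API."""

    def __init__(self, fail: bool = False) -> None:
        self.fail = fail
        self.submissions: list[dict] = []

    def submit(self, payload: dict, credentials: dict) -> dict:
        if self.fail:
            raise TransportError("mock synchrotron: simulated endpoint failure")
        if not credentials.get("username") or not credentials.get("password"):
            raise TransportError("mock synchrotron: missing credentials")
        self.submissions.append(payload)
        n_samples = sum(
            len(c["samples"])
            for d in payload["dewars"]
            for c in d["containers"]
        )
        return {
            "receipt_id": f"MOCK-{len(self.submissions):04d}",
            "accepted_samples": n_samples,
        }


class HttpTransport:
    """POST the payload as JSON to an HTTP endpoint."""

    def __init__(self, url: str, timeout: float = 10.0) -> None:
        self.url = url
        self.timeout = timeout

    def submit(self, payload: dict, credentials: dict) -> dict:
        body = json.dumps({"credentials": credentials, "payload": payload})
        request = urllib.request.Request(
            self.url, data=body.encode(),
            headers={"Content-Type": "application/json"}, method="POST",
        )
        try:
            with urllib.request.urlopen(request, timeout=self.timeout) as resp:
                return json.loads(resp.read().decode())
        except (urllib.error.URLError, OSError) as exc:
            raise TransportError(f"endpoint {self.url}: {exc}") from exc


def make_transport(endpoint: str):
    if endpoint.startswith("mock:"):
        return MockSynchrotron()
    return HttpTransport(endpoint)


class _MockHandler(BaseHTTPRequestHandler):
    def do_POST(self):  # noqa: N802 - http.server API
        length = int(self.headers.get("Content-Length", 0))
        data = json.loads(self.rfile.read(length).decode())
        mock: MockSynchrotron = self.server.mock  # type: ignore[attr-defined]
        try:
            receipt = mock.submit(data["payload"], data.get("credentials", {}))
            status, body = 200, receipt
        except TransportError as exc:
            status, body = 500, {"error": str(exc)}
        encoded = json.dumps(body).encode()
        self.send_response(status)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(encoded)))
        self.end_headers()
        self.wfile.write(encoded)

    def log_message(self, *args):  # silence request logging
        pass


def serve_mock(host: str = "127.0.0.1", port: int = 0):
    """Start the mock endpoint on a background thread.

    Returns ``(server, url)``; call ``server.shutdown()`` when done.
    """
    server = ThreadingHTTPServer((host, port), _MockHandler)
    server.mock = MockSynchrotron()  # type: ignore[attr-defined]
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    url = f"http://{host}:{server.server_address[1]}/shipments"
    return server, url
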