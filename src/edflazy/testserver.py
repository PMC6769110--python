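"""A minimal local HTTP server with single-range request support.

Used by the test suite and the ``serve-fixtures`` CLI subcommand so the
HTTP loading strategy can be exercised without any external network.  Range
support can be switched off to reproduce a server that ignores the header.
"""

from __future__ import annotations

import contextlib
import re
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path

__all__ = ["RangeRequestHandler", "serve_directory"]

_RANGE_RE = re.compile(r"bytes=(\d+)-(\d*)$")


class RangeRequestHandler(BaseHTTPRequestHandler):
    """Serves files from ``directory`` honoring single ``Range`` headers."""

    directory: Path
    support_ranges: bool = True
    protocol_version = "HTTP/1.1"

    def log_message(self, format, *args):  # noqa: A002 - stdlib signature
        pass

    def _resolve(self) -> Path | None:
        name = self.path.lstrip("/")
        target = (self.directory / name).resolve()
        if not str(target).startswith(str(self.directory.resolve())):
            return None
        return target if target.is_file() else None

    def do_HEAD(self):
        target = self._resolve()
        if target is None:
            self.send_error(404)
            return
        self.send_response(200)
        self.send_header("Content-Length", str(target.stat().st_size))
        if self.support_ranges:
            self.send_header("Accept-Ranges", "bytes")
        self.end_headers()

    def do_GET(self):
        target = self._resolve()
        if target is None:
            self.send_error(404)
            return
        data = target.read_bytes()
        range_header = self.headers.get("Range")
        match = _RANGE_RE.match(range_header) if range_header else None
        if match and self.support_ranges:
            start = int(match.group(1))
            end = int(match.group(2)) if match.group(2) else len(data) - 1
            end = min(end, len(data) - 1)
            if start >= len(data) or start > end:
                self.send_error(416)
                return
            body = data[start : end + 1]
            self.send_response(206)
            self.send_header("Content-Range", f"bytes {start}-{end}/{len(data)}")
        else:
            body = data
            self.send_response(200)
        self.send_header("Content-Length", str(len(body)))
        self.send_header("Content-Type", "application/octet-stream")
        self.end_headers()
        self.wfile.write(body)


@contextlib.contextmanager
def serve_directory(directory, support_ranges: bool = True, port: int = 0):
    """Context manager yielding the base URL of a background server."""
    handler = type(
        "Handler",
        (RangeRequestHandler,),
        {"directory": Path(directory), "support_ranges": support_ranges},
    )
    server = ThreadingHTTPServer(("127.0.0.1", port), handler)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    try:
        yield f"http://127.0.0.1:{server.server_address[1]}"
    finally:
        server.shutdown()
        server.server_close()
        thread.join(timeout=5)
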