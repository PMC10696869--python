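"""URI dereferencing with RDF-preferring content negotiation.

Every unique URI of the assessed document is resolved over HTTP (or
against an offline fixture map) and classified: a final status in the
4xx/5xx range makes the URI non-resolvable; otherwise the normalized
``Content-Type`` decides whether the response carries an RDF
serialization and may be parsed downstream.
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol
from urllib.parse import urldefrag, urlparse

#: Media type -> rdflib parser format, for every RDF serialization the
#: tool negotiates.  ``text/plain`` is treated as N-Triples.
RDF_MEDIA_TYPES: dict[str, str] = {
    "text/turtle": "turtle",
    "application/x-turtle": "turtle",
    "text/plain": "nt",
    "application/ld+json": "json-ld",
    "text/n3": "n3",
    "application/rdf+xml": "xml",
}

#: Sentinel status for requests that never produced an HTTP response
#: (network failure, malformed URI, non-http scheme).
SENTINEL_STATUS = 0

DEFAULT_USER_AGENT = "rdfqa/0.1 (RDF quality assessment)"


def build_accept_header(
    media_type_table: Optional[Mapping[str, str]] = None,
) -> str:
    """Build an ``Accept`` header preferring RDF media types.

    Each RDF media type is listed at full quality (implicit q=1.0) and
    ``*/*`` is appended with the lowest weight, so a server offering any
    RDF representation will prefer it but a non-RDF-only server still
    answers (a non-RDF content type is not an error, merely the end of
    the analysis cascade for that URI).
    """
    table = media_type_table if media_type_table is not None else RDF_MEDIA_TYPES
    return ", ".join(table) + ", */*;q=0.1"


@dataclass
class FetchResult:
    """Raw transport-level result of dereferencing one request URI."""

    status_code: int
    content_type: Optional[str]
    body: bytes
    final_url: str


class TransportContract(Protocol):
    """Anything that can answer ``fetch(uri, accept)``."""

    def fetch(self, uri: str, accept: str) -> FetchResult: ...


@dataclass
class ResolutionOutcome:
    """Classified result of resolving one URI."""

    uri: str
    status_code: int
    resolvable: bool
    content_type: Optional[str]
    is_rdf_content: bool
    final_url: str
    body: bytes = field(default=b"", repr=False)
    reason: str = ""


class OfflineTransport:
    """Fixture-map transport: a pure function of the request URI.

    The map is ``uri -> {"status": int, "content_type": str, "body": str}``.
    Unknown URIs yield 404 by default; with ``strict=True`` they raise
    instead, which catches any accidental escape from the fixture set.
    Every call is appended to ``calls`` for cache/idempotence auditing.
    """

    def __init__(self, fixture_map: Mapping[str, Mapping], strict: bool = False):
        self.fixture_map = dict(fixture_map)
        self.strict = strict
        self.calls: list[str] = []

    @classmethod
    def from_json(cls, path: str, strict: bool = False) -> "OfflineTransport":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh), strict=strict)

    def fetch(self, uri: str, accept: str) -> FetchResult:
        self.calls.append(uri)
        entry = self.fixture_map.get(uri)
        if entry is None:
            if self.strict:
                raise KeyError(f"URI not in offline fixture map: {uri}")
            return FetchResult(404, "text/plain", b"not in fixture map", uri)
        body = entry.get("body", "")
        if isinstance(body, str):
            body = body.encode("utf-8")
        return FetchResult(
            int(entry.get("status", 200)),
            entry.get("content_type"),
            body,
            entry.get("final_url", uri),
        )


class LiveTransport:
    """HTTP transport over :mod:`urllib` with retry/backoff.

    Redirects are followed; 5xx, 429, and network timeouts are retried
    with exponential backoff (4xx are terminal and never retried).
    """

    def __init__(
        self,
        timeout: float = 30.0,
        retries: int = 3,
        backoff: float = 1.0,
        user_agent: str = DEFAULT_USER_AGENT,
    ):
        self.timeout = timeout
        self.retries = retries
        self.backoff = backoff
        self.user_agent = user_agent

    def _retryable(self, status: int) -> bool:
        return status >= 500 or status == 429

    def fetch(self, uri: str, accept: str) -> FetchResult:
        attempt = 0
        while True:
            attempt += 1
            request = urllib.request.Request(
                uri,
                headers={"Accept": accept, "User-Agent": self.user_agent},
                method="GET",
            )
            try:
                with urllib.request.urlopen(request, timeout=self.timeout) as resp:
                    return FetchResult(
                        resp.status,
                        resp.headers.get("Content-Type"),
                        resp.read(),
                        resp.url,
                    )
            except urllib.error.HTTPError as exc:
                result = FetchResult(
                    exc.code,
                    exc.headers.get("Content-Type") if exc.headers else None,
                    exc.read() if hasattr(exc, "read") else b"",
                    exc.url or uri,
                )
                if not self._retryable(exc.code) or attempt > self.retries:
                    return result
            except (urllib.error.URLError, OSError):
                if attempt > self.retries:
                    return FetchResult(SENTINEL_STATUS, None, b"", uri)
            time.sleep(self.backoff * 2 ** (attempt - 1))


def normalize_media_type(content_type: Optional[str]) -> Optional[str]:
    """Lowercase the media type and strip parameters such as charset."""
    if not content_type:
        return None
    return content_type.split(";", 1)[0].strip().lower() or None


def strip_fragment(uri: str) -> str:
    return urldefrag(uri)[0]


def _is_http_uri(uri: str) -> tuple[bool, str]:
    try:
        parsed = urlparse(uri)
    except ValueError:
        return False, "malformed URI"
    if parsed.scheme not in ("http", "https"):
        return False, f"non-http(s) scheme {parsed.scheme!r}"
    if not parsed.netloc:
        return False, "malformed URI (no authority)"
    return True, ""


def resolve_uri(
    uri: str,
    transport: TransportContract,
    cache: Optional[dict[str, FetchResult]] = None,
    accept: Optional[str] = None,
) -> ResolutionOutcome:
    """Resolve one URI and classify the outcome.

    The fragment is stripped for the HTTP request (standard
    dereferencing) but the outcome is recorded against the full URI
    string.  ``cache`` maps request URIs to fetch results so that two
    hash URIs sharing a document trigger one fetch.
    """
    ok, why = _is_http_uri(uri)
    if not ok:
        return ResolutionOutcome(
            uri=uri,
            status_code=SENTINEL_STATUS,
            resolvable=False,
            content_type=None,
            is_rdf_content=False,
            final_url=uri,
            reason=why,
        )
    request_uri = strip_fragment(uri)
    accept = accept if accept is not None else build_accept_header()
    if cache is not None and request_uri in cache:
        fetched = cache[request_uri]
    else:
        fetched = transport.fetch(request_uri, accept)
        if cache is not None:
            cache[request_uri] = fetched
    resolvable = 100 <= fetched.status_code < 400
    content_type = normalize_media_type(fetched.content_type)
    is_rdf = resolvable and content_type in RDF_MEDIA_TYPES
    reason = "" if resolvable else (
        f"HTTP status {fetched.status_code}"
        if fetched.status_code != SENTINEL_STATUS
        else "network failure"
    )
    return ResolutionOutcome(
        uri=uri,
        status_code=fetched.status_code,
        resolvable=resolvable,
        content_type=content_type,
        is_rdf_content=is_rdf,
        final_url=fetched.final_url,
        body=fetched.body,
        reason=reason,
    )


def classify_resolvability(
    inventory,
    transport: TransportContract,
    cache: Optional[dict[str, FetchResult]] = None,
) -> dict[str, ResolutionOutcome]:
    """Resolve every unique URI of an inventory.

    Returns one outcome per URI; each distinct defragmented request URI
    is fetched at most once thanks to the shared cache.
    """
    if cache is None:
        cache = {}
    accept = build_accept_header()
    return {
        uri: resolve_uri(uri, transport, cache=cache, accept=accept)
        for uri in sorted(inventory.unique_uris)
    }
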