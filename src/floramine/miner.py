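"""Resumable, rate-limited crawling and parsing of POWO-style taxon pages.

The mining pipeline walks family → genus → species pages, parsing the
HTML of each into the domain model. It works identically against a live
base URL and a local directory of rendered pages (the synthetic site),
because both are addressed through the same :class:`TaxonURI`
abstraction and scheme dispatch in the fetcher.

Politeness: a long crawl pauses for ``pause_seconds`` after every
``requests_per_pause``-th request (defaults 300 s / 500 requests), so the
server is never hammered for hours on end. The counter is cumulative and
the pause fires on every multiple of the threshold; retries count as
requests, because a retry is still a server hit. The clock is an injected
dependency, so tests exercise the schedule in milliseconds.

Resumability: the crawler persists a checkpoint after *every* completed
taxon (written atomically: temp file + rename, with a trailing integrity
hash). Restarting with an existing checkpoint re-fetches nothing already
completed and continues from the pending queue, so an interrupted crawl
plus its resumption yields exactly the records of an uninterrupted one.

Parsers are driven by a dialect table keyed by the markup version stamped
in each page's ``site-dialect`` meta tag; an unknown dialect is an
explicit error, never best-effort scraping.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import lxml.html

from .model import (
    ACCEPTED,
    HETEROTYPIC,
    HOMOTYPIC,
    Distribution,
    GenusSummary,
    NameRecord,
    SpeciesRecord,
    parse_publication_year,
)

__all__ = [
    "TaxonURI",
    "RateLimitPolicy",
    "CrawlCheckpoint",
    "PageFetcher",
    "Crawler",
    "FetchError",
    "PageResolutionError",
    "ParseError",
    "CheckpointError",
    "parse_index_page",
    "parse_family_page",
    "parse_genus_page",
    "parse_species_page",
    "detect_dialect",
    "DEFAULT_DIALECT",
    "DIALECTS",
]

DEFAULT_DIALECT = "synthflora-1"

#: XPath selectors per markup dialect. New page layouts get a new entry
#: here; nothing else in the parser changes.
DIALECTS: dict[str, dict[str, str]] = {
    "synthflora-1": {
        "family_heading": '//h1[@class="taxon-name"][@data-rank="family"]',
        "genus_heading": '//h1[@class="taxon-name"][@data-rank="genus"]',
        "species_heading": '//h1[@class="accepted-name"][@data-rank="species"]',
        "family_list": '//ul[@class="family-list"]',
        "family_links": '//ul[@class="family-list"]/li/a',
        "genus_list": '//ul[@class="genus-list"]',
        "genus_links": '//ul[@class="genus-list"]/li/a',
        "species_list": '//ul[@class="species-list"]',
        "species_links": '//ul[@class="species-list"]/li/a',
        "classification_family": '//p[@class="classification"]/span[@class="family"]',
        "protologue": '//div[@class="protologue"]',
        "native_regions": '//section[@class="distribution"]//ul[@class="native"]/li',
        "introduced_regions": '//section[@class="distribution"]//ul[@class="introduced"]/li',
        "synonyms": '//ul[@class="synonym-list"]/li',
    }
}


class FetchError(RuntimeError):
    """A page could not be retrieved after retries."""


class PageResolutionError(FetchError):
    """The URI does not resolve at all (e.g. missing local file)."""


class ParseError(ValueError):
    """A page does not match the expected markup dialect."""


class CheckpointError(RuntimeError):
    """A checkpoint file is corrupt or unreadable."""


@dataclass(frozen=True)
class TaxonURI:
    """Locator for one taxon page, at family, genus or species rank."""

    family: str
    rank: str  # family | genus | species
    record_id: str
    uri: str


@dataclass(frozen=True)
class RateLimitPolicy:
    requests_per_pause: int = 500
    pause_seconds: float = 300.0

    def __post_init__(self):
        if self.requests_per_pause < 1:
            raise ValueError("requests_per_pause must be >= 1")
        if self.pause_seconds < 0:
            raise ValueError("pause_seconds must be >= 0")


class PageFetcher:
    """Retrieves pages from a base URL or local directory with politeness.

    ``clock`` needs only a ``sleep(seconds)`` method; tests inject a mock
    to observe the pause schedule. Transient failures are retried up to
    ``max_retries`` times with doubling backoff, then surface as
    :class:`FetchError`. Every attempt increments ``request_count``.
    """

    def __init__(
        self,
        base: str | Path,
        policy: RateLimitPolicy | None = None,
        clock=time,
        max_retries: int = 3,
        backoff_seconds: float = 1.0,
    ):
        self.base = str(base)
        self.policy = policy or RateLimitPolicy()
        self.clock = clock
        self.max_retries = max_retries
        self.backoff_seconds = backoff_seconds
        self.request_count = 0
        self.log: list[str] = []  # successful page loads, in order

    @property
    def is_remote(self) -> bool:
        return self.base.startswith(("http://", "https://"))

    def _load_once(self, rel_uri: str) -> str:
        if self.is_remote:
            url = urllib.parse.urljoin(self.base.rstrip("/") + "/", rel_uri)
            try:
                with urllib.request.urlopen(url, timeout=60) as resp:
                    return resp.read().decode("utf-8")
            except urllib.error.HTTPError as exc:
                if exc.code == 404:
                    raise PageResolutionError(f"{url}: HTTP 404") from exc
                raise OSError(f"{url}: HTTP {exc.code}") from exc
            except urllib.error.URLError as exc:
                raise OSError(f"{url}: {exc.reason}") from exc
        path = Path(self.base) / rel_uri
        if not path.exists():
            raise PageResolutionError(f"no such page: {path}")
        return path.read_text(encoding="utf-8")

    def _count_request(self) -> None:
        self.request_count += 1
        if self.request_count % self.policy.requests_per_pause == 0:
            self.clock.sleep(self.policy.pause_seconds)

    def fetch(self, uri: TaxonURI | str) -> str:
        rel = uri.uri if isinstance(uri, TaxonURI) else uri
        delay = self.backoff_seconds
        last_exc: Exception | None = None
        for attempt in range(1 + self.max_retries):
            self._count_request()
            try:
                text = self._load_once(rel)
            except PageResolutionError:
                raise
            except OSError as exc:  # transient: retry with doubling backoff
                last_exc = exc
                if attempt < self.max_retries:
                    self.clock.sleep(delay)
                    delay *= 2
                continue
            self.log.append(rel)
            return text
        raise FetchError(f"{rel}: failed after {self.max_retries} retries: {last_exc}")


# ---------------------------------------------------------------------------
# Page parsers


def _doc(html: str):
    try:
        return lxml.html.fromstring(html)
    except Exception as exc:  # pragma: no cover - lxml is extremely lenient
        raise ParseError(f"unparseable HTML: {exc}") from exc


def detect_dialect(doc_or_html) -> str:
    doc = _doc(doc_or_html) if isinstance(doc_or_html, str) else doc_or_html
    metas = doc.xpath('//meta[@name="site-dialect"]/@content')
    if not metas:
        raise ParseError("page carries no site-dialect meta tag")
    dialect = metas[0]
    if dialect not in DIALECTS:
        raise ParseError(f"unknown markup dialect {dialect!r}; known: {sorted(DIALECTS)}")
    return dialect


def _text(el) -> str:
    return " ".join(el.text_content().split())


def _span(el, cls: str) -> str:
    hits = el.xpath(f'.//span[@class="{cls}"]')
    return _text(hits[0]) if hits else ""


def _link_uri(a) -> tuple[str, str]:
    return a.get("data-record-id", ""), a.get("data-uri", a.get("href", ""))


def parse_index_page(html: str) -> list[TaxonURI]:
    """Family roots from a site index page (the URI-catalogue analog)."""
    doc = _doc(html)
    sel = DIALECTS[detect_dialect(doc)]
    if not doc.xpath(sel["family_list"]):
        raise ParseError(f'missing selector: {sel["family_list"]}')
    roots = []
    for a in doc.xpath(sel["family_links"]):
        rid, uri = _link_uri(a)
        roots.append(TaxonURI(family=_text(a), rank="family", record_id=rid, uri=uri))
    return roots


def parse_family_page(html: str) -> tuple[str, list[TaxonURI]]:
    """Family name plus one genus-rank TaxonURI per listed genus."""
    doc = _doc(html)
    sel = DIALECTS[detect_dialect(doc)]
    headings = doc.xpath(sel["family_heading"])
    if not headings:
        raise ParseError(f'missing selector: {sel["family_heading"]}')
    family = _text(headings[0])
    lists = doc.xpath(sel["genus_list"])
    if not lists:
        raise ParseError(f'missing selector: {sel["genus_list"]}')
    genera = []
    for a in doc.xpath(sel["genus_links"]):
        rid, uri = _link_uri(a)
        genera.append(TaxonURI(family=family, rank="genus", record_id=rid, uri=uri))
    return family, genera


def parse_genus_page(html: str) -> tuple[GenusSummary, list[TaxonURI]]:
    """Genus summary plus one species-rank TaxonURI per accepted species.

    ``species_count`` equals the number of accepted species links found.
    """
    doc = _doc(html)
    sel = DIALECTS[detect_dialect(doc)]
    headings = doc.xpath(sel["genus_heading"])
    if not headings:
        raise ParseError(f'missing selector: {sel["genus_heading"]}')
    h = headings[0]
    fams = doc.xpath(sel["classification_family"])
    family = _text(fams[0]) if fams else ""
    protos = doc.xpath(sel["protologue"])
    if not doc.xpath(sel["species_list"]):
        raise ParseError(f'missing selector: {sel["species_list"]}')
    species = []
    for a in doc.xpath(sel["species_links"]):
        rid, uri = _link_uri(a)
        species.append(TaxonURI(family=family, rank="species", record_id=rid, uri=uri))
    summary = GenusSummary(
        genus=_span(h, "genus"),
        authorship=_span(h, "authorship"),
        protologue=_text(protos[0]) if protos else "",
        species_count=len(species),
        record_id=h.get("data-record-id", ""),
        uri=h.get("data-uri", ""),
        family=family,
    )
    return summary, species


def parse_species_page(html: str) -> SpeciesRecord:
    """Full species record from a species-rank page.

    A page with no distribution section yields an explicitly *unknown*
    distribution — downstream lists print "unknown" rather than dropping
    the species.
    """
    doc = _doc(html)
    sel = DIALECTS[detect_dialect(doc)]
    headings = doc.xpath(sel["species_heading"])
    if not headings:
        raise ParseError(f'missing selector: {sel["species_heading"]}')
    h = headings[0]
    fams = doc.xpath(sel["classification_family"])
    protos = doc.xpath(sel["protologue"])
    protologue = _text(protos[0]) if protos else ""
    accepted = NameRecord(
        genus=_span(h, "genus"),
        epithet=_span(h, "epithet"),
        authorship=_span(h, "authorship"),
        protologue=protologue,
        year=parse_publication_year(protologue),
        status=ACCEPTED,
        record_id=h.get("data-record-id", ""),
        uri=h.get("data-uri", ""),
    )
    native = frozenset(_text(li) for li in doc.xpath(sel["native_regions"]))
    introduced = frozenset(_text(li) for li in doc.xpath(sel["introduced_regions"]))
    if native or introduced:
        dist = Distribution(native, introduced)
    else:
        dist = Distribution.unknown()
    synonyms = []
    for li in doc.xpath(sel["synonyms"]):
        classes = (li.get("class") or "").split()
        status = HOMOTYPIC if "homotypic" in classes else HETEROTYPIC
        syn_proto = _span(li, "protologue")
        synonyms.append(
            NameRecord(
                genus=_span(li, "genus"),
                epithet=_span(li, "epithet"),
                authorship=_span(li, "authorship"),
                protologue=syn_proto,
                year=parse_publication_year(syn_proto),
                status=status,
                record_id=li.get("data-record-id", ""),
                uri=li.get("data-uri", ""),
            )
        )
    return SpeciesRecord(
        accepted=accepted,
        synonyms=tuple(synonyms),
        distribution=dist,
        family=_text(fams[0]) if fams else "",
    )


# ---------------------------------------------------------------------------
# Checkpointed crawl

_CHECKPOINT_FORMAT = "crawl-checkpoint-1"


@dataclass
class CrawlCheckpoint:
    """Persistent crawl state: what is done, what remains, what failed."""

    completed: list = field(default_factory=list)  # TaxonURI, in completion order
    pending: list = field(default_factory=list)  # TaxonURI, in visit order
    request_count: int = 0
    failures: list = field(default_factory=list)  # (TaxonURI, reason)

    def completed_uris(self) -> set[str]:
        return {t.uri for t in self.completed}


def _taxon_dict(t: TaxonURI) -> dict:
    return {"family": t.family, "rank": t.rank, "record_id": t.record_id, "uri": t.uri}


def _taxon_from(d: dict) -> TaxonURI:
    return TaxonURI(d["family"], d["rank"], d["record_id"], d["uri"])


def save_checkpoint(cp: CrawlCheckpoint, path: str | Path) -> None:
    """Atomic write: JSON lines with a trailing integrity hash, written to
    a temp file and renamed into place."""
    path = Path(path)
    lines = [json.dumps({"format": _CHECKPOINT_FORMAT, "request_count": cp.request_count})]
    lines += [json.dumps({"kind": "completed", **_taxon_dict(t)}) for t in cp.completed]
    lines += [json.dumps({"kind": "pending", **_taxon_dict(t)}) for t in cp.pending]
    lines += [
        json.dumps({"kind": "failure", "reason": reason, **_taxon_dict(t)})
        for t, reason in cp.failures
    ]
    body = "\n".join(lines) + "\n"
    digest = hashlib.sha256(body.encode("utf-8")).hexdigest()
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(body + json.dumps({"sha256": digest}) + "\n", encoding="utf-8")
    os.replace(tmp, path)


def load_checkpoint(path: str | Path) -> CrawlCheckpoint:
    """Load and verify a checkpoint; any defect raises CheckpointError
    naming the problem rather than silently starting over."""
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    lines = raw.splitlines()
    if len(lines) < 2:
        raise CheckpointError(f"{path}: truncated checkpoint ({len(lines)} lines)")
    try:
        trailer = json.loads(lines[-1])
        expected = trailer["sha256"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise CheckpointError(f"{path}: missing or malformed integrity trailer") from exc
    body = "\n".join(lines[:-1]) + "\n"
    actual = hashlib.sha256(body.encode("utf-8")).hexdigest()
    if actual != expected:
        raise CheckpointError(
            f"{path}: integrity hash mismatch (stored {expected[:12]}…, computed {actual[:12]}…)"
        )
    try:
        header = json.loads(lines[0])
        if header.get("format") != _CHECKPOINT_FORMAT:
            raise CheckpointError(
                f"{path}: unknown checkpoint format {header.get('format')!r}"
            )
        cp = CrawlCheckpoint(request_count=int(header.get("request_count", 0)))
        for line in lines[1:-1]:
            rec = json.loads(line)
            if rec["kind"] == "completed":
                cp.completed.append(_taxon_from(rec))
            elif rec["kind"] == "pending":
                cp.pending.append(_taxon_from(rec))
            elif rec["kind"] == "failure":
                cp.failures.append((_taxon_from(rec), rec["reason"]))
            else:
                raise CheckpointError(f"{path}: unknown record kind {rec['kind']!r}")
    except CheckpointError:
        raise
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise CheckpointError(f"{path}: malformed checkpoint record: {exc}") from exc
    return cp


class Crawler:
    """Breadth-first family → genus → species crawl with checkpointing.

    ``run`` yields one :class:`SpeciesRecord` per species page. The
    checkpoint is persisted after every completed taxon; a record is
    yielded only after its completion is on disk, so an interrupted crawl
    resumed from the same checkpoint never re-yields and never re-fetches
    a finished taxon. Fetch failures are recorded on the checkpoint's
    failure list and skipped, never silently dropped.
    """

    def __init__(self, fetcher: PageFetcher, checkpoint_path: str | Path):
        self.fetcher = fetcher
        self.checkpoint_path = Path(checkpoint_path)
        self.checkpoint: CrawlCheckpoint | None = None
        #: Genus summaries seen while crawling (side output; covers the
        #: genus pages fetched by *this* run, not ones completed before a
        #: resume).
        self.genus_summaries: list[GenusSummary] = []

    def _init_state(self, roots) -> CrawlCheckpoint:
        if self.checkpoint_path.exists():
            cp = load_checkpoint(self.checkpoint_path)
            self.fetcher.request_count = cp.request_count
            return cp
        if not roots:
            raise ValueError("a fresh crawl needs at least one root TaxonURI")
        return CrawlCheckpoint(pending=list(roots))

    def _save(self, cp: CrawlCheckpoint) -> None:
        cp.request_count = self.fetcher.request_count
        save_checkpoint(cp, self.checkpoint_path)

    def run(self, roots=None) -> Iterator[SpeciesRecord]:
        cp = self.checkpoint = self._init_state(roots or [])
        seen = cp.completed_uris()
        while cp.pending:
            taxon = cp.pending[0]
            if taxon.uri in seen:  # checkpoint-enforced: never fetch twice
                cp.pending.pop(0)
                self._save(cp)
                continue
            try:
                html = self.fetcher.fetch(taxon)
            except FetchError as exc:
                cp.pending.pop(0)
                cp.completed.append(taxon)
                cp.failures.append((taxon, str(exc)))
                seen.add(taxon.uri)
                self._save(cp)
                continue
            record: SpeciesRecord | None = None
            if taxon.rank == "family":
                family, genera = parse_family_page(html)
                if family and family != taxon.family:
                    genera = [replace(g, family=family) for g in genera]
                cp.pending.extend(g for g in genera if g.uri not in seen)
            elif taxon.rank == "genus":
                summary, species = parse_genus_page(html)
                self.genus_summaries.append(summary)
                cp.pending.extend(s for s in species if s.uri not in seen)
            elif taxon.rank == "species":
                record = parse_species_page(html)
            else:
                raise ParseError(f"unknown taxon rank {taxon.rank!r}")
            cp.pending.pop(0)
            cp.completed.append(taxon)
            seen.add(taxon.uri)
            self._save(cp)
            if record is not None:
                yield record
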