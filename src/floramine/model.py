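"""Domain model for plant checklists.

The objects here mirror what a POWO-style taxon page exposes: a published
name (accepted or synonym) with authorship and protologue citation, an
accepted species with its synonymy and native/introduced distribution in
TDWG level-3 "botanical countries", and a genus-level summary row.

Nomenclatural conventions encoded here:

* Years of publication are only meaningful from 1753 (the starting point of
  binomial nomenclature, *Species Plantarum*) up to the current calendar
  year; anything outside that window is treated as unknown rather than
  propagated as a database error.
* A homotypic synonym shares the accepted name's type, so the earliest
  homotypic year (including the accepted name's own) is the basionym year —
  the year the species was actually first described. Heterotypic synonyms
  are based on different types and never participate in basionym dating.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field

__all__ = [
    "ACCEPTED",
    "HOMOTYPIC",
    "HETEROTYPIC",
    "NAME_STATUSES",
    "NOMENCLATURE_START",
    "NameRecord",
    "Distribution",
    "SpeciesRecord",
    "GenusSummary",
    "current_year",
    "parse_publication_year",
    "basionym_year",
    "validate_species",
    "strip_hybrid_marker",
]

ACCEPTED = "accepted"
HOMOTYPIC = "homotypic_synonym"
HETEROTYPIC = "heterotypic_synonym"
NAME_STATUSES = frozenset({ACCEPTED, HOMOTYPIC, HETEROTYPIC})

#: First year of valid botanical nomenclature (Species Plantarum).
NOMENCLATURE_START = 1753

HYBRID_MARKER = "×"  # multiplication sign used for nothospecies


def current_year() -> int:
    return _dt.date.today().year


_PAREN_YEAR = re.compile(r"\((\d{4})\)")
_BARE_YEAR = re.compile(r"(?<!\d)(\d{4})(?!\d)")


def parse_publication_year(
    citation: str | None,
    *,
    earliest: int = NOMENCLATURE_START,
    latest: int | None = None,
) -> int | None:
    """Extract the publication year from a protologue citation string.

    Rule: the first parenthesised four-digit year inside the valid window
    wins (the usual Kew citation style, e.g. ``"Sp. Pl.: 1042 (1753)"``);
    failing that, the last bare four-digit token inside the window (older
    citation styles, e.g. ``"Fl. Bras. 2(2): 44. 1877"``). Unparseable or
    out-of-window input yields ``None``, never an exception.
    """
    if latest is None:
        latest = current_year()
    if not citation:
        return None
    for m in _PAREN_YEAR.finditer(citation):
        year = int(m.group(1))
        if earliest <= year <= latest:
            return year
    for m in reversed(list(_BARE_YEAR.finditer(citation))):
        year = int(m.group(1))
        if earliest <= year <= latest:
            return year
    return None


def strip_hybrid_marker(epithet: str) -> str:
    """Drop the nothospecies marker for identity comparisons.

    ``"× grandis"`` and ``"grandis"`` denote the same epithet for matching
    purposes; display strings keep the marker.
    """
    return epithet.replace(HYBRID_MARKER, "").strip()


@dataclass(frozen=True)
class NameRecord:
    """One published name: accepted or synonym.

    ``record_id`` is the stable database identifier (the "Kew ID" of a POWO
    record); ``uri`` locates the page the record was mined from.
    """

    genus: str
    epithet: str
    authorship: str = ""
    protologue: str = ""
    year: int | None = None
    status: str = ACCEPTED
    record_id: str = ""
    uri: str = ""

    @property
    def binomial(self) -> str:
        return f"{self.genus} {self.epithet}"

    @property
    def full_name(self) -> str:
        return f"{self.genus} {self.epithet} {self.authorship}".strip()

    def identity_key(self) -> tuple[str, str, str]:
        """(genus, epithet, authorship) triple; hybrid markers ignored,
        authorship case-sensitive (homonyms differ only by author)."""
        return (self.genus, strip_hybrid_marker(self.epithet), self.authorship)


def _as_frozenset(value) -> frozenset:
    return value if isinstance(value, frozenset) else frozenset(value or ())


@dataclass(frozen=True)
class Distribution:
    """Native and introduced ranges as sets of botanical-country names.

    ``is_unknown`` is the explicit flag POWO-style lists print as
    "unknown": it must hold exactly when no distribution information
    exists, i.e. both sets are empty.
    """

    native_botanical: frozenset = frozenset()
    introduced_botanical: frozenset = frozenset()
    is_unknown: bool = False

    def __post_init__(self):
        object.__setattr__(self, "native_botanical", _as_frozenset(self.native_botanical))
        object.__setattr__(self, "introduced_botanical", _as_frozenset(self.introduced_botanical))

    @classmethod
    def unknown(cls) -> "Distribution":
        return cls(is_unknown=True)

    @property
    def is_empty(self) -> bool:
        return not self.native_botanical and not self.introduced_botanical


@dataclass(frozen=True)
class SpeciesRecord:
    """An accepted species with its synonymy and distribution."""

    accepted: NameRecord
    synonyms: tuple = ()
    distribution: Distribution = field(default_factory=Distribution.unknown)
    family: str = ""

    def __post_init__(self):
        object.__setattr__(self, "synonyms", tuple(self.synonyms))

    @property
    def binomial(self) -> str:
        return self.accepted.binomial

    def homotypic_synonyms(self) -> tuple:
        return tuple(s for s in self.synonyms if s.status == HOMOTYPIC)

    def heterotypic_synonyms(self) -> tuple:
        return tuple(s for s in self.synonyms if s.status == HETEROTYPIC)


@dataclass(frozen=True)
class GenusSummary:
    """Genus-level row: name, authorship, protologue, accepted-species count."""

    genus: str
    authorship: str = ""
    protologue: str = ""
    species_count: int = 0
    record_id: str = ""
    uri: str = ""
    family: str = ""


def basionym_year(species: SpeciesRecord) -> int | None:
    """Year the species was first described, under any homotypic name.

    Minimum of the accepted name's year and all homotypic synonym years,
    ignoring unknowns; ``None`` when every candidate year is unknown.
    Heterotypic synonyms never participate: their types are different
    taxa that were merely sunk into this species later.
    """
    candidates = [species.accepted.year]
    candidates.extend(s.year for s in species.homotypic_synonyms())
    known = [y for y in candidates if y is not None]
    return min(known) if known else None


def _check_name(name: NameRecord, label: str, allowed_statuses, out: list[str]) -> None:
    if not name.genus:
        out.append(f"{label}: genus is empty")
    if not name.epithet:
        out.append(f"{label}: epithet is empty")
    if name.year is not None and not (NOMENCLATURE_START <= name.year <= current_year()):
        out.append(
            f"{label}: year {name.year} outside [{NOMENCLATURE_START}, {current_year()}]"
        )
    if name.status not in NAME_STATUSES:
        out.append(f"{label}: status {name.status!r} is not one of {sorted(NAME_STATUSES)}")
    elif name.status not in allowed_statuses:
        out.append(f"{label}: status {name.status!r} not allowed here")


def validate_species(record: SpeciesRecord) -> list[str]:
    """Check every domain invariant; return human-readable violations.

    Empty list means the record is well formed. Statuses outside the
    accepted/homotypic/heterotypic triple (POWO's "unplaced", "artificial
    hybrid", ...) are rejected with a named violation rather than coerced.
    """
    violations: list[str] = []
    _check_name(record.accepted, "accepted", {ACCEPTED}, violations)
    for i, syn in enumerate(record.synonyms):
        _check_name(syn, f"synonyms[{i}]", {HOMOTYPIC, HETEROTYPIC}, violations)
        if syn.identity_key() == record.accepted.identity_key():
            violations.append(
                f"synonyms[{i}]: duplicates the accepted name triple {syn.identity_key()}"
            )
    dist = record.distribution
    if dist.is_unknown != dist.is_empty:
        violations.append(
            "distribution: is_unknown must hold exactly when both the native and "
            f"introduced sets are empty (is_unknown={dist.is_unknown}, "
            f"native={sorted(dist.native_botanical)}, "
            f"introduced={sorted(dist.introduced_botanical)})"
        )
    return violations
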