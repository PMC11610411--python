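"""Botanical-country (TDWG WGSRPD level 3) to political-country conversion.

POWO records distributions in botanical countries — the level-3 units of
the World Geographical Scheme for Recording Plant Distributions. Some of
these coincide with political countries (Peru, Madagascar), many do not:
Borneo spans Brunei, Indonesia and Malaysia; Brazil is split into five
units; Mexico into six. Country-level conservation work needs the
political view, so every checklist this package produces carries both.

The mapping is a many-to-many table shipped as a CSV data file
(``data/botanical_countries.csv``) — a hand-compiled subset of the WGSRPD
level-3 scheme covering the regions the synthetic floras draw from; a
complete level-3 table in the same three-column format can be dropped in.
Lookups are insensitive to case, surrounding whitespace and diacritics
("Panamá" and "panama" both resolve), and an optional alias column admits
historical or variant names ("Burma" for Myanmar). Lookup failures are
data, not exceptions: unmatched names are reported in
``unresolved_regions`` with a logged warning.
"""

from __future__ import annotations

import csv
import logging
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .model import Distribution, SpeciesRecord

__all__ = [
    "RegionMapping",
    "RegionConversion",
    "CountryDistribution",
    "AnnotatedSpecies",
    "MappingSchemaError",
    "load_mapping",
    "bundled_mapping_path",
    "convert_regions",
    "attach_country_distribution",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("botanical_country", "political_country")


class MappingSchemaError(ValueError):
    """The mapping CSV lacks the required columns."""


def _norm(name: str) -> str:
    """Case-, whitespace- and diacritic-insensitive lookup key."""
    decomposed = unicodedata.normalize("NFKD", name)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return " ".join(stripped.casefold().split())


@dataclass
class RegionMapping:
    """Many-to-many botanical-country ↔ political-country table."""

    entries: frozenset  # of (botanical_country, political_country) pairs
    _lookup: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        lookup: dict[str, set[str]] = {}
        for botanical, country in self.entries:
            lookup.setdefault(_norm(botanical), set()).add(country)
        lookup.update(self._lookup)  # alias keys registered by load_mapping
        self._lookup = lookup

    def register_alias(self, alias: str, botanical: str) -> None:
        key = _norm(botanical)
        if key in self._lookup:
            self._lookup.setdefault(_norm(alias), set()).update(self._lookup[key])

    @property
    def botanical_countries(self) -> set[str]:
        return {b for b, _ in self.entries}

    @property
    def political_countries(self) -> set[str]:
        return {c for _, c in self.entries}

    def countries_for(self, botanical: str) -> set[str] | None:
        """Political countries for one botanical-country name, or None."""
        hit = self._lookup.get(_norm(botanical))
        return set(hit) if hit else None

    def knows_country(self, country: str) -> bool:
        return _norm(country) in {_norm(c) for c in self.political_countries}


@dataclass(frozen=True)
class RegionConversion:
    """Result of converting one botanical-country set to countries."""

    countries: frozenset = frozenset()
    unresolved: frozenset = frozenset()
    is_unknown: bool = False


@dataclass(frozen=True)
class CountryDistribution:
    """Country-level view of a species range, native and introduced."""

    native_countries: frozenset = frozenset()
    introduced_countries: frozenset = frozenset()
    unresolved_regions: frozenset = frozenset()
    is_unknown: bool = False


@dataclass(frozen=True)
class AnnotatedSpecies:
    """A species record plus its country-level distribution.

    The original botanical-country sets stay untouched on ``species``;
    the converted view sits alongside, so every exported list carries
    both levels.
    """

    species: SpeciesRecord
    countries: CountryDistribution

    @property
    def binomial(self) -> str:
        return self.species.binomial


def bundled_mapping_path() -> Path:
    return Path(resources.files("floramine.data") / "botanical_countries.csv")


def load_mapping(path: str | Path | None = None) -> RegionMapping:
    """Load a mapping CSV (header: botanical_country,political_country[,alias]).

    Defaults to the bundled table. Duplicate rows collapse; a missing
    required column raises :class:`MappingSchemaError`.
    """
    path = bundled_mapping_path() if path is None else Path(path)
    pairs: set[tuple[str, str]] = set()
    aliases: list[tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise MappingSchemaError(
                f"{path}: missing required column(s) {missing}; found header {header}"
            )
        n_rows = 0
        for row in reader:
            botanical = (row["botanical_country"] or "").strip()
            country = (row["political_country"] or "").strip()
            if not botanical or not country:
                continue
            pairs.add((botanical, country))
            n_rows += 1
            alias = (row.get("alias") or "").strip()
            if alias:
                aliases.append((alias, botanical))
    mapping = RegionMapping(entries=frozenset(pairs))
    for alias, botanical in aliases:
        mapping.register_alias(alias, botanical)
    logger.info(
        "loaded region mapping %s: %d rows, %d botanical countries, %d countries",
        path, n_rows, len(mapping.botanical_countries), len(mapping.political_countries),
    )
    return mapping


def convert_regions(botanical, mapping: RegionMapping) -> RegionConversion:
    """Convert a set of botanical-country names to political countries.

    The output is the union of mapped countries over all inputs; names
    that fail lookup land in ``unresolved`` (with a warning), and an empty
    input yields an empty result flagged unknown — mirroring how species
    with no distribution information are listed as "unknown".
    """
    names = set(botanical or ())
    if not names:
        return RegionConversion(is_unknown=True)
    countries: set[str] = set()
    unresolved: set[str] = set()
    for name in names:
        hit = mapping.countries_for(name)
        if hit is None:
            unresolved.add(name)
            logger.warning("botanical country %r not found in region mapping", name)
        else:
            countries.update(hit)
    return RegionConversion(
        countries=frozenset(countries), unresolved=frozenset(unresolved)
    )


def attach_country_distribution(
    record: SpeciesRecord, mapping: RegionMapping
) -> AnnotatedSpecies:
    """Annotate a species with its country-level distribution.

    Native and introduced sets are converted independently; the botanical
    sets on the record are preserved untouched.
    """
    dist: Distribution = record.distribution
    if dist.is_unknown:
        return AnnotatedSpecies(record, CountryDistribution(is_unknown=True))
    native = convert_regions(dist.native_botanical, mapping)
    introduced = convert_regions(dist.introduced_botanical, mapping)
    return AnnotatedSpecies(
        record,
        CountryDistribution(
            native_countries=native.countries,
            introduced_countries=introduced.countries,
            unresolved_regions=native.unresolved | introduced.unresolved,
        ),
    )
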