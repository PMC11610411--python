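"""Query, filter and export semantics over a mined checklist.

These are the workhorse operations a checklist user runs once the taxon
pages are crawled (or a ground-truth table is loaded): count the species
of a family, list the genera of a family with per-genus species counts,
list species with full distribution at both the botanical-country and
political-country levels, pull the distribution of a designated list of
species, select megadiverse genera above a threshold, select the topmost
species-rich genera, and save any of those as CSV.

Conventions:

* Only *accepted* species are ever counted; synonyms never contribute to
  richness or counts.
* A country constraint keeps a species if it occurs natively in ANY of
  the listed countries (introduced occurrences count only when
  ``include_introduced`` is set); distribution-based filtering happens at
  the political-country level, after botanical-country conversion.
* The megadiverse threshold is strict ("more than 500 species" in
  Frodin's sense): a genus with exactly the threshold count is excluded.
  Users wanting >= semantics can pass ``threshold - 1``.
* Top-N selection keeps every genus tied with the N-th count, so a tie
  is never broken arbitrarily; the result may be longer than N.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .geography import AnnotatedSpecies, RegionMapping, attach_country_distribution, load_mapping
from .model import GenusSummary, SpeciesRecord

__all__ = [
    "Checklist",
    "QueryFilter",
    "UnknownTaxonError",
    "UnknownCountryError",
    "family_species_count",
    "genus_list",
    "species_list",
    "species_distribution",
    "megadiverse_genera",
    "top_genera",
    "MEGADIVERSE_THRESHOLD",
    "DEFAULT_TOP_N",
    "species_rows",
    "genus_rows",
    "export_csv",
    "read_csv_rows",
    "SPECIES_COLUMNS",
    "GENUS_COLUMNS",
]

#: Default megadiverse cutoff — Frodin's review of large plant genera
#: used "more than 500 species", read strictly.
MEGADIVERSE_THRESHOLD = 500

#: Default size of the top-genera list. No canonical value exists; ten
#: keeps the output a readable league table. Override with ``n=``.
DEFAULT_TOP_N = 10


class UnknownTaxonError(KeyError):
    """A requested family/genus is absent from the checklist."""


class UnknownCountryError(KeyError):
    """A country constraint does not resolve against the region mapping."""


@dataclass(frozen=True)
class QueryFilter:
    """What to keep: taxa by name, and optionally by country of occurrence.

    At least one of ``families`` / ``genera`` / ``species`` should be set
    for a targeted query; all ``None`` means "everything". Country names
    must resolve against the checklist's region mapping.
    """

    families: tuple | None = None
    genera: tuple | None = None
    species: tuple | None = None  # binomials
    countries: tuple | None = None
    include_introduced: bool = False


class Checklist:
    """A mined checklist: species records plus the region mapping.

    ``genus_index`` (optional) carries genus-level metadata — authorship,
    protologue, identifiers — as parsed from genus pages; without it,
    genus rows are synthesised from the species records alone.
    ``family_names`` may add families known to exist but currently empty
    (e.g. all their names are synonymised elsewhere).
    """

    def __init__(
        self,
        species: list,
        mapping: RegionMapping | None = None,
        genus_index: list | None = None,
        family_names: list | None = None,
    ):
        self.species: list[SpeciesRecord] = list(species)
        self.mapping = mapping if mapping is not None else load_mapping()
        self.genus_index: list[GenusSummary] = list(genus_index or [])
        self._extra_families = set(family_names or [])
        self._annotated: list[AnnotatedSpecies] | None = None

    @property
    def families(self) -> set[str]:
        fams = {s.family for s in self.species if s.family}
        fams.update(g.family for g in self.genus_index if g.family)
        fams.update(self._extra_families)
        return fams

    @property
    def genera(self) -> set[str]:
        gens = {s.accepted.genus for s in self.species}
        gens.update(g.genus for g in self.genus_index)
        return gens

    @property
    def annotated(self) -> list:
        if self._annotated is None:
            self._annotated = [
                attach_country_distribution(s, self.mapping) for s in self.species
            ]
        return self._annotated

    def genus_summary(self, genus: str) -> GenusSummary | None:
        for g in self.genus_index:
            if g.genus == genus:
                return g
        return None


def _check_countries(checklist: Checklist, countries) -> None:
    for c in countries or ():
        if not checklist.mapping.knows_country(c):
            raise UnknownCountryError(
                f"country {c!r} does not resolve against the region mapping"
            )


def _passes_country(ann: AnnotatedSpecies, countries, include_introduced: bool) -> bool:
    if not countries:
        return True
    wanted = set(countries)
    if ann.countries.native_countries & wanted:
        return True
    return include_introduced and bool(ann.countries.introduced_countries & wanted)


def _matching(checklist: Checklist, f: QueryFilter) -> list:
    _check_countries(checklist, f.countries)
    out = []
    for ann in checklist.annotated:
        sp = ann.species
        if f.families is not None and sp.family not in f.families:
            continue
        if f.genera is not None and sp.accepted.genus not in f.genera:
            continue
        if f.species is not None and sp.binomial not in f.species:
            continue
        if not _passes_country(ann, f.countries, f.include_introduced):
            continue
        out.append(ann)
    return out


def family_species_count(checklist: Checklist, family: str) -> int:
    """Number of distinct accepted species in a family.

    Synonyms never count. A family wholly unknown to the checklist is a
    lookup error; a known family whose names are all synonymised
    elsewhere counts zero.
    """
    if family not in checklist.families:
        raise UnknownTaxonError(f"family {family!r} not present in this checklist")
    return len({s.binomial for s in checklist.species if s.family == family})


def genus_list(checklist: Checklist, qfilter: QueryFilter | None = None) -> list:
    """Genus-level rows with per-genus accepted-species counts.

    Under a country constraint, ``species_count`` counts only the species
    passing the constraint. Genus metadata (authorship, protologue,
    identifiers) is taken from the checklist's genus index when present.
    """
    f = qfilter or QueryFilter()
    matched = _matching(checklist, f)
    counts: dict[str, int] = {}
    genus_family: dict[str, str] = {}
    for ann in matched:
        g = ann.species.accepted.genus
        counts[g] = counts.get(g, 0) + 1
        genus_family[g] = ann.species.family
    # Genera known only from the index (e.g. all names synonymised away)
    # stay visible with a zero count — but a country constraint keeps the
    # list to genera that actually occur there.
    for g in checklist.genus_index:
        if f.countries:
            break
        if f.genera is not None and g.genus not in f.genera:
            continue
        if f.families is not None and g.family not in f.families:
            continue
        counts.setdefault(g.genus, 0)
        genus_family.setdefault(g.genus, g.family)
    rows = []
    for genus in sorted(counts):
        meta = checklist.genus_summary(genus)
        rows.append(
            GenusSummary(
                genus=genus,
                authorship=meta.authorship if meta else "",
                protologue=meta.protologue if meta else "",
                species_count=counts[genus],
                record_id=meta.record_id if meta else "",
                uri=meta.uri if meta else "",
                family=genus_family.get(genus, meta.family if meta else ""),
            )
        )
    return rows


def species_list(checklist: Checklist, qfilter: QueryFilter | None = None) -> list:
    """Annotated accepted-species rows for the requested taxa.

    Every row carries authorship, protologue, and native/introduced
    distribution at both the botanical-country and country levels;
    unknown-distribution species are included and flagged, never dropped.
    """
    return _matching(checklist, qfilter or QueryFilter())


def species_distribution(
    checklist: Checklist, binomials
) -> tuple[list, list[str]]:
    """Records for a designated list of binomials, plus the miss list.

    Binomials not found in the checklist are reported back, never
    silently dropped.
    """
    wanted = list(binomials)
    by_binomial = {ann.binomial: ann for ann in checklist.annotated}
    found = [by_binomial[b] for b in wanted if b in by_binomial]
    misses = [b for b in wanted if b not in by_binomial]
    return found, misses


def _genus_counts(checklist: Checklist, family: str | None) -> list:
    f = QueryFilter(families=(family,) if family else None)
    if family is not None and family not in checklist.families:
        raise UnknownTaxonError(f"family {family!r} not present in this checklist")
    return genus_list(checklist, f)


def megadiverse_genera(
    checklist: Checklist, family: str | None = None, threshold: int = MEGADIVERSE_THRESHOLD
) -> list:
    """Genera with strictly more than ``threshold`` accepted species,
    sorted by count descending (then genus name)."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    rows = [g for g in _genus_counts(checklist, family) if g.species_count > threshold]
    return sorted(rows, key=lambda g: (-g.species_count, g.genus))


def top_genera(
    checklist: Checklist, family: str | None = None, n: int = DEFAULT_TOP_N
) -> list:
    """The ``n`` most species-rich genera, keeping all ties with the
    n-th count (so the result may exceed ``n``); sorted by count
    descending, then genus name."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rows = sorted(_genus_counts(checklist, family), key=lambda g: (-g.species_count, g.genus))
    if len(rows) <= n:
        return rows
    cutoff = rows[n - 1].species_count
    return [g for g in rows if g.species_count >= cutoff]


# ---------------------------------------------------------------------------
# CSV export

SPECIES_COLUMNS = [
    "family", "genus", "species", "authorship", "protologue", "year",
    "native_botanical", "native_countries", "introduced_botanical",
    "introduced_countries", "record_id", "uri",
]

GENUS_COLUMNS = [
    "family", "genus", "authorship", "protologue", "species_count",
    "record_id", "uri",
]


def _join(values) -> str:
    return "|".join(sorted(values))


def species_rows(annotated) -> list[dict]:
    """Flatten annotated species into export dictionaries (all strings).

    Unknown distributions are printed as the literal ``unknown`` in the
    native botanical-country column, mirroring how the source database's
    lists mark them.
    """
    rows = []
    for ann in annotated:
        sp = ann.species
        unknown = sp.distribution.is_unknown
        rows.append(
            {
                "family": sp.family,
                "genus": sp.accepted.genus,
                "species": sp.accepted.epithet,
                "authorship": sp.accepted.authorship,
                "protologue": sp.accepted.protologue,
                "year": "" if sp.accepted.year is None else str(sp.accepted.year),
                "native_botanical": "unknown" if unknown else _join(sp.distribution.native_botanical),
                "native_countries": "unknown" if unknown else _join(ann.countries.native_countries),
                "introduced_botanical": "" if unknown else _join(sp.distribution.introduced_botanical),
                "introduced_countries": "" if unknown else _join(ann.countries.introduced_countries),
                "record_id": sp.accepted.record_id,
                "uri": sp.accepted.uri,
            }
        )
    return rows


def genus_rows(summaries) -> list[dict]:
    return [
        {
            "family": g.family,
            "genus": g.genus,
            "authorship": g.authorship,
            "protologue": g.protologue,
            "species_count": str(g.species_count),
            "record_id": g.record_id,
            "uri": g.uri,
        }
        for g in summaries
    ]


def export_csv(
    rows: list[dict], out_dir: str | Path, basename: str, columns: list[str] | None = None
) -> Path:
    """Write rows to ``out_dir/basename.csv`` (UTF-8, comma, header row).

    Creates the directory if absent. The column order is fixed: the
    given ``columns``, else the species schema when the rows match it,
    else the genus schema, else the first row's keys. Writing is
    dialect-stable: write → read → write is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{basename}.csv"
    if columns is None:
        if rows and set(rows[0]) == set(SPECIES_COLUMNS):
            columns = SPECIES_COLUMNS
        elif rows and set(rows[0]) == set(GENUS_COLUMNS):
            columns = GENUS_COLUMNS
        else:
            columns = list(rows[0].keys()) if rows else SPECIES_COLUMNS
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=columns, lineterminator="\n")
            writer.writeheader()
            writer.writerows(rows)
    except OSError as exc:
        raise OSError(f"could not write {path}: {exc}") from exc
    return path


def read_csv_rows(path: str | Path) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))
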