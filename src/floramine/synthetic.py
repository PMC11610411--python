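"""Synthetic floras with known ground truth, rendered as a static taxon site.

The live checklist service this package mines is a moving target: its
contents change between database versions and mining it requires a
network. For testing and development this module generates floras with
fully controlled statistical structure — family/genus/species counts,
synonymy load, homotypic fraction, publication-year window, distribution
regions, unknown-distribution rate — and renders them as a tree of static
HTML taxon pages in the same shape the miner parses (family page listing
genera, genus page listing species, species page with protologue,
synonymy and native/introduced botanical-country lists). Because the
generator knows the truth, crawl→parse→analyze can be checked exactly.

Everything is driven by a single seeded PRNG: the same spec and seed
always produce the same flora, byte for byte.

Nomenclatural realism the generator enforces:

* a homotypic synonym (the basionym lineage) is never published after the
  accepted name built on its type;
* (genus, epithet) pairs are unique across the whole flora, so round-trip
  comparisons are collision-free;
* protologue citations carry their year in one of the two citation styles
  the year parser understands (parenthesised, or trailing bare year).
"""

from __future__ import annotations

import csv
import html as _html
import random
from dataclasses import dataclass, field, replace
from pathlib import Path

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
    "CountRange",
    "SyntheticFloraSpec",
    "FamilySummary",
    "SiteManifest",
    "SyntheticFlora",
    "FloraConfigError",
    "generate_flora",
    "render_site",
    "export_ground_truth",
    "load_ground_truth",
    "demo_flora",
    "DIALECT",
    "GROUND_TRUTH_COLUMNS",
]

#: Markup dialect tag stamped into every generated page and the manifest.
DIALECT = "synthflora-1"

#: Botanical countries (WGSRPD level 3) the default generator draws from;
#: all resolve in the bundled region mapping.
DEFAULT_REGION_POOL = (
    "Borneo", "Peru", "Madagascar", "New Guinea", "Malaya", "Sumatera",
    "Jawa", "Philippines", "Thailand", "Vietnam", "India",
    "Brazil North", "Brazil Northeast", "Brazil Southeast", "Colombia",
    "Ecuador", "Mexico Central", "Mexico Southwest", "Tanzania",
    "Cape Provinces", "Queensland", "New South Wales",
    "China South-Central", "Cuba", "Hispaniola",
)

_SYLLABLES = (
    "an", "bel", "cor", "dra", "el", "fos", "gar", "hel", "ix", "jun",
    "kal", "lim", "mor", "nec", "oth", "pel", "qui", "ras", "sol", "tam",
    "ul", "vex", "wid", "xan", "yar", "zel",
)
_EPITHET_SUFFIXES = ("ensis", "ana", "oides", "iflora", "ifolia", "icola", "osa", "ata")
_AUTHORS = (
    "L.", "Sm.", "Benth.", "Hook.f.", "Mart.", "Kunth", "DC.", "A.Gray",
    "Baker", "Ridl.", "Merr.", "Standl.", "Harms", "Taub.",
)
_JOURNALS = (
    "Sp. Pl.", "Gen. Pl.", "Fl. Bras.", "Fl. Ind.", "Prodr.", "Ic. Pl.",
    "Bull. Misc. Inform. Kew", "J. Bot.", "Ann. Sci. Nat.", "Syst. Veg.",
)


class FloraConfigError(ValueError):
    """A synthetic-flora spec violates its own invariants."""


@dataclass(frozen=True)
class CountRange:
    """Inclusive uniform integer range."""

    lo: int
    hi: int

    def sample(self, rng: random.Random) -> int:
        return rng.randint(self.lo, self.hi)


@dataclass(frozen=True)
class SyntheticFloraSpec:
    n_families: int = 3
    genera_per_family: CountRange = CountRange(2, 6)
    species_per_genus: CountRange = CountRange(1, 15)
    synonyms_per_species: CountRange = CountRange(0, 4)
    homotypic_fraction: float = 0.4
    year_range: tuple[int, int] = (1753, 2022)
    region_pool: tuple[str, ...] = DEFAULT_REGION_POOL
    p_unknown_distribution: float = 0.05
    p_introduced: float = 0.2
    p_unknown_year: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_families < 1:
            problems.append("n_families must be >= 1")
        for label, rng_ in (
            ("genera_per_family", self.genera_per_family),
            ("species_per_genus", self.species_per_genus),
            ("synonyms_per_species", self.synonyms_per_species),
        ):
            if rng_.lo < 0 or rng_.hi < rng_.lo:
                problems.append(f"{label} must satisfy 0 <= lo <= hi, got {rng_}")
        for label, p in (
            ("homotypic_fraction", self.homotypic_fraction),
            ("p_unknown_distribution", self.p_unknown_distribution),
            ("p_introduced", self.p_introduced),
            ("p_unknown_year", self.p_unknown_year),
        ):
            if not 0.0 <= p <= 1.0:
                problems.append(f"{label} must lie in [0, 1], got {p}")
        lo, hi = self.year_range
        if not (1753 <= lo <= hi):
            problems.append(f"year_range must sit within [1753, now], got {self.year_range}")
        if not self.region_pool:
            problems.append("region_pool must be non-empty")
        if problems:
            raise FloraConfigError("; ".join(problems))


@dataclass(frozen=True)
class FamilySummary:
    family: str
    record_id: str
    uri: str


@dataclass(frozen=True)
class SiteManifest:
    """What :func:`render_site` wrote: one (taxon label, relative path)
    entry per taxon page, plus the site index and the markup dialect."""

    dialect: str
    entries: tuple  # of (label, relative path)
    index_path: str = "index.html"


@dataclass
class SyntheticFlora:
    species: list
    genus_index: list
    families: list
    site_manifest: SiteManifest | None = None

    @property
    def family_names(self) -> list[str]:
        return [f.family for f in self.families]

    def genera_of(self, family: str) -> list[GenusSummary]:
        return [g for g in self.genus_index if g.family == family]

    def species_of_genus(self, genus: str) -> list[SpeciesRecord]:
        return [s for s in self.species if s.accepted.genus == genus]


class _NameFactory:
    """Seeded unique name/citation synthesis."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self._used_genera: set[str] = set()
        self._used_binomials: set[tuple[str, str]] = set()
        self._next_id = 1

    def record_id(self, prefix: int) -> str:
        rid = f"{prefix}{self._next_id:07d}-1"
        self._next_id += 1
        return rid

    def genus_name(self) -> str:
        while True:
            n = self.rng.randint(2, 4)
            word = "".join(self.rng.choice(_SYLLABLES) for _ in range(n)).capitalize()
            if word not in self._used_genera:
                self._used_genera.add(word)
                return word

    def epithet(self, genus: str) -> str:
        while True:
            stem = "".join(self.rng.choice(_SYLLABLES) for _ in range(self.rng.randint(1, 3)))
            word = stem + self.rng.choice(_EPITHET_SUFFIXES)
            if (genus, word) not in self._used_binomials:
                self._used_binomials.add((genus, word))
                return word

    def authorship(self) -> str:
        if self.rng.random() < 0.2:
            a, b = self.rng.sample(_AUTHORS, 2)
            return f"{a} & {b}"
        return self.rng.choice(_AUTHORS)

    def protologue(self, year: int | None) -> str:
        journal = self.rng.choice(_JOURNALS)
        vol = self.rng.randint(1, 60)
        page = self.rng.randint(1, 899)
        if year is None:
            return f"{journal} {vol}: {page}"
        if self.rng.random() < 0.2:
            return f"{journal} {vol}: {page}. {year}"
        return f"{journal} {vol}: {page} ({year})"


def generate_flora(spec: SyntheticFloraSpec) -> SyntheticFlora:
    """Generate a ground-truth flora; deterministic for a fixed seed."""
    spec.validate()
    rng = random.Random(spec.seed)
    names = _NameFactory(rng)
    lo_year, hi_year = spec.year_range

    def maybe_year(year: int) -> int | None:
        return None if rng.random() < spec.p_unknown_year else year

    families: list[FamilySummary] = []
    genus_index: list[GenusSummary] = []
    all_species: list[SpeciesRecord] = []

    for _ in range(spec.n_families):
        fam_name = names.genus_name() + "aceae"
        fam_id = names.record_id(1)
        families.append(FamilySummary(fam_name, fam_id, f"taxon/{fam_id}.html"))
        for _ in range(spec.genera_per_family.sample(rng)):
            genus = names.genus_name()
            gen_id = names.record_id(2)
            gen_year = rng.randint(lo_year, hi_year)
            gen_species: list[SpeciesRecord] = []
            for _ in range(spec.species_per_genus.sample(rng)):
                accepted_year = rng.randint(lo_year, hi_year)
                sp_id = names.record_id(3)
                accepted = NameRecord(
                    genus=genus,
                    epithet=names.epithet(genus),
                    authorship=names.authorship(),
                    year=maybe_year(accepted_year),
                    status=ACCEPTED,
                    record_id=sp_id,
                    uri=f"taxon/{sp_id}.html",
                )
                accepted = replace(accepted, protologue=names.protologue(accepted.year))
                synonyms = []
                for _ in range(spec.synonyms_per_species.sample(rng)):
                    homotypic = rng.random() < spec.homotypic_fraction
                    syn_genus = (
                        genus if rng.random() < 0.5 else names.genus_name()
                    )
                    syn_year = (
                        rng.randint(lo_year, accepted_year)
                        if homotypic
                        else rng.randint(lo_year, hi_year)
                    )
                    syn_id = names.record_id(4)
                    syn = NameRecord(
                        genus=syn_genus,
                        epithet=names.epithet(syn_genus),
                        authorship=names.authorship(),
                        year=maybe_year(syn_year),
                        status=HOMOTYPIC if homotypic else HETEROTYPIC,
                        record_id=syn_id,
                        uri=f"taxon/{syn_id}.html",
                    )
                    synonyms.append(replace(syn, protologue=names.protologue(syn.year)))
                if rng.random() < spec.p_unknown_distribution:
                    dist = Distribution.unknown()
                else:
                    pool = list(spec.region_pool)
                    n_native = rng.randint(1, min(5, len(pool)))
                    native = rng.sample(pool, n_native)
                    introduced: list[str] = []
                    if rng.random() < spec.p_introduced:
                        rest = [r for r in pool if r not in native]
                        if rest:
                            introduced = rng.sample(rest, rng.randint(1, min(3, len(rest))))
                    dist = Distribution(frozenset(native), frozenset(introduced))
                gen_species.append(
                    SpeciesRecord(accepted, tuple(synonyms), dist, family=fam_name)
                )
            genus_index.append(
                GenusSummary(
                    genus=genus,
                    authorship=names.authorship(),
                    protologue=names.protologue(gen_year),
                    species_count=len(gen_species),
                    record_id=gen_id,
                    uri=f"taxon/{gen_id}.html",
                    family=fam_name,
                )
            )
            all_species.extend(gen_species)
    return SyntheticFlora(species=all_species, genus_index=genus_index, families=families)


# ---------------------------------------------------------------------------
# Static-site rendering


def _esc(text: str) -> str:
    return _html.escape(text, quote=True)


def _page(title: str, canonical: str, body: str) -> str:
    return (
        "<!DOCTYPE html>\n<html>\n<head>\n"
        '<meta charset="utf-8">\n'
        f'<meta name="site-dialect" content="{DIALECT}">\n'
        f'<link rel="canonical" href="/{_esc(canonical)}">\n'
        f"<title>{_esc(title)}</title>\n</head>\n<body>\n{body}\n</body>\n</html>\n"
    )


def _name_spans(name: NameRecord) -> str:
    return (
        f'<span class="genus">{_esc(name.genus)}</span> '
        f'<span class="epithet">{_esc(name.epithet)}</span> '
        f'<span class="authorship">{_esc(name.authorship)}</span>'
    )


def _species_page(sp: SpeciesRecord) -> str:
    a = sp.accepted
    parts = [
        f'<h1 class="accepted-name" data-rank="species" '
        f'data-record-id="{_esc(a.record_id)}" data-uri="{_esc(a.uri)}">'
        f"{_name_spans(a)}</h1>",
        f'<p class="classification">Family: <span class="family">{_esc(sp.family)}</span></p>',
        f'<div class="protologue">{_esc(a.protologue)}</div>',
    ]
    dist = sp.distribution
    if not dist.is_unknown:
        # The distribution section is omitted entirely for unknown species;
        # the parser turns its absence into the explicit "unknown" flag.
        sec = ['<section class="distribution">']
        if dist.native_botanical:
            items = "".join(
                f'<li class="region">{_esc(r)}</li>' for r in sorted(dist.native_botanical)
            )
            sec.append(f'<h2>Native to:</h2>\n<ul class="native">{items}</ul>')
        if dist.introduced_botanical:
            items = "".join(
                f'<li class="region">{_esc(r)}</li>'
                for r in sorted(dist.introduced_botanical)
            )
            sec.append(f'<h2>Introduced into:</h2>\n<ul class="introduced">{items}</ul>')
        sec.append("</section>")
        parts.append("\n".join(sec))
    if sp.synonyms:
        kind = {HOMOTYPIC: "homotypic", HETEROTYPIC: "heterotypic"}
        items = "".join(
            f'<li class="synonym {kind[s.status]}" data-record-id="{_esc(s.record_id)}" '
            f'data-uri="{_esc(s.uri)}">{_name_spans(s)}, '
            f'<span class="protologue">{_esc(s.protologue)}</span></li>'
            for s in sp.synonyms
        )
        parts.append(
            f'<section class="synonyms"><h2>Synonyms</h2>'
            f'<ul class="synonym-list">{items}</ul></section>'
        )
    return _page(sp.binomial, a.uri, "\n".join(parts))


def _genus_page(summary: GenusSummary, species: list) -> str:
    links = "".join(
        f'<li class="species-entry"><a href="{_esc(Path(sp.accepted.uri).name)}" '
        f'data-record-id="{_esc(sp.accepted.record_id)}" data-uri="{_esc(sp.accepted.uri)}">'
        f'<span class="genus">{_esc(sp.accepted.genus)}</span> '
        f'<span class="epithet">{_esc(sp.accepted.epithet)}</span></a></li>'
        for sp in species
    )
    body = "\n".join(
        [
            f'<h1 class="taxon-name" data-rank="genus" '
            f'data-record-id="{_esc(summary.record_id)}" data-uri="{_esc(summary.uri)}">'
            f'<span class="genus">{_esc(summary.genus)}</span> '
            f'<span class="authorship">{_esc(summary.authorship)}</span></h1>',
            f'<p class="classification">Family: <span class="family">{_esc(summary.family)}</span></p>',
            f'<div class="protologue">{_esc(summary.protologue)}</div>',
            f'<ul class="species-list">{links}</ul>',
        ]
    )
    return _page(summary.genus, summary.uri, body)


def _family_page(fam: FamilySummary, genera: list) -> str:
    links = "".join(
        f'<li class="genus-entry"><a href="{_esc(Path(g.uri).name)}" '
        f'data-record-id="{_esc(g.record_id)}" data-uri="{_esc(g.uri)}">'
        f'<span class="genus">{_esc(g.genus)}</span></a></li>'
        for g in genera
    )
    body = "\n".join(
        [
            f'<h1 class="taxon-name" data-rank="family" '
            f'data-record-id="{_esc(fam.record_id)}" data-uri="{_esc(fam.uri)}">'
            f"{_esc(fam.family)}</h1>",
            f'<ul class="genus-list">{links}</ul>',
        ]
    )
    return _page(fam.family, fam.uri, body)


def _index_page(families: list) -> str:
    links = "".join(
        f'<li class="family-entry"><a href="{_esc(f.uri)}" '
        f'data-record-id="{_esc(f.record_id)}" data-uri="{_esc(f.uri)}">'
        f'<span class="family">{_esc(f.family)}</span></a></li>'
        for f in families
    )
    return _page("Index", "index.html", f'<ul class="family-list">{links}</ul>')


def render_site(flora: SyntheticFlora, out_dir: str | Path) -> SiteManifest:
    """Render the flora as a static taxon site under ``out_dir``.

    One page per family, genus and species (under ``taxon/``), plus an
    ``index.html`` listing the families. Returns the manifest of taxon
    pages, which is also stored on ``flora.site_manifest``.
    """
    out = Path(out_dir)
    (out / "taxon").mkdir(parents=True, exist_ok=True)
    entries: list[tuple[str, str]] = []

    (out / "index.html").write_text(_index_page(flora.families), encoding="utf-8")
    for fam in flora.families:
        genera = flora.genera_of(fam.family)
        (out / fam.uri).write_text(_family_page(fam, genera), encoding="utf-8")
        entries.append((fam.family, fam.uri))
        for g in genera:
            species = flora.species_of_genus(g.genus)
            (out / g.uri).write_text(_genus_page(g, species), encoding="utf-8")
            entries.append((g.genus, g.uri))
            for sp in species:
                (out / sp.accepted.uri).write_text(_species_page(sp), encoding="utf-8")
                entries.append((sp.binomial, sp.accepted.uri))
    manifest = SiteManifest(dialect=DIALECT, entries=tuple(entries))
    flora.site_manifest = manifest
    return manifest


# ---------------------------------------------------------------------------
# Ground-truth CSV

GROUND_TRUTH_COLUMNS = [
    "family", "genus", "epithet", "authorship", "protologue", "year",
    "status", "record_id", "uri", "accepted_record_id",
    "native_botanical", "introduced_botanical", "is_unknown",
]


def _name_row(name: NameRecord, family: str, accepted_id: str, dist: Distribution | None) -> dict:
    return {
        "family": family,
        "genus": name.genus,
        "epithet": name.epithet,
        "authorship": name.authorship,
        "protologue": name.protologue,
        "year": "" if name.year is None else str(name.year),
        "status": name.status,
        "record_id": name.record_id,
        "uri": name.uri,
        "accepted_record_id": accepted_id,
        "native_botanical": "|".join(sorted(dist.native_botanical)) if dist else "",
        "introduced_botanical": "|".join(sorted(dist.introduced_botanical)) if dist else "",
        "is_unknown": ("true" if dist.is_unknown else "false") if dist else "",
    }


def export_ground_truth(flora: SyntheticFlora, path: str | Path) -> Path:
    """Write one CSV row per published name (accepted and synonyms).

    Multi-valued cells are '|'-joined; synonym rows point at their
    accepted name through ``accepted_record_id``. Reading the file back
    with :func:`load_ground_truth` reproduces the species list exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=GROUND_TRUTH_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for sp in flora.species:
            writer.writerow(
                _name_row(sp.accepted, sp.family, sp.accepted.record_id, sp.distribution)
            )
            for syn in sp.synonyms:
                writer.writerow(_name_row(syn, sp.family, sp.accepted.record_id, None))
    return path


def _row_name(row: dict) -> NameRecord:
    return NameRecord(
        genus=row["genus"],
        epithet=row["epithet"],
        authorship=row["authorship"],
        protologue=row["protologue"],
        year=int(row["year"]) if row["year"] else None,
        status=row["status"],
        record_id=row["record_id"],
        uri=row["uri"],
    )


def load_ground_truth(path: str | Path) -> list[SpeciesRecord]:
    """Rebuild the species list from a ground-truth CSV."""
    species: list[SpeciesRecord] = []
    current: dict | None = None

    def flush():
        if current is not None:
            species.append(
                SpeciesRecord(
                    accepted=current["accepted"],
                    synonyms=tuple(current["synonyms"]),
                    distribution=current["distribution"],
                    family=current["family"],
                )
            )

    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            name = _row_name(row)
            if name.status == ACCEPTED:
                flush()
                if row["is_unknown"] == "true":
                    dist = Distribution.unknown()
                else:
                    dist = Distribution(
                        frozenset(filter(None, row["native_botanical"].split("|"))),
                        frozenset(filter(None, row["introduced_botanical"].split("|"))),
                    )
                current = {
                    "accepted": name,
                    "synonyms": [],
                    "distribution": dist,
                    "family": row["family"],
                }
            else:
                if current is None:
                    raise ValueError(f"{path}: synonym row before any accepted row")
                current["synonyms"].append(name)
    flush()
    return species


# ---------------------------------------------------------------------------
# A tiny fixed flora used throughout the documentation and tests.


def demo_flora() -> SyntheticFlora:
    """Four-species demonstration flora (1 family, 2 genera).

    *Alpha unus* L. 1753 (native Borneo); *Alpha duo* Benth. 1850 with a
    homotypic synonym from 1801, so its basionym year is 1801 (native
    Peru); *Alpha tres* Hook.f. 1820 with no distribution information
    (unknown); *Beta quattuor* (Sm.) Mart. 1900 (native Borneo and Peru,
    introduced Madagascar) with one heterotypic synonym from 1880.
    """
    fam = FamilySummary("Demoaceae", "10000001-1", "taxon/10000001-1.html")

    def nm(genus, epithet, auth, proto, year, status, rid):
        return NameRecord(genus, epithet, auth, proto, year, status, rid, f"taxon/{rid}.html")

    unus = SpeciesRecord(
        nm("Alpha", "unus", "L.", "Sp. Pl.: 1042 (1753)", 1753, ACCEPTED, "30000001-1"),
        (),
        Distribution(frozenset({"Borneo"})),
        family="Demoaceae",
    )
    duo = SpeciesRecord(
        nm("Alpha", "duo", "Benth.", "Fl. Demo. 3: 44 (1850)", 1850, ACCEPTED, "30000002-1"),
        (
            nm("Primus", "duo", "Sm.", "Syn. Fl. 1: 12 (1801)", 1801, HOMOTYPIC, "40000001-1"),
        ),
        Distribution(frozenset({"Peru"})),
        family="Demoaceae",
    )
    tres = SpeciesRecord(
        nm("Alpha", "tres", "Hook.f.", "Ic. Pl. 9: 801 (1820)", 1820, ACCEPTED, "30000003-1"),
        (),
        Distribution.unknown(),
        family="Demoaceae",
    )
    quattuor = SpeciesRecord(
        nm("Beta", "quattuor", "(Sm.) Mart.", "Fl. Demo. 12: 209 (1900)", 1900, ACCEPTED, "30000004-1"),
        (
            nm("Gamma", "quattuor", "Sm.", "J. Bot. 18: 33 (1880)", 1880, HETEROTYPIC, "40000002-1"),
        ),
        Distribution(frozenset({"Borneo", "Peru"}), frozenset({"Madagascar"})),
        family="Demoaceae",
    )
    genus_index = [
        GenusSummary("Alpha", "L.", "Gen. Pl. 5: 101 (1754)", 3,
                     "20000001-1", "taxon/20000001-1.html", "Demoaceae"),
        GenusSummary("Beta", "Sm.", "Gen. Nov. 2: 14 (1810)", 1,
                     "20000002-1", "taxon/20000002-1.html", "Demoaceae"),
    ]
    return SyntheticFlora(
        species=[unus, duo, tres, quattuor],
        genus_index=genus_index,
        families=[fam],
    )
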