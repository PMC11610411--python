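# Methods notes

## The data model and its nomenclatural assumptions

A checklist is a list of *accepted* species; each carries its synonymy
(homotypic or heterotypic) and a distribution over TDWG level-3
botanical countries, split into native and introduced. Only accepted
names ever contribute to counts, richness or curves; synonyms exist to
date nomenclatural history.

Publication years are parsed from protologue citation strings with a
two-step rule: the first parenthesised four-digit year wins (the modern
Kew citation style, `"Sp. Pl.: 1042 (1753)"`), else the last bare
four-digit token (older styles, `"Fl. Bras. 2(2): 44. 1877"`). Only
years in **[1753, current year]** are accepted — 1753 is the starting
point of binomial nomenclature, and later years can only be data errors
— anything else maps to *unknown*, never an exception. The rule is
idempotent under re-serialisation (render a year into a citation
template, re-parse, get the same year), which is property-tested.

The **basionym year** of a species is the minimum over the accepted
name's year and all *homotypic* synonym years (unknowns ignored).
Homotypic synonyms share the accepted name's type, so the earliest of
them is the original description; heterotypic synonyms are based on
different types — taxa merely sunk into this species later — and never
participate. This single rule drives the dual discovery curves.

Statuses outside {accepted, homotypic_synonym, heterotypic_synonym}
(a live database also has "unplaced" and "artificial hybrid" entries)
are rejected by validation with a named violation rather than coerced:
silently reclassifying them would bias counts invisibly. Hybrid markers
("×") are ignored for name identity but preserved for display. Name
identity is the (genus, epithet, authorship) triple with case-sensitive
authorship, because homonyms differ only by author. Infraspecific names
are out of the model: every output is species-level.

## The synthetic-flora generator

The generator emulates what the miner faces on the live service: a
hierarchy of taxon pages with authorship, protologue citations in two
styles, homotypic/heterotypic synonym lists, native/introduced region
lists, and species whose distribution section is simply absent. Its
defaults define the study conditions used throughout the tests:

| parameter | default | why |
|---|---|---|
| n_families | 3 | enough hierarchy to exercise grouping without slowing tests |
| genera_per_family | U[2, 6] | small-family shape typical of focused checklists |
| species_per_genus | U[1, 15] | right-skewed genus sizes in miniature |
| synonyms_per_species | U[0, 4] | median ~2 synonyms per accepted name, a realistic synonymy load |
| homotypic_fraction | 0.4 | recombinations are common but a minority of synonymy |
| year_range | [1753, 2022] | the valid nomenclatural window the discovery curves span |
| p_unknown_distribution | 0.05 | a few percent of names lack distribution data |
| p_introduced | 0.2 | a minority of species have documented introduced ranges |
| p_unknown_year | 0.03 | occasional citations without a parseable year |

Two constraints are enforced by construction rather than sampled: a
homotypic synonym's year never exceeds its accepted name's year (a
basionym precedes its recombination — this is what makes the
basionym-curve dominance a theorem rather than a tendency), and
(genus, epithet) pairs are unique across the flora so round-trip
comparisons are collision-free. All randomness flows from one seeded
PRNG; the same spec and seed give identical floras and identical pages.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: markup drift across database versions
(pages are stamped with a dialect tag, and the parser refuses unknown
dialects instead of guessing), incomplete or malformed live markup,
names with nonstandard citation formats, infraspecific page structure,
and the true heavy-tailed genus-size distribution (a synthetic "genus"
tops out at tens of species, not thousands).

## Mining: politeness, retries, checkpoints

The pause rule is modular: after every `requests_per_pause`-th request
(default 500) the fetcher sleeps `pause_seconds` (default 300), so total
pause time after *n* requests is `floor(n/500) × 300 s`. The counter is
cumulative across resumes (it is persisted in the checkpoint) and
retries increment it, since a retry is still a server hit. Transient
failures retry up to 3 times with doubling backoff (1 s, 2 s, 4 s);
a missing page is a resolution error and is not retried. The clock is
injected, so all of this is tested in milliseconds.

Checkpoints are JSON-lines files — header, one line per
completed/pending/failed taxon, and a trailing SHA-256 of the body —
written to a temp file and renamed into place after *every* completed
taxon. A species record is yielded only after its completion is on
disk, so interruption at any point, followed by a resume, produces
exactly the uninterrupted record multiset with zero duplicate fetches;
the tests sweep the interruption point across the whole schedule. A
corrupt checkpoint (bad hash, truncation, unknown record kind) refuses
to load with a named defect rather than silently restarting.

## Geography

The bundled mapping is a hand-compiled subset of the WGSRPD level-3
scheme (~100 rows, ~45 botanical countries) written for this package;
it covers every region the default generator uses and is documented as
a subset — a complete level-3 table in the same
`botanical_country,political_country[,alias]` format can be dropped in.
Conversion is a union over per-region lookups, which makes it a
homomorphism over set union (property-tested). Lookups normalise case,
surrounding whitespace and diacritics; the alias column admits
historical names ("Burma"). Unmatched names are reported as data
(`unresolved_regions`, with a warning), never raised: a species list
with one unmappable region should still convert the rest. Disputed
territories keep the table's plain country names; the package does no
geopolitical adjudication, and no level-1/2 continental aggregation is
attempted.

## Query semantics

* Megadiverse cutoff is **strict** (`count > 500` by default), reading
  "more than 500 species" literally; users wanting ≥ semantics pass
  `threshold − 1`. Documented on the CLI flag as well.
* Top-N keeps every genus tied with the N-th count (the result may
  exceed N): truncating a tie alphabetically would misrepresent
  richness ranks. Default N = 10 — there is no canonical value; it is a
  league-table size, surfaced prominently in the CLI help.
* A country constraint means native occurrence in **any** of the listed
  countries ("all" semantics would make multi-country queries nearly
  empty and cannot be expressed by repeated single-country queries);
  introduced occurrences count only under `include_introduced`, because
  richness maps conventionally show native distributions.
* Unknown-distribution species are always included and flagged
  (exported as the literal `unknown`), and excluded-but-reported in
  richness tables (`unknown_count`): silently dropping them would
  misstate totals.

## Richness and discovery analytics

Richness counts **distinct species per region**: a species native to
three regions adds one to each. This yields the incidence identity
Σ_regions counts = Σ_species |regions(species)|, asserted exactly at
both geographic levels on every run.

Accumulation curves report cumulative counts at each observed year;
species with unknown basis-year are excluded and tallied, so final
count + unknown tally = total species (endpoint conservation). Curves
are drawn as step functions from 1753 regardless of the earliest datum,
so panels across taxa align.

The "violin" view of nomenclatural change is a presentation of the
normative change table (accepted year × synonym years × kinds, exported
as a sidecar CSV): the table is the tested artifact, the kernel-density
rendering is cosmetic. Every renderer writes its plot data as a CSV
sidecar, making graphical claims testable without pixel comparisons;
palettes default to the perceptually uniform, colour-vision-deficiency-
safe viridis family.

## Problem sizes and numerics

Test and acceptance runs use 20 seeded floras of roughly 50–400 species
(3 families, 3–6 genera each, 4–12 species per genus) for round-trip
checks, an 8–10 page flora for the exhaustive interruption sweep, and a
roughly 200-species flora for invariant measurement — sizes chosen so
the full pipeline (render, crawl, parse, convert, analyse) runs in
seconds while still exercising every statistical branch (unknown
distributions, unknown years, both synonym kinds, both citation
styles). All comparisons in the oracle tests are exact set/sequence
equality; nothing is tolerance-based except the generator's
unknown-fraction convergence check (binomial noise at n ≈ 800).

## Known limitations

* The parser supports exactly the documented markup dialect; pointing
  it at the live service requires adding a dialect entry with that
  site's selectors.
* The bundled region table is a subset; conversions for regions outside
  it are reported unresolved rather than guessed.
* Genus metadata (authorship, protologue) comes from genus pages seen
  during the crawl; resuming a crawl whose genus pages completed in an
  earlier run yields species records but not those genera's metadata.
* No fuzzy matching of user-supplied names; misspelled binomials are
  reported as misses.
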